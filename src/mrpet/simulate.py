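"""Synthetic whole-body tracer subjects with known ground truth.

Every downstream stage (washout fitting, test-retest statistics,
biodistribution accounting, dosimetry) is exercised on data generated here,
so each generated quantity carries an exactly known truth:

* tissue TACs rise to an early peak (half-sine ramp) and then wash out
  mono-exponentially at a tissue-specific elimination rate k_E, so the
  log-linear estimator's assumption holds exactly in the noiseless limit;
* venous plasma follows a bi-exponential; whole blood is plasma divided by
  a saturating plasma-to-blood ratio pinned to 1.51 at 10 min and 1.59 at
  90 min;
* plasma radio-species fractions keep the parent tracer at a ~30% plateau
  while the glutathione conjugate falls from 63% (5 min) to 38% (40 min),
  the unidentified lipophilic species taking up the remainder;
* cumulative excretion saturates at exactly 55 %ID (urinary bladder) and
  2.7 %ID (gall bladder) at the 90-min scan end;
* noise, when enabled, is zero-mean Gaussian with variance proportional to
  model / (frame duration x physical decay factor), the usual dynamic-PET
  count-statistics heuristic, from one seeded stream per subject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .biodistribution import DEFAULT_SPECIES_WINDOWS, ExcretionSample, HplcFractionSet
from .kinetics import TimeActivityCurve
from .nuclides import C11, Nuclide, decay_factor
from .schedule import FrameSchedule, default_schedule

__all__ = [
    "TissueKineticParams",
    "SubjectParams",
    "SubjectDataset",
    "TISSUE_DEFAULTS",
    "BLOOD_SAMPLE_TIMES_MIN",
    "SPECIES_SAMPLE_TIMES_MIN",
    "peak_suv_for_auc",
    "default_tissue_params",
    "default_subject_params",
    "simulate_tissue_tac",
    "simulate_blood_plasma",
    "simulate_species_fractions",
    "simulate_excretion",
    "simulate_hplc_fractions",
    "simulate_subject",
    "simulate_cohort",
]

#: venous sampling scheme, minutes post injection
BLOOD_SAMPLE_TIMES_MIN: tuple[float, ...] = (5, 10, 20, 30, 40, 60, 90)
#: plasma metabolite (HPLC) sampling scheme
SPECIES_SAMPLE_TIMES_MIN: tuple[float, ...] = (5, 20, 40)

#: Per-tissue study-condition defaults.  k_E values (1/h) are the cohort
#: means of the study population (overall and per sex, with SDs); peak
#: times are all before the 15-min start of the washout window.  For the
#: two brain regions the peak SUV is solved from the measured 0-90 min
#: area under the curve; elsewhere it is a plausible magnitude.
TISSUE_DEFAULTS: dict[str, dict] = {
    "cerebral_cortex": dict(k_E=0.055, k_E_M=0.057, sd_M=0.009, k_E_F=0.051,
                            sd_F=0.011, peak_time=5.0, auc_0_90=192.0),
    "cerebellum": dict(k_E=0.033, k_E_M=0.038, sd_M=0.006, k_E_F=0.027,
                       sd_F=0.008, peak_time=5.0, auc_0_90=265.0),
    "choroid_plexus": dict(k_E=0.292, k_E_M=0.298, sd_M=0.040, k_E_F=0.284,
                           sd_F=0.079, peak_time=5.0, peak_suv=2.5),
    "retina": dict(k_E=0.234, k_E_M=0.230, sd_M=0.059, k_E_F=0.240,
                   sd_F=0.025, peak_time=5.0, peak_suv=1.5),
    "right_lung": dict(k_E=0.875, k_E_M=0.928, sd_M=0.075, k_E_F=0.813,
                       sd_F=0.080, peak_time=3.0, peak_suv=3.0),
    "myocardium": dict(k_E=0.641, k_E_M=0.606, sd_M=0.108, k_E_F=0.682,
                       sd_F=0.093, peak_time=3.0, peak_suv=2.5),
    "right_kidney_cortex": dict(k_E=1.378, k_E_M=1.238, sd_M=0.261, k_E_F=1.542,
                                sd_F=0.166, peak_time=3.0, peak_suv=8.0),
    "liver": dict(k_E=0.685, k_E_M=0.675, sd_M=0.069, k_E_F=0.698,
                  sd_F=0.081, peak_time=4.0, peak_suv=4.0),
}


@dataclass(frozen=True)
class TissueKineticParams:
    """Ground-truth washout kinetics for one tissue."""

    tissue: str
    peak_suv: float
    peak_time_min: float
    k_E_true_per_h: float

    def __post_init__(self) -> None:
        if self.peak_suv <= 0:
            raise ValueError("peak SUV must be positive")
        if not 0 < self.peak_time_min < 15:
            raise ValueError("peak time must lie in (0, 15) min so the "
                             "15-90 min window is pure washout")
        if self.k_E_true_per_h < 0:
            raise ValueError("k_E cannot be negative")


def _model_value(p: TissueKineticParams, t_min: np.ndarray) -> np.ndarray:
    """Noiseless decay-corrected model SUV at arbitrary times (minutes)."""
    t = np.asarray(t_min, float)
    k_per_min = p.k_E_true_per_h / 60.0
    ramp = p.peak_suv * np.sin(0.5 * np.pi * np.clip(t, 0, p.peak_time_min) / p.peak_time_min)
    wash = p.peak_suv * np.exp(-k_per_min * np.maximum(t - p.peak_time_min, 0.0))
    return np.where(t <= p.peak_time_min, ramp, wash)


def _model_integral(p: TissueKineticParams, t0: float, t1: float) -> float:
    """Exact integral of the model over [t0, t1] (SUV*min)."""
    tp, peak = p.peak_time_min, p.peak_suv
    k = p.k_E_true_per_h / 60.0
    total = 0.0
    a, b = max(t0, 0.0), min(t1, tp)
    if b > a:  # half-sine ramp segment
        w = 0.5 * math.pi / tp
        total += peak / w * (math.cos(w * a) - math.cos(w * b))
    a, b = max(t0, tp), t1
    if b > a:  # exponential washout segment
        if k > 0:
            total += peak / k * (math.exp(-k * (a - tp)) - math.exp(-k * (b - tp)))
        else:
            total += peak * (b - a)
    return total


def peak_suv_for_auc(
    k_E_per_h: float, peak_time_min: float, auc_suv_min: float, t_end_min: float = 90.0
) -> float:
    """Peak SUV making the model's exact 0..t_end area equal ``auc_suv_min``."""
    probe = TissueKineticParams("_probe", 1.0, peak_time_min, k_E_per_h)
    unit_area = _model_integral(probe, 0.0, t_end_min)
    return auc_suv_min / unit_area


def default_tissue_params(sex: str | None = None) -> list[TissueKineticParams]:
    """The eight study tissues at their default (or sex-specific mean) k_E."""
    out = []
    for tissue, d in TISSUE_DEFAULTS.items():
        k_E = d["k_E"] if sex is None else d[f"k_E_{sex}"]
        peak = d.get("peak_suv")
        if peak is None:
            peak = peak_suv_for_auc(k_E, d["peak_time"], d["auc_0_90"])
        out.append(TissueKineticParams(tissue, peak, d["peak_time"], k_E))
    return out


@dataclass(frozen=True)
class SubjectParams:
    """Complete ground truth for one synthetic subject."""

    subject_id: str
    sex: str
    weight_kg: float
    injected_mbq: float
    tissue_params: tuple[TissueKineticParams, ...]
    # plasma bi-exponential (decay-corrected SUV)
    plasma_a1_suv: float = 14.0
    plasma_lambda1_per_min: float = 0.45
    plasma_a2_suv: float = 1.6
    plasma_lambda2_per_min: float = 0.004
    # plasma-to-blood ratio anchors and saturating-exponential rate
    ratio_10min: float = 1.51
    ratio_90min: float = 1.59
    ratio_rate_per_min: float = 0.03
    # plasma radio-species model
    parent_fraction: float = 0.30
    conjugate_frac_5min: float = 0.63
    conjugate_frac_40min: float = 0.38
    # cumulative excretion at scan end (fractions of injected activity)
    urinary_frac_90: float = 0.55
    biliary_frac_90: float = 0.027
    urinary_rate_per_min: float = 0.025
    biliary_rate_per_min: float = 0.02
    noise_scale: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if self.weight_kg <= 0 or self.injected_mbq <= 0:
            raise ValueError("weight and injected activity must be positive")
        for f in (self.parent_fraction, self.conjugate_frac_5min,
                  self.conjugate_frac_40min, self.urinary_frac_90, self.biliary_frac_90):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.urinary_frac_90 + self.biliary_frac_90 >= 1:
            raise ValueError("total excreted fraction must stay below 1")
        if min(self.ratio_10min, self.ratio_90min) < 1:
            raise ValueError("plasma-to-blood ratios below 1 are not physical here")
        if self.noise_scale < 0:
            raise ValueError("noise_scale cannot be negative")


def default_subject_params(
    subject_id: str = "sim01",
    sex: str = "M",
    seed: int = 0,
    noise_scale: float = 0.02,
    sex_specific_kE: bool = False,
) -> SubjectParams:
    """A default subject at the study-condition parameter values."""
    weight = 78.0 if sex == "M" else 66.0
    return SubjectParams(
        subject_id=subject_id,
        sex=sex,
        weight_kg=weight,
        injected_mbq=368.0,
        tissue_params=tuple(default_tissue_params(sex if sex_specific_kE else None)),
        noise_scale=noise_scale,
        seed=seed,
    )


def simulate_tissue_tac(
    p: TissueKineticParams,
    schedule: FrameSchedule,
    nuclide: Nuclide = C11,
    noise_scale: float = 0.0,
    rng: np.random.Generator | int | None = None,
    sampling: str = "frame_average",
) -> TimeActivityCurve:
    """Simulate one decay-corrected tissue TAC on a frame schedule.

    ``sampling="frame_average"`` (the physical case) emits the exact time
    average of the model over each frame; ``"midpoint"`` evaluates the model
    at frame midpoints (useful for bias-free estimator checks).  Noise is
    zero-mean Gaussian with SD ``noise_scale * sqrt(model / (duration_min *
    decay_factor(midpoint)))``; negative noisy values are clipped to zero.
    """
    mids = schedule.midpoints_min
    if sampling == "midpoint":
        values = _model_value(p, mids)
    elif sampling == "frame_average":
        starts = schedule.frame_starts_min
        durs = schedule.frame_durations_min
        values = np.array(
            [_model_integral(p, s, s + d) / d for s, d in zip(starts, durs)]
        )
    else:
        raise ValueError("sampling must be 'frame_average' or 'midpoint'")
    if noise_scale > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        df = np.array([decay_factor(nuclide, t) for t in mids])
        sd = noise_scale * np.sqrt(values / (schedule.frame_durations_min * df))
        values = np.clip(values + gen.normal(0.0, 1.0, values.size) * sd, 0.0, None)
    return TimeActivityCurve.from_schedule(p.tissue, schedule, values)


def _ratio_model(p: SubjectParams, t_min: np.ndarray) -> np.ndarray:
    """Saturating-exponential plasma-to-blood ratio through the two anchors."""
    k = p.ratio_rate_per_min
    e10, e90 = math.exp(-10 * k), math.exp(-90 * k)
    amp = (p.ratio_90min - p.ratio_10min) / (e10 - e90)
    r_inf = p.ratio_90min + amp * e90
    return r_inf - amp * np.exp(-k * np.asarray(t_min, float))


def simulate_blood_plasma(
    p: SubjectParams, times_min: tuple[float, ...] = BLOOD_SAMPLE_TIMES_MIN
) -> pd.DataFrame:
    """Paired decay-corrected venous plasma and whole-blood curves (SUV).

    Plasma follows the subject's bi-exponential; blood = plasma / ratio(t),
    where ratio(t) saturates monotonically through the 10-min and 90-min
    anchor values exactly.
    """
    t = np.asarray(times_min, float)
    plasma = (p.plasma_a1_suv * np.exp(-p.plasma_lambda1_per_min * t)
              + p.plasma_a2_suv * np.exp(-p.plasma_lambda2_per_min * t))
    ratio = _ratio_model(p, t)
    return pd.DataFrame(
        {"time_min": t, "plasma_suv": plasma, "blood_suv": plasma / ratio}
    )


def simulate_species_fractions(
    p: SubjectParams, times_min: tuple[float, ...] = SPECIES_SAMPLE_TIMES_MIN
) -> pd.DataFrame:
    """Plasma radio-species fractions (parent, conjugate, other) over time.

    The parent tracer sits at a constant plateau; the glutathione conjugate
    declines linearly in log-time through its 5- and 40-min anchors; the
    unidentified species is the complement.  Fractions sum to 1 exactly.
    """
    t = np.asarray(times_min, float)
    if np.any(t <= 0):
        raise ValueError("species sampling times must be positive")
    slope = (p.conjugate_frac_40min - p.conjugate_frac_5min) / math.log(40.0 / 5.0)
    conjugate = p.conjugate_frac_5min + slope * np.log(t / 5.0)
    parent = np.full_like(t, p.parent_fraction)
    other = 1.0 - parent - conjugate
    if np.any(other < -1e-12) or np.any(conjugate < 0):
        raise ValueError(
            "species model leaves a negative remainder at some requested time; "
            "fractions must stay within [0, 1]"
        )
    return pd.DataFrame(
        {"time_min": t, "parent": parent, "conjugate": conjugate,
         "other": np.clip(other, 0.0, None)}
    )


def simulate_excretion(
    p: SubjectParams,
    schedule: FrameSchedule | None = None,
    times_min: np.ndarray | None = None,
) -> pd.DataFrame:
    """Cumulative excreted activity (%ID) for bladder and gall bladder.

    Saturating curves F (1 - exp(-k t)) with F chosen so the value at the
    90-min scan end equals the configured fraction exactly.  Sampled on the
    schedule's frame-boundary grid unless explicit times are given.
    """
    if times_min is None:
        schedule = schedule if schedule is not None else default_schedule()
        times_min = schedule.boundaries_min
    t = np.asarray(times_min, float)

    def _cum(frac_90: float, rate: float) -> np.ndarray:
        plateau = frac_90 / (1.0 - math.exp(-rate * 90.0))
        return 100.0 * plateau * (1.0 - np.exp(-rate * t))

    return pd.DataFrame(
        {
            "time_min": t,
            "bladder_pct_id": _cum(p.urinary_frac_90, p.urinary_rate_per_min),
            "gallbladder_pct_id": _cum(p.biliary_frac_90, p.biliary_rate_per_min),
        }
    )


def simulate_hplc_fractions(
    p: SubjectParams,
    sample_time_min: float,
    nuclide: Nuclide = C11,
    total_corrected_counts: float = 1e6,
    hplc_start_min: float | None = None,
) -> HplcFractionSet:
    """Synthetic gamma-counted HPLC 1-min fractions for one plasma sample.

    Counts are split across the species retention windows according to the
    subject's species-fraction model at ``sample_time_min`` (the "other"
    species elutes after the parent), then physically decayed to each
    fraction's count time — the inverse of what ``species_percentages``
    computes.
    """
    fr = simulate_species_fractions(p, (sample_time_min,)).iloc[0]
    if hplc_start_min is None:
        hplc_start_min = sample_time_min + 10.0
    retention = np.arange(0.5, 14.5, 1.0)  # 14 one-minute fractions
    count_times = hplc_start_min + retention  # counted as they elute
    corrected = np.zeros_like(retention)

    def _window_mask(lo: float, hi: float) -> np.ndarray:
        return (retention >= lo) & (retention < hi)

    conj = _window_mask(*DEFAULT_SPECIES_WINDOWS["conjugate"])
    par = _window_mask(*DEFAULT_SPECIES_WINDOWS["parent"])
    late = retention >= DEFAULT_SPECIES_WINDOWS["parent"][1]
    corrected[conj] = total_corrected_counts * fr["conjugate"] / conj.sum()
    corrected[par] = total_corrected_counts * fr["parent"] / par.sum()
    corrected[late] = total_corrected_counts * fr["other"] / late.sum()
    measured = corrected * np.exp(-nuclide.decay_constant_per_min * count_times)
    return HplcFractionSet(sample_time_min, retention, measured, count_times)


@dataclass(frozen=True)
class SubjectDataset:
    """All generated curves and samples for one scan of one subject."""

    schedule: FrameSchedule
    params: SubjectParams
    tacs: dict[str, TimeActivityCurve]
    blood: pd.DataFrame
    species: pd.DataFrame
    excretion: pd.DataFrame
    urine_sample: ExcretionSample | None = None
    occasion: str = "test"

    def __post_init__(self) -> None:
        for tac in self.tacs.values():
            if np.any(tac.values < 0):
                raise ValueError("TAC values cannot be negative")
        sums = self.species[["parent", "conjugate", "other"]].sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("species fractions must sum to 1 before noise")


def simulate_subject(
    params: SubjectParams,
    schedule: FrameSchedule | None = None,
    nuclide: Nuclide = C11,
    occasion: str = "test",
    urine_measurement_cv: float = 0.08,
) -> SubjectDataset:
    """Generate a complete dataset for one subject scan.

    One seeded random stream per subject drives TAC noise and the urine
    aliquot measurement error; with ``params.noise_scale == 0`` the whole
    dataset is noiseless and every configured value is hit exactly.
    """
    schedule = schedule if schedule is not None else default_schedule()
    rng = np.random.default_rng(params.seed)
    tacs = {
        tp.tissue: simulate_tissue_tac(tp, schedule, nuclide, params.noise_scale, rng)
        for tp in params.tissue_params
    }
    excretion = simulate_excretion(params, schedule)
    # urine aliquot counted shortly after the scan; measurement error only
    # when noise is enabled
    err = rng.normal(0.0, urine_measurement_cv) if params.noise_scale > 0 else 0.0
    measured_frac = params.urinary_frac_90 * max(1.0 + err, 0.0)
    volume_ml = 250.0
    count_time = 95.0
    conc_corrected = measured_frac * params.injected_mbq * 1000.0 / volume_ml
    urine = ExcretionSample(
        concentration_kbq_per_ml=conc_corrected * decay_factor(nuclide, count_time),
        volume_ml=volume_ml,
        injected_mbq=params.injected_mbq,
        count_time_min=count_time,
    )
    return SubjectDataset(
        schedule=schedule,
        params=params,
        tacs=tacs,
        blood=simulate_blood_plasma(params),
        species=simulate_species_fractions(params),
        excretion=excretion,
        urine_sample=urine,
        occasion=occasion,
    )


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean log-normal multiplier with coefficient of variation ``cv``."""
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(-0.5 * sigma * sigma, sigma))


def simulate_cohort(
    n_male: int = 7,
    n_female: int = 6,
    n_retest_male: int = 3,
    n_retest_female: int = 3,
    between_subject_cv: float = 0.15,
    noise_scale: float = 0.02,
    seed: int = 0,
    schedule: FrameSchedule | None = None,
    nuclide: Nuclide = C11,
) -> list[SubjectDataset]:
    """Simulate a study cohort with optional retest scans.

    Per-subject k_E values are drawn log-normally (unit-mean multiplier with
    the given CV) around the sex-specific default means; retest subjects get
    a second dataset with identical ground truth but a fresh noise stream.
    Fully reproducible from ``seed``.
    """
    if min(n_male, n_female, n_retest_male, n_retest_female) < 0:
        raise ValueError("cohort counts cannot be negative")
    if n_retest_male > n_male or n_retest_female > n_female:
        raise ValueError("cannot retest more subjects than were scanned")
    master = np.random.default_rng(seed)
    datasets: list[SubjectDataset] = []
    idx = 0
    for sex, n_sub, n_retest in (("M", n_male, n_retest_male),
                                 ("F", n_female, n_retest_female)):
        for i in range(n_sub):
            idx += 1
            sub_seed = int(master.integers(0, 2**31 - 1))
            base_weight = 78.0 if sex == "M" else 66.0
            weight = max(40.0, base_weight + master.normal(0.0, 8.0)) \
                if between_subject_cv > 0 else base_weight
            injected = max(200.0, 368.0 + master.normal(0.0, 18.0)) \
                if between_subject_cv > 0 else 368.0
            tissue_params = tuple(
                replace(tp, k_E_true_per_h=tp.k_E_true_per_h
                        * _lognormal_factor(master, between_subject_cv))
                for tp in default_tissue_params(sex)
            )
            params = SubjectParams(
                subject_id=f"sub{idx:02d}",
                sex=sex,
                weight_kg=weight,
                injected_mbq=injected,
                tissue_params=tissue_params,
                noise_scale=noise_scale,
                seed=sub_seed,
            )
            datasets.append(simulate_subject(params, schedule, nuclide, "test"))
            if i < n_retest:
                retest_seed = int(master.integers(0, 2**31 - 1))
                retest_params = replace(
                    params,
                    seed=retest_seed if noise_scale > 0 else sub_seed,
                )
                datasets.append(
                    simulate_subject(retest_params, schedule, nuclide, "retest")
                )
    return datasets
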