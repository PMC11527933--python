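"""End-to-end orchestration: simulate -> kinetics -> statistics -> dosimetry.

One :class:`RunConfig` drives a fully deterministic run that emits the five
report tables (``ke_results.tsv``, ``trtv_report.tsv``,
``sex_comparison.tsv``, ``biodistribution_report.tsv``,
``dose_report.tsv``), a run manifest and a per-stage log.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from . import dosimetry, io
from .biodistribution import percent_injected, plasma_to_blood
from .kinetics import batch_kE, summarize_kE
from .nuclides import C11, Nuclide, decay_factor
from .reproducibility import sex_comparison_table, trtv_table
from .schedule import default_schedule
from .simulate import SubjectDataset, simulate_cohort

__all__ = [
    "RunConfig",
    "ORGAN_VOLUMES_ML",
    "subject_source_curves",
    "biodistribution_report",
    "subject_dose",
    "dose_report_table",
    "run_pipeline",
    "make_fixtures",
]

logger = logging.getLogger("mrpet")

#: nominal effective source-region volumes (ml) used to convert SUV curves
#: to whole-organ activity; synthetic plumbing values, not phantom masses
ORGAN_VOLUMES_ML: dict[str, tuple[str, float]] = {
    # source region -> (tissue TAC to draw from, effective volume)
    "kidneys": ("right_kidney_cortex", 280.0),
    "liver": ("liver", 1700.0),
    "lungs": ("right_lung", 900.0),
}


class RunConfig(BaseModel):
    """Validated configuration for one pipeline run; unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_male: int = 7
    n_female: int = 6
    n_retest_male: int = 3
    n_retest_female: int = 3
    noise_scale: float = 0.02
    between_subject_cv: float = 0.15
    window_min: tuple[float, float] = (15.0, 90.0)
    schedule: Literal["extended", "literal"] = "extended"
    svalue_file: str | None = None
    weights_file: str | None = None
    outdir: str = "mrpet_out"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.n_male + self.n_female < 1:
            raise ValueError("cohort must contain at least one subject")
        if min(self.n_male, self.n_female, self.n_retest_male, self.n_retest_female) < 0:
            raise ValueError("cohort counts cannot be negative")
        if self.noise_scale < 0 or self.between_subject_cv < 0:
            raise ValueError("noise and CV levels cannot be negative")
        if not self.window_min[0] < self.window_min[1]:
            raise ValueError("fit window must satisfy t_lo < t_hi")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml(self, path: str | Path) -> Path:
        import yaml

        path = Path(path)
        path.write_text(yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True))
        return path


def subject_source_curves(
    ds: SubjectDataset, nuclide: Nuclide = C11,
    organ_volumes: dict[str, tuple[str, float]] | None = None,
) -> dict[str, dosimetry.SourceRegionCurve]:
    """Physical source-region activity curves (MBq) for one subject.

    Organ curves come from the decay-corrected SUV TACs converted with the
    subject's weight, injected activity and a nominal organ volume, then
    multiplied by the physical decay factor; bladder and gall-bladder
    curves come from the cumulative %ID excretion model.
    """
    organ_volumes = organ_volumes if organ_volumes is not None else ORGAN_VOLUMES_ML
    p = ds.params
    curves: dict[str, dosimetry.SourceRegionCurve] = {}
    for region, (tissue, volume_ml) in organ_volumes.items():
        if tissue not in ds.tacs:
            continue
        tac = ds.tacs[tissue]
        conc_kbq_ml = tac.values * p.injected_mbq / p.weight_kg  # SUV -> kBq/ml
        a_corr_mbq = conc_kbq_ml * volume_ml / 1000.0
        df = np.array([decay_factor(nuclide, t) for t in tac.times_min])
        curves[region] = dosimetry.SourceRegionCurve(
            region, tac.times_min, a_corr_mbq * df, p.injected_mbq
        )
    exc = ds.excretion
    t = exc["time_min"].to_numpy(float)
    df = np.exp(-nuclide.decay_constant_per_min * t)
    for region, col in (("urinary_bladder", "bladder_pct_id"),
                        ("gall_bladder", "gallbladder_pct_id")):
        frac = exc[col].to_numpy(float) / 100.0
        curves[region] = dosimetry.SourceRegionCurve(
            region, t[t > 0], (frac * p.injected_mbq * df)[t > 0], p.injected_mbq
        )
    return curves


def biodistribution_report(datasets: list[SubjectDataset],
                           nuclide: Nuclide = C11) -> pd.DataFrame:
    """Per-scan blood/plasma/excretion accounting table."""
    rows = []
    for ds in datasets:
        ratios = plasma_to_blood(ds.blood)
        exc = ds.excretion
        end = exc.iloc[-1]
        row = {
            "subject": ds.params.subject_id,
            "sex": ds.params.sex,
            "occasion": ds.occasion,
            "plasma_to_blood_10min": float(ratios.loc[10.0]),
            "plasma_to_blood_90min": float(ratios.loc[90.0]),
            "bladder_pct_id_90min_voi": float(end["bladder_pct_id"]),
            "gallbladder_pct_id_90min_voi": float(end["gallbladder_pct_id"]),
        }
        for _, sp in ds.species.iterrows():
            t = int(sp["time_min"])
            row[f"parent_pct_{t}min"] = 100.0 * sp["parent"]
            row[f"conjugate_pct_{t}min"] = 100.0 * sp["conjugate"]
        if ds.urine_sample is not None:
            row["urine_pct_id_sample"] = percent_injected(ds.urine_sample, nuclide)
        rows.append(row)
    return pd.DataFrame(rows)


def subject_dose(
    ds: SubjectDataset,
    svalues_by_phantom: dict[str, dosimetry.SValueMatrix],
    weights: dict[str, float],
    target_map: dict[str, str],
    nuclide: Nuclide = C11,
) -> dosimetry.DoseReport:
    """Residence times -> organ doses -> effective dose for one subject."""
    phantom = "adult_male" if ds.params.sex == "M" else "adult_female"
    curves = subject_source_curves(ds, nuclide)
    rts = dosimetry.ResidenceTimeSet.from_sources(curves, nuclide)
    report = dosimetry.organ_doses(rts, svalues_by_phantom[phantom])
    e = dosimetry.effective_dose(report, weights, target_map)
    return dosimetry.DoseReport(report.organ_doses_ugy_per_mbq, phantom, e)


def dose_report_table(datasets: list[SubjectDataset],
                      svalue_file: str | None = None,
                      weights_file: str | None = None,
                      nuclide: Nuclide = C11) -> pd.DataFrame:
    """Cohort dose table: per-organ mean +/- SD by sex, effective dose last."""
    svalues = {
        ph: dosimetry.load_svalue_matrix(svalue_file, ph)
        for ph in ("adult_male", "adult_female")
    }
    weights, target_map = dosimetry.load_tissue_weights(weights_file)
    per_subject: dict[str, list[dosimetry.DoseReport]] = {"M": [], "F": []}
    for ds in datasets:
        if ds.occasion != "test":
            continue
        per_subject[ds.params.sex].append(
            subject_dose(ds, svalues, weights, target_map, nuclide)
        )
    organs = list(next(iter(svalues.values())).targets)
    rows = []
    for organ in organs:
        row = {"quantity": f"{organ}_ugy_per_mbq"}
        for sex in ("M", "F"):
            vals = [r.organ_doses_ugy_per_mbq[organ] for r in per_subject[sex]]
            row[f"mean_{sex}"] = float(np.mean(vals)) if vals else np.nan
            row[f"sd_{sex}"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    row = {"quantity": "effective_dose_usv_per_mbq"}
    for sex in ("M", "F"):
        vals = [r.effective_dose_usv_per_mbq for r in per_subject[sex]]
        row[f"mean_{sex}"] = float(np.mean(vals)) if vals else np.nan
        row[f"sd_{sex}"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    rows.append(row)
    return pd.DataFrame(rows)


_REPORT_FILES = (
    "ke_results.tsv",
    "trtv_report.tsv",
    "sex_comparison.tsv",
    "biodistribution_report.tsv",
    "dose_report.tsv",
)


def run_pipeline(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every stage deterministically and write the report bundle.

    Any stage error aborts with a stage-tagged message and removes the
    partial report files.  Returns the report tables keyed by file stem.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    timings: dict[str, float] = {}
    results: dict[str, pd.DataFrame] = {}
    stage = "setup"

    def _run(name: str, fn):
        nonlocal stage
        stage = name
        t0 = time.perf_counter()
        out = fn()
        timings[name] = round(time.perf_counter() - t0, 4)
        logger.info("[%s] done in %.2f s", name, timings[name])
        return out

    try:
        schedule = default_schedule(extended=cfg.schedule == "extended")
        datasets = _run(
            "simulate",
            lambda: simulate_cohort(
                cfg.n_male, cfg.n_female, cfg.n_retest_male, cfg.n_retest_female,
                cfg.between_subject_cv, cfg.noise_scale, cfg.seed, schedule,
            ),
        )
        ke = _run("fit-ke", lambda: batch_kE(datasets, window_min=cfg.window_min))
        results["ke_results"] = ke
        results["trtv_report"] = _run("trtv", lambda: trtv_table(ke))
        results["sex_comparison"] = _run("sex-comparison",
                                         lambda: sex_comparison_table(ke))
        results["biodistribution_report"] = _run(
            "biodist", lambda: biodistribution_report(datasets)
        )
        results["dose_report"] = _run(
            "dose", lambda: dose_report_table(datasets, cfg.svalue_file,
                                              cfg.weights_file)
        )
        stage = "write-reports"
        for stem, df in results.items():
            written.append(io.write_table(df, outdir / f"{stem}.tsv"))
        stage = "manifest"
        cfg_json = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
        manifest = {
            "config": cfg.model_dump(mode="json"),
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": cfg.seed,
            "n_datasets": len(datasets),
            "versions": {
                "mrpet": _package_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        written.append(outdir / "manifest.json")
        log_lines = [f"{name}\t{dt:.4f} s" for name, dt in timings.items()]
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return results


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("mrpet")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def make_fixtures(outdir: str | Path, seed: int = 0) -> Path:
    """Write the test/doc fixture bundle.

    One noiseless cohort (CV 0, noise 0 — every configured value exact),
    one noisy default cohort, plus copies of the synthetic S-value matrix
    and the tissue-weight table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    noiseless = simulate_cohort(2, 2, 1, 1, between_subject_cv=0.0,
                                noise_scale=0.0, seed=seed)
    io.write_cohort(noiseless, outdir / "cohort_noiseless")
    noisy = simulate_cohort(2, 2, 1, 1, seed=seed)
    io.write_cohort(noisy, outdir / "cohort_noisy")
    from importlib import resources

    for name in ("svalues_synthetic.csv", "tissue_weights_icrp103.yaml"):
        (outdir / name).write_text(
            resources.files("mrpet.data").joinpath(name).read_text()
        )
    return outdir
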