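"""Organ-level internal dosimetry by the MIRD schema.

The chain is: source-region activity curves (MBq, physical, i.e. NOT
decay-corrected) -> time-integrated activity per unit injected activity
(residence times, hours) -> rest-of-body allocation so the residence-time
budget closes at 1/lambda -> absorbed organ doses via an S-value matrix
(dose per unit time-integrated activity, phantom-specific) -> effective
dose as the ICRP tissue-weighted sum.

Integration uses the convention standard in clinical dosimetry: the
decay-corrected curve is interpolated linearly between measured points
(activity assumed zero at injection when the first sample is later) and
the physical decay factor is integrated analytically within each segment;
after the last measured point the region is assumed to hold its activity
subject to physical decay only, contributing the analytic tail
A(t_last)/lambda.  This is exact whenever the decay-corrected curve is
piecewise linear — in particular for the pure-decay closed-form cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .nuclides import Nuclide

__all__ = [
    "SourceRegionCurve",
    "ResidenceTimeSet",
    "SValueMatrix",
    "DoseReport",
    "residence_time",
    "rest_of_body",
    "organ_doses",
    "effective_dose",
    "dose_for_administration",
    "load_svalue_matrix",
    "load_tissue_weights",
]


@dataclass(frozen=True)
class SourceRegionCurve:
    """Physical (not decay-corrected) activity of one source region."""

    region: str
    times_min: np.ndarray
    activity_mbq: np.ndarray
    injected_mbq: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, float)
        a = np.asarray(self.activity_mbq, float)
        if t.shape != a.shape or t.ndim != 1 or t.size == 0:
            raise ValueError("times and activities must be matching 1-d arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if t[0] < 0:
            raise ValueError("times cannot precede injection")
        if np.any(a < 0):
            raise ValueError("activity cannot be negative")
        if self.injected_mbq <= 0:
            raise ValueError("injected activity must be positive")
        if np.any(a > self.injected_mbq * (1 + 1e-9)):
            raise ValueError("region cannot hold more than the injected activity")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "activity_mbq", a)


def _segment_integral(lam: float, t0: float, t1: float, c0: float, c1: float) -> float:
    """Integral of (linear decay-corrected activity) * exp(-lam t) on [t0, t1]."""
    h = t1 - t0
    e0, e1 = math.exp(-lam * t0), math.exp(-lam * t1)
    i_const = (e0 - e1) / lam
    i_ramp = -(h * e1) / lam + (e0 - e1) / lam**2
    return c0 * i_const + (c1 - c0) / h * i_ramp


def residence_time(c: SourceRegionCurve, nuclide: Nuclide) -> float:
    """Time-integrated activity coefficient (residence time) in hours.

    Integrates the measured points to the last sample (leading implicit
    zero at injection when the curve starts later), then adds the physical-
    decay-only tail A(t_last)/lambda, and normalises by the injected
    activity.
    """
    lam = nuclide.decay_constant_per_min
    t = c.times_min
    # decay-corrected activity at the measured points
    corr = c.activity_mbq * np.exp(lam * t)
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        corr = np.concatenate([[0.0], corr])
    integral_min = sum(
        _segment_integral(lam, t[i], t[i + 1], corr[i], corr[i + 1])
        for i in range(t.size - 1)
    )
    tail_min = c.activity_mbq[-1] / lam  # physical decay from the last sample
    return (integral_min + tail_min) / c.injected_mbq / 60.0


def rest_of_body(taus_h: dict[str, float], nuclide: Nuclide) -> tuple[float, float]:
    """Rest-of-body residence time (hours) and the sampled share.

    The total residence-time budget for any nuclide is 1/lambda (the whole
    injected activity must decay somewhere); the rest of body receives the
    part not assigned to sampled organs.  Returns ``(rest_tau_h,
    sampled_share)``; a sampled sum exceeding the physical total signals
    inconsistent inputs and raises.
    """
    total_h = 1.0 / nuclide.decay_constant_per_h
    sampled = float(sum(taus_h.values()))
    if any(v < 0 for v in taus_h.values()):
        raise ValueError("residence times cannot be negative")
    if sampled > total_h * (1 + 1e-9):
        raise ValueError(
            f"sampled residence times ({sampled:.4f} h) exceed the physical "
            f"total 1/lambda = {total_h:.4f} h"
        )
    return total_h - sampled, sampled / total_h


@dataclass(frozen=True)
class ResidenceTimeSet:
    """Per-source residence times plus the rest-of-body remainder (hours)."""

    taus_h: dict[str, float]
    rest_of_body_tau_h: float
    nuclide: Nuclide

    def __post_init__(self) -> None:
        total = sum(self.taus_h.values()) + self.rest_of_body_tau_h
        expected = 1.0 / self.nuclide.decay_constant_per_h
        if abs(total - expected) > 1e-9 * expected:
            raise ValueError(
                "residence times (sampled + rest of body) must sum to 1/lambda"
            )

    @classmethod
    def from_sources(
        cls, curves: dict[str, SourceRegionCurve], nuclide: Nuclide
    ) -> "ResidenceTimeSet":
        taus = {name: residence_time(c, nuclide) for name, c in curves.items()}
        rest, _ = rest_of_body(taus, nuclide)
        return cls(taus, rest, nuclide)

    @property
    def sampled_share(self) -> float:
        total = 1.0 / self.nuclide.decay_constant_per_h
        return sum(self.taus_h.values()) / total


@dataclass(frozen=True)
class SValueMatrix:
    """Target x source matrix of S values in mGy/(MBq*s) for one phantom."""

    table: pd.DataFrame  # index: targets, columns: sources
    phantom: str

    def __post_init__(self) -> None:
        if self.table.isna().any().any():
            raise ValueError("S-value matrix must be rectangular and complete")
        if (self.table.to_numpy() < 0).any():
            raise ValueError("S values cannot be negative")
        for region in self.table.columns:
            if region in self.table.index and self.table.loc[region, region] <= 0:
                raise ValueError(f"missing self-dose entry for {region!r}")

    @property
    def targets(self) -> list[str]:
        return list(self.table.index)

    @property
    def sources(self) -> list[str]:
        return list(self.table.columns)

    @classmethod
    def from_csv(cls, path: str | Path, phantom: str) -> "SValueMatrix":
        """Read a long-format CSV: target, source, S_mGy_per_MBq_s, phantom."""
        df = pd.read_csv(path)
        required = {"target", "source", "S_mGy_per_MBq_s", "phantom"}
        if not required.issubset(df.columns):
            raise ValueError(f"S-value CSV needs columns {sorted(required)}")
        sub = df[df["phantom"] == phantom]
        if sub.empty:
            raise ValueError(f"phantom {phantom!r} not present in {path}")
        table = sub.pivot(index="target", columns="source", values="S_mGy_per_MBq_s")
        return cls(table, phantom)


@dataclass(frozen=True)
class DoseReport:
    """Absorbed organ doses (uGy/MBq) and optional effective dose (uSv/MBq)."""

    organ_doses_ugy_per_mbq: dict[str, float]
    phantom: str
    effective_dose_usv_per_mbq: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"organ": organ, "dose_ugy_per_mbq": dose}
            for organ, dose in self.organ_doses_ugy_per_mbq.items()
        ]
        df = pd.DataFrame(rows)
        if self.effective_dose_usv_per_mbq is not None:
            df = pd.concat(
                [df, pd.DataFrame([{"organ": "effective_dose_usv_per_mbq",
                                    "dose_ugy_per_mbq": self.effective_dose_usv_per_mbq}])],
                ignore_index=True,
            )
        df.insert(0, "phantom", self.phantom)
        return df


def organ_doses(
    r: ResidenceTimeSet, s: SValueMatrix, rest_of_body_region: str = "rest_of_body"
) -> DoseReport:
    """Absorbed dose per target: sum over sources of tau * S.

    tau is converted from hours to seconds; S carries mGy/(MBq*s); the
    result is reported in uGy/MBq.
    """
    taus = dict(r.taus_h)
    taus[rest_of_body_region] = r.rest_of_body_tau_h
    missing = [name for name in taus if name not in s.sources]
    if missing:
        raise KeyError(
            f"source region(s) {missing} have no column in the S-value matrix "
            f"(phantom {s.phantom!r})"
        )
    doses = {}
    for target in s.targets:
        dose_mgy = sum(
            tau * 3600.0 * float(s.table.loc[target, src]) for src, tau in taus.items()
        )
        doses[target] = dose_mgy * 1000.0
    return DoseReport(doses, s.phantom)


def effective_dose(
    d: DoseReport,
    weights: dict[str, float],
    target_map: dict[str, str] | None = None,
    rest_of_body_region: str = "rest_of_body",
) -> float:
    """ICRP effective dose in uSv/MBq from a per-organ dose report.

    Each weighted tissue resolves to an organ dose directly, through
    ``target_map``, or — when the phantom's dose report carries no entry for
    it — to the rest-of-body surrogate dose.  With radiation weighting 1
    for photons and positrons, uGy/MBq and uSv/MBq coincide numerically.
    Weights must sum to 1 within 1e-6.
    """
    wsum = sum(weights.values())
    if abs(wsum - 1.0) > 1e-6:
        raise ValueError(f"tissue weighting factors must sum to 1, got {wsum}")
    target_map = target_map or {}
    organ = d.organ_doses_ugy_per_mbq
    total = 0.0
    for tissue, w in weights.items():
        name = target_map.get(tissue, tissue)
        dose = organ.get(name)
        if dose is None:
            dose = organ.get(rest_of_body_region)
            if dose is None:
                raise KeyError(
                    f"tissue {tissue!r} resolves to no organ dose and the report "
                    f"has no {rest_of_body_region!r} surrogate"
                )
        total += w * dose
    return total


def dose_for_administration(e_usv_per_mbq: float, injected_mbq: float) -> float:
    """Effective dose in mSv for an administered activity (full precision).

    Report layers round the value to two decimals for display.
    """
    if e_usv_per_mbq < 0 or injected_mbq < 0:
        raise ValueError("inputs cannot be negative")
    return e_usv_per_mbq * injected_mbq / 1000.0


def _data_path(name: str):
    return resources.files("mrpet.data").joinpath(name)


def load_svalue_matrix(path: str | Path | None = None, phantom: str = "adult_male") -> SValueMatrix:
    """Load an S-value matrix CSV; defaults to the packaged synthetic fixture.

    The packaged matrix is a six-region synthetic stand-in (self-dose
    dominant, symmetric cross terms, a rest-of-body remainder column), not
    ICRP reference-phantom data; supply a real matrix for actual dosimetry.
    """
    if path is None:
        with resources.as_file(_data_path("svalues_synthetic.csv")) as p:
            return SValueMatrix.from_csv(p, phantom)
    return SValueMatrix.from_csv(path, phantom)


def load_tissue_weights(path: str | Path | None = None) -> tuple[dict[str, float], dict[str, str]]:
    """Load ICRP 103 tissue weighting factors and the tissue-to-organ map.

    Returns ``(weights, target_map)``; tissues absent from ``target_map``
    and from the dose report fall back to the rest-of-body surrogate.
    """
    if path is None:
        with resources.as_file(_data_path("tissue_weights_icrp103.yaml")) as p:
            raw = yaml.safe_load(p.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    return dict(raw["weights"]), dict(raw.get("target_map", {}))
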