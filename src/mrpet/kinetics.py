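"""Tissue washout kinetics: the elimination rate constant k_E.

The outcome measure of the analysis is k_E, the fraction of radioactivity
eliminated from a tissue per unit time (1/h).  Because the tracer's
glutathione conjugate is cleared from tissue by MRP transporters, the
late-scan washout of a decay-corrected tissue time-activity curve (TAC) is
mono-exponential and k_E is the negative slope of ln(SUV) against time over
the 15-90 min window, obtained by ordinary least squares.  k_E is a
model-free washout slope; it is not the compartmental efflux constant k2,
which would require an arterial input function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .nuclides import Nuclide
from .schedule import FrameSchedule

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import SubjectDataset

__all__ = [
    "TimeActivityCurve",
    "WashoutModel",
    "WashoutResults",
    "KEResult",
    "estimate_kE",
    "kE_decay_consistency",
    "auc_trapezoid",
    "batch_kE",
    "summarize_kE",
    "DEFAULT_WINDOW_MIN",
]

#: fitting window in minutes post injection, half-open on frame midpoints
DEFAULT_WINDOW_MIN: tuple[float, float] = (15.0, 90.0)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Activity concentration (SUV) of one region over the scan.

    Normally built from a :class:`FrameSchedule` (sample times are frame
    midpoints); :meth:`from_samples` builds a curve on an arbitrary time
    grid, e.g. for blood samples or fine model evaluations.
    """

    tissue: str
    times_min: np.ndarray
    values: np.ndarray
    decay_corrected: bool = True
    schedule: FrameSchedule | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "values", v)

    @classmethod
    def from_schedule(
        cls,
        tissue: str,
        schedule: FrameSchedule,
        values: np.ndarray,
        decay_corrected: bool = True,
    ) -> "TimeActivityCurve":
        values = np.asarray(values, dtype=float)
        if values.size != schedule.n_frames:
            raise ValueError("value count must match frame count")
        return cls(tissue, schedule.midpoints_min, values, decay_corrected, schedule)

    @classmethod
    def from_samples(
        cls, tissue: str, times_min: Sequence[float], values: Sequence[float],
        decay_corrected: bool = True,
    ) -> "TimeActivityCurve":
        return cls(tissue, np.asarray(times_min, float), np.asarray(values, float),
                   decay_corrected)

    def __len__(self) -> int:
        return int(self.times_min.size)

    def scaled(self, factor: float) -> "TimeActivityCurve":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return TimeActivityCurve(self.tissue, self.times_min, self.values * factor,
                                 self.decay_corrected, self.schedule)


@dataclass(frozen=True)
class WashoutResults:
    """Fitted log-linear washout: point estimates, uncertainty, diagnostics.

    ``k_E_per_h`` is the negative slope of ln(SUV) vs time in hours.  A
    rising curve gives a negative k_E, returned as-is with
    ``negative_slope_flag`` set.  A perfectly flat curve has k_E = 0 and
    r_squared defined as 1 (a perfect fit with no variance to explain).
    """

    tissue: str
    k_E_per_h: float
    intercept_ln_suv: float
    r_squared: float
    n_frames_used: int
    window_min: tuple[float, float]
    k_E_se_per_h: float = float("nan")
    intercept_se: float = float("nan")
    negative_slope_flag: bool = False

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            {"k_E_per_h": self.k_E_per_h, "intercept_ln_suv": self.intercept_ln_suv}
        )

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            {"k_E_per_h": self.k_E_se_per_h, "intercept_ln_suv": self.intercept_se}
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy import stats

        df = max(self.n_frames_used - 2, 1)
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        lo = self.params - tcrit * self.bse
        hi = self.params + tcrit * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def summary(self) -> str:
        lines = [
            "Log-linear washout fit",
            "======================",
            f"tissue:            {self.tissue}",
            f"window:            {self.window_min[0]:.0f}-{self.window_min[1]:.0f} min",
            f"frames used:       {self.n_frames_used}",
            f"k_E [1/h]:         {self.k_E_per_h:.4f} (SE {self.k_E_se_per_h:.4f})",
            f"ln SUV intercept:  {self.intercept_ln_suv:.4f} (SE {self.intercept_se:.4f})",
            f"R-squared:         {self.r_squared:.4f}",
        ]
        if self.negative_slope_flag:
            lines.append("note: curve rises over the window (negative k_E)")
        return "\n".join(lines)

    def predict(self, times_min: np.ndarray) -> np.ndarray:
        """Model SUV at the given times (minutes)."""
        t_h = np.asarray(times_min, float) / 60.0
        return np.exp(self.intercept_ln_suv - self.k_E_per_h * t_h)

    def plot(self, tac: TimeActivityCurve | None = None, ax=None):
        """Plot ln(SUV) data and the fitted line; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if tac is not None:
            pos = tac.values > 0
            ax.plot(tac.times_min[pos], np.log(tac.values[pos]), "o", label="ln SUV")
        tt = np.linspace(self.window_min[0], self.window_min[1], 50)
        ax.plot(tt, self.intercept_ln_suv - self.k_E_per_h * tt / 60.0, "-",
                label=f"k_E = {self.k_E_per_h:.3f} /h")
        ax.set_xlabel("time post injection [min]")
        ax.set_ylabel("ln SUV")
        ax.set_title(self.tissue)
        ax.legend()
        return ax


#: the result type named for what it carries
KEResult = WashoutResults


class WashoutModel:
    """Log-linear washout model  ln C(t) = ln C0 - k_E * t  on a fixed window.

    Frames are selected by midpoint inclusion in the half-open window
    [t_lo, t_hi) in minutes.  ``fit`` runs unweighted OLS of ln(SUV) on time
    in hours and returns a :class:`WashoutResults`.
    """

    def __init__(self, tac: TimeActivityCurve,
                 window_min: tuple[float, float] = DEFAULT_WINDOW_MIN) -> None:
        if not tac.decay_corrected:
            raise ValueError("TAC must be decay-corrected before fitting k_E; "
                             "use kE_decay_consistency for uncorrected curves")
        self._init(tac, window_min)

    def _init(self, tac: TimeActivityCurve, window_min: tuple[float, float]) -> None:
        t_lo, t_hi = float(window_min[0]), float(window_min[1])
        if not t_lo < t_hi:
            raise ValueError("window must satisfy t_lo < t_hi")
        mask = (tac.times_min >= t_lo) & (tac.times_min < t_hi)
        if int(mask.sum()) < 3:
            raise ValueError(
                f"need at least 3 frames with midpoint in [{t_lo}, {t_hi}) min, "
                f"got {int(mask.sum())}"
            )
        vals = tac.values[mask]
        if np.any(vals <= 0):
            bad = np.flatnonzero(mask)[vals <= 0]
            raise ValueError(
                "non-positive TAC value(s) inside the fit window at frame index "
                f"{bad.tolist()} (t = {tac.times_min[bad].round(2).tolist()} min)"
            )
        self.tac = tac
        self.window_min = (t_lo, t_hi)
        self._t_h = tac.times_min[mask] / 60.0
        self._ln_y = np.log(vals)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, tissue: str,
        time_col: str = "time_min", value_col: str = "suv",
        window_min: tuple[float, float] = DEFAULT_WINDOW_MIN,
    ) -> "WashoutModel":
        """Build from a long-format table filtered to one tissue."""
        sub = df[df["tissue"] == tissue] if "tissue" in df.columns else df
        tac = TimeActivityCurve.from_samples(
            tissue, sub[time_col].to_numpy(), sub[value_col].to_numpy()
        )
        return cls(tac, window_min)

    def fit(self) -> WashoutResults:
        X = sm.add_constant(self._t_h)
        res = sm.OLS(self._ln_y, X).fit()
        intercept, slope = res.params
        se_int, se_slope = res.bse
        if np.ptp(self._ln_y) < 1e-14:
            # flat curve: perfect fit of a constant, no variance to explain
            r2 = 1.0
            slope = 0.0
        else:
            r2 = float(res.rsquared)
        k_E = -float(slope)
        return WashoutResults(
            tissue=self.tac.tissue,
            k_E_per_h=k_E,
            intercept_ln_suv=float(intercept),
            r_squared=r2,
            n_frames_used=int(self._t_h.size),
            window_min=self.window_min,
            k_E_se_per_h=float(se_slope),
            intercept_se=float(se_int),
            negative_slope_flag=k_E < 0,
        )


def estimate_kE(
    tac: TimeActivityCurve, window_min: tuple[float, float] = DEFAULT_WINDOW_MIN
) -> WashoutResults:
    """Estimate k_E (1/h) from a decay-corrected TAC by log-linear OLS."""
    return WashoutModel(tac, window_min).fit()


def kE_decay_consistency(
    tac_uncorrected: TimeActivityCurve,
    nuclide: Nuclide,
    window_min: tuple[float, float] = DEFAULT_WINDOW_MIN,
) -> WashoutResults:
    """Fit the washout slope of a NOT-decay-corrected curve.

    Because physical decay multiplies the tissue curve by exp(-lambda t),
    the fitted rate exceeds the decay-corrected k_E by exactly
    lambda = ln2/half-life (in 1/h) — a cross-check on decay handling.
    """
    if tac_uncorrected.decay_corrected:
        raise ValueError("expected a NOT decay-corrected TAC")
    model = WashoutModel.__new__(WashoutModel)
    model._init(tac_uncorrected, window_min)
    return model.fit()


def auc_trapezoid(
    tac: TimeActivityCurve, window_min: tuple[float, float]
) -> float:
    """Area under the sampled TAC over a window, in SUV*min.

    Trapezoidal rule on the sample grid with linear interpolation at the
    window edges.  The window must lie inside the sampled time range.
    """
    t_lo, t_hi = float(window_min[0]), float(window_min[1])
    t, v = tac.times_min, tac.values
    if t.size < 2:
        raise ValueError("need at least 2 samples")
    if t_lo < t[0] - 1e-9 or t_hi > t[-1] + 1e-9:
        raise ValueError(
            f"window [{t_lo}, {t_hi}] outside sampled range [{t[0]}, {t[-1]}] min"
        )
    if not t_lo < t_hi:
        raise ValueError("window must satisfy t_lo < t_hi")
    inner = (t > t_lo) & (t < t_hi)
    tt = np.concatenate([[t_lo], t[inner], [t_hi]])
    vv = np.concatenate([[np.interp(t_lo, t, v)], v[inner], [np.interp(t_hi, t, v)]])
    return float(np.trapezoid(vv, tt))


def batch_kE(
    datasets: Iterable["SubjectDataset"],
    tissues: Sequence[str] | None = None,
    window_min: tuple[float, float] = DEFAULT_WINDOW_MIN,
) -> pd.DataFrame:
    """Fit k_E for every (subject, occasion, tissue) in a cohort.

    Returns a long-format table with one row per fitted curve.  Tissues
    missing from a dataset produce a warning and are skipped.
    """
    rows = []
    for ds in datasets:
        names = tissues if tissues is not None else list(ds.tacs)
        for tissue in names:
            if tissue not in ds.tacs:
                warnings.warn(
                    f"tissue {tissue!r} missing for subject {ds.params.subject_id} "
                    f"({ds.occasion}); skipped"
                )
                continue
            res = estimate_kE(ds.tacs[tissue], window_min)
            rows.append(
                {
                    "subject": ds.params.subject_id,
                    "sex": ds.params.sex,
                    "occasion": ds.occasion,
                    "tissue": tissue,
                    "k_E_per_h": res.k_E_per_h,
                    "intercept_ln_suv": res.intercept_ln_suv,
                    "r_squared": res.r_squared,
                    "n_frames": res.n_frames_used,
                }
            )
    return pd.DataFrame(rows)


def summarize_kE(results: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue mean +/- SD of k_E, overall and per sex (test scans only).

    Retest scans contribute to test-retest statistics, not to the group
    means.  A single observation reports SD 0.
    """
    test = results[results["occasion"] == "test"]
    out = []
    for tissue, grp in test.groupby("tissue", sort=False):

        def _ms(vals: pd.Series) -> tuple[float, float]:
            m = float(vals.mean())
            s = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            return m, s

        mean_all, sd_all = _ms(grp["k_E_per_h"])
        row = {"tissue": tissue, "n": len(grp), "k_E_mean": mean_all, "k_E_sd": sd_all}
        for sex in ("M", "F"):
            sub = grp[grp["sex"] == sex]["k_E_per_h"]
            if len(sub):
                m, s = _ms(sub)
                row[f"k_E_mean_{sex}"], row[f"k_E_sd_{sex}"], row[f"n_{sex}"] = m, s, len(sub)
        out.append(row)
    return pd.DataFrame(out)
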