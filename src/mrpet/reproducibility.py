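"""Test-retest variability and group-comparison statistics.

TRTV is the signed percent difference of a paired measurement relative to
the pair mean: 100 * (test - retest) / ((test + retest) / 2).  Paired
(test vs retest) and unpaired (men vs women) comparisons use classical
two-sided t-tests at alpha = 0.05; the statistics are computed from the
textbook formulas with p-values from the t distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeasurement",
    "TTestResult",
    "trtv",
    "trtv_table",
    "paired_test",
    "unpaired_test",
    "sex_comparison_table",
    "ALPHA",
]

ALPHA = 0.05


@dataclass(frozen=True)
class PairedMeasurement:
    """One tissue's k_E in the test and retest scan of one subject."""

    subject_id: str
    tissue: str
    value_test: float
    value_retest: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.value_test) and np.isfinite(self.value_retest)):
            raise ValueError("paired values must be finite")


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    df: float

    @property
    def significant(self) -> bool:
        return self.pvalue <= ALPHA


def trtv(value_test: float, value_retest: float) -> float:
    """Test-retest variability in percent: difference over pair mean.

    Antisymmetric in its arguments and invariant to common rescaling.
    Positive values mean the test scan measured higher than the retest.
    """
    pair_sum = value_test + value_retest
    if pair_sum <= 0:
        raise ValueError("pair sum must be positive for TRTV")
    return 100.0 * (value_test - value_retest) / (pair_sum / 2.0)


def trtv_table(results: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-tissue TRTV from a long-format k_E results table.

    Expects the ``batch_kE`` output columns (subject, sex, occasion, tissue,
    k_E_per_h); only subjects with both occasions contribute.
    """
    wide = results.pivot_table(
        index=["subject", "sex", "tissue"], columns="occasion",
        values="k_E_per_h", aggfunc="first",
    ).reset_index()
    if "retest" not in wide.columns:
        return pd.DataFrame(columns=["subject", "sex", "tissue", "k_E_test",
                                     "k_E_retest", "trtv_pct"])
    paired = wide.dropna(subset=["test", "retest"])
    out = paired.rename(columns={"test": "k_E_test", "retest": "k_E_retest"}).copy()
    vals = []
    for row in out.itertuples():
        if row.k_E_test + row.k_E_retest <= 0:
            warnings.warn(
                f"non-positive k_E pair for subject {row.subject}, tissue "
                f"{row.tissue}; TRTV undefined, row reported as NaN"
            )
            vals.append(float("nan"))
        else:
            vals.append(trtv(row.k_E_test, row.k_E_retest))
    out["trtv_pct"] = vals
    return out.reset_index(drop=True)


def paired_test(values_test: np.ndarray, values_retest: np.ndarray) -> TTestResult:
    """Two-sided paired t-test on test-minus-retest differences.

    t = mean(d) / (sd(d) / sqrt(n)), df = n - 1.  Identical vectors (zero
    difference variance, zero mean difference) report t = 0, p = 1.
    """
    x = np.asarray(values_test, float)
    y = np.asarray(values_retest, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-d arrays of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0:
        if mean == 0:
            return TTestResult(0.0, 1.0, n - 1)
        return TTestResult(np.inf * np.sign(mean), 0.0, n - 1)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return TTestResult(float(t), float(p), n - 1)


def unpaired_test(group_a: np.ndarray, group_b: np.ndarray) -> TTestResult:
    """Two-sided two-sample t-test with pooled variance (Student's t).

    Zero pooled variance with equal means reports t = 0, p = 1; with
    different means the statistic diverges and p -> 0.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.ndim != 1 or b.ndim != 1 or a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = a.size, b.size
    df = na + nb - 2
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if pooled_var == 0:
        if diff == 0:
            return TTestResult(0.0, 1.0, df)
        return TTestResult(np.inf * np.sign(diff), 0.0, df)
    t = diff / np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(p), df)


def sex_comparison_table(results: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue male-vs-female comparison of k_E (test scans only)."""
    test = results[results["occasion"] == "test"]
    rows = []
    for tissue, grp in test.groupby("tissue", sort=False):
        males = grp[grp["sex"] == "M"]["k_E_per_h"].to_numpy()
        females = grp[grp["sex"] == "F"]["k_E_per_h"].to_numpy()
        if males.size < 2 or females.size < 2:
            continue
        res = unpaired_test(males, females)
        rows.append(
            {
                "tissue": tissue,
                "mean_m": males.mean(),
                "sd_m": males.std(ddof=1),
                "mean_f": females.mean(),
                "sd_f": females.std(ddof=1),
                "t": res.statistic,
                "p": res.pvalue,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)
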