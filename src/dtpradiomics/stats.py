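"""Test-retest repeatability and uptake-time susceptibility statistics.

The analysis takes a longitudinal feature table (lesion x day x uptake
time x feature) and, per feature:

1. tests the 60-vs-90-min difference on day 1 with a paired Wilcoxon
   signed-rank test, Benjamini-Hochberg-corrected across features;
2. measures repeatability between days with the intraclass correlation
   coefficient ICC(A,1) (two-way model, absolute agreement, single
   rating) at each uptake time, gated at 0.9;
3. normalizes the per-lesion uptake-time change by the test-retest
   variability:  z = ((RF90 - RF60) - mean(TRT60)) / sd(TRT60), where
   TRT60 is the day-2 minus day-1 difference at 60 min;
4. assigns a use case: features failing the ICC gate at either time are
   DISCARDED; repeatable features that are both FDR-significant and have
   |mean z| >= 1 suit dual-time-point imaging (DTP); repeatable features
   that are neither are robust cross-sectional features (CS2); the rest
   have an unclear time dependence (CS1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "UptakeZResult",
    "icc_agreement_single",
    "wilcoxon_signed_rank",
    "bh_fdr",
    "uptake_z",
    "classify_feature",
    "classify_all",
    "USE_CASES",
]

log = logging.getLogger(__name__)

USE_CASES = ("DTP", "CS1", "CS2", "DISCARDED")


def icc_agreement_single(pairs: np.ndarray) -> float:
    """ICC(A,1): two-way model, absolute agreement, single rating.

    ``pairs`` is an (n, k) array, rows lesions, columns repeated
    measurements (here k = 2 days).  Computed from the two-way ANOVA mean
    squares as ``(MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE))``.
    """
    x = np.asarray(pairs, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need an (n, k>=2) array of repeated measurements")
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in ICC input")
    gm = x.mean()
    ss_total = float(((x - gm) ** 2).sum())
    if ss_total == 0:
        raise ValueError("ICC undefined: zero total variance")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - gm) ** 2).sum())
    ss_cols = n * float(((col_means - gm) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(
        (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    )


def wilcoxon_signed_rank(x60: np.ndarray, x90: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped (classic Wilcoxon rule).  The exact null
    distribution is used for n <= 25 tie-free differences, otherwise the
    normal approximation with continuity and tie correction.  If every
    difference is zero there is no evidence of change and p = 1 (with a
    warning).
    """
    x60 = np.asarray(x60, dtype=np.float64)
    x90 = np.asarray(x90, dtype=np.float64)
    if x60.shape != x90.shape:
        raise ValueError("paired samples must be aligned by lesion")
    d = x90 - x60
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=True, method=method)
    return float(res.pvalue)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class UptakeZResult:
    """Per-lesion uptake-time z scores of one feature."""

    z: np.ndarray
    mean_z: float
    sd_z: float
    trt60: np.ndarray


def uptake_z(
    rf60_day1: np.ndarray, rf90_day1: np.ndarray, rf60_day2: np.ndarray
) -> UptakeZResult:
    """Uptake-time change in units of test-retest variability.

    ``z_l = ((RF90 - RF60)_l - mean(TRT60)) / sd(TRT60)`` with
    ``TRT60_l = RF60(day2)_l - RF60(day1)_l``; the mean and SD of TRT60
    are taken across lesions (sample SD).
    """
    rf60_day1 = np.asarray(rf60_day1, dtype=np.float64)
    rf90_day1 = np.asarray(rf90_day1, dtype=np.float64)
    rf60_day2 = np.asarray(rf60_day2, dtype=np.float64)
    if not (rf60_day1.shape == rf90_day1.shape == rf60_day2.shape):
        raise ValueError("per-lesion arrays must be aligned")
    if rf60_day1.size < 2:
        raise ValueError("need at least 2 lesions")
    trt60 = rf60_day2 - rf60_day1
    sd = float(trt60.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate test-retest: sd(TRT60) = 0")
    z = ((rf90_day1 - rf60_day1) - trt60.mean()) / sd
    return UptakeZResult(
        z=z, mean_z=float(z.mean()), sd_z=float(z.std(ddof=1)), trt60=trt60
    )


def classify_feature(
    icc60: float,
    icc90: float,
    q: float,
    mean_z: float,
    icc_gate: float = 0.9,
    alpha: float = 0.05,
    z_gate: float = 1.0,
) -> str:
    """Assign a use case from repeatability and uptake-time susceptibility.

    DISCARDED unless the ICC exceeds the gate at both uptake times; then
    DTP if the time effect is both FDR-significant and large relative to
    test-retest variability (|mean z| >= z_gate), CS2 if it is neither,
    and CS1 (unclear dependence) otherwise.
    """
    for v in (icc60, icc90, q, mean_z):
        if not np.isfinite(v):
            raise ValueError("classification inputs must be finite")
    if icc60 <= icc_gate or icc90 <= icc_gate:
        return "DISCARDED"
    significant = q < alpha
    susceptible = abs(mean_z) >= z_gate
    if significant and susceptible:
        return "DTP"
    if not significant and not susceptible:
        return "CS2"
    return "CS1"


def _lesion_uid(table: pd.DataFrame) -> pd.Series:
    if "patient" in table.columns:
        return table["patient"].astype(str) + "_" + table["lesion"].astype(str)
    return table["lesion"].astype(str)


def classify_all(
    table: pd.DataFrame,
    icc_gate: float = 0.9,
    alpha: float = 0.05,
    z_gate: float = 1.0,
) -> pd.DataFrame:
    """Run the full per-feature analysis on a longitudinal feature table.

    ``table`` is long format with at least the columns ``lesion``
    (optionally ``patient``), ``day`` (1, 2), ``time_min`` (two values),
    ``feature`` and ``value`` for a single settings combination.  Lesions
    missing any of the 4 (day, time) cells are excluded with a log entry,
    as are features whose statistics are degenerate.  BH correction is
    applied jointly across the analyzed features.
    """
    table = table.copy()
    table["_uid"] = _lesion_uid(table)
    times = sorted(table["time_min"].unique())
    if len(times) != 2:
        raise ValueError(f"expected exactly 2 uptake times, got {times}")
    t60, t90 = times
    days = sorted(table["day"].unique())
    if len(days) != 2:
        raise ValueError(f"expected exactly 2 days, got {days}")
    d1, d2 = days

    wide = table.pivot_table(
        index=["_uid", "feature"], columns=["day", "time_min"], values="value"
    )
    complete = wide.dropna()
    # a lesion is analyzable only if complete for all its features
    rows = []
    pvals = []
    for feature, sub in complete.groupby(level="feature"):
        sub = sub.droplevel("feature")
        if len(sub) < 3:
            log.warning("feature %s excluded: only %d complete lesions", feature, len(sub))
            continue
        try:
            icc60 = icc_agreement_single(sub[[(d1, t60), (d2, t60)]].to_numpy())
            icc90 = icc_agreement_single(sub[[(d1, t90), (d2, t90)]].to_numpy())
            zres = uptake_z(
                sub[(d1, t60)].to_numpy(),
                sub[(d1, t90)].to_numpy(),
                sub[(d2, t60)].to_numpy(),
            )
        except ValueError as exc:
            log.warning("feature %s excluded: %s", feature, exc)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = wilcoxon_signed_rank(
                sub[(d1, t60)].to_numpy(), sub[(d1, t90)].to_numpy()
            )
        pvals.append(p)
        rows.append(
            {
                "feature": feature,
                "icc60": icc60,
                "icc90": icc90,
                "p_raw": p,
                "mean_z": zres.mean_z,
                "sd_z": zres.sd_z,
            }
        )
    if not rows:
        raise ValueError("no analyzable features in the table")
    out = pd.DataFrame(rows)
    out["q_fdr"] = bh_fdr(np.asarray(pvals))
    out["use_case"] = [
        classify_feature(r.icc60, r.icc90, r.q_fdr, r.mean_z, icc_gate, alpha, z_gate)
        for r in out.itertuples()
    ]
    return out[
        ["feature", "icc60", "icc90", "p_raw", "q_fdr", "mean_z", "sd_z", "use_case"]
    ]
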