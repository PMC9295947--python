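"""Z-scores and centiles against the uncomplicated-pregnancy reference.

A scan's z-score is its deviation from the fitted UN reference curve
standardised by the prediction SD at that gestational age,

    z = (T2* - mu_hat(GA)) / sigma_pred(GA),

where ``sigma_pred**2`` combines the delta-method curve variance with the
residual variance.  Standardising by the prediction SD (rather than the
narrower curve-CI SD) makes z-scores of reference-population scans unit
variance.  Percentiles are ``100 * Phi(z)``.  The module also provides the
study's group-comparison statistics: two-sample Kolmogorov-Smirnov test,
Cohen's d, the chi-square proportion test with relative risk, and the
20-bin percentile histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .growth import GestationalFit

__all__ = [
    "ZScore",
    "GroupStats",
    "zscore",
    "score_cohort",
    "assign_window",
    "group_stats",
    "ks_test",
    "cohens_d",
    "chi2_proportion",
    "percentile_histogram",
    "GA_WINDOW_LABELS",
    "PERCENTILE_BIN_EDGES",
]

GA_RANGE = (10.0, 40.0)
GA_WINDOW_EDGES = (10.0, 20.0, 30.0, 40.0)
GA_WINDOW_LABELS = ("10-20", "20-30", "30+")

#: 20 equally spaced percentile bins, [0,5), [5,10), ..., [95,100]
PERCENTILE_BIN_EDGES = np.linspace(0.0, 100.0, 21)


@dataclass(frozen=True)
class ZScore:
    scan_id: str
    z: float
    percentile: float


@dataclass(frozen=True)
class GroupStats:
    group: str
    n: int
    mean_z: float
    sd_z: float
    median_z: float

    def to_dict(self) -> dict:
        return {"group": self.group, "n": self.n, "mean_z": self.mean_z,
                "sd_z": self.sd_z, "median_z": self.median_z}


def zscore(t2star_ms, ga_weeks, reference: GestationalFit):
    """Standardised deviation of observations from the UN reference fit.

    Refuses gestational ages outside the modeled 10-40 week range rather
    than extrapolating the reference curve.
    """
    if not reference.converged:
        raise ValueError("reference fit did not converge")
    ga = np.asarray(ga_weeks, dtype=float)
    if np.any(ga < GA_RANGE[0]) or np.any(ga > GA_RANGE[1]):
        raise ValueError(f"gestational age outside {GA_RANGE}: extrapolation refused")
    y = np.asarray(t2star_ms, dtype=float)
    scalar = y.ndim == 0 and ga.ndim == 0
    ga1 = np.atleast_1d(ga)
    z = (np.atleast_1d(y) - reference.predict(ga1)) / reference.prediction_sd(ga1)
    return float(z[0]) if scalar else z


def percentile_of(z):
    """Gaussian percentile 100*Phi(z), in [0, 100]."""
    return 100.0 * stats.norm.cdf(z)


def assign_window(ga_weeks):
    """Gestational window label per scan: [10,20), [20,30), [30,40]."""
    ga = np.atleast_1d(np.asarray(ga_weeks, dtype=float))
    idx = np.clip(np.digitize(ga, GA_WINDOW_EDGES[1:3], right=False), 0, 2)
    return np.asarray(GA_WINDOW_LABELS, dtype=object)[idx]


def score_cohort(df: pd.DataFrame, reference: GestationalFit,
                 y: str = "t2star_ms") -> pd.DataFrame:
    """Score every scan of a cohort table against the UN reference.

    Returns a table with scan_id, subject_id, group, site, ga_weeks,
    z, percentile and gestational window.
    """
    out = df.reset_index(drop=True).copy()
    out["scan_id"] = [f"{s}_{i}" for i, s in enumerate(out["subject_id"])]
    out["z"] = zscore(out[y].to_numpy(), out["ga_weeks"].to_numpy(), reference)
    out["percentile"] = percentile_of(out["z"].to_numpy())
    out["window"] = assign_window(out["ga_weeks"].to_numpy())
    cols = ["scan_id", "subject_id", "group", "site", "ga_weeks", "z", "percentile", "window"]
    return out[[c for c in cols if c in out.columns]]


def group_stats(scores: pd.DataFrame, by: str = "group") -> list[GroupStats]:
    """Mean/SD/median of z per group (both summaries are reported)."""
    out = []
    for g, sub in scores.groupby(by, sort=True):
        z = sub["z"].to_numpy()
        out.append(GroupStats(str(g), len(z), float(np.mean(z)),
                              float(np.std(z, ddof=1)) if len(z) > 1 else 0.0,
                              float(np.median(z))))
    return out


def ks_test(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample two-tailed Kolmogorov-Smirnov test (D, asymptotic p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def cohens_d(sample_a, sample_b) -> float:
    """Absolute standardized mean difference with pooled SD."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    na, nb = a.size, b.size
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled == 0:
        raise ValueError("zero pooled SD: effect size undefined")
    return float(abs(a.mean() - b.mean()) / pooled)


def chi2_proportion(count_a: int, n_a: int, count_b: int, n_b: int):
    """Chi-square proportion test on a 2x2 table, without continuity correction.

    Returns ``(statistic, p, rr, (rr_lo, rr_hi))`` where rr is the relative
    risk (proportion A over proportion B) with a Wald 95% CI on log RR.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= count_a <= n_a and 0 <= count_b <= n_b):
        raise ValueError("counts must lie within group sizes")
    table = np.array([[count_a, n_a - count_a], [count_b, n_b - count_b]], dtype=float)
    if np.any(table.sum(axis=0) == 0):
        stat, p = 0.0, 1.0
    else:
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    pa, pb = count_a / n_a, count_b / n_b
    rr = np.inf if pb == 0 else pa / pb
    if count_a > 0 and count_b > 0 and np.isfinite(rr) and rr > 0:
        se = np.sqrt(1 / count_a - 1 / n_a + 1 / count_b - 1 / n_b)
        lo, hi = np.exp(np.log(rr) + np.array([-1, 1]) * 1.959963984540054 * se)
    else:
        lo, hi = np.nan, np.nan
    return float(stat), float(p), float(rr), (float(lo), float(hi))


def percentile_histogram(scores: pd.DataFrame, by: str = "group") -> pd.DataFrame:
    """Counts of scan percentiles in twenty 5%-wide bins, per group.

    Bins are left-closed right-open except the last ([95, 100]).  Returns a
    DataFrame indexed by bin lower edge with one count column per group;
    groups absent from the table get all-zero columns only if requested via
    ``scores[by]`` categories.
    """
    out = {}
    for g, sub in scores.groupby(by, sort=True):
        counts, _ = np.histogram(sub["percentile"].to_numpy(), bins=PERCENTILE_BIN_EDGES)
        out[str(g)] = counts
    idx = pd.Index(PERCENTILE_BIN_EDGES[:-1], name="bin_lo")
    return pd.DataFrame(out, index=idx, dtype=int)
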