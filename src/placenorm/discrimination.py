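"""ROC evaluation of T2* percentile as a classifier of adverse outcome.

Orientation: low percentile flags an adverse scan, i.e. a scan is called
positive when its percentile is at or below the cutoff.  Thresholds are
midpoints between consecutive distinct scores plus -inf/+inf sentinels, so
every achievable (sensitivity, specificity) operating point appears once.
AUC is the trapezoidal area under the ROC polyline, which with this
threshold set equals the Mann-Whitney concordance probability (ties
counted half).  Youden's J = sensitivity + specificity - 1 locates the
optimal cutoff C_opt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ROCCurve", "roc_curve", "windowed_roc", "subject_level_scores"]


@dataclass
class ROCCurve:
    """ROC operating points plus summary statistics."""

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    j_max: float
    c_opt: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {
            "thresholds": [float(v) for v in self.thresholds],
            "sens": [float(v) for v in self.sens],
            "spec": [float(v) for v in self.spec],
            "auc": self.auc,
            "j_max": self.j_max,
            "c_opt": self.c_opt,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


def roc_curve(scores, is_adverse) -> ROCCurve:
    """ROC curve for adverse-outcome discrimination by a low score.

    Parameters
    ----------
    scores : array-like
        Percentiles (or any score on the same orientation: lower = more
        suspicious).
    is_adverse : array-like of bool
        True for scans from the adverse (positive) class.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(is_adverse, dtype=bool).ravel()
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    distinct = np.unique(s)
    thresholds = np.concatenate(
        [[-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]]
    )
    # positive call: score <= threshold
    calls = s[None, :] <= thresholds[:, None]
    sens = (calls & y[None, :]).sum(axis=1) / n_pos
    spec = (~calls & ~y[None, :]).sum(axis=1) / n_neg

    fpr = 1.0 - spec
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(sens[order], fpr[order]))

    j = sens + spec - 1.0
    i_best = int(np.argmax(j))
    return ROCCurve(
        thresholds=thresholds,
        sens=sens,
        spec=spec,
        auc=auc,
        j_max=float(j[i_best]),
        c_opt=float(thresholds[i_best]),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def windowed_roc(
    scores: pd.DataFrame,
    positive_group: str = "PA",
    negative_group: str = "UN",
    windows=("10-20", "20-30", "30+"),
    score_col: str = "percentile",
) -> dict[str, ROCCurve]:
    """ROC per gestational window plus overall, for one group contrast.

    Scans outside the two contrasted groups are excluded (the primary
    contrast is PA vs UN).  A window with only one class present is
    skipped with a warning.
    """
    sub = scores[scores["group"].isin([positive_group, negative_group])]
    labels = (sub["group"] == positive_group).to_numpy()
    out = {"overall": roc_curve(sub[score_col].to_numpy(), labels)}
    for w in windows:
        mask = (sub["window"] == w).to_numpy()
        try:
            out[w] = roc_curve(sub[score_col].to_numpy()[mask], labels[mask])
        except ValueError as exc:
            warnings.warn(f"window {w!r} skipped: {exc}", stacklevel=2)
    return out


def subject_level_scores(scores: pd.DataFrame, score_col: str = "percentile") -> pd.DataFrame:
    """Max-severity aggregation: minimum percentile per subject (per window).

    Optional alternative to scan-level ROC, one row per subject and window.
    """
    idx = scores.groupby(["subject_id", "window"])[score_col].idxmin()
    return scores.loc[idx].reset_index(drop=True)
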