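"""Biomarker statistics for CTC count validation.

ROC analysis of counts as a cancer/healthy classifier, operating-point
sensitivity and specificity at a count cutoff, inter-run reproducibility
(CV%), and percent reduction of counts under treatment.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountSample",
    "ROCResult",
    "ReproStats",
    "roc_curve",
    "sens_spec_at_cutoff",
    "reproducibility_cv",
    "percent_reduction",
]

SCORE_FIELDS = ("ctc_count", "dual_positive_count", "total_count")


@dataclasses.dataclass
class CountSample:
    """Per-subject cell counts with cancer/healthy group membership."""

    subject_id: str
    group: str  # "cancer" or "healthy"
    ctc_count: int
    dual_positive_count: int = 0
    total_count: int = 0

    def __post_init__(self) -> None:
        if self.group not in ("cancer", "healthy"):
            raise ValueError("group must be 'cancer' or 'healthy'")
        for f in SCORE_FIELDS:
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be nonnegative")


@dataclasses.dataclass
class ROCResult:
    auc: float
    operating_points: pd.DataFrame  # columns: cutoff, sensitivity, specificity
    youden_optimal_cutoff: float


@dataclasses.dataclass
class ReproStats:
    """Per-subject replicate mean, sample SD and coefficient of variation."""

    table: pd.DataFrame  # columns: subject_id, n, mean, sd, cv_pct, cv_defined


def _split_scores(samples: Sequence[CountSample], score: str) -> tuple[np.ndarray, np.ndarray]:
    if score not in SCORE_FIELDS:
        raise ValueError(f"score must be one of {SCORE_FIELDS}")
    cancer = np.array([getattr(s, score) for s in samples if s.group == "cancer"], dtype=float)
    healthy = np.array([getattr(s, score) for s in samples if s.group == "healthy"], dtype=float)
    if cancer.size == 0 or healthy.size == 0:
        raise ValueError("both groups must be non-empty")
    return cancer, healthy


def roc_curve(samples: Sequence[CountSample], score: str = "ctc_count") -> ROCResult:
    """ROC analysis with orientation: higher count indicates cancer.

    AUC is computed from the Mann-Whitney rank statistic,
    P(score_cancer > score_healthy) + 0.5 P(tie), which handles the heavy
    ties of small integer counts exactly (curve integration would too, but
    the rank form makes the tie convention explicit).  Operating points are
    evaluated at half-integer cutoffs between consecutive distinct scores,
    with 'count > cutoff' called positive.  The Youden-optimal cutoff
    maximizes sensitivity + specificity - 1.
    """
    cancer, healthy = _split_scores(samples, score)
    combined = np.concatenate([cancer, healthy])
    ranks = stats.rankdata(combined)
    n1, n2 = cancer.size, healthy.size
    auc = (ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n2)

    uniq = np.unique(combined)
    cutoffs = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]])
    rows = []
    for c in cutoffs:
        sens, spec = _sens_spec(cancer, healthy, c)
        rows.append({"cutoff": float(c), "sensitivity": sens, "specificity": spec})
    points = pd.DataFrame(rows)
    youden = points["sensitivity"] + points["specificity"] - 1.0
    best = points.loc[youden.idxmax(), "cutoff"]
    return ROCResult(float(auc), points, float(best))


def _sens_spec(cancer: np.ndarray, healthy: np.ndarray, cutoff: float) -> tuple[float, float]:
    sens = float(np.mean(cancer > cutoff))
    spec = float(np.mean(healthy <= cutoff))
    return sens, spec


def sens_spec_at_cutoff(
    samples: Sequence[CountSample], cutoff: float, score: str = "ctc_count"
) -> tuple[float, float]:
    """Sensitivity and specificity when 'count > cutoff' predicts cancer."""
    cancer, healthy = _split_scores(samples, score)
    return _sens_spec(cancer, healthy, cutoff)


def reproducibility_cv(replicates: Mapping[str, Sequence[float]]) -> ReproStats:
    """Inter-run reproducibility: per-subject mean, sample SD, CV%.

    CV% = 100 * SD / mean with the n-1 SD; undefined (flagged) when the
    replicate mean is zero.
    """
    rows = []
    for subject, values in replicates.items():
        v = np.asarray(list(values), dtype=float)
        if v.size < 2:
            raise ValueError(f"subject {subject!r}: need >= 2 replicates")
        mean = float(v.mean())
        sd = float(v.std(ddof=1))
        defined = mean > 0
        rows.append(
            {
                "subject_id": subject,
                "n": int(v.size),
                "mean": mean,
                "sd": sd,
                "cv_pct": 100.0 * sd / mean if defined else np.nan,
                "cv_defined": defined,
            }
        )
    return ReproStats(pd.DataFrame(rows))


def percent_reduction(pre_count: float, post_count: float) -> float:
    """Percent decline of a count after treatment: 100*(pre - post)/pre."""
    if pre_count <= 0:
        raise ValueError("pre-treatment count must be positive")
    return 100.0 * (pre_count - post_count) / pre_count
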