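"""Off-target profile summaries and evaluation metrics.

The per-guide *anti-OT score* condenses a genome-wide off-target profile
(predicted occurrence probabilities ``OT_i`` over all candidate loci) into
one number in (0, 1]:

    S = ln(1 + exp(-sum_i OT_i)) / ln 2

S equals 1 exactly when the summed off-target probability is zero and
strictly decreases as any OT_i grows — a higher score means a lower
predicted genome-wide off-target propensity. (The widely printed variant
with a positive exponent is >= 1 and increasing, contradicting both the
stated range and the ordering; ``literal=True`` evaluates that form for
comparison.)

Evaluation metrics are those used to benchmark guide-design models:
ROC-AUC and PR-AUC for the imbalanced classification setting, Spearman
and a weighted Spearman correlation for regression, where each site's
weight is proportional to the rank of its measured cleavage (indel)
frequency — errors on the strongest true off-targets cost the most.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "OffTargetProfile",
    "ProfileEntry",
    "MetricReport",
    "anti_ot_score",
    "severity_bands",
    "classification_metrics",
    "regression_metrics",
    "weighted_spearman",
]

BAND_COLORS = {"mild": "green", "moderate": "yellow", "severe": "red"}


@dataclass(frozen=True)
class ProfileEntry:
    chrom: str
    start: int
    end: int
    strand: str
    mismatch_count: int
    ot: float  # predicted occurrence probability

    def __post_init__(self):
        if not 0.0 <= self.ot <= 1.0:
            raise ValueError(f"OT probability {self.ot} outside [0, 1]")


@dataclass
class OffTargetProfile:
    guide_id: str
    entries: list[ProfileEntry]

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([e.ot for e in self.entries])

    @property
    def anti_ot(self) -> float:
        return anti_ot_score(self.probabilities)


def anti_ot_score(probs, literal: bool = False) -> float:
    """Summary score in (0, 1]; 1 iff the summed probability is zero."""
    probs = np.asarray(probs, dtype=float).ravel()
    if probs.size and (((probs < 0) | (probs > 1)).any() or not np.isfinite(probs).all()):
        raise ValueError("occurrence probabilities must lie in [0, 1]")
    total = float(probs.sum())
    sign = 1.0 if literal else -1.0
    return float(np.log1p(np.exp(sign * total)) / np.log(2.0))


def severity_bands(profile: OffTargetProfile,
                   thresholds: tuple[float, float] = (1 / 3, 2 / 3)
                   ) -> pd.DataFrame:
    """Band each candidate site mild/moderate/severe by its OT probability.

    mild: OT < t1; moderate: t1 <= OT < t2; severe: OT >= t2. Output is
    ordered by genomic coordinate for circular-track plotting, with the
    conventional green/yellow/red colors attached.
    """
    t1, t2 = thresholds
    if not 0.0 < t1 < t2 < 1.0:
        raise ValueError(f"thresholds must satisfy 0 < t1 < t2 < 1, got {thresholds}")
    rows = []
    for e in sorted(profile.entries, key=lambda e: (e.chrom, e.start, e.strand)):
        band = "mild" if e.ot < t1 else ("moderate" if e.ot < t2 else "severe")
        rows.append({
            "guide_id": profile.guide_id, "chrom": e.chrom, "start": e.start,
            "end": e.end, "strand": e.strand, "mismatch_count": e.mismatch_count,
            "OT": e.ot, "band": band, "color": BAND_COLORS[band],
        })
    return pd.DataFrame(
        rows, columns=["guide_id", "chrom", "start", "end", "strand",
                       "mismatch_count", "OT", "band", "color"])


def classification_metrics(scores, labels) -> tuple[float, float]:
    """(ROC-AUC with midrank tie handling, step-integrated PR-AUC)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return (float(roc_auc_score(labels, scores)),
            float(average_precision_score(labels, scores)))


def weighted_spearman(preds, truths, weights=None) -> float:
    """Weighted Pearson correlation on midranks.

    Default weights are proportional to the rank of each truth value
    (largest truth -> largest weight), normalized to sum 1; with equal
    weights this reduces exactly to the ordinary Spearman correlation.
    """
    preds = np.asarray(preds, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if preds.shape != truths.shape:
        raise ValueError("preds and truths must have equal length")
    rp, rt = rankdata(preds), rankdata(truths)
    if weights is None:
        weights = rankdata(truths)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    mp, mt = np.sum(w * rp), np.sum(w * rt)
    cov = np.sum(w * (rp - mp) * (rt - mt))
    sp = np.sqrt(np.sum(w * (rp - mp) ** 2))
    st = np.sqrt(np.sum(w * (rt - mt) ** 2))
    return float(cov / (sp * st))


def regression_metrics(preds, truths, weights=None) -> tuple[float, float]:
    """(Spearman, rank-weighted Spearman); requires length >= 3."""
    preds = np.asarray(preds, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if preds.shape != truths.shape:
        raise ValueError("preds and truths must have equal length")
    if preds.size < 3:
        raise ValueError("need at least 3 observations")
    rho = float(spearmanr(preds, truths).statistic)
    return rho, weighted_spearman(preds, truths, weights)


@dataclass
class MetricReport:
    roc_auc: float | None = None
    pr_auc: float | None = None
    spearman: float | None = None
    weighted_spearman: float | None = None
    n: int = 0
    positives: int = 0

    @classmethod
    def from_predictions(cls, scores, labels=None, truths=None) -> "MetricReport":
        rep = cls(n=len(np.asarray(scores)))
        if labels is not None:
            labels = np.asarray(labels)
            rep.positives = int(labels.sum())
            rep.roc_auc, rep.pr_auc = classification_metrics(scores, labels)
        if truths is not None:
            rep.spearman, rep.weighted_spearman = regression_metrics(scores, truths)
        return rep

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}
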