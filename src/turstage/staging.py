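"""Area-ratio staging engine.

The staging score is the tumor-to-uterus area ratio (TUR): on one segmented
slice, the number of tumor pixels divided by the number of tumor-plus-uterus
pixels.  Deeply invasive (stage IB) tumors occupy a larger fraction of the
organ than superficial (stage IA) ones, so TUR separates the stages.  Per
MRI sequence, an ROC over cohort TUR scores yields an AUC and a
Youden-optimal criterion; per-sequence stage calls can then be fused across
sequences by a k-of-n vote.

A two-Gaussian TUR model (stage-conditional normals) serves as the
simulation oracle: ``gaussian_auc`` gives the closed-form AUC
Phi(Δμ / sqrt(σ₀² + σ₁²)) and ``simulate_tur_cohort`` draws matched
truncated-normal scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .errors import ConfigurationError, EmptySegmentationError, SingleClassError
from .phantom import TUMOR, UTERUS

POSITIVE_STAGE = "IB"  # larger mean TUR in every sequence
NEGATIVE_STAGE = "IA"


@dataclass(frozen=True)
class TurRecord:
    patient_id: str
    sequence: str
    tur: float
    true_stage: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.tur <= 1.0:
            raise ConfigurationError(f"tur must lie in [0, 1], got {self.tur}")
        if self.true_stage is not None and self.true_stage not in ("IA", "IB"):
            raise ConfigurationError(f"true_stage must be IA or IB, got {self.true_stage!r}")


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray       # sorted ascending; the candidate criteria
    sensitivity: np.ndarray      # P(tur >= t | IB), non-increasing in t
    specificity: np.ndarray      # P(tur <  t | IA), non-decreasing in t
    auc: float
    criterion: float             # Youden-optimal threshold (smallest on ties)
    sens_at_criterion: float
    spec_at_criterion: float


@dataclass(frozen=True)
class FusionRule:
    """Call stage IB when at least ``k`` of the listed sequences vote IB."""

    sequences: tuple[str, ...]
    k: int = 1

    def __post_init__(self):
        if not self.sequences:
            raise ConfigurationError("fusion rule needs at least one sequence")
        if not 1 <= self.k <= len(self.sequences):
            raise ConfigurationError(
                f"k must lie in [1, {len(self.sequences)}], got {self.k}"
            )


@dataclass(frozen=True)
class PerformanceSummary:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float  # NaN when no true positives exist
    specificity: float  # NaN when no true negatives exist


def compute_tur(mask: np.ndarray) -> float:
    """TUR of one label mask: tumor / (tumor + uterus) pixel counts.

    Unitless and voxel-size independent.  Raises on a segmentation with no
    uterus or tumor pixels rather than returning a silent 0 — an empty
    prediction is a segmentation failure, not a stage-IA signal.
    """
    mask = np.asarray(mask)
    tumor = int((mask == TUMOR).sum())
    uterus = int((mask == UTERUS).sum())
    if tumor + uterus == 0:
        raise EmptySegmentationError("empty segmentation: no uterus or tumor pixels")
    return tumor / (tumor + uterus)


def _scores_labels(records: Sequence[TurRecord]) -> tuple[np.ndarray, np.ndarray]:
    missing = [r.patient_id for r in records if r.true_stage is None]
    if missing:
        raise ConfigurationError(f"records without true_stage: {missing[:5]}")
    scores = np.array([r.tur for r in records], dtype=float)
    labels = np.array([r.true_stage == POSITIVE_STAGE for r in records])
    return scores, labels


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann–Whitney U statistic, ties counted 1/2."""
    pos = scores[labels]
    neg = scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise SingleClassError("AUC needs both classes present")
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * equal) / (len(pos) * len(neg)))


def roc_curve(records: Sequence[TurRecord]) -> RocResult:
    """ROC over a cohort's TUR scores with stage IB as the positive class.

    Operating points are evaluated at every distinct score under the decision
    rule "call IB when tur >= threshold".  The AUC is the trapezoid area,
    identical to the Mann–Whitney U statistic with ties counted 1/2.  The
    criterion maximizes Youden's J = sensitivity + specificity − 1, ties
    broken toward the smallest threshold.
    """
    scores, labels = _scores_labels(records)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError(
            f"ROC needs both stages; got {n_pos} IB and {n_neg} IA records"
        )
    thresholds = np.unique(scores)  # ascending
    sens = np.array([(scores[labels] >= t).sum() / n_pos for t in thresholds])
    spec = np.array([(scores[~labels] < t).sum() / n_neg for t in thresholds])

    # trapezoid area over (FPR, TPR) points ordered from (0,0) upward;
    # descending thresholds give increasing FPR
    fpr = np.concatenate([[0.0], (1.0 - spec)[::-1]])
    tpr = np.concatenate([[0.0], sens[::-1]])
    auc = float(np.trapezoid(tpr, fpr))

    j = sens + spec - 1.0
    best = int(np.argmax(j))  # first (= smallest threshold) among ties
    return RocResult(thresholds, sens, spec, auc,
                     float(thresholds[best]), float(sens[best]), float(spec[best]))


def gaussian_auc(mu_ia: float, sd_ia: float, mu_ib: float, sd_ib: float) -> float:
    """Closed-form AUC of two normal score distributions, IB positive."""
    if sd_ia <= 0 or sd_ib <= 0:
        raise ConfigurationError("standard deviations must be > 0")
    return float(norm.cdf((mu_ib - mu_ia) / np.hypot(sd_ia, sd_ib)))


def simulate_tur_cohort(
    mu_ia: float, sd_ia: float, mu_ib: float, sd_ib: float,
    n_ia: int, n_ib: int, rng: np.random.Generator,
    bounds: tuple[float, float] = (0.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Draw stage-conditional TUR scores, rejection-truncated to ``bounds``.

    Returns (ia_scores, ib_scores).  The two-Gaussian model underlying this
    draw is the simulation oracle for the ROC machinery.
    """
    lo, hi = bounds
    out = []
    for mu, sd, n in ((mu_ia, sd_ia, n_ia), (mu_ib, sd_ib, n_ib)):
        draws = np.empty(n)
        filled = 0
        while filled < n:
            x = rng.normal(mu, sd, size=max(16, 2 * (n - filled)))
            x = x[(x >= lo) & (x <= hi)][: n - filled]
            draws[filled:filled + len(x)] = x
            filled += len(x)
        out.append(draws)
    return out[0], out[1]


def classify(tur: float, criterion: float) -> str:
    """Stage call for one score: IB iff ``tur >= criterion``."""
    if not 0.0 <= criterion <= 1.0:
        raise ConfigurationError(f"criterion must lie in [0, 1], got {criterion}")
    return POSITIVE_STAGE if tur >= criterion else NEGATIVE_STAGE


def fuse(votes: Mapping[str, str], rule: FusionRule) -> str:
    """Combine per-sequence stage votes: IB iff at least ``rule.k`` votes are IB."""
    missing = [s for s in rule.sequences if s not in votes]
    if missing:
        raise ConfigurationError(f"missing votes for sequences: {missing}")
    n_ib = sum(1 for s in rule.sequences if votes[s] == POSITIVE_STAGE)
    return POSITIVE_STAGE if n_ib >= rule.k else NEGATIVE_STAGE


def evaluate(predicted: Sequence[str], true: Sequence[str]) -> PerformanceSummary:
    """Accuracy / sensitivity / specificity of stage calls, IB positive.

    A ratio whose denominator class is absent is reported as NaN (undefined),
    never coerced to 0.
    """
    if len(predicted) != len(true) or len(predicted) == 0:
        raise ConfigurationError("predicted and true stage lists must be equal and non-empty")
    pred = np.array([p == POSITIVE_STAGE for p in predicted])
    truth = np.array([t == POSITIVE_STAGE for t in true])
    tp = int((pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    acc = (tp + tn) / len(pred)
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return PerformanceSummary(tp, tn, fp, fn, acc, sens, spec)
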