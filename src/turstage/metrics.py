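"""Segmentation quality metrics: Dice similarity coefficient and cohort stats.

The Dice similarity coefficient (DSC) between a reference pixel set X and a
predicted set Y is 2|X∩Y| / (|X|+|Y|): 1 for perfect overlap, 0 for disjoint
sets.  For the uterus the pixel set is the whole organ — pixels labelled
uterus *or* tumor — because clinical ground truth draws the tumor inside the
organ outline, and organ overlap is only well defined against the full
region.  A strict uterus-label-only mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ShapeMismatchError
from .phantom import TUMOR, UTERUS

STRUCTURES = ("uterus", "tumor")


@dataclass(frozen=True)
class DscRecord:
    patient_id: str
    sequence: str
    structure: str
    dsc: float

    def __post_init__(self):
        if not 0.0 <= self.dsc <= 1.0:
            raise ConfigurationError(f"dsc must lie in [0, 1], got {self.dsc}")


def _membership(mask: np.ndarray, structure: str, whole_organ_uterus: bool) -> np.ndarray:
    if structure == "tumor":
        return mask == TUMOR
    if structure == "uterus":
        if whole_organ_uterus:
            return (mask == UTERUS) | (mask == TUMOR)
        return mask == UTERUS
    raise ConfigurationError(f"structure must be one of {STRUCTURES}, got {structure!r}")


def dsc(reference: np.ndarray, predicted: np.ndarray, structure: str,
        whole_organ_uterus: bool = True) -> float:
    """Dice coefficient for one structure between two label masks.

    Both-empty sets score 1.0 (perfect agreement on absence); an empty
    reference against a non-empty prediction scores 0.
    """
    reference = np.asarray(reference)
    predicted = np.asarray(predicted)
    if reference.shape != predicted.shape:
        raise ShapeMismatchError(
            f"mask shapes differ: {reference.shape} vs {predicted.shape}"
        )
    x = _membership(reference, structure, whole_organ_uterus)
    y = _membership(predicted, structure, whole_organ_uterus)
    denom = int(x.sum()) + int(y.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((x & y).sum()) / denom


def summarize(records: list[DscRecord]) -> pd.DataFrame:
    """Per (sequence, structure) mean, sample SD, median and n of DSC values."""
    if not records:
        raise ConfigurationError("no DSC records to summarize")
    df = pd.DataFrame([r.__dict__ for r in records])
    out = (
        df.groupby(["sequence", "structure"], sort=True)["dsc"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0,
             median="median", n="size")
        .reset_index()
    )
    return out


def compare_groups(sample_a, sample_b, paired: bool = False,
                   equal_var: bool = False) -> float:
    """Two-sided t-test p-value between two DSC (or TUR) samples.

    Defaults to the Welch unequal-variance form; ``paired=True`` switches to
    a paired t-test, ``equal_var=True`` to the pooled Student form.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError("each sample needs n >= 2 for a t-test")
    if paired:
        if len(a) != len(b):
            raise ConfigurationError("paired test needs equal sample sizes")
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=equal_var)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p
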