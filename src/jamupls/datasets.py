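"""Published reference summaries of the motivating 3,138-formula formulary.

The raw formulary is not redistributable, but its printed summary tables
are: the 9-class confusion matrix of the reported PLS-DA efficacy model and
the per-plant significance-count partition of the reported permutation
test.  They serve as fixed inputs for the summary utilities.
"""

from __future__ import annotations

import numpy as np

from .pls import ConfusionMatrix
from .simulate import JAMU_CLASS_NAMES

__all__ = [
    "reported_confusion_counts",
    "reported_confusion_matrix",
    "reported_significance_partition",
]

# Rows = observed efficacy, columns = predicted efficacy, class order
# URI, DOA, DMB, GST, FML, MSC, PIN, RSP, WND.
_CONFUSION_COUNTS = (
    (39, 0, 0, 21, 2, 10, 0, 0, 0),
    (0, 164, 0, 29, 36, 18, 0, 0, 2),
    (0, 1, 5, 10, 0, 3, 1, 2, 0),
    (3, 17, 0, 880, 12, 46, 9, 6, 7),
    (0, 13, 0, 61, 266, 50, 5, 1, 2),
    (6, 6, 1, 127, 41, 638, 16, 0, 5),
    (1, 0, 0, 90, 4, 77, 133, 4, 2),
    (3, 0, 0, 21, 4, 23, 3, 52, 1),
    (2, 3, 0, 57, 11, 11, 4, 0, 71),
)

# Of 465 plants: how many were permutation-significant for exactly
# 0, 1, 2 and 3 efficacies.
_SIGNIFICANCE_PARTITION = (234, 189, 38, 4)


def reported_confusion_counts() -> np.ndarray:
    """9x9 confusion counts of the reported efficacy classifier."""
    return np.array(_CONFUSION_COUNTS, dtype=np.int64)


def reported_confusion_matrix() -> ConfusionMatrix:
    """The reported confusion counts wrapped in the summary utility."""
    return ConfusionMatrix.from_counts(reported_confusion_counts(), JAMU_CLASS_NAMES)


def reported_significance_partition() -> np.ndarray:
    """Counts of plants significant for exactly 0..3 efficacies (sums to 465)."""
    return np.array(_SIGNIFICANCE_PARTITION, dtype=np.int64)
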