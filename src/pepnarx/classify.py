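"""Activity segmentation and SVM classification of peptide sequences.

Peptides are labeled into activity segments on the ln(EC50) axis: the
two-class scheme cuts at the series median, the three-class scheme at
EC50 = 1 (ln = 0) and the median.  An RBF-kernel support vector machine
then predicts the segment from eight sequence-only descriptors, providing
the "rough location" the two-stage EC50 predictor needs.

The eight descriptors are this package's concrete realization of four
descriptor categories (amino-acid composition, digital description of the
sequence, sequence code, sequence length):

    f1  fraction of distinct residues (composition diversity)
    f2  maximum per-residue frequency (composition dominance)
    f3  mean of the digit vector
    f4  population standard deviation of the digit vector
    f5  ln of the base-21 sequence code
    f6  leading (N-terminal) digit
    f7  sequence length
    f8  terminal (C-terminal) digit

All are pure functions of the sequence and never of EC50.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .codec import PeptideRecord, encode_sequence

__all__ = [
    "SegmentScheme",
    "featurize",
    "featurize_records",
    "assign_labels",
    "train_svm",
    "N_FEATURES",
]

N_FEATURES = 8


@dataclass(frozen=True)
class SegmentScheme:
    """Class boundaries on the ln(EC50) axis.

    Intervals are half-open, [b_{i-1}, b_i), with a boundary value belonging
    to the upper class; the lowest interval is open below.
    """

    k: int
    boundaries: tuple[float, ...]
    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.k != len(self.boundaries) + 1:
            raise ValueError("k must equal len(boundaries) + 1")
        if any(b2 <= b1 for b1, b2 in zip(self.boundaries, self.boundaries[1:])):
            raise ValueError("boundaries must be strictly increasing")

    @classmethod
    def two_class(cls, ln_values: np.ndarray) -> "SegmentScheme":
        """Single cut at the median of the ln(EC50) series."""
        med = float(np.median(np.asarray(ln_values, dtype=float)))
        return cls(k=2, boundaries=(med,), labels=(0, 1))

    @classmethod
    def three_class(cls, ln_values: np.ndarray) -> "SegmentScheme":
        """Cuts at EC50 = 1 (ln = 0) and the median of the ln(EC50) series."""
        med = float(np.median(np.asarray(ln_values, dtype=float)))
        if med == 0.0:
            raise ValueError(
                "three-class scheme degenerates when the median ln(EC50) is exactly 0"
            )
        lo, hi = sorted((0.0, med))
        return cls(k=3, boundaries=(lo, hi), labels=(0, 1, 2))

    @classmethod
    def from_records(cls, records: list[PeptideRecord], k: int) -> "SegmentScheme":
        ln_values = np.array([r.ln_ec50 for r in records])
        if k == 2:
            return cls.two_class(ln_values)
        if k == 3:
            return cls.three_class(ln_values)
        raise ValueError(f"k must be 2 or 3, got {k}")

    def assign(self, ln_value: float | np.ndarray) -> np.ndarray:
        """Label(s) for ln(EC50) value(s) under the half-open convention."""
        return np.searchsorted(np.asarray(self.boundaries), ln_value, side="right")


def assign_labels(records: list[PeptideRecord], scheme: SegmentScheme) -> np.ndarray:
    """Segment label of each record's measured activity."""
    ln_values = np.array([r.ln_ec50 for r in records])
    return scheme.assign(ln_values).astype(int)


def featurize(sequence: str) -> np.ndarray:
    """The 8 sequence descriptors for one peptide (see module docstring)."""
    enc = encode_sequence(sequence)
    digits = np.asarray(enc.digits, dtype=float)
    length = len(digits)
    counts = np.bincount(enc.digits, minlength=21)[1:]
    freqs = counts / length
    return np.array(
        [
            float(np.count_nonzero(counts)) / length,  # distinct-residue fraction
            float(freqs.max()),                         # dominant-residue frequency
            float(digits.mean()),
            float(digits.std()),
            enc.log_code,
            float(digits[0]),
            float(length),
            float(digits[-1]),
        ]
    )


def featurize_records(records: list[PeptideRecord]) -> np.ndarray:
    return np.vstack([featurize(r.sequence) for r in records])


def train_svm(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int,
    test_fraction: float = 0.3,
    C: float = 1.0,
    gamma: str | float = "scale",
) -> tuple[Pipeline, float]:
    """Train the RBF-kernel SVM on a seeded stratified train/test split.

    Features are standardized inside the pipeline.  The 70/30 split mirrors
    the reference protocol's train/test proportion.  Returns the fitted
    pipeline and its held-out accuracy.
    """
    X = np.asarray(features, dtype=float)
    yl = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    if len(np.unique(yl)) < 2:
        raise ValueError("training labels contain a single class")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, yl, test_size=test_fraction, random_state=seed, stratify=yl
    )
    clf = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed)),
        ]
    )
    clf.fit(X_tr, y_tr)
    accuracy = float(clf.score(X_te, y_te))
    return clf, accuracy
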