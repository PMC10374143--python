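"""Data-complexity measures: F3 (feature overlap), N2 (neighborhood) and
C2 (class balance), each oriented so that higher values mean a harder
classification problem, and each bounded in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .datasets import LabeledDataset


@dataclass(frozen=True)
class ComplexityProfile:
    """F3/N2/C2 triple for one dataset."""

    f3: float
    n2: float
    c2: float

    def as_dict(self) -> dict[str, float]:
        return {"f3": self.f3, "n2": self.n2, "c2": self.c2}


def f3(data: LabeledDataset) -> float:
    """Maximum individual feature efficiency, complexity-oriented.

    Per feature, the overlap region is [max of class minima, min of class
    maxima]; F3 is the smallest (over features) fraction of rows falling
    inside that region.  0 means one feature separates the classes
    perfectly; 1 means every feature's class ranges coincide fully.
    """
    classes = np.unique(data.y)
    if classes.size < 2:
        raise ValueError("F3 requires both classes present")
    best = 1.0
    for j in range(data.n_features):
        col = data.X[:, j]
        lo = max(col[data.y == c].min() for c in classes)
        hi = min(col[data.y == c].max() for c in classes)
        inside = 0 if lo > hi else int(((col >= lo) & (col <= hi)).sum())
        best = min(best, inside / data.n)
    return best


def n2(data: LabeledDataset) -> float:
    """Intra/inter-class nearest-neighbor distance ratio, mapped to [0, 1].

    r = sum of distances to the nearest same-class neighbor over the sum of
    distances to the nearest other-class neighbor; N2 = r / (1 + r).
    """
    classes = np.unique(data.y)
    if classes.size < 2 or any((data.y == c).sum() < 2 for c in classes):
        raise ValueError("N2 requires at least 2 rows per class")
    d = cdist(data.X, data.X)
    np.fill_diagonal(d, np.inf)
    same = data.y[:, None] == data.y[None, :]
    intra = np.where(same, d, np.inf).min(axis=1)
    inter = np.where(~same, d, np.inf).min(axis=1)
    if inter.sum() == 0:
        warnings.warn("N2: all cross-class nearest distances are zero; returning 0")
        return 0.0
    r = intra.sum() / inter.sum()
    return r / (1.0 + r)


def c2(data: LabeledDataset) -> float:
    """Class-balance complexity index.

    IRm = ((C-1)/C) * sum_c n_c / (n - n_c);  C2 = 1 - 1/IRm.
    0 for balanced data, approaching 1 as imbalance grows.
    """
    classes, counts = np.unique(data.y, return_counts=True)
    C = classes.size
    if C < 2:
        raise ValueError("C2 requires at least 2 classes")
    n = counts.sum()
    irm = (C - 1) / C * float((counts / (n - counts)).sum())
    return 1.0 - 1.0 / irm


def profile(data: LabeledDataset) -> ComplexityProfile:
    """All three measures for one dataset."""
    return ComplexityProfile(f3=f3(data), n2=n2(data), c2=c2(data))


TERTILES = "tertiles"
TOP25 = "top25"
BOTTOM25 = "bottom25"


def stratify(values, rule: str = TERTILES) -> np.ndarray:
    """Group datasets by a complexity measure.

    ``tertiles`` returns integer bins 0/1/2 of (approximately) equal
    frequency; ``top25`` / ``bottom25`` return a boolean flag for
    membership in the stated quartile.  Quantiles use inclusive linear
    interpolation; tied values all land on the same side of a cut.
    """
    values = np.asarray(values, dtype=float)
    if rule == TERTILES:
        if np.unique(values).size == 1:
            warnings.warn("stratify: constant values; single tertile bin")
            return np.zeros(values.size, dtype=int)
        q1, q2 = np.quantile(values, [1 / 3, 2 / 3])
        return (values > q1).astype(int) + (values > q2).astype(int)
    if rule in (TOP25, BOTTOM25):
        if values.size < 4:
            raise ValueError("quartile rules need at least 4 datasets")
        if np.unique(values).size == 1:
            warnings.warn("stratify: constant values; flagging all datasets")
            return np.ones(values.size, dtype=bool)
        if rule == TOP25:
            return values >= np.quantile(values, 0.75)
        return values <= np.quantile(values, 0.25)
    raise ValueError(f"unknown stratification rule {rule!r}")
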