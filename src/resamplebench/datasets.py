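"""Core data containers shared by the simulator, resamplers and runners.

The package works on binary-classification tables in which class ``1`` is,
by convention, the minority (positive) class and class ``0`` the majority.
A :class:`LabeledDataset` is a thin wrapper around a feature matrix and a
label vector; per-row provenance tags let hybrid resamplers report how many
original versus synthetic rows they deleted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MINORITY = 1
MAJORITY = 0

#: provenance tags
ORIGINAL = "original"
SYNTHETIC = "synthetic"


@dataclass
class LabeledDataset:
    """A feature matrix with binary labels (1 = minority class).

    Parameters
    ----------
    X
        Feature matrix of shape ``(n, p)``, float.
    y
        Label vector of shape ``(n,)`` with values in ``{0, 1}``.
    feature_names
        Column names; defaults to ``X1..Xp``.
    eta
        Optional per-row response value in ``(0, 1)`` kept for diagnostics
        by the domain simulator.
    provenance
        Optional per-row tag, ``"original"`` or ``"synthetic"``.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    eta: np.ndarray | None = None
    provenance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X.reshape(-1, 1)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]}"
            )
        if self.y.size and not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be 0 (majority) or 1 (minority)")
        if not self.feature_names:
            self.feature_names = [f"X{j + 1}" for j in range(self.X.shape[1])]
        if self.eta is not None:
            self.eta = np.asarray(self.eta, dtype=float)
        if self.provenance is not None:
            self.provenance = np.asarray(self.provenance, dtype=object)

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def minority_count(self) -> int:
        return int((self.y == MINORITY).sum())

    @property
    def majority_count(self) -> int:
        return int((self.y == MAJORITY).sum())

    @property
    def imbalance_ratio(self) -> float:
        """Majority count divided by minority count (IR)."""
        if self.minority_count == 0:
            return float("inf")
        return self.majority_count / self.minority_count

    def class_indices(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.y == label)

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        """Row subset preserving eta/provenance side-car arrays."""
        idx = np.asarray(idx)
        return LabeledDataset(
            X=self.X[idx],
            y=self.y[idx],
            feature_names=list(self.feature_names),
            eta=None if self.eta is None else self.eta[idx],
            provenance=None if self.provenance is None else self.provenance[idx],
        )

    def with_provenance(self, default: str = ORIGINAL) -> "LabeledDataset":
        if self.provenance is not None:
            return self
        return replace(self, provenance=np.full(self.n, default, dtype=object))

    # -- I/O -------------------------------------------------------------
    def to_frame(self, include_eta: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df["y"] = self.y
        if include_eta and self.eta is not None:
            df["eta"] = self.eta
        return df

    def to_csv(self, path: str | Path, include_eta: bool = True) -> None:
        self.to_frame(include_eta=include_eta).to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label_col: str = "y") -> "LabeledDataset":
        if label_col not in df.columns:
            raise ValueError(f"label column {label_col!r} not found")
        eta = df["eta"].to_numpy() if "eta" in df.columns else None
        feats = [c for c in df.columns if c not in (label_col, "eta")]
        return cls(
            X=df[feats].to_numpy(dtype=float),
            y=df[label_col].to_numpy(),
            feature_names=feats,
            eta=eta,
        )

    @classmethod
    def from_csv(cls, path: str | Path, label_col: str = "y") -> "LabeledDataset":
        return cls.from_frame(pd.read_csv(path), label_col=label_col)


@dataclass
class ResampleResult:
    """Output of a resampling method.

    ``added`` and ``removed`` count rows per class label; the dataset's
    ``provenance`` array tags every surviving row as original or synthetic.
    """

    dataset: LabeledDataset
    added: dict[int, int] = field(default_factory=lambda: {0: 0, 1: 0})
    removed: dict[int, int] = field(default_factory=lambda: {0: 0, 1: 0})

    @property
    def n_added(self) -> int:
        return sum(self.added.values())

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())
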