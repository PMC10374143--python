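"""Synthetic imbalanced-domain generator.

The generative model draws six jointly Gaussian variables with a common
pairwise correlation rho (default 0.3), binarises the last three at the
30/20/15% quantiles, and pushes a weighted sum of the six features plus a
standard-normal noise term through a sigmoid to obtain a response
eta in (0, 1):

    eta = sigmoid(1.1*X1 + 0.9*X2 + 0.7*X3 + X4 + X5 - X6 + eps)

A *backbone model* partitions [0, 1) into 2**c equal intervals, each tagged
minority or majority.  Domain complexity is controlled by c and by the
layout of the tags (low: c=1; medium: c=2 alternating; extreme: c=2 with
the two minority intervals pushed to the outer ends), sample size by the
level s in {1, 3, 5} and class imbalance by the level i in {1, 3, 5}
through per-interval quotas:

    majority interval quota = round( (5000/32) * 2**s / 2**c )
    minority interval quota = round( (5000/32) * 2**s / 2**c / (32 / 2**i) )

Rows are produced by rejection sampling until every interval quota is met
exactly, so realised class counts are deterministic.  The full factorial
of 3 complexity x 3 size x 3 imbalance levels gives 27 domains.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .datasets import MAJORITY, MINORITY, LabeledDataset

# -- generative constants ------------------------------------------------

#: coefficients of the linear predictor, in feature order X1..X6
ETA_COEFFS = np.array([1.1, 0.9, 0.7, 1.0, 1.0, -1.0])

#: latent thresholds: X_j = 0 iff latent_j < Phi^{-1}(q_j)
BINARY_ZERO_PROBS = (0.3, 0.2, 0.15)

#: base interval size before size/complexity scaling
QUOTA_BASE = 5000.0 / 32.0

COMPLEXITY_LEVELS = ("low", "medium", "extreme")
SIZE_LEVELS = (1, 3, 5)
IMBALANCE_LEVELS = (1, 3, 5)

#: minority/majority tags per eta-interval, low to high interval order
DEFAULT_LAYOUTS = {
    "low": ("MAJ", "MIN"),
    "medium": ("MAJ", "MIN", "MAJ", "MIN"),
    "extreme": ("MIN", "MAJ", "MAJ", "MIN"),
}

_BATCH_SIZE = 4096
_MAX_DRAWS = 10_000_000


@dataclass(frozen=True)
class DomainSpec:
    """Identifies one simulated domain: (complexity, size, imbalance)."""

    complexity_level: str
    s: int
    i: int
    rho: float = 0.3
    seed: int = 0
    layout: tuple[str, ...] | None = None  # override MIN/MAJ interval tags

    def __post_init__(self) -> None:
        if self.complexity_level not in COMPLEXITY_LEVELS:
            raise ValueError(f"unknown complexity level {self.complexity_level!r}")
        if self.s not in SIZE_LEVELS:
            raise ValueError(f"size level s must be one of {SIZE_LEVELS}, got {self.s}")
        if self.i not in IMBALANCE_LEVELS:
            raise ValueError(
                f"imbalance level i must be one of {IMBALANCE_LEVELS}, got {self.i}"
            )
        if not -0.2 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1/5, 1) for a valid 6-dim model")

    @property
    def c(self) -> int:
        """Interval exponent: backbone has 2**c intervals."""
        return 1 if self.complexity_level == "low" else 2

    @property
    def name(self) -> str:
        return f"{self.complexity_level}_s{self.s}_i{self.i}"

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["layout"] is not None:
            d["layout"] = list(d["layout"])
        return d


@dataclass
class BackboneModel:
    """Ordered partition of eta in [0, 1) into equal-width class intervals."""

    edges: np.ndarray  # (m+1,) interval boundaries, edges[0]=0, edges[-1]=1
    classes: tuple[int, ...]  # per-interval label (MINORITY / MAJORITY)
    quotas: tuple[int, ...]  # per-interval sample quota

    def __post_init__(self) -> None:
        m = len(self.classes)
        if len(self.quotas) != m or len(self.edges) != m + 1:
            raise ValueError("edges/classes/quotas lengths inconsistent")
        if MINORITY not in self.classes or MAJORITY not in self.classes:
            raise ValueError("backbone needs at least one interval of each class")
        if any(q < 0 for q in self.quotas):
            raise ValueError("quotas must be non-negative")

    @property
    def n_intervals(self) -> int:
        return len(self.classes)

    @property
    def total(self) -> int:
        return int(sum(self.quotas))

    def class_total(self, label: int) -> int:
        return int(sum(q for q, c in zip(self.quotas, self.classes) if c == label))

    def interval_of(self, eta: np.ndarray) -> np.ndarray:
        """Interval index per row; intervals are [a, b) with the last closed at 1."""
        idx = np.searchsorted(self.edges, eta, side="right") - 1
        return np.clip(idx, 0, self.n_intervals - 1)


# -- elementary operations ----------------------------------------------


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def sample_latent(
    n: int, rho: float = 0.3, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``n`` samples of the 6-variate equicorrelated standard Gaussian.

    Every marginal is N(0, 1) and every off-diagonal pair has population
    correlation ``rho``.  The 6x6 equicorrelation matrix is positive
    definite iff rho > -1/5 (and rho < 1).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not -0.2 < rho < 1.0:
        raise ValueError(f"rho={rho} does not give a positive-definite matrix")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov = np.full((6, 6), rho)
    np.fill_diagonal(cov, 1.0)
    return rng.multivariate_normal(np.zeros(6), cov, size=n, method="cholesky")


def discretize(latent: np.ndarray) -> np.ndarray:
    """Binarise latent columns 4-6 at the Phi^{-1}(0.3/0.2/0.15) thresholds.

    ``X_{3+j} = 0`` iff the latent draw falls below the threshold, else 1;
    the first three columns pass through unchanged.
    """
    latent = np.asarray(latent, dtype=float)
    out = latent.copy()
    for j, q in enumerate(BINARY_ZERO_PROBS):
        out[:, 3 + j] = (latent[:, 3 + j] >= norm.ppf(q)).astype(float)
    return out


def compute_eta(features: np.ndarray, epsilon: np.ndarray | float) -> np.ndarray:
    """Sigmoid response of the linear predictor plus noise, strictly in (0, 1)."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    z = features @ ETA_COEFFS + np.asarray(epsilon, dtype=float)
    z = np.clip(z, -36.0, 36.0)  # guard: keeps eta strictly inside (0,1) in float64
    return 1.0 / (1.0 + np.exp(-z))


def interval_quota(c: int, s: int, i: int, interval_class: int) -> int:
    """Per-interval sample quota for the given complexity/size/imbalance levels.

    The divisor-free formula gives the majority interval quota; dividing by
    ``32 / 2**i`` gives the minority interval quota (i = 5 yields IR = 1).
    """
    if c not in (1, 2):
        raise ValueError(f"c must be 1 or 2, got {c}")
    if s not in SIZE_LEVELS or i not in IMBALANCE_LEVELS:
        raise ValueError(f"s and i must be in {{1,3,5}}, got s={s}, i={i}")
    base = QUOTA_BASE * (2**s) / (2**c)
    if interval_class == MAJORITY:
        return round_half_away(base)
    if interval_class == MINORITY:
        return round_half_away(base / (32.0 / 2**i))
    raise ValueError(f"interval_class must be 0 or 1, got {interval_class}")


def build_backbone(
    complexity_level: str,
    s: int,
    i: int,
    layout: tuple[str, ...] | None = None,
) -> BackboneModel:
    """Backbone with the conventional MIN/MAJ layout for each complexity level.

    low:     [0,.5) MAJ | [.5,1] MIN
    medium:  MAJ | MIN | MAJ | MIN          (alternating quarters)
    extreme: MIN | MAJ | MAJ | MIN          (minority clusters at the ends)

    ``layout`` overrides the tag sequence (e.g. ``("MAJ","MIN","MAJ","MIN")``).
    """
    spec = DomainSpec(complexity_level, s, i, layout=tuple(layout) if layout else None)
    tags = layout if layout is not None else DEFAULT_LAYOUTS[complexity_level]
    tags = tuple(str(t).upper() for t in tags)
    if any(t not in ("MIN", "MAJ") for t in tags):
        raise ValueError(f"layout tags must be MIN or MAJ, got {tags}")
    m = len(tags)
    if m != 2**spec.c:
        raise ValueError(f"layout length {m} != 2**c = {2 ** spec.c}")
    classes = tuple(MINORITY if t == "MIN" else MAJORITY for t in tags)
    quotas = tuple(interval_quota(spec.c, s, i, cls) for cls in classes)
    return BackboneModel(edges=np.linspace(0.0, 1.0, m + 1), classes=classes, quotas=quotas)


# -- domain generation ---------------------------------------------------


def _fill_quotas(
    backbone: BackboneModel,
    quotas: tuple[int, ...],
    rho: float,
    rng: np.random.Generator,
) -> LabeledDataset:
    """Rejection-sample rows until every interval quota is met exactly."""
    needed = np.array(quotas, dtype=int)
    rows_X: list[np.ndarray] = []
    rows_eta: list[np.ndarray] = []
    rows_y: list[np.ndarray] = []
    drawn = 0
    while needed.sum() > 0:
        if drawn >= _MAX_DRAWS:
            raise RuntimeError(
                f"interval quotas unreachable after {drawn} draws: still need {needed}"
            )
        batch = min(_BATCH_SIZE, _MAX_DRAWS - drawn)
        latent = sample_latent(batch, rho=rho, seed=rng)
        feats = discretize(latent)
        eps = rng.standard_normal(batch)
        eta = compute_eta(feats, eps)
        iv = backbone.interval_of(eta)
        drawn += batch
        # accept rows interval by interval, preserving draw order
        for j in np.flatnonzero(needed):
            take = np.flatnonzero(iv == j)[: needed[j]]
            if take.size == 0:
                continue
            rows_X.append(feats[take])
            rows_eta.append(eta[take])
            rows_y.append(np.full(take.size, backbone.classes[j], dtype=int))
            needed[j] -= take.size
    if rows_X:
        X = np.vstack(rows_X)
        eta_all = np.concatenate(rows_eta)
        y = np.concatenate(rows_y)
    else:  # all-zero quotas (empty test set request)
        X = np.empty((0, 6))
        eta_all = np.empty(0)
        y = np.empty(0, dtype=int)
    return LabeledDataset(X=X, y=y, eta=eta_all)


def generate_domain(spec: DomainSpec) -> LabeledDataset:
    """Generate one training domain; class counts equal the summed quotas."""
    backbone = build_backbone(spec.complexity_level, spec.s, spec.i, spec.layout)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    return _fill_quotas(backbone, backbone.quotas, spec.rho, rng)


def _rescale_quotas(quotas: tuple[int, ...], total: int) -> tuple[int, ...]:
    """Proportional rescale to an exact total via largest-remainder rounding."""
    if total == 0:
        return tuple(0 for _ in quotas)
    src_total = sum(quotas)
    raw = [q * total / src_total for q in quotas]
    floors = [int(math.floor(r)) for r in raw]
    shortfall = total - sum(floors)
    order = sorted(range(len(raw)), key=lambda j: (-(raw[j] - floors[j]), j))
    for j in order[:shortfall]:
        floors[j] += 1
    return tuple(floors)


def generate_test_set(spec: DomainSpec, total: int = 5000) -> LabeledDataset:
    """Matched test set: same backbone layout, quotas rescaled to ``total``.

    The imbalance ratio matches the training domain's within rounding; the
    random stream is independent of the training stream for the same seed.
    """
    if total < 0:
        raise ValueError("total must be >= 0")
    backbone = build_backbone(spec.complexity_level, spec.s, spec.i, spec.layout)
    quotas = _rescale_quotas(backbone.quotas, total)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    return _fill_quotas(backbone, quotas, spec.rho, rng)


def enumerate_domains(base_seed: int = 0, rho: float = 0.3) -> list[DomainSpec]:
    """The full 3 x 3 x 3 factorial of domain specs, in stable order.

    Ordering: complexity (low, medium, extreme) outermost, then s, then i;
    each spec gets seed ``base_seed + index``.
    """
    specs = []
    idx = 0
    for level in COMPLEXITY_LEVELS:
        for s in SIZE_LEVELS:
            for i in IMBALANCE_LEVELS:
                specs.append(
                    DomainSpec(level, s, i, rho=rho, seed=base_seed + idx)
                )
                idx += 1
    return specs


def write_domain(spec: DomainSpec, outdir: str | Path, test_size: int = 0) -> dict:
    """Write a domain CSV (+ optional test CSV) and a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = generate_domain(spec)
    data.to_csv(outdir / f"{spec.name}.csv")
    manifest = {
        "spec": spec.to_dict(),
        "n": data.n,
        "n_majority": data.majority_count,
        "n_minority": data.minority_count,
        "imbalance_ratio": data.imbalance_ratio,
    }
    if test_size > 0:
        test = generate_test_set(spec, total=test_size)
        test.to_csv(outdir / f"{spec.name}_test.csv")
        manifest["test_n"] = test.n
    with open(outdir / f"{spec.name}.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
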