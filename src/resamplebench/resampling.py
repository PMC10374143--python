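"""From-scratch resampling methods for imbalanced binary classification.

Three families are provided, all operating on a :class:`LabeledDataset`
(label 1 = minority) and returning a :class:`ResampleResult`:

* **oversampling** — random duplication, SMOTE, ADASYN, Borderline-SMOTE;
  synthetic rows are convex combinations of two minority rows.
* **undersampling** — random deletion, NearMiss-3, Tomek-link removal,
  CNN condensation, ENN / RENN / ALL-KNN editing, OSS, NCR and the
  instance-hardness threshold; output rows are a subset of input rows.
* **filtering (hybrid)** — SMOTE followed by a cleaning pass (Tomek links,
  ENN on both classes, or the iterative-partitioning filter), which may
  delete both original and synthetic rows.

All neighbor queries use Euclidean distance on the raw feature columns
(binary features participate as 0/1); ties are broken toward the lower row
index and a point is never its own neighbor.  Every method is deterministic
for a fixed seed.
"""

from __future__ import annotations

import logging
from typing import Callable

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .datasets import (
    MAJORITY,
    MINORITY,
    ORIGINAL,
    SYNTHETIC,
    LabeledDataset,
    ResampleResult,
)
from .simulate import round_half_away

logger = logging.getLogger(__name__)

EDIT_MAJORITY = "majority"
EDIT_ALL = "all"


# -- neighbor machinery --------------------------------------------------


def neighbor_indices(
    query: np.ndarray,
    candidates: np.ndarray,
    k: int,
    exclude_self: np.ndarray | None = None,
) -> np.ndarray:
    """Indices (into ``candidates``) of the k nearest candidates per query row.

    Euclidean metric; ties broken toward the lower candidate index via a
    stable sort.  ``exclude_self[q]`` gives the candidate index that is the
    query row itself and must not appear in its own neighbor list.
    """
    d = cdist(np.atleast_2d(query), np.atleast_2d(candidates))
    if exclude_self is not None:
        d[np.arange(d.shape[0]), exclude_self] = np.inf
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k]


def _self_knn(X: np.ndarray, k: int) -> np.ndarray:
    """k nearest neighbors of each row among all rows, self excluded."""
    return neighbor_indices(X, X, k, exclude_self=np.arange(X.shape[0]))


def _require_both_classes(data: LabeledDataset, method: str) -> None:
    if data.minority_count == 0 or data.majority_count == 0:
        raise ValueError(f"{method}: both classes must be non-empty")


def _undersample_result(data: LabeledDataset, keep_idx: np.ndarray) -> ResampleResult:
    """Build a ResampleResult for a pure deletion of the complement of keep_idx."""
    data = data.with_provenance()
    keep_idx = np.asarray(keep_idx, dtype=int)
    keep_mask = np.zeros(data.n, dtype=bool)
    keep_mask[keep_idx] = True
    removed = {
        MAJORITY: int(((~keep_mask) & (data.y == MAJORITY)).sum()),
        MINORITY: int(((~keep_mask) & (data.y == MINORITY)).sum()),
    }
    return ResampleResult(dataset=data.subset(keep_idx), removed=removed)


def _append_synthetic(
    data: LabeledDataset, synth_X: np.ndarray, label: int
) -> ResampleResult:
    data = data.with_provenance()
    n_new = synth_X.shape[0]
    out = LabeledDataset(
        X=np.vstack([data.X, synth_X]) if n_new else data.X.copy(),
        y=np.concatenate([data.y, np.full(n_new, label, dtype=int)]),
        feature_names=list(data.feature_names),
        provenance=np.concatenate(
            [data.provenance, np.full(n_new, SYNTHETIC, dtype=object)]
        ),
    )
    return ResampleResult(dataset=out, added={MAJORITY: 0, MINORITY: n_new})


def _oversample_deficit(data: LabeledDataset, target_ratio: float) -> int:
    """Synthetic minority rows needed so minority/majority = target_ratio."""
    return max(0, round_half_away(target_ratio * data.majority_count) - data.minority_count)


def _undersample_keep_count(data: LabeledDataset, target_ratio: float) -> int:
    """Majority rows to keep so minority/majority = target_ratio."""
    want = round_half_away(data.minority_count / target_ratio)
    return min(data.majority_count, max(0, want))


# -- oversampling --------------------------------------------------------


def random_oversample(
    data: LabeledDataset, target_ratio: float = 1.0, seed: int | None = None
) -> ResampleResult:
    """Duplicate minority rows uniformly at random with replacement."""
    _require_both_classes(data, "random oversampling")
    rng = np.random.default_rng(seed)
    n_new = _oversample_deficit(data, target_ratio)
    minority = data.class_indices(MINORITY)
    picks = rng.integers(0, minority.size, size=n_new)
    return _append_synthetic(data, data.X[minority[picks]], MINORITY)


def _smote_points(
    X_min: np.ndarray,
    seed_rows: np.ndarray,
    n_new: int,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generate ``n_new`` interpolated points seeded from ``seed_rows``.

    Each point: pick a random seed row x_i, one of its k nearest minority
    neighbors x_zi, and return x_i + u * (x_zi - x_i) with u ~ U(0, 1).
    """
    if n_new == 0:
        return np.empty((0, X_min.shape[1]))
    k_eff = min(k, X_min.shape[0] - 1)
    # neighbors of the seed rows within the whole minority set
    nn = neighbor_indices(X_min[seed_rows], X_min, k_eff, exclude_self=seed_rows)
    si = rng.integers(0, seed_rows.size, size=n_new)
    ni = rng.integers(0, k_eff, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    base = X_min[seed_rows[si]]
    neigh = X_min[nn[si, ni]]
    return base + u[:, None] * (neigh - base)


def smote(
    data: LabeledDataset,
    k: int = 5,
    target_ratio: float = 1.0,
    seed: int | None = None,
) -> ResampleResult:
    """Synthetic minority oversampling by random interpolation between a
    minority row and one of its k minority nearest neighbors."""
    _require_both_classes(data, "SMOTE")
    if data.minority_count < 2:
        raise ValueError("SMOTE needs at least 2 minority rows")
    rng = np.random.default_rng(seed)
    n_new = _oversample_deficit(data, target_ratio)
    minority = data.class_indices(MINORITY)
    X_min = data.X[minority]
    synth = _smote_points(X_min, np.arange(X_min.shape[0]), n_new, k, rng)
    return _append_synthetic(data, synth, MINORITY)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    if total == 0 or weights.sum() == 0:
        return np.zeros(weights.size, dtype=int)
    raw = weights / weights.sum() * total
    floors = np.floor(raw).astype(int)
    short = total - floors.sum()
    frac_order = np.lexsort((np.arange(weights.size), -(raw - floors)))
    floors[frac_order[:short]] += 1
    return floors


def adasyn(
    data: LabeledDataset,
    k: int = 5,
    target_ratio: float = 1.0,
    seed: int | None = None,
) -> ResampleResult:
    """Density-adaptive SMOTE: harder minority rows get more synthetic mass.

    Hardness r_i = fraction of majority points among the k nearest neighbors
    of minority row i over the whole dataset; the synthetic budget is split
    proportionally to r (largest-remainder rounding).  If every r_i is 0 the
    allocation falls back to uniform.
    """
    _require_both_classes(data, "ADASYN")
    if data.minority_count < 2:
        raise ValueError("ADASYN needs at least 2 minority rows")
    rng = np.random.default_rng(seed)
    G = _oversample_deficit(data, target_ratio)
    minority = data.class_indices(MINORITY)
    if G == 0:
        return _append_synthetic(data, np.empty((0, data.n_features)), MINORITY)
    k_all = min(k, data.n - 1)
    nn_all = neighbor_indices(data.X[minority], data.X, k_all, exclude_self=minority)
    r = (data.y[nn_all] == MAJORITY).sum(axis=1) / k_all
    if r.sum() == 0:
        logger.warning("ADASYN: all hardness ratios zero; using uniform allocation")
        r = np.ones_like(r)
    alloc = _largest_remainder(r, G)
    X_min = data.X[minority]
    k_eff = min(k, X_min.shape[0] - 1)
    nn_min = neighbor_indices(X_min, X_min, k_eff, exclude_self=np.arange(X_min.shape[0]))
    pieces = []
    for i in np.flatnonzero(alloc):
        ni = rng.integers(0, k_eff, size=alloc[i])
        u = rng.uniform(0.0, 1.0, size=alloc[i])
        pieces.append(X_min[i] + u[:, None] * (X_min[nn_min[i, ni]] - X_min[i]))
    synth = np.vstack(pieces) if pieces else np.empty((0, data.n_features))
    return _append_synthetic(data, synth, MINORITY)


def borderline_smote(
    data: LabeledDataset,
    m: int = 5,
    k: int = 5,
    target_ratio: float = 1.0,
    seed: int | None = None,
) -> ResampleResult:
    """Borderline-SMOTE (variant 1): only DANGER minority rows seed SMOTE.

    A minority row is in DANGER when at least half but not all of its m
    nearest neighbors (over all rows) belong to the majority class; rows
    with all-majority neighborhoods are treated as noise and excluded.
    """
    _require_both_classes(data, "Borderline-SMOTE")
    if data.minority_count < 2:
        raise ValueError("Borderline-SMOTE needs at least 2 minority rows")
    rng = np.random.default_rng(seed)
    minority = data.class_indices(MINORITY)
    m_eff = min(m, data.n - 1)
    nn_all = neighbor_indices(data.X[minority], data.X, m_eff, exclude_self=minority)
    n_maj = (data.y[nn_all] == MAJORITY).sum(axis=1)
    danger = np.flatnonzero((n_maj >= m_eff / 2.0) & (n_maj < m_eff))
    if danger.size == 0:
        logger.warning("Borderline-SMOTE: DANGER set empty; returning input unchanged")
        return _append_synthetic(data, np.empty((0, data.n_features)), MINORITY)
    n_new = _oversample_deficit(data, target_ratio)
    synth = _smote_points(data.X[minority], danger, n_new, k, rng)
    return _append_synthetic(data, synth, MINORITY)


# -- undersampling -------------------------------------------------------


def random_undersample(
    data: LabeledDataset, target_ratio: float = 1.0, seed: int | None = None
) -> ResampleResult:
    """Drop majority rows uniformly at random without replacement."""
    _require_both_classes(data, "random undersampling")
    rng = np.random.default_rng(seed)
    majority = data.class_indices(MAJORITY)
    n_keep = _undersample_keep_count(data, target_ratio)
    kept_maj = rng.choice(majority, size=n_keep, replace=False)
    keep = np.sort(np.concatenate([data.class_indices(MINORITY), kept_maj]))
    return _undersample_result(data, keep)


def nearmiss3(
    data: LabeledDataset,
    m_keep: int = 3,
    n_dist: int = 3,
    target_ratio: float = 1.0,
) -> ResampleResult:
    """Two-stage NearMiss-3 heuristic undersampling of the majority class.

    Stage 1 retains, for each minority row, its ``m_keep`` nearest majority
    rows (union).  Stage 2 ranks the retained rows by their average distance
    to their ``n_dist`` nearest minority rows and keeps the smallest until
    the target majority count is reached.
    """
    _require_both_classes(data, "NearMiss-3")
    minority = data.class_indices(MINORITY)
    majority = data.class_indices(MAJORITY)
    m_eff = min(m_keep, majority.size)
    nn_maj = neighbor_indices(data.X[minority], data.X[majority], m_eff)
    retained = np.unique(majority[nn_maj.ravel()])
    n_eff = min(n_dist, minority.size)
    d_min = cdist(data.X[retained], data.X[minority])
    d_sorted = np.sort(d_min, axis=1)[:, :n_eff]
    avg = d_sorted.mean(axis=1)
    n_target = min(retained.size, _undersample_keep_count(data, target_ratio))
    order = np.lexsort((retained, avg))  # smallest average distance first
    kept_maj = np.sort(retained[order[:n_target]])
    keep = np.sort(np.concatenate([minority, kept_maj]))
    return _undersample_result(data, keep)


def find_tomek_links(data: LabeledDataset) -> list[tuple[int, int]]:
    """All Tomek links: mutual-nearest-neighbor pairs of opposite classes.

    A pair (x, y) with different labels is a link iff no third point z is
    strictly closer to x than y or strictly closer to y than x.
    """
    if data.n < 2:
        raise ValueError("Tomek links need at least 2 rows")
    nn = _self_knn(data.X, 1)[:, 0]
    links = []
    for i in range(data.n):
        j = int(nn[i])
        if j > i and int(nn[j]) == i and data.y[i] != data.y[j]:
            links.append((i, j))
    return links


def tomek_undersample(data: LabeledDataset) -> ResampleResult:
    """Remove the majority member of every Tomek link."""
    links = find_tomek_links(data)
    drop = {i if data.y[i] == MAJORITY else j for i, j in links}
    keep = np.setdiff1d(np.arange(data.n), np.array(sorted(drop), dtype=int))
    return _undersample_result(data, keep)


def _enn_drop_mask(X: np.ndarray, y: np.ndarray, k: int, edit_mask: np.ndarray) -> np.ndarray:
    """Rows (within edit_mask) whose k-NN majority vote disagrees with their label.

    Votes are computed on the full data; ties (k even) keep the row.
    """
    n = X.shape[0]
    k_eff = min(k, n - 1)
    nn = _self_knn(X, k_eff)
    votes_min = (y[nn] == MINORITY).sum(axis=1)
    votes_maj = k_eff - votes_min
    predicted_other = np.where(
        y == MINORITY, votes_maj > votes_min, votes_min > votes_maj
    )
    return predicted_other & edit_mask


def enn_edit(
    data: LabeledDataset, k: int = 3, edit_class: str = EDIT_MAJORITY
) -> ResampleResult:
    """Edited nearest neighbors: delete rows misclassified by their k-NN vote.

    ``edit_class`` selects which rows are editable: ``"majority"`` (the
    undersampling orientation) or ``"all"`` (the hybrid-cleaning
    orientation).  Decisions are computed once on the original data.
    """
    if data.n < k + 1:
        raise ValueError(f"ENN needs at least k+1={k + 1} rows")
    edit_mask = (
        data.y == MAJORITY if edit_class == EDIT_MAJORITY else np.ones(data.n, bool)
    )
    drop = _enn_drop_mask(data.X, data.y, k, edit_mask)
    return _undersample_result(data, np.flatnonzero(~drop))


def renn(
    data: LabeledDataset,
    k: int = 3,
    edit_class: str = EDIT_MAJORITY,
    max_iter: int = 100,
) -> ResampleResult:
    """Repeated ENN until a pass removes nothing (or max_iter)."""
    current = data.with_provenance()
    total_removed = {MAJORITY: 0, MINORITY: 0}
    for _ in range(max_iter):
        step = enn_edit(current, k=k, edit_class=edit_class)
        if step.n_removed == 0:
            break
        for cls in total_removed:
            total_removed[cls] += step.removed[cls]
        current = step.dataset
    return ResampleResult(dataset=current, removed=total_removed)


def all_knn(
    data: LabeledDataset, k_max: int = 3, edit_class: str = EDIT_MAJORITY
) -> ResampleResult:
    """ENN swept over k = 1..k_max; a row removed at any k stays removed."""
    current = data.with_provenance()
    total_removed = {MAJORITY: 0, MINORITY: 0}
    for k in range(1, k_max + 1):
        if current.n < k + 1:
            break
        step = enn_edit(current, k=k, edit_class=edit_class)
        for cls in total_removed:
            total_removed[cls] += step.removed[cls]
        current = step.dataset
    return ResampleResult(dataset=current, removed=total_removed)


def cnn_condense(data: LabeledDataset, seed: int | None = None) -> ResampleResult:
    """Condensed nearest neighbor: smallest 1-NN-consistent majority subset.

    The store starts with all minority rows plus one random majority row;
    remaining majority rows are scanned in seeded random order and added
    whenever the current store's 1-NN rule misclassifies them, repeating
    passes until a full pass adds nothing.
    """
    _require_both_classes(data, "CNN")
    rng = np.random.default_rng(seed)
    minority = data.class_indices(MINORITY)
    majority = data.class_indices(MAJORITY)
    first = rng.choice(majority)
    store = list(minority) + [int(first)]
    pool = [int(i) for i in rng.permutation(np.setdiff1d(majority, [first]))]
    changed = True
    while changed and pool:
        changed = False
        remaining = []
        for i in pool:
            nn = neighbor_indices(data.X[i][None, :], data.X[store], 1)[0, 0]
            if data.y[store[nn]] != data.y[i]:
                store.append(i)
                changed = True
            else:
                remaining.append(i)
        pool = remaining
    return _undersample_result(data, np.sort(np.array(store, dtype=int)))


def oss(data: LabeledDataset, seed: int | None = None) -> ResampleResult:
    """One-sided selection: CNN condensation followed by Tomek-link removal."""
    condensed = cnn_condense(data, seed=seed)
    cleaned = tomek_undersample(condensed.dataset)
    removed = {
        cls: condensed.removed[cls] + cleaned.removed[cls]
        for cls in (MAJORITY, MINORITY)
    }
    return ResampleResult(dataset=cleaned.dataset, removed=removed)


def ncr(data: LabeledDataset, k: int = 3) -> ResampleResult:
    """Neighborhood cleaning rule.

    Rule A deletes majority rows misclassified by their k-NN vote; rule B
    deletes, for each misclassified minority row, the majority rows among
    its k neighbors.  Both rules are evaluated on the original data.
    """
    if data.n < k + 1:
        raise ValueError(f"NCR needs at least k+1={k + 1} rows")
    _require_both_classes(data, "NCR")
    k_eff = min(k, data.n - 1)
    nn = _self_knn(data.X, k_eff)
    votes_min = (data.y[nn] == MINORITY).sum(axis=1)
    votes_maj = k_eff - votes_min
    drop = np.zeros(data.n, dtype=bool)
    # rule A: misclassified majority rows
    drop |= (data.y == MAJORITY) & (votes_min > votes_maj)
    # rule B: majority neighbors of misclassified minority rows
    for i in np.flatnonzero((data.y == MINORITY) & (votes_maj > votes_min)):
        neigh = nn[i]
        drop[neigh[data.y[neigh] == MAJORITY]] = True
    drop &= data.y == MAJORITY  # only majority rows are ever deleted
    return _undersample_result(data, np.flatnonzero(~drop))


def iht(
    data: LabeledDataset,
    learner=None,
    cv_folds: int = 3,
    target_ratio: float = 1.0,
    seed: int | None = None,
) -> ResampleResult:
    """Instance-hardness threshold undersampling.

    Each row's out-of-fold predicted probability of its own class is
    estimated by ``cv_folds``-fold cross-fitting of ``learner`` (default: a
    random forest); the hardest majority rows (lowest probability) are
    removed until the target class ratio is reached.
    """
    _require_both_classes(data, "IHT")
    rng = np.random.default_rng(seed)
    base_seed = int(rng.integers(0, 2**31 - 1))
    if learner is None:
        learner = RandomForestClassifier(n_estimators=50, random_state=base_seed)
    folds = int(min(cv_folds, data.minority_count, data.majority_count))
    prob_own = np.full(data.n, np.nan)
    if folds < 2:
        # too few rows per class to cross-fit: fit once on everything
        model = clone(learner).fit(data.X, data.y)
        prob_own = _prob_of_own_class(model, data.X, data.y)
    else:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=base_seed)
        for train, test in skf.split(data.X, data.y):
            model = clone(learner).fit(data.X[train], data.y[train])
            prob_own[test] = _prob_of_own_class(model, data.X[test], data.y[test])
    majority = data.class_indices(MAJORITY)
    n_keep = _undersample_keep_count(data, target_ratio)
    order = np.lexsort((majority, prob_own[majority]))  # hardest first
    kept_maj = np.sort(majority[order[majority.size - n_keep:]]) if n_keep else np.array([], int)
    keep = np.sort(np.concatenate([data.class_indices(MINORITY), kept_maj]))
    return _undersample_result(data, keep)


def _prob_of_own_class(model, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(X)
    cols = {int(c): j for j, c in enumerate(model.classes_)}
    out = np.zeros(X.shape[0])
    for label, j in cols.items():
        out[y == label] = proba[y == label, j]
    return out


# -- filtering hybrids ---------------------------------------------------


def ipf_filter(
    data: LabeledDataset,
    n_partitions: int = 9,
    max_clean_iters: int = 10,
    seed: int | None = None,
) -> ResampleResult:
    """Iterative-partitioning noise filter.

    Each iteration splits the current rows into ``n_partitions`` stratified
    folds, trains one decision tree per fold, and removes every row
    misclassified by more than half of the trees.  Cleaning stops after
    three consecutive iterations that each remove less than 1% of the
    current rows, or after ``max_clean_iters`` iterations.
    """
    current = data.with_provenance()
    rng = np.random.default_rng(seed)
    total_removed = {MAJORITY: 0, MINORITY: 0}
    calm_streak = 0
    for _ in range(max_clean_iters):
        n = current.n
        votes_wrong = np.zeros(n, dtype=int)
        folds = _partition(current.y, n_partitions, rng)
        n_trees = 0
        for fold in folds:
            if fold.size == 0:
                continue
            tree = DecisionTreeClassifier(random_state=int(rng.integers(2**31 - 1)))
            tree.fit(current.X[fold], current.y[fold])
            votes_wrong += tree.predict(current.X) != current.y
            n_trees += 1
        drop = votes_wrong > n_trees / 2.0
        # never erase a class entirely
        for cls in (MAJORITY, MINORITY):
            cls_mask = current.y == cls
            if drop[cls_mask].all() and cls_mask.any():
                drop &= ~cls_mask
        frac = drop.sum() / n if n else 0.0
        if drop.any():
            for cls in (MAJORITY, MINORITY):
                total_removed[cls] += int((drop & (current.y == cls)).sum())
            current = current.subset(np.flatnonzero(~drop))
        calm_streak = calm_streak + 1 if frac < 0.01 else 0
        if calm_streak >= 3:
            break
    return ResampleResult(dataset=current, removed=total_removed)


def _partition(y: np.ndarray, n_parts: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Stratified random partition into ``n_parts`` folds; one redraw on a
    degenerate (single-class) fold, then an error."""
    n_parts = min(n_parts, y.size)
    classes, counts = np.unique(y, return_counts=True)
    # two-class folds are only achievable when every class has >= n_parts rows
    achievable = classes.size >= 2 and counts.min() >= n_parts
    for attempt in range(2):
        folds: list[list[int]] = [[] for _ in range(n_parts)]
        for cls in classes:
            idx = rng.permutation(np.flatnonzero(y == cls))
            for j, i in enumerate(idx):
                folds[j % n_parts].append(int(i))
        out = [np.array(sorted(f), dtype=int) for f in folds]
        ok = all(np.unique(y[f]).size == classes.size for f in out if f.size)
        if ok or not achievable:
            return out
    raise RuntimeError("could not build partitions with both classes per fold")


def smote_then_clean(
    data: LabeledDataset,
    cleaner: str,
    smote_params: dict | None = None,
    cleaner_params: dict | None = None,
    seed: int | None = None,
) -> ResampleResult:
    """SMOTE to balance, then a cleaning pass over the augmented data.

    ``cleaner`` is one of ``"tomek"`` (both members of every Tomek link are
    removed), ``"enn"`` (ENN editing applied to both classes) or ``"ipf"``
    (iterative-partitioning filter).  Provenance tags survive, so deletions
    of synthetic versus original rows remain countable.
    """
    smote_params = dict(smote_params or {})
    cleaner_params = dict(cleaner_params or {})
    rng = np.random.default_rng(seed)
    over = smote(data, seed=int(rng.integers(2**31 - 1)), **smote_params)
    augmented = over.dataset
    if cleaner == "tomek":
        links = find_tomek_links(augmented)
        drop = sorted({i for pair in links for i in pair})
        keep = np.setdiff1d(np.arange(augmented.n), np.array(drop, dtype=int))
        cleaned = _undersample_result(augmented, keep)
    elif cleaner == "enn":
        cleaner_params.setdefault("edit_class", EDIT_ALL)
        cleaned = enn_edit(augmented, **cleaner_params)
    elif cleaner == "ipf":
        cleaned = ipf_filter(
            augmented, seed=int(rng.integers(2**31 - 1)), **cleaner_params
        )
    else:
        raise ValueError(f"unknown cleaner {cleaner!r}")
    return ResampleResult(
        dataset=cleaned.dataset, added=over.added, removed=cleaned.removed
    )


# -- registry ------------------------------------------------------------

FAMILY_OVERSAMPLING = "oversampling"
FAMILY_UNDERSAMPLING = "undersampling"
FAMILY_FILTERING = "filtering"

#: name -> (callable(data, seed=..., **params), family); names follow the
#: conventional method labels ("SMOTE-TL", "ALL KNN", "NCR", ...)
REGISTRY: dict[str, tuple[Callable[..., ResampleResult], str]] = {
    "Random Oversampling": (random_oversample, FAMILY_OVERSAMPLING),
    "SMOTE": (smote, FAMILY_OVERSAMPLING),
    "ADASYN": (adasyn, FAMILY_OVERSAMPLING),
    "Borderline SMOTE": (borderline_smote, FAMILY_OVERSAMPLING),
    "Random Undersampling": (random_undersample, FAMILY_UNDERSAMPLING),
    "Near-miss": (nearmiss3, FAMILY_UNDERSAMPLING),
    "Tomek Link": (tomek_undersample, FAMILY_UNDERSAMPLING),
    "CNN": (cnn_condense, FAMILY_UNDERSAMPLING),
    "ENN": (enn_edit, FAMILY_UNDERSAMPLING),
    "RENN": (renn, FAMILY_UNDERSAMPLING),
    "ALL KNN": (all_knn, FAMILY_UNDERSAMPLING),
    "OSS": (oss, FAMILY_UNDERSAMPLING),
    "NCR": (ncr, FAMILY_UNDERSAMPLING),
    "IHT": (iht, FAMILY_UNDERSAMPLING),
    "SMOTE-TL": (lambda data, **kw: smote_then_clean(data, "tomek", **kw), FAMILY_FILTERING),
    "SMOTE-ENN": (lambda data, **kw: smote_then_clean(data, "enn", **kw), FAMILY_FILTERING),
    "SMOTE-IPF": (lambda data, **kw: smote_then_clean(data, "ipf", **kw), FAMILY_FILTERING),
}

#: methods whose signature accepts a seed
_SEEDLESS = {"Near-miss", "Tomek Link", "ENN", "RENN", "ALL KNN", "NCR"}


def list_methods(family: str | None = None) -> list[str]:
    return [n for n, (_, fam) in REGISTRY.items() if family in (None, fam)]


def family_of(name: str) -> str:
    return REGISTRY[name][1]


def apply_method(
    name: str, data: LabeledDataset, params: dict | None = None, seed: int | None = None
) -> ResampleResult:
    """Run a registered resampler by name with optional parameter overrides."""
    if name not in REGISTRY:
        raise KeyError(f"unknown resampling method {name!r}; see list_methods()")
    fn, _ = REGISTRY[name]
    kwargs = dict(params or {})
    if name not in _SEEDLESS:
        kwargs.setdefault("seed", seed)
    return fn(data, **kwargs)
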