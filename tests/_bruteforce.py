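"""Independent brute-force oracles for the neighbor-based resamplers and
the ranking metrics.

Everything here is written with explicit Python loops over exhaustive
pairwise distance matrices, deliberately sharing no code with the package
implementations.  Tie-breaking follows the same documented convention
(lower row index wins; a point is not its own neighbor).
"""

from __future__ import annotations

import math

import numpy as np


def dist_matrix(X: np.ndarray) -> list[list[float]]:
    n = len(X)
    return [
        [math.dist(X[i], X[j]) for j in range(n)]
        for i in range(n)
    ]


def knn_of(D, i: int, k: int, candidates=None) -> list[int]:
    """k nearest candidate indices to row i, self excluded, ties by index."""
    cands = [j for j in (candidates if candidates is not None else range(len(D))) if j != i]
    cands.sort(key=lambda j: (D[i][j], j))
    return cands[:k]


def knn_vote(D, y, i: int, k: int) -> int:
    neigh = knn_of(D, i, k)
    ones = sum(1 for j in neigh if y[j] == 1)
    zeros = len(neigh) - ones
    if ones == zeros:
        return int(y[i])  # tie keeps the row's own label
    return 1 if ones > zeros else 0


def bf_enn_removed(X, y, k=3, edit_all=False) -> set[int]:
    D = dist_matrix(X)
    out = set()
    for i in range(len(X)):
        if not edit_all and y[i] != 0:
            continue
        if knn_vote(D, y, i, min(k, len(X) - 1)) != y[i]:
            out.add(i)
    return out


def bf_renn_removed(X, y, k=3, max_iter=100) -> set[int]:
    alive = list(range(len(X)))
    removed: set[int] = set()
    for _ in range(max_iter):
        Xa = [X[i] for i in alive]
        ya = [y[i] for i in alive]
        local = bf_enn_removed(np.asarray(Xa), np.asarray(ya), k=k)
        if not local:
            break
        removed |= {alive[j] for j in local}
        alive = [i for j, i in enumerate(alive) if j not in local]
    return removed


def bf_allknn_removed(X, y, k_max=3) -> set[int]:
    alive = list(range(len(X)))
    removed: set[int] = set()
    for k in range(1, k_max + 1):
        if len(alive) < k + 1:
            break
        Xa = np.asarray([X[i] for i in alive])
        ya = np.asarray([y[i] for i in alive])
        local = bf_enn_removed(Xa, ya, k=k)
        removed |= {alive[j] for j in local}
        alive = [i for j, i in enumerate(alive) if j not in local]
    return removed


def bf_tomek_links(X, y) -> set[tuple[int, int]]:
    D = dist_matrix(X)
    links = set()
    for i in range(len(X)):
        for j in range(i + 1, len(X)):
            if y[i] == y[j]:
                continue
            dij = D[i][j]
            closer_to_i = any(D[i][z] < dij or (D[i][z] == dij and z < j) for z in range(len(X)) if z not in (i, j))
            closer_to_j = any(D[j][z] < dij or (D[j][z] == dij and z < i) for z in range(len(X)) if z not in (i, j))
            if not closer_to_i and not closer_to_j:
                links.add((i, j))
    return links


def bf_ncr_removed(X, y, k=3) -> set[int]:
    D = dist_matrix(X)
    n = len(X)
    k_eff = min(k, n - 1)
    drop = set()
    for i in range(n):
        neigh = knn_of(D, i, k_eff)
        ones = sum(1 for j in neigh if y[j] == 1)
        zeros = k_eff - ones
        if y[i] == 0 and ones > zeros:
            drop.add(i)
        if y[i] == 1 and zeros > ones:
            drop |= {j for j in neigh if y[j] == 0}
    return {i for i in drop if y[i] == 0}


def bf_nearmiss3_kept_majority(X, y, m_keep=3, n_dist=3, n_target=None) -> list[int]:
    D = dist_matrix(X)
    minority = [i for i in range(len(X)) if y[i] == 1]
    majority = [i for i in range(len(X)) if y[i] == 0]
    retained = set()
    for i in minority:
        retained |= set(knn_of(D, i, min(m_keep, len(majority)), candidates=majority))
    if n_target is None:
        n_target = len(minority)
    n_target = min(n_target, len(retained))
    scored = []
    for j in sorted(retained):
        dists = sorted(D[j][i] for i in minority)
        scored.append((sum(dists[: min(n_dist, len(dists))]) / min(n_dist, len(dists)), j))
    scored.sort()
    return sorted(j for _, j in scored[:n_target])


def bf_adasyn_hardness(X, y, k=5) -> list[float]:
    D = dist_matrix(X)
    k_eff = min(k, len(X) - 1)
    out = []
    for i in range(len(X)):
        if y[i] != 1:
            continue
        neigh = knn_of(D, i, k_eff)
        out.append(sum(1 for j in neigh if y[j] == 0) / k_eff)
    return out


def bf_borderline_danger(X, y, m=5) -> list[int]:
    """Minority rows (positions within the minority subset) in the DANGER set."""
    D = dist_matrix(X)
    m_eff = min(m, len(X) - 1)
    danger = []
    pos = 0
    for i in range(len(X)):
        if y[i] != 1:
            continue
        neigh = knn_of(D, i, m_eff)
        n_maj = sum(1 for j in neigh if y[j] == 0)
        if m_eff / 2.0 <= n_maj < m_eff:
            danger.append(pos)
        pos += 1
    return danger


def bf_cnn_store(X, y, seed) -> list[int]:
    """CNN store replicating the package's seeded scan order but with an
    independently coded 1-NN rule."""
    rng = np.random.default_rng(seed)
    minority = [i for i in range(len(X)) if y[i] == 1]
    majority = [i for i in range(len(X)) if y[i] == 0]
    first = int(rng.choice(np.asarray(majority)))
    store = list(minority) + [first]
    pool = [int(i) for i in rng.permutation(np.setdiff1d(np.asarray(majority), [first]))]
    changed = True
    while changed and pool:
        changed = False
        remaining = []
        for i in pool:
            best = min(store, key=lambda s: (math.dist(X[i], X[s]), store.index(s)))
            if y[best] != y[i]:
                store.append(i)
                changed = True
            else:
                remaining.append(i)
        pool = remaining
    return sorted(store)


# -- metric oracles ------------------------------------------------------


def bf_average_precision(scores, labels) -> float:
    """AP = sum over distinct thresholds of (delta recall) * precision."""
    pairs = sorted(zip(scores, labels), key=lambda t: -t[0])
    total_pos = sum(labels)
    ap = 0.0
    tp = fp = 0
    prev_recall = 0.0
    i = 0
    n = len(pairs)
    while i < n:
        j = i
        while j < n and pairs[j][0] == pairs[i][0]:
            tp += pairs[j][1]
            fp += 1 - pairs[j][1]
            j += 1
        recall = tp / total_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


def bf_auroc(scores, labels) -> float:
    """Pair-counting: P(score_pos > score_neg) + 0.5 P(equal)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))
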