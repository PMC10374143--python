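"""Scoring and rank-comparison machinery.

Classifier scores are summarised by the area under the precision-recall
curve (AUPRC, non-interpolated average precision with the minority class
as positive) and the ROC area (AUROC).  Method comparison follows a
rank-difference protocol: within each replicate every method's AUPRC —
including the no-resampling baseline — is ranked (1 = best, average ranks
for ties) and a method's *rank difference* is the baseline's rank minus
its own, so positive values mean resampling improved the standing.
Differences are averaged over replicates and tested with a paired t-test
on the underlying AUPRC values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, ttest_rel
from sklearn.metrics import average_precision_score, roc_auc_score

BASELINE = "none"
ALPHA = 0.05


@dataclass(frozen=True)
class RankRecord:
    """One method's score, rank and rank difference within one replicate."""

    replicate: int
    method: str
    auprc: float
    rank: float
    rank_diff: float


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present to score a ranking")
    return labels


def auprc(scores, labels) -> float:
    """Average precision: AP = sum_k (R_k - R_{k-1}) P_k over thresholds,
    with the minority class (label 1) as positive and ties grouped."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    return float(average_precision_score(labels, scores))


def auroc(scores, labels) -> float:
    """Trapezoidal ROC area (equals the tie-corrected rank-sum statistic)."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    return float(roc_auc_score(labels, scores))


def rank_methods(
    auprc_by_method: dict[str, float],
    baseline: str = BASELINE,
    replicate: int = 0,
) -> list[RankRecord]:
    """Rank one replicate's methods by AUPRC (1 = best, average-rank ties).

    The baseline is part of the ranked pool; rank_diff = baseline rank
    minus method rank, so the baseline's own rank_diff is 0.
    """
    if len(auprc_by_method) < 2:
        raise ValueError("need at least 2 methods (including the baseline) to rank")
    if baseline not in auprc_by_method:
        raise ValueError(f"baseline {baseline!r} missing from the score table")
    names = list(auprc_by_method)
    values = np.array([auprc_by_method[n] for n in names], dtype=float)
    ranks = rankdata(-values, method="average")
    base_rank = ranks[names.index(baseline)]
    return [
        RankRecord(
            replicate=replicate,
            method=n,
            auprc=float(v),
            rank=float(r),
            rank_diff=float(base_rank - r),
        )
        for n, v, r in zip(names, values, ranks)
    ]


def aggregate_ranks(
    records: list[RankRecord],
    method: str,
    baseline: str = BASELINE,
    alpha: float = ALPHA,
) -> dict:
    """Mean rank difference of ``method`` across replicates plus a paired
    t-test on per-replicate (AUPRC_method - AUPRC_baseline).

    Zero-variance differences are flagged non-significant unless every
    difference is non-zero with the same sign (noted in the output).
    """
    by_rep: dict[int, dict[str, RankRecord]] = {}
    for rec in records:
        by_rep.setdefault(rec.replicate, {})[rec.method] = rec
    reps = sorted(r for r, d in by_rep.items() if method in d and baseline in d)
    if len(reps) < 2:
        raise ValueError("need at least 2 replicates with both method and baseline")
    diffs = np.array([by_rep[r][method].auprc - by_rep[r][baseline].auprc for r in reps])
    mean_rank_diff = float(np.mean([by_rep[r][method].rank_diff for r in reps]))
    note = ""
    if np.allclose(diffs, diffs[0]):
        pvalue = float("nan")
        if diffs[0] != 0 and (np.sign(diffs) == np.sign(diffs[0])).all():
            significant = True
            note = "constant non-zero shift; t-test degenerate"
        else:
            significant = False
            note = "zero-variance differences"
    else:
        stat = ttest_rel(
            [by_rep[r][method].auprc for r in reps],
            [by_rep[r][baseline].auprc for r in reps],
        )
        pvalue = float(stat.pvalue)
        significant = bool(pvalue < alpha)
    return {
        "method": method,
        "n_replicates": len(reps),
        "mean_rank_diff": mean_rank_diff,
        "mean_auprc_diff": float(diffs.mean()),
        "pvalue": pvalue,
        "significant": significant,
        "note": note,
    }


def mean_auprc_change(
    before: dict[str, float],
    after: dict[str, float],
    strata: dict[str, object],
) -> dict[object, float]:
    """Per-stratum mean of (AUPRC after resampling - AUPRC before).

    All three mappings must share the same dataset ids.
    """
    ids = sorted(before)
    if sorted(after) != ids or sorted(strata) != ids:
        missing = set(ids) ^ set(after) | set(ids) ^ set(strata)
        raise ValueError(f"unmatched dataset ids: {sorted(missing)}")
    out: dict[object, list[float]] = {}
    for i in ids:
        out.setdefault(strata[i], []).append(after[i] - before[i])
    return {k: float(np.mean(v)) for k, v in out.items()}


def top_combinations(results: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Best (resampling, classifier) pairs by average within-dataset rank.

    ``results`` is long format with columns ``dataset``, ``method``,
    ``classifier`` and ``auprc``; every pair must be scored on every
    dataset.  Pairs are ranked within each dataset (1 = best AUPRC,
    average-rank ties), ranks averaged across datasets, and the ``k``
    smallest averages returned.
    """
    required = {"dataset", "method", "classifier", "auprc"}
    if not required.issubset(results.columns):
        raise ValueError(f"results must have columns {sorted(required)}")
    wide = results.pivot_table(
        index="dataset", columns=["method", "classifier"], values="auprc"
    )
    if wide.isna().any().any():
        gaps = [
            f"{m}/{c} on {d}"
            for (m, c) in wide.columns
            for d in wide.index[wide[(m, c)].isna()]
        ]
        raise ValueError(f"missing AUPRC cells: {gaps[:10]}")
    ranks = wide.apply(lambda row: rankdata(-row.values, method="average"), axis=1, result_type="expand")
    ranks.columns = wide.columns
    avg = ranks.mean(axis=0).sort_values(kind="stable")
    table = avg.head(k).reset_index()
    table.columns = ["method", "classifier", "average_rank"]
    return table
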