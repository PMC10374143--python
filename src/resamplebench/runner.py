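"""Study orchestration: the simulation benchmark and the real-CSV protocol.

The simulation study generates each requested domain ``replicates`` times,
applies the no-resampling baseline plus every configured resampler to the
training data, tunes a decision tree by stratified 3-fold cross-validated
grid search on each resampled set, and scores AUPRC/AUROC on a shared
5000-row test set per domain.  Scores are turned into within-replicate
ranks and rank differences against the baseline.

The real-data protocol consumes a directory of CSVs with a binary label
column: features are encoded (one-hot below five categories, ordinal codes
otherwise), each dataset is split 7:3 stratified by class, a complexity
profile (F3/N2/C2) is computed on the full dataset, and every
resampler x classifier combination is tuned by 3-fold CV and scored on the
held-out 30%.

Seeding: every random stream is derived from the master seed through
``numpy.random.SeedSequence([master, domain_index, replicate, stream])``
so runs are reproducible and streams are independent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from . import complexity as cx
from .datasets import LabeledDataset
from .evaluation import (
    BASELINE,
    mean_auprc_change,
    RankRecord,
    aggregate_ranks,
    auprc,
    auroc,
    rank_methods,
    top_combinations,
)
from .resampling import REGISTRY, apply_method, family_of, list_methods
from .simulate import COMPLEXITY_LEVELS, DomainSpec, generate_domain, generate_test_set

logger = logging.getLogger(__name__)

#: decision-tree tuning grid used when a classifier entry gives none
DT_GRID = {"max_depth": [3, 5, 10, None], "min_samples_leaf": [1, 5, 10]}


def classifier_registry() -> dict[str, tuple[object, dict]]:
    """The five classifier families as (estimator, tuning grid) pairs.

    Estimators are consumed through a fit / score contract: continuous
    scores come from ``predict_proba`` when available, otherwise from
    ``decision_function`` (linear margin classifier).
    """
    return {
        "DT": (DecisionTreeClassifier(), dict(DT_GRID)),
        "KNN": (KNeighborsClassifier(), {"n_neighbors": [3, 5, 7]}),
        "SVM": (LinearSVC(), {"C": [0.1, 1.0, 10.0]}),
        "RF": (RandomForestClassifier(n_estimators=100), {"max_depth": [5, 10, None]}),
        "MLP": (
            MLPClassifier(hidden_layer_sizes=(32,), max_iter=500),
            {"alpha": [1e-4, 1e-2]},
        ),
    }


@dataclass
class StudyConfig:
    """Configuration of a simulation or real-data study."""

    complexity_levels: tuple[str, ...] = COMPLEXITY_LEVELS
    s_levels: tuple[int, ...] = (1, 3, 5)
    i_levels: tuple[int, ...] = (1, 3, 5)
    replicates: int = 50
    test_size: int = 5000
    methods: tuple[str, ...] = tuple(REGISTRY)
    method_params: dict[str, dict] = field(default_factory=dict)
    classifiers: tuple[str, ...] = ("DT",)
    cv_folds: int = 3
    seed: int = 0
    outdir: str = "results"
    label_col: str = "y"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        unknown = [m for m in self.methods if m not in REGISTRY]
        if unknown:
            raise ValueError(f"unknown resamplers in config: {unknown}")
        known_clf = classifier_registry()
        bad = [c for c in self.classifiers if c not in known_clf]
        if bad:
            raise ValueError(f"unknown classifiers in config: {bad}")

    def domains(self) -> list[DomainSpec]:
        specs = []
        idx = 0
        for level in self.complexity_levels:
            for s in self.s_levels:
                for i in self.i_levels:
                    specs.append(DomainSpec(level, s, i, seed=self._child(idx, 0, 0)))
                    idx += 1
        return specs

    def _child(self, *path: int) -> int:
        ss = np.random.SeedSequence([self.seed, *path])
        return int(ss.generate_state(1)[0] % (2**31 - 1))

    def to_json(self, path: str | Path) -> None:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        d = json.loads(Path(path).read_text())
        for k in ("complexity_levels", "s_levels", "i_levels", "methods", "classifiers"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


# -- classifier tuning ---------------------------------------------------


def _tune_and_score(
    clf_name: str,
    train: LabeledDataset,
    test: LabeledDataset,
    cv_folds: int,
    seed: int,
) -> tuple[float, float]:
    """Grid-search a classifier on the training data, score on the test set."""
    est, grid = classifier_registry()[clf_name]
    if "random_state" in est.get_params():
        est.set_params(random_state=seed)
    folds = int(min(cv_folds, train.minority_count, train.majority_count))
    if folds >= 2:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        search = GridSearchCV(est, grid, scoring="average_precision", cv=cv, n_jobs=1)
        search.fit(train.X, train.y)
        model = search.best_estimator_
    else:  # too few rows per class to cross-validate; fit defaults
        model = est.fit(train.X, train.y)
    if hasattr(model, "predict_proba"):
        pos = list(model.classes_).index(1)
        scores = model.predict_proba(test.X)[:, pos]
    else:
        scores = model.decision_function(test.X)
    return auprc(scores, test.y), auroc(scores, test.y)


# -- simulation study ----------------------------------------------------


def run_simulation_study(config: StudyConfig) -> pd.DataFrame:
    """Run the full simulation benchmark; returns a long-format table with
    one row per (domain, replicate, method) carrying AUPRC/AUROC, the
    within-replicate rank and the rank difference vs the baseline."""
    rows: list[dict] = []
    clf_name = config.classifiers[0]
    for d_idx, spec0 in enumerate(config.domains()):
        test = generate_test_set(
            DomainSpec(
                spec0.complexity_level,
                spec0.s,
                spec0.i,
                seed=config._child(d_idx, 0, 1),
            ),
            total=config.test_size,
        )
        for rep in range(config.replicates):
            spec = DomainSpec(
                spec0.complexity_level,
                spec0.s,
                spec0.i,
                seed=config._child(d_idx, rep, 2),
            )
            train = generate_domain(spec)
            scored: dict[str, tuple[float, float]] = {}
            for m_idx, method in enumerate((BASELINE, *config.methods)):
                m_seed = config._child(d_idx, rep, 3 + m_idx)
                try:
                    if method == BASELINE:
                        fit_data = train
                    else:
                        fit_data = apply_method(
                            method, train, config.method_params.get(method), seed=m_seed
                        ).dataset
                    scored[method] = _tune_and_score(
                        clf_name, fit_data, test, config.cv_folds, m_seed
                    )
                except Exception as exc:  # failures excluded from this replicate
                    logger.warning(
                        "%s failed on %s replicate %d: %s", method, spec0.name, rep, exc
                    )
            records = rank_methods(
                {m: s[0] for m, s in scored.items()}, replicate=rep
            )
            for rec in records:
                rows.append(
                    {
                        "complexity": spec0.complexity_level,
                        "s": spec0.s,
                        "i": spec0.i,
                        "domain": spec0.name,
                        "replicate": rep,
                        "seed": spec.seed,
                        "method": rec.method,
                        "family": None if rec.method == BASELINE else family_of(rec.method),
                        "classifier": clf_name,
                        "auprc": rec.auprc,
                        "auroc": scored[rec.method][1],
                        "rank": rec.rank,
                        "rank_diff": rec.rank_diff,
                    }
                )
    return pd.DataFrame(rows)


def summarize_rank_diffs(results: pd.DataFrame) -> pd.DataFrame:
    """Mean rank difference per (domain, method) with paired-t significance —
    the tabular counterpart of the per-complexity bar charts."""
    out = []
    for (domain, _), grp in results.groupby(["domain", "classifier"]):
        records = [
            RankRecord(r.replicate, r.method, r.auprc, r.rank, r.rank_diff)
            for r in grp.itertuples()
        ]
        for method in sorted(grp["method"].unique()):
            if method == BASELINE:
                continue
            agg = aggregate_ranks(records, method)
            out.append(
                {
                    "domain": domain,
                    "complexity": grp["complexity"].iloc[0],
                    "s": grp["s"].iloc[0],
                    "i": grp["i"].iloc[0],
                    "method": method,
                    "family": family_of(method),
                    "mean_rank_diff": agg["mean_rank_diff"],
                    "mean_auprc_diff": agg["mean_auprc_diff"],
                    "pvalue": agg["pvalue"],
                    "significant": agg["significant"],
                }
            )
    return pd.DataFrame(out)


def family_mean_rank_diffs(results: pd.DataFrame) -> pd.DataFrame:
    """Mean rank difference per (complexity level, method family)."""
    sub = results[results["method"] != BASELINE]
    return (
        sub.groupby(["complexity", "family"])["rank_diff"]
        .mean()
        .rename("mean_rank_diff")
        .reset_index()
    )


# -- real-data protocol --------------------------------------------------


class FeatureEncoder:
    """Mixed-column encoder for real CSVs.

    Categorical columns with fewer than five levels are one-hot encoded;
    categoricals with five or more levels get ordinal integer codes;
    numeric columns pass through.  The fitted level maps are persisted so
    transform rejects unseen levels.
    """

    def __init__(self, categorical: list[str] | None = None):
        self.declared = categorical
        self.onehot_: dict[str, list] = {}
        self.ordinal_: dict[str, dict] = {}
        self.columns_: list[str] | None = None

    def fit(self, df: pd.DataFrame) -> "FeatureEncoder":
        cats = (
            self.declared
            if self.declared is not None
            else [c for c in df.columns if df[c].dtype == object or str(df[c].dtype) == "category"]
        )
        for col in cats:
            levels = sorted(df[col].astype(str).unique())
            if len(levels) < 5:
                self.onehot_[col] = levels
            else:
                self.ordinal_[col] = {lv: i for i, lv in enumerate(levels)}
        self.columns_ = list(df.columns)
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for col in df.columns:
            if col in self.onehot_:
                vals = df[col].astype(str)
                unseen = set(vals) - set(self.onehot_[col])
                if unseen:
                    raise ValueError(f"unseen levels in {col!r}: {sorted(unseen)}")
                for lv in self.onehot_[col]:
                    out[f"{col}={lv}"] = (vals == lv).astype(float)
            elif col in self.ordinal_:
                vals = df[col].astype(str)
                unseen = set(vals) - set(self.ordinal_[col])
                if unseen:
                    raise ValueError(f"unseen levels in {col!r}: {sorted(unseen)}")
                out[col] = vals.map(self.ordinal_[col]).astype(float)
            else:
                out[col] = df[col].astype(float)
        return pd.DataFrame(out, index=df.index)

    def fit_transform(self, df: pd.DataFrame) -> pd.DataFrame:
        return self.fit(df).transform(df)


def encode_features(
    df: pd.DataFrame, label_col: str = "y", categorical: list[str] | None = None
) -> tuple[LabeledDataset, FeatureEncoder]:
    """Encode a raw table into a LabeledDataset plus the fitted encoder."""
    if label_col not in df.columns:
        raise ValueError(f"label column {label_col!r} not found")
    enc = FeatureEncoder(categorical=categorical)
    feats = enc.fit_transform(df.drop(columns=[label_col]))
    y = df[label_col].to_numpy()
    data = LabeledDataset(
        X=feats.to_numpy(), y=y, feature_names=list(feats.columns)
    )
    return data, enc


def _stratified_split(
    data: LabeledDataset, seed: int, test_frac: float = 0.3, attempts: int = 5
) -> tuple[LabeledDataset, LabeledDataset] | None:
    for a in range(attempts):
        idx_tr, idx_te = train_test_split(
            np.arange(data.n),
            test_size=test_frac,
            random_state=seed + a,
            stratify=data.y,
        )
        tr, te = data.subset(np.sort(idx_tr)), data.subset(np.sort(idx_te))
        if tr.minority_count > 1 and te.minority_count > 0:
            return tr, te
    return None


def run_real_study(
    dataset_dir: str | Path, config: StudyConfig
) -> dict[str, pd.DataFrame]:
    """Run the real-CSV protocol over every ``*.csv`` in ``dataset_dir``.

    Returns a dict with ``results`` (per dataset x method x classifier
    AUPRC/AUROC), ``profiles`` (complexity measures and strata), and
    ``top_combinations_<measure>_<group>`` tables.
    """
    paths = sorted(Path(dataset_dir).glob("*.csv"))
    if not paths:
        raise ValueError(f"no CSV datasets found in {dataset_dir}")
    rows, prof_rows = [], []
    for p_idx, path in enumerate(paths):
        df = pd.read_csv(path)
        data, _ = encode_features(df, label_col=config.label_col)
        split = _stratified_split(data, seed=config._child(100, p_idx, 0))
        if split is None:
            logger.warning("skipping %s: could not build a two-class split", path.name)
            continue
        train, holdout = split
        prof = cx.profile(data)
        prof_rows.append({"dataset": path.stem, **prof.as_dict()})
        for m_idx, method in enumerate((BASELINE, *config.methods)):
            m_seed = config._child(100, p_idx, 1 + m_idx)
            try:
                fit_data = (
                    train
                    if method == BASELINE
                    else apply_method(
                        method, train, config.method_params.get(method), seed=m_seed
                    ).dataset
                )
            except Exception as exc:
                logger.warning("%s failed on %s: %s", method, path.name, exc)
                continue
            for clf in config.classifiers:
                try:
                    ap, roc = _tune_and_score(
                        clf, fit_data, holdout, config.cv_folds, m_seed
                    )
                except Exception as exc:
                    logger.warning("%s/%s failed on %s: %s", method, clf, path.name, exc)
                    continue
                rows.append(
                    {
                        "dataset": path.stem,
                        "method": method,
                        "classifier": clf,
                        "auprc": ap,
                        "auroc": roc,
                    }
                )
    results = pd.DataFrame(rows)
    profiles = pd.DataFrame(prof_rows)
    out: dict[str, pd.DataFrame] = {"results": results, "profiles": profiles}
    if len(profiles) >= 4:
        profiles["c2_imbalanced"] = cx.stratify(profiles["c2"], cx.TOP25)
        for measure in ("f3", "n2", "c2"):
            profiles[f"{measure}_tertile"] = cx.stratify(profiles[measure], cx.TERTILES)
            out[f"auprc_change_{measure}"] = _auprc_change_by_stratum(
                results, dict(zip(profiles["dataset"], profiles[f"{measure}_tertile"]))
            )
        for measure in ("f3", "n2"):
            for group, rule in (("complex", cx.TOP25), ("noncomplex", cx.BOTTOM25)):
                flag = cx.stratify(profiles[measure], rule)
                chosen = profiles.loc[flag, "dataset"]
                sub = results[results["dataset"].isin(chosen)]
                if len(sub):
                    out[f"top_combinations_{measure}_{group}"] = top_combinations(sub)
    return out


def _auprc_change_by_stratum(results: pd.DataFrame, strata: dict) -> pd.DataFrame:
    """Per (method, classifier): mean AUPRC change vs the no-resampling
    baseline within each complexity stratum — the tabular counterpart of
    the before/after bar charts."""
    rows = []
    for (method, clf), grp in results.groupby(["method", "classifier"]):
        if method == BASELINE:
            continue
        base = results[
            (results["method"] == BASELINE) & (results["classifier"] == clf)
        ].set_index("dataset")["auprc"]
        after = grp.set_index("dataset")["auprc"]
        common = sorted(set(base.index) & set(after.index))
        means = mean_auprc_change(
            {d: float(base[d]) for d in common},
            {d: float(after[d]) for d in common},
            {d: strata[d] for d in common},
        )
        for stratum, delta in sorted(means.items()):
            rows.append(
                {
                    "method": method,
                    "classifier": clf,
                    "stratum": stratum,
                    "mean_auprc_change": delta,
                }
            )
    return pd.DataFrame(rows)


# -- reporting -----------------------------------------------------------


def make_report(
    results: pd.DataFrame, config: StudyConfig, outdir: str | Path | None = None
) -> dict[str, Path]:
    """Write the summary bundle: per-domain mean rank-diff table with
    significance flags, the family-level table, and a JSON manifest of the
    configuration.  Regenerating from the same results CSV is idempotent."""
    if results.empty or results["method"].nunique() < 2:
        raise ValueError("results table is empty or has no methods to report")
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    results = results.sort_values(
        ["domain", "classifier", "replicate", "method"], kind="stable"
    ).reset_index(drop=True)
    paths["results"] = outdir / "results.csv"
    # %.17g round-trips float64 exactly, so report regeneration is idempotent
    results.to_csv(paths["results"], index=False, float_format="%.17g")
    summary = summarize_rank_diffs(results)
    paths["rank_diffs"] = outdir / "rank_diffs.csv"
    summary.to_csv(paths["rank_diffs"], index=False)
    fam = family_mean_rank_diffs(results)
    paths["family_rank_diffs"] = outdir / "family_rank_diffs.csv"
    fam.to_csv(paths["family_rank_diffs"], index=False)
    paths["manifest"] = outdir / "manifest.json"
    config.to_json(paths["manifest"])
    return paths
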