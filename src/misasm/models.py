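"""Region classifiers: balanced resampling, hold-outs, grid search, reports.

The workflow mirrors standard practice for unbalanced genomic region
classification: a 10% held-out test set, class-balanced resampled datasets
(each with class counts equal to the minority class), a grid search on the
first 10 balanced datasets by 10-fold cross-validated macro-F1, and random
forests with the entropy split criterion so feature importances are
information-gain based.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, f1_score, precision_score, recall_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_predict

DEFAULT_GRID = {
    "max_depth": [3, 5, 10, None],
    "max_features": ["sqrt", 0.25, 0.5],
    "n_estimators": [100, 500],
}


def make_balanced_datasets(labels, n_datasets: int = 100, seed: int = 0) -> list[np.ndarray]:
    """Index sets with every class downsampled (without replacement) to the
    minority class count; deterministic per seed."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    if counts.min() == 0:
        raise ValueError("a class has 0 instances")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_datasets):
        idx = np.concatenate(
            [
                rng.choice(np.flatnonzero(labels == c), size=n_min, replace=False)
                for c in classes
            ]
        )
        out.append(np.sort(idx))
    return out


def split_holdout(
    labels,
    fraction: float = 0.10,
    mode: str = "random",
    seed: int = 0,
    coords: pd.DataFrame | None = None,
    spans_per_chrom: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random 10% hold-out, or span mode (two genomic spans per
    chromosome supply the test regions; training stays strictly outside)."""
    labels = np.asarray(labels)
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if mode == "random":
        test = []
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            n = max(1, int(round(fraction * len(idx))))
            test.append(rng.choice(idx, size=n, replace=False))
        test = np.sort(np.concatenate(test))
        train = np.setdiff1d(np.arange(len(labels)), test)
        return train, test
    if mode != "span":
        raise ValueError("mode must be 'random' or 'span'")
    if coords is None:
        raise ValueError("span mode requires region coordinates")
    in_span = np.zeros(len(labels), dtype=bool)
    for chrom, grp in coords.groupby("chrom"):
        L = int(grp["end"].max())
        span_len = max(int(L * fraction / spans_per_chrom), 1)
        for _ in range(spans_per_chrom):
            s = int(rng.integers(0, max(L - span_len, 1)))
            hit = (coords["chrom"] == chrom) & (coords["start"] < s + span_len) & (
                coords["end"] > s
            )
            in_span |= hit.to_numpy()
    test = np.flatnonzero(in_span)
    train = np.flatnonzero(~in_span)
    for c in np.unique(labels):
        if not np.any(labels[train] == c):
            raise ValueError(f"test spans swallowed every instance of class {c!r}")
    return train, test


def grid_search_train(
    X: pd.DataFrame,
    y,
    param_grid: dict | None = None,
    folds: int = 10,
    seed: int = 0,
) -> tuple[dict, RandomForestClassifier]:
    """Exhaustive grid search by cross-validated macro-F1; entropy criterion."""
    y = np.asarray(y)
    param_grid = param_grid or DEFAULT_GRID
    _, counts = np.unique(y, return_counts=True)
    if folds > counts.min():
        raise ValueError("fold count exceeds smallest class size")
    base = RandomForestClassifier(criterion="entropy", random_state=seed, n_jobs=1)
    gs = GridSearchCV(
        base,
        param_grid,
        scoring="f1_macro",
        cv=StratifiedKFold(folds, shuffle=True, random_state=seed),
        n_jobs=1,
    )
    gs.fit(X, y)
    return gs.best_params_, gs.best_estimator_


@dataclass
class ModelReport:
    classes: list[str]
    cv_recall: pd.DataFrame  # datasets x classes
    test_recall: pd.DataFrame
    cv_macro_f1: np.ndarray
    test_macro_f1: np.ndarray
    cv_confusion: np.ndarray  # row-normalised, averaged over datasets
    test_confusion: np.ndarray
    importances: pd.DataFrame  # datasets x features
    params: dict = field(default_factory=dict)
    seed: int = 0

    def summary(self) -> dict:
        return {
            "classes": self.classes,
            "cv_macro_f1_mean": float(self.cv_macro_f1.mean()),
            "cv_macro_f1_sd": float(self.cv_macro_f1.std()),
            "test_macro_f1_mean": float(self.test_macro_f1.mean()),
            "test_macro_f1_sd": float(self.test_macro_f1.std()),
            "cv_recall_mean": self.cv_recall.mean().to_dict(),
            "test_recall_mean": self.test_recall.mean().to_dict(),
            "params": {k: (v if v is None or isinstance(v, (int, float, str)) else str(v))
                       for k, v in self.params.items()},
            "seed": self.seed,
        }


def evaluate(
    X: pd.DataFrame,
    y,
    datasets: list[np.ndarray],
    params: dict,
    test_idx: np.ndarray,
    folds: int = 10,
    seed: int = 0,
) -> ModelReport:
    """Fit one forest per balanced dataset; report CV and held-out metrics.

    ``datasets`` index into the training portion only; ``test_idx`` rows are
    never seen during fitting.
    """
    y = np.asarray(y)
    if len(test_idx) == 0:
        raise ValueError("empty test set")
    classes = sorted(np.unique(y).tolist())
    cv_rec, te_rec, cv_f1, te_f1, imps = [], [], [], [], []
    cv_cms, te_cms = [], []
    for di, idx in enumerate(datasets):
        Xd, yd = X.iloc[idx], y[idx]
        clf = RandomForestClassifier(
            criterion="entropy", random_state=seed + di, n_jobs=1, **params
        )
        n_folds = min(folds, np.unique(yd, return_counts=True)[1].min())
        pred_cv = cross_val_predict(
            clf, Xd, yd, cv=StratifiedKFold(n_folds, shuffle=True, random_state=seed)
        )
        clf.fit(Xd, yd)
        pred_te = clf.predict(X.iloc[test_idx])
        yt = y[test_idx]
        cv_rec.append(recall_score(yd, pred_cv, labels=classes, average=None, zero_division=0))
        te_rec.append(recall_score(yt, pred_te, labels=classes, average=None, zero_division=0))
        cv_f1.append(f1_score(yd, pred_cv, labels=classes, average="macro", zero_division=0))
        te_f1.append(f1_score(yt, pred_te, labels=classes, average="macro", zero_division=0))
        cv_cms.append(confusion_matrix(yd, pred_cv, labels=classes, normalize="true"))
        te_cms.append(confusion_matrix(yt, pred_te, labels=classes, normalize="true"))
        imps.append(clf.feature_importances_)
    return ModelReport(
        classes=classes,
        cv_recall=pd.DataFrame(cv_rec, columns=classes),
        test_recall=pd.DataFrame(te_rec, columns=classes),
        cv_macro_f1=np.asarray(cv_f1),
        test_macro_f1=np.asarray(te_f1),
        cv_confusion=np.mean(cv_cms, axis=0),
        test_confusion=np.mean(te_cms, axis=0),
        importances=pd.DataFrame(imps, columns=list(X.columns)),
        params=params,
        seed=seed,
    )


def select_top_features(importances: pd.DataFrame, n: int) -> list[str]:
    """Top-n features by mean importance across datasets, ties lexicographic."""
    mean_imp = importances.mean(axis=0)
    if n > len(mean_imp):
        import warnings

        warnings.warn("n exceeds feature count: returning all features")
        n = len(mean_imp)
    order = sorted(mean_imp.index, key=lambda c: (-mean_imp[c], c))
    return order[:n]


def importance_ranks(importances: pd.DataFrame) -> pd.Series:
    """Rank per feature (1 = most important) by mean importance."""
    mean_imp = importances.mean(axis=0)
    order = sorted(mean_imp.index, key=lambda c: (-mean_imp[c], c))
    return pd.Series({c: i + 1 for i, c in enumerate(order)}, name="rank")


def group_median_ranks(ranks: pd.Series, groups: dict[str, list[str]]) -> dict[str, float]:
    """Median importance rank per named feature group."""
    return {
        g: float(np.median([ranks[c] for c in cols if c in ranks]))
        for g, cols in groups.items()
        if any(c in ranks for c in cols)
    }


@dataclass
class ModelSpec:
    """Declarative description of which feature columns a named model uses."""

    name: str
    base: bool = True
    flank_sizes: tuple[int, ...] = ()
    top_kmers: int = 0
    top_ssrs: int = 0
    functional: bool = False
    functional_only: bool = False
    binary: bool = False
    label_column: str = "coverage_class"
    positive_pair: tuple[str, str] | None = None  # e.g. ("HC", "BG")


def model_catalog(flank_sizes=(500, 1000, 2000, 4000, 8000, 16000, 32000)) -> dict[str, ModelSpec]:
    """Named model registry: base-only, flank-only per size, combined,
    top-k-mer/SSR augmented, all-inclusive, functional and binary variants,
    plus the two misassembly discriminators."""
    cat: dict[str, ModelSpec] = {}
    cat["1"] = ModelSpec("1")
    for i, s in enumerate(flank_sizes, start=2):
        cat[str(i)] = ModelSpec(str(i), base=False, flank_sizes=(s,))
    cat["9"] = ModelSpec("9", flank_sizes=tuple(flank_sizes))
    for name, n in (("10", 100), ("18", 500), ("26", 1000)):
        cat[name] = ModelSpec(name, top_kmers=n, top_ssrs=n)
    cat["34"] = ModelSpec("34", flank_sizes=tuple(flank_sizes), top_kmers=100, top_ssrs=100)
    cat["35"] = ModelSpec("35", flank_sizes=tuple(flank_sizes), top_kmers=100, top_ssrs=100, functional=True)
    cat["36"] = ModelSpec("36", base=False, functional=True, functional_only=True)
    for b in ("1", "34", "35", "36"):
        spec = cat[b]
        cat[b + "B"] = ModelSpec(
            b + "B",
            base=spec.base,
            flank_sizes=spec.flank_sizes,
            top_kmers=spec.top_kmers,
            top_ssrs=spec.top_ssrs,
            functional=spec.functional,
            functional_only=spec.functional_only,
            binary=True,
            positive_pair=("HC", "BG"),
        )
    cat["37"] = ModelSpec(
        "37", flank_sizes=tuple(flank_sizes), top_kmers=100, top_ssrs=100,
        functional=True, binary=True, label_column="misassembly_label",
        positive_pair=("HC_M2/M3", "HC_C2/C3"),
    )
    cat["38"] = ModelSpec(
        "38", flank_sizes=tuple(flank_sizes), top_kmers=100, top_ssrs=100,
        functional=True, binary=True, label_column="misassembly_label",
        positive_pair=("HC_M2/M3", "BG_M2/M3"),
    )
    return cat


def resolve_feature_columns(
    spec: ModelSpec,
    columns: list[str],
    top_kmer_cols: list[str] | None = None,
    top_ssr_cols: list[str] | None = None,
) -> list[str]:
    """Select the matrix columns a model consumes."""
    base_cols = [
        c for c in columns
        if not c.startswith(("flank", "kmer_", "ssr_", "fn_"))
    ]
    chosen: list[str] = []
    if spec.functional_only:
        return [c for c in columns if c.startswith("fn_")]
    if spec.base:
        chosen += base_cols
    for s in spec.flank_sizes:
        chosen += [c for c in columns if c.startswith(f"flank{s}_")]
    if spec.top_kmers:
        pool = top_kmer_cols if top_kmer_cols is not None else [
            c for c in columns if c.startswith("kmer_")
        ]
        chosen += pool[: spec.top_kmers]
    if spec.top_ssrs:
        pool = top_ssr_cols if top_ssr_cols is not None else [
            c for c in columns if c.startswith("ssr_")
        ]
        chosen += pool[: spec.top_ssrs]
    if spec.functional:
        chosen += [c for c in columns if c.startswith("fn_")]
    if not chosen:
        raise ValueError(f"model {spec.name!r} selected no feature columns")
    return chosen
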