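"""Stratified cross-validated city classification with in-fold selection.

The harness guards against information leakage: for every fold, feature
selection (by default the negative-binomial differential screen) and the
quantile-normal + z-score transform are fitted on the training samples only,
then applied to the held-out fold.  Classifiers plug in through
:class:`ClassifierSpec`; reference configurations ship for MLP, KNN and SVC.
Performance is reported as per-fold macro F1 with a pooled confusion matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .data import AbundanceTable, SampleMetadata
from .differential import run_pairwise, select_top_k

logger = logging.getLogger(__name__)


@dataclass
class FoldPlan:
    """Deterministic stratified assignment of samples to k folds."""

    assignment: dict[str, int]
    seed: int
    k: int

    def fold_samples(self, fold: int) -> list[str]:
        return [s for s, f in self.assignment.items() if f == fold]


def stratified_folds(labels: pd.Series, k: int = 5, seed: int = 0) -> FoldPlan:
    """Shuffle within class by seed, then deal round-robin across folds.

    Per-class fold counts differ by at most one; classes with fewer than k
    members trigger a warning and best-effort assignment.  The starting fold
    rotates per class so fold sizes stay balanced overall.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    start = 0
    for cls in sorted(labels.unique()):
        members = list(labels.index[labels == cls])
        if len(members) < k:
            logger.warning("class %r has %d < %d members", cls, len(members), k)
        order = rng.permutation(len(members))
        for pos, idx in enumerate(order):
            assignment[members[idx]] = (start + pos) % k
        start = (start + len(members)) % k
    return FoldPlan(assignment=assignment, seed=seed, k=k)


class QuantileNormalTransform:
    """Per-feature rank map to standard normal quantiles, then z-score.

    Training values are ranked (ties averaged), mapped to uniform positions
    r/(n+1) clipped to [eps, 1-eps], and pushed through the normal quantile
    function.  New values interpolate linearly through the training map and
    clip to the training extremes.  The z-score uses training mean/sd; a
    constant training feature transforms to all zeros.
    """

    eps = 1e-7

    def fit(self, train: np.ndarray) -> "QuantileNormalTransform":
        train = np.asarray(train, dtype=float)
        n, p = train.shape
        self._sorted = np.sort(train, axis=0)
        self._grid = []
        self._mean = np.zeros(p)
        self._sd = np.ones(p)
        self._constant = np.zeros(p, dtype=bool)
        train_t = np.zeros_like(train)
        for j in range(p):
            col = train[:, j]
            if np.ptp(col) == 0:
                self._constant[j] = True
                self._grid.append((self._sorted[:, j], np.zeros(n)))
                logger.debug("feature %d constant in training; transformed to zeros", j)
                continue
            ranks = stats.rankdata(col, method="average")
            u = np.clip(ranks / (n + 1.0), self.eps, 1 - self.eps)
            z = stats.norm.ppf(u)
            # map over sorted training values for interpolation of new data
            order = np.argsort(col, kind="mergesort")
            self._grid.append((col[order], z[order]))
            train_t[:, j] = z
            self._mean[j] = z.mean()
            sd = z.std(ddof=0)
            self._sd[j] = sd if sd > 0 else 1.0
        self._train_t = (train_t - self._mean) / self._sd
        self._train_t[:, self._constant] = 0.0
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for j in range(x.shape[1]):
            if self._constant[j]:
                continue
            xs, zs = self._grid[j]
            out[:, j] = np.interp(x[:, j], xs, zs)  # clips to end values
            out[:, j] = (out[:, j] - self._mean[j]) / self._sd[j]
        return out

    @property
    def transformed_train(self) -> np.ndarray:
        return self._train_t


def quantile_normal_transform(
    train_features: np.ndarray, apply_features: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Functional wrapper: fit on train, return (train, apply) transformed."""
    t = QuantileNormalTransform().fit(np.asarray(train_features, float))
    return t.transformed_train, t.transform(np.asarray(apply_features, float))


def macro_f1(true_labels: Sequence, predicted_labels: Sequence) -> float:
    """Unweighted mean per-class F1 over classes present in the truth.

    Per class, F1 = 2PR/(P+R) with precision P and recall R from the
    one-vs-rest confusion counts; a class with P + R = 0 contributes 0.
    """
    true = np.asarray(true_labels)
    pred = np.asarray(predicted_labels)
    if true.size == 0 or true.shape != pred.shape:
        raise ValueError("label vectors must be nonempty and equal length")
    scores = []
    for cls in np.unique(true):
        tp = np.sum((true == cls) & (pred == cls))
        fp = np.sum((true != cls) & (pred == cls))
        fn = np.sum((true == cls) & (pred != cls))
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        recall = tp / (tp + fn) if (tp + fn) else 0.0
        f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
        scores.append(f1)
    return float(np.mean(scores))


@dataclass
class ClassifierSpec:
    """Named classifier configuration resolvable to a scikit-learn estimator."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0
    builder: Optional[Callable] = None  # for name == "custom"

    def build(self):
        params = dict(self.hyperparameters)
        if self.name == "MLP":
            params.setdefault("hidden_layer_sizes", (200,))
            params.setdefault("max_iter", 1000)
            return MLPClassifier(random_state=self.seed, **params)
        if self.name == "KNN":
            params.setdefault("n_neighbors", 23)
            return KNeighborsClassifier(**params)
        if self.name == "SVC":
            if params.pop("degree", None) is not None:
                # degree only applies to polynomial kernels
                logger.warning("SVC degree ignored for non-polynomial kernel")
            params.setdefault("kernel", "linear")
            return SVC(random_state=self.seed, **params)
        if self.name == "custom":
            if self.builder is None:
                raise ValueError("custom spec needs a builder callable")
            return self.builder(**params)
        raise ValueError(f"unknown classifier {self.name!r}")


def reference_specs(seed: int = 0) -> list[ClassifierSpec]:
    """Reference OTU-feature configurations: MLP 200x1, KNN k=23, linear SVC."""
    return [
        ClassifierSpec("MLP", {"hidden_layer_sizes": (200,)}, seed=seed),
        ClassifierSpec("KNN", {"n_neighbors": 23}),
        ClassifierSpec("SVC", {"kernel": "linear"}, seed=seed),
    ]


def functional_specs(seed: int = 0) -> list[ClassifierSpec]:
    """Grid-searched functional-profile configurations."""
    return [
        ClassifierSpec(
            "MLP",
            {
                "hidden_layer_sizes": (100,),
                "activation": "tanh",
                "batch_size": "auto",
                "solver": "sgd",
                "learning_rate": "adaptive",
                "max_iter": 3000,
                "early_stopping": False,
            },
            seed=seed,
        ),
        ClassifierSpec("KNN", {"n_neighbors": 2, "weights": "distance"}),
        ClassifierSpec("SVC", {"kernel": "linear"}, seed=seed),
    ]


@dataclass
class CVReport:
    """Cross-validation outcome for one classifier spec."""

    classifier: str
    per_fold_macro_f1: list[float]
    confusion: pd.DataFrame
    per_fold_features: dict[int, list[str]]
    failed_folds: list[int] = field(default_factory=list)

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.per_fold_macro_f1))

    @property
    def sd_f1(self) -> float:
        return float(np.std(self.per_fold_macro_f1, ddof=1)) if len(self.per_fold_macro_f1) > 1 else 0.0

    @property
    def shared_features(self) -> list[str]:
        """Features selected in every fold."""
        sets = [set(v) for v in self.per_fold_features.values()]
        return sorted(set.intersection(*sets)) if sets else []

    @property
    def pooled_accuracy(self) -> float:
        total = self.confusion.to_numpy().sum()
        return float(np.trace(self.confusion.to_numpy()) / total) if total else 0.0


def nb_selector(top_k: int = 5, min_samples: int = 2, levels: Sequence[str] = ("otu",)):
    """In-fold feature selector: union of per-pair top-k NB-differential taxa."""

    def select(train_table: AbundanceTable, train_metadata: SampleMetadata) -> list[str]:
        result = run_pairwise(
            train_table, train_metadata, models=("NB",), levels=levels, min_samples=min_samples
        )
        _, summary = select_top_k(result, "NB", k=top_k)
        return summary["selected_union"]

    return select


def passthrough_selector(train_table: AbundanceTable, train_metadata: SampleMetadata) -> list[str]:
    """Keep every feature (functional-profile path)."""
    return list(train_table.otu_ids)


def run_cv(
    table: AbundanceTable,
    metadata: SampleMetadata,
    classifier_specs: Sequence[ClassifierSpec],
    selector: Callable[[AbundanceTable, SampleMetadata], list[str]] = passthrough_selector,
    transform: bool = True,
    k: int = 5,
    seed: int = 0,
) -> dict[str, CVReport]:
    """k-fold stratified CV with strictly in-fold selection and transforms.

    Classes are cities (years merged).  Per fold the selector sees only the
    training-sample table/metadata, the transform is fitted on training
    features only, and every spec is trained and scored on the held-out
    fold.  Returns one :class:`CVReport` per classifier name.
    """
    metadata.require_samples(table.sample_ids)
    labels = metadata.frame.loc[table.sample_ids, "city"].astype(str)
    plan = stratified_folds(labels, k=k, seed=seed)
    classes = sorted(labels.unique())

    reports = {
        spec.name: CVReport(
            classifier=spec.name,
            per_fold_macro_f1=[],
            confusion=pd.DataFrame(0, index=classes, columns=classes, dtype=int),
            per_fold_features={},
        )
        for spec in classifier_specs
    }

    for fold in range(k):
        test_ids = [s for s in table.sample_ids if plan.assignment[s] == fold]
        train_ids = [s for s in table.sample_ids if plan.assignment[s] != fold]
        train_table = table.subset_samples(train_ids)
        train_meta = SampleMetadata(metadata.frame.loc[train_ids].copy())
        features = selector(train_table, train_meta)
        if not features:
            logger.warning("fold %d: selector returned no features; using all", fold)
            features = list(table.otu_ids)
        feat_table = table.subset_otus(features)
        col = {s: j for j, s in enumerate(feat_table.sample_ids)}
        x_train = feat_table.counts[:, [col[s] for s in train_ids]].T.astype(float)
        x_test = feat_table.counts[:, [col[s] for s in test_ids]].T.astype(float)
        if transform:
            x_train, x_test = quantile_normal_transform(x_train, x_test)
        y_train = labels.loc[train_ids].to_numpy()
        y_test = labels.loc[test_ids].to_numpy()
        for spec in classifier_specs:
            report = reports[spec.name]
            report.per_fold_features[fold] = list(features)
            try:
                clf = spec.build()
                clf.fit(x_train, y_train)
                y_pred = clf.predict(x_test)
            except Exception as exc:  # pragma: no cover - defensive
                logger.warning("fold %d: %s failed: %s", fold, spec.name, exc)
                report.failed_folds.append(fold)
                continue
            report.per_fold_macro_f1.append(macro_f1(y_test, y_pred))
            for t, p in zip(y_test, y_pred):
                if p not in report.confusion.columns:
                    report.confusion[p] = 0
                report.confusion.loc[t, p] += 1
    return reports
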