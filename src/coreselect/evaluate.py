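"""Evaluation machinery: macro-F1, cluster-validity indices, class
coverage, and the repeated-split benchmark of coreset vs random
reduction.

The benchmark mirrors the protocol used to validate embedding-based
coreset selection: hold out 10% of the labeled items as a test set,
reduce the remaining pool to each retention fraction by each strategy,
train a classifier on 90% of the coreset (10% validation), score
macro-averaged F1 on the test set, and repeat with fresh splits,
reporting mean ± sample standard deviation. The image-finetuning
classifier of full-scale studies is replaced here by a pluggable
embedding-space trainer; the default is a multinomial logistic model fit
by full-batch gradient descent, which keeps the benchmark desk-scale
while preserving the comparison's structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from ._seeds import derive_seed
from .cluster import KMeansConfig
from .io import DatasetManifest, EmbeddingMatrix
from .select import CoresetResult, SelectionPlan, Strategy, select_coreset, subset_size

logger = logging.getLogger(__name__)

__all__ = [
    "EvalReport",
    "BenchmarkSpec",
    "SoftmaxClassifier",
    "macro_f1",
    "per_class_f1",
    "davies_bouldin",
    "silhouette",
    "class_coverage",
    "run_benchmark",
]


# ---------------------------------------------------------------------------
# classification metrics


def per_class_f1(
    y_true: Sequence, y_pred: Sequence, class_set: Sequence
) -> dict:
    """Per-class F1 from confusion counts.

    A class with zero precision + recall (never predicted and absent
    from the truth, or always wrong) scores 0 — the convention that
    makes missing classes visible in the macro average.
    """
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    if len(y_true) == 0:
        raise ValueError("empty evaluation inputs")
    classes = list(class_set)
    allowed = set(classes)
    for y in (y_true, y_pred):
        stray = {v for v in y if v not in allowed}
        if stray:
            raise ValueError(f"labels outside class_set: {sorted(map(str, stray))}")
    scores: dict = {}
    degenerate = []
    for c in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        if tp == 0 and fp == 0 and fn == 0:
            scores[c] = 0.0
            degenerate.append(c)
        else:
            scores[c] = 2 * tp / (2 * tp + fp + fn)
    if degenerate:
        logger.warning(
            "classes absent from both truth and predictions score 0: %s",
            degenerate,
        )
    return scores


def macro_f1(y_true: Sequence, y_pred: Sequence, class_set: Sequence) -> float:
    """Unweighted mean of per-class F1 over ``class_set``.

    Insensitive to class frequency, which is the point: a rare class
    with no correct predictions drags the average down as much as a
    common one.
    """
    scores = per_class_f1(y_true, y_pred, class_set)
    return float(np.mean(list(scores.values())))


# ---------------------------------------------------------------------------
# cluster-validity indices (Euclidean, matching the clustering metric)


def _groups(labels: np.ndarray) -> list[np.ndarray]:
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("at least two groups are required")
    return [np.flatnonzero(labels == u) for u in uniq]


def davies_bouldin(embeddings: EmbeddingMatrix, labels: Sequence) -> float:
    """Davies-Bouldin index: mean over groups of the worst ratio
    (S_i + S_j) / M_ij, with S the mean member-to-centroid distance and
    M_ij the centroid separation. 0 is best; higher means groups are
    wide relative to their spacing."""
    labels = np.asarray(labels)
    x = embeddings.vectors
    if labels.shape[0] != x.shape[0]:
        raise ValueError("one label per item required")
    groups = _groups(labels)
    centroids = np.stack([x[g].mean(axis=0) for g in groups])
    spreads = np.array(
        [np.linalg.norm(x[g] - centroids[i], axis=1).mean() for i, g in enumerate(groups)]
    )
    sep = cdist(centroids, centroids)
    k = len(groups)
    ratios = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i != j:
                ratios[i, j] = (spreads[i] + spreads[j]) / sep[i, j]
    return float(np.max(ratios, axis=1).mean())


def silhouette(embeddings: EmbeddingMatrix, labels: Sequence) -> float:
    """Mean silhouette coefficient (b − a) / max(a, b).

    a is the mean distance to co-members (excluding the point itself),
    b the smallest mean distance to another group. A point alone in its
    group is given silhouette 0 by convention.
    """
    labels = np.asarray(labels)
    x = embeddings.vectors
    if labels.shape[0] != x.shape[0]:
        raise ValueError("one label per item required")
    _, codes = np.unique(labels, return_inverse=True)
    groups = _groups(codes)
    dist = cdist(x, x)
    n = x.shape[0]
    scores = np.zeros(n)
    mean_to_group = np.stack([dist[:, g].mean(axis=1) for g in groups], axis=1)
    sizes = np.array([g.size for g in groups])
    for i in range(n):
        gi = int(codes[i])
        size = sizes[gi]
        if size <= 1:
            scores[i] = 0.0
            continue
        a = mean_to_group[i, gi] * size / (size - 1)  # exclude self-distance 0
        b = np.min(np.delete(mean_to_group[i], gi))
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean())


# ---------------------------------------------------------------------------
# coverage


def class_coverage(
    result: CoresetResult, manifest: DatasetManifest
) -> tuple[int, dict[str, int]]:
    """How many ground-truth classes the selection leaves empty, and the
    per-class selected counts (over all classes in the manifest)."""
    labels = manifest.labels_by_id()
    counts = {c: 0 for c in manifest.class_set()}
    for item_id in result.selected_ids:
        if item_id not in labels:
            raise ValueError(f"selected id {item_id!r} has no label in the manifest")
        counts[labels[item_id]] += 1
    classes_empty = sum(1 for v in counts.values() if v == 0)
    return classes_empty, counts


# ---------------------------------------------------------------------------
# the desk-scale classifier stand-in


class SoftmaxClassifier:
    """Multinomial logistic regression by full-batch gradient descent.

    A deliberately simple embedding-space classifier standing in for
    image fine-tuning in the benchmark: features are standardized with
    training-set statistics, weights start from a small seeded Gaussian,
    and a fixed number of plain gradient steps is taken. When a
    validation split is supplied, the weights with the lowest validation
    loss are kept, mirroring best-checkpoint selection. Only classes
    present in the training data can be predicted — which is exactly how
    missing coverage turns into zero F1 downstream.
    """

    def __init__(self, epochs: int = 200, lr: float = 0.1, seed: int = 0):
        self.epochs = epochs
        self.lr = lr
        self.seed = seed
        self.classes_: list | None = None

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        return (x - self._mu) / self._sd

    def fit(
        self,
        x_train: np.ndarray,
        y_train: Sequence,
        x_val: np.ndarray | None = None,
        y_val: Sequence | None = None,
    ) -> "SoftmaxClassifier":
        x_train = np.asarray(x_train, dtype=np.float64)
        self.classes_ = sorted(set(y_train))
        index = {c: i for i, c in enumerate(self.classes_)}
        y = np.array([index[c] for c in y_train])
        self._mu = x_train.mean(axis=0)
        self._sd = np.maximum(x_train.std(axis=0), 1e-8)
        x = self._standardize(x_train)
        n, d = x.shape
        c = len(self.classes_)
        rng = np.random.default_rng(self.seed)
        w = 0.01 * rng.standard_normal((d, c))
        b = np.zeros(c)

        has_val = x_val is not None and y_val is not None and len(y_val) > 0
        if has_val:
            keep = [i for i, lab in enumerate(y_val) if lab in index]
            has_val = len(keep) > 0
            if has_val:
                xv = self._standardize(np.asarray(x_val, dtype=np.float64)[keep])
                yv = np.array([index[y_val[i]] for i in keep])
        best_loss = np.inf
        best = (w.copy(), b.copy())

        onehot = np.zeros((n, c))
        onehot[np.arange(n), y] = 1.0
        for _ in range(self.epochs):
            logits = x @ w + b
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            grad = (p - onehot) / n
            w -= self.lr * (x.T @ grad)
            b -= self.lr * grad.sum(axis=0)
            if has_val:
                lv = xv @ w + b
                lv -= lv.max(axis=1, keepdims=True)
                pv = np.exp(lv)
                pv /= pv.sum(axis=1, keepdims=True)
                loss = -np.mean(np.log(np.maximum(pv[np.arange(len(yv)), yv], 1e-300)))
                if loss < best_loss:
                    best_loss = loss
                    best = (w.copy(), b.copy())
        if has_val:
            w, b = best
        self._w, self._b = w, b
        return self

    def predict(self, x: np.ndarray) -> list:
        assert self.classes_ is not None, "fit first"
        logits = self._standardize(np.asarray(x, dtype=np.float64)) @ self._w + self._b
        return [self.classes_[i] for i in np.argmax(logits, axis=1)]


ClassifierFactory = Callable[[int], SoftmaxClassifier]


def _default_classifier(seed: int) -> SoftmaxClassifier:
    return SoftmaxClassifier(epochs=200, lr=0.1, seed=seed)


# ---------------------------------------------------------------------------
# reports and the benchmark


@dataclass
class EvalReport:
    """Bundle of evaluation outputs for one coreset."""

    macro_f1: float | None = None
    per_class_f1: dict | None = None
    classes_empty_in_selection: int = 0
    per_class_selected_counts: dict = field(default_factory=dict)
    davies_bouldin: float | None = None
    silhouette: float | None = None

    def to_dict(self) -> dict:
        return {
            "macro_f1": self.macro_f1,
            "per_class_f1": self.per_class_f1,
            "classes_empty_in_selection": self.classes_empty_in_selection,
            "per_class_selected_counts": self.per_class_selected_counts,
            "davies_bouldin": self.davies_bouldin,
            "silhouette": self.silhouette,
        }


@dataclass
class BenchmarkSpec:
    """Protocol of the repeated-split comparison.

    For each repetition a fresh 10% test split is drawn, the remaining
    pool is reduced by every (fraction, strategy) pair, the classifier
    is trained on 90% of each coreset with 10% held for validation, and
    macro-F1 on the test split is recorded. Macro-F1 averages over the
    classes present in the test ground truth.
    """

    fractions: Sequence[float]
    strategies: Sequence[Strategy]
    repetitions: int = 3
    test_fraction: float = 0.10
    val_fraction: float = 0.10
    base_seed: int = 0
    classifier: ClassifierFactory = _default_classifier
    clusterer_cfg: KMeansConfig | None = None
    n_classes: int | None = None  # prior for class-based strategies

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie in (0, 1)")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.repetitions < 1:
            raise ValueError("repetitions must be ≥ 1")
        if not self.fractions:
            raise ValueError("at least one retention fraction required")
        if not self.strategies:
            raise ValueError("at least one strategy required")


def _train_val_split(
    ids: list[str], val_fraction: float, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    ids = sorted(ids)  # canonical order: the split depends on the set, not on selection order
    n_val = int(np.floor(len(ids) * val_fraction))
    if n_val < 1 or len(ids) - n_val < 1:
        raise ValueError(
            f"coreset of {len(ids)} items cannot support a {val_fraction:.0%} validation split"
        )
    perm = rng.permutation(len(ids))
    val = [ids[i] for i in perm[:n_val]]
    train = [ids[i] for i in perm[n_val:]]
    return train, val


def run_benchmark(
    embeddings: EmbeddingMatrix,
    manifest: DatasetManifest,
    spec: BenchmarkSpec,
) -> pd.DataFrame:
    """Run the repeated-split benchmark; one row per (fraction, strategy).

    Returns a DataFrame with columns ``fraction, strategy, mean_f1,
    std_f1, reps, mean_classes_empty`` (std is the sample standard
    deviation over repetitions; 0.0 when there is a single repetition).
    Fully reproducible from ``spec.base_seed``.
    """
    if not manifest.is_labeled:
        raise ValueError("the benchmark requires a labeled manifest")
    labels = manifest.labels_by_id()
    missing = [i for i in embeddings.ids if i not in labels]
    if missing:
        raise ValueError(f"manifest lacks labels for {len(missing)} embedded items")
    id_to_row = embeddings.index_of()
    n_classes = spec.n_classes or len(manifest.class_set())

    cells: dict[tuple[float, Strategy], dict[str, list[float]]] = {
        (f, s): {"f1": [], "empty": []} for f in spec.fractions for s in spec.strategies
    }
    for rep in range(spec.repetitions):
        rep_seed = spec.base_seed + rep
        rng_test = np.random.default_rng(derive_seed(rep_seed, "test-split"))
        n = embeddings.n_items
        n_test = int(np.floor(n * spec.test_fraction))
        if n_test < 1 or n - n_test < 1:
            raise ValueError("test_fraction leaves an empty test or training pool")
        perm = rng_test.permutation(n)
        test_rows = np.sort(perm[:n_test])
        pool_rows = np.sort(perm[n_test:])
        pool = embeddings.subset(pool_rows)
        x_test = embeddings.vectors[test_rows]
        y_test = [labels[embeddings.ids[i]] for i in test_rows]
        test_classes = sorted(set(y_test))

        for fraction in spec.fractions:
            m = subset_size(pool.n_items, fraction, "floor")
            # classifier seed and val split depend on (rep, fraction) only,
            # so strategies selecting the identical set score identically
            rng_split = np.random.default_rng(
                derive_seed(rep_seed, f"val-split-{fraction}")
            )
            split_state = rng_split.bit_generator.state
            train_seed = derive_seed(rep_seed, f"train-{fraction}")
            for strategy in spec.strategies:
                plan = SelectionPlan(
                    strategy=strategy,
                    coreset_size_m=m,
                    n_classes=n_classes
                    if strategy in (Strategy.K_EQ_CLASSES, Strategy.K_EQ_2CLASSES)
                    else None,
                    seed=derive_seed(rep_seed, f"select-{strategy.value}-{fraction}"),
                )
                result = select_coreset(pool, plan, spec.clusterer_cfg)
                empty, _ = class_coverage(result, manifest)

                rng_split.bit_generator.state = split_state
                train_ids, val_ids = _train_val_split(
                    result.selected_ids, spec.val_fraction, rng_split
                )
                x_tr = embeddings.vectors[[id_to_row[i] for i in train_ids]]
                y_tr = [labels[i] for i in train_ids]
                x_va = embeddings.vectors[[id_to_row[i] for i in val_ids]]
                y_va = [labels[i] for i in val_ids]
                clf = spec.classifier(train_seed)
                clf.fit(x_tr, y_tr, x_va, y_va)
                pred = clf.predict(x_test)
                # score over classes present in the test truth; a prediction
                # of any other class simply counts against the true class
                scores = per_class_f1(y_test, pred, sorted(set(y_test) | set(pred)))
                f1 = float(np.mean([scores[c] for c in test_classes]))
                cells[(fraction, strategy)]["f1"].append(f1)
                cells[(fraction, strategy)]["empty"].append(float(empty))
                logger.info(
                    "rep %d fraction %.4f strategy %s: M=%d macro-F1=%.4f empty=%d",
                    rep, fraction, strategy.value, m, f1, empty,
                )

    rows = []
    for (fraction, strategy), vals in cells.items():
        f1s = np.array(vals["f1"])
        rows.append(
            {
                "fraction": fraction,
                "strategy": strategy.value,
                "mean_f1": float(f1s.mean()),
                "std_f1": float(f1s.std(ddof=1)) if len(f1s) > 1 else 0.0,
                "reps": len(f1s),
                "mean_classes_empty": float(np.mean(vals["empty"])),
            }
        )
    return pd.DataFrame(rows)
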