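"""K-means over embedding vectors, written from first principles.

This is Lloyd's algorithm with k-means++ seeding, multiple restarts and
empty-cluster repair — the clustering engine of the coreset pipeline.
The objective is the classical inertia: the sum over items of squared
Euclidean distance to the assigned centroid. No third-party clustering
implementation is used; the selection strategies downstream depend on
the exact invariants documented on :class:`ClusterModel` (every item on
its nearest centroid with ties to the lowest index, no empty clusters
after repair), so they are enforced here rather than assumed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import EmbeddingMatrix

__all__ = ["KMeansConfig", "ClusterModel", "kmeans_fit", "assign", "inertia"]


@dataclass(frozen=True)
class KMeansConfig:
    """Knobs of the K-means fit.

    ``k`` is the fixed number of clusters the method requires up front.
    ``tol`` is the relative inertia improvement below which iteration
    stops; assignments becoming stationary also stops it. ``n_init``
    independent seedings are run and the lowest-inertia model kept,
    damping the variance of the random initialization.
    """

    k: int
    max_iter: int = 300
    tol: float = 1e-4
    n_init: int = 10
    seed: int = 0
    init: str = "kmeanspp"  # or "random_points"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be ≥ 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be ≥ 1")
        if self.tol < 0:
            raise ValueError("tol must be ≥ 0")
        if self.n_init < 1:
            raise ValueError("n_init must be ≥ 1")
        if self.init not in ("kmeanspp", "random_points"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class ClusterModel:
    """A fitted partition: centroids, assignments, inertia, diagnostics.

    ``inertia_history`` records the objective after every assignment
    step of the winning restart; Lloyd's algorithm guarantees it is
    non-increasing.
    """

    centroids: np.ndarray
    assignments: np.ndarray
    inertia: float
    n_iter_run: int
    converged: bool
    inertia_history: list[float] = field(default_factory=list)
    config: KMeansConfig | None = None

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def cluster_sizes(self) -> list[int]:
        return np.bincount(self.assignments, minlength=self.k).tolist()

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == cluster)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "centroids": self.centroids.tolist(),
            "assignments": self.assignments.tolist(),
            "inertia": self.inertia,
            "n_iter_run": self.n_iter_run,
            "converged": self.converged,
            "cluster_sizes": self.cluster_sizes,
            "config": None
            if self.config is None
            else {
                "k": self.config.k,
                "max_iter": self.config.max_iter,
                "tol": self.config.tol,
                "n_init": self.config.n_init,
                "seed": self.config.seed,
                "init": self.config.init,
            },
        }
        path.write_text(json.dumps(payload) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        payload = json.loads(Path(path).read_text())
        cfg = payload.get("config")
        return cls(
            centroids=np.array(payload["centroids"], dtype=np.float64),
            assignments=np.array(payload["assignments"], dtype=np.int64),
            inertia=float(payload["inertia"]),
            n_iter_run=int(payload["n_iter_run"]),
            converged=bool(payload["converged"]),
            config=None if cfg is None else KMeansConfig(**cfg),
        )


def _sq_dists(x: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances via the expansion
    ‖x‖² − 2x·c + ‖c‖², clipped at zero against round-off."""
    d = (
        np.einsum("ij,ij->i", x, x)[:, None]
        - 2.0 * (x @ centers.T)
        + np.einsum("ij,ij->i", centers, centers)[None, :]
    )
    np.maximum(d, 0.0, out=d)
    return d


def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = x.shape[0]
    centers = np.empty((k, x.shape[1]))
    centers[0] = x[rng.integers(n)]
    closest = _sq_dists(x, centers[0:1])[:, 0]
    for j in range(1, k):
        total = closest.sum()
        if total > 0:
            idx = rng.choice(n, p=closest / total)
        else:  # all remaining mass on already-chosen points (duplicates)
            idx = rng.integers(n)
        centers[j] = x[idx]
        np.minimum(closest, _sq_dists(x, centers[j : j + 1])[:, 0], out=closest)
    return centers


def _repair_empty(
    x: np.ndarray, centers: np.ndarray, dists: np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """Relocate each empty cluster's centroid to the point currently
    farthest from its assigned centroid, then reassign. Bounded passes;
    with k ≤ number of distinct points this terminates with no empties."""
    k = centers.shape[0]
    for _ in range(k):
        sizes = np.bincount(labels, minlength=k)
        empties = np.flatnonzero(sizes == 0)
        if empties.size == 0:
            break
        c = int(empties[0])
        contrib = dists[np.arange(x.shape[0]), labels]
        far = int(np.argmax(contrib))
        if contrib[far] <= 0.0:
            # all points coincide with their centroids (duplicate-heavy
            # input with k exceeding the number of distinct points); no
            # relocation can fill the cluster
            break
        centers[c] = x[far]
        dists[:, c] = _sq_dists(x, centers[c : c + 1])[:, 0]
        labels = np.argmin(dists, axis=1)
    return labels


def _lloyd(
    x: np.ndarray, centers: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float, int, bool, list[float]]:
    n, _ = x.shape
    k = centers.shape[0]
    dists = _sq_dists(x, centers)
    labels = np.argmin(dists, axis=1)
    labels = _repair_empty(x, centers, dists, labels)
    cur_inertia = float(dists[np.arange(n), labels].sum())
    history = [cur_inertia]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # update step: centroids become member means
        new_centers = centers.copy()
        sums = np.zeros_like(centers)
        np.add.at(sums, labels, x)
        sizes = np.bincount(labels, minlength=k)
        nonempty = sizes > 0
        new_centers[nonempty] = sums[nonempty] / sizes[nonempty, None]
        # assignment step
        dists = _sq_dists(x, new_centers)
        new_labels = np.argmin(dists, axis=1)
        new_labels = _repair_empty(x, new_centers, dists, new_labels)
        new_inertia = float(dists[np.arange(n), new_labels].sum())
        history.append(new_inertia)
        if np.array_equal(new_labels, labels):
            centers, labels, cur_inertia = new_centers, new_labels, new_inertia
            converged = True
            break
        improvement = cur_inertia - new_inertia
        prev = cur_inertia
        centers, labels, cur_inertia = new_centers, new_labels, new_inertia
        if prev > 0 and improvement <= tol * prev:
            converged = True
            break
    return centers, labels, cur_inertia, it, converged, history


def kmeans_fit(embeddings: EmbeddingMatrix, config: KMeansConfig) -> ClusterModel:
    """Fit K-means; returns the best of ``n_init`` seeded restarts.

    Deterministic given ``config.seed``. Raises if k exceeds the number
    of items.
    """
    x = embeddings.vectors
    n = x.shape[0]
    if config.k > n:
        raise ValueError(f"k={config.k} exceeds the number of items N={n}")
    seed_seq = np.random.SeedSequence(config.seed)
    best: ClusterModel | None = None
    for child in seed_seq.spawn(config.n_init):
        rng = np.random.default_rng(child)
        if config.init == "kmeanspp":
            centers = _kmeanspp_init(x, config.k, rng)
        else:
            centers = x[rng.choice(n, size=config.k, replace=False)].copy()
        centers, labels, inert, n_iter, converged, history = _lloyd(
            x, centers, config.max_iter, config.tol
        )
        if best is None or inert < best.inertia:
            best = ClusterModel(
                centroids=centers,
                assignments=labels,
                inertia=inert,
                n_iter_run=n_iter,
                converged=converged,
                inertia_history=history,
                config=config,
            )
    assert best is not None
    return best


def assign(model: ClusterModel, embeddings: EmbeddingMatrix) -> np.ndarray:
    """Map each item to its nearest centroid (squared Euclidean);
    exact ties go to the lowest cluster index."""
    if embeddings.dim != model.centroids.shape[1]:
        raise ValueError(
            f"embedding dim {embeddings.dim} != centroid dim {model.centroids.shape[1]}"
        )
    return np.argmin(_sq_dists(embeddings.vectors, model.centroids), axis=1)


def inertia(
    embeddings: EmbeddingMatrix, centroids: np.ndarray, assignments: np.ndarray
) -> float:
    """Sum of squared distances of items to their assigned centroids."""
    centroids = np.asarray(centroids, dtype=np.float64)
    assignments = np.asarray(assignments)
    if assignments.shape[0] != embeddings.n_items:
        raise ValueError("one assignment per item required")
    if assignments.size and (assignments.min() < 0 or assignments.max() >= centroids.shape[0]):
        raise ValueError("assignment index out of range")
    diff = embeddings.vectors - centroids[assignments]
    return float(np.einsum("ij,ij->", diff, diff))
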