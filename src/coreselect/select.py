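"""Coreset construction from fitted clusters.

Three cluster-count strategies plus a random baseline:

* ``K_EQ_IMAGES`` — K equals the coreset size M; one item is drawn from
  each cluster. The most diverse configuration and the method's best.
* ``K_EQ_CLASSES`` / ``K_EQ_2CLASSES`` — K equals the (known) number of
  classes, or twice it; roughly M/K items are drawn per cluster.
* ``RANDOM`` — M items uniformly without replacement, ignoring the
  embedding geometry entirely; the baseline every strategy is judged
  against.

The coreset size can be given directly (M) or as a retention fraction of
the pool, with the two integer conventions observed in practice (floor
vs nearest) both exposed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

from ._seeds import derive_seed
from .cluster import ClusterModel, KMeansConfig, kmeans_fit
from .io import EmbeddingMatrix

__all__ = [
    "Strategy",
    "SelectionPlan",
    "CoresetResult",
    "subset_size",
    "allocate_per_cluster",
    "random_select",
    "select_coreset",
]


class Strategy(str, Enum):
    K_EQ_IMAGES = "images"
    K_EQ_CLASSES = "classes"
    K_EQ_2CLASSES = "2classes"
    RANDOM = "random"


@dataclass(frozen=True)
class SelectionPlan:
    """What to select: strategy, budget (M or fraction), seed.

    ``n_classes`` is a user-supplied prior required by the class-based
    strategies — the pool itself is unlabeled, but the number of classes
    is assumed known. ``within_cluster`` chooses how items are drawn
    inside each cluster: uniformly at random (default) or nearest to the
    centroid.
    """

    strategy: Strategy
    coreset_size_m: int | None = None
    retention_fraction: float | None = None
    n_classes: int | None = None
    seed: int = 0
    within_cluster: str = "random"  # or "nearest"

    def __post_init__(self) -> None:
        if (self.coreset_size_m is None) == (self.retention_fraction is None):
            raise ValueError(
                "provide exactly one of coreset_size_m or retention_fraction"
            )
        if self.coreset_size_m is not None and self.coreset_size_m < 1:
            raise ValueError("coreset size M must be a positive integer")
        if self.retention_fraction is not None and not (
            0.0 < self.retention_fraction <= 1.0
        ):
            raise ValueError("retention_fraction must lie in (0, 1]")
        if self.strategy in (Strategy.K_EQ_CLASSES, Strategy.K_EQ_2CLASSES):
            if self.n_classes is None or self.n_classes < 1:
                raise ValueError(
                    f"strategy {self.strategy.value!r} requires a positive n_classes"
                )
        if self.within_cluster not in ("random", "nearest"):
            raise ValueError(f"unknown within_cluster mode {self.within_cluster!r}")

    def resolve_m(self, pool_n: int) -> int:
        if self.coreset_size_m is not None:
            return self.coreset_size_m
        assert self.retention_fraction is not None
        return subset_size(pool_n, self.retention_fraction, "floor")


@dataclass
class CoresetResult:
    """The M selected ids with, for cluster-based strategies, the index
    of the cluster each id came from (−1 for the random baseline)."""

    selected_ids: list[str]
    provenance: dict[str, int]
    plan_echo: SelectionPlan
    k_used: int

    @property
    def m(self) -> int:
        return len(self.selected_ids)

    def write(self, path: str | Path, sidecar: bool = True) -> Path:
        """Newline-delimited id list; JSON sidecar with provenance."""
        path = Path(path)
        path.write_text("".join(i + "\n" for i in self.selected_ids))
        if sidecar:
            plan = self.plan_echo
            payload = {
                "strategy": plan.strategy.value,
                "coreset_size_m": self.m,
                "retention_fraction": plan.retention_fraction,
                "n_classes": plan.n_classes,
                "seed": plan.seed,
                "within_cluster": plan.within_cluster,
                "k_used": self.k_used,
                "provenance": self.provenance,
            }
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(payload, indent=2) + "\n"
            )
        return path

    @staticmethod
    def read_ids(path: str | Path) -> list[str]:
        return [
            line for line in Path(path).read_text().splitlines() if line.strip()
        ]


def subset_size(pool_n: int, fraction: float, convention: str = "floor") -> int:
    """Number of items a retention fraction keeps from a pool of ``pool_n``.

    ``floor`` truncates pool_n × fraction; ``nearest`` rounds half away
    from zero. Both conventions occur in published subset tables, so the
    choice is explicit. Errors if the result would be 0.
    """
    if pool_n < 1:
        raise ValueError("pool_n must be ≥ 1")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    # guard against binary-representation dust in pool_n × fraction
    product = round(pool_n * fraction, 9)
    if convention == "floor":
        size = math.floor(product)
    elif convention == "nearest":
        size = math.floor(product + 0.5)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if size < 1:
        raise ValueError(
            f"fraction {fraction} of pool {pool_n} yields an empty subset"
        )
    return min(size, pool_n)


def allocate_per_cluster(m: int, cluster_sizes: Sequence[int]) -> list[int]:
    """Split a budget of M draws across K clusters as evenly as possible.

    Base allocation floor(M/K) everywhere; the M mod K leftover goes one
    each to the largest clusters (ties by lowest cluster index). A quota
    exceeding its cluster's size is capped and the deficit redistributed
    one draw at a time to the cluster with the most remaining capacity.
    When every cluster is large enough, allocations differ by at most 1.
    """
    sizes = np.asarray(cluster_sizes, dtype=np.int64)
    if sizes.size == 0:
        raise ValueError("at least one cluster required")
    if np.any(sizes < 0):
        raise ValueError("cluster sizes must be non-negative")
    if m < 0:
        raise ValueError("M must be non-negative")
    if sizes.sum() < m:
        raise ValueError(f"cannot draw M={m} items from {int(sizes.sum())} available")
    k = sizes.size
    alloc = np.full(k, m // k, dtype=np.int64)
    remainder = m % k
    if remainder:
        largest = np.argsort(-sizes, kind="stable")[:remainder]
        alloc[largest] += 1
    overflow = np.maximum(alloc - sizes, 0)
    deficit = int(overflow.sum())
    alloc = np.minimum(alloc, sizes)
    while deficit > 0:
        capacity = sizes - alloc
        target = int(np.argmax(capacity))  # ties → lowest index
        if capacity[target] == 0:
            raise ValueError("no remaining capacity to absorb the deficit")
        alloc[target] += 1
        deficit -= 1
    return alloc.tolist()


def random_select(ids: Sequence[str], m: int, seed: int) -> CoresetResult:
    """The baseline: M ids uniformly without replacement."""
    n = len(ids)
    if m < 1:
        raise ValueError("coreset size M must be a positive integer")
    if m > n:
        raise ValueError(f"M={m} exceeds pool size N={n}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=m, replace=False)
    selected = [str(ids[i]) for i in chosen]
    plan = SelectionPlan(strategy=Strategy.RANDOM, coreset_size_m=m, seed=seed)
    return CoresetResult(
        selected_ids=selected,
        provenance={i: -1 for i in selected},
        plan_echo=plan,
        k_used=0,
    )


def _draw_from_cluster(
    members: np.ndarray,
    quota: int,
    mode: str,
    rng: np.random.Generator,
    dists: np.ndarray | None,
) -> np.ndarray:
    if quota == 0:
        return members[:0]
    if mode == "nearest":
        assert dists is not None
        order = np.argsort(dists[members], kind="stable")
        return members[order[:quota]]
    return rng.choice(members, size=quota, replace=False)


def select_coreset(
    embeddings: EmbeddingMatrix,
    plan: SelectionPlan,
    clusterer_cfg: KMeansConfig | None = None,
) -> CoresetResult:
    """Build the coreset for ``plan`` over the given embedding pool.

    Cluster-based strategies fit K-means (K = M, number of classes, or
    twice it), then draw from each cluster: exactly one item for
    ``K_EQ_IMAGES``, otherwise the per-cluster quotas of
    :func:`allocate_per_cluster`. The K-means seed and the within-cluster
    sampling seed are derived from ``plan.seed`` with distinct stage
    tags, so both are reproducible. ``clusterer_cfg`` supplies the
    remaining K-means knobs (its ``k`` and ``seed`` are overridden).
    """
    n = embeddings.n_items
    m = plan.resolve_m(n)
    if m > n:
        raise ValueError(f"M={m} exceeds pool size N={n}")

    if plan.strategy is Strategy.RANDOM:
        result = random_select(embeddings.ids, m, derive_seed(plan.seed, "sample"))
        return CoresetResult(
            selected_ids=result.selected_ids,
            provenance=result.provenance,
            plan_echo=plan,
            k_used=0,
        )

    if plan.strategy is Strategy.K_EQ_IMAGES:
        k = m
    elif plan.strategy is Strategy.K_EQ_CLASSES:
        k = int(plan.n_classes)  # type: ignore[arg-type]
    else:
        k = 2 * int(plan.n_classes)  # type: ignore[arg-type]
    if k > n:
        raise ValueError(f"strategy {plan.strategy.value!r} needs k={k} ≤ N={n}")
    if k > m:
        raise ValueError(
            f"strategy {plan.strategy.value!r} yields k={k} clusters for only M={m} draws"
        )

    if clusterer_cfg is None:
        clusterer_cfg = KMeansConfig(k=k)
    cfg = replace(clusterer_cfg, k=k, seed=derive_seed(plan.seed, "kmeans"))
    model = kmeans_fit(embeddings, cfg)

    if plan.strategy is Strategy.K_EQ_IMAGES:
        quotas = [1] * k
    else:
        quotas = allocate_per_cluster(m, model.cluster_sizes)

    dists = None
    if plan.within_cluster == "nearest":
        diff = embeddings.vectors - model.centroids[model.assignments]
        dists = np.einsum("ij,ij->i", diff, diff)

    rng = np.random.default_rng(derive_seed(plan.seed, "sample"))
    selected: list[str] = []
    provenance: dict[str, int] = {}
    for c in range(k):
        members = model.members(c)
        for i in _draw_from_cluster(members, quotas[c], plan.within_cluster, rng, dists):
            item_id = embeddings.ids[int(i)]
            selected.append(item_id)
            provenance[item_id] = c
    return CoresetResult(
        selected_ids=selected, provenance=provenance, plan_echo=plan, k_used=k
    )
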