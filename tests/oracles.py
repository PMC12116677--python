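"""Independent brute-force oracles used only to check the package."""

import itertools

import numpy as np


def exhaustive_kmeans_optimum(x: np.ndarray, k: int) -> float:
    """Global K-means optimum by enumerating all k^N labelings.

    Uses the identity: the within-cluster sum of squares of a cluster
    with member sum S and count n is  sum ||x_i||^2 - ||S||^2 / n,  so a
    labeling's total cost needs only per-cluster sums and counts. The
    enumeration is exhaustive (feasible for N <= 10, k <= 3); the inner
    algebra is vectorized over all labelings at once.
    """
    n, d = x.shape
    sq = float(np.einsum("ij,ij->", x, x))
    labelings = np.array(
        list(itertools.product(range(k), repeat=n)), dtype=np.int8
    )  # P x N
    onehot = (labelings[:, :, None] == np.arange(k, dtype=np.int8)).astype(np.float64)
    counts = onehot.sum(axis=1)  # P x k
    sums = np.einsum("pnk,nd->pkd", onehot, x)  # P x k x d
    norm2 = np.einsum("pkd,pkd->pk", sums, sums)
    with np.errstate(divide="ignore", invalid="ignore"):
        reduction = np.where(counts > 0, norm2 / counts, 0.0)
    costs = sq - reduction.sum(axis=1)
    return float(costs.min())


def nearest_centroid_assign(x: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """O(N*k) scan: per item, index of the nearest centroid, ties to the
    lowest index. Deliberately naive."""
    out = np.empty(x.shape[0], dtype=int)
    for i in range(x.shape[0]):
        best_d, best_c = np.inf, -1
        for c in range(centroids.shape[0]):
            d = float(((x[i] - centroids[c]) ** 2).sum())
            if d < best_d:
                best_d, best_c = d, c
        out[i] = best_c
    return out
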