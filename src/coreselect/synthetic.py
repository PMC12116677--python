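"""Synthetic embedding clouds with class structure and imbalance.

The generator emulates what a strong self-supervised feature extractor
produces on a class-structured image collection: each class occupies one
(or a few) Gaussian modes in embedding space, classes differ wildly in
frequency, and a single ``separation`` knob controls how far apart the
class modes sit relative to their spread. This is the substrate on which
clustering, selection and evaluation are exercised without any image
downloads.

``PLANTVILLAGE_CLASS_COUNTS`` transcribes the per-class image counts of
the public PlantVillage leaf-disease collection (38 classes, 54 303
images, heavily skewed: 152 to 5 507 images per class); scaled-down
versions of this profile are the package's standard imbalanced study
pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import DatasetManifest, EmbeddingMatrix, ManifestRecord

__all__ = [
    "BlobSpec",
    "generate_blobs",
    "generate_manifest",
    "power_law_counts",
    "scale_counts",
    "PLANTVILLAGE_CLASS_COUNTS",
]

# Per-class image counts of the 38-class PlantVillage leaf collection,
# in its published class order. Total: 54 303.
PLANTVILLAGE_CLASS_COUNTS: tuple[int, ...] = (
    630, 621, 276, 1645, 1502, 854, 1052, 513, 1192, 1162, 985, 1180,
    1384, 423, 1076, 5507, 2291, 360, 997, 1478, 1000, 152, 1000, 371,
    5090, 1835, 456, 1109, 2127, 1000, 1592, 1910, 952, 1771, 1676,
    1404, 373, 5357,
)


def scale_counts(counts: Sequence[int], factor: float) -> list[int]:
    """Divide a count profile by ``factor``, rounding, flooring at 1."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    return [max(1, round(c / factor)) for c in counts]


def power_law_counts(n_classes: int, imbalance_exponent: float, total_n: int) -> list[int]:
    """Imbalanced count profile: count of class rank r ∝ r^(−exponent).

    Rescaled so the counts sum exactly to ``total_n`` (largest-remainder
    apportionment), floored at 1 item per class. Exponent 0 gives a
    balanced profile; larger exponents give steeper skew.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be ≥ 1")
    if imbalance_exponent < 0:
        raise ValueError("imbalance_exponent must be ≥ 0")
    if total_n < n_classes:
        raise ValueError("total_n must allow at least 1 item per class")
    ranks = np.arange(1, n_classes + 1, dtype=np.float64)
    weights = ranks ** (-imbalance_exponent)
    ideal = weights / weights.sum() * total_n
    counts = np.maximum(1, np.floor(ideal).astype(int))
    # largest-remainder top-up / trim to hit total_n exactly
    while counts.sum() < total_n:
        remainders = ideal - counts
        counts[int(np.argmax(remainders))] += 1
    while counts.sum() > total_n:
        over = np.where(counts > 1, counts - ideal, -np.inf)
        counts[int(np.argmax(over))] -= 1
    return [int(c) for c in counts]


@dataclass
class BlobSpec:
    """Specification of a synthetic class-clustered embedding cloud.

    Exactly one of ``class_counts`` or (``imbalance_exponent`` +
    ``total_n``) fixes the per-class item counts. ``separation`` is the
    ratio of the class-centroid hypersphere radius to the within-class
    spread ``noise_sd``; values ≥ 8 give essentially separable classes,
    values near 1 give heavy overlap. ``submodes_per_class`` > 1 splits
    each class into several offset Gaussian sub-modes to mimic
    intra-class variability (e.g. the same flower species in two colors).
    """

    n_classes: int
    class_counts: Sequence[int] | None = None
    imbalance_exponent: float | None = None
    total_n: int | None = None
    dim: int = 32
    separation: float = 8.0
    submodes_per_class: int = 1
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be ≥ 1")
        if self.dim < 1:
            raise ValueError("dim must be ≥ 1")
        if self.separation <= 0:
            raise ValueError("separation must be > 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.submodes_per_class < 1:
            raise ValueError("submodes_per_class must be ≥ 1")
        has_counts = self.class_counts is not None
        has_profile = self.imbalance_exponent is not None and self.total_n is not None
        if has_counts == has_profile:
            raise ValueError(
                "provide exactly one of class_counts or (imbalance_exponent, total_n)"
            )
        if has_counts:
            counts = list(self.class_counts)  # type: ignore[arg-type]
            if len(counts) != self.n_classes:
                raise ValueError(
                    f"class_counts has length {len(counts)}, expected {self.n_classes}"
                )
            if any(c < 1 for c in counts):
                raise ValueError("all class counts must be ≥ 1")

    def resolved_counts(self) -> list[int]:
        if self.class_counts is not None:
            return [int(c) for c in self.class_counts]
        assert self.imbalance_exponent is not None and self.total_n is not None
        return power_law_counts(self.n_classes, self.imbalance_exponent, self.total_n)


def _spaced_sphere_points(
    rng: np.random.Generator, n: int, dim: int, radius: float
) -> np.ndarray:
    """Uniform directions on the radius-``radius`` hypersphere with a
    minimum-spacing rejection step.

    A draw closer than a target spacing (initially equal to the radius)
    to an already-placed point is rejected; when a draw cannot be placed
    within a retry budget the target spacing is halved. This keeps the
    placement essentially uniform in high dimension (where random
    directions are nearly orthogonal and the constraint is almost never
    active) while preventing the low-dimensional accident of two class
    centroids landing on top of each other.
    """
    points = np.empty((n, dim))
    spacing = radius
    placed = 0
    while placed < n:
        ok = False
        for _ in range(200):
            v = rng.standard_normal(dim)
            norm = np.linalg.norm(v)
            if norm == 0.0:
                continue
            candidate = v / norm * radius
            if placed == 0 or np.min(
                np.linalg.norm(points[:placed] - candidate, axis=1)
            ) >= spacing:
                points[placed] = candidate
                placed += 1
                ok = True
                break
        if not ok:
            spacing /= 2.0
    return points


def generate_blobs(spec: BlobSpec) -> tuple[EmbeddingMatrix, np.ndarray]:
    """Generate the embedding cloud and per-item integer class labels.

    Class centroids sit on a hypersphere of radius
    ``separation × noise_sd``; sub-mode centers are offset from their
    class centroid by half that radius in a random direction; items are
    the sub-mode center plus isotropic Gaussian noise of sd ``noise_sd``.
    Per-class counts are exact by construction and output is bit-identical
    for identical spec + seed. Item ids are zero-padded decimal strings
    in generation order.
    """
    counts = spec.resolved_counts()
    rng = np.random.default_rng(spec.seed)
    radius = spec.separation * spec.noise_sd
    centroids = _spaced_sphere_points(rng, spec.n_classes, spec.dim, radius)

    total = sum(counts)
    vectors = np.empty((total, spec.dim))
    labels = np.empty(total, dtype=np.int64)
    row = 0
    for c, count in enumerate(counts):
        if spec.submodes_per_class == 1:
            centers = centroids[c][None, :]
        else:
            offsets = rng.standard_normal((spec.submodes_per_class, spec.dim))
            offsets /= np.linalg.norm(offsets, axis=1)[:, None]
            centers = centroids[c] + 0.5 * radius * offsets
        # spread the class count as evenly as possible over its sub-modes
        per_mode = np.full(len(centers), count // len(centers))
        per_mode[: count % len(centers)] += 1
        for center, m in zip(centers, per_mode):
            if m == 0:
                continue
            vectors[row : row + m] = center + spec.noise_sd * rng.standard_normal(
                (m, spec.dim)
            )
            labels[row : row + m] = c
            row += m
    width = max(1, len(str(total - 1)))
    ids = [f"{i:0{width}d}" for i in range(total)]
    return EmbeddingMatrix(ids, vectors), labels


def generate_manifest(
    embeddings: EmbeddingMatrix,
    labels: Sequence[int] | Sequence[str],
    class_names: Sequence[str] | None = None,
) -> DatasetManifest:
    """Attach ground-truth labels to the generated items.

    The URIs are synthetic placeholders; the manifest's labels exist only
    so that evaluation can measure class coverage and classifier F1 —
    selection itself never sees them.
    """
    if len(labels) != embeddings.n_items:
        raise ValueError(
            f"{len(labels)} labels for {embeddings.n_items} items"
        )
    records = []
    for item_id, label in zip(embeddings.ids, labels):
        if class_names is not None:
            name = class_names[int(label)]
        else:
            name = f"class_{int(label):02d}" if not isinstance(label, str) else label
        records.append(
            ManifestRecord(id=item_id, uri=f"synthetic://{item_id}", label=name)
        )
    return DatasetManifest(records)
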