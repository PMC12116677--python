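import numpy as np
import pytest

import coreselect as cs


@pytest.fixture
def toy4():
    """Two tight pairs 10 apart: the hand-computable clustering fixture."""
    return cs.EmbeddingMatrix(
        ["a", "b", "c", "d"],
        np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]]),
    )


@pytest.fixture
def two_groups():
    """10 points in 2 well-separated groups of 5 (separation 10, dim 2)."""
    spec = cs.BlobSpec(
        n_classes=2, class_counts=[5, 5], dim=2, separation=10.0, seed=7
    )
    return cs.generate_blobs(spec)


@pytest.fixture(scope="session")
def study_pool():
    """The imbalanced 38-class study pool: per-class counts of the
    PlantVillage collection scaled down 10x, separation 8, dim 32."""
    counts = cs.scale_counts(cs.PLANTVILLAGE_CLASS_COUNTS, 10)
    spec = cs.BlobSpec(
        n_classes=38, class_counts=counts, dim=32, separation=8.0, seed=2024
    )
    embeddings, labels = cs.generate_blobs(spec)
    manifest = cs.generate_manifest(embeddings, labels)
    return embeddings, labels, manifest
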