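import numpy as np
import pytest
from sklearn.metrics import (
    davies_bouldin_score,
    f1_score,
    silhouette_score,
)

import coreselect as cs


# --- macro-F1 ---------------------------------------------------------------

def test_macro_f1_perfect():
    assert cs.macro_f1(["A", "B", "A"], ["A", "B", "A"], ["A", "B"]) == 1.0


def test_macro_f1_hand_computed():
    # F1_A = 2/3, F1_B = 4/5 -> macro 11/15
    value = cs.macro_f1(["A", "A", "B", "B"], ["A", "B", "B", "B"], ["A", "B"])
    assert value == pytest.approx(11 / 15)


def test_macro_f1_degenerate_class_scores_zero(caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="coreselect.evaluate"):
        scores = cs.per_class_f1(["A", "A"], ["A", "A"], ["A", "C"])
    assert scores["C"] == 0.0
    assert "C" in caplog.text
    assert cs.macro_f1(["A", "A"], ["A", "A"], ["A", "C"]) == pytest.approx(0.5)


def test_macro_f1_relabel_invariance():
    rng = np.random.default_rng(3)
    y_true = rng.integers(0, 4, 100).tolist()
    y_pred = rng.integers(0, 4, 100).tolist()
    base = cs.macro_f1(y_true, y_pred, [0, 1, 2, 3])
    relabel = {0: "w", 1: "x", 2: "y", 3: "z"}
    mapped = cs.macro_f1(
        [relabel[t] for t in y_true],
        [relabel[p] for p in y_pred],
        ["w", "x", "y", "z"],
    )
    assert mapped == pytest.approx(base)
    assert 0.0 <= base <= 1.0


def test_macro_f1_agrees_with_reference():
    rng = np.random.default_rng(8)
    y_true = rng.integers(0, 5, 200)
    y_pred = rng.integers(0, 5, 200)
    ours = cs.macro_f1(y_true.tolist(), y_pred.tolist(), list(range(5)))
    ref = f1_score(y_true, y_pred, labels=list(range(5)), average="macro")
    assert ours == pytest.approx(ref, abs=1e-12)


def test_macro_f1_input_validation():
    with pytest.raises(ValueError):
        cs.macro_f1([], [], ["A"])
    with pytest.raises(ValueError):
        cs.macro_f1(["A"], ["A", "B"], ["A", "B"])
    with pytest.raises(ValueError, match="outside"):
        cs.macro_f1(["A"], ["Q"], ["A"])


# --- validity indices -------------------------------------------------------

def test_davies_bouldin_toy(toy4):
    assert cs.davies_bouldin(toy4, [0, 0, 1, 1]) == pytest.approx(0.1)


def test_davies_bouldin_tight_groups_near_zero():
    x = np.vstack([np.full((5, 2), 0.0), np.full((5, 2), 9.0)])
    x += 1e-9 * np.arange(10)[:, None]  # epsilon spread, distinct points
    embeddings = cs.EmbeddingMatrix([str(i) for i in range(10)], x)
    assert cs.davies_bouldin(embeddings, [0] * 5 + [1] * 5) == pytest.approx(0.0, abs=1e-8)


def test_silhouette_toy(toy4):
    expected = 1 - 2 / (10 + np.sqrt(101))  # a=1, b=(10+sqrt(101))/2 per point
    assert cs.silhouette(toy4, [0, 0, 1, 1]) == pytest.approx(expected, abs=1e-6)


def test_silhouette_label_permutation_invariance(toy4):
    assert cs.silhouette(toy4, [1, 1, 0, 0]) == cs.silhouette(toy4, [0, 0, 1, 1])


def test_silhouette_overlapping_groups_near_zero():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((500, 4))
    embeddings = cs.EmbeddingMatrix([str(i) for i in range(500)], x)
    labels = rng.integers(0, 2, 500)
    assert abs(cs.silhouette(embeddings, labels)) < 0.1


def test_silhouette_singleton_group_scores_zero():
    x = np.array([[0.0, 0.0], [0.0, 1.0], [9.0, 0.0]])
    embeddings = cs.EmbeddingMatrix(["a", "b", "c"], x)
    # point c is alone in its group -> contributes 0
    value = cs.silhouette(embeddings, [0, 0, 1])
    # s(a) = (9-1)/9, s(b) = (sqrt(82)-1)/sqrt(82), s(c) = 0
    expected = (8 / 9 + 1 - 1 / np.sqrt(82) + 0.0) / 3
    assert value == pytest.approx(expected, abs=1e-12)


def test_indices_require_two_groups(toy4):
    with pytest.raises(ValueError):
        cs.davies_bouldin(toy4, [0, 0, 0, 0])
    with pytest.raises(ValueError):
        cs.silhouette(toy4, [1, 1, 1, 1])


@pytest.mark.parametrize("index_pair", [
    (cs.davies_bouldin, davies_bouldin_score),
    (cs.silhouette, silhouette_score),
])
def test_indices_agree_with_independent_reference(index_pair):
    """50 random instances (n <= 200, d <= 10, groups <= 6): agreement
    with the independently implemented reference within 1e-9."""
    ours, reference = index_pair
    rng = np.random.default_rng(1234)
    for _ in range(50):
        n = int(rng.integers(20, 201))
        d = int(rng.integers(2, 11))
        g = int(rng.integers(2, 7))
        x = rng.standard_normal((n, d)) + rng.integers(0, 4, (n, 1))
        labels = rng.integers(0, g, n)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(0, g, n)
        embeddings = cs.EmbeddingMatrix([str(i) for i in range(n)], x)
        assert ours(embeddings, labels) == pytest.approx(
            reference(x, labels), abs=1e-9
        )


# --- coverage ---------------------------------------------------------------

def _coreset_from_ids(ids):
    plan = cs.SelectionPlan(strategy=cs.Strategy.RANDOM, coreset_size_m=len(ids))
    return cs.CoresetResult(list(ids), {i: -1 for i in ids}, plan, 0)


def test_coverage_all_classes_present(two_groups):
    embeddings, labels = two_groups
    manifest = cs.generate_manifest(embeddings, labels)
    empty, counts = cs.class_coverage(_coreset_from_ids(embeddings.ids), manifest)
    assert empty == 0
    assert sum(counts.values()) == 10


def test_coverage_pigeonhole():
    spec = cs.BlobSpec(n_classes=5, class_counts=[3] * 5, dim=2, separation=5.0, seed=0)
    embeddings, labels = cs.generate_blobs(spec)
    manifest = cs.generate_manifest(embeddings, labels)
    empty, counts = cs.class_coverage(_coreset_from_ids(embeddings.ids[:3]), manifest)
    assert empty >= 2  # 3 items cannot cover 5 classes
    assert sum(v == 0 for v in counts.values()) == empty


def test_coverage_missing_label_rejected(two_groups):
    embeddings, labels = two_groups
    manifest = cs.generate_manifest(embeddings, labels)
    with pytest.raises(ValueError, match="ghost"):
        cs.class_coverage(_coreset_from_ids(["ghost"]), manifest)


def test_random_selection_misses_rare_classes(study_pool):
    """On the imbalanced 38-class pool, random draws of 146 items leave
    some classes empty on average (the failure mode coreset selection
    is designed to avoid)."""
    embeddings, _, manifest = study_pool
    empties = []
    for seed in range(30):
        result = cs.random_select(embeddings.ids, 146, seed=seed)
        empty, _ = cs.class_coverage(result, manifest)
        empties.append(empty)
    assert np.mean(empties) > 0


# --- benchmark --------------------------------------------------------------

def _small_pool(seed=0):
    spec = cs.BlobSpec(
        n_classes=4, class_counts=[40, 25, 60, 35], dim=8, separation=8.0, seed=seed
    )
    embeddings, labels = cs.generate_blobs(spec)
    return embeddings, cs.generate_manifest(embeddings, labels)


def test_benchmark_table_shape_and_determinism():
    embeddings, manifest = _small_pool()
    spec = cs.BenchmarkSpec(
        fractions=[0.10, 0.30],
        strategies=[cs.Strategy.K_EQ_IMAGES, cs.Strategy.RANDOM],
        repetitions=2,
        base_seed=7,
        clusterer_cfg=cs.KMeansConfig(k=1, n_init=2, max_iter=100),
    )
    t1 = cs.run_benchmark(embeddings, manifest, spec)
    t2 = cs.run_benchmark(embeddings, manifest, spec)
    assert len(t1) == 4  # |fractions| x |strategies|
    assert set(t1.columns) >= {"fraction", "strategy", "mean_f1", "std_f1", "reps"}
    assert (t1["reps"] == 2).all()
    assert t1.equals(t2)
    assert t1["mean_f1"].between(0, 1).all()


def test_benchmark_full_pool_strategies_coincide():
    """At retention 1.0 both the K=M strategy and the random baseline use
    the entire pool, so with the shared classifier seed the scores are
    identical."""
    embeddings, manifest = _small_pool(seed=3)
    spec = cs.BenchmarkSpec(
        fractions=[1.0],
        strategies=[cs.Strategy.K_EQ_IMAGES, cs.Strategy.RANDOM],
        repetitions=1,
        base_seed=11,
        clusterer_cfg=cs.KMeansConfig(k=1, n_init=1, max_iter=50),
    )
    table = cs.run_benchmark(embeddings, manifest, spec)
    f1 = table.set_index("strategy")["mean_f1"]
    assert f1["images"] == f1["random"]


def test_benchmark_requires_labels(two_groups):
    embeddings, _ = two_groups
    manifest = cs.DatasetManifest(
        [cs.ManifestRecord(i, f"u{i}") for i in embeddings.ids]
    )
    spec = cs.BenchmarkSpec(
        fractions=[0.5], strategies=[cs.Strategy.RANDOM], repetitions=1
    )
    with pytest.raises(ValueError, match="label"):
        cs.run_benchmark(embeddings, manifest, spec)


def test_benchmark_tiny_coreset_rejected():
    embeddings, manifest = _small_pool()
    spec = cs.BenchmarkSpec(
        fractions=[0.02],  # M = 2 -> no room for a 10% validation split
        strategies=[cs.Strategy.RANDOM],
        repetitions=1,
    )
    with pytest.raises(ValueError, match="validation"):
        cs.run_benchmark(embeddings, manifest, spec)


def test_softmax_classifier_separable():
    embeddings, manifest = _small_pool(seed=9)
    labels = manifest.labels_by_id()
    y = [labels[i] for i in embeddings.ids]
    clf = cs.SoftmaxClassifier(epochs=200, lr=0.1, seed=0)
    clf.fit(embeddings.vectors, y)
    pred = clf.predict(embeddings.vectors)
    assert np.mean([p == t for p, t in zip(pred, y)]) > 0.98


def test_softmax_classifier_only_predicts_seen_classes():
    rng = np.random.default_rng(2)
    x = rng.standard_normal((20, 3))
    clf = cs.SoftmaxClassifier(epochs=50, seed=1)
    clf.fit(x, ["a"] * 10 + ["b"] * 10)
    assert set(clf.predict(rng.standard_normal((50, 3)))) <= {"a", "b"}


def test_benchmark_directional_trend(study_pool):
    """On the imbalanced pool the coreset advantage over random shrinks
    as the retention fraction grows (negative Spearman trend), echoing
    the behaviour the method is built around."""
    from scipy.stats import spearmanr

    embeddings, _, manifest = study_pool
    fractions = [0.003, 0.01, 0.05, 0.30]
    spec = cs.BenchmarkSpec(
        fractions=fractions,
        strategies=[cs.Strategy.K_EQ_IMAGES, cs.Strategy.RANDOM],
        repetitions=3,
        base_seed=17,
        clusterer_cfg=cs.KMeansConfig(k=1, n_init=1, max_iter=100),
    )
    table = cs.run_benchmark(embeddings, manifest, spec)
    pivot = table.pivot(index="fraction", columns="strategy", values="mean_f1")
    gaps = (pivot["images"] - pivot["random"]).loc[fractions]
    rho = spearmanr(fractions, gaps.values).statistic
    assert rho < 0
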