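import numpy as np
import pytest

from conftest import provider_for
from otoaudit.cluster import (
    DuplicateSetCollection,
    EmbeddingMatrix,
    crossfold_embeddings,
    embed_default,
    group_by_threshold,
    leakage_auc_compare,
    redundancy_report,
    style_report,
)
from otoaudit.data_model import ImageRecord, Manifest
from otoaudit.synthetic import SyntheticConfig, generate_images, render_base_image


class TestEmbedDefault:
    def test_unit_norm_and_determinism(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            img = rng.integers(0, 256, (32, 40, 3)).astype(np.uint8)
            v = embed_default(img)
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-9)
            assert np.array_equal(v, embed_default(img))

    def test_identical_images_zero_distance(self, sample_image):
        a, b = embed_default(sample_image), embed_default(sample_image.copy())
        assert 1 - a @ b == pytest.approx(0.0, abs=1e-12)

    def test_negative_image_far_away(self, sample_image):
        a = embed_default(sample_image)
        b = embed_default(255 - sample_image)
        assert 1 - a @ b > 0.1


def _emb(ids, vectors):
    v = np.asarray(vectors, float)
    v = v / np.linalg.norm(v, axis=1, keepdims=True)
    return EmbeddingMatrix(ids=tuple(ids), vectors=v)


class TestGroupByThreshold:
    def test_exact_duplicates_only_at_alpha_zero(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(8, 16))
        vectors = np.vstack([base[:1], base[:1], base[:1], base[1:]])
        ids = [f"v{i}" for i in range(10)]
        sets = group_by_threshold(_emb(ids, vectors), 0.0)
        assert sets.sets == (("v0", "v1", "v2"),)

    def test_large_alpha_saturates(self):
        rng = np.random.default_rng(2)
        emb = _emb([f"v{i}" for i in range(12)], rng.normal(size=(12, 8)))
        sets = group_by_threshold(emb, 2.0)
        assert len(sets.sets) == 1 and len(sets.sets[0]) == 12

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        vecs = rng.normal(size=(30, 10))
        ids = [f"v{i}" for i in range(30)]
        a = group_by_threshold(_emb(ids, vecs), 0.4)
        perm = rng.permutation(30)
        b = group_by_threshold(_emb([ids[i] for i in perm], vecs[perm]), 0.4)
        assert a.sets == b.sets

    def test_threshold_monotonicity_refinement(self):
        rng = np.random.default_rng(4)
        emb = _emb([f"v{i}" for i in range(40)], rng.normal(size=(40, 6)))
        prev = group_by_threshold(emb, 0.05)
        for alpha in (0.1, 0.2, 0.4, 0.8):
            cur = group_by_threshold(emb, alpha)
            containing = {i: s for s in cur.sets for i in s}
            for small in prev.sets:
                assert len({id(containing.get(i)) for i in small}) == 1, (
                    f"set {small} split when alpha grew to {alpha}"
                )
            prev = cur

    def test_planted_duplicates_recovered_exactly(self):
        cfg = SyntheticConfig(
            n_per_class=60, duplicate_fraction=0.2, duplicate_jitter=0.0, seed=21
        )
        manifest, truth, images = generate_images(cfg)
        emb = crossfold_embeddings(
            manifest, image_provider=provider_for(manifest, images)
        )
        sets = group_by_threshold(emb, 0.003)
        assert set(sets.sets) == set(truth.true_duplicate_sets)

    def test_subpixel_jitter_still_recovered(self):
        """The empirically calibrated recovery bound: noise-only jitter
        (no integer translation) keeps duplicates within the threshold."""
        cfg = SyntheticConfig(
            n_per_class=60, duplicate_fraction=0.2, duplicate_jitter=0.5, seed=22
        )
        manifest, truth, images = generate_images(cfg)
        emb = crossfold_embeddings(
            manifest, image_provider=provider_for(manifest, images)
        )
        sets = group_by_threshold(emb, 0.003)
        assert set(sets.sets) == set(truth.true_duplicate_sets)


class TestCrossfoldEmbeddings:
    def test_default_equals_single_pass(self, small_biased_dataset):
        manifest, _, images = small_biased_dataset
        provider = provider_for(manifest, images)
        emb = crossfold_embeddings(manifest, image_provider=provider)
        for i, r in enumerate(manifest.records):
            np.testing.assert_allclose(
                emb.vectors[i], embed_default(provider(r)), atol=1e-12
            )

    def test_trainable_factory_averaged_and_deterministic(self, small_biased_dataset):
        manifest, _, images = small_biased_dataset
        provider = provider_for(manifest, images)
        seen_sizes = []

        def factory(train_images, train_labels, seed):
            seen_sizes.append(len(train_images))
            mean = np.mean([im.mean() for im in train_images])

            def embed(img):
                v = embed_default(img).copy()
                v[0] += mean / 255.0  # fold-dependent component
                return v / np.linalg.norm(v)

            return embed

        a = crossfold_embeddings(
            manifest, image_provider=provider, embedder_factory=factory, k=5, seed=3
        )
        assert len(seen_sizes) == 5
        assert all(abs(s - 160) <= 1 for s in seen_sizes)  # 4/5 of 200
        b = crossfold_embeddings(
            manifest, image_provider=provider, embedder_factory=factory, k=5, seed=3
        )
        np.testing.assert_array_equal(a.vectors, b.vectors)
        norms = np.linalg.norm(a.vectors, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_factory_failure_reports_fold(self, small_biased_dataset):
        manifest, _, images = small_biased_dataset

        def bad_factory(train_images, train_labels, seed):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="fold 0"):
            crossfold_embeddings(
                manifest,
                image_provider=provider_for(manifest, images),
                embedder_factory=bad_factory,
            )


def _manifest_with_splits(rows):
    """rows: list of (image_id, label, split)"""
    return Manifest(
        records=tuple(
            ImageRecord(image_id=i, path=f"{i}.png", label=lab, split=split)
            for i, lab, split in rows
        )
    )


class TestRedundancyReport:
    def test_worked_example(self):
        man = _manifest_with_splits(
            [("a", 1, "train"), ("b", 1, "internal_val"), ("c", 0, "train"),
             ("d", 0, "train"), ("e", 0, "internal_val"), ("f", 1, "internal_val")]
        )
        sets = DuplicateSetCollection(sets=(("a", "b", "c"), ("d", "e")), alpha=0.1)
        rep = redundancy_report(sets, man)
        assert (rep.set_count, rep.avg_size, rep.max_size) == (2, 2.5, 3)
        assert rep.redundant_count == 3
        assert rep.test_set_size == 3
        assert rep.test_with_dup_count == 2  # b and e share sets with train imgs
        assert rep.test_without_dup_count == 1
        assert rep.test_with_dup_abnormal_ratio == pytest.approx(0.5)

    def test_no_sets_all_clean(self):
        man = _manifest_with_splits(
            [("a", 1, "train"), ("b", 0, "internal_val"), ("c", 1, "internal_val")]
        )
        rep = redundancy_report(DuplicateSetCollection(sets=(), alpha=0.1), man)
        assert rep.set_count == 0 and rep.redundant_count == 0
        assert rep.test_without_dup_count == rep.test_set_size == 2

    def test_identities_on_random_inputs(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(10, 60))
            rows = [
                (f"i{k}", int(rng.integers(0, 2)),
                 "train" if rng.random() < 0.8 else "internal_val")
                for k in range(n)
            ]
            man = _manifest_with_splits(rows)
            ids = [s[0] for s in rows]
            rng.shuffle(ids)
            sets, pos = [], 0
            while pos + 2 <= len(ids) and len(sets) < 5:
                size = int(rng.integers(2, 5))
                sets.append(tuple(sorted(ids[pos : pos + size])))
                pos += size
            rep = redundancy_report(
                DuplicateSetCollection(sets=tuple(sets), alpha=0.1), man
            )
            assert rep.redundant_count == sum(len(s) - 1 for s in sets)
            assert rep.test_with_dup_count + rep.test_without_dup_count == rep.test_set_size


class TestLeakageCompare:
    def test_null_partition_p_moderate(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=200)
        labels = np.r_[np.ones(100), np.zeros(100)]
        mask = np.zeros(200, bool)
        mask[::2] = True
        out = leakage_auc_compare(scores, labels, mask)
        assert out["n_with"] + out["n_without"] == 200
        assert 0.05 < out["p_value"] < 0.95

    def test_one_class_subset_not_computable(self):
        scores = np.r_[np.ones(4) * 0.9, np.zeros(10)]
        labels = np.r_[np.ones(4), np.ones(3), np.zeros(7)]
        mask = np.r_[np.ones(4), np.zeros(10)].astype(bool)
        out = leakage_auc_compare(scores, labels, mask)
        assert out["auc_with"] is None and out["p_value"] is None


class TestStyleReport:
    def test_planted_styles_flagged_pure(self):
        cfg = SyntheticConfig(
            n_per_class=100, style_bias_prob=1.0, clinical_contrast=60.0, seed=31
        )
        manifest, truth, images = generate_images(cfg)
        emb = crossfold_embeddings(
            manifest, image_provider=provider_for(manifest, images)
        )
        clusters = style_report(emb, manifest, alpha_style=0.06, min_size=20)
        flagged = [c for c in clusters if c.flagged]
        assert len(flagged) == 2
        for c in flagged:
            assert c.purity == 1.0
            assert c.fisher_p < 1e-10

    def test_no_false_flags_without_style_bias(self):
        cfg = SyntheticConfig(
            n_per_class=100, style_bias_prob=0.0, clinical_contrast=60.0, seed=32
        )
        manifest, _, images = generate_images(cfg)
        emb = crossfold_embeddings(
            manifest, image_provider=provider_for(manifest, images)
        )
        clusters = style_report(emb, manifest, alpha_style=0.06, min_size=20)
        assert all(c.purity < 0.9 and not c.flagged for c in clusters)

    def test_min_size_larger_than_n_empty(self, small_biased_dataset):
        manifest, _, images = small_biased_dataset
        emb = crossfold_embeddings(
            manifest, image_provider=provider_for(manifest, images)
        )
        assert style_report(emb, manifest, alpha_style=0.06, min_size=10_000) == []
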