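import numpy as np
import pandas as pd
import pytest

from txseg.downstream import (
    CountMatrix,
    agreement,
    classification_report_from_predictions,
    cluster_cells,
    count_matrix,
    morpho_embed,
    rf_evaluate,
    roc_auc,
    zscore_features,
)
from txseg.simulate import planted_counts


class TestCountMatrix:
    def test_simple_tally(self):
        t = pd.DataFrame(
            {"x": [0] * 4, "y": [0] * 4, "gene": ["X", "X", "X", "Y"], "qv": [30.0] * 4}
        )
        cm = count_matrix(np.array([1, 1, 1, 2]), t, cells=[1, 2])
        assert cm.counts[cm.cells.index(1), cm.genes.index("X")] == 3
        assert cm.counts[cm.cells.index(2), cm.genes.index("Y")] == 1

    def test_unassigned_and_dropped_cells_contribute_nowhere(self):
        t = pd.DataFrame(
            {"x": [0] * 5, "y": [0] * 5, "gene": ["X"] * 5, "qv": [30.0] * 5}
        )
        cm = count_matrix(np.array([0, 1, 2, 3, 1]), t, cells=[1, 2])
        assert cm.total == 3  # label 0 and label 3 excluded

    def test_conservation(self, rng):
        n = 500
        t = pd.DataFrame(
            {
                "x": np.zeros(n),
                "y": np.zeros(n),
                "gene": rng.choice([f"g{i}" for i in range(8)], n),
                "qv": np.full(n, 30.0),
            }
        )
        assign = rng.integers(0, 6, n)
        cells = [1, 2, 3]
        cm = count_matrix(assign, t, cells)
        assert cm.total == int(np.isin(assign, cells).sum())

    def test_mtx_round_trip(self, tmp_path, rng):
        from scipy.io import mmread

        cm = CountMatrix(cells=[1, 2], genes=["a", "b", "c"], counts=rng.integers(0, 9, (2, 3)))
        cm.write_mtx(tmp_path / "counts")
        back = np.asarray(mmread(tmp_path / "counts.mtx").todense())
        np.testing.assert_array_equal(back, cm.counts)


class TestClustering:
    @pytest.fixture(scope="class")
    def planted(self):
        return planted_counts(n_types=10, cells_per_type=100, seed=3)

    def test_recovers_planted_profiles(self, planted):
        cm, types = planted
        labels = cluster_cells(cm, target_k=10, seed=0)
        assert labels.max() + 1 == 10
        assert agreement(types, labels).ari > 0.9

    def test_deterministic_per_seed(self, planted):
        cm, _ = planted
        a = cluster_cells(cm, target_k=10, seed=0)
        b = cluster_cells(cm, target_k=10, seed=0)
        np.testing.assert_array_equal(a, b)

    def test_duplicated_archetypes_exact_recovery(self):
        rng = np.random.default_rng(0)
        arche = rng.integers(0, 50, (5, 20))
        counts = np.repeat(arche, 25, axis=0)  # 25 identical cells per type
        cm = CountMatrix(
            cells=list(range(125)), genes=[f"g{i}" for i in range(20)], counts=counts
        )
        labels = cluster_cells(cm, target_k=5, seed=0)
        truth = np.repeat(np.arange(5), 25)
        assert agreement(truth, labels).ari == pytest.approx(1.0)

    def test_too_few_cells_rejected(self):
        cm = CountMatrix(cells=[1, 2], genes=["a", "b"], counts=np.ones((2, 2), dtype=int))
        with pytest.raises(ValueError):
            cluster_cells(cm, target_k=10)


class TestAgreement:
    def test_identical_labelings_all_ones(self, rng):
        a = rng.integers(0, 6, 300)
        ag = agreement(a, a.copy())
        assert ag.ari == ag.ami == ag.homogeneity == ag.completeness == 1.0

    def test_single_cluster_has_zero_homogeneity(self):
        truth = np.repeat([0, 1, 2], 30)
        one = np.zeros(90, dtype=int)
        ag = agreement(truth, one)
        assert ag.homogeneity == pytest.approx(0.0)
        assert ag.completeness == pytest.approx(1.0)

    def test_homogeneity_completeness_duality(self, rng):
        a = rng.integers(0, 4, 200)
        b = rng.integers(0, 7, 200)
        assert agreement(a, b).homogeneity == pytest.approx(agreement(b, a).completeness)

    def test_random_labels_near_zero_ari(self, rng):
        a = rng.integers(0, 5, 200)
        b = rng.permutation(a)
        assert abs(agreement(a, b).ari) < 0.05

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            agreement([0, 1], [0, 1, 2])


class TestClassificationMetrics:
    def test_two_class_worked_example(self):
        # TP1=1, FP1=0, FN1=1, TP2=2 → accuracy 3/4, F1 = (2/3, 4/5)
        y_true = [1, 1, 2, 2]
        y_pred = [1, 2, 2, 2]
        rep = classification_report_from_predictions(y_true, y_pred)
        assert rep.accuracy == pytest.approx(3 / 4)
        assert rep.per_class[1].f1 == pytest.approx(2 / 3)
        assert rep.per_class[2].f1 == pytest.approx(4 / 5)
        assert rep.macro_f1 == pytest.approx(11 / 15)

    def test_metrics_match_sklearn_on_random_predictions(self, rng):
        from sklearn.metrics import f1_score, roc_auc_score

        for _ in range(100):
            n = int(rng.integers(20, 60))
            k = int(rng.integers(2, 5))
            y_true = rng.integers(0, k, n)
            while len(np.unique(y_true)) < k:
                y_true = rng.integers(0, k, n)
            y_pred = rng.integers(0, k, n)
            scores = rng.random((n, k))
            scores /= scores.sum(1, keepdims=True)
            rep = classification_report_from_predictions(
                y_true, y_pred, scores=scores, classes=list(range(k))
            )
            assert rep.macro_f1 == pytest.approx(
                f1_score(y_true, y_pred, average="macro", zero_division=0)
            )
            sk_macro_auc = np.mean(
                [roc_auc_score(y_true == c, scores[:, c]) for c in range(k)]
            )
            assert rep.macro_auc == pytest.approx(sk_macro_auc)

    def test_roc_auc_tie_handling(self):
        # all scores equal → AUC 1/2 by tie averaging
        assert roc_auc([True, False, True, False], [0.5] * 4) == pytest.approx(0.5)
        # perfectly separating scores → 1
        assert roc_auc([False, False, True, True], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_absent_class_excluded_with_flag(self):
        rep = classification_report_from_predictions([0, 0, 1], [0, 1, 1], classes=[0, 1, 2])
        assert rep.excluded == [2]
        assert rep.macro_f1 == pytest.approx(
            (rep.per_class[0].f1 + rep.per_class[1].f1) / 2
        )


class TestMorphoEmbedding:
    @pytest.fixture(scope="class")
    def populations(self):
        rng = np.random.default_rng(7)
        n = 60
        elongated = pd.DataFrame(
            {
                "aspect_ratio": rng.normal(3.0, 0.2, n),
                "roundness": rng.normal(0.3, 0.03, n),
                "area": rng.normal(80, 5, n),
            }
        )
        compact = pd.DataFrame(
            {
                "aspect_ratio": rng.normal(1.1, 0.05, n),
                "roundness": rng.normal(0.85, 0.03, n),
                "area": rng.normal(40, 5, n),
            }
        )
        feats = pd.concat([elongated, compact], ignore_index=True)
        types = np.array(["spindle"] * n + ["round"] * n)
        return feats, types

    def test_zscore_standardizes(self, populations):
        feats, _ = populations
        z, dropped = zscore_features(feats)
        assert dropped == []
        assert np.allclose(z.mean(), 0, atol=1e-12)
        assert np.allclose(z.std(ddof=0), 1, atol=1e-12)

    def test_constant_feature_dropped_with_warning(self, populations):
        feats, _ = populations
        feats = feats.assign(const=1.0)
        with pytest.warns(UserWarning, match="const"):
            _, dropped = zscore_features(feats)
        assert dropped == ["const"]

    def test_separated_populations_have_separated_centroids(self, populations):
        feats, types = populations
        emb = morpho_embed(feats, datasets=np.repeat("d0", len(feats)), types=types, seed=0)
        cents = emb.centroids
        gap = np.hypot(*(cents.loc[("d0", "spindle")] - cents.loc[("d0", "round")]))
        spread = []
        for t in ("spindle", "round"):
            pts = emb.embedding[types == t]
            spread.append(np.hypot(*(pts - pts.mean(0)).T).mean())
        assert gap > np.mean(spread)

    def test_duplicated_dataset_centroids_coincide(self, populations):
        feats, types = populations
        both = pd.concat([feats, feats], ignore_index=True)
        ds = np.array(["a"] * len(feats) + ["b"] * len(feats))
        emb = morpho_embed(both, datasets=ds, types=np.concatenate([types, types]), seed=0)
        # duplicated points land essentially on top of each other, so the
        # per-dataset centroids coincide up to embedding jitter
        for t in ("spindle", "round"):
            np.testing.assert_allclose(
                emb.centroids.loc[("a", t)], emb.centroids.loc[("b", t)], atol=0.1
            )


class TestRandomForestProtocol:
    def test_separable_morphologies_classified_perfectly(self, rng):
        n = 80
        frames = []
        types = []
        for i in range(5):
            frames.append(
                pd.DataFrame(
                    {
                        "area": rng.normal(40 + 25 * i, 1.0, n),
                        "aspect_ratio": rng.normal(1 + 0.6 * i, 0.05, n),
                    }
                )
            )
            types += [f"type{i}"] * n
        rep = rf_evaluate(pd.concat(frames, ignore_index=True), np.array(types), seed=0)
        assert rep.accuracy > 0.95
        assert rep.macro_f1 > 0.95
        assert rep.macro_auc > 0.95

    def test_unknown_cells_excluded_and_top5_kept(self, rng):
        n = 30
        feats = pd.DataFrame({"a": rng.normal(0, 1, 7 * n)})
        types = np.concatenate(
            [np.repeat(f"t{i}", n) for i in range(6)] + [np.repeat("unknown", n)]
        )
        feats.loc[types == "t5", "a"] += 100  # make one class separable
        rep = rf_evaluate(feats, types, seed=0, n_top_classes=5)
        assert "unknown" not in rep.classes
        assert len(rep.classes) == 5
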