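import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_dataset
from dropkit.cell_quality import (
    SizeThresholds,
    extract_features,
    extreme_fraction_threshold,
    filter_cells,
    initial_labels,
    score_cells,
    size_thresholds,
    train_quality_classifier,
)
from dropkit.simulate import simulate_quality_features


class TestSizeThresholds:
    def test_two_population_recovery(self, quality_scale):
        data, truth = quality_scale
        sizes = data.cell_sizes()
        th = size_thresholds(sizes.to_numpy())
        cells = sizes.reindex(truth.cells[truth.cells.is_cell].index).dropna()
        bg = sizes.drop(index=cells.index, errors="ignore")
        boundary = np.sqrt(bg.max() * cells.min())
        assert boundary / 2 <= th.t_l <= boundary * 2
        assert boundary / 2 <= th.t_u <= boundary * 2

    def test_strictly_linear_curve_raises(self):
        rng = np.random.default_rng(0)
        ranks = np.arange(1, 301)
        sizes = 1e4 / ranks  # exactly linear in log-log
        with pytest.raises(ValueError, match="manually"):
            size_thresholds(sizes)

    def test_too_few_barcodes_raises(self):
        with pytest.raises(ValueError):
            size_thresholds(np.arange(50))

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            SizeThresholds(10, 5)


class TestInitialLabels:
    def test_top_75_percent_above_upper(self):
        sizes = pd.Series(np.arange(1, 201), index=[f"c{i}" for i in range(200)])
        th = SizeThresholds(t_l=20, t_u=100)
        labels = initial_labels(sizes, th)
        assert (labels == "high").sum() == 75  # 100 cells above t_U, top 75%
        # the high label goes to the largest cells
        assert set(sizes[labels == "high"].index) == set(sizes.nlargest(75).index)

    def test_partition_is_complete(self):
        rng = np.random.default_rng(1)
        sizes = pd.Series(rng.integers(1, 1000, 500))
        labels = initial_labels(sizes, SizeThresholds(50, 500))
        assert labels.isin(["high", "low", "unknown"]).all()
        assert len(labels) == len(sizes)
        assert (sizes[labels == "low"] < 50).all()


class TestExtractFeatures:
    def test_hand_built_fixture(self):
        rows = [
            ("AAAA", "AA", "MT-g", 4),
            ("AAAA", "AC", "g1", 2),
            ("AAAA", "AG", "g1", 2),
            ("AAAA", "AT", "g2", 1),
        ]
        data = make_dataset(rows)
        feats = extract_features(data, {"MT-g"})
        row = feats.loc["AAAA"]
        assert row["mito_fraction"] == pytest.approx(1 / 4)
        assert row["reads_per_umi"] == pytest.approx(9 / 4)
        assert row["umis_per_gene"] == pytest.approx(4 / 3)
        assert row["low_exp_fraction"] == pytest.approx(2 / 3)
        assert row["intergenic_fraction"] == 0.0

    def test_all_singletons_low_expressed(self):
        data = make_dataset([("AAAA", "AA", "g1", 1), ("AAAA", "AC", "g2", 1)])
        feats = extract_features(data, set())
        assert feats.loc["AAAA", "low_exp_fraction"] == 1.0
        assert feats.loc["AAAA", "reads_per_umi"] == 1.0

    def test_intergenic_fraction(self):
        data = make_dataset([("AAAA", "AA", "g1", 6)])
        inter = make_dataset([("AAAA", "AC", "__intergenic__", 2)])
        inter.df["intergenic"] = True
        from dropkit.records import Dataset

        combined = Dataset(
            pd.concat([data.df, inter.df], ignore_index=True),
            np.vstack([data.quals, inter.quals]),
            2,
            aggregate=False,
        )
        feats = extract_features(combined, set())
        assert feats.loc["AAAA", "intergenic_fraction"] == pytest.approx(2 / 8)


class TestExtremeThreshold:
    def test_constant_vector(self):
        assert extreme_fraction_threshold(np.full(20, 0.3)) == pytest.approx(0.3)

    def test_uniform_grid_hand_computed(self):
        values = np.arange(10) / 100.0  # 0.00 .. 0.09
        m = stats.trim_mean(values, 0.2)
        a = stats.median_abs_deviation(values, scale=1.0)
        assert extreme_fraction_threshold(values) == pytest.approx(m + 4 * a)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(2)
        values = rng.random(50)
        shuffled = values.copy()
        rng.shuffle(shuffled)
        assert extreme_fraction_threshold(values) == pytest.approx(
            extreme_fraction_threshold(shuffled)
        )


class TestClassifier:
    def test_separable_case_nearly_perfect(self):
        features, labels, true_labels, _ = simulate_quality_features(150, 0.0, seed=3)
        clf = train_quality_classifier(features, labels)
        scores = score_cells(clf, features)
        pred = scores >= 0.5
        truth = true_labels == "high"
        assert (pred == truth).mean() >= 0.99

    def test_missing_class_raises(self):
        features, labels, _, _ = simulate_quality_features(40, 0.0, seed=3)
        labels[:] = "high"
        with pytest.raises(ValueError):
            train_quality_classifier(features, labels)

    def test_scores_bounded(self):
        features, labels, _, _ = simulate_quality_features(100, 0.0, seed=4)
        clf = train_quality_classifier(features, labels)
        rng = np.random.default_rng(0)
        random_feats = pd.DataFrame(
            rng.random((500, features.shape[1])) * 3, columns=features.columns
        )
        s = score_cells(clf, random_feats)
        assert ((s >= 0) & (s <= 1)).all()

    def test_score_tracks_generative_quality(self, quality_scale):
        """Damaged cells' severity latent should be mirrored by the score."""
        data, truth = quality_scale
        sizes = data.cell_sizes()
        mito = {g for g in data.df["gene"].unique() if g.startswith("MT-")}
        feats = extract_features(data, mito)
        th = size_thresholds(sizes.to_numpy())
        labels = initial_labels(sizes, th)
        clf = train_quality_classifier(feats, labels)
        scores = score_cells(clf, feats)
        cells = truth.cells[truth.cells.is_cell]
        joined = pd.concat([scores, cells["quality"]], axis=1).dropna()
        damaged = cells[cells.damaged].index.intersection(joined.index)
        healthy = cells[~cells.damaged].index.intersection(joined.index)
        assert scores[damaged].median() < scores[healthy].median()
        rho = stats.spearmanr(
            joined["quality_score"], joined["quality"]
        ).statistic
        assert rho > 0.3


class TestFilterCells:
    def test_rescue_and_filter_rules(self):
        scores = pd.Series({"big_bad": 0.05, "small_good": 0.95, "big_good": 0.5})
        sizes = pd.Series({"big_bad": 500, "small_good": 50, "big_good": 600})
        th = SizeThresholds(t_l=30, t_u=100)
        out = filter_cells(scores, sizes, th)
        assert out.loc["big_bad", "status"] == "filtered"
        assert out.loc["small_good", "status"] == "rescued"
        assert out.loc["big_good", "kept"]

    def test_all_high_scores_keep_everything_passing_min_genes(self):
        idx = [f"c{i}" for i in range(6)]
        scores = pd.Series(1.0, index=idx)
        sizes = pd.Series([10, 20, 200, 300, 400, 500], index=idx)
        genes = pd.Series([1, 5, 50, 50, 50, 2], index=idx)
        out = filter_cells(scores, sizes, SizeThresholds(15, 100), genes, min_genes=5)
        assert out["kept"].sum() == 4  # c0 (1 gene) and c5 (2 genes) fail min_genes
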