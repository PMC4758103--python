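import numpy as np
import pandas as pd
import pytest

from cellqc.exceptions import ModelIOError, ValidationError
from cellqc.features import FeatureTable
from cellqc.feature_selection import FeatureScaling
from cellqc.io import QualityLabels
from cellqc.svm_model import (
    CellQualityModel,
    EnsembleModel,
    SVMHyperparams,
    hyperparameter_search,
    load_model,
    nested_cross_validation,
    save_model,
    small_grid,
    train_ensemble,
)
from conftest import make_feature_table


def labeled_clusters(n_low=20, n_high=60, sep=3.0, seed=0, n_feat=2):
    rng = np.random.default_rng(seed)
    X = np.vstack([
        rng.normal(sep, 0.3, size=(n_low, n_feat)),
        rng.normal(-sep, 0.3, size=(n_high, n_feat)),
    ])
    ft = make_feature_table(X)
    labels = QualityLabels(
        pd.Series(["LOW"] * n_low + ["HIGH"] * n_high, index=ft.cell_ids)
    )
    return ft, labels


TINY_GRID = [
    SVMHyperparams(g, c, w)
    for g in (0.25, 1.0) for c in (1.0, 10.0) for w in (1.0,)
]


class TestHyperparameterSearch:
    def test_separable_data_tie_breaks_to_smallest(self):
        ft, labels = labeled_clusters()
        hp = hyperparameter_search(ft, labels, TINY_GRID, k=4, seed=0)
        assert (hp.gamma, hp.cost) == (0.25, 1.0)

    def test_single_class_rejected(self):
        ft, _ = labeled_clusters()
        all_high = QualityLabels(pd.Series("HIGH", index=ft.cell_ids))
        with pytest.raises(ValidationError, match="single class"):
            hyperparameter_search(ft, all_high, TINY_GRID, k=2)

    def test_same_seed_same_selection(self):
        ft, labels = labeled_clusters(sep=0.5, seed=2)
        grid = small_grid()
        hp1 = hyperparameter_search(ft, labels, grid, k=4, seed=9)
        hp2 = hyperparameter_search(ft, labels, grid, k=4, seed=9)
        assert hp1 == hp2

    def test_empty_grid_rejected(self):
        ft, labels = labeled_clusters()
        with pytest.raises(ValidationError, match="grid"):
            hyperparameter_search(ft, labels, [], k=2)

    def test_class_weights_matter_on_imbalanced_overlap(self):
        """With overlapping classes at 12/88 imbalance, the F2-selected
        weight upweights LOW rather than collapsing to all-HIGH."""
        rng = np.random.default_rng(1)
        X = np.vstack([
            rng.normal(0.8, 1.0, size=(12, 1)),
            rng.normal(-0.8, 1.0, size=(88, 1)),
        ])
        ft = make_feature_table(X)
        labels = QualityLabels(
            pd.Series(["LOW"] * 12 + ["HIGH"] * 88, index=ft.cell_ids)
        )
        grid = [SVMHyperparams(0.03125, 0.0625, w) for w in (1.0, 4.0, 8.0, 16.0)]
        hp = hyperparameter_search(ft, labels, grid, k=5, seed=0)
        assert hp.class_weight_low > 1.0


class TestNestedCV:
    def test_separable_fixture_perfect(self):
        ft, labels = labeled_clusters(n_low=20, n_high=40)
        cv = nested_cross_validation(
            ft, labels, TINY_GRID, k_outer=5, k_inner=4, seed=0
        )
        assert cv.mean_sensitivity == 1.0
        assert cv.mean_specificity == 1.0
        assert len(cv.folds) == 5

    def test_minimal_two_fold_runs(self):
        ft, labels = labeled_clusters(n_low=4, n_high=4)
        cv = nested_cross_validation(
            ft, labels, TINY_GRID, k_outer=2, k_inner=2, seed=0
        )
        assert len(cv.folds) == 2

    def test_summary_mentions_folds(self):
        ft, labels = labeled_clusters(n_low=6, n_high=10)
        cv = nested_cross_validation(
            ft, labels, TINY_GRID, k_outer=3, k_inner=2, seed=0
        )
        assert "outer folds" in cv.summary()


class _Stub:
    """Stands in for a fitted member: votes LOW per a fixed pattern."""

    def __init__(self, pattern):
        self.pattern = np.asarray(pattern)

    def predict(self, X):
        return self.pattern[: len(X)]


def stub_ensemble(patterns, n_feat=2):
    names = [f"f{j}" for j in range(n_feat)]
    scaling = FeatureScaling(
        pd.Series(0.0, index=names),
        pd.Series(1.0, index=names),
        pd.Series(False, index=names),
    )
    hp = SVMHyperparams(1.0, 1.0)
    return EnsembleModel([( _Stub(p), hp) for p in patterns], names, scaling)


class TestEnsembleVoting:
    def test_majority_vote_and_fraction(self):
        # 3 of 5 members vote LOW for the first cell, 1 of 5 for the second
        patterns = [[1, 0], [1, 0], [1, 1], [0, 0], [0, 0]]
        model = stub_ensemble(patterns)
        ft = make_feature_table(np.zeros((2, 2)))
        labels, frac = model.predict(ft)
        assert labels.quality.tolist() == ["LOW", "HIGH"]
        assert frac.tolist() == [0.6, 0.2]

    def test_exact_tie_resolves_to_low(self):
        patterns = [[1], [1], [0], [0]]
        model = stub_ensemble(patterns)
        ft = make_feature_table(np.zeros((1, 2)))
        labels, frac = model.predict(ft)
        assert labels.quality.tolist() == ["LOW"]
        assert frac.tolist() == [0.5]

    def test_missing_feature_is_an_error(self):
        model = stub_ensemble([[1]])
        ft = make_feature_table(np.zeros((1, 1)), names=["f0"])
        with pytest.raises(ValidationError, match="f1"):
            model.predict(ft)


class TestTrainEnsemble:
    def test_member_count_and_metadata(self):
        ft, labels = labeled_clusters()
        model = train_ensemble(ft, labels, TINY_GRID, n_members=3, k=4, seed=0)
        assert model.n_members == 3
        assert model.metadata["n_low"] == 20

    def test_single_member_degenerates_to_tuned_svm(self):
        ft, labels = labeled_clusters()
        model = train_ensemble(ft, labels, TINY_GRID, n_members=1, k=4, seed=0)
        pred, frac = model.predict(ft)
        assert set(frac.unique()) <= {0.0, 1.0}

    def test_same_seed_byte_identical_archive(self, tmp_path):
        ft, labels = labeled_clusters()
        m1 = train_ensemble(ft, labels, TINY_GRID, n_members=2, k=4, seed=5)
        m2 = train_ensemble(ft, labels, TINY_GRID, n_members=2, k=4, seed=5)
        save_model(m1, tmp_path / "a.pkl")
        save_model(m2, tmp_path / "b.pkl")
        assert (tmp_path / "a.pkl").read_bytes() == (tmp_path / "b.pkl").read_bytes()

    def test_training_predictions_recover_labels(self):
        ft, labels = labeled_clusters()
        model = train_ensemble(ft, labels, TINY_GRID, n_members=3, k=4, seed=0)
        pred, _ = model.predict(ft)
        assert (pred.quality == labels.quality).all()

    def test_prediction_invariant_to_cell_order_and_extra_features(self):
        ft, labels = labeled_clusters()
        model = train_ensemble(ft, labels, TINY_GRID, n_members=3, k=4, seed=0)
        _, frac = model.predict(ft)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ft.n_cells)
        shuffled = FeatureTable(
            ft.values.iloc[perm].assign(extra=1.0),
            pd.Series("technical", index=[*ft.feature_names, "extra"]),
            pd.Series(False, index=[*ft.feature_names, "extra"]),
        )
        _, frac2 = model.predict(shuffled)
        pd.testing.assert_series_equal(
            frac2.sort_index(), frac.sort_index(), check_names=False
        )


class TestModelIO:
    def test_save_load_predict_round_trip(self, tmp_path):
        ft, labels = labeled_clusters()
        model = train_ensemble(ft, labels, TINY_GRID, n_members=2, k=4, seed=1)
        _, before = model.predict(ft)
        save_model(model, tmp_path / "m.pkl")
        loaded = load_model(tmp_path / "m.pkl")
        _, after = loaded.predict(ft)
        pd.testing.assert_series_equal(before, after)
        assert loaded.feature_names == model.feature_names

    def test_truncated_file_is_integrity_error(self, tmp_path):
        ft, labels = labeled_clusters()
        model = train_ensemble(ft, labels, TINY_GRID, n_members=1, k=4, seed=1)
        save_model(model, tmp_path / "m.pkl")
        data = (tmp_path / "m.pkl").read_bytes()
        (tmp_path / "trunc.pkl").write_bytes(data[: len(data) // 2])
        with pytest.raises(ModelIOError):
            load_model(tmp_path / "trunc.pkl")

    def test_non_model_file_rejected(self, tmp_path):
        (tmp_path / "junk.pkl").write_bytes(b"not a pickle at all")
        with pytest.raises(ModelIOError):
            load_model(tmp_path / "junk.pkl")


class TestModelResultsInterface:
    def test_from_dataframe_fit_predict_summary(self):
        ft, labels = labeled_clusters()
        model = CellQualityModel.from_dataframe(ft.values, labels.quality)
        results = model.fit(n_members=2, grid=TINY_GRID, k=4, seed=0)
        assert results.n_members == 2
        pred, frac = results.predict(ft.values)
        assert set(pred.quality.unique()) <= {"LOW", "HIGH"}
        text = results.summary()
        assert "members" in text and "gamma" in text
        assert results.training_metrics().f_beta == 1.0

    def test_common_only_restricts_features(self, sim_features):
        ft, labels = sim_features
        model = CellQualityModel(ft, labels, common_only=True)
        assert set(model.features.feature_names) < set(ft.feature_names)
        assert all(ft.common_flag[f] for f in model.features.feature_names)

    def test_cross_validate_returns_report(self):
        ft, labels = labeled_clusters(n_low=10, n_high=30)
        model = CellQualityModel.from_dataframe(
            ft.values, labels.quality
        )
        cv = model.cross_validate(grid=TINY_GRID, k_outer=3, k_inner=2, seed=0)
        assert len(cv.folds) == 3
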