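"""Scale adjustment, MFSL binning, grouped splits and the classifier bank."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pkg_ldct import severity_model as sm


class TestScaleAdjustment:
    @pytest.mark.parametrize(
        "raw,scale,expected",
        [(41.0, "UPDRS", 48.0), (0.0, "UPDRS", 7.0), (48.0, "MDS-UPDRS", 48.0)],
    )
    def test_seven_point_correction(self, raw, scale, expected):
        assert sm.adjust_updrs(raw, scale) == expected

    def test_unknown_scale_rejected(self):
        with pytest.raises(ValueError):
            sm.adjust_updrs(10.0, "UPDRS-IV")

    def test_negative_total_rejected(self):
        with pytest.raises(ValueError):
            sm.adjust_updrs(-1.0, "UPDRS")


class TestBinning:
    @pytest.mark.parametrize("score,level", [(35.0, 3), (60.0, 5), (9.9, 0), (0.0, 0), (10.0, 1), (22.5, 2), (47.5, 4), (120.0, 5)])
    def test_level_assignment(self, score, level):
        assert sm.updrs_to_mfsl(score) == level

    def test_default_thresholds(self):
        assert sm.ordinal_thresholds() == [10.0, 22.5, 35.0, 47.5, 60.0]
        assert len(sm.ordinal_thresholds()) == sm.MfslBinning().n_levels - 1

    def test_custom_binning_arithmetic(self):
        binning = sm.MfslBinning(level0_upper=10.0, increment=10.0)
        assert sm.ordinal_thresholds(binning) == [10.0, 20.0, 30.0, 40.0, 50.0]

    @given(st.floats(0, 130), st.floats(0.01, 130))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_level_monotone_in_score(self, a, b):
        lo, hi = sorted([a, a + b])
        assert sm.updrs_to_mfsl(lo) <= sm.updrs_to_mfsl(hi)

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            sm.updrs_to_mfsl(-0.1)


def _sample_table(n_subjects=40, epochs_per=10, seed=0):
    """Synthetic epoch-sample table with a strong feature-severity link."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        updrs = rng.uniform(0, 75)
        for _ in range(epochs_per):
            base = updrs + rng.normal(0, 2)
            rows.append(
                {
                    "subject_id": f"s{s:03d}",
                    "group": "PwP",
                    "updrs": updrs,
                    "BKS_M10P": base - 2,
                    "BKS_M25P": base,
                    "TA_WM50P_Log": 0.01 * updrs + rng.normal(0, 0.05),
                }
            )
    return pd.DataFrame(rows)


class TestTrainingSetAndSplit:
    def test_controls_only_cohort_is_all_level_zero(self):
        table = _sample_table(10)
        table["updrs"] = 0.0
        labeled = sm.build_training_set(table)
        assert set(labeled["mfsl"]) == {0}

    def test_grouped_split_subject_disjoint_for_many_seeds(self):
        labeled = sm.build_training_set(_sample_table())
        y = (labeled["mfsl"] >= 3).to_numpy()
        for seed in range(20):
            mask = sm.grouped_split_mask(labeled, y, sm.SplitSpec(seed=seed), 3)
            test_subj = set(labeled.loc[mask, "subject_id"])
            train_subj = set(labeled.loc[~mask, "subject_id"])
            assert test_subj.isdisjoint(train_subj)

    def test_grouped_split_takes_roughly_thirty_percent_per_class(self):
        labeled = sm.build_training_set(_sample_table(n_subjects=200, epochs_per=5, seed=1))
        y = (labeled["mfsl"] >= 2).to_numpy()
        mask = sm.grouped_split_mask(labeled, y, sm.SplitSpec(seed=0), 2)
        for cls in (True, False):
            frac = mask[y == cls].mean()
            assert 0.2 < frac < 0.4

    def test_split_reproducible_for_fixed_seed(self):
        labeled = sm.build_training_set(_sample_table())
        y = (labeled["mfsl"] >= 1).to_numpy()
        m1 = sm.grouped_split_mask(labeled, y, sm.SplitSpec(seed=5), 1)
        m2 = sm.grouped_split_mask(labeled, y, sm.SplitSpec(seed=5), 1)
        np.testing.assert_array_equal(m1, m2)


class TestTraining:
    def test_separable_classes_reach_perfect_cv_auc(self):
        labeled = sm.build_training_set(_sample_table(n_subjects=60, epochs_per=8))
        model = sm.train(labeled, split=sm.SplitSpec(seed=0, cv_folds=5))
        assert len(model.classifiers) == 5
        assert np.all(model.training_report["cv_roc_auc"] > 0.99)

    def test_shuffled_labels_give_chance_level_auc(self):
        labeled = sm.build_training_set(_sample_table(n_subjects=100, epochs_per=20, seed=2))
        rng = np.random.default_rng(0)
        # permute severity across subjects to break the feature link
        perm = dict(
            zip(
                labeled["subject_id"].unique(),
                rng.permutation(
                    labeled.groupby("subject_id")["mfsl"].first().to_numpy()
                ),
            )
        )
        labeled["mfsl"] = labeled["subject_id"].map(perm)
        model = sm.train(labeled, split=sm.SplitSpec(seed=1, cv_folds=5))
        k3 = model.training_report.set_index("classifier").loc[3]
        assert abs(k3["cv_roc_auc"] - 0.5) < 0.12

    def test_single_class_side_is_training_error(self):
        labeled = sm.build_training_set(_sample_table(20))
        labeled["mfsl"] = 2  # nothing on either side of most thresholds
        with pytest.raises(sm.TrainingError):
            sm.train(labeled, split=sm.SplitSpec(cv_folds=3))

    def test_pca_logistic_reduces_the_two_bks_features(self):
        labeled = sm.build_training_set(_sample_table(n_subjects=40, epochs_per=5))
        model = sm.train(labeled, "pca_logistic", sm.SplitSpec(seed=0, cv_folds=4))
        reduce = model.classifiers[0].named_steps["reduce"]
        pca = reduce.named_transformers_["pca"].named_steps["p"]
        assert pca.n_components_ == 1
        # the final logistic consumes 2 inputs: the PC and the tremor feature
        assert model.classifiers[0].named_steps["clf"].coef_.shape == (1, 2)

    def test_model_roundtrip_through_disk(self, tmp_path):
        labeled = sm.build_training_set(_sample_table(n_subjects=30, epochs_per=5))
        model = sm.train(labeled, split=sm.SplitSpec(seed=0, cv_folds=3))
        model.save(tmp_path / "m")
        back = sm.SeverityModel.load(tmp_path / "m")
        assert back.features == model.features
        assert back.thresholds == model.thresholds
        X = labeled.sample(50, random_state=0)
        np.testing.assert_array_equal(back.predict_mfsl(X), model.predict_mfsl(X))


class _StubClassifier:
    def __init__(self, vote):
        self.vote = vote

    def predict(self, X):
        return np.full(len(X), self.vote)


class TestPrediction:
    def _model(self, votes):
        return sm.SeverityModel(
            binning=sm.MfslBinning(),
            features=("BKS_M10P", "BKS_M25P", "TA_WM50P_Log"),
            model_family="logistic",
            classifiers=[_StubClassifier(v) for v in votes],
        )

    def _rows(self, n=4):
        return pd.DataFrame(
            {"BKS_M10P": np.zeros(n), "BKS_M25P": np.zeros(n), "TA_WM50P_Log": np.zeros(n)}
        )

    @pytest.mark.parametrize(
        "votes,expected",
        [([0, 0, 0, 0, 0], 0), ([1, 1, 1, 1, 1], 5), ([1, 1, 1, 0, 0], 3)],
    )
    def test_mfsl_is_the_indicator_sum(self, votes, expected):
        model = self._model(votes)
        np.testing.assert_array_equal(model.predict_mfsl(self._rows()), expected)

    def test_missing_feature_rows_yield_nan(self):
        model = self._model([1, 0, 0, 0, 0])
        rows = self._rows()
        rows.loc[1, "BKS_M25P"] = np.nan
        out = sm.predict_epoch_mfsl(model, rows)
        assert np.isnan(out[1]) and np.all(out[[0, 2, 3]] == 1)
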