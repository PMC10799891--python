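"""Per-feature AUCs, concordance scoring, DeLong intervals, nested CV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from circimbalance.classification import (
    ConcordanceModel,
    FeatureSet,
    FittedModel,
    auc_midrank,
    concordance_score,
    delong_ci,
    fit_concordance,
    fit_final,
    nested_cv,
    per_feature_auc,
    transfer,
)


def pair_counting_auc(scores, y):
    """O(n^2) oracle: fraction of case/control pairs ranked correctly."""
    scores = np.asarray(scores, float)
    y = np.asarray(y, int)
    total = wins = 0.0
    for xi in scores[y == 1]:
        for wj in scores[y == 0]:
            total += 1
            if xi > wj:
                wins += 1
            elif xi == wj:
                wins += 0.5
    return wins / total


class TestAuc:
    def test_perfect_and_constant(self):
        y = np.r_[np.ones(3, int), np.zeros(3, int)]
        assert auc_midrank(np.r_[4.0, 5, 6, 1, 2, 3], y) == 1.0
        assert auc_midrank(np.ones(6), y) == 0.5

    def test_orientation_not_flipped(self):
        y = np.r_[np.ones(3, int), np.zeros(3, int)]
        assert auc_midrank(np.r_[1.0, 2, 3, 4, 5, 6], y) == 0.0

    def test_tie_case_matches_pair_counting(self):
        scores = np.array([1.0, 2.0, 2.0, 3.0, 0.5, 2.0])
        y = np.array([1, 1, 1, 0, 0, 0])
        assert auc_midrank(scores, y) == pytest.approx(pair_counting_auc(scores, y))

    @given(st.lists(st.integers(0, 5), min_size=6, max_size=20))
    def test_matches_pair_counting_oracle(self, raw):
        scores = np.asarray(raw, float)
        y = (np.arange(len(scores)) % 2).astype(int)
        assert auc_midrank(scores, y) == pytest.approx(pair_counting_auc(scores, y))

    def test_per_feature_matrix_form(self, rng):
        X = pd.DataFrame(
            rng.normal(size=(4, 12)), columns=[f"s{i}" for i in range(12)]
        )
        labels = pd.Series(["PD"] * 6 + ["Control"] * 6, index=X.columns)
        aucs = per_feature_auc(X, labels)
        y = np.r_[np.ones(6, int), np.zeros(6, int)]
        for i in range(4):
            assert aucs.iloc[i] == pytest.approx(pair_counting_auc(X.iloc[i], y))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_midrank(np.arange(4.0), np.ones(4, int))


class TestDeLong:
    def test_perfect_separation_degenerate_interval(self):
        scores = np.r_[np.ones(5) * 10, np.zeros(5)]
        labels = np.r_[np.ones(5, int), np.zeros(5, int)]
        res = delong_ci(scores, labels)
        assert (res.auc, res.ci_low, res.ci_high) == (1.0, 1.0, 1.0)

    def test_variance_matches_structural_component_enumeration(self, rng):
        scores = rng.normal(size=10)
        y = np.array([1, 0] * 5)
        res = delong_ci(scores, y)
        x, w = scores[y == 1], scores[y == 0]
        v10 = np.array([np.mean([(xi > wj) + 0.5 * (xi == wj) for wj in w]) for xi in x])
        v01 = np.array([np.mean([(xi > wj) + 0.5 * (xi == wj) for xi in x]) for wj in w])
        expected = v10.var(ddof=1) / 5 + v01.var(ddof=1) / 5
        assert res.var == pytest.approx(expected)
        assert res.ci_low <= res.auc <= res.ci_high

    def test_degenerate_class_rejected(self):
        with pytest.raises(ValueError):
            delong_ci(np.arange(4.0), np.array([1, 1, 1, 0]))


class TestConcordance:
    def _model(self):
        feats = ["b1", "b2", "b3"]
        return ConcordanceModel(
            features=feats,
            control_means=pd.Series([10.0, 10.0, 10.0], index=feats),
            directions=pd.Series([-1.0, -1.0, 1.0], index=feats),
        )

    def test_rule_forced_example(self):
        sample = pd.Series([8.0, 12.0, 15.0], index=["b1", "b2", "b3"])
        assert concordance_score(self._model(), sample) == 2

    def test_zero_deviation_never_agrees(self):
        sample = pd.Series([10.0, 10.0, 10.0], index=["b1", "b2", "b3"])
        assert concordance_score(self._model(), sample) == 0

    def test_full_agreement_is_feature_count(self):
        sample = pd.Series([5.0, 5.0, 15.0], index=["b1", "b2", "b3"])
        assert concordance_score(self._model(), sample) == 3

    def test_missing_feature_rejected(self):
        sample = pd.Series([5.0], index=["b1"])
        with pytest.raises(ValueError, match="missing"):
            concordance_score(self._model(), sample)

    def test_monotone_transform_invariance(self, rng):
        """Scores are unchanged by a strictly increasing transform applied
        to sample values and control means alike."""
        model = self._model()
        X = pd.DataFrame(
            rng.uniform(1, 20, size=(3, 6)),
            index=model.features,
            columns=[f"s{i}" for i in range(6)],
        )
        before = concordance_score(model, X)
        transformed = ConcordanceModel(
            features=model.features,
            control_means=np.log(model.control_means),
            directions=model.directions,
        )
        after = concordance_score(transformed, np.log(X))
        assert before.equals(after)

    def test_fit_uses_training_controls_and_de_signs(self, rng):
        X = pd.DataFrame(
            rng.normal(10, 2, size=(4, 10)),
            index=["b1", "b2", "b3", "b4"],
            columns=[f"s{i}" for i in range(10)],
        )
        labels = pd.Series(["PD"] * 5 + ["Control"] * 5, index=X.columns)
        lfc = pd.Series([-0.4, 0.3, 0.0, np.nan], index=X.index)
        with pytest.warns(UserWarning, match="without a direction"):
            model = fit_concordance(X, labels, lfc)
        assert model.features == ["b1", "b2"]
        ctrl = X.loc[model.features, labels == "Control"].mean(axis=1)
        assert np.allclose(model.control_means, ctrl)
        assert list(model.directions) == [-1.0, 1.0]

    def test_serialization_roundtrip_scores_identically(self, rng):
        model = self._model()
        X = pd.DataFrame(
            rng.normal(10, 3, size=(3, 5)),
            index=model.features,
            columns=[f"s{i}" for i in range(5)],
        )
        clone = ConcordanceModel.from_dict(model.to_dict())
        assert concordance_score(model, X).equals(concordance_score(clone, X))


def _labelled_features(rng, n=60, p=20, shift=0.0):
    half = n // 2
    X = rng.normal(size=(p, n))
    X[:, :half] += shift
    frame = pd.DataFrame(
        X, index=[f"g{i}" for i in range(p)], columns=[f"s{i}" for i in range(n)]
    )
    labels = pd.Series(["PD"] * half + ["Control"] * (n - half), index=frame.columns)
    return frame, labels


class TestNestedCv:
    def test_identical_seed_identical_results(self, rng):
        X, labels = _labelled_features(rng, shift=0.6)
        fs = [FeatureSet("gene", X)]
        a = nested_cv(fs, labels, outer_folds=3, inner_folds=3, seed=5)
        b = nested_cv(fs, labels, outer_folds=3, inner_folds=3, seed=5)
        assert a["gene"].roc.auc == b["gene"].roc.auc
        assert a["gene"].predictions.equals(b["gene"].predictions)

    def test_signal_detected(self, rng):
        X, labels = _labelled_features(rng, shift=1.0)
        res = nested_cv([FeatureSet("gene", X)], labels, outer_folds=3, inner_folds=3, seed=1)
        assert res["gene"].roc.auc > 0.8

    def test_unscreened_features_survive_preselection(self, rng):
        """In a combined set, junction features outside the gene screen
        are always kept."""
        X, labels = _labelled_features(rng, n=40, p=10)
        counts = pd.DataFrame(
            rng.poisson(30, size=(5, 40)),
            index=[f"g{i}" for i in range(5)],
            columns=X.columns,
        )
        combined = FeatureSet("gene+bsj", X, preselect_counts=counts)
        res = nested_cv([combined], labels, outer_folds=2, inner_folds=2, seed=2)
        # 5 screened genes can be dropped, but the 5 junction-like rows remain
        assert min(res["gene+bsj"].n_features_per_fold) >= 5

    def test_too_few_samples_per_class_rejected(self, rng):
        X, labels = _labelled_features(rng, n=10)
        with pytest.raises(ValueError, match="fewer samples"):
            nested_cv([FeatureSet("gene", X)], labels, outer_folds=8, inner_folds=2, seed=0)


class TestTransfer:
    def test_self_transfer_matches_apparent_auc(self, rng):
        X, labels = _labelled_features(rng, shift=0.8)
        fs = FeatureSet("gene", X)
        model = fit_final(fs, labels, inner_folds=3, seed=0)
        roc, n_imputed = transfer(model, X, labels)
        assert n_imputed == 0
        apparent = auc_midrank(
            model.score(X).to_numpy(), (labels == "PD").to_numpy().astype(int)
        )
        assert roc.auc == pytest.approx(apparent)

    def test_permuted_labels_near_half(self, rng):
        X, labels = _labelled_features(rng, n=100, shift=0.8)
        model = fit_final(FeatureSet("gene", X), labels, inner_folds=3, seed=0)
        perm = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        roc, _ = transfer(model, X, perm)
        assert abs(roc.auc - 0.5) < 0.2

    def test_missing_features_imputed_at_control_mean(self, rng):
        X, labels = _labelled_features(rng, shift=0.5)
        model = fit_final(FeatureSet("gene", X), labels, inner_folds=3, seed=0)
        reduced = X.drop(index=X.index[:3])
        roc, n_imputed = transfer(model, reduced, labels)
        assert n_imputed == 3
        assert 0.0 <= roc.auc <= 1.0

    def test_empty_intersection_rejected(self, rng):
        X, labels = _labelled_features(rng)
        model = fit_final(FeatureSet("gene", X), labels, inner_folds=3, seed=0)
        other = X.copy()
        other.index = [f"other{i}" for i in range(len(X))]
        with pytest.raises(ValueError, match="no model feature"):
            transfer(model, other, labels)

    def test_model_json_roundtrip(self, rng):
        X, labels = _labelled_features(rng, shift=0.5)
        model = fit_final(FeatureSet("gene", X), labels, inner_folds=3, seed=0)
        clone = FittedModel.from_json(model.to_json())
        assert np.allclose(model.score(X), clone.score(X))
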