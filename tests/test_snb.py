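"""Bayesian scoring, SNB training, ROC, cross-validation, benchmark NB."""

import math

import numpy as np
import pandas as pd
import pytest

from fragmind import snb
from fragmind.errors import DegenerateTrainingError


def eq1_oracle(A, T, P):
    """Hand transcription of the Laplacian-corrected score formula."""
    return math.log(((A + 1) / (T + 1 / P)) / P)


class TestBayesFeatureScore:
    def test_no_data_feature_is_neutral(self):
        assert snb.bayes_feature_score(0, 0, 0.3) == pytest.approx(0.0)

    def test_prior_rate_feature_is_neutral(self):
        assert snb.bayes_feature_score(5, 10, 0.5) == pytest.approx(0.0)

    def test_enriched_feature_matches_hand_evaluation(self):
        # A=9, T=10, P=0.5 -> ln((10/12)/0.5) = ln(5/3)
        assert snb.bayes_feature_score(9, 10, 0.5) == pytest.approx(math.log(5 / 3))

    @pytest.mark.parametrize("A,T,P", [(0, 7, 0.25), (3, 3, 0.8), (2, 9, 0.4)])
    def test_general_agreement_with_formula_oracle(self, A, T, P):
        assert snb.bayes_feature_score(A, T, P) == pytest.approx(eq1_oracle(A, T, P))

    def test_degenerate_prior_rejected(self):
        with pytest.raises(DegenerateTrainingError):
            snb.bayes_feature_score(1, 2, 1.0)

    def test_sign_tracks_deviation_from_prior(self):
        # single binary feature: sign(s) == sign(A/T - P) whenever T > 0
        rng = np.random.default_rng(1)
        for _ in range(50):
            T = int(rng.integers(1, 40))
            A = int(rng.integers(0, T + 1))
            P = float(rng.uniform(0.05, 0.95))
            s = snb.bayes_feature_score(A, T, P)
            ratio = A / T
            if abs(ratio - P) > 0.05:  # away from the neutral point
                assert np.sign(s) == np.sign(ratio - P)


class TestTrainAndScore:
    def _toy(self):
        # 3 fragments, one categorical descriptor with 2 levels
        features = pd.DataFrame({"color": ["r", "r", "b"]}, index=["a", "b", "c"])
        labels = np.array([1, 0, 1])
        return labels, features

    def test_toy_model_matches_hand_computed_counts_and_scores(self):
        labels, features = self._toy()
        model = snb.train_snb(labels, features)
        P = 2 / 3
        assert model.features[("color", "r")] == (2, 1, pytest.approx(eq1_oracle(1, 2, P)))
        assert model.features[("color", "b")] == (1, 1, pytest.approx(eq1_oracle(1, 1, P)))

    def test_total_score_is_sum_of_feature_scores(self):
        features = pd.DataFrame(
            {"x": ["lo", "hi", "lo", "hi"], "y": ["p", "p", "q", "q"]},
            index=list("abcd"),
        )
        labels = np.array([1, 0, 1, 0])
        model = snb.train_snb(labels, features)
        sx = model.features[("x", "lo")][2]
        sy = model.features[("y", "p")][2]
        assert snb.score_compound(model, {"x": "lo", "y": "p"}) == pytest.approx(sx + sy)

    def test_row_order_does_not_change_the_model(self):
        labels, features = self._toy()
        model_a = snb.train_snb(labels, features)
        perm = [2, 0, 1]
        model_b = snb.train_snb(labels[perm], features.iloc[perm])
        assert model_a.features == model_b.features

    def test_unseen_level_contributes_zero(self):
        labels, features = self._toy()
        model = snb.train_snb(labels, features)
        assert snb.score_compound(model, {"color": "never-seen"}) == 0.0

    def test_zero_total_classifies_as_undesirable(self):
        labels, features = self._toy()
        model = snb.train_snb(labels, features)
        frame = pd.DataFrame({"color": ["never-seen"]})
        assert model.classify(frame).tolist() == [0]

    def test_one_class_labels_rejected(self):
        features = pd.DataFrame({"c": ["x", "y"]})
        with pytest.raises(DegenerateTrainingError):
            snb.train_snb(np.array([1, 1]), features)

    def test_model_serializes_losslessly(self, tmp_path):
        labels, features = self._toy()
        model = snb.train_snb(labels, features)
        path = tmp_path / "model.json"
        model.to_json(str(path))
        back = snb.SNBModel.from_json(str(path))
        assert back.p_good == model.p_good
        assert back.features == model.features
        assert back.descriptors == model.descriptors


def brute_force_auc(scores, labels):
    """Probability a random positive outranks a random negative."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation_scores_one(self):
        assert snb.roc_auc([5, 4, 1, 0], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores_half(self):
        assert snb.roc_auc([2, 2, 2, 2], [1, 0, 1, 0]) == 0.5

    def test_worked_example(self):
        assert snb.roc_auc([3, 2, 1, 0], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_agrees_with_pairwise_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = int(rng.integers(10, 200))
            scores = rng.choice(np.arange(12), size=n).astype(float)  # many ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            assert snb.roc_auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        scores = rng.normal(size=120)
        labels = rng.integers(0, 2, size=120)
        assert snb.roc_auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, size=80)
        a = snb.roc_auc(scores, labels)
        b = snb.roc_auc(np.exp(scores) * 3 + 1, labels)
        assert a == pytest.approx(b)

    def test_one_class_rejected(self):
        with pytest.raises(DegenerateTrainingError):
            snb.roc_auc([1.0, 2.0], [1, 1])


class TestCrossval:
    def test_noise_free_threshold_rule_is_nearly_perfectly_learnable(self, small_study):
        from fragmind import synthetic_data as syn

        sel = syn.SimulatedSelector(
            "clean", syn.And((syn.Clause("num_atoms", ">=", 15),)), noise_rate=0.0
        )
        matrix = syn.build_selection_matrix([sel], small_study.fragments, small_study.table)
        cv = snb.crossval_snb(["num_atoms"], matrix.row("clean"), small_study.presentations, small_study.table)
        assert cv.mean_roc > 0.97
        assert len(cv.fold_rocs) == 4

    def test_each_batch_held_out_exactly_once(self, small_study):
        cv = snb.crossval_snb(
            ["num_atoms"], small_study.matrix.row("rules1"), small_study.presentations, small_study.table
        )
        held_out = [b for _, test in cv.folds for b in test]
        assert sorted(held_out) == list(range(1, 9))

    def test_engine_equals_direct_crossval(self, small_study):
        row = small_study.matrix.row("rules2")
        direct = snb.crossval_snb(
            ["num_atoms", "tpsa"], row, small_study.presentations, small_study.table
        )
        engine = snb.CVEngine(row, small_study.presentations, small_study.table)
        via_engine = engine.evaluate(["num_atoms", "tpsa"])
        assert direct.fold_rocs == pytest.approx(via_engine.fold_rocs)


class TestBenchmarkNB:
    def test_noise_free_substructure_rule_is_learnable_from_ecfp(self, small_study):
        from fragmind import descriptors as desc
        from fragmind import synthetic_data as syn

        sel = syn.SimulatedSelector(
            "fg_clean", syn.And((syn.BitClause("fg_key", 3, 1),)), noise_rate=0.0
        )
        matrix = syn.build_selection_matrix([sel], small_study.fragments, small_study.table)
        ecfp = {
            fid: desc.ecfp_features(smi)
            for fid, smi in zip(small_study.fragments.fragment_ids, small_study.fragments.smiles)
        }
        cv = snb.train_benchmark_nb(
            matrix.row("fg_clean"), small_study.presentations, small_study.table, ecfp
        )
        assert cv.mean_roc > 0.95

    def test_deterministic_given_fixed_folds(self, small_study):
        from fragmind import descriptors as desc

        ecfp = {
            fid: desc.ecfp_features(smi)
            for fid, smi in zip(small_study.fragments.fragment_ids, small_study.fragments.smiles)
        }
        row = small_study.matrix.row("rules1")
        a = snb.train_benchmark_nb(row, small_study.presentations, small_study.table, ecfp)
        b = snb.train_benchmark_nb(row, small_study.presentations, small_study.table, ecfp)
        assert a.fold_rocs == b.fold_rocs
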