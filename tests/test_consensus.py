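"""Modified Tanimoto similarity, voting, and the cultural consensus model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragmind import consensus as cns
from fragmind import synthetic_data as syn
from fragmind.errors import ParameterError


class TestModifiedTanimoto:
    def test_identical_mixed_vectors_score_one(self):
        assert cns.modified_tanimoto([1, 1, 0, 0], [1, 1, 0, 0]) == 1.0

    def test_complementary_vectors_score_zero(self):
        assert cns.modified_tanimoto([1, 1, 0], [0, 0, 1]) == 0.0

    def test_worked_four_bit_example(self):
        # a=b=c=d=1 -> S1=S0=1/3, p=0.5 -> S_MT=1/3
        assert cns.modified_tanimoto([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(1 / 3)

    def test_all_zero_identity_still_scores_one(self):
        assert cns.modified_tanimoto([0, 0, 0], [0, 0, 0]) == 1.0

    def test_missing_entries_dropped_pairwise(self):
        v1 = [1, np.nan, 0, 1]
        v2 = [1, 1, np.nan, 1]
        assert cns.modified_tanimoto(v1, v2) == 1.0  # only co-evaluated all agree

    def test_no_overlap_is_an_error(self):
        with pytest.raises(ParameterError):
            cns.modified_tanimoto([np.nan, 1], [0, np.nan])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=2, max_size=40))
    def test_symmetric_bounded_and_within_component_range(self, pairs):
        v1 = [a for a, _ in pairs]
        v2 = [b for _, b in pairs]
        s12 = cns.modified_tanimoto(v1, v2)
        s21 = cns.modified_tanimoto(v2, v1)
        assert s12 == pytest.approx(s21)
        assert 0.0 <= s12 <= 1.0
        a = sum(1 for x, y in pairs if x == y == 1)
        d = sum(1 for x, y in pairs if x == y == 0)
        bc = sum(1 for x, y in pairs if x != y)
        s1 = a / (a + bc) if a + bc else 1.0
        s0 = d / (d + bc) if d + bc else 1.0
        assert min(s1, s0) - 1e-12 <= s12 <= max(s1, s0) + 1e-12


class TestConsistency:
    def test_noise_free_selector_is_perfectly_consistent(self, small_study):
        sel = syn.SimulatedSelector(
            "clean", syn.And((syn.Clause("num_atoms", ">=", 15),)), noise_rate=0.0
        )
        matrix = syn.build_selection_matrix([sel], small_study.fragments, small_study.table)
        scores = cns.consistency(matrix, small_study.fragments)
        assert scores["clean"] == 1.0

    def test_noisy_selector_is_imperfect_but_reproducible(self, small_study):
        scores_a = cns.consistency(small_study.matrix, small_study.fragments)
        scores_b = cns.consistency(small_study.matrix, small_study.fragments)
        assert scores_a["rules1"] < 1.0
        assert scores_a.equals(scores_b)


class TestAgreementAndVoting:
    def _matrix(self, n_select, n_total):
        pres = pd.DataFrame(
            {"presentation_id": ["f1@b1"], "fragment_id": ["f1"], "batch": [1], "order": [0]}
        )
        choices = pd.DataFrame(
            {"f1@b1": [1.0] * n_select + [0.0] * (n_total - n_select)},
            index=[f"c{i}" for i in range(n_total)],
        )
        return syn.SelectionMatrix(choices, pres)

    def test_fifteen_of_nineteen_fraction(self):
        fr = cns.agreement_fractions(self._matrix(15, 19))
        assert fr.loc["f1", "fraction_selecting"] == pytest.approx(15 / 19)
        assert fr.loc["f1", "n_evaluated"] == 19

    def test_fractions_sum_to_one(self, small_study):
        fr = cns.agreement_fractions(small_study.matrix)
        np.testing.assert_allclose(
            fr["fraction_selecting"] + fr["fraction_rejecting"], 1.0
        )

    def test_vote_thresholds(self):
        good = cns.consensus_vote(cns.agreement_fractions(self._matrix(15, 19)), 0.75)
        none = cns.consensus_vote(cns.agreement_fractions(self._matrix(14, 19)), 0.75)
        assert good["f1"] == "consensus-good"
        assert none["f1"] == "none"

    def test_unanimity_threshold_labels_only_unanimous(self):
        assert cns.consensus_vote(cns.agreement_fractions(self._matrix(19, 19)), 1.0)["f1"] == "consensus-good"
        assert cns.consensus_vote(cns.agreement_fractions(self._matrix(18, 19)), 1.0)["f1"] == "none"

    def test_stricter_threshold_labels_a_subset(self, small_study):
        fr = cns.agreement_fractions(small_study.matrix)
        loose = cns.consensus_vote(fr, 0.75)
        strict = cns.consensus_vote(fr, 0.9)
        labelled_strict = set(strict.index[strict != "none"])
        labelled_loose = set(loose.index[loose != "none"])
        assert labelled_strict <= labelled_loose

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ParameterError):
            cns.consensus_vote(cns.agreement_fractions(self._matrix(10, 19)), 0.4)


def _matrix_from_array(resp):
    n_r, n_i = resp.shape
    pres = pd.DataFrame(
        {
            "presentation_id": [f"f{j}@b1" for j in range(n_i)],
            "fragment_id": [f"f{j}" for j in range(n_i)],
            "batch": [1] * n_i,
            "order": list(range(n_i)),
        }
    )
    choices = pd.DataFrame(
        resp.astype(float), index=[f"r{i}" for i in range(n_r)], columns=pres["presentation_id"]
    )
    return syn.SelectionMatrix(choices, pres)


class TestCCM:
    def test_identical_respondents_saturate(self):
        rng = np.random.default_rng(0)
        answers = rng.integers(0, 2, size=60)
        resp = np.tile(answers, (5, 1))
        result = cns.ccm_fit(_matrix_from_array(resp))
        assert result.single_culture
        assert result.ratio == cns.RATIO_CAP
        np.testing.assert_allclose(result.competences, 1.0, atol=1e-6)

    def test_two_complementary_blocks_are_not_one_culture(self):
        rng = np.random.default_rng(1)
        answers = rng.integers(0, 2, size=200)
        block_a = np.tile(answers, (4, 1))
        block_b = np.tile(1 - answers, (4, 1))
        noise = rng.random(block_a.shape) < 0.02
        resp = np.vstack([np.where(noise[:4], 1 - block_a, block_a), block_b])
        result = cns.ccm_fit(_matrix_from_array(resp))
        assert not result.single_culture

    def test_shared_rule_with_noise_is_one_culture(self):
        rng = np.random.default_rng(2)
        answers = rng.integers(0, 2, size=300)
        resp = np.tile(answers, (8, 1))
        flips = rng.random(resp.shape) < 0.05
        resp = np.where(flips, 1 - resp, resp)
        result = cns.ccm_fit(_matrix_from_array(resp))
        assert result.single_culture and result.ratio > 3

    def test_mean_raw_match_for_shared_rule_matches_flip_rate_oracle(self):
        rng = np.random.default_rng(3)
        eps = 0.05
        answers = rng.integers(0, 2, size=10_000)
        resp = np.tile(answers, (4, 1))
        flips = rng.random(resp.shape) < eps
        resp = np.where(flips, 1 - resp, resp)
        matches = []
        for i in range(4):
            for j in range(i + 1, 4):
                matches.append(np.mean(resp[i] == resp[j]))
        expected = 1 - 2 * eps * (1 - eps)
        assert np.mean(matches) == pytest.approx(expected, abs=0.01)

    def test_competence_ordering_invariant_to_item_permutation(self):
        rng = np.random.default_rng(4)
        answers = rng.integers(0, 2, size=150)
        resp = np.tile(answers, (5, 1))
        for i in range(5):  # heterogeneous noise -> distinct competences
            flips = rng.random(150) < 0.03 * (i + 1)
            resp[i] = np.where(flips, 1 - resp[i], resp[i])
        base = cns.ccm_fit(_matrix_from_array(resp))
        perm = rng.permutation(150)
        shuffled = cns.ccm_fit(_matrix_from_array(resp[:, perm]))
        assert np.argsort(base.competences).tolist() == np.argsort(shuffled.competences).tolist()

    def test_too_few_respondents_rejected(self):
        with pytest.raises(ParameterError):
            cns.ccm_fit(_matrix_from_array(np.array([[1, 0], [0, 1]])))


class TestConsensusFeatures:
    def _votes_and_features(self):
        votes = pd.Series(
            {
                "f0": "consensus-good",
                "f1": "consensus-good",
                "f2": "consensus-bad",
                "f3": "consensus-bad",
                "f4": "none",
                "f5": "none",
            }
        )
        ecfp = {
            "f0": frozenset({1, 2}),
            "f1": frozenset({1, 3}),
            "f2": frozenset({4, 5}),
            "f3": frozenset({4, 6}),
            "f4": frozenset({2, 5}),
            "f5": frozenset({3, 7}),
        }
        return votes, ecfp

    def test_min_count_excludes_singleton_features(self):
        votes, ecfp = self._votes_and_features()
        good, bad = cns.consensus_feature_extraction(votes, ecfp, k=10, min_count=2)
        for frame in (good, bad):
            assert (frame["T"] >= 2).all()
            assert 6 not in set(frame["feature"])  # seen once only

    def test_bad_only_feature_tops_the_undesirable_list(self):
        votes, ecfp = self._votes_and_features()
        _, bad = cns.consensus_feature_extraction(votes, ecfp, k=10, min_count=2)
        assert bad.iloc[0]["feature"] == 4
        assert bad.iloc[0]["score"] > 0  # positive for the 'bad' class model

    def test_ranking_matches_score_formula_oracle(self):
        import math

        votes, ecfp = self._votes_and_features()
        good, _ = cns.consensus_feature_extraction(votes, ecfp, k=10, min_count=2)
        p = 2 / 6
        row = good[good["feature"] == 1].iloc[0]
        assert row["score"] == pytest.approx(math.log(((2 + 1) / (2 + 1 / p)) / p))
        assert good.iloc[0]["feature"] == 1


class TestSimilarityMatrix:
    def test_symmetric_unit_diagonal(self, small_study):
        ids = small_study.matrix.selector_ids[:4]
        sub = syn.SelectionMatrix(
            small_study.matrix.choices.loc[ids], small_study.presentations
        )
        sim = cns.similarity_matrix(sub)
        np.testing.assert_allclose(sim.to_numpy(), sim.to_numpy().T)
        np.testing.assert_allclose(np.diag(sim.to_numpy()), 1.0)
        assert ((sim.to_numpy() >= 0) & (sim.to_numpy() <= 1)).all()
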