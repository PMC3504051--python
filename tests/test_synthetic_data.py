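"""Generator, batch assignment, selector rules, noise, self-reports."""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem
from rdkit.Chem import Descriptors as RDDescriptors

from fragmind import synthetic_data as syn
from fragmind.descriptors import DescriptorMeta, DescriptorTable
from fragmind.errors import ParameterError, SchemaError


class TestGenerateFragments:
    def test_empty_request_gives_empty_set(self):
        assert syn.generate_fragments(0, seed=1).n_fragments == 0

    def test_same_seed_reproduces_identical_library(self):
        a = syn.generate_fragments(50, seed=3)
        b = syn.generate_fragments(50, seed=3)
        assert a.smiles == b.smiles

    def test_structures_unique_valid_and_inside_weight_window(self):
        frags = syn.generate_fragments(150, seed=5)
        assert len(set(frags.smiles)) == 150
        for smi in frags.smiles:
            mol = Chem.MolFromSmiles(smi)  # independent structure-parser check
            assert mol is not None
            assert syn.MIN_FRAGMENT_MW <= RDDescriptors.MolWt(mol) <= syn.MAX_FRAGMENT_MW


class TestAssignBatches:
    def test_duplicates_span_two_batches_and_union_covers_all(self):
        frags = syn.assign_batches(syn.generate_fragments(300, seed=2), 8, 30, seed=4)
        assert int(frags.is_duplicate.sum()) == 30
        for dup, batches in zip(frags.is_duplicate, frags.table["batch_ids"]):
            assert len(set(batches)) == (2 if dup else 1)
        assert frags.n_batches == 8

    def test_batch_sizes_balanced_after_duplication(self):
        frags = syn.assign_batches(syn.generate_fragments(300, seed=2), 8, 30, seed=4)
        sizes = frags.presentations().groupby("batch").size()
        assert sizes.max() - sizes.min() <= 1

    def test_zero_duplicates_means_single_batch_membership(self):
        frags = syn.assign_batches(syn.generate_fragments(60, seed=2), 4, 0, seed=4)
        assert not frags.is_duplicate.any()

    def test_too_many_duplicates_rejected(self):
        frags = syn.generate_fragments(20, seed=2)
        with pytest.raises(ParameterError):
            syn.assign_batches(frags, 4, 20, seed=0)


def _toy_table(atoms, tpsa):
    values = pd.DataFrame(
        {"num_atoms": atoms, "tpsa": tpsa},
        index=[f"F{i}" for i in range(len(atoms))],
    )
    meta = {
        "num_atoms": DescriptorMeta("count", frozenset({"size"})),
        "tpsa": DescriptorMeta("continuous", frozenset({"polarity"})),
    }
    return DescriptorTable(values, meta)


class TestRuleSelect:
    def test_conjunction_of_size_and_polarity_thresholds(self):
        # atoms>=15 AND MPSA<60: a 20-atom fragment at MPSA 50 qualifies
        rule = syn.And((syn.Clause("num_atoms", ">=", 15), syn.Clause("tpsa", "<", 60)))
        sel = syn.SimulatedSelector("s3", rule, noise_rate=0.0)
        table = _toy_table([20, 20, 10], [50.0, 70.0, 50.0])
        assert syn.rule_select(sel, table).tolist() == [1, 0, 0]

    def test_xor_pattern_selects_both_quadrants(self):
        big_polar = syn.And((syn.Clause("num_atoms", ">=", 15), syn.Clause("tpsa", ">=", 60)))
        small_nonpolar = syn.And((syn.Clause("num_atoms", "<", 15), syn.Clause("tpsa", "<", 60)))
        sel = syn.SimulatedSelector("s4", syn.Or((big_polar, small_nonpolar)), noise_rate=0.0)
        table = _toy_table([20, 10, 10, 20], [70.0, 50.0, 70.0, 50.0])
        assert syn.rule_select(sel, table).tolist() == [1, 1, 0, 0]

    def test_missing_descriptor_is_a_schema_error(self):
        sel = syn.SimulatedSelector("bad", syn.And((syn.Clause("clogp", ">", 1),)))
        with pytest.raises(SchemaError):
            syn.rule_select(sel, _toy_table([10], [10.0]))

    def test_rule_evaluation_is_deterministic(self):
        rule = syn.And((syn.Clause("num_atoms", ">=", 15),))
        sel = syn.SimulatedSelector("s1", rule, noise_rate=0.0)
        table = _toy_table([20, 10, 15], [1.0, 2.0, 3.0])
        a = syn.rule_select(sel, table)
        assert a.equals(syn.rule_select(sel, table))

    def test_rule_roundtrips_through_json(self):
        rule = syn.Or(
            (
                syn.And((syn.Clause("num_atoms", ">=", 15), syn.BitClause("fg_key", 12, 0))),
                syn.Clause("tpsa", "<", 60),
            )
        )
        assert syn.rule_from_json(rule.to_json()) == rule


class TestLabelNoise:
    def test_zero_and_full_noise_are_identity_and_complement(self):
        labels = np.array([0, 1, 1, 0, 1])
        assert (syn.apply_label_noise(labels, 0.0, 1) == labels).all()
        assert (syn.apply_label_noise(labels, 1.0, 1) == 1 - labels).all()

    def test_flip_count_matches_binomial_expectation(self):
        n = 10_000
        labels = np.zeros(n, dtype=int)
        flips = syn.apply_label_noise(labels, 0.05, seed=11).sum()
        sd = np.sqrt(n * 0.05 * 0.95)
        assert abs(flips - n * 0.05) < 3 * sd

    def test_two_independent_noise_passes_disagree_at_2e_1me(self):
        n = 20_000
        labels = np.zeros(n, dtype=int)
        a = syn.apply_label_noise(labels, 0.05, seed=1)
        b = syn.apply_label_noise(labels, 0.05, seed=2)
        rate = np.mean(a != b)
        expected = 2 * 0.05 * 0.95
        assert abs(rate - expected) < 4 * np.sqrt(expected * (1 - expected) / n)


class TestRandomSelect:
    def test_selected_count_within_binomial_band(self):
        frags = syn.generate_fragments(4000, seed=9)
        row = syn.random_select(frags, 0.5, seed=1)
        assert abs(row.sum() - 2000) < 3 * np.sqrt(1000)

    def test_different_seeds_differ(self):
        frags = syn.generate_fragments(200, seed=9)
        a = syn.random_select(frags, 0.5, seed=1)
        b = syn.random_select(frags, 0.5, seed=2)
        assert (a != b).any()

    def test_pass_fraction_bounds_enforced(self):
        frags = syn.generate_fragments(10, seed=9)
        with pytest.raises(ParameterError):
            syn.random_select(frags, 0.0, seed=1)


class TestSelfReport:
    def _selector(self):
        rule = syn.And((syn.Clause("num_atoms", ">=", 15),))
        return syn.SimulatedSelector("s", rule, declared_parameters=frozenset({"size", "polarity"}))

    def test_no_extras_returns_ground_truth(self):
        sel = self._selector()
        assert syn.simulate_self_report(sel, 0, seed=1) == sel.declared_parameters

    def test_over_reporting_adds_distinct_distractors(self):
        sel = self._selector()
        report = syn.simulate_self_report(sel, 6, seed=1)
        assert len(report) == 8
        assert sel.declared_parameters <= report

    def test_distractors_never_duplicate_ground_truth(self):
        sel = self._selector()
        for seed in range(5):
            report = syn.simulate_self_report(sel, 12, seed=seed)
            assert len(report) == len(sel.declared_parameters) + 12


class TestSelectionMatrix:
    def test_duplicate_presentations_receive_independent_noise(self, small_study):
        row = small_study.matrix.row("rules1")
        dup = small_study.fragments.table[small_study.fragments.is_duplicate]
        pairs = 0
        disagreements = 0
        for frag_id, batches in zip(dup["fragment_id"], dup["batch_ids"]):
            b1, b2 = sorted(batches)
            v1, v2 = row[f"{frag_id}@b{b1}"], row[f"{frag_id}@b{b2}"]
            pairs += 1
            disagreements += int(v1 != v2)
        assert pairs == int(dup.shape[0])
        assert 0 < disagreements < pairs  # noise present but not dominant

    def test_csv_roundtrip(self, tmp_path, small_study):
        path = tmp_path / "sel.csv"
        small_study.matrix.to_csv(path)
        back = syn.SelectionMatrix.from_csv(path, small_study.presentations)
        pd.testing.assert_frame_equal(back.choices, small_study.matrix.choices, check_names=False)
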