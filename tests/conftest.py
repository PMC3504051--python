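"""Shared fixtures: synthetic study libraries built once per session."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
import pytest

from fragmind import synthetic_data as syn
from fragmind.descriptors import DescriptorTable, compute_descriptors


@dataclass
class Study:
    """A generated survey: fragments, descriptors, selectors, responses."""

    fragments: syn.FragmentSet
    table: DescriptorTable
    roster: list[syn.SimulatedSelector]
    matrix: syn.SelectionMatrix
    presentations: pd.DataFrame


def _build_study(n_fragments: int, n_duplicates: int, seed: int) -> Study:
    fragments = syn.generate_fragments(n_fragments, seed=seed)
    fragments = syn.assign_batches(fragments, 8, n_duplicates, seed=seed + 1)
    table = compute_descriptors(fragments)
    roster = syn.default_roster()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix = syn.build_selection_matrix(roster, fragments, table)
    return Study(fragments, table, roster, matrix, fragments.presentations())


@pytest.fixture(scope="session")
def small_study() -> Study:
    """600-fragment study: fast enough for per-module integration tests."""
    return _build_study(600, 48, seed=7)


@pytest.fixture(scope="session")
def full_study() -> Study:
    """The full study conditions: ~3,700 fragments, 8 batches, 227 duplicates."""
    return _build_study(3700, 227, seed=1)
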