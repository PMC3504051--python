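"""Forward feature-subset selection over parameter classes.

Candidate SNB models are descriptor subsets: all single descriptors,
plus combinations of descriptors that individually show enrichment
(single-descriptor CV ROC > 0.6), excluding pairs flagged as redundant
(high rank correlation, or a curated exclusion list of descriptors that
measure the same property).  Candidates are grouped by *parameter
count* -- the number of distinct parameter classes their descriptors
span.  Selection walks parameter counts greedily: the best (N+1)-count
model replaces the best N-count model only when its cross-validated mean
ROC improves by strictly more than 0.009.  A local-minimum guard then
compares the selected model against the global best over every evaluated
candidate and, if the global best is more than 0.009 better, restarts
the walk allowing it to continue past the first non-improving step.

The class of the best one-parameter model is the *primary* parameter;
any further classes in the selected model are *secondary*.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .descriptors import DescriptorTable
from .errors import ParameterError
from .snb import CVEngine, CVResult, spec_name

#: ROC-improvement threshold for accepting one more parameter.
DEFAULT_DELTA = 0.009

#: Descriptor pairs that measure the same property and are never combined.
DEFAULT_EXCLUSIONS: frozenset[frozenset[str]] = frozenset(
    {
        frozenset({"num_atoms", "mol_weight"}),
        frozenset({"tpsa", "fractional_tpsa"}),
        frozenset({"hbd", "hba"}),
        frozenset({"aromatic_rings", "ring_key"}),
        frozenset({"sulfonamides", "fg_key"}),
    }
)


def redundant_pairs(
    table: DescriptorTable,
    corr_threshold: float = 0.7,
    exclusions: frozenset[frozenset[str]] = DEFAULT_EXCLUSIONS,
) -> set[frozenset[str]]:
    """Descriptor pairs too correlated (|rank corr| > threshold) to pair.

    Key-valued descriptors cannot be rank-correlated and are governed only
    by the curated exclusion list.
    """
    numeric = [d for d in table.descriptor_names if table.meta[d].kind != "key"]
    pairs = {p for p in exclusions}
    vals = table.values[numeric].to_numpy(dtype=float)
    if len(numeric) >= 2 and len(vals) >= 3:
        rho = spearmanr(vals).statistic
        rho = np.atleast_2d(rho)
        for i, j in itertools.combinations(range(len(numeric)), 2):
            if abs(rho[i, j]) > corr_threshold:
                pairs.add(frozenset({numeric[i], numeric[j]}))
    return pairs


def enumerate_candidates(
    table: DescriptorTable,
    single_rocs: Mapping[str, float],
    max_combo: int = 4,
    enrich_threshold: float = 0.6,
    redundant: set[frozenset[str]] | None = None,
    per_class_top: int = 1,
) -> list[tuple[str, ...]]:
    """All single descriptors plus non-redundant combos of enriched ones.

    Exhaustively combining every enriched descriptor is neither feasible
    nor useful -- same-class descriptors are largely redundant and a huge
    candidate list inflates the winner's cross-validated ROC by selection
    bias.  Combinations are therefore built from a curated pool: the
    ``per_class_top`` best enriched descriptors of each parameter-class
    signature, keeping the candidate list in the low hundreds.
    """
    descriptors = [d for d in table.descriptor_names if d in single_rocs]
    if redundant is None:
        redundant = redundant_pairs(table)
    candidates: list[tuple[str, ...]] = [(d,) for d in descriptors]
    enriched = [d for d in descriptors if single_rocs[d] > enrich_threshold]
    by_class: dict[frozenset[str], list[str]] = {}
    for d in sorted(enriched, key=lambda d: (-single_rocs[d], d)):
        by_class.setdefault(table.classes_of(d), []).append(d)
    pool = sorted(d for reps in by_class.values() for d in reps[:per_class_top])
    for size in range(2, max_combo + 1):
        for combo in itertools.combinations(pool, size):
            if any(frozenset(p) in redundant for p in itertools.combinations(combo, 2)):
                continue
            candidates.append(combo)
    return candidates


@dataclass
class ModelSearchResult:
    """Outcome of the forward subset search for one selector."""

    best_per_count: dict[int, tuple[tuple[str, ...], float]]  # N -> (subset, mean ROC)
    selected_subset: tuple[str, ...]
    selected_roc: float
    primary_parameter: str
    secondary_parameters: frozenset[str]
    delta: float
    candidate_rocs: dict[tuple[str, ...], float] = field(default_factory=dict)

    @property
    def selected_parameters(self) -> frozenset[str]:
        return frozenset({self.primary_parameter}) | self.secondary_parameters

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "selected": {"descriptors": list(self.selected_subset), "mean_roc": self.selected_roc},
            "primary_parameter": self.primary_parameter,
            "secondary_parameters": sorted(self.secondary_parameters),
            "delta": self.delta,
            "best_per_count": {
                str(n): {"descriptors": list(sub), "mean_roc": roc}
                for n, (sub, roc) in sorted(self.best_per_count.items())
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _param_count(subset: Sequence[str], table: DescriptorTable) -> int:
    return len(table.classes_of(tuple(subset)))


def _tie_break_key(item):
    subset, roc = item
    return (-roc, len(subset), tuple(sorted(subset)))


#: Guard against float artifacts at the exact ">delta" boundary
#: (0.809 - 0.800 must not count as an improvement over 0.009).
_EPS = 1e-12


def _greedy_walk(counts: list[int], best: dict, delta: float, stop_on_fail: bool) -> int:
    """Walk increasing parameter counts, accepting strict >delta gains."""
    current = counts[0]
    for nxt in counts[1:]:
        if best[nxt][1] - best[current][1] > delta + _EPS:
            current = nxt
        elif stop_on_fail:
            break
    return current


def select_subset(
    candidate_rocs: Mapping[tuple[str, ...], float],
    table: DescriptorTable,
    delta: float = DEFAULT_DELTA,
) -> ModelSearchResult:
    """Greedy forward selection over parameter counts with a local-minimum guard."""
    if not candidate_rocs:
        raise ParameterError("no candidates evaluated")
    by_count: dict[int, list] = {}
    for subset, roc in candidate_rocs.items():
        by_count.setdefault(_param_count(subset, table), []).append((tuple(subset), roc))
    if 1 not in by_count:
        raise ParameterError("need at least one one-parameter candidate")
    best = {n: min(items, key=_tie_break_key) for n, items in by_count.items()}
    counts = sorted(best)

    selected_n = _greedy_walk(counts, best, delta, stop_on_fail=True)
    global_n = max(counts, key=lambda n: (best[n][1], -n))
    if best[global_n][1] - best[selected_n][1] > delta + _EPS:
        # local minimum: re-walk without stopping at the first flat step
        selected_n = _greedy_walk(counts, best, delta, stop_on_fail=False)
    selected_subset, selected_roc = best[selected_n]

    primary_subset, _ = best[1]
    primary = sorted(table.classes_of(primary_subset))[0]
    secondary = table.classes_of(selected_subset) - {primary}
    return ModelSearchResult(
        best_per_count=dict(best),
        selected_subset=selected_subset,
        selected_roc=selected_roc,
        primary_parameter=primary,
        secondary_parameters=frozenset(secondary),
        delta=delta,
        candidate_rocs={tuple(k): v for k, v in candidate_rocs.items()},
    )


def extract_parameters(result: ModelSearchResult) -> tuple[str, frozenset[str]]:
    return result.primary_parameter, result.secondary_parameters


def run_subset_search(
    selections: pd.Series,
    presentations: pd.DataFrame,
    table: DescriptorTable,
    delta: float = DEFAULT_DELTA,
    max_combo: int = 4,
    enrich_threshold: float = 0.6,
    folds=None,
) -> ModelSearchResult:
    """End-to-end search for one selector: screen, enumerate, CV, select."""
    from .snb import DEFAULT_FOLDS

    engine = CVEngine(selections, presentations, table, folds=folds or DEFAULT_FOLDS)
    single_rocs = {d: engine.evaluate([d]).mean_roc for d in table.descriptor_names}
    candidates = enumerate_candidates(
        table, single_rocs, max_combo=max_combo, enrich_threshold=enrich_threshold
    )
    candidate_rocs = {tuple(c): engine.evaluate(list(c)).mean_roc for c in candidates}
    return select_subset(candidate_rocs, table, delta=delta)
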