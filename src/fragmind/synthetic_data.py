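"""Synthetic fragment library and simulated chemist selectors.

Real fragment-prioritization surveys are proprietary, so every
downstream analysis in this package runs on a synthetic study: a library
of fragment-sized molecules (MW <= 300) built by scaffold decoration,
split into batches with deliberate cross-batch duplicates, and a roster
of simulated "chemists" that label fragments by descriptor rules (with
independent 5% label noise per presentation), by simple size/polarity
strategies including an XOR pattern, or uniformly at random.

The default study conditions mirror the emulated survey: ~3,700 unique
fragments, 8 batches of ~500, 227 duplicated molecules, 5% label noise,
and random selectors at pass fractions 0.1 / 0.5 / 0.9.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors as RDDescriptors

from .descriptors import PARAMETER_CLASSES, DescriptorTable
from .errors import ConfigurationError, ParameterError, SchemaError

RDLogger.DisableLog("rdApp.*")

MAX_FRAGMENT_MW = 300.0
#: Fragment libraries exclude solvent-sized molecules; typical screening
#: fragments sit in the 150-300 Da window.
MIN_FRAGMENT_MW = 150.0

# Scaffold decoration grammar.  [*] marks attachment points; substituents
# attach through their first atom, "[H]" caps a point with hydrogen.
DEFAULT_SCAFFOLDS: tuple[str, ...] = (
    "c1ccc(cc1)[*]",
    "c1ccc(cc1[*])[*]",
    "c1cc(ccc1[*])[*]",
    "c1ccncc1[*]",
    "c1cc(ncc1[*])[*]",
    "c1cncnc1[*]",
    "c1cnc(nc1[*])[*]",
    "c1ccoc1[*]",
    "c1cc(oc1[*])[*]",
    "c1ccsc1[*]",
    "c1cc(sc1[*])[*]",
    "c1c[nH]cc1[*]",
    "c1cn([*])cn1",
    "c1csc(n1)[*]",
    "C1CCNCC1[*]",
    "C1CCN(CC1[*])[*]",
    "C1CCOC1[*]",
    "C1COCCN1[*]",
    "C1CCCCC1[*]",
    "C1CC(CCC1[*])[*]",
    "C1CC1[*]",
    "C1CCC1[*]",
    "c1ccc2[nH]ccc2c1[*]",
    "c1ccc2ccccc2c1[*]",
    "c1ccc2ncccc2c1[*]",
    "c1ccc2c(c1)cnn2[*]",
    "c1ccc(cc1)C2CCNC2[*]",
    "c1ccc(cc1[*])N2CCOCC2",
    "c1ccc(cc1[*])C2CCCCC2",
    "[*]c1ccc2c(c1)OCO2",
    "c1ccc(cc1)Cc2ccccc2[*]",
    "c1ccc(cc1)Oc2ccccc2[*]",
    "c1cc(ccc1[*])c2ccccc2[*]",
    "c1ccc(cc1[*])C(=O)N2CCCC2",
    "c1cc(cc(c1[*])[*])[*]",
    "c1c(cc(nc1[*])[*])[*]",
    "c1ccc2c(c1)CCN(C2)[*]",
    "c1ccc2c(c1[*])CCCC2[*]",
    "c1cc2ccc(cc2cc1[*])[*]",
    "C1CN(CCN1[*])[*]",
    "c1ccc(cc1[*])S(=O)(=O)N2CCCC2",
    "c1cnc2[nH]ccc2c1[*]",
    "c1cc(on1)[*]",
    "c1cc(no1)[*]",
    "C1CC(NC1[*])[*]",
    "c1cn[nH]c1[*]",
    "c1cc(n[nH]1)[*]",
    "c1nnc(o1)[*]",
    "C1CNC(=O)N1[*]",
    "c1ccc2c(c1)ncn2[*]",
    "O=C1CCCN1[*]",
    "O=C1NCCN1[*]",
    "c1cc2cn[nH]c2cc1[*]",
    "c1cc2c(cc1[*])[nH]nc2[*]",
    "O=C(N1CCCC1)c2ccc(cc2)[*]",
    "c1cc(nc(n1)N2CCOCC2)[*]",
    "O=c1cc[nH]c(=O)n1[*]",
    "O=C1NCc2ccccc2N1[*]",
    "c1nc2cnc(cn2n1)[*]",
    "c1cnc(cn1)[*]",
    "c1ccnnc1[*]",
    "c1ncnc(n1)[*]",
    "c1cnc(nc1[*])[*]",
    "c1cc2ncncc2cc1[*]",
    "c1cnc2ncccc2c1[*]",
    "c1nnc(s1)[*]",
    "c1onc(n1)[*]",
    "c1cc2c(ncn2)cn1[*]",
    "c1cn(nn1)[*]",
    "c1cnn(c1)[*]",
    "c1cc(nnc1[*])[*]",
    "c1cc(nn1[*])[*]",
    "c1nc(nn1[*])[*]",
    "O=C([*])Nc1ccc(cc1)[*]",
    "O=S(=O)([*])Nc1ccccc1[*]",
    "O=C(NC[*])Nc1ccc(cc1)[*]",
    "O=C(N1CCN(CC1)[*])[*]",
    "c1ncc(s1)C(=O)N[*]",
    "c1cnc(nc1N[*])[*]",
    "O=C(Nc1ccncc1)[*]",
    "O=c1[nH]cnc2c1cnn2[*]",
    "c1cc(c(=O)[nH]n1)[*]",
    "C1CCC2CCCCC2C1[*]",
    "c1ccc2c(c1)CCC2[*]",
    "c1ccc(cc1)CCc2ccccc2[*]",
)
DEFAULT_SUBSTITUENTS: tuple[str, ...] = (
    "[H]", "C", "CC", "CCC", "C(C)C", "O", "OC", "OCC", "N", "NC",
    "N(C)C", "F", "Cl", "Br", "C#N", "C(=O)O", "C(=O)N", "C(=O)NC",
    "S(N)(=O)=O", "C(F)(F)F", "C(=O)C", "CO", "C(C)O", "CCN", "OC(F)F",
    "S(C)(=O)=O", "NS(C)(=O)=O", "C(=O)OC", "c1ccccc1", "Cc1ccccc1",
    "N1CCOCC1", "N1CCCC1", "C1CC1", "OCC(F)(F)F", "NC(=O)C",
    "NC(=O)N", "C(=O)NCC", "NC(=O)OC", "CNC(=O)C", "CC(=O)N",
    "CS(N)(=O)=O", "CNS(C)(=O)=O", "Cn1ccnc1", "c1ncc[nH]1", "c1cn[nH]c1",
    "n1ccnnc1", "OCC(O)C", "c1ccncc1", "C(=O)N(C)C", "NC(=O)NC",
    "S(=O)(=O)N(C)C", "NC(N)=O", "C(=O)NO", "Nc1ncccn1", "OCC(=O)N",
    "[N+](=O)[O-]",
)

#: Small polar groups are drawn with double weight, emulating the
#: polarity-enriched composition of a property-filtered fragment archive.
POLAR_BOOSTED_SUBSTITUENTS: frozenset[str] = frozenset(
    {"O", "N", "C#N", "C(=O)O", "S(N)(=O)=O", "C(=O)N", "[N+](=O)[O-]"}
)


@dataclass(frozen=True)
class FragmentGrammar:
    """Scaffold/substituent configuration for library enumeration.

    ``boosted_substituents`` are drawn with double weight relative to the
    rest of the substituent pool.
    """

    scaffolds: tuple[str, ...] = DEFAULT_SCAFFOLDS
    substituents: tuple[str, ...] = DEFAULT_SUBSTITUENTS
    boosted_substituents: frozenset[str] = POLAR_BOOSTED_SUBSTITUENTS

    @property
    def substituent_pool(self) -> tuple[str, ...]:
        boosted = tuple(s for s in self.substituents if s in self.boosted_substituents)
        return self.substituents + boosted

    def validate(self) -> None:
        if not self.scaffolds or not self.substituents:
            raise ConfigurationError("grammar needs at least one scaffold and one substituent")
        for smi in self.scaffolds:
            if Chem.MolFromSmiles(smi) is None:
                raise ConfigurationError(f"invalid scaffold SMILES: {smi!r}")
        for smi in self.substituents:
            if smi != "[H]" and Chem.MolFromSmiles(smi) is None:
                raise ConfigurationError(f"invalid substituent SMILES: {smi!r}")


@dataclass
class FragmentSet:
    """Identified fragment structures with batch membership.

    ``batch_ids`` lists, per fragment, the 1-based batches in which the
    fragment was presented (more than one for deliberate duplicates).
    Each (fragment, batch) pair is one *presentation*; per-batch
    presentation order is randomized at batch-assignment time.
    """

    table: pd.DataFrame  # columns: fragment_id, smiles, batch_ids (list[int])

    @property
    def fragment_ids(self) -> list[str]:
        return list(self.table["fragment_id"])

    @property
    def smiles(self) -> list[str]:
        return list(self.table["smiles"])

    @property
    def is_duplicate(self) -> pd.Series:
        return self.table["batch_ids"].map(len) > 1

    @property
    def n_fragments(self) -> int:
        return len(self.table)

    @property
    def n_batches(self) -> int:
        ids = set(itertools.chain.from_iterable(self.table["batch_ids"]))
        return len(ids)

    def presentations(self) -> pd.DataFrame:
        """Long table of (presentation_id, fragment_id, batch, order)."""
        rows = []
        for frag_id, batches, orders in zip(
            self.table["fragment_id"], self.table["batch_ids"], self.table["batch_order"]
        ):
            for b, o in zip(batches, orders):
                rows.append({"presentation_id": f"{frag_id}@b{b}", "fragment_id": frag_id, "batch": b, "order": o})
        frame = pd.DataFrame(rows)
        return frame.sort_values(["batch", "order"]).reset_index(drop=True)

    def to_csv(self, path: str) -> None:
        out = self.table.copy()
        out["is_duplicate"] = self.is_duplicate
        out["batch_ids"] = out["batch_ids"].map(lambda bs: ";".join(map(str, bs)))
        out = out.drop(columns=["batch_order"], errors="ignore")
        out.to_csv(path, index=False)

    def to_smiles_file(self, path: str) -> None:
        with open(path, "w") as fh:
            for smi, frag_id in zip(self.smiles, self.fragment_ids):
                fh.write(f"{smi} {frag_id}\n")


_DUMMY = Chem.MolFromSmarts("[#0]")


def _decorate(scaffold: Chem.Mol, substituents: Sequence[str]) -> Chem.Mol | None:
    mol = scaffold
    for sub in substituents:
        if sub == "[H]":
            mol = Chem.DeleteSubstructs(mol, _DUMMY)
        else:
            rep = Chem.MolFromSmiles(sub)
            mol = Chem.ReplaceSubstructs(mol, _DUMMY, rep)[0]
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def generate_fragments(
    n_fragments: int,
    seed: int,
    grammar: FragmentGrammar | None = None,
    max_attempt_factor: int = 200,
) -> FragmentSet:
    """Enumerate ``n_fragments`` unique fragment structures (MW <= 300).

    Scaffolds are decorated with random substituent tuples drawn from the
    grammar under a seeded generator; duplicate canonical SMILES and
    molecules above the fragment weight cap are discarded.  Enumeration is
    deterministic given the seed.
    """
    if n_fragments < 0:
        raise ParameterError("n_fragments must be >= 0")
    grammar = grammar or FragmentGrammar()
    grammar.validate()
    rng = np.random.default_rng(seed)
    scaffold_mols = [Chem.MolFromSmiles(s) for s in grammar.scaffolds]
    n_sites = [Chem.MolToSmiles(m).count("*") for m in scaffold_mols]
    seen: set[str] = set()
    smiles_out: list[str] = []
    max_attempts = max(max_attempt_factor * max(n_fragments, 1), 1000)
    attempts = 0
    while len(smiles_out) < n_fragments:
        if attempts >= max_attempts:
            raise ConfigurationError(
                f"grammar exhausted after {attempts} attempts: produced "
                f"{len(smiles_out)}/{n_fragments} unique structures under the MW cap"
            )
        attempts += 1
        i = int(rng.integers(len(scaffold_mols)))
        pool = grammar.substituent_pool
        subs = [pool[int(j)] for j in rng.integers(len(pool), size=n_sites[i])]
        mol = _decorate(scaffold_mols[i], subs)
        if mol is None:
            continue
        smi = Chem.MolToSmiles(mol)
        if smi in seen or not MIN_FRAGMENT_MW <= RDDescriptors.MolWt(mol) <= MAX_FRAGMENT_MW:
            continue
        seen.add(smi)
        smiles_out.append(smi)
    width = max(4, len(str(max(n_fragments, 1))))
    table = pd.DataFrame(
        {
            "fragment_id": [f"F{i:0{width}d}" for i in range(n_fragments)],
            "smiles": smiles_out,
            "batch_ids": [[1] for _ in range(n_fragments)],
            "batch_order": [[i] for i in range(n_fragments)],
        }
    )
    return FragmentSet(table)


def assign_batches(
    fragments: FragmentSet,
    n_batches: int = 8,
    n_duplicates: int = 227,
    seed: int = 0,
) -> FragmentSet:
    """Partition fragments into batches, duplicating some across batches.

    ``n_duplicates`` fragments are presented in two distinct batches (to
    probe self-consistency of selectors); batch sizes end within +/-1 of
    equal after duplication, and per-batch presentation order is shuffled
    under the seed.
    """
    if n_batches < 2:
        raise ParameterError("n_batches must be >= 2")
    n = fragments.n_fragments
    if n_duplicates >= n:
        raise ParameterError("n_duplicates must be smaller than the number of fragments")
    rng = np.random.default_rng(seed)
    total = n + n_duplicates
    sizes = [total // n_batches + (1 if i < total % n_batches else 0) for i in range(n_batches)]
    slots = np.concatenate([np.full(sz, b + 1, dtype=int) for b, sz in enumerate(sizes)])
    rng.shuffle(slots)
    home = slots[:n]
    extra = list(slots[n:])
    dup_idx = rng.choice(n, size=n_duplicates, replace=False)
    batch_ids: list[list[int]] = [[int(b)] for b in home]
    # Pair each duplicate with a leftover slot from a different batch;
    # swap within the leftover pool when a collision occurs.
    for k, idx in enumerate(dup_idx):
        if extra[k] == batch_ids[idx][0]:
            for j in range(k + 1, len(extra)):
                if extra[j] != batch_ids[idx][0]:
                    extra[k], extra[j] = extra[j], extra[k]
                    break
            else:
                others = [b for b in range(1, n_batches + 1) if b != batch_ids[idx][0]]
                extra[k] = int(rng.choice(others))
        batch_ids[idx].append(int(extra[k]))

    # randomized presentation order within each batch
    members: dict[int, list[int]] = {b: [] for b in range(1, n_batches + 1)}
    for i, bs in enumerate(batch_ids):
        for b in bs:
            members[b].append(i)
    order_of: dict[tuple[int, int], int] = {}
    for b, idxs in members.items():
        perm = rng.permutation(len(idxs))
        for pos, i in zip(perm, idxs):
            order_of[(i, b)] = int(pos)
    table = fragments.table.copy()
    table["batch_ids"] = batch_ids
    table["batch_order"] = [[order_of[(i, b)] for b in bs] for i, bs in enumerate(batch_ids)]
    return FragmentSet(table)


# --------------------------------------------------------------------------
# selector rules


@dataclass(frozen=True)
class Clause:
    """Threshold predicate over one descriptor value."""

    descriptor: str
    op: str  # "<", "<=", ">", ">=", "=="
    value: float

    _OPS = {
        "<": np.less,
        "<=": np.less_equal,
        ">": np.greater,
        ">=": np.greater_equal,
        "==": np.equal,
    }

    def evaluate(self, descriptors: DescriptorTable) -> np.ndarray:
        if self.op not in self._OPS:
            raise ConfigurationError(f"unknown operator {self.op!r}")
        col = descriptors.column(self.descriptor)
        return np.asarray(self._OPS[self.op](col.to_numpy(dtype=float), self.value))

    def to_json(self) -> dict:
        return {"clause": [self.descriptor, self.op, self.value]}


@dataclass(frozen=True)
class BitClause:
    """Substructure predicate: tests one bit of a key-valued descriptor.

    ``bit`` indexes the catalog order of the key (e.g. position 12 of the
    functional-group key is the aliphatic-ether bit); ``value`` is the
    required presence (1) or absence (0).
    """

    descriptor: str
    bit: int
    value: int

    def evaluate(self, descriptors: DescriptorTable) -> np.ndarray:
        col = descriptors.column(self.descriptor).astype(str)
        return col.str[self.bit].astype(int).to_numpy() == self.value

    def to_json(self) -> dict:
        return {"bit_clause": [self.descriptor, self.bit, self.value]}


@dataclass(frozen=True)
class And:
    terms: tuple

    def evaluate(self, descriptors: DescriptorTable) -> np.ndarray:
        return np.logical_and.reduce([t.evaluate(descriptors) for t in self.terms])

    def to_json(self) -> dict:
        return {"and": [t.to_json() for t in self.terms]}


@dataclass(frozen=True)
class Or:
    terms: tuple

    def evaluate(self, descriptors: DescriptorTable) -> np.ndarray:
        return np.logical_or.reduce([t.evaluate(descriptors) for t in self.terms])

    def to_json(self) -> dict:
        return {"or": [t.to_json() for t in self.terms]}


def rule_from_json(obj: dict):
    if "clause" in obj:
        return Clause(*obj["clause"])
    if "bit_clause" in obj:
        return BitClause(*obj["bit_clause"])
    if "and" in obj:
        return And(tuple(rule_from_json(t) for t in obj["and"]))
    if "or" in obj:
        return Or(tuple(rule_from_json(t) for t in obj["or"]))
    raise ConfigurationError(f"unknown rule node: {obj!r}")


def _rule_descriptors(rule) -> set[str]:
    if isinstance(rule, (Clause, BitClause)):
        return {rule.descriptor}
    return set().union(*(_rule_descriptors(t) for t in rule.terms))


@dataclass(frozen=True)
class SimulatedSelector:
    """A simulated chemist: a labelling rule plus noise and ground truth.

    ``declared_parameters`` records the parameter classes the rule truly
    uses; recovery experiments compare extracted model parameters against
    this set.  ``rule=None`` denotes a random selector with the given
    ``pass_fraction``.
    """

    selector_id: str
    rule: object | None
    noise_rate: float = 0.05
    seed: int = 0
    declared_parameters: frozenset[str] = frozenset()
    pass_fraction: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ParameterError("noise_rate must be in [0, 1]")
        if self.rule is None and self.pass_fraction is None:
            raise ConfigurationError("selector needs a rule or a pass_fraction")

    def to_json(self) -> dict:
        return {
            "selector_id": self.selector_id,
            "rule": self.rule.to_json() if self.rule is not None else None,
            "noise_rate": self.noise_rate,
            "seed": self.seed,
            "declared_parameters": sorted(self.declared_parameters),
            "pass_fraction": self.pass_fraction,
        }


def rule_select(selector: SimulatedSelector, descriptors: DescriptorTable) -> pd.Series:
    """Noise-free per-fragment labels: 1 iff the rule evaluates true."""
    if selector.rule is None:
        raise ConfigurationError(f"selector {selector.selector_id!r} has no rule")
    missing = _rule_descriptors(selector.rule) - set(descriptors.descriptor_names)
    if missing:
        raise SchemaError(f"rule references missing descriptors: {sorted(missing)}")
    labels = selector.rule.evaluate(descriptors).astype(int)
    return pd.Series(labels, index=descriptors.values.index, name=selector.selector_id)


def apply_label_noise(labels: np.ndarray, noise_rate: float, seed: int) -> np.ndarray:
    """Independently flip each binary label with probability ``noise_rate``."""
    if not 0.0 <= noise_rate <= 1.0:
        raise ParameterError("noise_rate must be in [0, 1]")
    labels = np.asarray(labels, dtype=int)
    flips = np.random.default_rng(seed).random(labels.shape) < noise_rate
    return np.where(flips, 1 - labels, labels)


def random_select(fragments: FragmentSet, pass_fraction: float, seed: int) -> pd.Series:
    """Independent Bernoulli selection of each fragment."""
    if not 0.0 < pass_fraction < 1.0:
        raise ParameterError("pass_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = (rng.random(fragments.n_fragments) < pass_fraction).astype(int)
    return pd.Series(labels, index=fragments.fragment_ids, name=f"random_{pass_fraction}")


def simulate_self_report(selector: SimulatedSelector, n_extra: int, seed: int) -> frozenset[str]:
    """Fabricate an over-reported parameter list for a selector.

    Returns the ground-truth classes plus ``n_extra`` distinct distractor
    classes, emulating the tendency of human respondents to report far more
    criteria than their selections actually reflect.
    """
    if n_extra < 0:
        raise ParameterError("n_extra must be >= 0")
    pool = [c for c in PARAMETER_CLASSES if c not in selector.declared_parameters]
    n_extra = min(n_extra, len(pool))
    rng = np.random.default_rng(seed)
    extras = rng.choice(len(pool), size=n_extra, replace=False)
    return selector.declared_parameters | {pool[int(i)] for i in extras}


# --------------------------------------------------------------------------
# selection matrices


@dataclass
class SelectionMatrix:
    """Binary choices of selectors over fragment presentations.

    ``choices`` is selectors x presentations with values {0.0, 1.0, NaN};
    ``presentations`` maps presentation ids back to fragments and batches.
    """

    choices: pd.DataFrame
    presentations: pd.DataFrame

    def __post_init__(self) -> None:
        if not set(self.choices.columns) <= set(self.presentations["presentation_id"]):
            raise SchemaError("choice columns must be known presentation ids")
        if (self.choices.notna().sum(axis=1) == 0).any():
            raise SchemaError("every selector row needs >= 1 non-missing entry")

    @property
    def selector_ids(self) -> list[str]:
        return list(self.choices.index)

    def row(self, selector_id: str) -> pd.Series:
        return self.choices.loc[selector_id]

    def to_csv(self, path: str) -> None:
        self.choices.to_csv(path, index_label="selector_id", na_rep="NA")

    @classmethod
    def from_csv(cls, path: str, presentations: pd.DataFrame) -> "SelectionMatrix":
        choices = pd.read_csv(path, index_col="selector_id", na_values=["NA"])
        return cls(choices, presentations)


def build_selection_matrix(
    selectors: Sequence[SimulatedSelector],
    fragments: FragmentSet,
    descriptors: DescriptorTable,
) -> SelectionMatrix:
    """Run every selector over every presentation, with per-presentation noise.

    Noise is applied independently per presentation, so a duplicated
    fragment can legitimately receive discordant answers from the same
    selector -- the signal that the consistency analysis measures.
    Random selectors have no underlying opinion to remember: they draw an
    independent Bernoulli answer for every presentation, so their two
    views of a duplicated fragment are independent.
    """
    pres = fragments.presentations()
    frag_index = pres["fragment_id"].to_numpy()
    rows = {}
    for sel in selectors:
        if sel.rule is not None:
            base = rule_select(sel, descriptors)
            per_pres = base.loc[frag_index].to_numpy()
            noisy = apply_label_noise(per_pres, sel.noise_rate, sel.seed)
        else:
            rng = np.random.default_rng(sel.seed)
            noisy = (rng.random(len(pres)) < sel.pass_fraction).astype(int)
        rows[sel.selector_id] = noisy.astype(float)
    choices = pd.DataFrame(rows, index=pres["presentation_id"]).T
    return SelectionMatrix(choices, pres)


# --------------------------------------------------------------------------
# shipped selector rosters (study conditions)


def ruleset_selectors(noise_rate: float = 0.05, seed: int = 101) -> list[SimulatedSelector]:
    """Rule-based selectors with 1-4 ground-truth parameter classes.

    Thresholds sit where every clause genuinely filters the library;
    parameters accumulate as size -> polarity -> ring topology ->
    functional groups, giving one selector per ground-truth set size.
    The 4-rule selector uses milder property cutoffs plus a substructure
    exclusion (no aliphatic ether), so that its conjunction still passes
    a substantial fraction of fragments and each criterion carries
    signal despite the label noise.
    """
    atoms = Clause("num_atoms", ">=", 15)
    polar = Clause("tpsa", "<", 55)
    rings = Clause("aromatic_rings", "<=", 1)
    atoms_mild = Clause("num_atoms", ">=", 13)
    polar_mild = Clause("tpsa", "<", 75)
    no_ether = BitClause("fg_key", 12, 0)
    rules = [
        ("rules1", And((atoms,)), {"size"}),
        ("rules2", And((atoms, polar)), {"size", "polarity"}),
        ("rules3", And((atoms, polar, rings)), {"size", "polarity", "ring topology"}),
        (
            "rules4",
            And((atoms_mild, polar_mild, rings, no_ether)),
            {"size", "polarity", "ring topology", "functional groups"},
        ),
    ]
    return [
        SimulatedSelector(name, rule, noise_rate=noise_rate, seed=seed + i, declared_parameters=frozenset(params))
        for i, (name, rule, params) in enumerate(rules)
    ]


def strategy_selectors(noise_rate: float = 0.05, seed: int = 201) -> list[SimulatedSelector]:
    """The four size/polarity strategies, from simple thresholds to XOR.

    Strategy 4 selects (atoms>=15 AND MPSA>=60) OR (atoms<15 AND MPSA<60):
    the classic XOR pattern that only a jointly-keyed model can represent.
    """
    big = Clause("num_atoms", ">=", 15)
    small = Clause("num_atoms", "<", 15)
    polar = Clause("tpsa", ">=", 60)
    nonpolar = Clause("tpsa", "<", 60)
    rules = [
        ("strategy1", And((big,)), {"size"}),
        ("strategy2", And((nonpolar,)), {"polarity"}),
        ("strategy3", And((big, nonpolar)), {"size", "polarity"}),
        ("strategy4", Or((And((big, polar)), And((small, nonpolar)))), {"size", "polarity"}),
    ]
    return [
        SimulatedSelector(name, rule, noise_rate=noise_rate, seed=seed + i, declared_parameters=frozenset(params))
        for i, (name, rule, params) in enumerate(rules)
    ]


def random_selectors(
    pass_fractions: Sequence[float] = (0.1, 0.5, 0.9),
    n_seeds: int = 3,
    seed: int = 301,
) -> list[SimulatedSelector]:
    """Random selectors: no rule, independent Bernoulli passes, no noise."""
    out = []
    for pf in pass_fractions:
        for k in range(n_seeds):
            out.append(
                SimulatedSelector(
                    f"random_p{pf:g}_s{k}",
                    rule=None,
                    noise_rate=0.0,
                    seed=seed + 17 * k + int(pf * 1000),
                    pass_fraction=pf,
                )
            )
    return out


def default_roster(noise_rate: float = 0.05, seed: int = 100) -> list[SimulatedSelector]:
    """The full simulated-chemist roster used by the pipeline demo."""
    return (
        ruleset_selectors(noise_rate, seed + 1)
        + strategy_selectors(noise_rate, seed + 100)
        + random_selectors(seed=seed + 200)
    )


def selectors_to_json(selectors: Sequence[SimulatedSelector], path: str) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_json() for s in selectors], fh, indent=1)


def selectors_from_json(path: str) -> list[SimulatedSelector]:
    with open(path) as fh:
        raw = json.load(fh)
    out = []
    for obj in raw:
        out.append(
            SimulatedSelector(
                obj["selector_id"],
                rule_from_json(obj["rule"]) if obj["rule"] is not None else None,
                noise_rate=obj["noise_rate"],
                seed=obj["seed"],
                declared_parameters=frozenset(obj["declared_parameters"]),
                pass_fraction=obj["pass_fraction"],
            )
        )
    return out
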