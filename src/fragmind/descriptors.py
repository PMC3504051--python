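"""Medicinal-chemistry descriptors, parameter classes, binning, and keys.

Every descriptor is mapped to one or more of 14 semantic *parameter
classes* (size, polarity, ring topology, ...).  Classifier output is
reported in terms of these classes rather than raw descriptor names, so
that a model can be read as "this selector cares about size and
polarity".  Continuous descriptors are discretized into roughly five
equal-frequency bins before modelling; count descriptors keep their raw
integer levels when the level count is small; *key* descriptors (the
joint ring-topology key and the functional-group key) are categorical
strings whose levels encode several underlying measurements jointly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors as RDDescriptors, GraphDescriptors, Lipinski, rdMolDescriptors

from .errors import ConfigurationError, SchemaError

RDLogger.DisableLog("rdApp.*")

#: The 14 semantic parameter classes available to describe a model.
PARAMETER_CLASSES: tuple[str, ...] = (
    "ring topology",
    "functional groups",
    "h-bonding groups",
    "size",
    "polarity",
    "lipophilicity",
    "synthetic accessibility",
    "novelty/IP",
    "chains",
    "charge",
    "chiral centers",
    "complexity",
    "rotatable bonds",
    "shape",
)


@dataclass(frozen=True)
class DescriptorMeta:
    """Metadata for one descriptor column."""

    kind: str  # "continuous" | "count" | "key"
    parameter_classes: frozenset[str]

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "count", "key"):
            raise ConfigurationError(f"unknown descriptor kind {self.kind!r}")
        unknown = self.parameter_classes - set(PARAMETER_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown parameter classes {sorted(unknown)}")


#: Implemented descriptor set.  Novelty/IP is defined as a class but has no
#: descriptor: it would require a historical compound archive.
DESCRIPTOR_META: dict[str, DescriptorMeta] = {
    "num_atoms": DescriptorMeta("count", frozenset({"size"})),
    "mol_weight": DescriptorMeta("continuous", frozenset({"size"})),
    "tpsa": DescriptorMeta("continuous", frozenset({"polarity"})),
    "fractional_tpsa": DescriptorMeta("continuous", frozenset({"polarity"})),
    "clogp": DescriptorMeta("continuous", frozenset({"lipophilicity"})),
    "hbd": DescriptorMeta("count", frozenset({"h-bonding groups"})),
    "hba": DescriptorMeta("count", frozenset({"h-bonding groups"})),
    "rotatable_bonds": DescriptorMeta("count", frozenset({"rotatable bonds"})),
    "formal_charge": DescriptorMeta("count", frozenset({"charge"})),
    "chiral_centers": DescriptorMeta("count", frozenset({"chiral centers"})),
    "aromatic_rings": DescriptorMeta("count", frozenset({"ring topology"})),
    "ring_key": DescriptorMeta("key", frozenset({"ring topology"})),
    "sulfonamides": DescriptorMeta("count", frozenset({"functional groups"})),
    "fg_key": DescriptorMeta("key", frozenset({"functional groups"})),
    "chain_atoms": DescriptorMeta("count", frozenset({"chains"})),
    "chemical_handles": DescriptorMeta("count", frozenset({"synthetic accessibility"})),
    "bertz_complexity": DescriptorMeta("continuous", frozenset({"complexity"})),
    "kappa2": DescriptorMeta("continuous", frozenset({"shape"})),
    # narrow panel descriptors: ring-topology counts
    "ring_count": DescriptorMeta("count", frozenset({"ring topology"})),
    "aliphatic_rings": DescriptorMeta("count", frozenset({"ring topology"})),
    "saturated_rings": DescriptorMeta("count", frozenset({"ring topology"})),
    "aromatic_heterocycles": DescriptorMeta("count", frozenset({"ring topology"})),
    "aromatic_carbocycles": DescriptorMeta("count", frozenset({"ring topology"})),
    "ring_assemblies": DescriptorMeta("count", frozenset({"ring topology"})),
    "max_ring_size": DescriptorMeta("count", frozenset({"ring topology"})),
    "spiro_atoms": DescriptorMeta("count", frozenset({"ring topology"})),
    "bridgehead_atoms": DescriptorMeta("count", frozenset({"ring topology"})),
    "aromatic_proportion": DescriptorMeta("continuous", frozenset({"ring topology"})),
    # element counts
    "n_nitrogen": DescriptorMeta("count", frozenset({"h-bonding groups"})),
    "n_oxygen": DescriptorMeta("count", frozenset({"h-bonding groups"})),
    "n_sulfur": DescriptorMeta("count", frozenset({"functional groups"})),
    "n_fluorine": DescriptorMeta("count", frozenset({"lipophilicity"})),
    "n_chlorine": DescriptorMeta("count", frozenset({"lipophilicity"})),
    "n_bromine": DescriptorMeta("count", frozenset({"lipophilicity"})),
    "n_halogen": DescriptorMeta("count", frozenset({"lipophilicity"})),
    # h-bonding aggregates
    "nhoh_count": DescriptorMeta("count", frozenset({"h-bonding groups"})),
    "no_count": DescriptorMeta("count", frozenset({"h-bonding groups"})),
    # shape / complexity
    "kappa1": DescriptorMeta("continuous", frozenset({"shape"})),
    "kappa3": DescriptorMeta("continuous", frozenset({"shape"})),
    "hall_kier_alpha": DescriptorMeta("continuous", frozenset({"shape"})),
    # chains
    "terminal_methyls": DescriptorMeta("count", frozenset({"chains"})),
    # ionizable groups
    "basic_nitrogens": DescriptorMeta("count", frozenset({"charge"})),
    "acidic_groups": DescriptorMeta("count", frozenset({"charge"})),
    # ring-key components, also useful independently
    "ring_bonds": DescriptorMeta("count", frozenset({"ring topology"})),
    "aromatic_bonds": DescriptorMeta("count", frozenset({"ring topology"})),
    # surface area
    "labute_asa": DescriptorMeta("continuous", frozenset({"size"})),
}

_SULFONAMIDE = Chem.MolFromSmarts("[SX4](=[OX1])(=[OX1])[NX3]")
_TERMINAL_METHYL = Chem.MolFromSmarts("[CH3]")
_BASIC_NITROGEN = Chem.MolFromSmarts("[NX3;!a;!$([NX3][#6]=[O,S,N]);!$([NX3][S,P]=O)]")
_ACIDIC_GROUP = Chem.MolFromSmarts("[$([CX3](=O)[OX2H1]),$([SX4](=O)(=O)[OX2H1]),$(c1nnn[nH]1)]")


def _functional_group_count_meta() -> dict[str, DescriptorMeta]:
    """Per-group substructure-count descriptors, one per catalog entry.

    These narrow counts mirror the style of a full medicinal-chemistry
    descriptor panel: most are zero for most fragments, but each can
    carry a specific selection criterion (e.g. an ether exclusion).
    """
    return {
        f"n_{name}": DescriptorMeta("count", frozenset({"functional groups"}))
        for name in functional_group_catalog()
        if name != "sulfonamide"  # counted by the dedicated sulfonamides column
    }


def _handle_count_meta() -> dict[str, DescriptorMeta]:
    """Per-handle substructure counts (one per chemical-handle catalog entry)."""
    return {
        f"h_{name}": DescriptorMeta("count", frozenset({"synthetic accessibility"}))
        for name in chemical_handle_catalog()
    }


def load_smarts_catalog(source: str | None = None, *, resource: str | None = None) -> dict[str, Chem.Mol]:
    """Read a ``name SMARTS`` catalog file into compiled query molecules.

    ``source`` is a filesystem path; ``resource`` names one of the catalogs
    shipped with the package (``functional_groups.smarts`` or
    ``chemical_handles.smarts``).
    """
    if (source is None) == (resource is None):
        raise ConfigurationError("pass exactly one of source / resource")
    if resource is not None:
        text = resources.files("fragmind.data").joinpath(resource).read_text()
    else:
        with open(source) as fh:
            text = fh.read()
    catalog: dict[str, Chem.Mol] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, smarts = line.split(None, 1)
        query = Chem.MolFromSmarts(smarts.strip())
        if query is None:
            raise ConfigurationError(f"invalid SMARTS for {name!r}: {smarts!r}")
        catalog[name] = query
    if not catalog:
        raise ConfigurationError("empty SMARTS catalog")
    return catalog


def functional_group_catalog() -> dict[str, Chem.Mol]:
    return load_smarts_catalog(resource="functional_groups.smarts")


def chemical_handle_catalog() -> dict[str, Chem.Mol]:
    return load_smarts_catalog(resource="chemical_handles.smarts")


DESCRIPTOR_META.update(_functional_group_count_meta())
DESCRIPTOR_META.update(_handle_count_meta())


def joint_ring_key(ring_bonds: int, aromatic_bonds: int, ring_assemblies: int) -> str:
    """Join ring-bond, aromatic-bond and ring-assembly counts into one key.

    The key treats the three measurements jointly: e.g. ``11_11_1`` is a
    fused bicyclic aromatic (naphthalene-like), ``17_11_2`` a naphthalene
    plus a separate aliphatic six-ring, ``0_0_0`` an acyclic compound.
    """
    counts = (ring_bonds, aromatic_bonds, ring_assemblies)
    for c in counts:
        if c < 0:
            raise ValueError(f"ring key counts must be non-negative, got {counts}")
    return "_".join(str(int(c)) for c in counts)


def _ring_assembly_count(mol: Chem.Mol) -> int:
    """Number of connected ring systems; fused/spiro rings count once."""
    ring_info = mol.GetRingInfo()
    rings = [set(r) for r in ring_info.AtomRings()]
    n_components = 0
    while rings:
        component = rings.pop()
        merged = True
        while merged:
            merged = False
            for other in list(rings):
                if component & other:
                    component |= other
                    rings.remove(other)
                    merged = True
        n_components += 1
    return n_components


def ring_key_for_mol(mol: Chem.Mol) -> str:
    ring_bonds = sum(1 for b in mol.GetBonds() if b.IsInRing())
    aromatic_bonds = sum(1 for b in mol.GetBonds() if b.GetIsAromatic())
    return joint_ring_key(ring_bonds, aromatic_bonds, _ring_assembly_count(mol))


def functional_group_key(structure: str | Chem.Mol, catalog: Mapping[str, Chem.Mol] | None = None) -> str:
    """Binary presence/absence key over the functional-group catalog.

    Bit *i* is 1 iff catalog entry *i* (in catalog order) matches the
    structure at least once.
    """
    mol = _as_mol(structure)
    if catalog is None:
        catalog = functional_group_catalog()
    return "".join("1" if mol.HasSubstructMatch(q) else "0" for q in catalog.values())


def chemical_handles(structure: str | Chem.Mol, catalog: Mapping[str, Chem.Mol] | None = None) -> int:
    """Count synthetically elaborable substructures (chemical handles)."""
    mol = _as_mol(structure)
    if catalog is None:
        catalog = chemical_handle_catalog()
    return sum(len(mol.GetSubstructMatches(q)) for q in catalog.values())


def _as_mol(structure: str | Chem.Mol) -> Chem.Mol:
    if isinstance(structure, Chem.Mol):
        return structure
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise SchemaError(f"unparseable structure: {structure!r}")
    return mol


def ecfp_features(structure: str | Chem.Mol, diameter: int = 4) -> frozenset[int]:
    """Sparse extended-connectivity (circular substructure) feature ids.

    ``diameter`` is the substructure diameter in bonds (ECFP4 = 4); the
    underlying Morgan radius is ``diameter // 2``.
    """
    if diameter % 2 != 0 or diameter < 0:
        raise ValueError("diameter must be a non-negative even integer")
    mol = _as_mol(structure)
    fp = rdMolDescriptors.GetMorganFingerprint(mol, diameter // 2)
    return frozenset(fp.GetNonzeroElements())


@dataclass
class DescriptorTable:
    """Per-fragment descriptor values plus per-descriptor metadata."""

    values: pd.DataFrame  # indexed by fragment_id
    meta: dict[str, DescriptorMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.meta)
        if missing:
            raise SchemaError(f"descriptors without metadata: {sorted(missing)}")

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.values.columns)

    def column(self, name: str) -> pd.Series:
        if name not in self.values.columns:
            raise SchemaError(f"descriptor {name!r} not in table")
        return self.values[name]

    def classes_of(self, descriptor: str | Sequence[str]) -> frozenset[str]:
        """Parameter classes of one descriptor or a joint tuple of them."""
        if isinstance(descriptor, str):
            return self.meta[descriptor].parameter_classes
        out: frozenset[str] = frozenset()
        for name in descriptor:
            out |= self.meta[name].parameter_classes
        return out

    def to_csv(self, path: str) -> None:
        self.values.to_csv(path, index_label="fragment_id")
        sidecar = {
            name: {"kind": m.kind, "parameter_classes": sorted(m.parameter_classes)}
            for name, m in self.meta.items()
        }
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def from_csv(cls, path: str) -> "DescriptorTable":
        with open(str(path) + ".meta.json") as fh:
            sidecar = json.load(fh)
        meta = {
            name: DescriptorMeta(entry["kind"], frozenset(entry["parameter_classes"]))
            for name, entry in sidecar.items()
        }
        # key columns are strings; without the override a key like "0100"
        # would be read as the integer 100
        key_dtypes = {name: str for name, m in meta.items() if m.kind == "key"}
        values = pd.read_csv(path, index_col="fragment_id", dtype=key_dtypes)
        return cls(values, meta)


def compute_descriptors(fragments) -> DescriptorTable:
    """Compute the standard descriptor set for a fragment collection.

    ``fragments`` is a :class:`~fragmind.synthetic_data.FragmentSet` or any
    object with ``fragment_ids`` and ``smiles`` sequences.
    """
    fg_catalog = functional_group_catalog()
    handle_catalog = chemical_handle_catalog()
    rows = []
    for frag_id, smi in zip(fragments.fragment_ids, fragments.smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise SchemaError(f"unparseable structure for fragment {frag_id!r}: {smi!r}")
        tpsa = RDDescriptors.TPSA(mol)
        # labute approximate surface area as the denominator for the
        # fractional polar surface area
        asa = rdMolDescriptors.CalcLabuteASA(mol)
        group_counts = {
            f"n_{name}": len(mol.GetSubstructMatches(q))
            for name, q in fg_catalog.items()
            if name != "sulfonamide"
        }
        group_counts.update(
            {f"h_{name}": len(mol.GetSubstructMatches(q)) for name, q in handle_catalog.items()}
        )
        rows.append(
            {
                **group_counts,
                "fragment_id": frag_id,
                "num_atoms": mol.GetNumHeavyAtoms(),
                "mol_weight": RDDescriptors.MolWt(mol),
                "tpsa": tpsa,
                "fractional_tpsa": tpsa / asa if asa > 0 else 0.0,
                "clogp": Crippen.MolLogP(mol),
                "hbd": Lipinski.NumHDonors(mol),
                "hba": Lipinski.NumHAcceptors(mol),
                "rotatable_bonds": Lipinski.NumRotatableBonds(mol),
                "formal_charge": Chem.GetFormalCharge(mol),
                "chiral_centers": len(Chem.FindMolChiralCenters(mol, includeUnassigned=True)),
                "aromatic_rings": rdMolDescriptors.CalcNumAromaticRings(mol),
                "ring_key": ring_key_for_mol(mol),
                "sulfonamides": len(mol.GetSubstructMatches(_SULFONAMIDE)),
                "fg_key": functional_group_key(mol, fg_catalog),
                "chain_atoms": sum(1 for a in mol.GetAtoms() if not a.IsInRing()),
                "chemical_handles": chemical_handles(mol, handle_catalog),
                "bertz_complexity": GraphDescriptors.BertzCT(mol),
                "kappa2": rdMolDescriptors.CalcKappa2(mol),
                "ring_count": rdMolDescriptors.CalcNumRings(mol),
                "aliphatic_rings": rdMolDescriptors.CalcNumAliphaticRings(mol),
                "saturated_rings": rdMolDescriptors.CalcNumSaturatedRings(mol),
                "aromatic_heterocycles": rdMolDescriptors.CalcNumAromaticHeterocycles(mol),
                "aromatic_carbocycles": rdMolDescriptors.CalcNumAromaticCarbocycles(mol),
                "ring_assemblies": _ring_assembly_count(mol),
                "max_ring_size": max((len(r) for r in mol.GetRingInfo().AtomRings()), default=0),
                "spiro_atoms": rdMolDescriptors.CalcNumSpiroAtoms(mol),
                "bridgehead_atoms": rdMolDescriptors.CalcNumBridgeheadAtoms(mol),
                "aromatic_proportion": (
                    sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()) / mol.GetNumHeavyAtoms()
                ),
                "n_nitrogen": sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 7),
                "n_oxygen": sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 8),
                "n_sulfur": sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 16),
                "n_fluorine": sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 9),
                "n_chlorine": sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 17),
                "n_bromine": sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 35),
                "n_halogen": sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() in (9, 17, 35, 53)),
                "nhoh_count": Lipinski.NHOHCount(mol),
                "no_count": Lipinski.NOCount(mol),
                "kappa1": rdMolDescriptors.CalcKappa1(mol),
                "kappa3": rdMolDescriptors.CalcKappa3(mol),
                "hall_kier_alpha": rdMolDescriptors.CalcHallKierAlpha(mol),
                "terminal_methyls": len(mol.GetSubstructMatches(_TERMINAL_METHYL)),
                "basic_nitrogens": len(mol.GetSubstructMatches(_BASIC_NITROGEN)),
                "acidic_groups": len(mol.GetSubstructMatches(_ACIDIC_GROUP)),
                "ring_bonds": sum(1 for b in mol.GetBonds() if b.IsInRing()),
                "aromatic_bonds": sum(1 for b in mol.GetBonds() if b.GetIsAromatic()),
                "labute_asa": asa,
            }
        )
    values = pd.DataFrame(rows).set_index("fragment_id")
    return DescriptorTable(values, dict(DESCRIPTOR_META))


@dataclass
class BinnedTable:
    """Bin labels per fragment plus the edges used for continuous columns."""

    labels: pd.DataFrame
    edges: dict[str, np.ndarray]


class QuantileBinner:
    """Equal-frequency binner fit on training values only.

    Values outside the training range clamp into the end bins.  A constant
    training column degenerates to a single bin (a warning is emitted).
    """

    def __init__(self, n_bins: int = 5):
        if n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        self.n_bins = n_bins
        self.edges_: dict[str, np.ndarray] = {}

    def fit(self, frame: pd.DataFrame) -> "QuantileBinner":
        import warnings

        for col in frame.columns:
            vals = np.asarray(frame[col], dtype=float)
            if vals.min() == vals.max():
                warnings.warn(f"descriptor {col!r} is constant on the training data; single bin")
                self.edges_[col] = np.empty(0)
                continue
            qs = np.linspace(0, 1, self.n_bins + 1)[1:-1]
            self.edges_[col] = np.unique(np.quantile(vals, qs))
        return self

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for col in frame.columns:
            if col not in self.edges_:
                raise SchemaError(f"binner was not fit on descriptor {col!r}")
            out[col] = np.searchsorted(self.edges_[col], np.asarray(frame[col], dtype=float), side="right")
        return pd.DataFrame(out, index=frame.index)


def bin_continuous(table: DescriptorTable, n_bins: int = 5, train_ids: Iterable | None = None) -> BinnedTable:
    """Equal-frequency binning of continuous/count descriptors.

    Bin edges come from ``train_ids`` rows only (all rows when omitted);
    key-valued descriptors pass through unchanged.
    """
    numeric = [c for c in table.descriptor_names if table.meta[c].kind != "key"]
    keys = [c for c in table.descriptor_names if table.meta[c].kind == "key"]
    train = table.values.loc[list(train_ids)] if train_ids is not None else table.values
    binner = QuantileBinner(n_bins).fit(train[numeric])
    labels = binner.transform(table.values[numeric])
    for k in keys:
        labels[k] = table.values[k]
    return BinnedTable(labels[table.descriptor_names], dict(binner.edges_))
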