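"""Semi-naive Bayesian (SNB) classifier.

The model assigns every feature f -- a (descriptor, bin/level) pair -- a
Laplacian-corrected Bayesian score

    s_f = ln( ((A_f + 1) / (T_f + 1/P_good)) / P_good )

where T_f is the number of training compounds showing the feature, A_f
the number of those labelled "good", and P_good the class prior.  The
stabilizer K = 1/P_good makes a feature with no data (T_f = 0) exactly
neutral (s_f = 0) and pulls rare features toward the prior.  A compound's
total score is the sum of its feature scores; a positive total classifies
it as desirable (an exact zero is conservatively undesirable).

The classifier is *semi*-naive because selected descriptors are treated
jointly: a key descriptor (e.g. the ring-topology key, or an on-the-fly
atoms x polar-surface-area key) contributes one feature per observed key
level, letting the additive model represent interdependencies -- XOR
patterns included -- that independent descriptors cannot express.

Evaluation is the rank-based ROC AUC under 4-fold batch-jackknife
cross-validation: each fold holds out two of the eight survey batches,
and bin edges are recomputed from the training batches only.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .descriptors import DescriptorTable, QuantileBinner
from .errors import DegenerateTrainingError, SchemaError

#: Default 4-fold batch jackknife over 8 batches: test-set batch pairs.
DEFAULT_FOLDS: tuple[tuple[int, int], ...] = ((1, 2), (3, 4), (5, 6), (7, 8))

#: A model term: a single descriptor name, or a tuple of names treated jointly.
DescriptorSpec = "str | tuple[str, ...]"


def bayes_feature_score(A_f: float, T_f: float, P_good: float) -> float:
    """Laplacian-corrected Bayesian score of one feature."""
    if not 0.0 < P_good < 1.0:
        raise DegenerateTrainingError("class prior must be strictly between 0 and 1")
    if not 0 <= A_f <= T_f:
        raise ValueError("need 0 <= A_f <= T_f")
    return math.log((A_f + 1.0) / (T_f + 1.0 / P_good) / P_good)


def spec_name(spec) -> str:
    """Stable column name for a descriptor spec ('a*b' for joint tuples)."""
    if isinstance(spec, str):
        return spec
    return "*".join(spec)


class SNBFeaturizer:
    """Turn descriptor values into categorical feature levels per compound.

    Continuous descriptors are quantile-binned into ``n_bins`` bins (edges
    from the fit rows only); count descriptors keep raw integer levels
    while the training data show at most ``max_count_levels`` distinct
    values, and are binned otherwise; key descriptors pass through.  A
    joint spec (tuple of descriptor names) concatenates its components'
    levels into one composite level, using the finer ``n_bins_joint``
    resolution for continuous components so that the joint key can resolve
    interaction structure.
    """

    def __init__(
        self,
        table: DescriptorTable,
        specs: Sequence,
        n_bins: int = 5,
        n_bins_joint: int = 10,
        max_count_levels: int = 25,
    ):
        self.table = table
        self.specs = list(specs)
        self.n_bins = n_bins
        self.n_bins_joint = n_bins_joint
        self.max_count_levels = max_count_levels
        self._binners: dict[tuple[str, int], QuantileBinner] = {}
        self._fit_ids: pd.Index | None = None

    def _component_levels(self, name: str, frag_ids: pd.Index, n_bins: int) -> pd.Series:
        meta = self.table.meta[name]
        col = self.table.column(name)
        if meta.kind == "key":
            return col.loc[frag_ids].astype(str)
        train_vals = col.loc[self._fit_ids]
        if meta.kind == "count" and train_vals.nunique() <= self.max_count_levels:
            return col.loc[frag_ids].astype(int).astype(str)
        key = (name, n_bins)
        if key not in self._binners:
            self._binners[key] = QuantileBinner(n_bins).fit(train_vals.to_frame())
        binned = self._binners[key].transform(col.loc[frag_ids].to_frame())
        return binned[name].astype(str)

    def fit(self, frag_ids: Iterable) -> "SNBFeaturizer":
        self._fit_ids = pd.Index(frag_ids)
        self._binners.clear()
        return self

    def transform(self, frag_ids: Iterable) -> pd.DataFrame:
        if self._fit_ids is None:
            raise SchemaError("featurizer must be fit before transform")
        frag_ids = pd.Index(frag_ids)
        out = {}
        for spec in self.specs:
            if isinstance(spec, str):
                out[spec_name(spec)] = self._component_levels(spec, frag_ids, self.n_bins).to_numpy()
            else:
                parts = [self._component_levels(n, frag_ids, self.n_bins_joint) for n in spec]
                joined = parts[0].str.cat(parts[1:], sep="_")
                out[spec_name(spec)] = joined.to_numpy()
        return pd.DataFrame(out, index=frag_ids)


@dataclass
class SNBModel:
    """Trained SNB model: class prior plus per-feature count statistics.

    ``features`` maps (descriptor name, level) -> (T_f, A_f, s_f).  The
    model is fully inspectable: each score says how strongly a level
    argues for or against desirability.
    """

    p_good: float
    features: dict[tuple[str, str], tuple[int, int, float]]
    descriptors: list[str] = field(default_factory=list)

    def score_one(self, levels: Mapping[str, str]) -> float:
        total = 0.0
        for desc in self.descriptors:
            entry = self.features.get((desc, str(levels[desc])))
            if entry is not None:
                total += entry[2]  # unseen level: no data, contributes 0
        return total

    def score_frame(self, frame: pd.DataFrame) -> np.ndarray:
        """Total Bayesian score of every row of a featurized frame."""
        total = np.zeros(len(frame))
        for desc in self.descriptors:
            lut = {lvl: s for (d, lvl), (_, _, s) in self.features.items() if d == desc}
            total += frame[desc].map(lambda v: lut.get(str(v), 0.0)).to_numpy()
        return total

    def classify(self, frame: pd.DataFrame) -> np.ndarray:
        """1 = desirable (total score > 0), 0 = undesirable (ties included)."""
        return (self.score_frame(frame) > 0).astype(int)

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "prior": self.p_good,
            "descriptors": self.descriptors,
            "features": [
                {"descriptor": d, "level": lvl, "T": T, "A": A, "score": s}
                for (d, lvl), (T, A, s) in sorted(self.features.items())
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str) -> "SNBModel":
        try:
            payload = json.loads(text_or_path)
        except json.JSONDecodeError:
            with open(text_or_path) as fh:
                payload = json.load(fh)
        features = {
            (f["descriptor"], f["level"]): (f["T"], f["A"], f["score"]) for f in payload["features"]
        }
        return cls(payload["prior"], features, payload["descriptors"])


def train_snb(labels: np.ndarray, features: pd.DataFrame) -> SNBModel:
    """Fit per-(descriptor, level) Bayesian scores from binary labels."""
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(features):
        raise SchemaError("labels and feature rows must align")
    p_good = labels.mean()
    if p_good in (0.0, 1.0):
        raise DegenerateTrainingError("training labels contain a single class")
    model_features: dict[tuple[str, str], tuple[int, int, float]] = {}
    for desc in features.columns:
        col = features[desc].astype(str).to_numpy()
        frame = pd.DataFrame({"level": col, "y": labels})
        grouped = frame.groupby("level", sort=False)["y"].agg(["count", "sum"])
        for lvl, (T, A) in grouped.iterrows():
            model_features[(desc, lvl)] = (int(T), int(A), bayes_feature_score(A, T, p_good))
    return SNBModel(float(p_good), model_features, list(features.columns))


def score_compound(model: SNBModel, levels: Mapping[str, str]) -> float:
    """Total Bayesian score of one featurized compound."""
    return model.score_one(levels)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based ROC AUC (Mann-Whitney; ties contribute 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateTrainingError("ROC undefined with a single class")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class CVResult:
    """Per-fold ROC values under the batch jackknife."""

    fold_rocs: list[float]
    folds: list[tuple[tuple[int, ...], tuple[int, ...]]]  # (train batches, test batches)

    @property
    def mean_roc(self) -> float:
        return float(np.mean(self.fold_rocs))


def _fold_masks(presentations: pd.DataFrame, folds: Sequence[Sequence[int]]):
    batches = presentations["batch"].to_numpy()
    all_batches = tuple(sorted(set(batches.tolist())))
    for test_batches in folds:
        test = np.isin(batches, list(test_batches))
        train_batches = tuple(b for b in all_batches if b not in test_batches)
        yield train_batches, tuple(test_batches), ~test, test


def crossval_snb(
    specs: Sequence,
    selections: pd.Series,
    presentations: pd.DataFrame,
    table: DescriptorTable,
    folds: Sequence[Sequence[int]] = DEFAULT_FOLDS,
    n_bins: int = 5,
    n_bins_joint: int = 10,
) -> CVResult:
    """4-fold batch-jackknife cross-validation of an SNB descriptor subset.

    ``selections`` is one selector's row indexed by presentation id;
    missing entries are dropped.  Bin edges are computed per fold from the
    training batches only.  A fold whose test labels are one-class is
    skipped with a warning.
    """
    mask = selections.notna()
    pres = presentations[presentations["presentation_id"].isin(selections.index[mask])].reset_index(drop=True)
    y = selections.loc[pres["presentation_id"]].to_numpy(dtype=int)
    frag_ids = pres["fragment_id"]
    fold_rocs, fold_defs = [], []
    for train_b, test_b, train_m, test_m in _fold_masks(pres, folds):
        y_test = y[test_m]
        if y_test.sum() in (0, len(y_test)) or y[train_m].sum() in (0, int(train_m.sum())):
            warnings.warn(f"fold with test batches {test_b} has one-class labels; skipped")
            continue
        feat = SNBFeaturizer(table, specs, n_bins=n_bins, n_bins_joint=n_bins_joint)
        feat.fit(frag_ids[train_m])
        model = train_snb(y[train_m], feat.transform(frag_ids[train_m]))
        scores = model.score_frame(feat.transform(frag_ids[test_m]))
        fold_rocs.append(roc_auc(scores, y_test))
        fold_defs.append((train_b, test_b))
    if not fold_rocs:
        raise DegenerateTrainingError("no usable folds")
    return CVResult(fold_rocs, fold_defs)


class CVEngine:
    """Shared cross-validation state for evaluating many descriptor subsets.

    The SNB total score is additive over descriptors, so for each fold the
    per-descriptor test-score vectors are computed once; any candidate
    subset is then evaluated by summing its columns and ranking.  This is
    exactly equivalent to training the subset model from scratch, at a
    fraction of the cost.
    """

    def __init__(
        self,
        selections: pd.Series,
        presentations: pd.DataFrame,
        table: DescriptorTable,
        folds: Sequence[Sequence[int]] = DEFAULT_FOLDS,
        n_bins: int = 5,
        n_bins_joint: int = 10,
    ):
        self.table = table
        self.folds = folds
        self.n_bins = n_bins
        self.n_bins_joint = n_bins_joint
        mask = selections.notna()
        self.pres = presentations[
            presentations["presentation_id"].isin(selections.index[mask])
        ].reset_index(drop=True)
        self.y = selections.loc[self.pres["presentation_id"]].to_numpy(dtype=int)
        self._fold_cache: list[dict] = []
        for train_b, test_b, train_m, test_m in _fold_masks(self.pres, folds):
            y_test = self.y[test_m]
            y_train = self.y[train_m]
            if y_test.sum() in (0, len(y_test)) or y_train.sum() in (0, len(y_train)):
                warnings.warn(f"fold with test batches {test_b} has one-class labels; skipped")
                continue
            self._fold_cache.append(
                {
                    "train_b": train_b,
                    "test_b": test_b,
                    "train_m": train_m,
                    "test_m": test_m,
                    "scores": {},  # spec name -> test score vector
                }
            )
        if not self._fold_cache:
            raise DegenerateTrainingError("no usable folds")

    def _spec_scores(self, fold: dict, spec) -> np.ndarray:
        name = spec_name(spec)
        if name not in fold["scores"]:
            frag_ids = self.pres["fragment_id"]
            feat = SNBFeaturizer(
                self.table, [spec], n_bins=self.n_bins, n_bins_joint=self.n_bins_joint
            ).fit(frag_ids[fold["train_m"]])
            model = train_snb(self.y[fold["train_m"]], feat.transform(frag_ids[fold["train_m"]]))
            fold["scores"][name] = model.score_frame(feat.transform(frag_ids[fold["test_m"]]))
        return fold["scores"][name]

    def evaluate(self, specs: Sequence) -> CVResult:
        fold_rocs, fold_defs = [], []
        for fold in self._fold_cache:
            total = np.zeros(int(fold["test_m"].sum()))
            for spec in specs:
                total = total + self._spec_scores(fold, spec)
            fold_rocs.append(roc_auc(total, self.y[fold["test_m"]]))
            fold_defs.append((fold["train_b"], fold["test_b"]))
        return CVResult(fold_rocs, fold_defs)


# --------------------------------------------------------------------------
# benchmark: naive Bayes over sparse binary features (ECFP4 + physchem)

PHYSCHEM_BENCHMARK: tuple[str, ...] = (
    "clogp",
    "mol_weight",
    "hbd",
    "hba",
    "rotatable_bonds",
    "fractional_tpsa",
)


@dataclass
class BinaryFeatureNB:
    """Naive Bayes over sparse binary feature sets (e.g. ECFP bits)."""

    p_good: float
    features: dict[Hashable, tuple[int, int, float]]

    def score_sets(self, feature_sets: Sequence[frozenset]) -> np.ndarray:
        return np.array(
            [sum(self.features[f][2] for f in fs if f in self.features) for fs in feature_sets]
        )


def train_binary_nb(labels: np.ndarray, feature_sets: Sequence[frozenset]) -> BinaryFeatureNB:
    labels = np.asarray(labels, dtype=int)
    p_good = labels.mean()
    if p_good in (0.0, 1.0):
        raise DegenerateTrainingError("training labels contain a single class")
    T: dict[Hashable, int] = {}
    A: dict[Hashable, int] = {}
    for fs, y in zip(feature_sets, labels):
        for f in fs:
            T[f] = T.get(f, 0) + 1
            A[f] = A.get(f, 0) + y
    feats = {f: (T[f], A[f], bayes_feature_score(A[f], T[f], p_good)) for f in T}
    return BinaryFeatureNB(float(p_good), feats)


def train_benchmark_nb(
    selections: pd.Series,
    presentations: pd.DataFrame,
    table: DescriptorTable,
    ecfp_sets: Mapping[str, frozenset],
    folds: Sequence[Sequence[int]] = DEFAULT_FOLDS,
    n_bins: int = 5,
) -> CVResult:
    """Accuracy benchmark: NB on ECFP4 bits plus binned physchem properties.

    ``ecfp_sets`` maps fragment_id -> circular-substructure feature ids.
    The same Laplacian-corrected scoring machinery is used; each ECFP bit
    is one binary feature, each binned physchem descriptor one categorical
    feature.
    """
    mask = selections.notna()
    pres = presentations[presentations["presentation_id"].isin(selections.index[mask])].reset_index(drop=True)
    y = selections.loc[pres["presentation_id"]].to_numpy(dtype=int)
    frag_ids = pres["fragment_id"]
    fold_rocs, fold_defs = [], []
    for train_b, test_b, train_m, test_m in _fold_masks(pres, folds):
        y_test, y_train = y[test_m], y[train_m]
        if y_test.sum() in (0, len(y_test)) or y_train.sum() in (0, len(y_train)):
            warnings.warn(f"fold with test batches {test_b} has one-class labels; skipped")
            continue
        fp_train = [ecfp_sets[f] for f in frag_ids[train_m]]
        fp_test = [ecfp_sets[f] for f in frag_ids[test_m]]
        nb = train_binary_nb(y_train, fp_train)
        scores = nb.score_sets(fp_test)
        feat = SNBFeaturizer(table, list(PHYSCHEM_BENCHMARK), n_bins=n_bins).fit(frag_ids[train_m])
        phys_model = train_snb(y_train, feat.transform(frag_ids[train_m]))
        scores = scores + phys_model.score_frame(feat.transform(frag_ids[test_m]))
        fold_rocs.append(roc_auc(scores, y_test))
        fold_defs.append((train_b, test_b))
    if not fold_rocs:
        raise DegenerateTrainingError("no usable folds")
    return CVResult(fold_rocs, fold_defs)
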