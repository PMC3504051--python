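"""Balanced random-forest validation of descriptor importance.

An orthogonal check on the SNB results: a forest of 500 CART trees
(Gini splits, depth <= 20, >= 10 samples per node, sqrt(p) split
candidates) is grown on class-balanced bootstraps -- each tree sees an
equal-size resample of both classes, the majority class down-sampled.
Descriptors enter independently (no joint keys): trees encode
interactions through their split structure.

Importance is the *percent selection frequency*: the share of internal
split nodes across the forest that use each descriptor.  Frequencies are
averaged over 3 seeded trials x 4 jackknife training sets, standardized
to z-scores across descriptors within the model, and thresholded at
z > 2.1 to call a descriptor important.  The parameter class of the
top-z descriptor is the primary RF parameter; classes of other
descriptors above the cutoff are secondary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .descriptors import DescriptorTable, QuantileBinner
from .errors import DegenerateTrainingError
from .snb import DEFAULT_FOLDS, _fold_masks, roc_auc

DEFAULT_Z_CUTOFF = 2.1


@dataclass
class RFHyperparams:
    """Forest settings: 500 Gini trees, depth <= 20, >= 10 samples/node.

    ``min_impurity_decrease`` pre-prunes splits whose weighted Gini gain
    is compatible with chance; without it, deep trees pad the split
    counts with noise splits and wash out the selection-frequency
    contrast that the importance z-scores rely on.  Its default was
    calibrated, like the z cutoff itself, on the rule-based simulated
    selectors: the weakest value at which every ground-truth parameter
    class separates above the 2.1 cutoff while predictive accuracy is
    unaffected.
    """

    n_trees: int = 500
    max_depth: int = 20
    min_samples_node: int = 10
    n_bins: int = 5
    min_impurity_decrease: float = 6e-3

    def tree(self, seed: int) -> DecisionTreeClassifier:
        return DecisionTreeClassifier(
            criterion="gini",
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_node,
            max_features="sqrt",
            min_impurity_decrease=self.min_impurity_decrease,
            random_state=seed,
        )


@dataclass
class TrainedForest:
    trees: list[DecisionTreeClassifier]
    descriptor_names: list[str]
    selection_frequency: np.ndarray  # percent, per descriptor

    def predict_proba_good(self, X: np.ndarray) -> np.ndarray:
        votes = np.zeros(len(X))
        for t in self.trees:
            proba = t.predict_proba(X)
            good_col = list(t.classes_).index(1)
            votes += proba[:, good_col]
        return votes / len(self.trees)


def train_rf(
    labels: np.ndarray,
    X: pd.DataFrame,
    hyper: RFHyperparams | None = None,
    seed: int = 0,
) -> TrainedForest:
    """Grow a balanced forest on binned descriptors; count split usage.

    Each tree trains on a bootstrap of size 2*n_min: n_min draws with
    replacement from each class, down-sampling the majority class.
    """
    hyper = hyper or RFHyperparams()
    labels = np.asarray(labels, dtype=int)
    idx_pos = np.flatnonzero(labels == 1)
    idx_neg = np.flatnonzero(labels == 0)
    if len(idx_pos) == 0 or len(idx_neg) == 0:
        raise DegenerateTrainingError("forest training needs both classes")
    n_min = min(len(idx_pos), len(idx_neg))
    rng = np.random.default_rng(seed)
    Xv = X.to_numpy(dtype=float)
    split_counts = np.zeros(Xv.shape[1])
    trees = []
    for k in range(hyper.n_trees):
        boot = np.concatenate(
            [rng.choice(idx_pos, size=n_min, replace=True), rng.choice(idx_neg, size=n_min, replace=True)]
        )
        tree = hyper.tree(int(rng.integers(2**31 - 1)))
        tree.fit(Xv[boot], labels[boot])
        feats = tree.tree_.feature
        used = feats[feats >= 0]
        np.add.at(split_counts, used, 1)
        trees.append(tree)
    total = split_counts.sum()
    freq = 100.0 * split_counts / total if total > 0 else split_counts
    return TrainedForest(trees, list(X.columns), freq)


@dataclass
class RFImportance:
    """Mean percent selection frequency and within-model z-scores."""

    descriptor_names: list[str]
    mean_frequency: np.ndarray
    z_scores: np.ndarray
    cutoff: float = DEFAULT_Z_CUTOFF

    @property
    def important(self) -> list[str]:
        return [d for d, z in zip(self.descriptor_names, self.z_scores) if z > self.cutoff]

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "cutoff": self.cutoff,
            "descriptors": [
                {"descriptor": d, "mean_percent_frequency": float(f), "z": float(z)}
                for d, f, z in zip(self.descriptor_names, self.mean_frequency, self.z_scores)
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def importance_zscores(
    frequency_vectors: Sequence[np.ndarray],
    descriptor_names: Sequence[str],
    cutoff: float = DEFAULT_Z_CUTOFF,
) -> RFImportance:
    """Average trial x fold frequencies, standardize across descriptors."""
    freq = np.mean(np.asarray(frequency_vectors, dtype=float), axis=0)
    sd = freq.std(ddof=0)
    if sd == 0:
        raise DegenerateTrainingError("all descriptors equally used: z-scores undefined")
    z = (freq - freq.mean()) / sd
    return RFImportance(list(descriptor_names), freq, z, cutoff)


def rf_parameters(importance: RFImportance, table: DescriptorTable) -> tuple[str, frozenset[str]]:
    """Primary class = class of the arg-max-z descriptor; secondary = other
    classes of descriptors above the cutoff."""
    top = importance.descriptor_names[int(np.argmax(importance.z_scores))]
    primary = sorted(table.meta[top].parameter_classes)[0]
    secondary: set[str] = set()
    for d in importance.important:
        if d != top:
            secondary |= table.meta[d].parameter_classes
    return primary, frozenset(secondary - {primary})


def rf_validate(
    selections: pd.Series,
    presentations: pd.DataFrame,
    table: DescriptorTable,
    hyper: RFHyperparams | None = None,
    n_trials: int = 3,
    seed: int = 0,
    folds=DEFAULT_FOLDS,
    cutoff: float = DEFAULT_Z_CUTOFF,
) -> tuple[RFImportance, float]:
    """Full RF validation for one selector.

    Trains ``n_trials`` forests on each of the 4 jackknife training sets
    (12 frequency vectors), averages ROC over folds/trials, and returns
    the importance summary plus the mean test ROC.
    """
    hyper = hyper or RFHyperparams()
    mask = selections.notna()
    pres = presentations[presentations["presentation_id"].isin(selections.index[mask])].reset_index(drop=True)
    y = selections.loc[pres["presentation_id"]].to_numpy(dtype=int)
    frag_ids = pres["fragment_id"]
    # independent descriptors only: drop joint keys, ordinal-encode the rest
    numeric = [d for d in table.descriptor_names if table.meta[d].kind != "key"]
    rng = np.random.default_rng(seed)
    trial_seeds = [int(rng.integers(2**31 - 1)) for _ in range(n_trials)]
    freq_vectors, rocs = [], []
    for train_b, test_b, train_m, test_m in _fold_masks(pres, folds):
        y_train, y_test = y[train_m], y[test_m]
        if y_train.sum() in (0, len(y_train)) or y_test.sum() in (0, len(y_test)):
            continue
        train_vals = table.values.loc[frag_ids[train_m], numeric]
        # low-cardinality counts keep raw integer levels (quantile edges
        # degenerate on mostly-zero columns); the rest get ~5 bins
        binned_cols = [
            d
            for d in numeric
            if not (table.meta[d].kind == "count" and train_vals[d].nunique() <= 25)
        ]
        binner = QuantileBinner(hyper.n_bins).fit(train_vals[binned_cols])

        def _encode(vals: pd.DataFrame) -> pd.DataFrame:
            out = vals.copy()
            out[binned_cols] = binner.transform(vals[binned_cols])
            return out

        X_train = _encode(train_vals)
        X_test = _encode(table.values.loc[frag_ids[test_m], numeric])
        for s in trial_seeds:
            forest = train_rf(y_train, X_train, hyper, seed=s)
            freq_vectors.append(forest.selection_frequency)
            rocs.append(roc_auc(forest.predict_proba_good(X_test.to_numpy(dtype=float)), y_test))
    if not freq_vectors:
        raise DegenerateTrainingError("no usable folds for RF validation")
    importance = importance_zscores(freq_vectors, numeric, cutoff)
    return importance, float(np.mean(rocs))
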