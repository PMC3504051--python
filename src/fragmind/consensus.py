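"""Agreement analysis: similarity, voting, and the cultural consensus model.

Binary selection vectors are compared with the modified Tanimoto
similarity

    S_MT = ((2 - p)/3) * S1 + ((1 + p)/3) * S0

where S1 = a/(a+b+c) is the Tanimoto agreement on selections, S0 =
d/(d+b+c) the agreement on rejections (a = both selected, d = both
rejected, b/c = mismatches over co-evaluated items), and p the mean
fraction of selections across the two vectors.  When few compounds are
selected (p small) the blend weighs agreement in selections more
heavily, and symmetrically for rejections.  S_MT(v, v) = 1 for any
vector (a vacuous component with zero denominator counts as perfect
agreement) and complementary vectors score 0.

Consistency applies S_MT to a selector's first vs second response over
fragments deliberately presented in two batches; consensus applies it
between selectors over all co-evaluated fragments.

The cultural consensus model (informal, match-matrix variant) estimates
each respondent's agreement with the group ("estimated consensus" or
competence, 0-1) by minimum-residual factoring of the chance-corrected
inter-respondent match matrix m* = 2m - 1 (two response options).  A
single shared response pattern requires both a first-to-second
eigenvalue ratio above 3 and all-positive first-factor loadings:
complementary answer blocks also yield a dominant factor, but with
mixed-sign loadings.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, SchemaError
from .snb import bayes_feature_score
from .synthetic_data import FragmentSet, SelectionMatrix

#: Sentinel for an eigenvalue ratio whose denominator is ~0.
RATIO_CAP = 1e6


def modified_tanimoto(v1: Sequence[float], v2: Sequence[float]) -> float:
    """Modified Tanimoto similarity of two binary vectors.

    Missing entries (NaN) are dropped pairwise; at least one co-evaluated
    item is required.
    """
    x = np.asarray(v1, dtype=float)
    y = np.asarray(v2, dtype=float)
    if x.shape != y.shape:
        raise SchemaError("vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size == 0:
        raise ParameterError("no co-evaluated fragments")
    a = int(np.sum((x == 1) & (y == 1)))
    d = int(np.sum((x == 0) & (y == 0)))
    bc = int(np.sum(x != y))
    s1 = a / (a + bc) if a + bc > 0 else 1.0
    s0 = d / (d + bc) if d + bc > 0 else 1.0
    p = (x.mean() + y.mean()) / 2.0
    return float((2.0 - p) / 3.0 * s1 + (1.0 + p) / 3.0 * s0)


def consistency(matrix: SelectionMatrix, fragments: FragmentSet) -> pd.Series:
    """Per-selector S_MT between first and second views of duplicated fragments."""
    dup = fragments.table[fragments.is_duplicate]
    first_ids, second_ids = [], []
    for frag_id, batches in zip(dup["fragment_id"], dup["batch_ids"]):
        ordered = sorted(batches)
        first_ids.append(f"{frag_id}@b{ordered[0]}")
        second_ids.append(f"{frag_id}@b{ordered[1]}")
    out = {}
    for sel in matrix.selector_ids:
        row = matrix.row(sel)
        try:
            out[sel] = modified_tanimoto(
                row.reindex(first_ids).to_numpy(), row.reindex(second_ids).to_numpy()
            )
        except ParameterError:
            warnings.warn(f"selector {sel!r} has no duplicate responses; skipped")
    return pd.Series(out, name="consistency")


def fragment_response_matrix(matrix: SelectionMatrix) -> pd.DataFrame:
    """Selectors x fragments: mean response over a fragment's presentations."""
    frag_of = matrix.presentations.set_index("presentation_id")["fragment_id"]
    cols = matrix.choices.columns
    return matrix.choices.T.groupby(frag_of.loc[cols].to_numpy()).mean().T


def agreement_fractions(matrix: SelectionMatrix) -> pd.DataFrame:
    """Per-fragment fraction selecting / rejecting over non-missing responses."""
    pres = matrix.presentations
    frag_of = pres.set_index("presentation_id")["fragment_id"]
    long = matrix.choices.T.copy()
    long["fragment_id"] = frag_of.loc[long.index].to_numpy()
    melted = long.melt(id_vars="fragment_id", value_name="choice").dropna(subset=["choice"])
    grouped = melted.groupby("fragment_id")["choice"].agg(["mean", "count"])
    out = pd.DataFrame(
        {
            "fraction_selecting": grouped["mean"],
            "fraction_rejecting": 1.0 - grouped["mean"],
            "n_evaluated": grouped["count"].astype(int),
        }
    )
    return out


def consensus_vote(fractions: pd.DataFrame, threshold: float = 0.75) -> pd.Series:
    """Label fragments consensus-good / consensus-bad / none at a threshold."""
    if not 0.5 < threshold <= 1.0:
        raise ParameterError("threshold must be in (0.5, 1]")
    labels = pd.Series("none", index=fractions.index, name="consensus")
    labels[fractions["fraction_selecting"] >= threshold] = "consensus-good"
    labels[fractions["fraction_rejecting"] >= threshold] = "consensus-bad"
    return labels


@dataclass
class CCMResult:
    """Cultural-consensus fit: eigenvalue diagnostic plus competences."""

    respondent_ids: list[str]
    corrected_match: np.ndarray
    eigenvalues: np.ndarray
    ratio: float
    competences: np.ndarray  # clipped to [0, 1]
    single_culture: bool

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "eigenvalues": [float(v) for v in self.eigenvalues[:5]],
            "ratio": float(self.ratio),
            "single_culture": bool(self.single_culture),
            "competences": {
                r: float(c) for r, c in zip(self.respondent_ids, self.competences)
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _minres_first_factor(mstar: np.ndarray, n_iter: int = 25, tol: float = 1e-6):
    """One-factor minimum-residual fit of a correlation-like matrix.

    Only the off-diagonal entries are fit: the diagonal is replaced by
    iterated communalities before each eigendecomposition.
    """
    m = mstar.copy()
    n = m.shape[0]
    comm = np.clip(np.abs(m - np.eye(n)).max(axis=1), 1e-3, 1.0)
    loadings = np.zeros(n)
    eigvals = None
    for _ in range(n_iter):
        np.fill_diagonal(m, comm)
        eigvals, eigvecs = np.linalg.eigh(m)
        eigvals, eigvecs = eigvals[::-1], eigvecs[:, ::-1]
        lam1 = max(eigvals[0], 0.0)
        new_loadings = np.sqrt(lam1) * eigvecs[:, 0]
        if new_loadings.sum() < 0:
            new_loadings = -new_loadings
        new_comm = np.clip(new_loadings**2, 0.0, 1.0)
        if np.max(np.abs(new_loadings - loadings)) < tol:
            loadings, comm = new_loadings, new_comm
            break
        loadings, comm = new_loadings, new_comm
    return loadings, eigvals


def ccm_fit(matrix: SelectionMatrix, n_iter: int = 25, tol: float = 1e-6) -> CCMResult:
    """Fit the informal cultural consensus model to a selection matrix.

    Typically the matrix is restricted beforehand to high-agreement
    fragments; a single shared answer pattern (eigenvalue ratio > 3) is a
    prerequisite for interpreting the competences.
    """
    if len(matrix.selector_ids) < 3:
        raise ParameterError("CCM needs at least 3 respondents")
    if matrix.choices.shape[1] < 2:
        raise ParameterError("CCM needs at least 2 items")
    resp = matrix.choices.to_numpy(dtype=float)
    n = resp.shape[0]
    match = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            keep = ~(np.isnan(resp[i]) | np.isnan(resp[j]))
            if keep.sum() == 0:
                raise ParameterError(f"respondents {i} and {j} share no items")
            match[i, j] = match[j, i] = float(np.mean(resp[i, keep] == resp[j, keep]))
    corrected = 2.0 * match - 1.0  # guessing correction for 2 response options
    loadings, eigvals = _minres_first_factor(corrected, n_iter=n_iter, tol=tol)
    if (loadings < 0).any():
        warnings.warn("negative competences clipped to 0")
    competences = np.clip(loadings, 0.0, 1.0)
    lam1 = eigvals[0]
    lam2 = eigvals[1] if len(eigvals) > 1 else 0.0
    if lam2 <= tol:
        ratio = RATIO_CAP if lam1 > 0 else 0.0
        if lam1 <= 0:
            warnings.warn("fewer than 2 positive eigenvalues; ratio undefined")
    else:
        ratio = min(float(lam1 / lam2), RATIO_CAP)
    # materially negative loadings mean a complementary response pattern,
    # not a shared one, regardless of the eigenvalue ratio
    positive_loadings = bool(loadings.min() > -0.1)
    return CCMResult(
        respondent_ids=list(matrix.selector_ids),
        corrected_match=corrected,
        eigenvalues=np.asarray(eigvals),
        ratio=float(ratio),
        competences=competences,
        single_culture=bool(ratio > 3.0 and positive_loadings),
    )


def restrict_to_fragments(matrix: SelectionMatrix, fragment_ids: Sequence[str]) -> SelectionMatrix:
    """Keep only presentations of the given fragments."""
    pres = matrix.presentations
    keep = pres[pres["fragment_id"].isin(set(fragment_ids))]
    return SelectionMatrix(matrix.choices[list(keep["presentation_id"])], keep.reset_index(drop=True))


def similarity_matrix(matrix: SelectionMatrix) -> pd.DataFrame:
    """Pairwise between-selector S_MT over co-evaluated fragments."""
    resp = fragment_response_matrix(matrix)
    # a fragment seen twice counts once; average responses >0.5 -> selected
    binary = (resp >= 0.5).where(resp.notna()).astype(float)
    ids = list(binary.index)
    out = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            b = ids[j]
            s = modified_tanimoto(binary.loc[a].to_numpy(), binary.loc[b].to_numpy())
            out.iloc[i, j] = out.iloc[j, i] = s
    return out


def consensus_feature_extraction(
    vote_labels: pd.Series,
    ecfp_sets: dict[str, frozenset],
    k: int = 50,
    min_count: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank circular-substructure features indicative of consensus votes.

    Two Bayesian feature scorings are trained on the voting labels: one
    with consensus-good fragments as the positive class, one with
    consensus-bad.  For each, features seen at least ``min_count`` times
    are ranked by score and the top ``k`` returned.
    """
    frag_ids = [f for f in vote_labels.index if f in ecfp_sets]
    sets = [ecfp_sets[f] for f in frag_ids]
    votes = vote_labels.loc[frag_ids]

    def _rank(positive: pd.Series) -> pd.DataFrame:
        from .snb import train_binary_nb

        labels = positive.to_numpy(dtype=int)
        nb = train_binary_nb(labels, sets)
        rows = [
            {"feature": f, "T": T, "A": A, "score": s}
            for f, (T, A, s) in nb.features.items()
            if T >= min_count
        ]
        frame = pd.DataFrame(rows).sort_values("score", ascending=False).reset_index(drop=True)
        if len(frame) < k:
            warnings.warn(f"only {len(frame)} features with count >= {min_count}")
        return frame.head(k)

    desirable = _rank(votes == "consensus-good")
    undesirable = _rank(votes == "consensus-bad")
    return desirable, undesirable
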