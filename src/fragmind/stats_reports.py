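"""Statistical comparisons for the survey analysis.

Exact upper-tail binomial tests ask whether more selectors share a
parameter (or a parameter pair) than expected under a uniform-choice
null; one-tailed Fisher exact tests ask whether model-identified
parameters associate with self-reported ones; a two-tailed paired t-test
compares how many parameters respondents report against how many their
models actually use; and per-batch pass-fraction summaries describe how
liberally each selector passes fragments.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTrainingError, ParameterError
from .synthetic_data import SelectionMatrix


@dataclass
class TestResult:
    test: str
    p_value: float
    tail: str  # "one" | "two"
    statistic: float | None = None
    inputs: dict | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def binomial_agreement_test(k: int, n: int, p0: float) -> TestResult:
    """Exact upper-tail binomial test: P(X >= k) under Binomial(n, p0)."""
    if not 0 <= k <= n:
        raise ParameterError("need 0 <= k <= n")
    if not 0.0 < p0 < 1.0:
        raise ParameterError("p0 must be in (0, 1)")
    p = float(stats.binom.sf(k - 1, n, p0))
    return TestResult("binomial_agreement", min(p, 1.0), "one", statistic=float(k), inputs={"k": k, "n": n, "p0": p0})


def two_param_baseline(n_params: int) -> float:
    """Chance probability of agreeing on one of C(n, 2) parameter pairs."""
    if n_params < 2:
        raise ParameterError("need at least 2 parameters")
    return 1.0 / comb(n_params, 2)


def fisher_param_independence(uses_by_model: np.ndarray, reports: np.ndarray) -> TestResult:
    """One-tailed (positive-association) Fisher exact test on a 2x2 table.

    ``uses_by_model``: per-respondent indicator that a classifier used the
    parameter; ``reports``: indicator that the respondent self-reported it.
    """
    u = np.asarray(uses_by_model, dtype=bool)
    r = np.asarray(reports, dtype=bool)
    if u.shape != r.shape:
        raise ParameterError("vectors must have equal length")
    table = [
        [int(np.sum(u & r)), int(np.sum(u & ~r))],
        [int(np.sum(~u & r)), int(np.sum(~u & ~r))],
    ]
    _, p = stats.fisher_exact(table, alternative="greater")
    return TestResult("fisher_param_independence", float(p), "one", inputs={"table": table})


def paired_count_ttest(reported_counts: np.ndarray, model_counts: np.ndarray) -> TestResult:
    """Two-tailed paired t-test on per-respondent parameter counts."""
    a = np.asarray(reported_counts, dtype=float)
    b = np.asarray(model_counts, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ParameterError("need paired vectors of length >= 2")
    if np.var(a - b, ddof=1) == 0:
        raise DegenerateTrainingError("zero variance of paired differences")
    t, p = stats.ttest_rel(a, b)
    return TestResult("paired_count_ttest", float(p), "two", statistic=float(t), inputs={"n": int(a.size)})


def pass_fraction_summary(matrix: SelectionMatrix) -> tuple[pd.DataFrame, dict]:
    """Per-selector per-batch pass fractions, plus a cohort summary.

    Returns a frame indexed by selector with one column per batch plus
    ``mean`` and ``sd``, and a cohort dict with the across-selector mean
    pass fraction and mean per-selector SD.
    """
    pres = matrix.presentations.set_index("presentation_id")
    long = matrix.choices.T.copy()
    long["batch"] = pres.loc[long.index, "batch"].to_numpy()
    melted = long.melt(id_vars="batch", var_name="selector_id", value_name="choice", ignore_index=False)
    melted = melted.dropna(subset=["choice"])
    per_batch = melted.groupby(["selector_id", "batch"])["choice"].mean().unstack("batch")
    per_batch["mean"] = per_batch.mean(axis=1)
    per_batch["sd"] = per_batch.drop(columns="mean").std(axis=1, ddof=0)
    cohort = {
        "mean_pass_fraction": float(per_batch["mean"].mean()),
        "mean_sd": float(per_batch["sd"].mean()),
        "min_pass_fraction": float(per_batch["mean"].min()),
        "max_pass_fraction": float(per_batch["mean"].max()),
    }
    return per_batch, cohort
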