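"""Individual differences: rank correlations of learning parameters with
executive-function scores.

Each participant's fitted potential (A, the saturation level of the SL
score) and efficiency (tau, the exponential time constant) are correlated
with ten neuropsychological test scores and with each other using
Kendall's tau-b (tie-corrected) with two-sided p values.  Scores are
z-transformed first; ranks — and hence tau — are unaffected, but the
standardized table is what downstream consumers see.  No multiple-testing
adjustment is applied by default; Benjamini-Hochberg is available as an
explicit opt-in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthesis import NEUROPSYCH_TESTS


def zscore(values, name: str = "variable", ddof: int = 1) -> np.ndarray:
    """Standardize to mean 0, sample SD 1; errors on zero variance."""
    v = np.asarray(values, dtype=float)
    if v.size < 2 or np.unique(v).size < 2:
        raise ValueError(f"cannot z-score {name!r}: fewer than 2 distinct values")
    sd = v.std(ddof=ddof)
    return (v - v.mean()) / sd


@dataclass
class CorrelationResult:
    var1: str
    var2: str
    r: float  # Kendall tau-b
    p: float  # two-sided
    n: int


def kendall_tau(x, y, var1: str = "x", var2: str = "y", method: str = "asymptotic") -> CorrelationResult:
    """Kendall tau-b with two-sided p value.

    The asymptotic p uses the tie-adjusted normal approximation; for small
    samples (n <= 10) pass ``method="exact"`` (valid only without ties).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("all-tied vector: Kendall tau undefined")
    r, p = stats.kendalltau(x, y, variant="b", method=method)
    return CorrelationResult(var1, var2, float(r), float(p), int(x.size))


def correlate_profiles(
    curves: pd.DataFrame,
    scores: pd.DataFrame,
    tests: tuple[str, ...] = NEUROPSYCH_TESTS,
    fdr: bool = False,
) -> tuple[pd.DataFrame, CorrelationResult]:
    """Correlate fitted A and tau with each test score, plus A vs tau.

    Parameters
    ----------
    curves
        Per-participant fits with columns ``participant_id, A, tau`` and an
        optional boolean ``converged`` (non-converged rows are excluded).
    scores
        Per-participant test scores, one column per test.
    fdr
        If True, append Benjamini-Hochberg adjusted p values (an extension
        beyond the default uncorrected report).

    Returns the test-correlation table (ordered parameter x test) and the
    A-vs-tau result.
    """
    c = curves.copy()
    if "converged" in c.columns:
        dropped = c[~c["converged"].astype(bool)]["participant_id"].tolist()
        if dropped:
            import logging

            logging.getLogger(__name__).info(
                "excluding %d non-converged participants from correlations: %s",
                len(dropped), dropped,
            )
        c = c[c["converged"].astype(bool)]
    merged = c.merge(scores, on="participant_id", how="inner")
    if len(merged) < 5:
        raise ValueError(f"only {len(merged)} matched participants; need at least 5")

    za = zscore(merged["A"], "A")
    zt = zscore(merged["tau"], "tau")
    rows = []
    for param, zp in (("A", za), ("tau", zt)):
        for test in tests:
            res = kendall_tau(zp, zscore(merged[test], test), param, test)
            rows.append({"parameter": param, "test": test, "r": res.r, "p": res.p, "n": res.n})
    table = pd.DataFrame(rows)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        table["p_bh"] = multipletests(table["p"], method="fdr_bh")[1]
    a_vs_tau = kendall_tau(za, zt, "A", "tau")
    return table, a_vs_tau
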