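"""Block x condition effects regressions on group-averaged ASRT summaries.

Two planned contrasts probe the behavioral effects over learning time:

* probability: Random-High (code 0) vs Random-Low (code 1) — the
  interaction of condition with centered block order measures the growth of
  the statistical-learning effect;
* type: Pattern-High (code 0) vs Random-High (code 1) — a control contrast
  for sequence-type differences at matched probability.

Each is an ordinary least squares fit of
``outcome ~ block_c + code + block_c:code`` on one row per block x
condition (block order centered at its mean), for accuracy and for mean RT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .curves import aicc as _aicc, bic as _bic
from .triplets import PH, RH, RL

CONTRASTS = {
    "probability": (RH, RL),
    "type": (PH, RH),
}

_TERMS = ("const", "block_c", "code", "interaction")


def build_design(
    summaries: pd.DataFrame, contrast: str = "probability", outcome: str = "rt"
) -> pd.DataFrame:
    """Group-averaged design matrix for one contrast and outcome.

    Participant-level summaries are averaged per block x condition (each
    participant weighted equally); block order is centered at its mean; the
    reference condition is coded 0 so the fitted intercept is the reference
    condition's grand mean on this balanced design.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"contrast must be one of {tuple(CONTRASTS)}")
    if outcome not in ("rt", "accuracy"):
        raise ValueError("outcome must be 'rt' or 'accuracy'")
    ref, alt = CONTRASTS[contrast]
    col = "mean_rt_ms" if outcome == "rt" else "accuracy"
    d = summaries[summaries["condition"].isin((ref, alt))]
    g = d.groupby(["block", "condition"], sort=True)[col].mean().reset_index()
    blocks = np.sort(summaries["block"].unique())
    full = pd.MultiIndex.from_product([blocks, (ref, alt)], names=["block", "condition"])
    g = g.set_index(["block", "condition"]).reindex(full).reset_index()
    if g[col].isna().any():
        missing = g[g[col].isna()][["block", "condition"]].to_records(index=False)
        raise ValueError(f"missing block x condition cells: {list(missing)[:5]}")
    g["block_c"] = g["block"] - g["block"].mean()
    g["code"] = (g["condition"] == alt).astype(float)
    g["interaction"] = g["block_c"] * g["code"]
    g["outcome"] = g[col]
    return g[["block", "condition", "block_c", "code", "interaction", "outcome"]]


@dataclass
class RegressionFit:
    """OLS fit of ``outcome ~ block_c + code + block_c:code``."""

    coef: pd.DataFrame  # index: term; columns: beta, se, t, p, ci_low, ci_high
    f_stat: float
    f_pvalue: float
    adj_r2: float
    aicc: float
    bic: float
    n: int
    k: int

    def as_dict(self) -> dict:
        return {
            "coefficients": {
                term: {c: float(v) for c, v in row.items()}
                for term, row in self.coef.iterrows()
            },
            "f_stat": float(self.f_stat),
            "f_pvalue": float(self.f_pvalue),
            "adj_r2": float(self.adj_r2),
            "aicc": float(self.aicc),
            "bic": float(self.bic),
            "n": self.n,
            "k": self.k,
        }

    def markdown_table(self) -> str:
        lines = [
            "| Coefficient | beta | SE | t | P | CI95 |",
            "|---|---|---|---|---|---|",
        ]
        for term, r in self.coef.iterrows():
            lines.append(
                f"| {term} | {r['beta']:.4g} | {r['se']:.4g} | {r['t']:.3g} "
                f"| {r['p']:.3g} | {r['ci_low']:.4g} to {r['ci_high']:.4g} |"
            )
        lines.append("")
        lines.append(
            f"F = {self.f_stat:.4g} (P = {self.f_pvalue:.3g}), adj. R2 = {self.adj_r2:.3f}, "
            f"AICc = {self.aicc:.1f}, BIC = {self.bic:.1f}"
        )
        return "\n".join(lines)


def fit_ols(design: pd.DataFrame) -> RegressionFit:
    """Ordinary least squares with Gaussian-likelihood AICc/BIC (k = 5:
    four coefficients plus the error variance)."""
    if len(design) < 8:
        raise ValueError("need at least 8 rows")
    X = np.column_stack(
        [
            np.ones(len(design)),
            design["block_c"].to_numpy(float),
            design["code"].to_numpy(float),
            design["interaction"].to_numpy(float),
        ]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    y = design["outcome"].to_numpy(float)
    res = sm.OLS(y, X).fit()

    ci = res.conf_int(alpha=0.05)
    coef = pd.DataFrame(
        {
            "beta": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
        },
        index=list(_TERMS),
    )
    n, k = len(y), 5
    # zero-variance outcome: define adj R2 as 0 rather than NaN
    adj_r2 = 0.0 if np.allclose(y, y[0]) else float(res.rsquared_adj)
    return RegressionFit(
        coef=coef,
        f_stat=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        adj_r2=adj_r2,
        aicc=_aicc(k, n, float(res.llf)),
        bic=_bic(k, n, float(res.llf)),
        n=n,
        k=k,
    )
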