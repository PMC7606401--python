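"""Learning-curve model fitting and selection for SL-score series.

Three candidate curves describe the growth of the per-block SL score y over
block order x:

* exponential: ``y = w1 * (1 - exp(-(x - w2)/w3))`` — a first-order step
  response; ``w1 = A`` is the saturation level (potential of learning),
  ``w2 = x0`` the x-intercept (starting block) and ``w3 = tau`` the time
  constant (blocks to reach 1 - 1/e ~ 63.2% of A; efficiency of learning).
* power: ``y = w1 * (x - w2)**w3`` (domain requires x - w2 > 0).
* linear: ``y = w1 * (x - w2) + w3``.

Fitting is maximum likelihood under i.i.d. Gaussian observation noise with
unknown SD, minimized with bounded L-BFGS-B from the all-ones start, with
jittered restarts as a fallback.  Model comparison uses the small-sample
corrected Akaike criterion, the Bayesian information criterion, and the BIC
approximation of the Bayes factor ``exp(-0.5 * (BIC_m1 - BIC_m0))``.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

MODEL_FORMS = ("exponential", "power", "linear")

_LOG_2PI = math.log(2.0 * math.pi)
_PENALTY = 1e10

#: stated per-participant bounds for the exponential fit:
#: A in [-500, 500], x0 in [0, 50], tau in [1, 50], sigma in [0, 30]
INDIVIDUAL_BOUNDS: tuple[tuple[float, float], ...] = (
    (-500.0, 500.0), (0.0, 50.0), (1.0, 50.0), (1e-6, 30.0),
)
#: group-level bounds widen x0 to [-50, 50] (the group curve can start
#: before block 1, e.g. the published x0 = -0.39)
GROUP_BOUNDS: tuple[tuple[float, float], ...] = (
    (-500.0, 500.0), (-50.0, 50.0), (1.0, 50.0), (1e-6, 30.0),
)

_DEFAULT_BOUNDS: Mapping[str, tuple[tuple[float, float], ...]] = {
    "exponential": GROUP_BOUNDS,
    # keep x - w2 > 0 over x >= 1 via the upper bound on w2
    "power": ((-500.0, 500.0), (-50.0, 0.99), (-5.0, 5.0), (1e-6, 30.0)),
    "linear": ((-500.0, 500.0), (-50.0, 50.0), (-500.0, 500.0), (1e-6, 30.0)),
}


class DomainError(ValueError):
    """Model evaluated outside its mathematical domain."""


def _predict_raw(form: str, params: Sequence[float], x: np.ndarray) -> np.ndarray:
    w1, w2, w3 = params
    if form == "exponential":
        return w1 * (1.0 - np.exp(-(x - w2) / w3))
    if form == "power":
        base = x - w2
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(base > 0, w1 * np.power(np.maximum(base, 1e-300), w3), np.nan)
    if form == "linear":
        return w1 * (x - w2) + w3
    raise ValueError(f"unknown model form {form!r}")


def predict(form: str, params: Sequence[float], x) -> np.ndarray:
    """Evaluate a learning curve; raises :class:`DomainError` off-domain."""
    x = np.asarray(x, dtype=float)
    if form == "exponential" and params[2] <= 0:
        raise DomainError("exponential time constant w3 must be > 0")
    y = _predict_raw(form, params, x)
    if not np.all(np.isfinite(y)):
        raise DomainError(f"{form} model undefined at some requested x (params={tuple(params)})")
    return y


def neg_log_likelihood(
    theta: Sequence[float], x: np.ndarray, y: np.ndarray, form: str
) -> float:
    """Gaussian negative log-likelihood; off-domain evaluations return a
    large penalty (keeps bounded optimizers stable) with a debug log."""
    w1, w2, w3, sigma = theta
    if sigma <= 0:
        return _PENALTY
    mu = _predict_raw(form, (w1, w2, w3), x)
    bad = ~np.isfinite(mu)
    if bad.any():
        logger.debug("non-finite prediction for %s at theta=%s; penalized", form, tuple(theta))
        return _PENALTY * (1.0 + float(bad.sum()))
    resid = y - mu
    n = x.size
    return 0.5 * n * _LOG_2PI + n * math.log(sigma) + float(resid @ resid) / (2.0 * sigma * sigma)


def aicc(k: int, n: int, logL: float) -> float:
    """Small-sample corrected Akaike criterion ``2k*n/(n-k-1) - 2*logL``."""
    if n <= k + 1:
        raise ValueError(f"AICc requires n > k + 1 (got n={n}, k={k})")
    return 2.0 * k * n / (n - k - 1) - 2.0 * logL


def bic(k: int, n: int, logL: float) -> float:
    """Bayesian information criterion ``k*ln(n) - 2*logL``."""
    return k * math.log(n) - 2.0 * logL


def bayes_factor(bic_m1: float, bic_m0: float) -> float:
    """BIC approximation of the Bayes factor for M1 against M0."""
    return math.exp(-0.5 * (bic_m1 - bic_m0))


@dataclass
class FitResult:
    """One maximum-likelihood curve fit."""

    form: str
    w1: float
    w2: float
    w3: float
    sigma: float
    logL: float
    k: int
    n: int
    aicc: float
    bic: float
    converged: bool
    bounds_hit: tuple[str, ...] = ()
    data_hash: str = ""

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.w1, self.w2, self.w3)


def _hash_data(x: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(x, dtype=float).tobytes())
    h.update(np.ascontiguousarray(y, dtype=float).tobytes())
    return h.hexdigest()[:16]


def fit_mle(
    x,
    y,
    form: str = "exponential",
    bounds: Sequence[tuple[float, float]] | None = None,
    init: Sequence[float] = (1.0, 1.0, 1.0, 1.0),
    restarts: int = 10,
    seed: int | None = None,
) -> FitResult:
    """Bounded-MLE fit of one learning-curve form to an SL-score series.

    Starts L-BFGS-B from ``init`` (all ones by default); if that run fails
    or lands on a non-sigma bound, up to ``restarts`` jittered starts
    (log-uniform within positive bounds, uniform otherwise) are tried and
    the best likelihood kept.  Missing y values are skipped with n reduced.
    Never raises on optimizer failure: a fully failed fit is returned with
    ``converged=False``.
    """
    if form not in MODEL_FORMS:
        raise ValueError(f"unknown model form {form!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y) & np.isfinite(x)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 5:
        raise ValueError(f"need at least 5 non-missing points, got {n}")
    bnds = tuple(bounds) if bounds is not None else _DEFAULT_BOUNDS[form]
    init = np.clip(np.asarray(init, dtype=float), [b[0] for b in bnds], [b[1] for b in bnds])

    def run(start):
        return minimize(
            neg_log_likelihood, start, args=(x, y, form),
            method="L-BFGS-B", bounds=bnds,
            options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-10},
        )

    def at_bounds(theta, tol=1e-8):
        names = ("w1", "w2", "w3", "sigma")
        return tuple(
            nm for nm, v, (lo, hi) in zip(names, theta, bnds)
            if v - lo <= tol * max(1.0, abs(lo)) + 1e-12 or hi - v <= tol * max(1.0, abs(hi)) + 1e-12
        )

    best = run(init)
    # sigma pinned at its floor just means a near-perfect fit, not failure
    needs_restart = (not best.success) or any(
        nm != "sigma" for nm in at_bounds(best.x)
    ) or best.fun >= _PENALTY
    if needs_restart and restarts > 0:
        rng = np.random.default_rng(0 if seed is None else seed)
        for _ in range(restarts):
            start = np.empty(4)
            for j, (lo, hi) in enumerate(bnds):
                if lo > 0:
                    start[j] = math.exp(rng.uniform(math.log(lo), math.log(hi)))
                else:
                    start[j] = rng.uniform(lo, hi)
            res = run(start)
            if res.fun < best.fun:
                best = res

    converged = bool(best.success and best.fun < _PENALTY)
    if not converged and best.fun < _PENALTY:
        # near-perfect fits drive sigma to its floor, where the likelihood
        # surface degenerates and the line search stalls; that is convergence
        w1_, w2_, w3_, sig_ = best.x
        mu = _predict_raw(form, (w1_, w2_, w3_), x)
        if np.all(np.isfinite(mu)):
            rms = math.sqrt(float(np.mean((y - mu) ** 2)))
            if sig_ <= bnds[3][0] * 1.01 + 1e-12 and rms <= 2.0 * sig_:
                converged = True
    if not converged:
        logger.warning("fit_mle(%s) did not converge (message=%s)", form, getattr(best, "message", "?"))
    w1, w2, w3, sigma = (float(v) for v in best.x)
    logL = -float(best.fun)
    k = 4
    return FitResult(
        form=form, w1=w1, w2=w2, w3=w3, sigma=sigma, logL=logL, k=k, n=n,
        aicc=aicc(k, n, logL), bic=bic(k, n, logL), converged=converged,
        bounds_hit=at_bounds(best.x), data_hash=_hash_data(x, y),
    )


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonRow:
    m1: str
    m0: str
    delta_aicc: float
    bayes_factor: float
    interpretation: str


def interpret_bayes_factor(bf: float) -> str:
    """Evidence band for M1 against M0 (BIC-approximate Bayes factor)."""
    if bf <= 1.0:
        return "Substantially supports the M0"
    if bf <= 3.0:
        return "Not worth more than a bare mention"
    if bf <= 20.0:
        return "Positively supports the M1"
    if bf <= 150.0:
        return "Strongly supports the M1"
    return "Very strongly supports the M1"


def interpret_delta_aicc(d: float) -> str:
    """Evidence band for M1 against M0 from the AICc difference."""
    if d < 2.0:
        return "Substantially supports the M0"
    if d < 4.0:
        return "Not worth more than a bare mention"
    if d < 7.0:
        return "Positively supports the M1"
    if d < 10.0:
        return "Strongly supports the M1"
    return "Very strongly supports the M1"


@dataclass
class ModelSelection:
    rows: list[ComparisonRow]
    best_by_aicc: str
    best_by_bic: str
    criteria_agree: bool


def compare_models(fits: Sequence[FitResult]) -> ModelSelection:
    """All ordered pairwise comparisons plus the selected model.

    ``delta_aicc = AICc(m0) - AICc(m1)``: positive values favor m1.  The
    interpretation label follows the Bayes-factor bands.  Refuses fits made
    on differing data.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    hashes = {f.data_hash for f in fits}
    if len(hashes) > 1:
        raise ValueError("fits were made on differing data; refusing to compare")
    if len({f.n for f in fits}) > 1:
        raise ValueError("fits have differing n; refusing to compare")
    rows = []
    for f1 in fits:
        for f0 in fits:
            if f1 is f0:
                continue
            bf = bayes_factor(f1.bic, f0.bic)
            rows.append(
                ComparisonRow(
                    m1=f1.form, m0=f0.form,
                    delta_aicc=f0.aicc - f1.aicc,
                    bayes_factor=bf,
                    interpretation=interpret_bayes_factor(bf),
                )
            )
    best_by_aicc = min(fits, key=lambda f: f.aicc).form
    best_by_bic = min(fits, key=lambda f: f.bic).form
    agree = best_by_aicc == best_by_bic
    if not agree:
        logger.warning("AICc picks %s but BIC picks %s", best_by_aicc, best_by_bic)
    return ModelSelection(rows, best_by_aicc, best_by_bic, agree)


# ---------------------------------------------------------------------------
# participant-level fits
# ---------------------------------------------------------------------------

@dataclass
class ParticipantCurve:
    participant_id: str
    A: float
    x0: float
    tau: float
    sigma: float
    converged: bool
    bounds_hit: tuple[str, ...] = ()


def fit_participants(
    scores,
    bounds: Sequence[tuple[float, float]] = INDIVIDUAL_BOUNDS,
    restarts: int = 10,
    seed: int | None = None,
) -> list[ParticipantCurve]:
    """Exponential fit per participant under the individual bounds.

    ``scores`` is a tidy frame with columns participant_id, block, sl_score.
    Non-converged participants are flagged (callers exclude them from
    correlations) and logged, never dropped silently.
    """
    out = []
    for pid, sub in scores.groupby("participant_id", sort=True):
        fit = fit_mle(
            sub["block"].to_numpy(), sub["sl_score"].to_numpy(),
            form="exponential", bounds=bounds, restarts=restarts, seed=seed,
        )
        if not fit.converged:
            logger.warning("participant %s: exponential fit did not converge; flagged", pid)
        out.append(
            ParticipantCurve(
                participant_id=str(pid), A=fit.w1, x0=fit.w2, tau=fit.w3,
                sigma=fit.sigma, converged=fit.converged, bounds_hit=fit.bounds_hit,
            )
        )
    return out


def fit_group(
    scores,
    pooling: str = "mean",
    bounds: Sequence[tuple[float, float]] = GROUP_BOUNDS,
    forms: Sequence[str] = MODEL_FORMS,
    restarts: int = 10,
    seed: int | None = None,
) -> dict[str, FitResult]:
    """Fit all candidate forms to the group series.

    pooling="mean" fits the per-block mean over participants (n = n_blocks);
    pooling="stacked" fits every participant-block point.
    """
    if pooling == "mean":
        g = scores.groupby("block", sort=True)["sl_score"].mean().reset_index()
        x, y = g["block"].to_numpy(), g["sl_score"].to_numpy()
    elif pooling == "stacked":
        x, y = scores["block"].to_numpy(), scores["sl_score"].to_numpy()
    else:
        raise ValueError("pooling must be 'mean' or 'stacked'")
    fits = {}
    for form in forms:
        b = bounds if form == "exponential" else _DEFAULT_BOUNDS[form]
        fits[form] = fit_mle(x, y, form=form, bounds=b, restarts=restarts, seed=seed)
    return fits
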