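"""Learning-curve prediction, likelihood, information criteria, fitting and
model comparison."""

import math

import numpy as np
import pytest
from scipy import stats

from slcurves import (
    INDIVIDUAL_BOUNDS,
    MODEL_FORMS,
    DomainError,
    aicc,
    bayes_factor,
    bic,
    compare_models,
    fit_mle,
    fit_participants,
    interpret_bayes_factor,
    interpret_delta_aicc,
    neg_log_likelihood,
    predict,
)

X36 = np.arange(1, 37, dtype=float)
GROUP_PARAMS = (13.25, -0.39, 10.28)  # (A, x0, tau) of the estimated group curve


class TestPredict:
    def test_exponential_is_zero_at_x0(self):
        assert predict("exponential", (10, 2.5, 5), [2.5])[0] == pytest.approx(0.0)

    def test_exponential_reaches_632_percent_at_x0_plus_tau(self):
        A, x0, tau = GROUP_PARAMS
        y = predict("exponential", GROUP_PARAMS, [x0 + tau])[0]
        assert y == pytest.approx(A * (1 - 1 / math.e))
        assert y / A == pytest.approx(0.632, abs=5e-4)

    def test_exponential_saturates_at_A(self):
        A, x0, tau = GROUP_PARAMS
        y = predict("exponential", GROUP_PARAMS, [x0 + 25 * tau])[0]
        assert abs(y - A) < 1e-6 * A

    def test_exponential_strictly_increasing_for_positive_A_tau(self):
        y = predict("exponential", (10, 0, 5), X36)
        assert (np.diff(y) > 0).all()

    def test_power_domain_guard(self):
        with pytest.raises(DomainError):
            predict("power", (1.0, 5.0, 0.5), [2.0])  # x - w2 < 0

    def test_exponential_nonpositive_tau_rejected(self):
        with pytest.raises(DomainError):
            predict("exponential", (1.0, 0.0, 0.0), [1.0])

    def test_linear_form(self):
        assert predict("linear", (0.27, -0.5, 4.74), [10.0])[0] == pytest.approx(
            0.27 * 10.5 + 4.74
        )


class TestNegLogLikelihood:
    def test_perfect_fit_closed_form(self):
        y = predict("linear", (2.0, 0.0, 1.0), X36)
        s = 3.0
        nll = neg_log_likelihood((2.0, 0.0, 1.0, s), X36, y, "linear")
        assert nll == pytest.approx(36 * math.log(s * math.sqrt(2 * math.pi)))

    def test_three_point_hand_oracle(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([0.5, 1.9, 3.2])
        theta = (1.1, 0.2, 0.3, 0.8)
        mu = 1.1 * (x - 0.2) + 0.3
        oracle = -stats.norm.logpdf(y, loc=mu, scale=0.8).sum()
        assert neg_log_likelihood(theta, x, y, "linear") == pytest.approx(oracle, abs=1e-10)

    def test_doubling_residuals_increases_nll(self):
        y0 = predict("exponential", (10, 0, 5), X36)
        y1 = y0 + 1.0
        y2 = y0 + 2.0
        theta = (10, 0, 5, 2.0)
        assert (neg_log_likelihood(theta, X36, y2, "exponential")
                > neg_log_likelihood(theta, X36, y1, "exponential"))

    def test_off_domain_returns_penalty_not_exception(self):
        val = neg_log_likelihood((1.0, 50.0, 0.5, 1.0), X36, X36 * 0.0, "power")
        assert val >= 1e10


class TestInformationCriteria:
    def test_aicc_direct_arithmetic(self):
        assert aicc(4, 36, -100.0) == pytest.approx(8 * 36 / 31 + 200, abs=1e-12)

    def test_bic_direct_arithmetic(self):
        assert bic(4, 36, -100.0) == pytest.approx(4 * math.log(36) + 200, abs=1e-12)

    def test_aicc_tends_to_aic_for_large_n(self):
        assert aicc(4, 10**9, 0.0) == pytest.approx(8.0, abs=1e-6)

    def test_aicc_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(4, 5, -10.0)

    def test_bayes_factor_e4(self):
        assert bayes_factor(12_508, 12_516) == pytest.approx(math.exp(4))
        assert round(bayes_factor(12_508, 12_516), 1) == 54.6

    def test_bayes_factor_e25(self):
        assert round(bayes_factor(12_511, 12_516), 1) == 12.2

    def test_bayes_factor_identity_and_antisymmetry(self):
        assert bayes_factor(100.0, 100.0) == 1.0
        assert bayes_factor(90.0, 95.0) * bayes_factor(95.0, 90.0) == pytest.approx(1.0)


class TestInterpretation:
    @pytest.mark.parametrize(
        "bf, label",
        [
            (0.5, "Substantially supports the M0"),
            (1.0, "Substantially supports the M0"),
            (2.0, "Not worth more than a bare mention"),
            (4.5, "Positively supports the M1"),
            (54.6, "Strongly supports the M1"),
            (200.0, "Very strongly supports the M1"),
        ],
    )
    def test_bayes_factor_bands(self, bf, label):
        assert interpret_bayes_factor(bf) == label

    @pytest.mark.parametrize(
        "d, label",
        [
            (1.0, "Substantially supports the M0"),
            (3.0, "Not worth more than a bare mention"),
            (5.0, "Positively supports the M1"),
            (7.0, "Strongly supports the M1"),
            (12.0, "Very strongly supports the M1"),
        ],
    )
    def test_delta_aicc_bands(self, d, label):
        assert interpret_delta_aicc(d) == label


class TestFitMLE:
    def test_noiseless_exponential_recovery(self):
        y = predict("exponential", (10.0, 0.0, 5.0), X36)
        f = fit_mle(X36, y, "exponential", restarts=10, seed=0)
        assert f.converged
        assert f.w1 == pytest.approx(10.0, abs=1e-4)
        assert f.w2 == pytest.approx(0.0, abs=1e-4)
        assert f.w3 == pytest.approx(5.0, abs=1e-4)

    def test_linear_slope_recovery(self):
        y = 0.27 * (X36 + 0.50) + 4.74
        f = fit_mle(X36, y, "linear", restarts=5, seed=0)
        assert f.w1 == pytest.approx(0.27, abs=1e-4)
        # w2/w3 trade off; the identified combination is the intercept
        assert -f.w1 * f.w2 + f.w3 == pytest.approx(0.27 * 0.5 + 4.74, abs=1e-3)

    def test_criteria_reproduce_formulas_exactly(self):
        rng = np.random.default_rng(1)
        y = predict("exponential", GROUP_PARAMS, X36) + rng.normal(0, 2, 36)
        f = fit_mle(X36, y, "exponential", restarts=3, seed=1)
        assert f.k == 4 and f.n == 36
        assert f.aicc == pytest.approx(aicc(4, 36, f.logL), abs=1e-12)
        assert f.bic == pytest.approx(bic(4, 36, f.logL), abs=1e-12)

    def test_missing_points_skipped_with_n_decremented(self):
        y = predict("exponential", (10.0, 0.0, 5.0), X36)
        y[[3, 17]] = np.nan
        f = fit_mle(X36, y, "exponential", restarts=3, seed=0)
        assert f.n == 34
        assert f.w1 == pytest.approx(10.0, abs=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_mle([1, 2, 3], [0.1, 0.2, 0.3], "exponential")

    def test_widening_sigma_bound_never_decreases_likelihood(self):
        rng = np.random.default_rng(2)
        y = predict("exponential", GROUP_PARAMS, X36) + rng.normal(0, 8, 36)
        narrow = ((-500, 500), (-50, 50), (1, 50), (1e-6, 5.0))
        wide = ((-500, 500), (-50, 50), (1, 50), (1e-6, 30.0))
        f_narrow = fit_mle(X36, y, "exponential", bounds=narrow, restarts=5, seed=2)
        f_wide = fit_mle(X36, y, "exponential", bounds=wide, restarts=5, seed=2)
        assert f_wide.logL >= f_narrow.logL - 1e-9

    def test_stochastic_A_recovery_within_10_percent(self):
        """Median |A_hat - A| over 200 noisy group-scale series < 10% of A."""
        errs = []
        for rep in range(200):
            rng = np.random.default_rng(np.random.SeedSequence([41, rep]))
            y = predict("exponential", GROUP_PARAMS, X36) + rng.normal(0, 2, 36)
            f = fit_mle(X36, y, "exponential", restarts=3, seed=rep)
            errs.append(abs(f.w1 - GROUP_PARAMS[0]))
        assert np.median(errs) < 0.10 * GROUP_PARAMS[0]


class TestCompareModels:
    def _fits(self, seed=3, noise=2.0):
        rng = np.random.default_rng(seed)
        y = predict("exponential", GROUP_PARAMS, X36) + rng.normal(0, noise, 36)
        return [fit_mle(X36, y, fm, restarts=5, seed=seed) for fm in MODEL_FORMS]

    def test_all_ordered_pairs_and_consistency(self):
        fits = self._fits()
        sel = compare_models(fits)
        assert len(sel.rows) == 6
        by_pair = {(r.m1, r.m0): r for r in sel.rows}
        r_ab = by_pair[("exponential", "linear")]
        r_ba = by_pair[("linear", "exponential")]
        assert r_ab.bayes_factor * r_ba.bayes_factor == pytest.approx(1.0)
        assert r_ab.delta_aicc == pytest.approx(-r_ba.delta_aicc)

    def test_delta_aicc_additivity_over_chains(self):
        fits = self._fits()
        by_pair = {(r.m1, r.m0): r for r in compare_models(fits).rows}
        d_el = by_pair[("exponential", "linear")].delta_aicc
        d_ep = by_pair[("exponential", "power")].delta_aicc
        d_pl = by_pair[("power", "linear")].delta_aicc
        assert d_el == pytest.approx(d_ep + d_pl, abs=1e-9)

    def test_self_comparison_of_identical_fits(self):
        fits = self._fits()
        clone = self._fits()
        sel = compare_models([fits[0], clone[0]])
        row = sel.rows[0]
        assert row.delta_aicc == pytest.approx(0.0, abs=1e-9)
        assert row.bayes_factor == pytest.approx(1.0)
        assert row.interpretation == "Substantially supports the M0"

    def test_differing_data_refused(self):
        rng = np.random.default_rng(4)
        y1 = predict("exponential", GROUP_PARAMS, X36) + rng.normal(0, 2, 36)
        y2 = predict("exponential", GROUP_PARAMS, X36) + rng.normal(0, 2, 36)
        f1 = fit_mle(X36, y1, "exponential", restarts=2, seed=4)
        f2 = fit_mle(X36, y2, "linear", restarts=2, seed=4)
        with pytest.raises(ValueError, match="differing data"):
            compare_models([f1, f2])

    def test_exponential_data_selected_by_smallest_aicc(self):
        fits = self._fits(seed=6)
        sel = compare_models(fits)
        assert sel.best_by_aicc == "exponential"


class TestFitParticipants:
    def test_noiseless_heterogeneous_recovery(self):
        import pandas as pd

        rng = np.random.default_rng(7)
        rows = []
        truths = {}
        for i in range(8):
            A, x0, tau = rng.uniform(8, 20), rng.uniform(0, 2), rng.uniform(4, 20)
            truths[f"p{i}"] = (A, x0, tau)
            rows.append(pd.DataFrame({
                "participant_id": f"p{i}", "block": X36,
                "sl_score": predict("exponential", (A, x0, tau), X36),
            }))
        curves = fit_participants(pd.concat(rows), restarts=5, seed=7)
        for c in curves:
            A, x0, tau = truths[c.participant_id]
            assert c.converged
            assert c.A == pytest.approx(A, abs=1e-3)
            assert c.tau == pytest.approx(tau, abs=1e-3)

    def test_out_of_bound_tau_pinned_with_flag(self):
        import pandas as pd

        scores = pd.DataFrame({
            "participant_id": "p0", "block": X36,
            "sl_score": predict("exponential", (10.0, 0.0, 60.0), X36),
        })
        c = fit_participants(scores, bounds=INDIVIDUAL_BOUNDS, restarts=5, seed=0)[0]
        assert c.tau == pytest.approx(50.0)
        assert "w3" in c.bounds_hit

    def test_rank_order_of_tau_recovered(self):
        """Heterogeneous noisy cohort: fitted tau ranks match true tau with
        Kendall tau >= 0.8 (noise 5 ms at the participant-score level is
        emulated by ~1 ms noise on per-block means of ~25 trials)."""
        import pandas as pd

        rng = np.random.default_rng(8)
        rows, true_tau = [], {}
        for i in range(20):
            A = rng.uniform(10, 18)
            tau = rng.uniform(3, 25)
            true_tau[f"p{i:02d}"] = tau
            y = predict("exponential", (A, 0.5, tau), X36) + rng.normal(0, 1.0, 36)
            rows.append(pd.DataFrame({
                "participant_id": f"p{i:02d}", "block": X36, "sl_score": y,
            }))
        curves = fit_participants(pd.concat(rows), restarts=5, seed=8)
        fitted = [c.tau for c in sorted(curves, key=lambda c: c.participant_id)]
        truth = [true_tau[k] for k in sorted(true_tau)]
        r, _ = stats.kendalltau(truth, fitted)
        assert r >= 0.8
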