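"""Hierarchical Brownian model: transitions, likelihood, derived
quantities, simulators and fitting."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from bistable import DominanceSeries
from bistable.distributions import barrier_to_ig, BarrierDriftParams, ig_pdf
from bistable.hbm import (
    DEFAULT_TIMING,
    HBMiParams,
    Timing,
    alternation_rate,
    decompose_drift,
    derived_params,
    fit_hbmi,
    hbmi_loglik,
    marginal_transitions,
    mean_drifts,
    mu_conditional,
    phi_S_star,
    ptilde_SS,
    ptilde_UU,
    rate_vs_blank,
    simulate_hbm_path,
    simulate_hbmi_intervals,
)
from conftest import hbmi_likelihood_enum, random_hbmi_params

# a well-mixing constellation in the long-stable regime used throughout
MIXED = HBMiParams(
    b_S=20.41,
    nu_S_star=0.272,
    b_U=2.0,
    nu_U_star=1.0,
    b_tilde_S=30.0,
    b_tilde_U=0.0,
    nu_B_star=0.30,
)


class TestTiming:
    def test_default_protocol(self):
        assert DEFAULT_TIMING.l_p == 0.6
        assert DEFAULT_TIMING.l_b == 0.8

    def test_invalid(self):
        with pytest.raises(ValueError):
            Timing(l_p=-0.1, l_b=0.8)
        with pytest.raises(ValueError):
            Timing(l_p=0.0, l_b=0.8)


class TestMeanDrifts:
    def test_hand_value(self):
        # (0.8 * 0.24 + 0.6 * 0.72) / 1.4
        assert mean_drifts(0.24, 0.72, Timing(0.6, 0.8)) == pytest.approx(
            0.44571, abs=1e-5
        )

    def test_decompose_inverts(self):
        t = Timing(0.6, 0.8)
        star = mean_drifts(0.24, 0.72, t)
        assert decompose_drift(star, 0.72, t) == pytest.approx(0.24, rel=1e-12)

    def test_continuous_limit(self):
        t = Timing(0.6, 0.0)
        assert mean_drifts(0.5, 0.5, t) == 0.5
        with pytest.raises(ValueError):
            mean_drifts(0.3, 0.5, t)


class TestPtilde:
    # construction: nu_B = 0.5, d = 4 so the standardized arguments are
    # (btilde_S - 2)/2 and (btilde_U + 2)/2
    P = HBMiParams(
        b_S=1.0,
        nu_S_star=0.5,
        b_U=0.5,
        nu_U_star=0.8,
        b_tilde_S=1.0,
        b_tilde_U=-0.6,
        nu_B_star=0.5,
    )

    def test_hand_values(self):
        assert float(ptilde_SS(4.0, self.P)) == pytest.approx(0.69146, abs=1e-5)
        assert float(ptilde_UU(4.0, self.P)) == pytest.approx(0.75804, abs=1e-5)

    def test_duration_dependence_monotone(self):
        d = np.array([1.0, 5.0, 20.0, 100.0])
        pss = np.asarray(ptilde_SS(d, self.P))
        assert np.all(np.diff(pss) > 0)  # longer stable times stabilize

    def test_rejects_nonpositive_duration(self):
        with pytest.raises(ValueError):
            ptilde_SS(0.0, self.P)


class TestMarginalTransitions:
    def test_equals_expectation_of_ptilde(self):
        rng = np.random.default_rng(55)
        for _ in range(5):
            p = random_hbmi_params(rng)
            p_SS, p_UU = marginal_transitions(p)
            ig_S, ig_U = p.stable_ig, p.unstable_ig
            def expectation(ig, weight):
                f = lambda t: ig_pdf(t, ig) * float(weight(t))
                split = ig.mu + 14 * ig.sigma
                bulk, _ = quad(f, 0.0, split, limit=200)
                tail, _ = quad(f, split, np.inf, limit=200)
                return bulk + tail

            qss = expectation(ig_S, lambda t: ptilde_SS(t, p))
            quu = expectation(ig_U, lambda t: ptilde_UU(t, p))
            assert p_SS == pytest.approx(qss, abs=2e-6)
            assert p_UU == pytest.approx(quu, abs=2e-6)

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(56)
        n = 200_000
        for _ in range(3):
            p = random_hbmi_params(rng)
            p_SS, _ = marginal_transitions(p)
            ig = p.stable_ig
            t = rng.wald(ig.mu, ig.lam, size=n)
            endpoint = p.nu_B_star * t + np.sqrt(t) * rng.standard_normal(n)
            emp = float(np.mean(endpoint > p.b_tilde_S))
            se = math.sqrt(max(emp * (1 - emp), 1e-12) / n)
            assert abs(p_SS - emp) < 4 * se + 1e-4


class TestLikelihood:
    def test_matches_enumeration(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            p = random_hbmi_params(rng)
            ig_S, ig_U = p.stable_ig, p.unstable_ig
            n = int(rng.integers(2, 11))
            d = np.concatenate(
                [
                    rng.wald(ig_S.mu, ig_S.lam, size=n // 2),
                    rng.wald(ig_U.mu, ig_U.lam, size=n - n // 2),
                ]
            )
            rng.shuffle(d)
            s = DominanceSeries(durations=d, condition="intermittent")
            ll = hbmi_loglik(s, p)
            brute = hbmi_likelihood_enum(s, p)
            assert math.exp(ll) == pytest.approx(brute, rel=1e-10)

    def test_requires_both_regimes(self):
        p = HBMiParams(b_S=5.0, nu_S_star=0.1, b_tilde_S=1.0)
        with pytest.raises(ValueError):
            hbmi_loglik(DominanceSeries(durations=np.array([1.0, 2.0])), p)


class TestDerived:
    def test_total_expectation_identity(self):
        # mu+ p + mu- (1 - p) = mu* for both states (Eqs for conditional
        # means integrate the IG law against ptilde)
        rng = np.random.default_rng(91)
        for _ in range(5):
            p = random_hbmi_params(rng)
            p_SS, p_UU = marginal_transitions(p)
            if not (1e-4 < p_SS < 1 - 1e-4 and 1e-4 < p_UU < 1 - 1e-4):
                continue
            muS = mu_conditional(p, "S", True) * p_SS + mu_conditional(
                p, "S", False
            ) * (1 - p_SS)
            muU = mu_conditional(p, "U", True) * p_UU + mu_conditional(
                p, "U", False
            ) * (1 - p_UU)
            assert muS == pytest.approx(p.stable_ig.mu, rel=1e-8)
            assert muU == pytest.approx(p.unstable_ig.mu, rel=1e-8)

    def test_mu_minus_below_mu_plus(self):
        # staying stable selects longer stable dominance times
        d = derived_params(MIXED)
        assert d.mu_S_minus < d.mu_S_plus

    def test_phi_star_matches_simulation(self):
        series, path = simulate_hbmi_intervals(MIXED, T=300_000.0, seed=8)
        stable_time = float(series.durations[path.states == 0].sum())
        frac = stable_time / float(series.durations.sum())
        assert frac == pytest.approx(phi_S_star(MIXED), abs=0.02)

    def test_one_regime_reductions(self):
        stable_only = HBMiParams(b_S=5.0, nu_S_star=0.1, b_tilde_S=0.0)
        d = derived_params(stable_only)
        assert d.phi_S_star == 1.0
        assert d.rho == pytest.approx(1.0 / stable_only.stable_ig.mu)
        assert math.isnan(d.mu_U_star)


class TestAlternationRate:
    LOWVAR = HBMiParams(
        b_S=3.0,
        nu_S_star=0.12,
        b_U=0.5,
        nu_U_star=0.35,
        b_tilde_S=5.0,
        b_tilde_U=0.0,
        nu_B_star=0.35,
    )

    def test_matches_long_simulation(self):
        rho = alternation_rate(self.LOWVAR)
        T = 4e6
        series, _ = simulate_hbmi_intervals(self.LOWVAR, T=T, seed=14)
        assert series.n / T == pytest.approx(rho, rel=0.02)

    def test_rate_vs_blank_inverted_u(self):
        # a stable blank drift decreasing in l_b produces a non-monotone
        # alternation-rate curve
        nu0 = 0.8
        nu_S = lambda l_b: 0.9 * math.exp(-2.0 * l_b)
        nu_U = lambda l_b: 1.2 * math.exp(-0.3 * l_b)
        grid = np.linspace(0.05, 0.5, 12)
        rho = rate_vs_blank(8.0, 1.0, 10.0, 0.0, 0.4, nu0, nu_S, nu_U, grid)
        assert np.all(np.isfinite(rho))
        peak = int(np.argmax(rho))
        assert 0 < peak < len(rho) - 1  # interior maximum: inverted U

    def test_rate_vs_blank_warns_on_nonpositive_drift(self):
        nu0 = 0.2
        nu_S = lambda l_b: -0.5  # blank drift strongly negative
        nu_U = lambda l_b: 0.8
        with pytest.warns(RuntimeWarning):
            rho = rate_vs_blank(
                8.0, 1.0, 10.0, 0.0, 0.4, nu0, nu_S, nu_U, np.array([5.0])
            )
        assert math.isnan(rho[0])


class TestIntervalSimulator:
    def test_seed_determinism(self):
        a, _ = simulate_hbmi_intervals(MIXED, T=1200.0, seed=5)
        b, _ = simulate_hbmi_intervals(MIXED, T=1200.0, seed=5)
        np.testing.assert_array_equal(a.durations, b.durations)

    def test_truncated_tail(self):
        s, _ = simulate_hbmi_intervals(MIXED, T=1200.0, seed=5)
        assert float(s.durations.sum()) + s.truncated_tail == pytest.approx(1200.0)

    def test_transition_frequency_matches_marginal(self):
        _, path = simulate_hbmi_intervals(MIXED, T=400_000.0, seed=10)
        st = path.states
        p_SS, p_UU = marginal_transitions(MIXED)
        from_S = st[:-1] == 0
        emp_SS = float(np.mean(st[1:][from_S] == 0))
        n_S = int(from_S.sum())
        se = math.sqrt(p_SS * (1 - p_SS) / n_S)
        assert abs(emp_SS - p_SS) < 4 * se


class TestPathSimulator:
    CONT = HBMiParams(
        b_S=2.08, nu_S_star=0.40, nu0=0.40, b_tilde_S=0.0, pi_S=1.0
    )

    def test_continuous_first_passage_ks(self):
        # hitting intervals of the continuous path are IG(2b/nu0, ...)
        ig = barrier_to_ig(BarrierDriftParams(b=2.08, nu=0.40))
        lam = ig.lam
        cdf = stats.invgauss(ig.mu / lam, scale=lam).cdf
        passes = 0
        for seed in range(10):
            path = simulate_hbm_path(
                self.CONT, Timing(0.6, 0.0), dt=1e-3, T=2000.0, seed=seed
            )
            ints = np.diff(np.concatenate([[0.0], path.H]))
            if stats.kstest(ints, cdf).pvalue > 0.01:
                passes += 1
        assert passes >= 9

    def test_zero_noise_sawtooth(self):
        path = simulate_hbm_path(
            self.CONT, Timing(0.6, 0.0), dt=1e-3, T=100.0, seed=0, diffusion=0.0
        )
        periods = np.diff(path.H)
        expected = 2.0 * 2.08 / 0.40
        np.testing.assert_allclose(periods, expected, rtol=1e-3)

    def test_path_vs_interval_two_sample_ks(self):
        params = HBMiParams(
            b_S=MIXED.b_S,
            nu_S_star=MIXED.nu_S_star,
            b_U=MIXED.b_U,
            nu_U_star=MIXED.nu_U_star,
            b_tilde_S=MIXED.b_tilde_S,
            b_tilde_U=MIXED.b_tilde_U,
            nu_B_star=MIXED.nu_B_star,
            nu0=0.5,
        )
        passes = 0
        for seed in range(10):
            path = simulate_hbm_path(
                params, DEFAULT_TIMING, dt=1e-3, T=4000.0, seed=seed
            )
            d_path = np.diff(np.concatenate([[0.0], path.H]))
            series, _ = simulate_hbmi_intervals(params, T=4000.0, seed=1000 + seed)
            pv = stats.ks_2samp(d_path, series.durations).pvalue
            if pv > 0.01:
                passes += 1
        assert passes >= 9

    def test_requires_nu0(self):
        with pytest.raises(ValueError):
            simulate_hbm_path(MIXED, DEFAULT_TIMING, T=10.0, seed=0)

    def test_coarse_dt_warns(self):
        params = HBMiParams(
            b_S=5.0, nu_S_star=0.1, b_U=0.5, nu_U_star=0.5,
            b_tilde_S=1.0, b_tilde_U=0.0, nu_B_star=0.3, nu0=0.5,
        )
        with pytest.warns(RuntimeWarning):
            simulate_hbm_path(params, DEFAULT_TIMING, dt=0.2, T=10.0, seed=0)


class TestFitHBMi:
    def test_recovery_on_simulated_data(self):
        series, _ = simulate_hbmi_intervals(MIXED, T=7200.0, seed=1)
        fit = fit_hbmi(series, timing=DEFAULT_TIMING)
        assert fit.fallback is None
        truth = derived_params(MIXED)
        assert fit.derived.mu_S_star == pytest.approx(truth.mu_S_star, rel=0.25)
        assert fit.derived.mu_U_star == pytest.approx(truth.mu_U_star, rel=0.3)
        assert fit.derived.p_SS_star == pytest.approx(truth.p_SS_star, abs=0.2)
        # the ML fit cannot be worse than the truth on its own data
        assert fit.loglik >= hbmi_loglik(series, MIXED)

    def test_all_long_reduces_to_stable(self):
        rng = np.random.default_rng(3)
        d = rng.wald(150.0, 10_000.0, size=10)
        assert np.all(d > 30.0)
        s = DominanceSeries(durations=d, condition="intermittent")
        fit = fit_hbmi(s)
        assert fit.fallback == "stable"
        assert fit.params.regime == "stable"

    def test_all_short_reduces_to_unstable(self):
        rng = np.random.default_rng(4)
        d = rng.wald(4.0, 30.0, size=40)
        d = d[d <= 30.0][:20]
        s = DominanceSeries(durations=d, condition="intermittent")
        fit = fit_hbmi(s)
        assert fit.fallback == "unstable"
        assert fit.params.regime == "unstable"
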