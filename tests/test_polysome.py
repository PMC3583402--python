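"""Polysome protection model: closed forms, inversion, Monte-Carlo oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitotx.polysome import (LN2, PolysomeModel, PolysomeParams,
                             binding_intensity, decay_intensity, half_life,
                             half_life_ratio, solve_lambda, solve_nu)


def params(mu=1.0, nu=0.0, alpha=0.0, N=0.0, w=1.0, k=1):
    return PolysomeParams(mu=mu, nu=nu, alpha=alpha, N=N, w=w, k=k)


class TestBindingIntensity:
    def test_values(self):
        assert binding_intensity(1.0, 0.1, 0.0) == 0.0
        assert binding_intensity(1.0, 0.1, 10.0) == pytest.approx(5.0)
        # saturation at nu/alpha
        assert binding_intensity(1.0, 0.1, 1e6) == pytest.approx(10.0, rel=1e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            binding_intensity(-1.0, 0.1, 1.0)


class TestClosedForms:
    def test_unprotected_half_life(self):
        assert half_life(params(mu=2.0), lam=0.0) == pytest.approx(LN2 / 2.0)

    def test_derived_value(self):
        # d=2/3, w=1, lam=1, mu=1 -> ln2 * (5/3) * e
        tau = half_life(params(mu=1.0, w=1.0), lam=1.0)
        assert tau == pytest.approx(LN2 * (5 / 3) * math.e, rel=1e-12)
        assert tau == pytest.approx(3.140, abs=2e-3)

    def test_mu_zero_infinite(self):
        assert half_life(params(mu=0.0), lam=1.0) == math.inf

    @settings(max_examples=150, derandomize=True)
    @given(st.floats(0.01, 100), st.floats(0, 20), st.floats(1 / 15, 4 / 3))
    def test_tau_kappa_identity(self, mu, lam, w):
        p = params(mu=mu, w=w)
        assert half_life(p, lam) * decay_intensity(p, lam) == pytest.approx(
            LN2, rel=1e-12)

    def test_k_sites_scale_linearly(self):
        p1, p3 = params(k=1), params(k=3)
        assert decay_intensity(p3, 1.0) == pytest.approx(3 * decay_intensity(p1, 1.0))
        assert half_life(p3, 1.0) == pytest.approx(half_life(p1, 1.0) / 3)

    def test_kappa_strictly_decreasing_in_lambda(self):
        p = params()
        lams = np.linspace(0, 10, 50)
        kappas = [decay_intensity(p, l) for l in lams]
        assert all(a > b for a, b in zip(kappas, kappas[1:]))
        assert decay_intensity(p, 0.0) == pytest.approx(p.mu)

    def test_tau_strictly_increasing_in_lambda_w_d(self):
        assert half_life(params(), 2.0) > half_life(params(), 1.0)
        assert half_life(params(w=1.2), 1.0) > half_life(params(w=0.5), 1.0)


class TestHalfLifeRatio:
    def test_identity_and_monotonicity(self):
        assert half_life_ratio(1.0, 1.0, 2 / 3, 1.0) == 1.0
        assert half_life_ratio(1.0, 0.5, 2 / 3, 1.0) > 1.0

    def test_derived_value(self):
        # (1+2/3)/(1+1/3) * e^{0.5} = 1.25 e^{0.5}
        v = half_life_ratio(1.0, 0.5, 2 / 3, 1.0)
        assert v == pytest.approx(1.25 * math.exp(0.5), rel=1e-12)
        assert v == pytest.approx(2.061, abs=2e-3)

    def test_melas_expected_band_reachable(self):
        """A drop in ribosome number N -> N' produces tau/tau' in the
        experimentally expected 1.5-3 band for a plausible parameter set."""
        m = PolysomeModel.from_rates(mu=0.05, nu=0.02, alpha=0.01, N=100.0, w=1.0)
        ratio = m.half_life_ratio_vs(N_prime=40.0)
        assert 1.5 <= ratio <= 3.0


class TestInversion:
    def test_minimum_half_life_gives_zero(self):
        assert solve_nu(LN2 / 1.0, w=1.0, d=2 / 3, alpha=0.1, N=10.0, mu=1.0) == 0.0

    def test_below_minimum_infeasible(self):
        with pytest.raises(ValueError, match="below"):
            solve_nu(0.5 * LN2, w=1.0, d=2 / 3, alpha=0.1, N=10.0, mu=1.0)

    @pytest.mark.parametrize("tau_obs", [1.0, 5.0, 120.0])
    def test_round_trip(self, tau_obs):
        w, d, alpha, N, mu = 0.8, 2 / 3, 0.05, 20.0, 2.0
        nu = solve_nu(tau_obs, w, d, alpha, N, mu)
        lam = binding_intensity(nu, alpha, N)
        p = PolysomeParams(mu=mu, nu=nu, alpha=alpha, N=N, w=w)
        assert half_life(p, lam) == pytest.approx(tau_obs, rel=1e-10)

    def test_solve_lambda_monotone_in_tau(self):
        lams = [solve_lambda(t, mu=1.0, w=1.0, d=2 / 3) for t in (1.0, 2.0, 8.0)]
        assert lams[0] < lams[1] < lams[2]


class TestWindowProcessOracle:
    @pytest.mark.parametrize("lam,mu,w", [(1.0, 0.5, 0.8), (0.5, 1.0, 1.2),
                                          (2.0, 0.2, 0.3)])
    def test_monte_carlo_half_life_matches_closed_form(self, lam, mu, w):
        """Simulate the literal window process: ribosomes pass the cleavage
        site as a renewal stream with dead time d (their own size over their
        rate) and exponential gaps at rate λ; the ribonuclease attacks at
        Poisson rate μ but succeeds only once the site has been clear for at
        least w seconds.  The empirical half-life ln2 / (successes per unit
        time) of the stationary process must match the closed form.  (The
        closed form describes the stationary stream, so the oracle measures
        the long-run rate rather than a cold-start first passage.)"""
        d = 2 / 3
        rng = np.random.default_rng(2024)
        n_cycles = 200_000
        gaps = rng.exponential(1.0 / lam, size=n_cycles)
        open_time = np.clip(gaps - w, 0.0, None)
        successes = rng.poisson(mu * open_time).sum()
        total_time = n_cycles * d + gaps.sum()
        tau_hat = LN2 * total_time / successes
        expected = half_life(PolysomeParams(mu=mu, w=w,
                                            enforce_w_bounds=False), lam)
        assert tau_hat == pytest.approx(expected, rel=0.05)


class TestModelObject:
    def test_summary_reports_consistent_numbers(self):
        m = PolysomeModel.from_rates(mu=1.0, nu=1.0, alpha=0.1, N=10.0, w=1.0)
        r = m.evaluate()
        assert r["lambda"] == pytest.approx(5.0)
        assert r["half_life_s"] * r["decay_intensity_per_s"] == pytest.approx(LN2)
        text = m.summary()
        assert "half-life" in text and "5" in text

    def test_w_bounds_enforced_unless_overridden(self):
        with pytest.raises(ValueError, match="bounds"):
            PolysomeParams(mu=1.0, w=5.0)
        PolysomeParams(mu=1.0, w=5.0, enforce_w_bounds=False)
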