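"""PMF of the number of segregating sites: oracles, stability, invariants."""

import decimal
import math
from decimal import Decimal

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import special
from scipy.integrate import quad
from scipy.stats import poisson

import iimcoal as ic
from iimcoal.coalescent_core import ParameterError
from iimcoal.segsites import SegsitesContext, _logpmf_logspace, logpmf_array

from conftest import REGIMES, draw_params


def quadrature_pmf(state, s, theta, params, spec):
    """Independent oracle: integrate Pois(s; theta*t) against the density of T."""
    def integrand(t):
        return poisson.pmf(s, theta * t) * ic.density_T(state, t, params, spec)

    kw = dict(limit=400, epsabs=1e-300, epsrel=1e-10)
    total = quad(integrand, 0, params.tau0, points=[params.tau1], **kw)[0]
    # split the unbounded piece around the Poisson bump at t = s / theta so
    # adaptive quadrature cannot miss it, and force *relative* accuracy --
    # the default absolute tolerance is useless for deep-tail probabilities
    bump = max(s / theta, params.tau0 + 1.0)
    cuts = [params.tau0, 0.5 * (params.tau0 + bump), 2.0 * bump]
    for lo, hi in zip(cuts, cuts[1:]):
        total += quad(integrand, lo, hi, **kw)[0]
    total += quad(integrand, cuts[-1], np.inf, **kw)[0]
    return total


# ---------------------------------------------------------------------------
# 50-digit decimal arithmetic oracle
# ---------------------------------------------------------------------------

def _dec_pois_cdf(s: int, x: Decimal) -> Decimal:
    term = (-x).exp()
    acc = term
    for ell in range(1, s + 1):
        term *= x / ell
        acc += term
    return acc


def _dec_pois_tail(s: int, x: Decimal) -> Decimal:
    """P(Pois(x) > s), summed upward from l = s + 1 (stable when x << s)."""
    term = (-x).exp()
    for ell in range(1, s + 2):
        term *= x / ell
    acc = Decimal(0)
    ell = s + 1
    while True:
        acc += term
        ell += 1
        term *= x / ell
        if term < acc * Decimal("1e-60") and ell > x:
            return acc


def _dec_cdf_diff(s: int, x1: Decimal, x0: Decimal) -> Decimal:
    """pcdf(s, x1) - pcdf(s, x0) without the catastrophic 1 - tiny rounding."""
    if x0 < Decimal(max(s, 1)) / 2:
        return _dec_pois_tail(s, x0) - _dec_pois_tail(s, x1)
    return _dec_pois_cdf(s, x1) - _dec_pois_cdf(s, x0)


def decimal_pmf(state, s, theta, params, spec):
    """The segregating-sites PMF evaluated in 50-digit decimal arithmetic.

    Uses the same mixture representation (decay rates and coefficients from
    the double-precision spectrum) but carries every product, power and
    truncated Poisson sum in high precision, so it exposes any overflow or
    cancellation in the double-precision evaluation path.
    """
    with decimal.localcontext() as ctx:
        ctx.prec = 50
        th = Decimal(repr(theta))
        tau1 = Decimal(repr(params.tau1))
        tau0 = Decimal(repr(params.tau0))
        a = Decimal(repr(params.a))
        total = Decimal(0)
        if state != 3:
            c = Decimal(repr(params.c1 if state == 1 else params.c2))
            geom = (c * th) ** s / (1 + c * th) ** (s + 1)
            x_iso = (1 / c + th) * tau1
            one_minus = (
                _dec_pois_tail(s, x_iso)
                if x_iso < Decimal(max(s, 1)) / 2
                else 1 - _dec_pois_cdf(s, x_iso)
            )
            total += geom * one_minus
            surv_iso = (-tau1 / c).exp()
        else:
            surv_iso = Decimal(1)
        lam = [Decimal(repr(float(v))) for v in spec.lam]
        row = [Decimal(repr(float(v))) for v in spec.A[state - 1]]
        delta = tau0 - tau1
        for lj, aj in zip(lam, row):
            if aj == 0:
                continue
            bracket = _dec_cdf_diff(s, (th + lj) * tau1, (th + lj) * tau0)
            total += (
                surv_iso * aj * lj * th**s / (th + lj) ** (s + 1)
                * (lj * tau1).exp() * bracket
            )
        surv_mig = 1 - sum(row) + sum(
            aj * (-lj * delta).exp() for lj, aj in zip(lam, row)
        )
        total += (
            surv_iso * surv_mig * (a * th) ** s / (1 + a * th) ** (s + 1)
            * (tau0 / a).exp() * _dec_pois_cdf(s, (th + 1 / a) * tau0)
        )
        return total


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

class TestAgainstOracles:
    def test_pmf_matches_quadrature(self):
        rng = np.random.default_rng(11)
        worst = 0.0
        for trial in range(20):
            params = draw_params(rng, REGIMES[trial % 4])
            theta = rng.uniform(0.5, 4.0)
            ctx = SegsitesContext(params, theta)
            for state in (1, 2, 3):
                for s in (0, 3, 17, 120):
                    oracle = quadrature_pmf(state, s, theta, params, ctx.spectrum)
                    mine = ic.pmf_S(state, s, ctx)
                    if oracle > 1e-250:
                        worst = max(worst, abs(mine - oracle) / oracle)
        assert worst < 1e-7

    def test_poisson_cdf_as_incomplete_gamma_highprec(self):
        # the building block: e^-x sum_{l<=s} x^l/l! == Q(s+1, x), checked
        # against 50-digit arithmetic on a stress grid
        with decimal.localcontext() as ctx:
            ctx.prec = 50
            for s in (0, 3, 40, 500, 10_000):
                for x in (1e-3, 0.7, 15.0, 800.0, 1e4):
                    ours = Decimal(repr(float(special.gammaincc(s + 1, x))))
                    exact = _dec_pois_cdf(s, Decimal(repr(x)))
                    if exact > Decimal("1e-300"):
                        rel = abs(ours - exact) / exact
                        assert rel < Decimal("1e-10"), (s, x)

    def test_logpmf_large_s_matches_decimal_oracle(self, study_params):
        spec = ic.migration_spectrum(study_params)
        for state in (1, 3):
            for s, theta in ((120, 2.0), (700, 10.0), (5000, 50.0)):
                ctx = SegsitesContext(study_params, theta, spec)
                mine = ic.logpmf_S(state, s, ctx)
                exact = decimal_pmf(state, s, theta, study_params, spec)
                assert mine == pytest.approx(float(exact.ln()), abs=1e-8)


class TestStability:
    def test_logpmf_finite_and_consistent(self, study_params):
        ctx = SegsitesContext(study_params, 2.0)
        assert math.exp(ic.logpmf_S(1, 5, ctx)) == pytest.approx(
            ic.pmf_S(1, 5, ctx), rel=1e-12
        )
        big = SegsitesContext(study_params, 50.0)
        for state in (1, 2, 3):
            vals = [ic.logpmf_S(state, s, big) for s in (2000, 5000, 10_000)]
            assert all(np.isfinite(v) for v in vals)
            assert vals[0] > vals[1] > vals[2]  # monotone tail decay

    def test_fast_and_logspace_paths_agree(self, study_params):
        rng = np.random.default_rng(3)
        spec = ic.migration_spectrum(study_params)
        s = rng.poisson(5.0, 3000)
        th = 2.0 * rng.gamma(15.0, 1 / 15.0, 3000)
        for state in (1, 2, 3):
            fast = logpmf_array(state, s, th, study_params, spec)
            slow = _logpmf_logspace(state, s, th, study_params, spec)
            np.testing.assert_allclose(fast, slow, atol=1e-11)
        # deep-tail counts, all regimes: the cancellation-prone region
        s_grid = np.arange(130)
        for trial in range(8):
            p = draw_params(rng, REGIMES[trial % 4])
            th = np.full(130, rng.uniform(0.5, 4.0))
            spec_t = ic.migration_spectrum(p)
            for state in (1, 2, 3):
                fast = logpmf_array(state, s_grid, th, p, spec_t)
                slow = _logpmf_logspace(state, s_grid, th, p, spec_t)
                ok = np.isfinite(slow) & (slow > -600)
                np.testing.assert_allclose(fast[ok], slow[ok], atol=1e-9)

    def test_theta_to_zero_limit(self, study_params):
        ctx = SegsitesContext(study_params, 1e-12)
        for state in (1, 2, 3):
            assert ic.pmf_S(state, 0, ctx) == pytest.approx(1.0, abs=1e-9)

    @given(st.integers(0, 4), st.integers(0, 250), st.floats(0.2, 8.0))
    def test_pmf_nonnegative(self, trial, s, theta):
        rng = np.random.default_rng(trial)
        params = draw_params(rng, REGIMES[trial % 4])
        ctx = SegsitesContext(params, theta)
        for state in (1, 2, 3):
            p = ic.pmf_S(state, s, ctx)
            assert 0.0 <= p <= 1.0

    def test_input_validation(self, study_params):
        ctx = SegsitesContext(study_params, 2.0)
        with pytest.raises(ParameterError):
            ic.pmf_S(1, -1, ctx)
        with pytest.raises(ParameterError):
            ic.pmf_S(1, 2.5, ctx)
        with pytest.raises(ParameterError):
            SegsitesContext(study_params, -1.0)


class TestMoments:
    def test_normalizes_to_one(self, study_params):
        # truncation at mean + 12 sd of the compound distribution
        spec = ic.migration_spectrum(study_params)
        for state in (1, 2, 3):
            theta = 2.0
            ctx = SegsitesContext(study_params, theta, spec)
            m_t = ic.mean_T(state, study_params, spec)
            et2 = (
                quad(lambda t: t * t * ic.density_T(state, t, study_params, spec),
                     0, study_params.tau0, points=[study_params.tau1], limit=300)[0]
                + quad(lambda t: t * t * ic.density_T(state, t, study_params, spec),
                       study_params.tau0, np.inf, limit=300)[0]
            )
            var_s = theta * m_t + theta**2 * (et2 - m_t**2)
            # start from mean + 12 sd, then extend adaptively until the
            # geometric tail is provably below the tolerance
            s_star = int(theta * m_t + 12 * math.sqrt(var_s)) + 1
            while ic.pmf_S(state, s_star, ctx) > 1e-13:
                s_star += 5
            total = sum(ic.pmf_S(state, s, ctx) for s in range(s_star))
            assert abs(total - 1.0) < 1e-9

    def test_mean_s(self):
        # no gene flow, empty migration stage: E[S] = theta * (tau0 + a)
        p = ic.CoalParams(a=0.75, b=1.0, tau1=2.0, tau0=2.0, M1=0.0, M2=0.0)
        ctx = SegsitesContext(p, 2.0)
        assert ic.mean_S(3, ctx) == pytest.approx(5.5)
        sum_s = sum(s * ic.pmf_S(3, s, ctx) for s in range(250))
        assert ic.mean_S(3, ctx) == pytest.approx(sum_s, abs=1e-6)

    def test_mean_s_matches_pmf_sum_with_migration(self, study_params):
        ctx = SegsitesContext(study_params, 2.0)
        for state in (1, 2, 3):
            sum_s = sum(s * ic.pmf_S(state, s, ctx) for s in range(300))
            assert ic.mean_S(state, ctx) == pytest.approx(sum_s, abs=1e-6)
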