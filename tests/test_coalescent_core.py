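"""Generators, eigen-spectra and coalescence-time distributions."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, strategies as st
from scipy.integrate import quad

import iimcoal as ic
from iimcoal.coalescent_core import ParameterError

from conftest import REGIMES, draw_params

INTERNAL_ROW = {1: 0, 3: 1, 2: 2}  # state -> row of the (1, 3, 2, coal) order


def expm_cdf(params, state, t):
    """Absorption CDF of the migration-stage chain by matrix exponential."""
    q = ic.build_generator_mig(params).entries
    return scipy.linalg.expm(q * t)[INTERNAL_ROW[state], 3]


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

class TestGenerators:
    def test_migration_generator_rates(self):
        p = ic.CoalParams(a=1, b=1.0, tau1=0, tau0=1, M1=0.0, M2=1.0)
        q = ic.build_generator_mig(p).entries
        # exit rates fixed by the first-transition conditioning: 1/b + M2
        # from state 2, M2/2 from state 3
        assert -q[2, 2] == pytest.approx(2.0)
        assert -q[1, 1] == pytest.approx(0.5)
        assert -q[0, 0] == pytest.approx(1.0)

    def test_no_migration_decouples(self):
        p = ic.CoalParams(a=1, b=1.0, tau1=0, tau0=1, M1=0.0, M2=0.0)
        q = ic.build_generator_mig(p).entries
        assert q[0, 3] == 1.0 and q[2, 3] == 1.0
        assert q[0, 1] == q[2, 1] == q[1, 0] == q[1, 2] == 0.0

    @given(
        st.floats(0.0, 5.0),
        st.floats(0.0, 5.0),
        st.floats(0.1, 4.0),
    )
    def test_row_sums_zero(self, M1, M2, b):
        p = ic.CoalParams(a=1, b=b, tau1=0, tau0=1, M1=M1, M2=M2)
        q = ic.build_generator_mig(p).entries
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        off = q - np.diag(np.diag(q))
        assert (off >= 0).all()
        assert np.all(q[3] == 0.0)

    def test_single_population_generators(self):
        p = ic.CoalParams(a=0.75, b=1, c1=1.0, c2=2.0, tau1=1, tau0=2)
        assert ic.build_generator_iso(p, 1).entries[0, 1] == pytest.approx(1.0)
        assert ic.build_generator_iso(p, 2).entries[0, 1] == pytest.approx(0.5)
        assert ic.build_generator_anc(p).entries[0, 1] == pytest.approx(4.0 / 3.0)
        with pytest.raises(ParameterError):
            ic.build_generator_iso(p, 3)

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            ic.CoalParams(a=-1, b=1)
        with pytest.raises(ParameterError):
            ic.CoalParams(a=1, b=1, tau1=2.0, tau0=1.0)
        with pytest.raises(ParameterError):
            ic.CoalParams(a=1, b=1, M1=-0.1)


# ---------------------------------------------------------------------------
# Spectrum
# ---------------------------------------------------------------------------

class TestSpectrum:
    def test_matches_matrix_exponential_all_regimes(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for trial in range(52):
            params = draw_params(rng, REGIMES[trial % 4])
            spec = ic.migration_spectrum(params)
            for state in (1, 2, 3):
                for t in np.linspace(0.05, 8.0, 20):
                    ana = 1.0 - spec.survival(state, t)
                    worst = max(worst, abs(ana - expm_cdf(params, state, t)))
        assert worst < 1e-9

    def test_symmetric_case_collapses_to_two_components(self):
        # with M1 = M2 and b = 1 the within/between distinction is lumpable
        # and the component at decay rate 1 + M carries zero weight
        for M in (0.3, 0.5, 1.7):
            p = ic.CoalParams(a=1, b=1.0, tau1=0, tau0=1, M1=M, M2=M)
            spec = ic.migration_spectrum(p)
            j = int(np.argmin(np.abs(spec.lam - (1.0 + M))))
            assert np.abs(spec.lam[j] - (1.0 + M)) < 1e-9
            assert np.abs(spec.A[:, j]).max() < 1e-10

    def test_unidirectional_closed_form_state3(self):
        # M1 = 0, M2 = 1: state-3 mixture is (M2/(M2-2), 2/(2-M2), 0)
        p = ic.CoalParams(a=1, b=1.7, tau1=0, tau0=1, M1=0.0, M2=1.0)
        spec = ic.migration_spectrum(p)
        assert spec.regime == "uni_M1_zero"
        np.testing.assert_allclose(spec.A[2], [-1.0, 2.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(spec.lam, [1.0, 0.5, 1.0 / 1.7 + 1.0])
        assert spec.A[2].sum() == pytest.approx(1.0)

    def test_certain_absorption_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        for trial in range(12):
            params = draw_params(rng, REGIMES[trial % 4])
            spec = ic.migration_spectrum(params)
            sums = spec.A.sum(axis=1)
            if params.M1 == 0.0 and params.M2 == 0.0:
                # state 3 cannot coalesce during the migration stage
                np.testing.assert_allclose(sums, [1.0, 1.0, 0.0], atol=1e-9)
            else:
                np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_degenerate_rates_are_perturbed(self):
        # M2 = 2 collides two decay rates of the unidirectional closed form
        p = ic.CoalParams(a=1, b=1.3, tau1=0, tau0=2, M1=0.0, M2=2.0)
        spec = ic.migration_spectrum(p)
        for state in (1, 2, 3):
            for t in (0.3, 1.1, 2.5):
                assert 1.0 - spec.survival(state, t) == pytest.approx(
                    expm_cdf(p, state, t), abs=1e-6
                )


# ---------------------------------------------------------------------------
# Assembled distribution of T(i)
# ---------------------------------------------------------------------------

class TestCoalescenceTime:
    def test_density_normalizes(self, study_params):
        spec = ic.migration_spectrum(study_params)
        for state in (1, 2, 3):
            total = (
                quad(
                    lambda t: ic.density_T(state, t, study_params, spec),
                    0,
                    study_params.tau0,
                    points=[study_params.tau1],
                    limit=200,
                )[0]
                + quad(
                    lambda t: ic.density_T(state, t, study_params, spec),
                    study_params.tau0,
                    np.inf,
                    limit=200,
                )[0]
            )
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_density_matches_expm_derivative(self, study_params):
        # numerical derivative of the full CDF built from the expm oracle
        p = study_params
        spec = ic.migration_spectrum(p)

        def full_cdf(state, t):
            if t <= p.tau1:
                return 1.0 - np.exp(-t / (p.c1 if state == 1 else p.c2)) if state != 3 else 0.0
            surv_iso = (
                np.exp(-p.tau1 / (p.c1 if state == 1 else p.c2)) if state != 3 else 1.0
            )
            if t <= p.tau0:
                return 1.0 - surv_iso * (1.0 - expm_cdf(p, state, t - p.tau1))
            surv_mig = 1.0 - expm_cdf(p, state, p.tau0 - p.tau1)
            return 1.0 - surv_iso * surv_mig * np.exp(-(t - p.tau0) / p.a)

        h = 1e-5
        for state in (1, 2, 3):
            for t in (0.5, 1.5, 3.0):
                num = (full_cdf(state, t + h) - full_cdf(state, t - h)) / (2 * h)
                assert ic.density_T(state, t, p, spec) == pytest.approx(num, abs=1e-8)

    def test_pure_isolation_state3(self):
        # empty migration interval: no coalescence before tau0, Exp(1/a) after
        p = ic.CoalParams(a=0.8, b=1.0, tau1=2.0, tau0=2.0, M1=0.0, M2=0.0)
        spec = ic.migration_spectrum(p)
        assert ic.density_T(3, 1.0, p, spec) == 0.0
        assert ic.density_T(3, 3.0, p, spec) == pytest.approx(
            np.exp(-1.0 / 0.8) / 0.8
        )
        assert ic.mean_T(3, p, spec) == pytest.approx(2.0 + 0.8)

    def test_cdf_continuous_at_stage_boundaries(self):
        rng = np.random.default_rng(5)
        for trial in range(8):
            p = draw_params(rng, REGIMES[trial % 4])
            for state in (1, 2, 3):
                for t in (p.tau1, p.tau0):
                    below = ic.cdf_T(state, max(t - 1e-9, 0.0), p)
                    above = ic.cdf_T(state, t + 1e-9, p)
                    assert abs(above - below) < 1e-7

    def test_survival_basics(self, study_params):
        for state in (1, 2, 3):
            assert ic.survival_T(state, 0.0, study_params) == 1.0
            vals = [ic.survival_T(state, t, study_params) for t in np.linspace(0, 8, 40)]
            assert all(0.0 <= v <= 1.0 for v in vals)
            assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
        with pytest.raises(ParameterError):
            ic.survival_T(1, -0.5, study_params)

    def test_mean_matches_quadrature(self):
        rng = np.random.default_rng(9)
        for trial in range(8):
            p = draw_params(rng, REGIMES[trial % 4])
            spec = ic.migration_spectrum(p)
            for state in (1, 2, 3):
                m_quad = (
                    quad(lambda t: t * ic.density_T(state, t, p, spec), 0,
                         p.tau0, points=[p.tau1], limit=300)[0]
                    + quad(lambda t: t * ic.density_T(state, t, p, spec),
                           p.tau0, np.inf, limit=300)[0]
                )
                assert ic.mean_T(state, p, spec) == pytest.approx(m_quad, rel=1e-7)

    def test_limits_tau1_zero_and_equal(self):
        base = dict(a=1.0, b=1.2, c1=1.5, c2=0.8, M1=0.4, M2=0.6)
        p0 = ic.CoalParams(tau1=0.0, tau0=1.5, **base)
        assert ic.cdf_T(1, 0.0, p0) == 0.0
        p_eps = ic.CoalParams(tau1=1e-9, tau0=1.5, **base)
        assert ic.cdf_T(1, 0.7, p0) == pytest.approx(ic.cdf_T(1, 0.7, p_eps), abs=1e-6)
        p_eq = ic.CoalParams(tau1=1.5, tau0=1.5, **base)
        p_near = ic.CoalParams(tau1=1.5, tau0=1.5 + 1e-9, **base)
        assert ic.cdf_T(3, 2.0, p_eq) == pytest.approx(ic.cdf_T(3, 2.0, p_near), abs=1e-6)
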