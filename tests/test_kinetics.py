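"""Forward tracer-kinetic kernels against independent oracles."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.interpolate import interp1d

from legatos_dce._kinetics import (aath_curve, etm_curve, expconv,
                                   ktrans_from_fp_ps, tcxm_curve)
from legatos_dce.vif import population_aif

TUMOUR = dict(fp=0.514, ps=0.169, vp=0.047, ve=0.519)


def _aif(t):
    return population_aif(t, dose_ml=12.0).cp


def test_expconv_matches_dense_quadrature():
    """Exact piecewise-linear recursion vs brute-force quadrature of the
    same piecewise-linear integrand on a 1000x finer grid."""
    rng = np.random.default_rng(0)
    t = np.cumsum(rng.uniform(0.5, 2.0, 40))  # non-uniform, minutes
    c = np.abs(rng.normal(1.0, 0.5, t.size))
    for k in (0.0, 0.3, 4.0):
        got = expconv(t, c, k)
        tf = np.union1d(np.linspace(t[0], t[-1], 40_000), t)
        cf = np.interp(tf, t, c)
        ref = [np.trapezoid(cf[tf <= ti] * np.exp(-k * (ti - tf[tf <= ti])),
                            tf[tf <= ti]) for ti in t]
        assert np.allclose(got[1:], ref[1:], rtol=2e-4, atol=1e-6)


def test_expconv_zero_rate_is_running_integral():
    t = np.linspace(0, 5, 21)
    c = 2.0 + 0.5 * t
    got = expconv(t, c, 0.0)
    ref = 2.0 * t + 0.25 * t ** 2
    assert np.allclose(got, ref, atol=1e-12)


class TestExtendedTofts:
    def test_no_transfer_is_pure_vascular(self):
        t = np.arange(0.0, 120.0)
        cp = _aif(t)
        assert np.array_equal(etm_curve(0.0, 0.05, 0.3, cp, t), 0.05 * cp)

    def test_equilibrium_limit_constant_input(self):
        """For constant C_p = c and t -> inf, C_t -> (vp + ve) * c."""
        t = np.arange(0.0, 36_000.0, 60.0)
        cp = np.full(t.size, 2.0)
        ct = etm_curve(0.12, 0.05, 0.5, cp, t)
        assert ct[-1] == pytest.approx(0.55 * 2.0, rel=1e-6)

    def test_boxcar_input_matches_closed_form(self):
        """Near-boxcar C_p vs the analytic exponential-convolution formula."""
        kt, vp, ve, c0 = 0.25, 0.04, 0.35, 3.0
        kep = kt / ve
        t1, t2, eps = 1.0, 3.0, 1e-7  # minutes
        t = np.unique(np.concatenate([
            np.linspace(0, 6, 200), [t1, t1 + eps, t2, t2 + eps]]))
        cp = np.where((t >= t1 + eps) & (t <= t2), c0, 0.0)
        cp[t == t1] = 0.0
        ct = etm_curve(kt, vp, ve, cp, t * 60.0)

        def closed(ti):
            if ti <= t1:
                return 0.0
            if ti <= t2:
                return vp * c0 + kt * c0 * (1 - np.exp(-kep * (ti - t1))) / kep
            return kt * c0 * (np.exp(-kep * (ti - t2))
                              - np.exp(-kep * (ti - t1))) / kep

        ref = np.array([closed(ti) for ti in t])
        inner = (t > t1 + 2 * eps) & (np.abs(t - t2) > 2 * eps)
        assert np.allclose(ct[inner], ref[inner], atol=1e-6)

    def test_rejects_negative_parameters(self):
        t = np.arange(0.0, 10.0)
        with pytest.raises(ValueError):
            etm_curve(-0.1, 0.05, 0.3, np.ones(10), t)


class TestTwoCompartmentExchange:
    def test_matches_ode_solver(self):
        """Eigendecomposition solution vs scipy's stiff ODE integration."""
        t = np.arange(0.0, 300.0)
        cp = _aif(t)
        ct = tcxm_curve(cp=cp, t_s=t, **TUMOUR)
        cpf = interp1d(t / 60.0, cp, bounds_error=False,
                       fill_value=(0.0, cp[-1]))
        fp, ps, vp, ve = TUMOUR.values()

        def rhs(tt, x):
            return [(fp * (cpf(tt) - x[0]) + ps * (x[1] - x[0])) / vp,
                    ps * (x[0] - x[1]) / ve]

        sol = solve_ivp(rhs, (0, t[-1] / 60), [0, 0], t_eval=t / 60,
                        rtol=1e-10, atol=1e-12, max_step=0.5 / 60)
        ref = vp * sol.y[0] + ve * sol.y[1]
        assert np.allclose(ct, ref, atol=1e-7)

    def test_no_extraction_infinite_flow_is_vp_cp(self):
        t = np.arange(0.0, 120.0)
        cp = _aif(t)
        assert np.array_equal(tcxm_curve(np.inf, 0.0, 0.05, 0.0, cp, t),
                              0.05 * cp)

    def test_no_extraction_finite_flow_is_plasma_impulse_convolution(self):
        """PS = 0, ve = 0: single plasma compartment Fp * conv(Cp, e^-Fp/vp)."""
        t = np.arange(0.0, 200.0)
        cp = _aif(t)
        got = tcxm_curve(0.5, 0.0, 0.05, 0.0, cp, t)
        ref = 0.5 * expconv(t / 60.0, cp, 0.5 / 0.05)
        assert np.allclose(got, ref, atol=1e-12)

    def test_fast_exchange_limit_reduces_to_etm(self):
        """Fp = inf: exactly the extended Tofts curve with Ktrans = PS."""
        t = np.arange(0.0, 300.0)
        cp = _aif(t)
        got = tcxm_curve(np.inf, 0.12, 0.05, 0.4, cp, t)
        assert np.allclose(got, etm_curve(0.12, 0.05, 0.4, cp, t), atol=1e-14)

    def test_permeability_limited_nesting(self, aif300):
        """With PS << Fp the ETM fit of a 2CXM curve recovers Ktrans
        (= Fp*PS/(Fp+PS) ~ PS) within 2%."""
        from legatos_dce.containers import ImageSeries
        from legatos_dce.etm import ExtendedToftsModel

        t = np.arange(0.0, 600.0)
        vif = population_aif(t, dose_ml=12.0)
        fp, ps = 2.0, 0.02
        ct = tcxm_curve(fp, ps, 0.04, 0.5, vif.cp, t)
        series = ImageSeries(ct.reshape(1, 1, 1, -1), t, (1, 1, 1))
        res = ExtendedToftsModel(series, vif).fit()
        kt = res.ktrans[0, 0, 0]
        # permeability-limited: Ktrans within 2% of PS, and within 5% of the
        # exact flow-permeability composition
        assert kt == pytest.approx(ps, rel=0.02)
        assert kt == pytest.approx(ktrans_from_fp_ps(fp, ps), rel=0.05)

    def test_vp_ve_simplex_enforced(self):
        with pytest.raises(ValueError):
            tcxm_curve(0.5, 0.1, 0.7, 0.5, np.ones(5), np.arange(5.0))


class TestPlugFlowAath:
    def test_early_times_retain_all_delivered_tracer(self):
        """Before one capillary transit the tissue curve is exactly
        Fp * int C_p — the microsphere premise."""
        t = np.arange(0.0, 300.0)
        cp = _aif(t)
        fp, vp = 0.514, 0.047
        ct = aath_curve(fp, 0.169, vp, 0.519, cp, t)
        tc_s = vp / fp * 60.0
        integral = np.concatenate([[0], np.cumsum(
            0.5 * (cp[1:] + cp[:-1]) * np.diff(t / 60.0))])
        arrival = 20.0
        early = t <= arrival + tc_s
        assert np.allclose(ct[early], fp * integral[early], rtol=1e-9,
                           atol=1e-12)

    def test_fast_exchange_limit_reduces_to_etm(self):
        t = np.arange(0.0, 200.0)
        cp = _aif(t)
        assert np.allclose(aath_curve(np.inf, 0.1, 0.05, 0.4, cp, t),
                           etm_curve(0.1, 0.05, 0.4, cp, t), atol=1e-14)


def test_ktrans_from_fp_ps_limits():
    assert ktrans_from_fp_ps(0.514, 0.169) == pytest.approx(
        0.514 * 0.169 / (0.514 + 0.169))
    assert ktrans_from_fp_ps(np.inf, 0.2) == 0.2
    assert ktrans_from_fp_ps(0.0, 0.0) == 0.0
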