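import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from diazodiel.errors import (
    DegenerateYieldsError,
    InsufficientDataError,
    InvalidMeasurementError,
)
from diazodiel.frr_etr import (
    EtrContext,
    FrrfYieldSet,
    PECurveFit,
    etr_from_yields,
    fit_pe_curve,
    integrate_diel,
)
from diazodiel.light import DielLightProfile

CTX = EtrContext(chl=100.0)


class TestEtrFromYields:
    def test_hand_arithmetic_oracle(self):
        # (0.5·0.2/0.3)·(0.15/0.45)·100·11800/100/3600
        y = FrrfYieldSet(F0=0.2, Fm=0.5, Fp=0.3, Fmp=0.45, E=100.0)
        assert etr_from_yields(y, CTX) == pytest.approx(0.3642, abs=5e-5)

    def test_zero_photochemical_yield_gives_zero(self):
        y = FrrfYieldSet(F0=0.2, Fm=0.5, Fp=0.45, Fmp=0.45, E=500.0)
        assert etr_from_yields(y, CTX) == 0.0

    def test_darkness_gives_zero(self):
        y = FrrfYieldSet(F0=0.2, Fm=0.5, Fp=0.3, Fmp=0.45, E=0.0)
        assert etr_from_yields(y, CTX) == 0.0

    def test_degenerate_yields_rejected(self):
        with pytest.raises(DegenerateYieldsError):
            FrrfYieldSet(F0=0.5, Fm=0.5, Fp=0.3, Fmp=0.45, E=100.0)

    def test_fp_above_fmp_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            FrrfYieldSet(F0=0.2, Fm=0.5, Fp=0.5, Fmp=0.45, E=100.0)

    @given(
        e=st.floats(1.0, 2000.0),
        scale=st.floats(1.1, 10.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_linear_in_e_and_ka_inverse_in_chl(self, e, scale):
        y1 = FrrfYieldSet(F0=0.2, Fm=0.5, Fp=0.3, Fmp=0.45, E=e)
        y2 = FrrfYieldSet(F0=0.2, Fm=0.5, Fp=0.3, Fmp=0.45, E=e * scale)
        base = etr_from_yields(y1, CTX)
        assert etr_from_yields(y2, CTX) == pytest.approx(base * scale, rel=1e-12)
        ctx_ka = EtrContext(chl=CTX.chl, ka=CTX.ka * scale)
        assert etr_from_yields(y1, ctx_ka) == pytest.approx(base * scale, rel=1e-12)
        ctx_chl = EtrContext(chl=CTX.chl * scale, ka=CTX.ka)
        assert etr_from_yields(y1, ctx_chl) == pytest.approx(base / scale, rel=1e-12)

    def test_time_factor_flip(self):
        y = FrrfYieldSet(F0=0.2, Fm=0.5, Fp=0.3, Fmp=0.45, E=100.0)
        div = etr_from_yields(y, EtrContext(chl=100.0, time_factor="divide"))
        mul = etr_from_yields(y, EtrContext(chl=100.0, time_factor="multiply"))
        assert mul == pytest.approx(div * 3600.0**2, rel=1e-12)


def _model_points(a, b, c, e_levels):
    e = np.asarray(e_levels, dtype=float)
    p = np.where(e > 0, e / (a * e**2 + b * e + c), 0.0)
    return list(zip(e, p))


class TestFitPeCurve:
    E11 = np.linspace(0.0, 1500.0, 11)

    def test_recovers_generating_coefficients(self):
        a, b, c = 1e-6, 2e-3, 0.5
        fit = fit_pe_curve(_model_points(a, b, c, self.E11))
        assert fit.a == pytest.approx(a, rel=1e-6)
        assert fit.b == pytest.approx(b, rel=1e-6)
        assert fit.c == pytest.approx(c, rel=1e-6)

    def test_order_invariance(self):
        pts = _model_points(1e-6, 2e-3, 0.5, self.E11)
        f1 = fit_pe_curve(pts)
        f2 = fit_pe_curve(list(reversed(pts)))
        assert f1.alpha == pytest.approx(f2.alpha, rel=1e-10)
        assert f1.pmax == pytest.approx(f2.pmax, rel=1e-10)

    def test_scale_equivariance(self):
        pts = _model_points(1e-6, 2e-3, 0.5, self.E11)
        doubled = [(e, 2 * p) for e, p in pts]
        f1, f2 = fit_pe_curve(pts), fit_pe_curve(doubled)
        assert f2.alpha == pytest.approx(2 * f1.alpha, rel=1e-6)
        assert f2.pmax == pytest.approx(2 * f1.pmax, rel=1e-6)
        assert f2.ek == pytest.approx(f1.ek, rel=1e-6)

    def test_initial_slope_limit(self):
        fit = fit_pe_curve(_model_points(1e-6, 2e-3, 0.5, self.E11))
        e_low = fit.ek / 100.0
        assert fit(e_low) == pytest.approx(fit.alpha * e_low, rel=1e-2)
        e_lower = fit.ek / 1000.0
        assert fit(e_lower) == pytest.approx(fit.alpha * e_lower, rel=1e-3)

    def test_refit_on_own_curve_is_idempotent(self):
        fit = fit_pe_curve(_model_points(1e-6, 2e-3, 0.5, self.E11))
        refit = fit_pe_curve([(e, fit(e)) if e > 0 else (e, 0.0) for e in self.E11])
        assert refit.alpha == pytest.approx(fit.alpha, rel=1e-8)
        assert refit.pmax == pytest.approx(fit.pmax, rel=1e-8)
        assert refit.ek == pytest.approx(fit.ek, rel=1e-8)

    def test_ek_identity(self):
        fit = fit_pe_curve(_model_points(1e-6, 2e-3, 0.5, self.E11))
        assert fit.ek == fit.pmax / fit.alpha  # exact by construction

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_pe_curve([(0.0, 0.0), (100.0, 1.0), (200.0, 1.5)])

    def test_all_zero_responses_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_pe_curve([(e, 0.0) for e in (0.0, 100.0, 200.0, 400.0)])

    def test_no_photoinhibition_gives_infinite_eopt(self):
        fit = PECurveFit.from_photo_params(alpha=0.01, pmax=2.0)
        assert math.isinf(fit.eopt)
        assert fit.pmax == pytest.approx(2.0)
        # far above Ek the response approaches Pmax from below
        assert fit(1e7) == pytest.approx(2.0, rel=1e-3)


class TestIntegrateDiel:
    profile = DielLightProfile(e_max=400.0)

    def test_linear_response_closed_form(self):
        """Under a half-sine of peak E_max, ∫α·E dt = α·E_max·24/π."""
        alpha = 3e-3
        linear = PECurveFit(a=0.0, b=0.0, c=1.0 / alpha)
        got = integrate_diel(linear, self.profile, "light", dt=0.01)
        assert got == pytest.approx(alpha * 400.0 * 24.0 / math.pi, rel=1e-4)

    def test_dark_phase_integrates_to_zero(self):
        fit = PECurveFit.from_photo_params(alpha=0.01, pmax=2.0, eopt=1000.0)
        assert integrate_diel(fit, self.profile, "dark") == 0.0

    def test_convergence_under_step_halving(self):
        fit = PECurveFit.from_photo_params(alpha=0.01, pmax=2.0, eopt=1000.0)
        coarse = integrate_diel(fit, self.profile, "light", dt=0.1)
        fine = integrate_diel(fit, self.profile, "light", dt=0.05)
        assert abs(fine - coarse) / abs(fine) < 1e-4

    def test_oversized_step_rejected(self):
        fit = PECurveFit.from_photo_params(alpha=0.01, pmax=2.0)
        with pytest.raises(Exception):
            integrate_diel(fit, self.profile, "light", dt=0.5)
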