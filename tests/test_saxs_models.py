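import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad
from scipy.special import j1

from fibrilscatter.exceptions import (InsufficientDataError, NotRodlikeError)
from fibrilscatter.saxs_models import (FibrilModel, ellipse_rcs,
                                       elliptical_cylinder_intensity,
                                       elliptical_cylinder_pq,
                                       fit_form_factor, guinier_rod_fit,
                                       sheet_count, width_from_rcs,
                                       width_from_sheets)
from fibrilscatter.scatter_io import ScatteringCurve


def circular_cylinder_pq_oracle(q, radius, length):
    """Independent closed-form circular-cylinder form factor: adaptive
    quadrature of the [2 J1(qR sin a)/(qR sin a) * sinc(qL cos a / 2)]^2
    orientational average."""

    def integrand(alpha):
        s, c = math.sin(alpha), math.cos(alpha)
        x = q * radius * s
        amp = 2.0 * j1(x) / x if x > 1e-10 else 1.0
        y = 0.5 * q * length * c
        sc = math.sin(y) / y if abs(y) > 1e-10 else 1.0
        return (amp * sc) ** 2 * s

    val, _ = quad(integrand, 0.0, math.pi / 2, limit=800)
    return val


def debye_mc_pq_oracle(q_values, a, b, length, n_pairs=100_000, seed=42):
    """Brute-force Monte Carlo Debye form factor: the orientational average
    equals E[sinc(q |r1 - r2|)] over independent uniform points in the
    cylinder."""
    rng = np.random.default_rng(seed)

    def sample(n):
        # uniform in the elliptical cross section via the unit disc
        phi = rng.uniform(0.0, 2.0 * math.pi, n)
        rad = np.sqrt(rng.uniform(0.0, 1.0, n))
        return np.column_stack([a * rad * np.cos(phi),
                                b * rad * np.sin(phi),
                                rng.uniform(0.0, length, n)])

    d = np.linalg.norm(sample(n_pairs) - sample(n_pairs), axis=1)
    qd = np.outer(q_values, d)
    return np.mean(np.sinc(qd / math.pi), axis=1)


class TestEllipticalCylinderFormFactor:
    def test_matches_circular_closed_form(self):
        radius, length = 2.5, 60.0
        q = np.geomspace(0.02, 3.0, 20)
        ours = elliptical_cylinder_pq(q, radius, radius, length)
        oracle = np.array([circular_cylinder_pq_oracle(qi, radius, length)
                           for qi in q])
        np.testing.assert_allclose(ours, oracle, rtol=1e-3 * 0.999)
        assert np.max(np.abs(ours / oracle - 1)) < 1e-3  # <= 0.1%

    def test_matches_monte_carlo_debye_sum(self):
        # compared where P(q) is large enough that the 10^5-pair Monte
        # Carlo standard error stays well below the 2% target
        a, b, length = 1.5, 3.0, 20.0
        q = np.geomspace(0.05, 1.0, 12)
        ours = elliptical_cylinder_pq(q, a, b, length)
        oracle = debye_mc_pq_oracle(q, a, b, length)
        assert np.max(np.abs(ours / oracle - 1)) < 0.02

    def test_forward_limit_is_normalized(self):
        p0 = elliptical_cylinder_pq(np.array([1e-5]), 1.6, 3.0, 300.0)
        assert p0[0] == pytest.approx(1.0, abs=1e-4)

    def test_absolute_intensity_normalization(self):
        model = FibrilModel(a=1.6, b=3.0, length=300.0, contrast=0.85,
                            volume_fraction=0.006, background=0.01)
        i0 = elliptical_cylinder_intensity(model, np.array([1e-5]))[0]
        expected = 0.006 * 0.85 ** 2 * model.volume + 0.01
        assert i0 == pytest.approx(expected, rel=1e-4)

    def test_rod_regime_iq_plateau(self):
        q = np.linspace(0.05, 0.2, 15)
        pq = elliptical_cylinder_pq(q, 2.0, 4.0, 400.0)
        iq = pq * q
        assert np.max(iq) / np.min(iq) < 1.10 / 0.90

    def test_bounded_and_decreasing_at_low_q(self):
        q = np.geomspace(0.01, 0.3, 40)
        pq = elliptical_cylinder_pq(q, 1.6, 3.0, 100.0)
        assert np.all(pq > 0) and np.all(pq <= 1.0 + 1e-12)
        assert np.all(np.diff(pq) < 0)

    def test_low_q_guinier_expansion(self):
        a, b, length = 1.5, 3.0, 20.0
        rg2 = (a * a + b * b) / 4.0 + length ** 2 / 12.0
        q = np.linspace(0.02, 0.5 / math.sqrt(rg2), 10)
        pq = elliptical_cylinder_pq(q, a, b, length)
        np.testing.assert_allclose(pq, np.exp(-q ** 2 * rg2 / 3.0),
                                   rtol=0.01)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            elliptical_cylinder_pq(np.array([-0.1]), 1.0, 2.0, 50.0)
        with pytest.raises(ValueError):
            elliptical_cylinder_pq(np.array([0.1]), 3.0, 2.0, 50.0)


class TestFibrilModel:
    def test_invariants(self):
        with pytest.raises(ValueError):
            FibrilModel(a=3.0, b=2.0, length=100.0)
        with pytest.raises(ValueError):
            FibrilModel(a=1.0, b=2.0, length=3.0)
        with pytest.raises(ValueError):
            FibrilModel(a=1.0, b=2.0, length=100.0, volume_fraction=0.5)

    def test_derived_geometry(self):
        m = FibrilModel(a=2.0, b=3.0, length=100.0)
        assert m.volume == pytest.approx(math.pi * 600.0)
        assert m.rcs == pytest.approx(math.sqrt(13.0) / 2.0)


class TestFormFactorFit:
    def test_noise_free_self_consistency(self, water_preset):
        from fibrilscatter.synthetic_data import simulate_saxs
        truth = water_preset.model
        curve = simulate_saxs(water_preset, noise=False)
        init = replace(truth, a=truth.a * 1.3, b=truth.b * 0.7)
        fit = fit_form_factor(curve, init)
        assert fit.model.a == pytest.approx(truth.a, rel=5e-3)
        assert fit.model.b == pytest.approx(truth.b, rel=5e-3)
        assert not fit.at_bound

    def test_noisy_recovery_within_five_percent(self, water_preset,
                                                noisy_water_fit):
        truth = water_preset.model
        fit = noisy_water_fit
        assert fit.model.a == pytest.approx(truth.a, rel=0.05)
        assert fit.model.b == pytest.approx(truth.b, rel=0.05)
        assert 0.3 < fit.redchi < 3.0

    def test_correlation_peak_degrades_full_range_fit(self, meoh_preset):
        """Fitting a semidilute curve over the full q range is materially
        worse than fitting above the correlation peak — the reason the
        dilute-regime curves are the ones interpreted as form factors."""
        from fibrilscatter.synthetic_data import simulate_saxs
        from fibrilscatter.structure_factor import mesh_size
        curve = simulate_saxs(meoh_preset, seed=11)
        truth = meoh_preset.model
        init = replace(truth, a=truth.a * 1.1, b=truth.b * 0.9)
        q_peak = 2 * math.pi / mesh_size(2 * truth.b, truth.volume_fraction)
        full = fit_form_factor(curve, init)
        high = fit_form_factor(curve.restrict(qmin=2 * q_peak), init)
        assert full.redchi > 3.0 * high.redchi

    def test_insufficient_points_rejected(self):
        q = np.linspace(0.1, 0.2, 5)
        curve = ScatteringCurve(q, np.ones(5))
        with pytest.raises(InsufficientDataError):
            fit_form_factor(curve, FibrilModel(a=1.0, b=2.0, length=50.0))


class TestGuinierRodFit:
    def test_exact_synthetic_inversion(self):
        q = np.linspace(0.3, 0.9, 60)
        intensity = np.exp(5.0 - q ** 2 * 1.8 ** 2 / 2.0) / q
        fit = guinier_rod_fit(ScatteringCurve(q, intensity))
        assert fit.rcs == pytest.approx(1.8, rel=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_elliptical_cylinder_consistency(self):
        q = np.geomspace(0.05, 3.2, 400)
        model = FibrilModel(a=2.0, b=3.0, length=1000.0, contrast=0.85,
                            volume_fraction=0.006)
        curve = ScatteringCurve(q, elliptical_cylinder_intensity(model, q))
        fit = guinier_rod_fit(curve)
        assert fit.rcs == pytest.approx(math.sqrt(13.0) / 2.0, rel=0.02)
        assert fit.q_window[1] * fit.rcs <= 1.3

    def test_flat_curve_not_rodlike(self):
        q = np.linspace(0.3, 1.0, 50)
        with pytest.raises(NotRodlikeError):
            guinier_rod_fit(ScatteringCurve(q, np.ones(50)))

    def test_explicit_window_too_sparse(self):
        q = np.linspace(0.3, 0.9, 60)
        intensity = np.exp(-q ** 2) / q
        with pytest.raises(InsufficientDataError):
            guinier_rod_fit(ScatteringCurve(q, intensity),
                            q_window=(0.875, 0.9))


class TestLaminationGeometry:
    def test_circular_limit_is_disc_rg(self):
        assert ellipse_rcs(2.0, 2.0) == pytest.approx(2.0 / math.sqrt(2.0))

    def test_direct_value(self):
        assert ellipse_rcs(2.0, 3.0) == pytest.approx(math.sqrt(13.0) / 2.0)

    def test_thin_lamella_limit(self):
        assert ellipse_rcs(1e-4, 3.0) == pytest.approx(1.5, rel=1e-6)

    @given(st.floats(min_value=0.1, max_value=50.0),
           st.floats(min_value=0.1, max_value=50.0),
           st.floats(min_value=0.1, max_value=1.0))
    def test_symmetric_and_monotone(self, a, b, shrink):
        assert ellipse_rcs(a, b) == ellipse_rcs(b, a)
        assert ellipse_rcs(a * shrink, b) <= ellipse_rcs(a, b)

    def test_nine_sheets_from_fibril_width(self):
        # 4.86 nm wide ribbon at 0.54 nm sheet spacing
        assert sheet_count(4.86) == pytest.approx(9.0)
        assert width_from_sheets(10.0) == pytest.approx(5.4)

    def test_width_from_rcs_inverts_ellipse_rcs(self):
        rcs = ellipse_rcs(1.6, 3.0)
        assert width_from_rcs(rcs, thickness_2a=3.2) == pytest.approx(6.0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            ellipse_rcs(-1.0, 2.0)
        with pytest.raises(ValueError):
            sheet_count(0.0)
        with pytest.raises(ValueError):
            width_from_rcs(0.5, thickness_2a=3.9)
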