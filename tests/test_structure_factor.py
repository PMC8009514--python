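import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fibrilscatter.exceptions import InsufficientDataError
from fibrilscatter.scatter_io import ScatteringCurve
from fibrilscatter.structure_factor import (EffectiveStructureFactor,
                                            correlation_length,
                                            effective_structure_factor,
                                            extrapolate_seff0, locate_peak,
                                            mesh_size)


def _rodlike_intensity(q):
    return 5.0 / q * np.exp(-q ** 2 * 0.8)


class TestEffectiveStructureFactor:
    def test_identical_curves_give_unity(self):
        q = np.geomspace(0.03, 2.0, 200)
        c = ScatteringCurve(q, _rodlike_intensity(q))
        sf = effective_structure_factor(c, c, conc_ratio=1.0)
        np.testing.assert_allclose(sf.s_eff, 1.0, atol=1e-10)

    def test_constructed_structure_factor_recovered(self):
        q = np.geomspace(0.03, 2.0, 300)
        s_true = 1.0 - 0.7 * np.exp(-(q / 0.15) ** 2) \
            + 0.25 * np.exp(-0.5 * ((q - 0.2) / 0.06) ** 2)
        i_dil = _rodlike_intensity(q)
        conc = ScatteringCurve(q, 8.0 * i_dil * s_true)
        dil = ScatteringCurve(q, i_dil)
        sf = effective_structure_factor(conc, dil, conc_ratio=8.0)
        np.testing.assert_allclose(sf.s_eff, np.interp(sf.q, q, s_true),
                                   rtol=0.01)

    def test_high_q_tail_near_unity_on_semidilute_synthetic(self):
        """In the 0.635-1.227 nm^-1 range concentration curves superimpose:
        S_eff is 1 within the noise there."""
        from fibrilscatter.synthetic_data import get_preset, simulate_saxs
        preset = get_preset("A10K-MeOH")
        dilute = preset.with_concentration(0.125)
        sf = effective_structure_factor(
            simulate_saxs(preset, seed=1), simulate_saxs(dilute, seed=2),
            conc_ratio=preset.model.volume_fraction
            / dilute.model.volume_fraction,
            background_concentrated=preset.model.background,
            background_dilute=preset.model.background)
        tail = (sf.q >= 0.635) & (sf.q <= 1.227)
        assert np.median(sf.s_eff[tail]) == pytest.approx(1.0, abs=0.05)

    def test_insufficient_overlap_rejected(self):
        q1 = np.geomspace(0.03, 2.0, 100)
        q2 = np.geomspace(1.5, 2.0, 100)
        with pytest.raises(InsufficientDataError):
            effective_structure_factor(
                ScatteringCurve(q1, _rodlike_intensity(q1)),
                ScatteringCurve(q2, _rodlike_intensity(q2)), 1.0)

    def test_nonpositive_dilute_points_masked_with_warning(self):
        q = np.geomspace(0.03, 2.0, 100)
        i_dil = _rodlike_intensity(q)
        i_dil[50] = -1e-6
        with pytest.warns(UserWarning, match="masked"):
            sf = effective_structure_factor(
                ScatteringCurve(q, i_dil), ScatteringCurve(q, i_dil), 1.0)
        assert np.all(np.isfinite(sf.s_eff))


class TestLocatePeak:
    def _flat_with_bump(self, center=0.2, n=200, amp=0.5):
        q = np.linspace(0.02, 1.0, n)
        s = 1.0 + amp * np.exp(-0.5 * ((q - center) / 0.05) ** 2)
        return EffectiveStructureFactor(q, s, concentration=1.0)

    def test_gaussian_bump_located(self):
        q_peak = locate_peak(self._flat_with_bump(0.2))
        assert q_peak == pytest.approx(0.2, abs=0.002)

    def test_monotone_trace_has_no_peak(self):
        q = np.linspace(0.02, 1.0, 150)
        sf = EffectiveStructureFactor(q, 1.0 / (1.0 + q), concentration=1.0)
        assert locate_peak(sf) is None

    def test_equal_maxima_tie_breaks_to_lower_q(self):
        q = np.linspace(0.02, 1.0, 400)
        s = (1.0 + 0.5 * np.exp(-0.5 * ((q - 0.2) / 0.05) ** 2)
             + 0.5 * np.exp(-0.5 * ((q - 0.7) / 0.05) ** 2))
        sf = EffectiveStructureFactor(q, s, concentration=1.0)
        assert locate_peak(sf) == pytest.approx(0.2, abs=0.005)

    def test_q_max_restricts_search(self):
        sf = self._flat_with_bump(0.7)
        assert locate_peak(sf, q_max=0.5) is None
        assert locate_peak(sf) == pytest.approx(0.7, abs=0.005)

    def test_noise_level_peaks_rejected(self):
        rng = np.random.default_rng(3)
        q = np.linspace(0.02, 1.0, 200)
        s = 1.0 + 0.03 * rng.standard_normal(200)
        sf = EffectiveStructureFactor(q, s, concentration=1.0,
                                      s_err=np.full(200, 0.03))
        assert locate_peak(sf) is None


class TestCorrelationLength:
    def test_direct_values(self):
        assert correlation_length(0.2) == pytest.approx(31.4159, rel=1e-4)
        assert correlation_length(2.0 * math.pi) == pytest.approx(1.0)

    @given(st.floats(min_value=1e-3, max_value=10.0),
           st.floats(min_value=1.01, max_value=5.0))
    def test_monotone_decreasing(self, q_peak, factor):
        assert correlation_length(q_peak * factor) < correlation_length(
            q_peak)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            correlation_length(0.0)


class TestMeshSize:
    def test_phi_scaling_law(self):
        # quadrupling the volume fraction halves the mesh size
        assert mesh_size(5.0, 0.024) == pytest.approx(
            mesh_size(5.0, 0.006) / 2.0)

    def test_linear_in_diameter(self):
        assert mesh_size(10.0, 0.01) == pytest.approx(
            2.0 * mesh_size(5.0, 0.01))

    def test_frozen_reference_value(self):
        # d = 5 nm, phi = 0.006: the regression constant of the formula
        assert mesh_size(5.0, 0.006) == pytest.approx(57.2056, rel=1e-4)

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            mesh_size(-1.0, 0.01)
        with pytest.raises(ValueError):
            mesh_size(5.0, 1.5)


class TestSeffZeroExtrapolation:
    def test_unity_trace(self):
        q = np.linspace(0.02, 1.0, 100)
        sf = EffectiveStructureFactor(q, np.ones(100), concentration=1.0)
        s0, err = extrapolate_seff0(sf)
        assert s0 == pytest.approx(1.0, abs=1e-10)

    def test_constructed_repulsive_s0(self):
        q = np.linspace(0.02, 1.0, 300)
        s = 1.0 - 0.7 * np.exp(-(q / 0.4) ** 2)   # S(0) = 0.3
        sf = EffectiveStructureFactor(q, s, concentration=1.0, q_peak=0.4)
        s0, err = extrapolate_seff0(sf)
        assert s0 == pytest.approx(0.30, abs=0.02)

    def test_insufficient_low_q_rejected(self):
        q = np.linspace(0.5, 1.0, 50)
        sf = EffectiveStructureFactor(q, np.ones(50), concentration=1.0,
                                      q_peak=0.2)
        with pytest.raises(InsufficientDataError):
            extrapolate_seff0(sf)


class TestSemidiluteSeries:
    def test_xi_and_s0_decrease_with_concentration(self):
        """Repulsive fibril networks compress on concentration: both the
        correlation length and the osmotic-compressibility proxy S_eff(0)
        fall as the suspension is concentrated."""
        from fibrilscatter.synthetic_data import get_preset, simulate_saxs
        preset = get_preset("A10K-MeOH")
        dilute = preset.with_concentration(0.125)
        ref = simulate_saxs(dilute, noise=False)
        xis, s0s = [], []
        for wt in (0.25, 0.5, 1.0):
            pc = preset.with_concentration(wt)
            sf = effective_structure_factor(
                simulate_saxs(pc, noise=False), ref,
                conc_ratio=pc.model.volume_fraction
                / dilute.model.volume_fraction,
                background_concentrated=pc.model.background,
                background_dilute=pc.model.background)
            q_peak = locate_peak(sf)
            assert q_peak is not None
            sf.q_peak = q_peak
            xis.append(correlation_length(q_peak))
            s0s.append(extrapolate_seff0(sf)[0])
        assert xis[0] > xis[1] > xis[2]
        assert s0s[0] > s0s[1] > s0s[2]

    def test_dilute_aqueous_sample_is_structureless(self):
        """S_eff of a dilute (aqueous) sample is 1 within a few percent
        over the full range and shows no correlation peak."""
        from fibrilscatter.synthetic_data import get_preset, simulate_saxs
        preset = get_preset("A8K-water")
        dilute = preset.with_concentration(0.125)
        sf = effective_structure_factor(
            simulate_saxs(preset, noise=False),
            simulate_saxs(dilute, noise=False),
            conc_ratio=preset.model.volume_fraction
            / dilute.model.volume_fraction,
            background_concentrated=preset.model.background,
            background_dilute=preset.model.background)
        np.testing.assert_allclose(sf.s_eff, 1.0, atol=0.03)
        assert locate_peak(sf) is None
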