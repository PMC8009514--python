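"""Synthetic instrument emulation for every analysis stage.

The generators stand in for the SAXS/WAXS camera, the DLS correlator and
the dilution-series count rates, producing data with the statistical
structure the analysis assumes: elliptical-cylinder scattering with
counting noise, a low-q correlation peak in the semidilute (nonaqueous)
scenarios, Z-average rod diffusion in g2(tau), Bragg peaks riding on a
broad solvent hump, and a solubility break in intensity-vs-concentration
series.  All generators are pure functions of (preset, seed).

Scenario presets encode the study conditions: the two peptides (A8K and
A10K, thickness 2a = extended monomer length 3.2 / 3.9 nm) in water,
methanol and DMF at a nominal 1 wt% (volume fraction ~0.006 in the
nonaqueous solvents), fibril cross-section diameter ~6 nm, Z-average
lengths 200 / 800 / 1000 nm in water / MeOH / DMF, solvent viscosities
0.891 / 0.485 / 0.802 cP and densities 0.997 / 0.786 / 0.948 g/cm^3 at
25 C.  The nonaqueous cross sections are set slightly narrower than in
water (the lamination number drops to ~80-90%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .dls import BroersmaInputs, broersma_diffusion
from .saxs_models import FibrilModel, elliptical_cylinder_pq
from .scatter_io import (CorrelationTrace, DilutionSeries, SampleSpec,
                         ScatteringCurve)
from .structure_factor import mesh_size
from .solution_props import volume_fraction

__all__ = ["ScenarioPreset", "PRESETS", "get_preset", "simulate_saxs",
           "simulate_dls", "simulate_waxs", "simulate_dilution",
           "SOLVENTS", "PEPTIDES"]

#: solvent physical parameters at 25 C: density [g/cm^3], viscosity [cP],
#: refractive index at 633 nm, WAXS hump center [nm^-1]
SOLVENTS = {
    "water": dict(density=0.997, viscosity=0.891, refractive_index=1.331,
                  waxs_hump_center=20.0),
    "MeOH": dict(density=0.786, viscosity=0.485, refractive_index=1.326,
                 waxs_hump_center=16.0),
    "DMF": dict(density=0.948, viscosity=0.802, refractive_index=1.427,
                waxs_hump_center=13.0),
}

#: peptide parameters: molecular weight [g/mol] (counterion excluded),
#: residue count, density [g/cm^3], extended monomer length [nm]
PEPTIDES = {
    "A8K": dict(molecular_weight=715.0, n_residues=9, density=1.50,
                extended_length=3.2),
    "A10K": dict(molecular_weight=857.0, n_residues=11, density=1.26,
                 extended_length=3.9),
}

#: Z-average fibril length per solvent [nm]
_LENGTHS = {"water": 200.0, "MeOH": 800.0, "DMF": 1000.0}
#: cross-section major semiaxis [nm]: slightly narrower in the nonaqueous
#: solvents (fewer laminated sheets)
_B_SEMIAXIS = {"water": 3.0, "MeOH": 2.55, "DMF": 2.65}


@dataclass
class ScenarioPreset:
    """One peptide/solvent study condition, driving all four generators."""

    name: str
    model: FibrilModel
    sample: SampleSpec
    semidilute: bool
    length_median: float           # nm, of the rod-length distribution
    length_sigma_g: float = 1.5    # geometric SD; 1.0 = monodisperse
    dls_diameter: float = 6.0      # nm, hydrodynamic cross-section diameter
    beta: float = 0.98             # DLS coherence factor
    noise_floor: float = 0.02      # fractional SAXS noise floor
    counting_scale: float = 2e-3   # sqrt(I) counting-noise coefficient

    def with_concentration(self, wt_percent: float) -> "ScenarioPreset":
        """Same scenario at a different concentration (phi rescaled)."""
        sample = self.sample.with_concentration(wt_percent)
        model = replace(self.model, volume_fraction=volume_fraction(sample))
        return replace(self, sample=sample, model=model)


def _make_preset(peptide: str, solvent: str) -> ScenarioPreset:
    pep = PEPTIDES[peptide]
    sol = SOLVENTS[solvent]
    sample = SampleSpec(
        peptide_name=peptide, n_residues=pep["n_residues"],
        molecular_weight=pep["molecular_weight"],
        peptide_density=pep["density"],
        extended_length=pep["extended_length"],
        solvent_name=solvent, solvent_density=sol["density"],
        solvent_viscosity=sol["viscosity"],
        refractive_index=sol["refractive_index"],
        concentration_wt_percent=1.0)
    length = _LENGTHS[solvent]
    model = FibrilModel(
        a=pep["extended_length"] / 2.0, b=_B_SEMIAXIS[solvent],
        length=length, contrast=0.85,
        volume_fraction=volume_fraction(sample), background=2e-3)
    return ScenarioPreset(
        name=f"{peptide}-{solvent}", model=model, sample=sample,
        semidilute=solvent != "water", length_median=length)


PRESETS = {f"{p}-{s}": _make_preset(p, s)
           for p in PEPTIDES for s in SOLVENTS}


def get_preset(name: str) -> ScenarioPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; "
                       f"choose from {sorted(PRESETS)}") from None


# --------------------------------------------------------------------------
# SAXS
# --------------------------------------------------------------------------

def _empirical_structure_factor(q: np.ndarray, preset: ScenarioPreset,
                                ) -> np.ndarray:
    """Broad-peak semidilute structure factor.

    Peaked near 2 pi / xi with xi the geometric mesh size of the network;
    depressed at q -> 0 (repulsive interactions lower the osmotic
    compressibility, the more so the higher the concentration); -> 1 at
    high q where only intraparticle structure survives.
    """
    phi = preset.model.volume_fraction
    xi = mesh_size(2.0 * preset.model.b, phi)
    q_peak = 2.0 * math.pi / xi
    width = 0.35 * q_peak
    # overlap factor: deviations from S=1 fade out on dilution below the
    # overlap volume fraction, where the suspension re-enters the dilute
    # (pure form factor) regime
    overlap = float(np.clip(phi / 0.006, 0.0, 1.0))
    peak = 0.30 * np.exp(-0.5 * ((q - q_peak) / width) ** 2)
    depression = 0.80 * np.exp(-(q / (0.6 * q_peak)) ** 2)
    return 1.0 + overlap * (peak - depression)


def simulate_saxs(preset: ScenarioPreset,
                  q_grid: Optional[np.ndarray] = None,
                  seed: int = 0, noise: bool = True) -> ScatteringCurve:
    """Synthetic absolute-scale SAXS curve for one scenario.

    I(q) = phi drho^2 V_p P(q) S_eff(q) + background, with S_eff = 1 in the
    dilute (aqueous) scenarios and the broad-peak semidilute form
    otherwise.  Gaussian noise with sigma(q) = max(floor * I,
    counting * sqrt(I)); the returned sigma column is that model.
    """
    if q_grid is None:
        q_grid = np.geomspace(0.023, 3.5, 250)
    q_grid = np.asarray(q_grid, dtype=float)
    m = preset.model
    pq = elliptical_cylinder_pq(q_grid, m.a, m.b, m.length, check=False)
    i_clean = m.scale * m.volume * pq
    if preset.semidilute:
        i_clean = i_clean * _empirical_structure_factor(q_grid, preset)
    i_clean = i_clean + m.background
    if not noise:
        return ScatteringCurve(q_grid, i_clean, None,
                               label=preset.name, kind="saxs")
    sigma = np.maximum(preset.noise_floor * i_clean,
                       preset.counting_scale * np.sqrt(i_clean))
    rng = np.random.default_rng(seed)
    intensity = i_clean + sigma * rng.standard_normal(len(q_grid))
    intensity = np.maximum(intensity, 1e-12)
    return ScatteringCurve(q_grid, intensity, sigma,
                           label=preset.name, kind="saxs")


# --------------------------------------------------------------------------
# DLS
# --------------------------------------------------------------------------

def _length_distribution(preset: ScenarioPreset, n_modes: int = 25):
    """Discretized log-normal rod-length distribution with intensity
    weights w ~ n(L) L^2 (thin rods at low q scatter as mass squared)."""
    if preset.length_sigma_g <= 1.0:
        return np.array([preset.length_median]), np.array([1.0])
    s = math.log(preset.length_sigma_g)
    z = np.linspace(-3.0, 3.0, n_modes)
    lengths = preset.length_median * np.exp(s * z)
    pdf = np.exp(-0.5 * z ** 2)
    w = pdf * lengths ** 2
    return lengths, w / w.sum()


def simulate_dls(preset: ScenarioPreset,
                 tau_grid: Optional[np.ndarray] = None,
                 seed: int = 0, noise: float = 0.0) -> CorrelationTrace:
    """Synthetic g2(tau) of a suspension of rigid rods.

    g1 is the intensity(Z)-weighted mixture of single-rod diffusive decays
    exp(-D_i q^2 tau) with D_i from the Broersma relations;
    g2 = 1 + beta g1^2 (+ Gaussian noise of absolute size ``noise``).
    """
    if tau_grid is None:
        tau_grid = np.geomspace(1e-6, 10.0, 200)
    tau_grid = np.asarray(tau_grid, dtype=float)
    sp = preset.sample
    inputs = BroersmaInputs(eta=sp.solvent_viscosity,
                            temperature=sp.temperature,
                            diameter=preset.dls_diameter)
    lengths, weights = _length_distribution(preset)
    d_coeffs = np.array([broersma_diffusion(length, inputs).d_mean
                         for length in lengths])
    trace = CorrelationTrace(
        tau_grid, np.ones_like(tau_grid), beta=preset.beta,
        wavelength=632.8, angle=90.0,
        refractive_index=sp.refractive_index, label=preset.name)
    q_m = trace.q * 1e9
    g1 = (weights[:, None]
          * np.exp(-d_coeffs[:, None] * q_m ** 2 * tau_grid)).sum(axis=0)
    g2 = 1.0 + preset.beta * g1 ** 2
    if noise > 0:
        rng = np.random.default_rng(seed)
        g2 = g2 + noise * rng.standard_normal(len(tau_grid))
    trace.g2 = g2
    return trace


# --------------------------------------------------------------------------
# WAXS
# --------------------------------------------------------------------------

def simulate_waxs(solvent_name: str,
                  peak_positions: Sequence[float] = (11.8, 14.3, 16.1),
                  peak_heights: Optional[Sequence[float]] = None,
                  q_grid: Optional[np.ndarray] = None,
                  seed: int = 0, noise: float = 2e-3):
    """Synthetic WAXS (sample, solvent) curve pair.

    The solvent contributes a broad Gaussian hump centered at 20 (water),
    16 (MeOH) or 13 (DMF) nm^-1; the sample adds narrow Bragg Gaussians at
    ``peak_positions`` (default: the crystalline reflections of the
    laminated beta-sheet lattice).
    """
    if q_grid is None:
        q_grid = np.linspace(3.0, 25.0, 550)
    q_grid = np.asarray(q_grid, dtype=float)
    center = SOLVENTS[solvent_name]["waxs_hump_center"]
    hump = 0.05 + 1.0 * np.exp(-0.5 * ((q_grid - center) / 4.0) ** 2)
    if peak_heights is None:
        peak_heights = [0.06] * len(peak_positions)
    bragg = np.zeros_like(q_grid)
    for pos, height in zip(peak_positions, peak_heights):
        bragg += height * np.exp(-0.5 * ((q_grid - pos) / 0.15) ** 2)
    rng = np.random.default_rng(seed)
    sample_i = hump + bragg + noise * rng.standard_normal(len(q_grid))
    solvent_i = hump + noise * rng.standard_normal(len(q_grid))
    sigma = np.full(len(q_grid), max(noise, 1e-9))
    sample = ScatteringCurve(q_grid, np.maximum(sample_i, 1e-9), sigma,
                             label=f"sample-{solvent_name}", kind="waxs")
    solvent = ScatteringCurve(q_grid, np.maximum(solvent_i, 1e-9), sigma,
                              label=f"solvent-{solvent_name}", kind="waxs")
    return sample, solvent


# --------------------------------------------------------------------------
# dilution series
# --------------------------------------------------------------------------

def simulate_dilution(c_s_true: float, n_points: int = 12, seed: int = 0,
                      c_start: float = 1.0, baseline: float = 10.0,
                      gain: float = 2000.0,
                      noise_frac: float = 0.05) -> DilutionSeries:
    """Synthetic scattered-intensity dilution series with a solubility break.

    Above the true solubility the count rate grows as gain * (c - c_s)
    (the aggregate mass); below it only the solvent baseline remains.
    2-fold serial dilution from ``c_start`` wt%; multiplicative noise.
    """
    rng = np.random.default_rng(seed)
    conc = c_start / 2.0 ** np.arange(n_points)
    clean = gain * np.maximum(conc - c_s_true, 0.0) + baseline
    intensities = clean * (1.0 + noise_frac * rng.standard_normal(n_points))
    return DilutionSeries(conc, np.maximum(intensities, 0.0), baseline)
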