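# Methods

This note documents the models, numerical choices and limitations behind
each analysis stage, and what the synthetic data do and do not emulate.

## Units and conventions

All q in nm⁻¹, lengths in nm, absolute intensities in cm⁻¹, viscosities
accepted in cP (converted internally to Pa·s), temperatures in K,
concentrations in wt% unless a volume fraction is explicit.  The
scattering vector is q = (4πn/λ)·sin(θ_s/2) with θ_s the full scattering
angle and n the medium refractive index (n = 1 for X-rays); this is the
universal convention and reproduces the standard DLS magnitude
q ≈ 0.0187 nm⁻¹ for a 632.8 nm He–Ne source at 90° in water.

The DLS refractive indices shipped as defaults (water 1.331,
MeOH 1.326, DMF 1.427 at ~633 nm, 25 °C) are handbook values supplied as
configuration inputs, not quantities this analysis determines.

## Elliptical-cylinder form factor

The fibril is a homogeneous cylinder of elliptical cross section.  This
deliberately neglects the experimentally known twist of the ribbons and
any electron-density structure at their surface (solvation layers,
condensed counterions); the consequences are discussed under
*Limitations*.

The orientational average separates into a smooth cross-section term
G(w) — the azimuthal average of the squared 2J₁(x)/x amplitude — and a
longitudinal sinc² term that oscillates qL/2π times over the polar
integration variable.  Numerics:

* ψ (azimuth) integral: fixed 76-point Gauss–Legendre.  The integrand is
  smooth on the scale π/(2b); 76 points are far beyond sufficient for any
  cross section the fits allow (b ≤ 10 nm, q ≤ ~4 nm⁻¹).
* u = cos α (polar) integral: piecewise 8-point Gauss–Legendre on panels
  between consecutive zeros of sinc(qLu/2), capped at 512 resolved lobes
  (the truncated tail is O(10⁻⁷) of the integral relative to the leading
  lobe).  A fixed-order rule on [0,1] fails here: at q = 3 nm⁻¹ and
  L ≈ 300 nm the integrand oscillates ~140 times.  The panel scheme is
  exact to ~10⁻¹¹ against an adaptive-quadrature oracle in the circular
  limit at any aspect ratio tested.
* A doubled-order (16-point) refinement check runs at the three largest
  q of every public evaluation and raises if the two estimates differ by
  more than 10⁻³ relative.

Absolute scale: I(q) = φΔρ²V_p·P(q) + background with V_p = πabL.  In a
dilute measurement φ and Δρ² are perfectly degenerate with the overall
scale, so the fit varies the single product `scale` = φΔρ²; FibrilModel
keeps the two factors separately only for bookkeeping (decomposition via
a SampleSpec's volume fraction).  The `contrast` convention is effective:
Δρ² in cm⁻¹ nm⁻³ makes I come out in cm⁻¹ without an explicit 10⁷
nm→cm factor.

Fitting is Levenberg–Marquardt (lmfit) on (I_obs − I_model)/σ with soft
bounds a, b ∈ [0.5, 10] nm, a ≤ b restored by relabeling after the fit,
and bound-contact flagged in the result.  When the fibrils are longer
than the accessible π/q_min, L carries no information and is frozen at
2π/q_min by default.

## Rod-Guinier cross-section analysis

For a long rod, ln(I·q) is linear in q² with slope −R_CS²/2.  The
analysis starts at q = 0.3 nm⁻¹ (above the regime where the finite
length bends the curve) and iterates the upper edge to self-consistency
with q_max·R_CS ≤ qr_max.  The default qr_max = 1.1 sits inside the
usual 1.3 validity bound: on strongly anisotropic cross sections
(b/a = 1.5) the Guinier approximation acquires a small positive
curvature bias that grows with the window, and 1.1 keeps the systematic
error below ~2% while leaving enough q² leverage that 2% intensity noise
contributes only ~1% scatter.  A window is never taken below 5 points; a
non-negative slope raises a "not rodlike" error rather than returning a
meaningless R_CS.

## Indirect Fourier transform of I(q)·q

The cross-section pair-distance distribution p_cs(r) solves
I(q)q = 2π²∫p_cs(r)J₀(qr)dr on a uniform 101-point grid over [0, dmax]
with both end values pinned to zero, a second-difference smoothness
penalty, and optionally a non-negativity constraint (NNLS).  The
regularization weight is chosen deterministically:

* with experimental uncertainties — by the Morozov discrepancy
  principle, the largest λ whose weighted residual χ² stays within
  N + 2√(2N);
* without — at the maximum-curvature corner of the L-curve.

The discrepancy principle is preferred when σ is available because the
L-curve corner is unstable on noisy curves (the R_CS moment then
scatters by ±15%; with the discrepancy choice it stays within ~2% at the
standard noise level).  R_CS² = ∫p r²dr / (2∫p dr).  Choose dmax only a
little above the expected maximum cross-section dimension: the moment is
r²-weighted, so the ripple on a grossly oversized grid (e.g. 12 nm for a
6 nm fibril) leaks directly into the size estimate.  Mass pinned near
r = dmax triggers a "dmax too small" warning.

The transform targets the *cross-section* distribution only — the
length dimension is divided out by working on I·q — so no attempt is
made at a full 3-D p(r).

## Effective structure factor

S_eff(q) = [I_conc/c_conc]/[I_dil/c_dil] after subtracting flat
backgrounds and interpolating the dilute reference (monotone cubic in
log I; extrapolation refused, at least 50% q-overlap required).
Concentration scaling uses volume fractions when SampleSpecs are
available, wt% otherwise.  Uncertainties propagate in quadrature into an
s_err column.

Peak location: Savitzky–Golay presmoothing (window 7, order 2), local
maxima accepted when their prominence exceeds both an absolute floor
(default 0.01) and 4× the local propagated uncertainty, parabolic
3-point refinement, ties (heights within 10⁻³) broken toward low q.
"No peak" is a value, not an error — dilute and aqueous samples
legitimately lack one.  The search is typically restricted to
q ≤ 0.635 nm⁻¹ (the pipeline default), the region below which
concentration curves stop superimposing; above it only form-factor
cancellation noise lives.

ξ = 2π/q_peak is compared against the geometric mesh size of a rod
network, ξ_pred = √(πd²/4φ) — one rod axis threading each ξ² cell —
which is linear in the rod diameter and scales as φ^(−1/2)
(ξ_pred(5 nm, 0.006) = 57.2 nm).  S_eff(0) comes from a quadratic-in-q²
extrapolation over the points below q_peak/2 (or the lowest decade when
peakless).

## DLS reduction and Broersma hydrodynamics

C(τ) = (g²−1)/β is clipped at zero (counts logged) and fitted with the
squared cumulant form A[e^(−Γτ)(1 + μ₂τ²/2 − μ₃τ³/6)]², truncated where
C < 5% of C(0); a negative μ₂ triggers a first-order refit.  Fitting the
squared form on C itself (rather than ln g¹) keeps the weighting honest
near the baseline.  D̄ = Γ/q².

The rod length inversion uses the end-corrected rigid-cylinder
relations (the revised 1981 coefficient set):

    D_∥ = kT(δ − γ_∥)/(2πηL),  γ_∥ = 1.27 − 7.4(1/δ − 0.34)²
    D_⊥ = kT(δ − γ_⊥)/(4πηL),  γ_⊥ = 0.19 − 4.2(1/δ − 0.39)²
    D_t = ⅓D_∥ + ⅔D_⊥,         δ = ln(2L/d)

The coefficient variant is recorded in every result
(`variant: broersma-1981`); it reproduces the consistency point
D ≈ 8.6×10⁻¹² m² s⁻¹ ↔ L ≈ 200 nm (water, d = 6 nm) to ~2%.  The
validity flag reports 0.15 < 1/δ < 0.35 exactly (aspect ratios ≈ 8–400).
Inversion is bisection on the monotone branch from L ∈ [8d, 1000d], with
up to 10 doublings of the upper edge, to 10⁻⁶ relative tolerance.  The
default diameter d = 6 nm comes from the SAXS cross-section fits; the
dependence is logarithmic, so per-solvent differences of ±1 nm move the
length by only a few percent.

## Solution properties

* φ = (w/ρ_p)/(w/ρ_p + (1−w)/ρ_s): ideal volume additivity.
* Mean residue ellipticity [θ] = θ_mdeg·(MW/n_res)/(10·path_cm·c_mg/mL);
  counterion mass is excluded from concentrations throughout.
* Solubility: the scattered intensity of a dilution series is linear in
  (c − c_s) above the aggregation onset and flat at the solvent baseline
  below it.  The contiguous above-baseline run (> baseline + 3σ) from
  the concentrated end is fitted with 1/I²-weighted least squares —
  scattering noise is multiplicative, and the weighting anchors the
  crossing at the points nearest the break — and intersected with the
  baseline.  Results are gain-invariant.  Status values distinguish a
  series that never rises above baseline (below-detection) from one that
  never reaches it (lower-bound).  Molarity conversion assumes solution
  density ≈ solvent density, adequate below 1 wt%.
* WAXS: the solvent pattern is scaled onto the sample on the peak-free
  5–9 nm⁻¹ flank (scale clamped to [0.8, 1.2] so real Bragg intensity is
  never subtracted), the excess in the 10–18 nm⁻¹ window is smoothed,
  and maxima above 5× the residual noise are reported with parabolic
  positions and d = 2π/q.  The 5σ threshold keeps the false-positive
  rate negligible over the ~10² candidate points while crystalline
  reflections sit more than an order of magnitude higher.  Indexing the
  reflections to the 2-D oblique lattice is out of scope.

## Synthetic data: what it emulates, what it does not

Presets encode the six study conditions (A₈K/A₁₀K × water/MeOH/DMF):
peptide densities 1.50/1.26 g cm⁻³, molecular weights 715/857 g mol⁻¹
(9/11 residues), extended lengths 3.2/3.9 nm (= cross-section thickness
2a), solvent densities 0.997/0.786/0.948 g cm⁻³ and viscosities
0.891/0.485/0.802 cP at 25 °C, Z-average lengths 200/800/1000 nm, and a
nominal 1 wt% (φ ≈ 0.006 nonaqueous).  The cross-section width is set to
2b = 6.0 nm in water and ~15% narrower in the nonaqueous solvents
(fewer laminated sheets), consistent with the ~6 nm diameter the SAXS
fits indicate.  The effective contrast 0.85 (cm⁻¹ nm⁻³)^½ puts simulated
intensities on a realistic cm⁻¹ scale.

* SAXS: I = φΔρ²V_p P(q)·S_eff(q) + 2×10⁻³ cm⁻¹ background on a
  250-point log grid over 0.023–3.5 nm⁻¹ (the synchrotron window);
  Gaussian noise σ = max(0.02·I, 2×10⁻³√I) — a 2% floor plus a counting
  term.  The semidilute S_eff is an empirical broad peak at
  2π/ξ_pred(2b, φ) plus a low-q depression, both scaled by an overlap
  factor min(φ/0.006, 1) so the correlation peak disappears on dilution,
  as observed.  It is *not* a liquid-state theory; tests that pass on it
  show the extraction machinery works, not that any particular
  interaction model holds.
* DLS: g¹ is the intensity-weighted (w ∝ L², the low-q thin-rod
  Z-weighting) mixture of single-exponential decays with Broersma
  diffusion coefficients over a log-normal length distribution
  (σ_g = 1.5 default; σ_g = 1 gives monodisperse rods).  No rotational
  coupling, internal flexibility, or nonergodic slow mode is simulated —
  the glassy arrest seen at high concentration is outside the model, so
  the cumulant stage is only validated in the diffusive regime.
* WAXS: broad solvent hump (center 20/16/13 nm⁻¹ for water/MeOH/DMF,
  width 4 nm⁻¹) plus Gaussian Bragg peaks at 11.8/14.3/16.1 nm⁻¹,
  width 0.15 nm⁻¹.
* Dilution series: intensity = gain·max(c − c_s, 0) + baseline with 5%
  multiplicative noise, 2-fold serial dilution from 1 wt%.

All generators are pure functions of (preset, seed).

Because generator and analysis share the same cylinder kernel, fit
recovery tests demonstrate self-consistency and noise robustness; the
independent checks against the circular-cylinder closed form and a
Monte-Carlo Debye pair sum are what anchor the kernel itself.

## Problem sizes

The shipped tests and the acceptance script run on 150–400 point
curves, 250-point correlation traces, 10⁵-pair Monte-Carlo oracles and
single-curve fits — the sizes a desk analysis of one measurement
session actually uses; the full suite completes in a few minutes on one
core.

## Known limitations

* The homogeneous elliptical cylinder ignores ribbon twist and surface
  contrast; real cross sections inferred in different solvents carry a
  corresponding systematic uncertainty of a few Å.
* The Broersma window flag only warns: outside 8 < L/d < 400 the
  polynomial end corrections degrade smoothly but unboundedly.
* The cumulant mean on strongly bimodal traces (fast diffusive + slow
  structural mode) reflects the fitted window, not a physical average;
  the biexponential helper exists for exactly that diagnosis.
* The solubility estimator assumes the aggregate scattering is linear in
  (c − c_s) at fixed length distribution; strong length growth with
  concentration would curve the series and bias the intercept.
* Mass pinned at dmax, negative μ₂, bound-contact in fits and
  unsatisfiable Guinier windows are all surfaced as warnings/flags
  rather than silently absorbed.
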