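"""DLS reduction and rigid-rod hydrodynamics.

The measured intensity autocorrelation g2(tau) is reduced through the
Siegert relation C(tau) = (g2 - 1)/beta = |g1|^2 and fitted with the
cumulant expansion (Frisken form, fitted on C rather than on ln g1 so the
weighting is honest near the baseline):

    C(tau) = A [ exp(-G tau) (1 + mu2 tau^2 / 2 - mu3 tau^3 / 6) ]^2 ,

giving the mean decay rate G, the mean diffusion coefficient D = G/q^2 and
the polydispersity index mu2/G^2.

For a rigid cylinder of length L and diameter d, end-corrected (Broersma)
hydrodynamics relate D to geometry through delta = ln(2L/d):

    D_par  = kT (delta - gamma_par)  / (2 pi eta L)
    D_perp = kT (delta - gamma_perp) / (4 pi eta L)
    D_t    = 1/3 D_par + 2/3 D_perp

with the revised end-correction polynomials

    gamma_par  = 1.27 - 7.4 (1/delta - 0.34)^2
    gamma_perp = 0.19 - 4.2 (1/delta - 0.39)^2 ,

quoted valid for 0.15 < 1/delta < 0.35 (aspect ratios roughly 8-400); the
validity flag in the result reports exactly this window.  The inverse
problem (length from a measured D) is solved by bisection on the monotone
branch.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .exceptions import FitError, InsufficientDataError, OutOfRangeError
from .scatter_io import CorrelationTrace, CP_TO_PA_S

logger = logging.getLogger(__name__)

__all__ = ["CumulantResult", "DoubleExponentialResult", "BroersmaInputs",
           "BroersmaResult", "siegert_normalize", "cumulant_fit",
           "double_exponential_fit", "broersma_diffusion", "broersma_length",
           "BOLTZMANN_J_PER_K", "BROERSMA_VARIANT"]

BOLTZMANN_J_PER_K = 1.380649e-23
#: which published set of end-correction polynomials is implemented
BROERSMA_VARIANT = "broersma-1981"

_NM_TO_M = 1e-9


# --------------------------------------------------------------------------
# Siegert + cumulants
# --------------------------------------------------------------------------

def siegert_normalize(trace: CorrelationTrace) -> np.ndarray:
    """Field correlation C(tau) = (g2 - 1)/beta, clipped at zero.

    Clipping events (baseline noise pushing g2 below 1) are logged; a trace
    clipped everywhere carries no signal and raises.
    """
    c = (trace.g2 - 1.0) / trace.beta
    n_clip = int(np.sum(c < 0))
    if n_clip:
        logger.info("siegert_normalize: clipped %d of %d negative points",
                    n_clip, len(c))
    if n_clip == len(c):
        raise InsufficientDataError(
            "correlation trace is entirely at or below baseline")
    return np.clip(c, 0.0, None)


@dataclass
class CumulantResult:
    """Cumulant reduction of a normalized correlation function."""

    gamma_mean: float          # 1/s
    mu2: float                 # 1/s^2
    d_mean: float              # m^2/s
    amplitude: float
    fit_window: tuple          # (tau_min, tau_max) used [s]
    order: int
    mu3: float = 0.0
    q: float = float("nan")    # nm^-1

    @property
    def pdi(self) -> float:
        """Polydispersity index mu2 / gamma_mean^2."""
        return self.mu2 / self.gamma_mean ** 2


def _truncate_window(tau, c, cutoff_frac):
    c0 = c[0]
    if c0 <= 0:
        raise InsufficientDataError("C(tau) starts at zero")
    below = np.flatnonzero(c < cutoff_frac * c0)
    stop = below[0] if len(below) else len(c)
    stop = max(stop, 8)
    return tau[:stop], c[:stop]


def cumulant_fit(tau, c, q: float, order: int = 2,
                 cutoff_frac: float = 0.05) -> CumulantResult:
    """Fit the squared cumulant expansion to C(tau) = |g1|^2.

    Parameters
    ----------
    tau, c : arrays
        Lag times [s] and normalized correlation C = (g2-1)/beta.
    q : float
        Scattering vector [nm^-1]; sets the D = Gamma/q^2 conversion.
    order : {2, 3}
        Number of cumulants beyond the mean decay rate.
    cutoff_frac : float
        The fit window is truncated where C first falls below this fraction
        of C(0), keeping the expansion within its radius of usefulness.
    """
    if order not in (2, 3):
        raise ValueError("order must be 2 or 3")
    tau = np.asarray(tau, dtype=float)
    c = np.asarray(c, dtype=float)
    if c[0] <= 0 or np.min(c) > 0.1 * c[0]:
        raise InsufficientDataError(
            "C(tau) does not decay by a decade within the trace")
    tw, cw = _truncate_window(tau, c, cutoff_frac)

    # initial decay rate from the early-time log slope of C = A e^{-2 G tau}
    n0 = max(3, len(tw) // 4)
    pos = cw[:n0] > 0
    slope = np.polyfit(tw[:n0][pos], np.log(cw[:n0][pos]), 1)[0]
    g0 = max(-0.5 * slope, 1.0 / tw[-1])

    def model(p):
        a, g, mu2, mu3 = p
        poly = 1.0 + mu2 * tw ** 2 / 2.0 - mu3 * tw ** 3 / 6.0
        return a * (np.exp(-g * tw) * poly) ** 2

    def resid(p):
        return model(p) - cw

    x0 = [cw[0], g0, 0.0, 0.0]
    free3 = order == 3
    scale = [max(cw[0], 1e-3), g0, g0 ** 2, g0 ** 3 if free3 else 1.0]

    def resid_scaled(u):
        p = [u[0] * scale[0], u[1] * scale[1], u[2] * scale[2],
             (u[3] * scale[3]) if free3 else 0.0]
        return resid(p)

    n_par = 4 if free3 else 3
    sol = least_squares(resid_scaled, x0=[x0[0] / scale[0], 1.0, 0.0, 0.0][:n_par]
                        + ([] if free3 else []),
                        method="lm", max_nfev=20000)
    if not sol.success:
        raise FitError(f"cumulant fit failed: {sol.message}",
                       last_state=sol.x)
    u = list(sol.x) + [0.0] * (4 - len(sol.x))
    a = u[0] * scale[0]
    gamma = u[1] * scale[1]
    mu2 = u[2] * scale[2]
    mu3 = (u[3] * scale[3]) if free3 else 0.0
    if gamma <= 0:
        raise FitError("cumulant fit returned non-positive decay rate",
                       last_state=(a, gamma, mu2))
    if mu2 < 0:
        warnings.warn("negative second cumulant; refitting at first order",
                      stacklevel=2)
        def resid1(u):
            return u[0] * scale[0] * np.exp(-2 * u[1] * scale[1] * tw) - cw
        sol1 = least_squares(resid1, x0=[u[0], u[1]], method="lm")
        a = sol1.x[0] * scale[0]
        gamma = sol1.x[1] * scale[1]
        mu2 = 0.0
        mu3 = 0.0
    q_m = q * 1e9                       # nm^-1 -> m^-1
    return CumulantResult(gamma_mean=gamma, mu2=mu2,
                          d_mean=gamma / q_m ** 2, amplitude=a,
                          fit_window=(float(tw[0]), float(tw[-1])),
                          order=order, mu3=mu3, q=q)


@dataclass
class DoubleExponentialResult:
    """Biexponential description of g1: fast (1) and slow (2) modes."""

    amp1: float
    gamma1: float              # 1/s, fast
    amp2: float
    gamma2: float              # 1/s, slow
    collapsed: bool = False    # True when the two rates were degenerate


def double_exponential_fit(tau, c, rate_ratio_floor: float = 2.0,
                           ) -> DoubleExponentialResult:
    """Fit C = (a1 e^{-G1 tau} + a2 e^{-G2 tau})^2 with a1, a2 >= 0.

    When the optimizer returns nearly degenerate rates (ratio below
    ``rate_ratio_floor``) the result collapses to an effective single mode,
    flagged in the result.
    """
    tau = np.asarray(tau, dtype=float)
    c = np.asarray(c, dtype=float)
    tw, cw = _truncate_window(tau, c, 0.01)
    n0 = max(3, len(tw) // 4)
    pos = cw[:n0] > 0
    slope = np.polyfit(tw[:n0][pos], np.log(cw[:n0][pos]), 1)[0]
    g0 = max(-0.5 * slope, 1.0 / tw[-1])
    amp0 = math.sqrt(max(cw[0], 1e-12))

    def resid(u):
        a1, a2 = u[0] ** 2, u[1] ** 2      # squared -> non-negative
        g1_, g2_ = abs(u[2]) * g0, abs(u[3]) * g0
        g1v = a1 * np.exp(-g1_ * tw) + a2 * np.exp(-g2_ * tw)
        return g1v ** 2 - cw

    sol = least_squares(resid, x0=[math.sqrt(amp0 * 0.7),
                                   math.sqrt(amp0 * 0.3), 2.0, 0.5],
                        method="lm", max_nfev=40000)
    if not sol.success:
        raise FitError(f"double-exponential fit failed: {sol.message}",
                       last_state=sol.x)
    a1, a2 = sol.x[0] ** 2, sol.x[1] ** 2
    g1_, g2_ = abs(sol.x[2]) * g0, abs(sol.x[3]) * g0
    (a_fast, g_fast), (a_slow, g_slow) = sorted(
        [(a1, g1_), (a2, g2_)], key=lambda t: -t[1])
    if g_slow <= 0 or g_fast / max(g_slow, 1e-300) < rate_ratio_floor:
        amp = a_fast + a_slow
        g_eff = (a_fast * g_fast + a_slow * g_slow) / amp
        return DoubleExponentialResult(amp1=amp, gamma1=g_eff, amp2=0.0,
                                       gamma2=0.0, collapsed=True)
    return DoubleExponentialResult(amp1=a_fast, gamma1=g_fast,
                                   amp2=a_slow, gamma2=g_slow)


# --------------------------------------------------------------------------
# Broersma rod hydrodynamics
# --------------------------------------------------------------------------

@dataclass
class BroersmaInputs:
    """Inputs of the Broersma analysis: solvent, temperature, rod diameter,
    and (for the inverse problem) the measured mean diffusion coefficient."""

    eta: float                     # cP
    temperature: float = 298.15    # K
    diameter: float = 6.0          # nm, from the SAXS cross-section fits
    d_trans: Optional[float] = None  # measured D [m^2/s], inverse input

    def __post_init__(self):
        if self.eta <= 0 or self.temperature <= 0 or self.diameter <= 0:
            raise ValueError("eta, temperature and diameter must be positive")
        if self.d_trans is not None and self.d_trans <= 0:
            raise ValueError("d_trans must be positive")


@dataclass
class BroersmaResult:
    """Forward Broersma evaluation at one rod length."""

    length: float              # nm
    d_mean: float              # m^2/s
    d_par: float
    d_perp: float
    delta: float
    gamma_par: float
    gamma_perp: float
    valid: bool                # 0.15 < 1/delta < 0.35
    variant: str = BROERSMA_VARIANT


def broersma_diffusion(length: float, inputs: BroersmaInputs) -> BroersmaResult:
    """Mean translational diffusion coefficient of a rigid cylinder.

    ``length`` in nm; the result is in m^2/s.  The validity flag is False
    outside 0.15 < 1/delta < 0.35 (the quoted range of the end-correction
    polynomials), but the value is still returned.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    delta = math.log(2.0 * length / inputs.diameter)
    if delta <= 0:
        raise ValueError(
            f"length {length} nm must exceed half the diameter "
            f"{inputs.diameter} nm for the rod model to make sense")
    inv = 1.0 / delta
    gamma_par = 1.27 - 7.4 * (inv - 0.34) ** 2
    gamma_perp = 0.19 - 4.2 * (inv - 0.39) ** 2
    kt = BOLTZMANN_J_PER_K * inputs.temperature
    eta_si = inputs.eta * CP_TO_PA_S
    l_m = length * _NM_TO_M
    d_par = kt * (delta - gamma_par) / (2.0 * math.pi * eta_si * l_m)
    d_perp = kt * (delta - gamma_perp) / (4.0 * math.pi * eta_si * l_m)
    d_mean = d_par / 3.0 + 2.0 * d_perp / 3.0
    return BroersmaResult(length=length, d_mean=d_mean, d_par=d_par,
                          d_perp=d_perp, delta=delta, gamma_par=gamma_par,
                          gamma_perp=gamma_perp,
                          valid=0.15 < inv < 0.35)


def broersma_length(inputs: BroersmaInputs, rtol: float = 1e-6,
                    ) -> BroersmaResult:
    """Invert the Broersma relations: rod length from a measured D.

    Bisection on the monotone branch, starting from the bracket
    L in [8 d, 1000 d] (the quoted aspect-ratio validity range), with up to
    10 doublings of the upper edge for slower rods.
    """
    if inputs.d_trans is None:
        raise ValueError("inputs.d_trans (the measured D) is required")
    target = inputs.d_trans
    lo = 8.0 * inputs.diameter
    hi = 1000.0 * inputs.diameter

    d_lo = broersma_diffusion(lo, inputs).d_mean
    if target > d_lo:
        raise OutOfRangeError(
            f"D = {target:.3g} m^2/s exceeds the value {d_lo:.3g} at the "
            f"shortest rod in the bracket [{lo:.0f}, {hi:.0f}] nm")
    for _ in range(10):
        if broersma_diffusion(hi, inputs).d_mean <= target:
            break
        hi *= 2.0
    else:
        raise OutOfRangeError(
            f"D = {target:.3g} m^2/s below the attainable range even at "
            f"L = {hi:.0f} nm (bracket [{lo:.0f}, {hi:.0f}] nm)")

    while (hi - lo) > rtol * hi:
        mid = 0.5 * (lo + hi)
        if broersma_diffusion(mid, inputs).d_mean > target:
            lo = mid
        else:
            hi = mid
    return broersma_diffusion(0.5 * (lo + hi), inputs)
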