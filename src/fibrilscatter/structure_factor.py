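"""Effective structure factor of semidilute fibril suspensions.

At volume fractions where the fibrils overlap, the scattering is
I(q) = n P(q) S_eff(q): dividing a concentration-normalized curve by a
dilute reference curve (where S_eff ~ 1) isolates the interaggregate
correlations.  The correlation peak position q_peak gives the network
correlation length xi = 2 pi / q_peak, compared against the geometric mesh
size of a rod network, and the extrapolated S_eff(0) tracks the osmotic
compressibility of the suspension.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import find_peaks, savgol_filter

from .exceptions import InsufficientDataError
from .scatter_io import ScatteringCurve

__all__ = ["EffectiveStructureFactor", "effective_structure_factor",
           "locate_peak", "correlation_length", "mesh_size",
           "extrapolate_seff0"]


@dataclass
class EffectiveStructureFactor:
    """S_eff(q) of one concentrated sample against a dilute reference."""

    q: np.ndarray
    s_eff: np.ndarray
    concentration: float                  # wt% (or the ratio numerator)
    dilute_reference_label: str = ""
    s_err: Optional[np.ndarray] = None    # propagated 1-sigma uncertainty
    q_peak: Optional[float] = None        # None = no interior correlation peak
    xi: Optional[float] = None            # nm
    s_eff_0: Optional[float] = None
    s_eff_0_err: Optional[float] = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.s_eff = np.asarray(self.s_eff, dtype=float)
        if len(self.q) != len(self.s_eff):
            raise ValueError("q and s_eff must match in length")
        if self.s_err is not None:
            self.s_err = np.asarray(self.s_err, dtype=float)
            if len(self.s_err) != len(self.q):
                raise ValueError("s_err must match q in length")


def effective_structure_factor(concentrated: ScatteringCurve,
                               dilute: ScatteringCurve,
                               conc_ratio: float,
                               background_concentrated: float = 0.0,
                               background_dilute: float = 0.0,
                               ) -> EffectiveStructureFactor:
    """S_eff(q) = [I_conc(q)/c_conc] / [I_dil(q)/c_dil].

    ``conc_ratio`` is c_conc/c_dil on whatever concentration scale the two
    curves share (volume fraction preferred; wt% acceptable for identical
    solvents).  The dilute curve is interpolated onto the concentrated grid
    with a monotone cubic in log I vs q; extrapolation outside the dilute
    q range is refused, so only the overlap region is returned.
    """
    if conc_ratio <= 0:
        raise ValueError("conc_ratio must be positive")
    q_lo = max(concentrated.q[0], dilute.q[0])
    q_hi = min(concentrated.q[-1], dilute.q[-1])
    span = q_hi - q_lo
    full = concentrated.q[-1] - concentrated.q[0]
    if span <= 0 or span < 0.5 * full:
        raise InsufficientDataError(
            f"q overlap [{q_lo:.3g}, {q_hi:.3g}] covers less than half of "
            "the concentrated curve")

    sel = (concentrated.q >= q_lo) & (concentrated.q <= q_hi)
    qs = concentrated.q[sel]
    i_conc = concentrated.intensity[sel] - background_concentrated

    i_dil_raw = dilute.intensity - background_dilute
    pos = i_dil_raw > 0
    n_bad = int(np.sum(~pos))
    if n_bad:
        warnings.warn(f"{n_bad} non-positive dilute intensities masked "
                      "before interpolation", stacklevel=2)
    interp = PchipInterpolator(dilute.q[pos], np.log(i_dil_raw[pos]),
                               extrapolate=False)
    i_dil = np.exp(interp(qs))
    good = np.isfinite(i_dil) & (i_dil > 0)

    s = (i_conc[good] / conc_ratio) / i_dil[good]

    s_err = None
    if concentrated.sigma is not None and dilute.sigma is not None:
        sig_c = concentrated.sigma[sel][good]
        sig_d = np.interp(qs[good], dilute.q, dilute.sigma)
        s_err = np.abs(s) * np.sqrt((sig_c / i_conc[good]) ** 2
                                    + (sig_d / i_dil[good]) ** 2)
    return EffectiveStructureFactor(
        q=qs[good], s_eff=s, concentration=conc_ratio,
        dilute_reference_label=dilute.label, s_err=s_err)


def locate_peak(sf: EffectiveStructureFactor,
                window: int = 7, min_prominence: float = 0.01,
                q_max: Optional[float] = None) -> Optional[float]:
    """Correlation-peak position q_peak [nm^-1], or None when S_eff has no
    interior maximum (the dilute / aqueous case).

    The trace is Savitzky-Golay presmoothed (window 7, order 2) and local
    maxima are accepted only when their prominence exceeds
    ``min_prominence`` and, when the curves carried error bars, four times
    the local propagated uncertainty — a peak you cannot distinguish from
    the noise is no peak.  Among accepted peaks the highest wins and ties
    break toward low q, where the interaggregate correlation lives.  The
    returned position is refined by a parabola through the three points
    around the smoothed maximum.  ``q_max`` optionally restricts the search
    (e.g. to below the range where concentration curves superimpose).
    """
    s = sf.s_eff
    if len(s) < window + 2:
        raise InsufficientDataError("too few points to locate a peak")
    smooth = savgol_filter(s, window, polyorder=2)
    idx, props = find_peaks(smooth, prominence=max(min_prominence, 0.0))
    prom = props["prominences"]
    if q_max is not None:
        keep = sf.q[idx] <= q_max
        idx, prom = idx[keep], prom[keep]
    if sf.s_err is not None and len(idx):
        significant = ((prom >= 4.0 * sf.s_err[idx])
                       & (sf.s_err[idx] < 0.3 * np.abs(smooth[idx])))
        idx, prom = idx[significant], prom[significant]
    if len(idx) == 0:
        return None
    heights = smooth[idx]
    # maxima equal within 1e-3 are ties; take the lowest-q one
    best = idx[heights >= heights.max() - 1e-3]
    i = int(best[0])
    # parabolic refinement on the smoothed trace
    y1, y2, y3 = smooth[i - 1], smooth[i], smooth[i + 1]
    x1, x2, x3 = sf.q[i - 1], sf.q[i], sf.q[i + 1]
    denom = (y1 - 2 * y2 + y3)
    if denom >= 0:
        return float(x2)
    h = 0.5 * (x3 - x1)
    return float(x2 + 0.5 * h * (y1 - y3) / denom)


def correlation_length(q_peak: float) -> float:
    """Network correlation length xi = 2 pi / q_peak [nm]."""
    if q_peak <= 0:
        raise ValueError("q_peak must be positive")
    return 2.0 * math.pi / q_peak


def mesh_size(d: float, phi: float) -> float:
    """Geometric mesh size of a network of rods of diameter d at volume
    fraction phi:  xi = sqrt(pi d^2 / (4 phi))  [nm].

    One rod axis threads each xi * xi cell of the network cross section, so
    phi = (pi d^2/4)/xi^2; the prediction is linear in d and scales as
    phi^(-1/2).
    """
    if d <= 0:
        raise ValueError("d must be positive")
    if not (0.0 < phi < 1.0):
        raise ValueError("phi must be in (0, 1)")
    return math.sqrt(math.pi * d * d / (4.0 * phi))


def extrapolate_seff0(sf: EffectiveStructureFactor,
                      q_window: Optional[Sequence[float]] = None,
                      ) -> tuple:
    """Extrapolate S_eff to q = 0 with a quadratic in q^2.

    The fit uses points below q_peak/2 when a correlation peak exists,
    otherwise the lowest decade of q; returns (s_eff_0, uncertainty).
    """
    if q_window is None:
        if sf.q_peak:
            hi = sf.q_peak / 2.0
        else:
            hi = sf.q[0] * 10.0
        q_window = (0.0, hi)
    sel = (sf.q >= q_window[0]) & (sf.q <= q_window[1])
    if sel.sum() < 5:
        raise InsufficientDataError(
            f"only {int(sel.sum())} points below q = {q_window[1]:.3g} nm^-1")
    x = sf.q[sel] ** 2
    y = sf.s_eff[sel]
    design = np.column_stack([np.ones_like(x), x, x ** 2])
    coef, res, *_ = np.linalg.lstsq(design, y, rcond=None)
    dof = max(sel.sum() - 3, 1)
    s2 = (res[0] / dof) if len(res) else float(
        np.sum((design @ coef - y) ** 2) / dof)
    cov = s2 * np.linalg.inv(design.T @ design)
    return float(coef[0]), float(math.sqrt(max(cov[0, 0], 0.0)))
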