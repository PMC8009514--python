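"""Regularized indirect Fourier transform of I(q)q to the cross-section
pair-distance distribution function (PDDF).

For a long rodlike particle the length direction factors out of the
scattering and ``I(q) * q`` is proportional to the form factor of the cross
section alone.  Its real-space counterpart, the cross-section PDDF p_cs(r),
is related through a zeroth-order Bessel transform

    I(q) q  =  2 pi^2  int_0^{D_max} p_cs(r) J0(q r) dr .

The inverse problem is solved on a uniform r grid with the end points pinned
to zero, a second-difference (Tikhonov) smoothness penalty lambda ||D2 p||^2,
and, optionally, a non-negativity constraint (NNLS).  When no lambda is
given it is chosen automatically and deterministically: by the discrepancy
principle (largest lambda whose weighted residual chi-square stays within
N + 2 sqrt(2N)) when the curve carries uncertainties, and at the corner of
the L-curve (maximum curvature of log residual-norm vs log seminorm)
otherwise.  The result is sensitive to a grossly overestimated dmax — the
r^2-weighted tail of the grid then amplifies noise into the size moments —
so choose dmax a little above the expected maximum cross-section dimension.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import nnls
from scipy.special import j0

from .exceptions import InsufficientDataError, NumericalError
from .scatter_io import ScatteringCurve

__all__ = ["CrossSectionPDDF", "cross_section_ift", "rcs_from_pddf",
           "pddf_forward"]

_KERNEL_NORM = 2.0 * math.pi ** 2


@dataclass
class CrossSectionPDDF:
    """Cross-section pair-distance distribution on a uniform r grid.

    p carries arbitrary units (the absolute scale of the transform is not
    needed for any derived size); p(0) = p(dmax) = 0 by construction.
    """

    r: np.ndarray           # nm, uniform, 0..dmax
    p: np.ndarray
    dmax: float             # nm
    lambda_reg: float
    chi2_red: float = float("nan")

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if len(self.r) != len(self.p):
            raise ValueError("r and p must match in length")
        dr = np.diff(self.r)
        if not np.allclose(dr, dr[0], rtol=1e-8):
            raise ValueError("r grid must be uniform")


def _second_difference_matrix(n: int) -> np.ndarray:
    """Second differences of the interior coefficients, with the implicit
    zero end points included so curvature at the edges is penalized too."""
    full = np.zeros((n, n))
    for i in range(1, n - 1):
        full[i, i - 1] = 1.0
        full[i, i] = -2.0
        full[i, i + 1] = 1.0
    full[0, 0] = -2.0
    full[0, 1] = 1.0
    full[n - 1, n - 1] = -2.0
    full[n - 1, n - 2] = 1.0
    return full[:, 1:-1]


def _solve_penalized(kw, yw, dmat, lam, nonneg):
    stacked = np.vstack([kw, math.sqrt(lam) * dmat])
    rhs = np.concatenate([yw, np.zeros(dmat.shape[0])])
    if nonneg:
        coef, _ = nnls(stacked, rhs)
    else:
        coef, *_ = np.linalg.lstsq(stacked, rhs, rcond=None)
    return coef


def cross_section_ift(curve: ScatteringCurve, dmax: float,
                      n_points: int = 101,
                      lambda_reg: Optional[float] = None,
                      q_min: float = 0.3, q_max: float = 3.0,
                      nonneg: bool = False) -> CrossSectionPDDF:
    """Indirect Fourier transform of I(q)q to the cross-section PDDF.

    Parameters
    ----------
    curve : ScatteringCurve
        Must cover the cross-section regime; only q in [q_min, q_max] is
        used (default 0.3-3 nm^-1, below the wide-angle regime).
    dmax : float
        Assumed maximum cross-section dimension [nm], in [2, 20].
    n_points : int
        Size of the r grid (end points included and pinned to zero).
    lambda_reg : float, optional
        Smoothness weight; chosen by the discrepancy principle (with
        sigma) or the L-curve corner (without) when omitted.
    nonneg : bool
        Solve with a non-negativity constraint (NNLS) instead of the plain
        linear solve.
    """
    if not (2.0 <= dmax <= 20.0):
        raise ValueError(f"dmax must be in [2, 20] nm, got {dmax}")
    sub = curve.restrict(q_min, q_max)
    if len(sub) < 10:
        raise InsufficientDataError(
            f"only {len(sub)} points in q window [{q_min}, {q_max}] nm^-1")
    y = sub.intensity * sub.q
    if not np.any(y != 0):
        raise InsufficientDataError("intensity is identically zero")
    w = (1.0 / (sub.sigma * sub.q) if sub.sigma is not None
         else np.full(len(sub), 1.0 / max(np.abs(y).max(), 1e-300)))

    r = np.linspace(0.0, dmax, n_points)
    dr = r[1] - r[0]
    kernel = _KERNEL_NORM * j0(np.outer(sub.q, r[1:-1])) * dr
    kw = kernel * w[:, None]
    yw = y * w
    dmat = _second_difference_matrix(n_points)

    if lambda_reg is None:
        if sub.sigma is not None:
            lambda_reg = _discrepancy_lambda(kw, yw, dmat, nonneg)
        else:
            lambda_reg = _l_curve_corner(kw, yw, dmat, nonneg)
    coef = _solve_penalized(kw, yw, dmat, lambda_reg, nonneg)
    if not np.all(np.isfinite(coef)):
        raise NumericalError("IFT linear system is ill-conditioned")

    p = np.zeros(n_points)
    p[1:-1] = coef

    # dmax sanity: mass pinned against the outer boundary means the assumed
    # maximum dimension is too small
    outer = p[int(0.9 * n_points):]
    if len(outer) and np.max(np.abs(outer)) > 0.05 * np.max(np.abs(p)):
        warnings.warn(
            f"p(r) is non-negligible near r = dmax = {dmax} nm; "
            "dmax is probably too small", stacklevel=2)

    resid = kw @ coef - yw
    dof = max(len(y) - _effective_dof(kw, dmat, lambda_reg), 1.0)
    chi2_red = float(resid @ resid / dof)
    return CrossSectionPDDF(r=r, p=p, dmax=dmax, lambda_reg=float(lambda_reg),
                            chi2_red=chi2_red)


def _effective_dof(kw, dmat, lam):
    """Trace of the influence matrix of the penalized solve."""
    a = kw.T @ kw + lam * dmat.T @ dmat
    try:
        inv = np.linalg.solve(a, kw.T @ kw)
    except np.linalg.LinAlgError:
        return kw.shape[1]
    return float(np.trace(inv))


def _discrepancy_lambda(kw, yw, dmat, nonneg) -> float:
    """Largest lambda whose residual chi-square is statistically
    indistinguishable from the noise level (Morozov with a 2-sigma margin);
    requires the residuals to be in units of sigma."""
    n = len(yw)
    budget = n + 2.0 * math.sqrt(2.0 * n)
    lams = np.logspace(-10, 2, 49) * max(np.sum(kw * kw), 1e-300)
    last = lams[0]
    for lam in lams[::-1]:
        coef = _solve_penalized(kw, yw, dmat, lam, nonneg)
        resid = kw @ coef - yw
        if resid @ resid <= budget:
            return float(lam)
        last = lam
    return float(last)


def _l_curve_corner(kw, yw, dmat, nonneg) -> float:
    lams = np.logspace(-10, 2, 37) * max(np.sum(kw * kw), 1e-300)
    rho = np.empty(len(lams))
    eta = np.empty(len(lams))
    for i, lam in enumerate(lams):
        coef = _solve_penalized(kw, yw, dmat, lam, nonneg)
        rho[i] = np.linalg.norm(kw @ coef - yw)
        eta[i] = np.linalg.norm(dmat @ coef)
    lr = np.log10(np.maximum(rho, 1e-300))
    le = np.log10(np.maximum(eta, 1e-300))
    # discrete curvature of the (log rho, log eta) curve; corner = max
    kappa = np.zeros(len(lams))
    for i in range(1, len(lams) - 1):
        x1, x2, x3 = lr[i - 1], lr[i], lr[i + 1]
        y1, y2, y3 = le[i - 1], le[i], le[i + 1]
        area = (x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1)
        d12 = math.hypot(x2 - x1, y2 - y1)
        d23 = math.hypot(x3 - x2, y3 - y2)
        d13 = math.hypot(x3 - x1, y3 - y1)
        if d12 * d23 * d13 > 0:
            kappa[i] = 2.0 * area / (d12 * d23 * d13)
    idx = int(np.argmax(kappa))
    if kappa[idx] <= 0:
        idx = len(lams) // 2
    return float(lams[idx])


def pddf_forward(pddf: CrossSectionPDDF, q) -> np.ndarray:
    """Forward transform of a PDDF back to I(q)q, for residual inspection."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    dr = pddf.r[1] - pddf.r[0]
    return _KERNEL_NORM * (j0(np.outer(q, pddf.r)) @ pddf.p) * dr


def rcs_from_pddf(pddf: CrossSectionPDDF) -> float:
    """Cross-section radius of gyration from PDDF moments,
    R_CS^2 = int p r^2 dr / (2 int p dr)."""
    norm = np.trapezoid(pddf.p, pddf.r)
    if norm <= 0:
        raise ValueError("PDDF has non-positive integral")
    second = np.trapezoid(pddf.p * pddf.r ** 2, pddf.r)
    return math.sqrt(second / (2.0 * norm))
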