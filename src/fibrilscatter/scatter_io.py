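"""Domain types, unit conventions and file I/O for scattering and DLS data.

Unit conventions (package-wide)
-------------------------------
========================  =========================
scattering vector q       nm^-1
lengths (a, b, L, xi, d)  nm
absolute intensity I      cm^-1
viscosity eta             cP (converted internally to Pa s)
temperature T             K
concentration             wt% unless stated
lag time tau              s
========================  =========================

The scattering-vector magnitude follows the universal convention

    q = (4 pi n / lambda) * sin(theta_s / 2),

with ``theta_s`` the full scattering angle and ``n`` the refractive index of
the medium (n = 1 for X-rays).  This is exposed as :func:`q_from_geometry`.

Files are plain ASCII: whitespace- or comma-delimited numeric columns with
``#`` comment lines — the common reduced-SAXS ``.dat`` dialect.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .exceptions import InsufficientDataError, ParseError

logger = logging.getLogger(__name__)

#: multiply a cP value by this to obtain Pa s
CP_TO_PA_S = 1e-3
#: multiply an intensity in nm^-1 by this to obtain cm^-1
NM_INV_TO_CM_INV = 1e7

#: DLS refractive-index defaults per solvent.  These are standard handbook
#: values at 25 C for 633 nm light; they are configuration inputs, not
#: measured quantities of this analysis.
DEFAULT_REFRACTIVE_INDEX = {"water": 1.331, "MeOH": 1.326, "DMF": 1.427}


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class ScatteringCurve:
    """A reduced 1-D scattering profile I(q).

    Parameters
    ----------
    q : array
        Scattering vector magnitudes [nm^-1], strictly increasing, > 0.
    intensity : array
        Absolute scattered intensity [cm^-1].
    sigma : array, optional
        1-sigma uncertainty on the intensity [cm^-1], strictly positive.
    label : str
        Free-text label (sample name, solvent, concentration).
    kind : {"saxs", "waxs"}
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None
    label: str = ""
    kind: str = "saxs"

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.kind not in ("saxs", "waxs"):
            raise ValueError(f"kind must be 'saxs' or 'waxs', got {self.kind!r}")
        if self.q.ndim != 1 or len(self.q) != len(self.intensity):
            raise ValueError("q and intensity must be 1-D arrays of equal length")
        if np.any(self.q <= 0):
            raise ValueError("q must be strictly positive everywhere")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.sigma is not None:
            if len(self.sigma) != len(self.q):
                raise ValueError("sigma must match q in length")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be strictly positive when present")

    def __len__(self):
        return len(self.q)

    def restrict(self, qmin: float = -np.inf, qmax: float = np.inf) -> "ScatteringCurve":
        """Return the sub-curve with qmin <= q <= qmax."""
        m = (self.q >= qmin) & (self.q <= qmax)
        return ScatteringCurve(
            self.q[m], self.intensity[m],
            None if self.sigma is None else self.sigma[m],
            label=self.label, kind=self.kind,
        )


@dataclass
class CorrelationTrace:
    """A DLS intensity autocorrelation measurement g2(tau).

    ``beta`` is the instrumental coherence factor of the Siegert relation
    g2 = 1 + beta |g1|^2; the scattering geometry (laser wavelength [nm],
    scattering angle [deg], solvent refractive index) fixes q.
    """

    tau: np.ndarray
    g2: np.ndarray
    beta: float = 1.0
    wavelength: float = 632.8
    angle: float = 90.0
    refractive_index: float = 1.331
    label: str = ""

    def __post_init__(self):
        self.tau = np.asarray(self.tau, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        if self.tau.ndim != 1 or len(self.tau) != len(self.g2):
            raise ValueError("tau and g2 must be 1-D arrays of equal length")
        if np.any(np.diff(self.tau) <= 0):
            raise ValueError("tau must be strictly increasing")
        if not (0.0 < self.beta <= 1.0):
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")

    def __len__(self):
        return len(self.tau)

    @property
    def q(self) -> float:
        """Scattering vector magnitude [nm^-1] of the DLS geometry."""
        return q_from_geometry(self.wavelength, self.angle, self.refractive_index)


@dataclass
class SampleSpec:
    """Composition and solvent parameters of one peptide sample."""

    peptide_name: str
    n_residues: int
    molecular_weight: float          # g/mol, counterion excluded
    peptide_density: float           # g/cm^3
    extended_length: float           # nm, fully extended monomer
    solvent_name: str
    solvent_density: float           # g/cm^3
    solvent_viscosity: float         # cP
    temperature: float = 298.15      # K
    concentration_wt_percent: float = 1.0
    refractive_index: Optional[float] = None

    def __post_init__(self):
        for name in ("molecular_weight", "peptide_density", "extended_length",
                     "solvent_density", "solvent_viscosity", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.concentration_wt_percent < 100.0):
            raise ValueError("concentration_wt_percent must be in [0, 100)")
        if self.refractive_index is None:
            self.refractive_index = DEFAULT_REFRACTIVE_INDEX.get(
                self.solvent_name, 1.333)

    def with_concentration(self, wt_percent: float) -> "SampleSpec":
        return replace(self, concentration_wt_percent=wt_percent)


@dataclass
class DilutionSeries:
    """Scattered-intensity dilution series used for solubility estimation."""

    concentrations: np.ndarray       # wt%
    intensities: np.ndarray          # mean count rate [kHz]
    solvent_baseline: float          # count rate of the pure solvent [kHz]

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.concentrations) != len(self.intensities):
            raise ValueError("concentrations and intensities must match in length")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

def q_from_geometry(wavelength: float, scattering_angle: float,
                    refractive_index: float = 1.0) -> float:
    """Scattering vector magnitude q = (4 pi n / lambda) sin(theta_s/2).

    Parameters
    ----------
    wavelength : float
        In-vacuo wavelength [nm].
    scattering_angle : float
        Full scattering angle theta_s [deg], in (0, 180).
    refractive_index : float
        Medium refractive index (1 for X-rays).

    Returns
    -------
    float
        q [nm^-1].
    """
    if not (0.0 < scattering_angle < 180.0):
        raise ValueError(
            f"scattering angle must be in (0, 180) deg, got {scattering_angle}")
    if wavelength <= 0 or refractive_index <= 0:
        raise ValueError("wavelength and refractive index must be positive")
    theta = math.radians(scattering_angle)
    return 4.0 * math.pi * refractive_index * math.sin(theta / 2.0) / wavelength


# --------------------------------------------------------------------------
# file I/O
# --------------------------------------------------------------------------

_NUM_SPLIT = re.compile(r"[,\s]+")


def _parse_numeric_table(path, min_rows, max_cols):
    """Parse a '#'-commented ASCII table; returns (array, n_dropped)."""
    rows = []
    n_dropped = 0
    ncols = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in _NUM_SPLIT.split(line) if p]
            try:
                values = [float(p) for p in parts]
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric field in {line!r}")
            if ncols is None:
                ncols = min(len(values), max_cols)
                if len(values) < 2:
                    raise ParseError(
                        f"{path}: line {lineno}: expected >= 2 columns")
            if len(values) < ncols:
                raise ParseError(
                    f"{path}: line {lineno}: expected {ncols} columns, "
                    f"got {len(values)}")
            values = values[:ncols]
            if all(math.isfinite(v) for v in values):
                rows.append(values)
            else:
                n_dropped += 1
    if n_dropped:
        logger.warning("%s: dropped %d rows with non-finite values",
                       path, n_dropped)
    if len(rows) < min_rows:
        raise InsufficientDataError(
            f"{path}: only {len(rows)} usable rows (need >= {min_rows})")
    return np.array(rows, dtype=float), n_dropped


def read_curve(path, kind: str = "saxs") -> ScatteringCurve:
    """Read a 2- or 3-column (q, I[, sigma]) ASCII scattering file.

    Rows containing non-finite values are dropped (and logged); the curve is
    returned sorted by q.
    """
    table, _ = _parse_numeric_table(path, min_rows=5, max_cols=3)
    order = np.argsort(table[:, 0])
    table = table[order]
    sigma = table[:, 2] if table.shape[1] >= 3 else None
    return ScatteringCurve(table[:, 0], table[:, 1], sigma,
                           label=str(path), kind=kind)


def write_curve(curve: ScatteringCurve, path) -> None:
    """Write a curve in the same 2/3-column ASCII dialect read_curve accepts."""
    cols = [curve.q, curve.intensity]
    header = "q[1/nm] I[1/cm]"
    if curve.sigma is not None:
        cols.append(curve.sigma)
        header += " sigma[1/cm]"
    data = np.column_stack(cols)
    np.savetxt(path, data, fmt="%.15e",
               header=f"{curve.label}\n{header}".strip())


def read_correlation(path, beta: float = 1.0, wavelength: float = 632.8,
                     angle: float = 90.0,
                     refractive_index: float = 1.331) -> CorrelationTrace:
    """Read a 2-column (tau [s], g2) ASCII correlation file, sorted by tau.

    A heuristic flags traces whose maximum lag exceeds 1e3 s, the usual sign
    that the file stores tau in ms rather than s.
    """
    table, _ = _parse_numeric_table(path, min_rows=1, max_cols=2)
    order = np.argsort(table[:, 0])
    table = table[order]
    if table[-1, 0] > 1e3:
        logger.warning(
            "%s: max lag time %.3g s is implausibly long; "
            "is tau perhaps in ms?", path, table[-1, 0])
    return CorrelationTrace(table[:, 0], table[:, 1], beta=beta,
                            wavelength=wavelength, angle=angle,
                            refractive_index=refractive_index,
                            label=str(path))


def write_correlation(trace: CorrelationTrace, path) -> None:
    np.savetxt(path, np.column_stack([trace.tau, trace.g2]), fmt="%.15e",
               header=f"{trace.label}\ntau[s] g2")


def read_dilution_series(path, solvent_baseline: float) -> DilutionSeries:
    """Read a 2-column (concentration wt%, count rate kHz) CSV/ASCII file."""
    table, _ = _parse_numeric_table(path, min_rows=2, max_cols=2)
    return DilutionSeries(table[:, 0], table[:, 1], solvent_baseline)


def load_sample_spec(source) -> SampleSpec:
    """Build a SampleSpec from a YAML/JSON file path or a mapping."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    if not isinstance(source, dict):
        raise ParseError(f"sample spec must be a mapping, got {type(source)}")
    return SampleSpec(**source)
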