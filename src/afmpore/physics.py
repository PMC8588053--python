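"""Physical reference models for membrane pore-size metrology.

A dialysis membrane's molecular weight cutoff (MWCO) is converted to a
theoretical pore radius by treating the largest retained solute as a solid
sphere of known density (the Stokes radius).  Measured mean pore radii are
compared against that reference through accuracy-error metrics, and a
hydrogel swelling model ``r = rp * (1 + SR)`` rescales the reference to
probe whether hydration state can explain the measured departures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

AVOGADRO = 6.02214076e23
"""Avogadro constant (1/mol), CODATA 2018 exact value."""

CM_TO_NM = 1e7


@dataclass(frozen=True)
class AccuracyErrors:
    """Deviation of a measured mean radius from its theoretical reference.

    Attributes
    ----------
    relative_percent:
        ``100 * |measured - reference| / reference`` (dimensionless, %).
    absolute_nm:
        ``|measured - reference|`` in nm, unrounded.
    """

    relative_percent: float
    absolute_nm: float

    @property
    def relative_percent_display(self) -> float:
        """Relative error rounded to three significant figures."""
        return _round_sig(self.relative_percent, 3)

    @property
    def absolute_nm_display(self) -> int:
        """Absolute error rounded to the nearest integer nanometre."""
        return int(round(self.absolute_nm))


@dataclass(frozen=True)
class SwellingScan:
    """Absolute accuracy error as a function of hypothetical swelling ratio.

    ``adjusted_radius[i] = reference * (1 + sr_grid[i])`` and
    ``abs_error[i] = |measured - adjusted_radius[i]|``.
    """

    sr_grid: np.ndarray
    adjusted_radius: np.ndarray
    abs_error: np.ndarray

    @property
    def optimal_sr(self) -> float:
        """Grid swelling ratio minimising the absolute error (lowest index on ties)."""
        return float(self.sr_grid[int(np.argmin(self.abs_error))])

    @property
    def min_error(self) -> float:
        return float(self.abs_error.min())


def stokes_radius(molecular_weight: float, density: float = 1.0) -> float:
    """Theoretical Stokes radius (nm) of a solute of given molar mass.

    The solute of molar mass ``Mw`` (g/mol) is modelled as a solid sphere
    of density ``rho`` (g/cm^3), giving ``rp = (3 Mw / (4 rho pi NA))^(1/3)``
    in cm, returned in nm.  Strictly increasing in ``Mw`` and scaling as
    ``Mw^(1/3)``.

    Parameters
    ----------
    molecular_weight:
        Molar mass in g/mol (> 0).  See :func:`stokes_radius_kda` for kDa.
    density:
        Solid-phase density in g/cm^3 (> 0), default 1.0.
    """
    if molecular_weight <= 0:
        raise ValueError(f"molecular_weight must be > 0, got {molecular_weight}")
    if density <= 0:
        raise ValueError(f"density must be > 0, got {density}")
    r_cm = (3.0 * molecular_weight / (4.0 * density * math.pi * AVOGADRO)) ** (1.0 / 3.0)
    return r_cm * CM_TO_NM


def stokes_radius_kda(molecular_weight_kda: float, density: float = 1.0) -> float:
    """Convenience wrapper of :func:`stokes_radius` taking kDa."""
    return stokes_radius(molecular_weight_kda * 1000.0, density)


def accuracy_errors(measured_mean: float, reference_radius: float) -> AccuracyErrors:
    """Relative (%) and absolute (nm) accuracy error of a measured mean radius.

    Symmetric in the absolute deviation and zero iff the measured mean
    equals the reference.  Values are carried at full precision; display
    rounding (3 significant figures for the relative error, nearest nm for
    the absolute error) is exposed on :class:`AccuracyErrors`.
    """
    if reference_radius <= 0:
        raise ValueError(f"reference_radius must be > 0, got {reference_radius}")
    if measured_mean < 0:
        raise ValueError(f"measured_mean must be >= 0, got {measured_mean}")
    dev = abs(measured_mean - reference_radius)
    return AccuracyErrors(relative_percent=100.0 * dev / reference_radius, absolute_nm=dev)


def swelling_error_scan(
    measured_mean: float, reference_radius: float, sr_grid
) -> SwellingScan:
    """Scan absolute accuracy error over a grid of hypothetical swelling ratios.

    For each fractional swelling ratio ``SR`` the theoretical radius is
    rescaled to ``reference * (1 + SR)`` — the swollen-hydrogel pore — and
    the absolute error ``|measured - adjusted|`` recorded.  The error is
    V-shaped in SR with its continuous minimum at ``SR* = measured/reference - 1``.
    """
    if reference_radius <= 0:
        raise ValueError(f"reference_radius must be > 0, got {reference_radius}")
    grid = np.asarray(sr_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("swelling-ratio grid must be non-empty")
    if np.any(grid < 0):
        raise ValueError("swelling ratios must be >= 0")
    adjusted = reference_radius * (1.0 + grid)
    return SwellingScan(
        sr_grid=grid,
        adjusted_radius=adjusted,
        abs_error=np.abs(measured_mean - adjusted),
    )


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
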