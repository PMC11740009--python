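"""Analytic building blocks for CEST Z-spectrum modelling.

This module holds the closed-form machinery shared by the simulator, the
Lorentzian decomposition and the partially synthetic data generator:

* the exchange-dependent relaxation rate ``Rex`` of a dilute solute pool in
  the rotating frame,
* the effective water relaxation rate ``Reff`` under continuous-wave
  saturation,
* the analytic full width at half maximum of the ``Rex`` lineshape,
* the Lorentzian peak used to regenerate NOE(-1.6) spectra,
* the AREX (apparent exchange-dependent relaxation) metric, and
* the acquisition offset grid and ppm <-> rad/s unit conversions.

All internal spectral math is carried out in rad/s; ppm appears only at the
I/O boundary.  Widths carry an explicit unit tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAMMA_BAR_MHZ_PER_T",
    "OffsetGrid",
    "SaturationParams",
    "PoolParams",
    "WaterParams",
    "LorentzPeak",
    "build_offset_grid",
    "rex",
    "reff",
    "peak_width",
    "lorentz_peak",
    "arex",
]

#: Proton gyromagnetic ratio over 2*pi, MHz/T.
GAMMA_BAR_MHZ_PER_T = 42.5764


class GridError(ValueError):
    """Raised when an offset-grid specification is inconsistent."""


def _ppm_to_radps(ppm, larmor_MHz: float):
    """Convert a chemical-shift offset in ppm to angular frequency (rad/s)."""
    return 2.0 * np.pi * larmor_MHz * np.asarray(ppm, dtype=float)


def _radps_to_ppm(radps, larmor_MHz: float):
    return np.asarray(radps, dtype=float) / (2.0 * np.pi * larmor_MHz)


@dataclass(frozen=True)
class OffsetGrid:
    """Saturation frequency offsets of a Z-spectrum acquisition.

    Parameters
    ----------
    offsets_ppm
        Strictly increasing saturation offsets relative to water (ppm).
        Negative offsets are upfield (the NOE side).
    field_T
        Static field strength in tesla.
    """

    offsets_ppm: np.ndarray
    field_T: float = 4.7

    def __post_init__(self) -> None:
        arr = np.asarray(self.offsets_ppm, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise GridError("offset grid must be a nonempty 1-D array")
        if not np.all(np.diff(arr) > 0):
            raise GridError("offsets must be strictly increasing")
        object.__setattr__(self, "offsets_ppm", arr)

    @property
    def larmor_MHz(self) -> float:
        return GAMMA_BAR_MHZ_PER_T * self.field_T

    @property
    def offsets_radps(self) -> np.ndarray:
        return _ppm_to_radps(self.offsets_ppm, self.larmor_MHz)

    def ppm_to_radps(self, ppm):
        return _ppm_to_radps(ppm, self.larmor_MHz)

    def radps_to_ppm(self, radps):
        return _radps_to_ppm(radps, self.larmor_MHz)

    def __len__(self) -> int:
        return int(self.offsets_ppm.size)


@dataclass(frozen=True)
class SaturationParams:
    """Continuous-wave saturation block.

    ``omega1`` is the angular RF amplitude 2*pi*gamma_bar*B1 in rad/s.
    """

    B1_uT: float = 1.0
    t_sat: float = 5.0
    t_rec: float = 2.0

    def __post_init__(self) -> None:
        if self.B1_uT < 0:
            raise ValueError("B1 must be nonnegative")
        if self.t_sat <= 0:
            raise ValueError("saturation duration must be positive")

    @property
    def omega1(self) -> float:
        return 2.0 * np.pi * GAMMA_BAR_MHZ_PER_T * self.B1_uT


@dataclass(frozen=True)
class PoolParams:
    """A dilute solute pool: size ratio, exchange/coupling rate, transverse
    relaxation rate and chemical-shift offset."""

    name: str
    fs: float
    ksw: float
    R2s: float
    delta_ppm: float
    R1s: float = 1.0

    def __post_init__(self) -> None:
        if self.fs < 0:
            raise ValueError(f"pool {self.name}: fs must be >= 0")
        if self.ksw <= 0:
            raise ValueError(f"pool {self.name}: ksw must be > 0")
        if self.R2s <= 0:
            raise ValueError(f"pool {self.name}: R2s must be > 0")


@dataclass(frozen=True)
class WaterParams:
    """Observed water longitudinal rate and water transverse rate (s^-1)."""

    R1obs: float
    R2w: float

    def __post_init__(self) -> None:
        if self.R1obs <= 0 or self.R2w <= 0:
            raise ValueError("water rates must be positive")


@dataclass(frozen=True)
class LorentzPeak:
    """A Lorentzian peak A / (1 + (dw - delta)^2 / (W/2)^2).

    ``W`` is the full width at half maximum.  ``unit`` tags whether ``W``
    (and the offsets the peak is evaluated at) are in ppm or rad/s; amplitude
    is s^-1 for AREX-domain peaks and dimensionless for Z-domain peaks.
    """

    A: float
    W: float
    delta_ppm: float
    unit: str = "ppm"

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError("amplitude must be >= 0")
        if self.W <= 0:
            raise ValueError("width must be > 0")
        if self.unit not in ("ppm", "radps"):
            raise ValueError("unit must be 'ppm' or 'radps'")


def build_offset_grid(
    fine_step_ppm: float,
    coarse_step_ppm: float,
    fine_range: tuple[float, float],
    full_range: tuple[float, float],
    field_T: float = 4.7,
) -> OffsetGrid:
    """Union of a fine inner grid and a coarse outer grid of offsets.

    The default acquisition uses 0.125 ppm steps on [-5, 5] ppm and 1.25 ppm
    steps on the remainder of [-10, 10] ppm, for 89 offsets in total.

    Raises
    ------
    GridError
        If a step does not divide its range evenly, or the fine range is not
        contained in the full range.
    """

    flo, fhi = map(float, fine_range)
    lo, hi = map(float, full_range)
    if not (lo <= flo < fhi <= hi):
        raise GridError("fine range must be contained in the full range")
    for step, (a, b) in ((fine_step_ppm, (flo, fhi)), (coarse_step_ppm, (lo, hi))):
        if step <= 0:
            raise GridError("steps must be positive")
        n = (b - a) / step
        if abs(n - round(n)) > 1e-9:
            raise GridError(f"step {step} does not divide range [{a}, {b}] evenly")
    fine = np.linspace(flo, fhi, round((fhi - flo) / fine_step_ppm) + 1)
    coarse = np.linspace(lo, hi, round((hi - lo) / coarse_step_ppm) + 1)
    offsets = np.unique(np.round(np.concatenate([fine, coarse]), 9))
    return OffsetGrid(offsets_ppm=offsets, field_T=field_T)


def rex(pool: PoolParams, sat: SaturationParams, dw_radps, larmor_MHz: float):
    """Exchange-dependent relaxation rate of a solute pool (s^-1).

    ``Rex(dw) = fs*ksw*w1^2 / (w1^2 + (R2s+ksw)*ksw + (dw-delta)^2*ksw/(R2s+ksw))``
    with ``dw`` the saturation offset in rad/s.  Maximal at the pool centre.
    """

    w1 = sat.omega1
    delta = _ppm_to_radps(pool.delta_ppm, larmor_MHz)
    d = np.asarray(dw_radps, dtype=float) - delta
    rk = pool.R2s + pool.ksw
    denom = w1**2 + rk * pool.ksw + d**2 * pool.ksw / rk
    return pool.fs * pool.ksw * w1**2 / denom


def reff(water: WaterParams, sat: SaturationParams, dw_radps):
    """Effective water relaxation rate under CW saturation (s^-1).

    A convex combination of R1obs and R2w weighted by the tilt of the
    effective field: ``R1obs*dw^2/(w1^2+dw^2) + R2w*w1^2/(w1^2+dw^2)``.
    """

    w1 = sat.omega1
    dw = np.asarray(dw_radps, dtype=float)
    denom = w1**2 + dw**2
    if w1 == 0 and np.any(dw == 0):
        raise ZeroDivisionError("Reff undefined at dw = 0 with omega1 = 0")
    return (water.R1obs * dw**2 + water.R2w * w1**2) / denom


def peak_width(pool: PoolParams, sat: SaturationParams) -> float:
    """Analytic FWHM (rad/s) of the Rex lineshape.

    ``W = 2*sqrt(w1^2*(R2s+ksw)/ksw + (R2s+ksw)^2)``; increases with both
    saturation amplitude and solute linewidth.  Use
    :meth:`OffsetGrid.radps_to_ppm` to express it in ppm.
    """

    if pool.ksw == 0:
        raise ZeroDivisionError("peak width undefined for ksw = 0")
    rk = pool.R2s + pool.ksw
    return 2.0 * np.sqrt(sat.omega1**2 * rk / pool.ksw + rk**2)


def lorentz_peak(peak: LorentzPeak, dw):
    """Evaluate ``A / (1 + (dw - delta)^2/(0.5 W)^2)`` at offsets ``dw``.

    ``dw`` must be in the unit carried by ``peak`` (ppm by default).
    """

    d = np.asarray(dw, dtype=float) - peak.delta_ppm
    return peak.A / (1.0 + d**2 / (0.5 * peak.W) ** 2)


def arex(z_lab, z_ref, R1obs: float, fm: float = 0.0, mt_correction: bool = True):
    """AREX metric ``R1obs * (1/z_lab - 1/z_ref)``, optionally ``*(1+fm)``.

    Inversely subtracts the label from the reference signal with T1obs
    normalisation, isolating an exchange-mediated rate in s^-1.
    """

    zl = np.asarray(z_lab, dtype=float)
    zr = np.asarray(z_ref, dtype=float)
    if np.any(zl <= 0) or np.any(zr <= 0):
        raise ValueError("Z values must be positive for the AREX metric")
    out = R1obs * (1.0 / zl - 1.0 / zr)
    if mt_correction:
        out = out * (1.0 + fm)
    return out
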