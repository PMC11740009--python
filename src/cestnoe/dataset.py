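"""Labeled Z-spectrum samples and array stacking shared by the data generators.

Both the Bloch–McConnell generator and the partially synthetic generator emit
:class:`Sample` records — a Z-spectrum plus its analytic ground-truth
NOE(-1.6) amplitude and width — so the regressor training code can consume
either interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .core import OffsetGrid

__all__ = ["ZSpectrum", "Sample", "stack_samples"]


@dataclass
class ZSpectrum:
    """A normalized Z-spectrum S/S0 with its quantification side-channel.

    ``R1obs`` (s^-1) and the semi-solid pool size ratio ``fm`` travel with the
    spectrum because both the AREX metric and the regressor input need them.
    """

    grid: OffsetGrid
    z: np.ndarray
    R1obs: float
    fm: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (len(self.grid),):
            raise ValueError("z must have one value per grid offset")

    def validate(self) -> None:
        """Range check used at I/O boundaries (noise may push z slightly >1)."""
        if not np.all(np.isfinite(self.z)):
            raise ValueError("non-finite z values")
        if np.any(self.z <= 0) or np.any(self.z > 1.05):
            raise ValueError("z values outside (0, 1.05]")


@dataclass
class Sample:
    """A training/testing record: spectrum plus ground-truth peak parameters.

    ``target_A`` is the NOE(-1.6) amplitude in s^-1 (AREX domain), ``target_W``
    the full width at half maximum in ppm, both computed analytically with the
    B0 shift set to zero.
    """

    zspec: ZSpectrum
    target_A: float
    target_W: float
    params: dict[str, Any] = field(default_factory=dict)


def stack_samples(samples: list[Sample]) -> dict[str, np.ndarray]:
    """Stack samples into dense arrays (all must share one offset grid)."""

    if not samples:
        raise ValueError("no samples to stack")
    grid = samples[0].zspec.grid
    for s in samples:
        if len(s.zspec.grid) != len(grid) or not np.allclose(
            s.zspec.grid.offsets_ppm, grid.offsets_ppm
        ):
            raise ValueError("samples do not share one offset grid")
    return {
        "offsets_ppm": grid.offsets_ppm,
        "field_T": np.float64(grid.field_T),
        "z": np.stack([s.zspec.z for s in samples]),
        "R1obs": np.array([s.zspec.R1obs for s in samples]),
        "fm": np.array([s.zspec.fm for s in samples]),
        "target_A": np.array([s.target_A for s in samples]),
        "target_W": np.array([s.target_W for s in samples]),
    }
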