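"""Phase difference and conversion of unwrapped phase to physical height.

The specimen's optical path difference appears as the phase difference
Δφ = φ_O − φ_R between the object and reference reconstructions.  In
transmission geometry with refractive-index contrast Δn, an unwrapped Δφ maps
linearly to height:

    h(x, y) = Δφ(x, y) / (K · Δn),   K = 2π/λ

with h in micrometres when λ is in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from dhmkit.simulate import OpticalConstants

__all__ = [
    "PhaseMap",
    "HeightMap",
    "phase_difference",
    "phase_to_height",
    "flatten_background",
]


@dataclass
class PhaseMap:
    """2D phase array in radians.

    ``wrapped`` flags values restricted to (−π, π]; ``provenance`` records
    whether the map came from the object arm, the reference arm, or their
    difference.
    """

    values: np.ndarray
    wrapped: bool
    provenance: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ValueError("phase map must be 2D")
        self.values = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class HeightMap:
    """2D height array in micrometres, plus the optical constants used."""

    values: np.ndarray
    constants: "OpticalConstants | None" = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ValueError("height map must be 2D")
        if not np.all(np.isfinite(arr)):
            raise ValueError("height map must be finite")
        self.values = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def phase_difference(object_phase: PhaseMap, reference_phase: PhaseMap) -> PhaseMap:
    """Wrapped phase difference Δφ = φ_O − φ_R.

    The element-wise difference is rewrapped into (−π, π]; the linear carrier
    residual common to both arms cancels exactly.
    """
    if object_phase.shape != reference_phase.shape:
        raise ValueError(
            f"shape mismatch: object {object_phase.shape} vs "
            f"reference {reference_phase.shape}"
        )
    if not (object_phase.wrapped and reference_phase.wrapped):
        raise ValueError("phase_difference expects wrapped inputs")
    from dhmkit.unwrap import wrap

    delta = wrap(object_phase.values - reference_phase.values)
    return PhaseMap(values=delta, wrapped=True, provenance="difference")


def phase_to_height(delta_phase: PhaseMap, constants: "OpticalConstants") -> HeightMap:
    """Convert an unwrapped phase difference to height: h = Δφ / (K·Δn)."""
    if delta_phase.wrapped:
        raise ValueError("phase_to_height requires an unwrapped phase map; unwrap first")
    if constants.delta_n == 0:
        raise ValueError("refractive-index difference Δn must be nonzero")
    h = delta_phase.values / (constants.wavenumber * constants.delta_n)
    return HeightMap(values=h, constants=constants)


def flatten_background(height: HeightMap, margin: int = 8) -> HeightMap:
    """Remove the global height offset using a border background region.

    Subtracts the median of an all-around border of ``margin`` pixels, the
    usual flattening step before comparing reconstructions: it removes both
    the unwrapper's arbitrary global 2π·k offset and any residual piston.
    """
    if margin < 1:
        raise ValueError("margin must be >= 1")
    rows, cols = height.shape
    if 2 * margin >= min(rows, cols):
        raise ValueError(f"margin {margin} too large for shape {height.shape}")
    mask = np.zeros((rows, cols), dtype=bool)
    mask[:margin, :] = True
    mask[-margin:, :] = True
    mask[:, :margin] = True
    mask[:, -margin:] = True
    offset = float(np.median(height.values[mask]))
    return HeightMap(values=height.values - offset, constants=height.constants)
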