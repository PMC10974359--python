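"""Frequency-domain sideband processing of off-axis holograms.

The Fourier transform of an off-axis hologram splits into a central DC lobe
(|R|² + |O|²) and two conjugate sidebands (the R*O and RO* cross terms) offset
by the carrier frequency.  Cropping one sideband, re-centering it in a zero
array of the original resolution (the "Fourier shift" / zero-padding step) and
inverse transforming demodulates the carrier and yields the complex object
field at full resolution; its argument is the wrapped phase map.

FFT normalization: unnormalized forward, 1/N² inverse (numpy's default), so
Parseval reads  Σ|spectrum|²/N² = Σ|image|².  The DC bin of a centered
spectrum of an (V, H) image sits at (⌊V/2⌋, ⌊H/2⌋).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dhmkit.height import PhaseMap
from dhmkit.simulate import Hologram

__all__ = [
    "Spectrum",
    "SidebandWindow",
    "forward_spectrum",
    "locate_sideband",
    "window_and_pad",
    "extract_phase",
    "inverse_field",
]


@dataclass
class Spectrum:
    """DC-centered complex 2D spectrum of a hologram."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise ValueError("spectrum must be 2D")
        self.values = arr.astype(complex)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def dc_index(self) -> tuple[int, int]:
        """Index of the DC bin: (⌊V/2⌋, ⌊H/2⌋)."""
        return (self.shape[0] // 2, self.shape[1] // 2)


@dataclass(frozen=True)
class SidebandWindow:
    """Square crop window around a sideband, in centered-frequency offsets.

    ``center`` is the sideband position relative to the DC bin,
    (row offset, col offset); ``half_width`` w gives a (2w+1)² block.
    """

    center: tuple[int, int]
    half_width: int

    def __post_init__(self) -> None:
        if self.half_width < 1:
            raise ValueError("window half-width must be >= 1")


def forward_spectrum(hologram: Hologram | np.ndarray) -> Spectrum:
    """Centered 2D DFT of a real hologram."""
    image = hologram.intensity if isinstance(hologram, Hologram) else np.asarray(hologram)
    if image.ndim != 2:
        raise ValueError(f"expected 2D input, got ndim={image.ndim}")
    return Spectrum(np.fft.fftshift(np.fft.fft2(image)))


def locate_sideband(
    spectrum: Spectrum, dc_exclusion_radius: float
) -> tuple[int, int]:
    """Find the positive sideband: the magnitude maximum outside the DC lobe.

    The search is restricted to the upper half-plane in centered coordinates
    (row offset < 0, or row offset == 0 and column offset > 0), which picks
    one of the two conjugate sidebands deterministically; the other is its
    point reflection through DC.  Raises if no bin outside the exclusion disk
    rises above mean + 6·std of the out-of-disk magnitudes (e.g. a constant
    image has no sideband).

    Returns the (row offset, col offset) of the sideband relative to DC.
    """
    rows, cols = spectrum.shape
    if dc_exclusion_radius >= min(rows, cols) / 2:
        raise ValueError("DC exclusion radius must be smaller than half the array extent")
    cr, cc = spectrum.dc_index
    mag = np.abs(spectrum.values)

    dr = np.arange(rows)[:, None] - cr
    dc = np.arange(cols)[None, :] - cc
    outside_dc = dr**2 + dc**2 > dc_exclusion_radius**2

    out_vals = mag[outside_dc]
    threshold = out_vals.mean() + 6.0 * out_vals.std()
    upper_half = (dr < 0) | ((dr == 0) & (dc > 0))
    candidates = outside_dc & upper_half
    cand_mag = np.where(candidates, mag, -np.inf)
    peak = float(cand_mag.max())
    if peak <= threshold:
        raise ValueError("no sideband found: no off-DC bin exceeds mean + 6 std")
    # ties: larger magnitude first (by construction), then lexicographic (row, col)
    idx = np.argwhere(cand_mag == peak)
    r, c = idx[np.lexsort((idx[:, 1], idx[:, 0]))][0]
    return (int(r - cr), int(c - cc))


def window_and_pad(spectrum: Spectrum, window: SidebandWindow) -> Spectrum:
    """Crop a sideband block and re-center it on the DC bin of a zero array.

    The output has the source resolution; the (2w+1)×(2w+1) block around the
    sideband center is copied so that the sideband center lands exactly on the
    DC bin, demodulating the carrier on inverse transform.  All other entries
    are exactly zero.  Raises if the window overlaps the array edge (never
    silently truncates).
    """
    rows, cols = spectrum.shape
    cr, cc = spectrum.dc_index
    sr = cr + window.center[0]
    sc = cc + window.center[1]
    w = window.half_width
    if sr - w < 0 or sr + w >= rows or sc - w < 0 or sc + w >= cols:
        raise ValueError(
            f"window (center offset {window.center}, half-width {w}) "
            f"overlaps the spectrum edge for shape {spectrum.shape}"
        )
    out = np.zeros_like(spectrum.values)
    block = spectrum.values[sr - w : sr + w + 1, sc - w : sc + w + 1]
    out[cr - w : cr + w + 1, cc - w : cc + w + 1] = block
    return Spectrum(out)


def inverse_field(spectrum: Spectrum) -> np.ndarray:
    """Inverse FFT of a centered spectrum back to a complex spatial field."""
    return np.fft.ifft2(np.fft.ifftshift(spectrum.values))


def extract_phase(spectrum: Spectrum) -> PhaseMap:
    """Wrapped phase of the spatial field behind a windowed spectrum.

    Inverse transforms to the complex field and takes the four-quadrant
    arctangent of (imaginary, real) per pixel, giving values in (−π, π].
    """
    if not np.any(spectrum.values):
        raise ValueError("cannot extract phase from an all-zero spectrum")
    field = inverse_field(spectrum)
    phase = np.angle(field)
    # np.angle returns [-π, π]; fold the closed lower end onto +π
    phase[phase == -np.pi] = np.pi
    return PhaseMap(values=phase, wrapped=True)
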