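"""Synthetic off-axis holograms from a known ground-truth height map.

An off-axis hologram is the intensity of the coherent sum of an object wave
``O = A_o·exp(-j·φ_o)`` and a tilted reference wave
``R = A_r·exp(-j·2π(f_x·x + f_y·y))``:

    I(x, y) = |R + O|² = |R|² + |O|² + R*O + RO*

The two cross terms are the positive and negative sidebands in the Fourier
domain; the carrier frequency ``(f_x, f_y)`` (cycles/pixel) sets their distance
from the DC lobe.  The object phase encodes specimen height in transmission
geometry, ``φ_o = K·Δn·h`` with wavenumber ``K = 2π/λ`` and refractive-index
contrast ``Δn``, so a reconstruction pipeline run on these holograms can be
checked against the exact input height map.

Coordinates are 0-based and row-major: ``x`` is the column index, ``y`` the
row index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "OpticalConstants",
    "SimConfig",
    "HeightPhantom",
    "Hologram",
    "make_microsphere_phantom",
    "synthesize_hologram",
    "add_sensor_noise",
]


@dataclass(frozen=True)
class OpticalConstants:
    """Optical parameters of the microscope.

    Parameters
    ----------
    wavelength_um
        Laser wavelength λ in micrometres (default: 532 nm green laser).
    n_object, n_medium
        Refractive index of the specimen and of the surrounding medium;
        their difference Δn converts phase to physical height.
    n_air
        Refractive index of air (informational only).
    pixel_pitch_um
        Lateral sampling at the sensor, micrometres per pixel.
    magnification
        Objective magnification M; applied to the lateral pixel pitch only
        (``pixel_pitch_um / M``), heights are unaffected.
    """

    wavelength_um: float = 0.532
    n_object: float = 1.59
    n_medium: float = 1.53
    n_air: float = 1.0
    pixel_pitch_um: float = 0.1
    magnification: float = 1.0

    def __post_init__(self) -> None:
        if self.wavelength_um <= 0:
            raise ValueError(f"wavelength must be positive, got {self.wavelength_um}")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")

    @property
    def wavenumber(self) -> float:
        """Wavenumber K = 2π/λ in rad/μm."""
        return 2.0 * math.pi / self.wavelength_um

    @property
    def delta_n(self) -> float:
        """Refractive-index difference Δn = n_object − n_medium."""
        return self.n_object - self.n_medium

    @property
    def lateral_pitch_um(self) -> float:
        """Pixel pitch at the specimen plane: pixel_pitch / magnification."""
        return self.pixel_pitch_um / self.magnification


@dataclass(frozen=True)
class SimConfig:
    """Hologram synthesis settings.

    ``carrier`` is the reference-tilt spatial frequency (f_x, f_y) in
    cycles/pixel; both components must satisfy Nyquist (|f| < 0.5).
    ``noise_sigma`` is the standard deviation of additive Gaussian sensor
    noise on the recorded intensity.

    ``amplitude_texture`` adds a smooth multiplicative transmittance field
    (RMS fraction of A_o, correlation length ``texture_corr_px`` pixels) to
    the object-arm amplitude in both recordings.  A perfectly constant
    amplitude makes the DC term of the hologram a pure spectral delta; real
    specimens and optics scatter and absorb unevenly, which spreads the DC
    lobe and leaks structured error into wide sideband windows — the noise
    source that multi-window variance fusion targets.  Default 0 (clean
    analytic model); see :data:`NOISY_STUDY` for the noisy study conditions.
    """

    carrier: tuple[float, float] = (0.2, 0.0)
    amp_object: float = 1.0
    amp_reference: float = 1.0
    noise_sigma: float = 0.0
    amplitude_texture: float = 0.0
    texture_corr_px: float = 3.0
    shape: tuple[int, int] = (256, 256)  # (rows, cols)
    seed: int = 0

    def __post_init__(self) -> None:
        fx, fy = self.carrier
        if abs(fx) >= 0.5 or abs(fy) >= 0.5:
            raise ValueError(f"carrier {self.carrier} violates Nyquist (|f| < 0.5)")
        if self.amp_object <= 0 or self.amp_reference <= 0:
            raise ValueError("wave amplitudes must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.amplitude_texture < 0 or self.texture_corr_px <= 0:
            raise ValueError("invalid amplitude texture parameters")


#: noisy study conditions for denoising experiments: 2% full-scale sensor
#: noise (intensity range is [0, 4] at unit amplitudes) plus 30% RMS
#: transmittance texture with 0.3 μm correlation length at the default
#: 0.1 μm/px sampling
NOISY_STUDY = {
    "noise_sigma": 0.08,
    "amplitude_texture": 0.3,
    "texture_corr_px": 3.0,
}


@dataclass
class HeightPhantom:
    """Ground-truth height map in micrometres plus provenance metadata."""

    height: np.ndarray
    pixel_pitch_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        h = np.asarray(self.height, dtype=float)
        if not np.all(np.isfinite(h)):
            raise ValueError("phantom heights must be finite")
        if np.any(h < 0):
            raise ValueError("phantom heights must be non-negative")
        self.height = h


@dataclass
class Hologram:
    """Recorded interferogram: 2D real intensity with optical metadata."""

    intensity: np.ndarray
    constants: OpticalConstants | None = None
    config: SimConfig | None = None
    kind: str = "object"  # "object" | "reference"

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity, dtype=float)
        if arr.ndim != 2:
            raise ValueError("hologram intensity must be 2D")
        self.intensity = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


def make_microsphere_phantom(
    shape: tuple[int, int],
    pixel_pitch_um: float,
    diameter_um: float,
    centers_um: Sequence[tuple[float, float]],
) -> HeightPhantom:
    """Height map of transparent microspheres resting on the substrate.

    A sphere of diameter D contributes its chord length
    ``h(ρ) = 2·sqrt((D/2)² − ρ²)`` for radial distance ρ < D/2 from its
    center, 0 elsewhere, so peak height and support width both equal D.
    Overlapping spheres take the pointwise maximum.

    Parameters
    ----------
    shape
        Grid size (rows, cols).
    pixel_pitch_um
        Lateral pixel pitch in μm/pixel.
    diameter_um
        Sphere diameter D in μm.
    centers_um
        Sphere centers as (x, y) in μm (x along columns, y along rows).
        May be empty, yielding an all-zero map.
    """
    if diameter_um <= 0:
        raise ValueError(f"diameter must be positive, got {diameter_um}")
    rows, cols = shape
    extent_x = (cols - 1) * pixel_pitch_um
    extent_y = (rows - 1) * pixel_pitch_um
    for cx, cy in centers_um:
        if not (0.0 <= cx <= extent_x and 0.0 <= cy <= extent_y):
            raise ValueError(
                f"sphere center ({cx}, {cy}) μm lies outside the "
                f"{extent_x:.3g} x {extent_y:.3g} μm grid"
            )

    x = np.arange(cols) * pixel_pitch_um
    y = np.arange(rows) * pixel_pitch_um
    xx, yy = np.meshgrid(x, y)
    radius = diameter_um / 2.0
    height = np.zeros(shape, dtype=float)
    for cx, cy in centers_um:
        rho2 = (xx - cx) ** 2 + (yy - cy) ** 2
        chord = 2.0 * np.sqrt(np.clip(radius**2 - rho2, 0.0, None))
        np.maximum(height, chord, out=height)
    return HeightPhantom(
        height=height,
        pixel_pitch_um=pixel_pitch_um,
        meta={
            "kind": "microsphere",
            "diameter_um": diameter_um,
            "centers_um": [tuple(c) for c in centers_um],
        },
    )


def _reference_wave(shape: tuple[int, int], carrier: tuple[float, float], amp: float) -> np.ndarray:
    rows, cols = shape
    fx, fy = carrier
    x = np.arange(cols)
    y = np.arange(rows)
    xx, yy = np.meshgrid(x, y)
    return amp * np.exp(-2j * math.pi * (fx * xx + fy * yy))


def synthesize_hologram(
    phantom: HeightPhantom,
    constants: OpticalConstants,
    config: SimConfig,
) -> tuple[Hologram, Hologram]:
    """Record an object/reference hologram pair from a height phantom.

    The object wave carries the specimen phase ``φ_o = K·Δn·h``; the reference
    hologram is recorded with the specimen removed (h ≡ 0) under the same
    tilted reference wave.  If ``config.noise_sigma > 0``, independent
    additive Gaussian sensor noise is applied to both recordings, seeded from
    ``config.seed``.
    """
    if constants.delta_n == 0:
        raise ValueError("refractive-index difference Δn must be nonzero")
    if phantom.height.shape != tuple(config.shape):
        raise ValueError(
            f"phantom shape {phantom.height.shape} != config shape {config.shape}"
        )

    ref_wave = _reference_wave(config.shape, config.carrier, config.amp_reference)
    phi_o = constants.wavenumber * constants.delta_n * phantom.height

    amp = config.amp_object
    if config.amplitude_texture > 0:
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(config.seed + 2)
        field = gaussian_filter(rng.standard_normal(config.shape), config.texture_corr_px,
                                mode="wrap")
        field *= config.amplitude_texture / field.std()
        amp = np.clip(config.amp_object * (1.0 + field), 0.05 * config.amp_object, None)

    obj_wave = amp * np.exp(-1j * phi_o)
    flat_wave = (amp if np.ndim(amp) else np.full(config.shape, amp)).astype(complex)

    holo_obj = np.abs(ref_wave + obj_wave) ** 2
    holo_ref = np.abs(ref_wave + flat_wave) ** 2

    obj = Hologram(holo_obj, constants=constants, config=config, kind="object")
    ref = Hologram(holo_ref, constants=constants, config=config, kind="reference")
    if config.noise_sigma > 0:
        obj = add_sensor_noise(obj, config.noise_sigma, seed=config.seed)
        ref = add_sensor_noise(ref, config.noise_sigma, seed=config.seed + 1)
    return obj, ref


def add_sensor_noise(hologram: Hologram, sigma: float, seed: int) -> Hologram:
    """Add zero-mean Gaussian intensity noise, clipped at zero counts.

    Reproducible: the same seed yields bit-identical output.
    """
    if sigma < 0:
        raise ValueError(f"noise sigma must be non-negative, got {sigma}")
    if sigma == 0:
        return hologram
    rng = np.random.default_rng(seed)
    noisy = hologram.intensity + rng.normal(0.0, sigma, size=hologram.shape)
    np.clip(noisy, 0.0, None, out=noisy)
    return Hologram(noisy, constants=hologram.constants, config=hologram.config, kind=hologram.kind)
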