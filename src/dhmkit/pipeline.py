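"""End-to-end single-window reconstruction: hologram pair -> height map.

Chains the standard off-axis steps: forward FFT, sideband location, window +
zero-pad recentering, inverse FFT, phase difference between the object and
reference arms, Goldstein unwrapping, and conversion to physical height.
"""

from __future__ import annotations

import numpy as np

from dhmkit.fourier import (
    SidebandWindow,
    Spectrum,
    extract_phase,
    forward_spectrum,
    inverse_field,
    locate_sideband,
    window_and_pad,
)
from dhmkit.height import HeightMap, flatten_background, phase_difference, phase_to_height
from dhmkit.simulate import Hologram, OpticalConstants
from dhmkit.unwrap import goldstein_unwrap

__all__ = ["reconstruct_height", "reconstruct_phase_difference"]


def reconstruct_phase_difference(
    object_holo: Hologram,
    reference_holo: Hologram,
    half_width: int,
    dc_exclusion_radius: float = 10.0,
    sideband_center: tuple[int, int] | None = None,
):
    """Unwrapped phase difference Δφ for one sideband window size.

    Both holograms are windowed at the *same* sideband center (located on the
    object spectrum unless given) so the carrier cancels in the difference.
    The unwrapping seed is the pixel where the demodulated object field has
    maximum magnitude — the best-modulated, most trustworthy pixel.
    """
    spec_obj = forward_spectrum(object_holo)
    spec_ref = forward_spectrum(reference_holo)
    if sideband_center is None:
        sideband_center = locate_sideband(spec_obj, dc_exclusion_radius)
    window = SidebandWindow(center=sideband_center, half_width=half_width)

    win_obj = window_and_pad(spec_obj, window)
    win_ref = window_and_pad(spec_ref, window)
    phase_obj = extract_phase(win_obj)
    phase_ref = extract_phase(win_ref)
    quality = np.abs(inverse_field(win_obj))

    delta = phase_difference(phase_obj, phase_ref)
    return goldstein_unwrap(delta, quality=quality), sideband_center


def reconstruct_height(
    object_holo: Hologram,
    reference_holo: Hologram,
    constants: OpticalConstants,
    half_width: int,
    dc_exclusion_radius: float = 10.0,
    sideband_center: tuple[int, int] | None = None,
    sign: str = "auto",
    flatten_margin: int | None = 8,
) -> HeightMap:
    """Reconstruct the specimen height map from an object/reference pair.

    Parameters
    ----------
    half_width
        Sideband window half-width w in pixels; the crop is (2w+1)².
    sign
        Which of the two conjugate sidebands was windowed is an arbitrary
        convention, and the conjugate choice negates the reconstructed
        height.  ``"auto"`` (default) flips the sign when the dominant
        extremum after background flattening is negative — appropriate for
        specimens that protrude from the substrate; ``"raw"`` keeps the map
        as reconstructed.
    flatten_margin
        Border width (pixels) whose median height is subtracted (removes the
        unwrapper's global 2π offset and residual piston); ``None`` skips it.
    """
    if sign not in ("auto", "raw"):
        raise ValueError(f"unknown sign convention {sign!r}")
    delta_unwrapped, _ = reconstruct_phase_difference(
        object_holo,
        reference_holo,
        half_width,
        dc_exclusion_radius=dc_exclusion_radius,
        sideband_center=sideband_center,
    )
    height = phase_to_height(delta_unwrapped, constants)
    if flatten_margin is not None:
        height = flatten_background(height, margin=flatten_margin)
    if sign == "auto":
        v = height.values
        if abs(float(v.min())) > abs(float(v.max())):
            height = HeightMap(values=-v, constants=height.constants)
    return height
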