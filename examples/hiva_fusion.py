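"""HiVA multi-window variance fusion on a noisy simulated microsphere.

Reconstructs one noisy hologram pair at ten increasing sideband window sizes,
fuses the stack by log-variance thresholding, and compares the result with
the unfiltered widest-window map and a Gaussian σ=2 baseline, scored against
the ideal microsphere reference.
"""

import numpy as np

from dhmkit import (
    NOISY_STUDY,
    HeightMap,
    OpticalConstants,
    SimConfig,
    default_half_widths,
    forward_spectrum,
    gaussian_baseline,
    hiva_fuse,
    ideal_microsphere_reference,
    locate_sideband,
    make_microsphere_phantom,
    psnr,
    reconstruct_stack,
    ssim,
    stack_mean_variance,
    synthesize_hologram,
)

shape, pitch = (256, 256), 0.1
constants = OpticalConstants(pixel_pitch_um=pitch)
phantom = make_microsphere_phantom(shape, pitch, 10.0, [(12.8, 12.8)])
config = SimConfig(carrier=(0.2, 0.0), shape=shape, seed=1, **NOISY_STUDY)
obj, ref = synthesize_hologram(phantom, constants, config)

# window schedule: from narrow to the widest window that clears the DC lobe
center = locate_sideband(forward_spectrum(obj), dc_exclusion_radius=10)
distance = max(abs(center[0]), abs(center[1]))
widths = default_half_widths(distance, dc_radius=10)
print(f"DC-sideband distance: {distance} bins; window half-widths: {widths}")

stack = reconstruct_stack(obj, ref, widths, constants)
stats = stack_mean_variance(stack)
fused = hiva_fuse(stack, stats, mode="log_variance")

reference = ideal_microsphere_reference(10.0, shape, pitch)
maps = {
    "unfiltered (widest window)": stack.widest,
    "Gaussian sigma=2 baseline ": gaussian_baseline(HeightMap(stack.widest), 2.0).values,
    "HiVA log-variance fusion  ": fused.values,
}
print(f"{'method':28s}  SSIM    PSNR [dB]  peak [um]")
for name, values in maps.items():
    print(
        f"{name:28s}  {ssim(values, reference):.4f}  {psnr(values, reference):8.2f}"
        f"  {values.max():8.3f}"
    )
# High-variance pixels (noise that changes with window size) take the stack
# mean; stable pixels keep the widest window's full detail.  The fused map
# removes structured DC-leakage noise a fixed blur cannot target.
print(f"fraction of pixels averaged: {np.mean(np.log(stats.variance + 1e-300) >= stats.m_lv):.2f}")
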