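"""Simulate a noise-free 10 μm microsphere hologram and reconstruct its height.

Builds the forward model (object/reference interferogram pair at a 0.2
cycles/px carrier), then runs the standard off-axis pipeline: FFT, sideband
windowing, carrier demodulation, Goldstein unwrapping and phase-to-height
conversion.  With no noise, the recovered peak should match the 10 μm ground
truth to a small fraction of a percent.
"""

from dhmkit import (
    OpticalConstants,
    SimConfig,
    make_microsphere_phantom,
    reconstruct_height,
    synthesize_hologram,
)

shape, pitch = (256, 256), 0.1  # 25.6 μm field of view at 0.1 μm/px
constants = OpticalConstants(pixel_pitch_um=pitch)  # 532 nm laser, Δn = 0.06

phantom = make_microsphere_phantom(shape, pitch, diameter_um=10.0, centers_um=[(12.8, 12.8)])
config = SimConfig(carrier=(0.2, 0.0), shape=shape, noise_sigma=0.0)
obj, ref = synthesize_hologram(phantom, constants, config)

height = reconstruct_height(obj, ref, constants, half_width=40)

peak = height.values.max()
truth = phantom.height.max()
print(f"ground-truth peak height : {truth:.4f} um")
print(f"reconstructed peak height: {peak:.4f} um")
print(f"relative error           : {100 * abs(peak - truth) / truth:.4f} %")
# The error is pure discretization: the sideband window passes all of the
# sphere's significant spatial frequencies, so the pipeline inverts the
# forward model almost exactly.
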