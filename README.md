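# dhmkit

Quantitative 3D surface profiling for **off-axis digital holographic
microscopy (DHM)**: synthetic hologram generation, Fourier sideband
reconstruction, Goldstein phase unwrapping, **HiVA** multi-window
variance-fusion denoising, a desk-scale **conditional diffusion (DDPM)**
denoiser, and PSNR/SSIM evaluation against an ideal microsphere reference.

DHM records the interference pattern of an object wave and a tilted
reference wave; a single exposure carries the full complex field. Windowing
one Fourier sideband, re-centering it (zero-padding / Fourier shift) and
inverse transforming yields the wrapped phase; unwrapping and the relation

    h(x, y) = Δφ(x, y) / (K · Δn),     K = 2π/λ

convert the object/reference phase difference Δφ = φ_O − φ_R into physical
height (Δn is the specimen/medium refractive-index contrast). The window
size is a trade-off: wide windows keep detail but admit structured error
from the DC lobe, narrow ones suppress it but blur. HiVA reconstructs at Nd
increasing window sizes, forms per-pixel mean S and variance V across the
stack, and keeps the widest-window value where V is below its spatial
(log-)mean while averaging noise-dominated pixels — detail preservation and
denoising at once, provided the sideband sits far enough from DC. For the
regime where it does not, a small conditional diffusion model trained on
(noisy, HiVA-cleaned) pairs learns the denoising instead.

The package is aimed at quantitative-phase-imaging researchers who want a
tested, fully synthetic-verifiable implementation of this pipeline: every
stage can be exercised against a known ground-truth height map, no
microscope required.

## Worked example

A noise-free 10 μm polystyrene microsphere (λ = 532 nm, Δn = 0.06,
0.1 μm/px) simulated and reconstructed end-to-end
(`python examples/reconstruct_microsphere.py`):

```
ground-truth peak height : 10.0000 um
reconstructed peak height: 9.9994 um
relative error           : 0.0059 %
```

The same scene under the noisy study conditions (2% sensor noise plus
specimen transmittance texture), denoised three ways and scored against the
ideal sphere (`python examples/hiva_fusion.py`):

```
DC-sideband distance: 51 bins; window half-widths: (8, 12, 15, 19, 22, 26, 29, 33, 36, 40)
method                        SSIM    PSNR [dB]  peak [um]
unfiltered (widest window)    0.9196     36.59    10.349
Gaussian sigma=2 baseline     0.9633     38.95    10.055
HiVA log-variance fusion      0.9518     39.56    10.107
```

HiVA removes the most energy (best PSNR) while keeping the widest window's
detail; see `docs/methods.md` for why a plain blur can still edge it on SSIM
for perfectly smooth synthetic spheres.

Desk-scale conditional diffusion training
(`python examples/conditional_diffusion.py`):

```
parameters               : 14369
running loss (start)     : 0.3772
running loss (end)       : 0.0372
held-out MSE, noisy input: 0.6287 um^2
held-out MSE, denoised   : 0.1197 um^2
MSE reduction factor     : 5.3x
```

`python examples/benchmark_table.py` reprints the bundled 20-image benchmark
score table and its column means.

## Command line

A thin CLI wraps the library for shell workflows:

```bash
dhmkit simulate --phantom microsphere --diameter 10 --carrier 0.2,0 \
       --noise 0.08 --texture 0.3 --seed 1 --out run/
dhmkit reconstruct --object run/object.tiff --reference run/reference.tiff \
       --half-width 40 --out run/rec/
dhmkit hiva --object run/object.tiff --reference run/reference.tiff --out run/hiva/
dhmkit evaluate --heights hiva=run/hiva/hiva.npy --diameter 10 --out run/eval/
```

Images are 32-bit float TIFF/NPY with YAML sidecars; reports are
deterministic JSON (same config and seed → byte-identical). `dhmkit hiva`
exits non-zero with a clear message when the carrier puts the sideband too
close to the DC lobe for the requested windows. `dhmkit train` / `dhmkit
denoise` drive the diffusion denoiser on NPY stacks.

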