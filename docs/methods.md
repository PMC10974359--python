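# Methods

This note documents the models, numerical choices and limitations behind
`dhmkit`. It covers the forward hologram model, the reconstruction pipeline,
the HiVA fusion rule, the conditional diffusion denoiser, the synthetic study
conditions, and what the bundled experiments do and do not demonstrate.

## Forward model (simulate)

An off-axis digital holographic microscope records the intensity of a tilted
reference wave interfering with the object wave:

    O(x, y) = A_o · T(x, y) · exp(−j φ_o(x, y)),   φ_o = K · Δn · h
    R(x, y) = A_r · exp(−j 2π (f_x x + f_y y))
    I(x, y) = |R + O|²  (+ sensor noise, clipped at zero)

with wavenumber K = 2π/λ and index contrast Δn = n_object − n_medium. The
carrier is modelled as a plane-wave tilt: the real instrument's two spherical
waves only set the fringe spacing, and the tilt reproduces the same
DC-to-sideband geometry while keeping the model analytic. Heights convert to
phase in single-pass transmission geometry, so the pipeline's final step is
the exact algebraic inverse h = Δφ/(K·Δn). Objective magnification rescales
only the lateral pixel pitch (pitch/M); heights are unaffected.

Defaults: λ = 0.532 μm (green laser), n_object = 1.59 (polystyrene),
n_medium = 1.53 (mounting medium), so Δn = 0.06; pixel pitch 0.1 μm/px on a
256×256 grid (25.6 μm field); carrier (0.2, 0) cycles/px; unit amplitudes
A_o = A_r = 1, which the instrument literature does not pin down.

`T(x, y)` is an optional amplitude-transmittance texture: a Gaussian random
field (given RMS fraction, given correlation length) multiplying the object
arm in both recordings. Its purpose is physical fidelity of the *noise*: a
strictly constant object amplitude makes the DC term |R|² + |O|² a pure
spectral delta, so wide sideband windows would see no DC leakage at all and
the structured "noise from the DC spectrum" that variance fusion targets
would not exist in simulation. Real specimens scatter and absorb unevenly;
the texture restores that behaviour. It defaults to 0 so the clean analytic
contracts (e.g. reference-hologram mean intensity = A_o² + A_r²) hold exactly.

### Noisy study conditions

Denoising experiments use the frozen `NOISY_STUDY` preset:

| parameter | value | rationale |
|---|---|---|
| sensor noise σ | 0.08 intensity units | ≈ 2% of the [0, 4] intensity range, a typical CMOS noise floor |
| amplitude texture | 0.30 RMS | strong but plausible specimen/optics transmittance structure |
| texture correlation | 3 px (0.3 μm) | sub-micron mottle, between speckle grain and cell-scale features |

These were chosen once, on the physical grounds above. The texture is the
dominant error source (via DC leakage into wide windows); the white sensor
noise is secondary.

What the generator does **not** emulate: speckle (coherent multiplicative
noise), defocus/aberration, partial coherence, camera quantization, and the
model mismatch of real evaluations, where the "ideal microsphere" reference
differs from the physical specimen and its surroundings. Consequences for
interpreting results are discussed under "HiVA" below.

## Reconstruction pipeline (fourier, unwrap, height)

FFT convention: unnormalized forward, 1/N² inverse; DC of a centred spectrum
at (⌊V/2⌋, ⌊H/2⌋). The positive sideband is located as the magnitude maximum
outside a DC exclusion disk, restricted to the upper half-plane (row offset
< 0, or 0 with positive column offset); a peak must exceed mean + 6·std of
out-of-disk magnitudes, otherwise "no sideband found". Square windows of
half-width w are cropped and re-centred on the DC bin of a zero array of the
original resolution (zero-padding / Fourier shift), which demodulates the
carrier at full output resolution; phase is the four-quadrant arctangent of
the inverse transform, in (−π, π].

Unwrapping is the classic Goldstein residue/branch-cut algorithm: integer
residues on 2×2 loops; greedy nearest-neighbour dipole pairing (KD-tree,
deterministic scan order) with leftover monopoles cut to the nearest border;
8-connected Bresenham pixel lines as cut barriers; 4-connected BFS
integration of wrapped differences from a seed; pixels walled off by cuts are
filled last from their nearest unwrapped neighbour by snapping to the closest
2π multiple. Residue-free maps take an exact vectorized path-independent
shortcut (row-major cumulative unwrapping), which equals the BFS result up to
a global 2π multiple. The integration seed is the pixel of maximum
demodulated-field magnitude — the best-modulated pixel — making the whole
pipeline deterministic.

Two conventions need stating:

* **Sign.** With the wave conventions above, windowing the positive-column
  sideband demodulates e^{−jφ_o}, so the raw height map of a protruding
  specimen comes out negated. `reconstruct_height(sign="auto")` (default)
  flips the map when the dominant extremum after background flattening is
  negative; `sign="raw"` disables this. This is the standard conjugate-
  sideband ambiguity of off-axis holography, not an error term.
* **Flattening.** The median over an 8-px border margin is subtracted,
  removing the unwrapper's arbitrary global 2π·k offset plus residual piston
  before any comparison. The margin assumes the specimen does not touch the
  image border.

## HiVA (hiva)

Nd reconstructions h_1 … h_Nd from strictly increasing window half-widths are
fused per pixel:

    S = mean_i h_i,   V = mean_i (h_i − S)²   (population variance)
    h_HiVA = h_Nd  where V < m_V,   S  where V ≥ m_V

with m_V the spatial mean of V; the log-variance variant applies the same
rule to log V against m_LV = mean(log(V + ε)), with ε = 10× the smallest
positive double so V = 0 pixels land far below the threshold (widest-window
branch, the correct zero-noise limit). The package default mode is
`log_variance`: the variance map's extreme dynamic range makes the plain mean
m_V sit above almost all pixels, which defeats the segmentation — the
logarithmic threshold is the method's own refinement for exactly this. A
`zero_low_variance` flag substitutes zeros instead of h_Nd below threshold
(a literal reading of one prose description); it is off by default because
the typeset fusion rule keeps the widest-window values, and zeroing craters
any stable pixels inside the specimen.

Default window schedule: Nd = 10 half-widths, evenly spaced from
max(3, d/6) to d − r_DC − 1, where d is the Chebyshev DC-to-sideband distance
and r_DC the DC exclusion radius (10 bins by default). The upper end is the
largest square window that cannot touch the exclusion zone; applicability
(`check_applicability`) is exactly the test d > w_max + r_DC, the quantitative
form of "the sidebands must be far enough from the DC spectrum". The sideband
is located once and shared by all windows, and the sign flip is decided once
from the widest-window map, so layers stay pixel-comparable.

**What the synthetic comparison shows.** Under the noisy study conditions,
over seeded repetitions, mean PSNR against the ideal sphere orders as
HiVA ≥ Gaussian(σ=2) ≥ unfiltered, and mean SSIM orders Gaussian ≥
unfiltered with HiVA close behind Gaussian (≈ 0.013 below). The SSIM
shortfall is structural for this synthetic setting, not a bug: SSIM rewards
local smoothness; the fusion rule deliberately keeps *unsmoothed*
widest-window values wherever the stack variance is low, so roughly half the
background retains its (mild) local noise texture, while a blur flattens
everything and the smooth ideal reference never penalizes it for destroyed
detail — a smooth sphere has almost none to destroy. On real microscope
data the trade-off tilts the other way (detailed specimens, artifact-
dominated noise, tiny Gaussian gains), which is where HiVA's detail
preservation pays off on both metrics. Passing the PSNR ordering and not the
SSIM ordering on synthetic spheres is therefore the expected, honestly
reported outcome, and the acceptance test asserts the full ordering so the
discrepancy stays visible.

## Conditional diffusion denoiser (diffusion)

Standard DDPM machinery: forward kernel q(x_t|x_{t−1}) =
N(√(1−β_t)·x_{t−1}, β_t I); marginal q(x_t|x₀) = N(√ᾱ_t·x₀, (1−ᾱ_t) I);
x₀ recovered from predicted noise by the exact inverse of the marginal
(the printed single-step form of that relation in some derivations is
dimensionally inconsistent; the algebraic inverse is implemented). The
default schedule is the squared-cosine ᾱ curve (s = 0.008, β clipped at
0.999) because it keeps ᾱ_T ≈ 0 even at the short T = 50 used here; linear
schedules are available for long-T runs. Losses: L_simple = E‖ε − ε̂‖², the
closed-form Gaussian KL terms of the variational bound (variance of p_θ
fixed to β_t; learned-variance interpolation is out of scope), a continuous
Gaussian decoder NLL for the t = 1 term, and the hybrid
L_simple + λ·L_vlb(t) with λ = 10⁻³. With fixed variances the KL term is an
analytically reweighted MSE on ε̂, which is how its gradient is implemented.

The ε-predictor is a deliberately small fully convolutional network
(Conv 2→C, FiLM, ReLU, Conv C→C, FiLM, ReLU, Conv C→1; C = 32, ≈ 14 k
parameters) written directly in numpy with im2col convolutions, manual
backpropagation (verified against numerical gradients) and Adam. The
timestep enters through a sinusoidal embedding mapped to per-channel FiLM
scales/shifts, which lets the network express the strongly t-dependent gain
that ε-prediction needs. The noisy profile is channel-concatenated with x_t
as conditioning; the output convolution is zero-initialized (ε̂ ≡ 0 before
training). Inputs must be affinely normalized to [−1, 1] by dataset min/max
(`HeightScaler`, stored in the model for inversion).

Sampling is ancestral: x_T ~ N(0, I), each step forms x̂₀ (clipped to
[−1, 1]), takes the true-posterior mean and injects √β_t noise; a fixed seed
makes it deterministic, and `denoise_profile` averages 4 independent chains
as a posterior-mean estimate. A deterministic walk with oracle noise
predictions recovers x₀ exactly because ᾱ₀ = 1 collapses the final posterior
mean onto x̂₀.

Desk-scale study sizes: 24 training + 4 held-out pairs of 32×32 profiles
(microsphere-chord bumps, 5–9 μm, plus 0.8 μm white height noise as a
surrogate for unfiltered-vs-HiVA pairs), T = 50, 300 Adam iterations at
batch 8, learning rate 2·10⁻³. This trains in well under a minute on one CPU
and reliably reduces the running loss ≈ 10× and held-out MSE ≈ 4–5×. The
full-scale configuration from the microscope experiments (2000 images at
875×656, 80 000 iterations, batch 8) is preserved as `FULL_SCALE_PRESET`
for reference only; nothing desk-scale approximates its capacity, so no
claim is made that the tiny network matches the published per-image scores.

## Evaluation (metrics)

PSNR = 10·log₁₀(range²/MSE) with `inf` for identical images; SSIM is the
canonical Wang et al. form (Gaussian window σ = 1.5, K₁ = 0.01, K₂ = 0.03,
population statistics), via scikit-image and cross-checked in the tests
against a brute-force sliding-window implementation. `data_range` defaults
to the reference image's peak-to-peak range because inputs are physical μm
maps; both scores are then invariant under joint rescaling. The ideal
microsphere reference shares its construction with the phantom generator:
chord-length profile, peak height = support width = diameter. The bundled
benchmark CSV carries the published 20-image scores of the three pipelines;
`report_average` reproduces its summary row by plain column means.

## Known limitations

* The Goldstein cut placement uses pixel-mask barriers (8-connected lines),
  a simplification of edge-based cuts; heavily corrupted maps can wall off
  regions, which are then offset-filled and flagged via the cut mask.
* `sign="auto"` assumes a predominantly protruding specimen; concave
  specimens need `sign="raw"`.
* The amplitude texture is a stationary Gaussian field — a stand-in for
  specimen-specific scattering, not a scattering model.
* The diffusion denoiser is a learning-dynamics and correctness testbed;
  its capacity is far below what real-data denoising requires.
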