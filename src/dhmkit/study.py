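"""Pre-packaged study scenarios: denoiser comparison and desk-scale training.

These functions wire the library together the way the evaluation experiments
do: seeded noisy microsphere holograms, the three-way comparison (unfiltered
widest window, Gaussian σ=2 baseline, HiVA fusion) scored against the ideal
microsphere, and a small conditional-diffusion training run on synthetic
profile pairs.  They are used by the test suite, the acceptance script and
the examples, so every reported number comes from one code path.
"""

from __future__ import annotations

import numpy as np

from dhmkit.height import HeightMap
from dhmkit.hiva import default_half_widths, hiva_fuse, reconstruct_stack, stack_mean_variance
from dhmkit.fourier import forward_spectrum, locate_sideband
from dhmkit.metrics import gaussian_baseline, ideal_microsphere_reference, psnr, ssim
from dhmkit.simulate import (
    NOISY_STUDY,
    OpticalConstants,
    SimConfig,
    make_microsphere_phantom,
    synthesize_hologram,
)

__all__ = ["hiva_comparison_study", "make_profile_pairs", "diffusion_training_study"]

STUDY_SHAPE = (256, 256)
STUDY_PITCH = 0.1  # μm/px
STUDY_DIAMETER = 10.0  # μm
STUDY_CARRIER = (0.2, 0.0)


def hiva_comparison_study(
    n_images: int = 10,
    seed: int = 0,
    constants: OpticalConstants | None = None,
    dc_radius: float = 10.0,
) -> dict:
    """Three-way denoising comparison over seeded noisy microsphere holograms.

    For each of ``n_images`` seeds, a 10 μm microsphere hologram pair is
    synthesized under the noisy study conditions (:data:`~dhmkit.simulate.
    NOISY_STUDY`), reconstructed at the default multi-window schedule, and the
    unfiltered widest-window map, its Gaussian σ=2 filtered version and the
    HiVA log-variance fusion are scored (SSIM, PSNR) against the ideal
    microsphere reference.

    Returns a dict with per-image score lists and their means.
    """
    if constants is None:
        constants = OpticalConstants(pixel_pitch_um=STUDY_PITCH)
    center_px = (STUDY_SHAPE[0] // 2) * STUDY_PITCH
    phantom = make_microsphere_phantom(
        STUDY_SHAPE, STUDY_PITCH, STUDY_DIAMETER, [(center_px, center_px)]
    )
    reference = ideal_microsphere_reference(STUDY_DIAMETER, STUDY_SHAPE, STUDY_PITCH)
    data_range = float(reference.values.max() - reference.values.min())

    scores: dict[str, dict[str, list[float]]] = {
        m: {"ssim": [], "psnr": []} for m in ("unfiltered", "gaussian", "hiva")
    }
    for k in range(n_images):
        cfg = SimConfig(
            carrier=STUDY_CARRIER, shape=STUDY_SHAPE, seed=seed + k, **NOISY_STUDY
        )
        obj, ref_holo = synthesize_hologram(phantom, constants, cfg)
        sb = locate_sideband(forward_spectrum(obj), dc_radius)
        distance = max(abs(sb[0]), abs(sb[1]))
        widths = default_half_widths(distance, dc_radius)
        stack = reconstruct_stack(obj, ref_holo, widths, constants,
                                  dc_exclusion_radius=dc_radius)
        stats = stack_mean_variance(stack)
        maps = {
            "unfiltered": stack.widest,
            "gaussian": gaussian_baseline(HeightMap(stack.widest), 2.0).values,
            "hiva": hiva_fuse(stack, stats, mode="log_variance").values,
        }
        for name, values in maps.items():
            scores[name]["ssim"].append(ssim(values, reference, data_range=data_range))
            scores[name]["psnr"].append(psnr(values, reference, data_range=data_range))

    means = {
        name: {metric: float(np.mean(vals)) for metric, vals in d.items()}
        for name, d in scores.items()
    }
    return {"per_image": scores, "means": means, "n_images": n_images}


def make_profile_pairs(n_pairs: int, seed: int, size: int = 32, noise_sigma_um: float = 0.8):
    """Synthetic (noisy, clean) height-profile pairs for denoiser training.

    Clean profiles are small microsphere-chord bumps of varying diameter and
    position (a desk-scale surrogate for HiVA-cleaned reconstructions); noisy
    counterparts add white Gaussian height noise.  Profiles are in μm.
    """
    rng = np.random.default_rng(seed)
    pitch = 0.4  # μm/px on the small grid
    extent = (size - 1) * pitch
    clean, noisy = [], []
    for _ in range(n_pairs):
        d = rng.uniform(5.0, 9.0)
        cx = rng.uniform(0.3 * extent, 0.7 * extent)
        cy = rng.uniform(0.3 * extent, 0.7 * extent)
        ph = make_microsphere_phantom((size, size), pitch, d, [(cx, cy)])
        clean.append(ph.height)
        noisy.append(ph.height + rng.normal(0.0, noise_sigma_um, ph.height.shape))
    return noisy, clean


def diffusion_training_study(
    seed: int = 0,
    n_train: int = 24,
    n_test: int = 4,
    iterations: int = 300,
    t_steps: int = 50,
) -> dict:
    """Desk-scale conditional training run with a held-out evaluation.

    Trains the conditional ε-predictor on 32×32 (noisy, clean) pairs for
    ``iterations`` Adam steps at ``T = t_steps``, then denoises held-out noisy
    profiles by ancestral sampling.  Reports the running training loss at the
    start and end and the mean squared error of the noisy inputs and the
    denoised outputs against the clean truth (μm²).
    """
    from dhmkit.diffusion import (
        DiffusionConfig,
        HeightScaler,
        denoise_profile,
        train_conditional_denoiser,
    )

    noisy, clean = make_profile_pairs(n_train + n_test, seed=seed)
    scaler = HeightScaler.fit(noisy + clean)
    pairs = [
        (scaler.transform(nz), scaler.transform(cl))
        for nz, cl in zip(noisy[:n_train], clean[:n_train])
    ]
    cfg = DiffusionConfig(T=t_steps, iterations=iterations)
    model = train_conditional_denoiser(pairs, cfg, seed=seed, scaler=scaler)

    k = max(1, iterations // 10)
    initial_loss = float(np.mean(model.loss_history[:k]))
    final_loss = float(np.mean(model.loss_history[-k:]))

    mse_noisy, mse_denoised = [], []
    for nz, cl in zip(noisy[n_train:], clean[n_train:]):
        out = denoise_profile(nz, model, seed=seed + 1).values
        mse_noisy.append(float(np.mean((nz - cl) ** 2)))
        mse_denoised.append(float(np.mean((out - cl) ** 2)))

    return {
        "initial_loss": initial_loss,
        "final_loss": final_loss,
        "mse_noisy": float(np.mean(mse_noisy)),
        "mse_denoised": float(np.mean(mse_denoised)),
        "n_train": n_train,
        "n_test": n_test,
        "iterations": iterations,
        "T": t_steps,
        "n_params": model.n_params,
        "model": model,
    }
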