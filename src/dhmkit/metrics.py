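"""Image-quality evaluation of reconstructed height profiles.

Reconstructions are scored against an *ideal microsphere reference* — a
synthetic height map of a sphere whose peak height and support width both
equal its diameter — using PSNR and SSIM (the standard Wang et al. form:
Gaussian window σ = 1.5, K₁ = 0.01, K₂ = 0.03).  A Gaussian filter with
σ = 2 px serves as the conventional denoising baseline.

``data_range`` defaults to the peak-to-peak range of the *reference* image:
the inputs here are physical micrometre maps, not 8-bit images, so a fixed
255 would be meaningless.  Both scores are then invariant to rescaling image,
reference and range together.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.metrics import structural_similarity

from dhmkit.height import HeightMap
from dhmkit.simulate import make_microsphere_phantom

__all__ = [
    "gaussian_baseline",
    "ideal_microsphere_reference",
    "psnr",
    "ssim",
    "evaluation_report",
    "benchmark_scores",
    "report_average",
]


def _values(image: HeightMap | np.ndarray) -> np.ndarray:
    return image.values if isinstance(image, HeightMap) else np.asarray(image, dtype=float)


def gaussian_baseline(height: HeightMap | np.ndarray, sigma: float = 2.0) -> HeightMap:
    """Conventional baseline: 2D Gaussian smoothing with reflective boundary."""
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    vals = _values(height)
    out = gaussian_filter(vals, sigma=sigma, mode="reflect")
    constants = height.constants if isinstance(height, HeightMap) else None
    return HeightMap(values=out, constants=constants)


def ideal_microsphere_reference(
    diameter_um: float, shape: tuple[int, int], pixel_pitch_um: float
) -> HeightMap:
    """Ideal sphere height map: peak height = support width = diameter.

    Single sphere centered on the grid, chord-length profile
    2·sqrt((D/2)² − ρ²); the ground-truth reference for PSNR/SSIM scoring.
    """
    rows, cols = shape
    extent = (min(rows, cols) - 1) * pixel_pitch_um
    if diameter_um > extent:
        raise ValueError(
            f"diameter {diameter_um} μm exceeds the grid extent {extent:.3g} μm"
        )
    center = (((cols - 1) / 2) * pixel_pitch_um, ((rows - 1) / 2) * pixel_pitch_um)
    phantom = make_microsphere_phantom(shape, pixel_pitch_um, diameter_um, [center])
    return HeightMap(values=phantom.height)


def _check_pair(image: np.ndarray, reference: np.ndarray) -> None:
    if image.shape != reference.shape:
        raise ValueError(f"shape mismatch: {image.shape} vs {reference.shape}")


def _default_range(reference: np.ndarray) -> float:
    rng = float(reference.max() - reference.min())
    if rng == 0:
        raise ValueError("reference image is constant; pass data_range explicitly")
    return rng


def psnr(
    image: HeightMap | np.ndarray,
    reference: HeightMap | np.ndarray,
    data_range: float | None = None,
) -> float:
    """Peak signal-to-noise ratio 10·log10(data_range²/MSE) in dB.

    Identical images return ``inf``.
    """
    img, ref = _values(image), _values(reference)
    _check_pair(img, ref)
    if data_range is None:
        data_range = _default_range(ref)
    mse = float(np.mean((img - ref) ** 2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / mse))


def ssim(
    image: HeightMap | np.ndarray,
    reference: HeightMap | np.ndarray,
    data_range: float | None = None,
) -> float:
    """Mean structural similarity over Gaussian-weighted local windows."""
    img, ref = _values(image), _values(reference)
    _check_pair(img, ref)
    if min(img.shape) < 11:  # 11 = Gaussian window extent for sigma 1.5
        raise ValueError(f"image {img.shape} smaller than the SSIM window")
    if data_range is None:
        data_range = _default_range(ref)
    return float(
        structural_similarity(
            img,
            ref,
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def evaluation_report(
    methods: Mapping[str, Sequence[HeightMap | np.ndarray] | HeightMap | np.ndarray],
    reference: Sequence[HeightMap | np.ndarray] | HeightMap | np.ndarray,
    data_range: float | None = None,
) -> pd.DataFrame:
    """Per-image SSIM and PSNR for several methods, with an Average row.

    ``methods`` maps a method name to one height map or a sequence of them
    (one per evaluation image); ``reference`` is the matching ideal map or
    sequence.  Columns are ``ssim_<name>`` and ``psnr_<name>``; the final
    ``Average`` row holds arithmetic column means.
    """
    if not methods:
        raise ValueError("no methods to evaluate")

    def as_list(x):
        if isinstance(x, (HeightMap, np.ndarray)):
            return [x]
        return list(x)

    refs = as_list(reference)
    per_method = {name: as_list(maps) for name, maps in methods.items()}
    n = len(refs)
    for name, maps in per_method.items():
        if len(maps) != n:
            raise ValueError(f"method {name!r} has {len(maps)} maps, expected {n}")

    columns: dict[str, list[float]] = {}
    for name, maps in per_method.items():
        columns[f"ssim_{name}"] = [ssim(m, r, data_range) for m, r in zip(maps, refs)]
    for name, maps in per_method.items():
        columns[f"psnr_{name}"] = [psnr(m, r, data_range) for m, r in zip(maps, refs)]
    df = pd.DataFrame(columns, index=pd.Index(range(1, n + 1), name="data_number"))
    df.loc["Average"] = df.mean()
    return df


def benchmark_scores() -> pd.DataFrame:
    """Published per-image SSIM/PSNR benchmark for 20 reconstructed microsphere
    profiles under three pipelines (unfiltered, Gaussian σ=2, HiVA+diffusion).

    Returns the raw per-image rows; pass through :func:`report_average` (or
    ``df.mean()``) to recompute the summary row.
    """
    with resources.files("dhmkit.data").joinpath("microsphere_benchmark.csv").open() as fh:
        return pd.read_csv(fh, index_col="data_number")


def report_average(df: pd.DataFrame) -> pd.Series:
    """Arithmetic mean of every score column of a per-image report."""
    return df.mean(axis=0)
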