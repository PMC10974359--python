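"""HiVA — High-Variance pixel Averaging.

A single sideband window size trades detail against noise: wide windows keep
high spatial frequencies but admit phase error from the DC lobe, narrow
windows suppress that error but blur the specimen.  HiVA reconstructs the
height map at Nd increasing window sizes and uses the per-pixel variance
across the stack to tell noise from detail:

    S(x,y) = (1/Nd) Σᵢ hᵢ(x,y)                    (stack mean)
    V(x,y) = (1/Nd) Σᵢ (hᵢ(x,y) − S(x,y))²        (population variance)

Pixels whose variance stays below the spatial mean m_V are stable across
window sizes — genuine structure — and keep the widest-window (most detailed)
value h_Nd; high-variance pixels are noise-dominated and are replaced by the
stack mean S.  A logarithmic-variance variant thresholds log V against its
spatial mean m_LV, which is robust when a few pixels dominate the variance
range.

HiVA requires the sidebands to sit far enough from the DC lobe that even the
widest window never touches it; :func:`check_applicability` tests exactly
that geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dhmkit.fourier import Spectrum, forward_spectrum, locate_sideband
from dhmkit.height import HeightMap
from dhmkit.pipeline import reconstruct_height
from dhmkit.simulate import Hologram, OpticalConstants

__all__ = [
    "ReconstructionStack",
    "VarianceStats",
    "reconstruct_stack",
    "stack_mean_variance",
    "hiva_fuse",
    "check_applicability",
    "default_half_widths",
]

#: offset added to V before taking log, so V = 0 pixels land far below m_LV
#: (the widest-window branch), matching the zero-noise limit
EPS_LOG = np.finfo(float).tiny * 10.0


@dataclass
class ReconstructionStack:
    """Nd aligned height maps from strictly increasing window half-widths."""

    heights: np.ndarray  # (Nd, rows, cols), μm
    half_widths: tuple[int, ...]
    constants: OpticalConstants | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.heights, dtype=float)
        if arr.ndim != 3:
            raise ValueError("stack must be (Nd, rows, cols)")
        if len(self.half_widths) != arr.shape[0]:
            raise ValueError("one half-width per stack layer required")
        if any(b <= a for a, b in zip(self.half_widths, self.half_widths[1:])):
            raise ValueError(f"half-widths must be strictly increasing, got {self.half_widths}")
        self.heights = arr
        self.half_widths = tuple(int(w) for w in self.half_widths)

    @property
    def n_d(self) -> int:
        return self.heights.shape[0]

    @property
    def widest(self) -> np.ndarray:
        """h_Nd — the reconstruction from the widest window."""
        return self.heights[-1]


@dataclass
class VarianceStats:
    """Per-pixel mean/variance of a stack and the scalar fusion thresholds."""

    mean: np.ndarray      # S, μm
    variance: np.ndarray  # V, μm²
    m_v: float            # spatial mean of V
    m_lv: float           # spatial mean of log(V + EPS_LOG)


def default_half_widths(
    distance: int, dc_radius: float, n_d: int = 10, w_min: int | None = None
) -> tuple[int, ...]:
    """Evenly spaced window schedule from narrow to the widest admissible.

    ``distance`` is the Chebyshev DC-to-sideband distance.  The default spans
    max(3, distance/6) up to ``distance − dc_radius − 1`` (the largest window
    that cannot touch the DC exclusion zone) in Nd regular steps.
    """
    w_max = int(np.floor(distance - dc_radius - 1))
    if w_min is None:
        w_min = max(3, int(round(distance / 6)))
    if w_max < w_min:
        raise ValueError(
            f"no admissible window schedule: w_max {w_max} < w_min {w_min} "
            f"(DC-sideband distance {distance}, dc_radius {dc_radius})"
        )
    ws = np.unique(np.round(np.linspace(w_min, w_max, n_d)).astype(int))
    if len(ws) < 2:
        raise ValueError("schedule collapsed to fewer than 2 distinct widths")
    return tuple(int(w) for w in ws)


def check_applicability(
    spectrum: Spectrum,
    sideband_center: tuple[int, int],
    w_max: int,
    dc_radius: float,
) -> tuple[bool, dict]:
    """Is HiVA applicable: can the widest window avoid the DC lobe?

    True iff the Chebyshev distance from DC to the sideband center exceeds
    ``w_max + dc_radius``, i.e. a square window of half-width w_max around the
    sideband stays clear of the DC exclusion zone.  Diagnostics report the
    distance and the largest admissible half-width.
    """
    dr, dc = sideband_center
    distance = max(abs(dr), abs(dc))
    rows, cols = spectrum.shape
    cr, cc = spectrum.dc_index
    sr, sc = cr + dr, cc + dc
    edge_room = min(sr, rows - 1 - sr, sc, cols - 1 - sc)
    w_admissible = min(int(np.floor(distance - dc_radius - 1)), edge_room)
    ok = distance > w_max + dc_radius and w_max <= edge_room
    return ok, {
        "dc_sideband_distance": int(distance),
        "w_max_requested": int(w_max),
        "dc_radius": float(dc_radius),
        "largest_admissible_w": int(w_admissible),
    }


def reconstruct_stack(
    object_holo: Hologram,
    reference_holo: Hologram,
    half_widths,
    constants: OpticalConstants,
    dc_exclusion_radius: float = 10.0,
    sign: str = "auto",
    flatten_margin: int | None = 8,
) -> ReconstructionStack:
    """Run the full pipeline at each window size, sharing one sideband center.

    The sideband is located once on the object spectrum; the sign convention
    (see :func:`~dhmkit.pipeline.reconstruct_height`) is decided once, from
    the widest-window map, and applied to the whole stack so layers stay
    comparable pixel-wise.
    """
    half_widths = tuple(int(w) for w in half_widths)
    if any(b <= a for a, b in zip(half_widths, half_widths[1:])):
        raise ValueError(f"half-widths must be strictly increasing, got {half_widths}")
    spec_obj = forward_spectrum(object_holo)
    center = locate_sideband(spec_obj, dc_exclusion_radius)
    ok, diag = check_applicability(spec_obj, center, max(half_widths), dc_exclusion_radius)
    if not ok:
        raise ValueError(
            "HiVA not applicable: DC-sideband distance "
            f"{diag['dc_sideband_distance']} px cannot accommodate w={max(half_widths)} "
            f"with DC exclusion radius {dc_exclusion_radius} "
            f"(largest admissible w: {diag['largest_admissible_w']})"
        )

    layers = []
    for w in half_widths:
        hm = reconstruct_height(
            object_holo,
            reference_holo,
            constants,
            half_width=w,
            dc_exclusion_radius=dc_exclusion_radius,
            sideband_center=center,
            sign="raw",
            flatten_margin=flatten_margin,
        )
        layers.append(hm.values)
    stack = np.stack(layers)
    if sign == "auto":
        widest = stack[-1]
        if abs(float(widest.min())) > abs(float(widest.max())):
            stack = -stack
    elif sign != "raw":
        raise ValueError(f"unknown sign convention {sign!r}")
    return ReconstructionStack(heights=stack, half_widths=half_widths, constants=constants)


def stack_mean_variance(stack: ReconstructionStack) -> VarianceStats:
    """Per-pixel mean S and population variance V plus the m_V / m_LV thresholds."""
    if stack.n_d < 2:
        raise ValueError("variance needs at least 2 stack layers")
    s = stack.heights.mean(axis=0)
    v = ((stack.heights - s) ** 2).mean(axis=0)
    return VarianceStats(
        mean=s,
        variance=v,
        m_v=float(v.mean()),
        m_lv=float(np.log(v + EPS_LOG).mean()),
    )


def hiva_fuse(
    stack: ReconstructionStack,
    stats: VarianceStats | None = None,
    mode: str = "variance",
    zero_low_variance: bool = False,
) -> HeightMap:
    """Fuse a reconstruction stack by variance thresholding.

    ``mode="variance"``: pixels with V < m_V keep the widest-window value
    h_Nd, pixels with V ≥ m_V take the stack mean S.  ``mode="log_variance"``
    applies the same rule to log V against m_LV.  With ``zero_low_variance``,
    below-threshold pixels are set to 0 instead of h_Nd (an aggressive
    background-suppression variant); default off.
    """
    if stats is None:
        stats = stack_mean_variance(stack)
    if stats.mean.shape != stack.heights.shape[1:]:
        raise ValueError("stats shape does not match stack shape")
    if mode == "variance":
        low = stats.variance < stats.m_v
    elif mode == "log_variance":
        low = np.log(stats.variance + EPS_LOG) < stats.m_lv
    else:
        raise ValueError(f"unknown fusion mode {mode!r}")
    low_value = np.zeros_like(stats.mean) if zero_low_variance else stack.widest
    fused = np.where(low, low_value, stats.mean)
    return HeightMap(values=fused, constants=stack.constants)
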