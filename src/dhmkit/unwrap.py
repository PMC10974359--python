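"""Goldstein residue/branch-cut phase unwrapping.

Wrapped phase is only known modulo 2π.  Integrating wrapped differences
recovers the continuous phase wherever the true map is smooth, but fails near
*residues*: 2×2 loops whose wrapped differences sum to ±2π.  The Goldstein
algorithm neutralizes residues by connecting opposite charges (or a lone
charge and the image border) with branch cuts, then flood-fill integrates the
wrapped gradient along paths that never cross a cut.  Pixels walled off by
cuts are filled last from their nearest unwrapped neighbour by adding the
2π multiple that best matches that neighbour.

The output differs from the wrapped input by an integer multiple of 2π at
every integrated pixel, so no phase information is invented.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from dhmkit.height import PhaseMap

TWO_PI = 2.0 * np.pi

__all__ = ["wrap", "compute_residues", "goldstein_unwrap"]


def wrap(phase: np.ndarray | float) -> np.ndarray | float:
    """Wrap phase into (−π, π]; idempotent.

    Implemented as ``p − 2π·ceil((p − π)/2π)``, which maps +π to +π and −π to
    +π, keeping the interval half-open at the lower end.
    """
    p = np.asarray(phase, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("phase must be finite")
    out = p - TWO_PI * np.ceil((p - np.pi) / TWO_PI)
    if np.isscalar(phase) or np.ndim(phase) == 0:
        return float(out)
    return out


def compute_residues(wrapped: PhaseMap | np.ndarray) -> np.ndarray:
    """Integer residue charge of every 2×2 loop of a wrapped phase map.

    The loop at (i, j) spans pixels (i,j), (i,j+1), (i+1,j+1), (i+1,j); its
    charge is the sum of the four wrapped pairwise differences around the
    loop divided by 2π, always an integer in {−1, 0, +1}.  Smooth maps
    (adjacent steps < π) have zero charge everywhere.
    """
    phi = wrapped.values if isinstance(wrapped, PhaseMap) else np.asarray(wrapped, float)
    if phi.ndim != 2 or phi.shape[0] < 2 or phi.shape[1] < 2:
        raise ValueError("residues need a 2D map of at least 2x2 pixels")
    d1 = wrap(phi[:-1, 1:] - phi[:-1, :-1])   # top edge, left -> right
    d2 = wrap(phi[1:, 1:] - phi[:-1, 1:])     # right edge, down
    d3 = wrap(phi[1:, :-1] - phi[1:, 1:])     # bottom edge, right -> left
    d4 = wrap(phi[:-1, :-1] - phi[1:, :-1])   # left edge, up
    return np.rint((d1 + d2 + d3 + d4) / TWO_PI).astype(int)


def _bresenham(r0: int, c0: int, r1: int, c1: int) -> list[tuple[int, int]]:
    """8-connected line of pixels between two points, inclusive."""
    pts = []
    dr = abs(r1 - r0)
    dc = abs(c1 - c0)
    sr = 1 if r1 >= r0 else -1
    sc = 1 if c1 >= c0 else -1
    err = dc - dr
    r, c = r0, c0
    while True:
        pts.append((r, c))
        if r == r1 and c == c1:
            break
        e2 = 2 * err
        if e2 > -dr:
            err -= dr
            c += sc
        if e2 < dc:
            err += dc
            r += sr
    return pts


def _branch_cuts(residues: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Pixel mask of branch cuts pairing opposite residues (or cutting to border).

    Greedy dipole pairing: the globally closest (+, −) pair is connected
    first (Chebyshev distance, deterministic tie-break by index order),
    repeated until one sign is exhausted; leftover monopoles are cut to the
    nearest image border.  An 8-connected pixel line is an impassable barrier
    for the 4-connected integration flood fill.
    """
    rows, cols = shape
    cuts = np.zeros(shape, dtype=bool)
    pos = [tuple(p) for p in np.argwhere(residues > 0)]
    neg = [tuple(p) for p in np.argwhere(residues < 0)]

    # pair dipoles greedily: each positive charge connects to its nearest
    # still-unpaired negative charge (KD-tree nearest search, deterministic
    # scan order) — the canonical nearest-neighbour dipole pairing
    if pos and neg:
        from scipy.spatial import cKDTree

        neg_arr = np.array(neg)
        tree = cKDTree(neg_arr)
        used = np.zeros(len(neg), dtype=bool)
        leftovers = []
        for pr, pc in pos:
            k = 1
            partner = None
            while k <= len(neg):
                dist, idx = tree.query((pr, pc), k=k)
                idx = np.atleast_1d(idx)
                free = [i for i in idx if not used[i]]
                if free:
                    partner = free[0]
                    break
                k = min(2 * k, len(neg))
                if k == len(neg) and not free:
                    dist, idx = tree.query((pr, pc), k=k)
                    free = [i for i in np.atleast_1d(idx) if not used[i]]
                    partner = free[0] if free else None
                    break
            if partner is None:
                leftovers.append((pr, pc))
                continue
            used[partner] = True
            nr, nc = neg_arr[partner]
            for r, c in _bresenham(pr, pc, int(nr), int(nc)):
                cuts[r, c] = True
        pos = leftovers
        neg = [tuple(neg_arr[i]) for i in range(len(neg)) if not used[i]]

    # unpaired monopoles: cut straight to the nearest border
    for r, c in pos + neg:
        dists = {"top": r, "bottom": rows - 1 - r, "left": c, "right": cols - 1 - c}
        side = min(dists, key=dists.get)
        if side == "top":
            target = (0, c)
        elif side == "bottom":
            target = (rows - 1, c)
        elif side == "left":
            target = (r, 0)
        else:
            target = (r, cols - 1)
        for rr, cc in _bresenham(r, c, *target):
            cuts[rr, cc] = True
    return cuts


def _integrate(
    phi: np.ndarray, cuts: np.ndarray, seed: tuple[int, int]
) -> np.ndarray:
    """BFS integration of wrapped differences from a seed, avoiding cuts."""
    rows, cols = phi.shape
    out = np.array(phi, dtype=float)
    done = np.zeros(phi.shape, dtype=bool)
    sr, sc = seed
    done[sr, sc] = True
    queue = deque([(sr, sc)])
    while queue:
        r, c = queue.popleft()
        base = out[r, c]
        wc = phi[r, c]
        for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= nr < rows and 0 <= nc < cols and not done[nr, nc] and not cuts[nr, nc]:
                out[nr, nc] = base + wrap(phi[nr, nc] - wc)
                done[nr, nc] = True
                queue.append((nr, nc))

    # fill cut / isolated pixels from the nearest unwrapped neighbour,
    # snapping to the 2π multiple of the wrapped value closest to it
    if not done.all():
        pending = deque(map(tuple, np.argwhere(~done)))
        stall = 0
        while pending and stall <= len(pending):
            r, c = pending.popleft()
            nb = None
            for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if 0 <= nr < rows and 0 <= nc < cols and done[nr, nc]:
                    nb = (nr, nc)
                    break
            if nb is None:
                pending.append((r, c))
                stall += 1
                continue
            out[r, c] = phi[r, c] + TWO_PI * np.round((out[nb] - phi[r, c]) / TWO_PI)
            done[r, c] = True
            stall = 0
    return out


def goldstein_unwrap(
    wrapped: PhaseMap | np.ndarray,
    quality: np.ndarray | None = None,
    seed_pixel: tuple[int, int] | None = None,
    full_output: bool = False,
):
    """Unwrap a wrapped phase map with Goldstein branch cuts.

    Parameters
    ----------
    wrapped
        Wrapped phase map, values in (−π, π].
    quality
        Optional per-pixel quality map (e.g. the magnitude of the demodulated
        complex field); its maximum picks the integration seed.  Defaults to
        the image center (moved to the nearest un-cut pixel).
    seed_pixel
        Explicit integration seed, overriding ``quality``.
    full_output
        Also return a dict with the residue map and branch-cut mask (the
        cut mask doubles as a low-quality flag for heavily cut regions).

    Returns an unwrapped :class:`~dhmkit.height.PhaseMap`; at every
    flood-filled pixel, output − input is an integer multiple of 2π.
    """
    phi = wrapped.values if isinstance(wrapped, PhaseMap) else np.asarray(wrapped, float)
    if phi.ndim != 2:
        raise ValueError("goldstein_unwrap expects a 2D map")

    residues = compute_residues(phi)
    if residues.any():
        cuts = _branch_cuts(residues, phi.shape)
    else:
        cuts = np.zeros(phi.shape, dtype=bool)

    if seed_pixel is None:
        if quality is not None:
            q = np.where(cuts, -np.inf, np.asarray(quality, dtype=float))
            seed_pixel = tuple(np.unravel_index(int(np.argmax(q)), phi.shape))
        else:
            center = (phi.shape[0] // 2, phi.shape[1] // 2)
            if not cuts[center]:
                seed_pixel = center
            else:  # nearest un-cut pixel, deterministic scan order
                free = np.argwhere(~cuts)
                if len(free) == 0:
                    raise ValueError("branch cuts cover the whole map")
                d = np.abs(free - np.array(center)).max(axis=1)
                seed_pixel = tuple(free[int(np.argmin(d))])
    if cuts[seed_pixel]:
        raise ValueError(f"integration seed {seed_pixel} lies on a branch cut")

    if not residues.any():
        # residue-free: integration is path independent, use the fast
        # row-major cumulative unwrap anchored at the seed
        out = np.empty_like(phi)
        col0 = np.concatenate(([phi[0, 0]], phi[0, 0] + np.cumsum(wrap(np.diff(phi[:, 0])))))
        out[:, 0] = col0
        steps = wrap(np.diff(phi, axis=1))
        out[:, 1:] = out[:, :1] + np.cumsum(steps, axis=1)
        out -= TWO_PI * np.round((out[seed_pixel] - phi[seed_pixel]) / TWO_PI)
    else:
        out = _integrate(phi, cuts, seed_pixel)

    result = PhaseMap(values=out, wrapped=False)
    if full_output:
        return result, {"residues": residues, "cuts": cuts, "seed": seed_pixel}
    return result
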