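"""Deterministic synthetic inputs and brute-force oracles.

Generators for the point patterns and size samples used throughout the test
suite and examples: CSR (Poisson) patterns, jittered triangular lattices,
samples from the truncated-power-law stationary size density, and a
Monte-Carlo dart-throwing estimate of the circle-overlap lens area.  Every
entry point takes an explicit seed; there is no hidden global state.
"""

from __future__ import annotations

import math

import numpy as np

from .meanfield import steady_state_density
from .params import AllometryParams, CompetitionParams
from .spatial_stats import PointPattern

__all__ = [
    "make_poisson_pattern",
    "make_hex_pattern",
    "make_eq_curve_samples",
    "brute_force_overlap",
]


def _window_array(window) -> np.ndarray:
    if window is None:
        return np.array([[0.0, 1.0], [0.0, 1.0]])
    return np.asarray(window, dtype=float)


def make_poisson_pattern(n: int, window=None, seed: int = 0,
                         periodic: bool = False) -> PointPattern:
    """n uniform i.i.d. points in the window (CSR), reproducible from seed."""
    if n < 2:
        raise ValueError("need n >= 2")
    win = _window_array(window)
    rng = np.random.default_rng(seed)
    x = rng.uniform(win[0, 0], win[0, 1], n)
    y = rng.uniform(win[1, 0], win[1, 1], n)
    return PointPattern(np.column_stack([x, y]), window=win, periodic=periodic)


def make_hex_pattern(spacing: float, jitter_frac: float = 0.0, window=None,
                     seed: int = 0, periodic: bool = False) -> PointPattern:
    """Triangular-lattice points with uniform jitter, cropped to the window.

    Each lattice point is displaced by a uniform offset of amplitude
    jitter_frac * spacing in each coordinate.  jitter 0 gives the exact
    lattice with all nearest-neighbor distances equal to ``spacing`` and
    sixfold coordination for interior points.
    """
    win = _window_array(window)
    (x0, x1), (y0, y1) = win
    if spacing >= min(x1 - x0, y1 - y0):
        raise ValueError("spacing must be smaller than the window side")
    rng = np.random.default_rng(seed)
    row_h = spacing * math.sqrt(3.0) / 2.0
    rows = int(math.ceil((y1 - y0) / row_h)) + 2
    cols = int(math.ceil((x1 - x0) / spacing)) + 2
    pts = []
    for j in range(rows):
        yy = y0 + j * row_h
        off = 0.5 * spacing if j % 2 else 0.0
        for i in range(cols):
            pts.append((x0 + off + i * spacing, yy))
    pts = np.asarray(pts)
    if jitter_frac > 0:
        pts = pts + rng.uniform(-jitter_frac * spacing, jitter_frac * spacing,
                                pts.shape)
    keep = ((pts[:, 0] >= x0) & (pts[:, 0] < x1)
            & (pts[:, 1] >= y0) & (pts[:, 1] < y1))
    return PointPattern(pts[keep], window=win, periodic=periodic)


def make_eq_curve_samples(p: AllometryParams, c: CompetitionParams, n: int,
                          seed: int = 0, r_top: float | None = None,
                          grid_size: int = 20000) -> np.ndarray:
    """i.i.d. radii from the normalized stationary size density.

    Inverse-CDF sampling on a fine grid of the truncated-power-law steady
    state on [r0, r_top] (default 2*r_max).
    """
    if n < 1:
        raise ValueError("need n >= 1")
    if r_top is None:
        r_top = 2.0 * c.r_max
    r = np.linspace(p.r0, r_top, grid_size)
    dens = steady_state_density(r, p, c)
    mass = np.trapezoid(dens, r)
    if not np.isfinite(mass) or mass <= 0:
        raise ValueError("stationary density is not normalizable on the grid")
    cdf = np.concatenate([[0.0], np.cumsum((dens[:-1] + dens[1:]) / 2.0 * np.diff(r))])
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    return np.interp(u, cdf, r)


def brute_force_overlap(r1: float, r2: float, d: float, n_darts: int = 100_000,
                        seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo dart estimate of the circle-circle lens area.

    Darts are thrown uniformly into the bounding box of the smaller circle
    (centred at distance d from the first); the hit fraction scales the box
    area.  Returns (estimate, standard error).
    """
    if n_darts < 10_000:
        raise ValueError("use at least 10^4 darts")
    if d >= r1 + r2:
        return 0.0, 0.0
    small, big = min(r1, r2), max(r1, r2)
    # centre the small circle at (d, 0), big at origin; lens is inside the
    # small circle's bounding box
    rng = np.random.default_rng(seed)
    xs = rng.uniform(d - small, d + small, n_darts)
    ys = rng.uniform(-small, small, n_darts)
    inside = ((xs - d) ** 2 + ys**2 <= small**2) & (xs**2 + ys**2 <= big**2)
    frac = inside.mean()
    box = (2.0 * small) ** 2
    est = frac * box
    stderr = box * math.sqrt(max(frac * (1 - frac), 0.0) / n_darts)
    return float(est), float(stderr)
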