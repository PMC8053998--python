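"""Mean-field size-class model: discrete chain, continuum PDE, steady state.

The population is described by a number density n(r, t) per unit radius on a
uniform grid [r0, 2*r_max].  Individuals advect toward larger r with speed
rdot(r), die naturally at rate mu(r), and — when competition is enabled —
die from resource stress at rate s*B*r^kappa (symmetric attrition) and/or
from canopy shading by all sufficiently larger individuals (asymmetric
competition with a Heaviside or logistic kernel).  A scalar sapling pool fed
at rate g0 supplies the inflow boundary flux.

The transport term is discretized with first-order upwind finite volumes
(the advection speed is one-signed, and upwinding preserves positivity);
sinks are explicit with per-step clipping so the density can never go
negative.  The closed-form steady state

    n(r) = n0_tilde * (r/r0)^(-alpha) * exp(-F/(kappa+1-b) * r^(kappa+1-b))

with alpha = b + 8 A_bar/(3 a_bar c_m^(1-b)) and
F = 8 B s c_m^(b-1)/(3 a_bar) serves as the analytic reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.signal import find_peaks

from . import allometry
from .params import AllometryParams, CompetitionParams

__all__ = [
    "SizeDistribution",
    "Trajectory",
    "step_discrete_classes",
    "step_pde",
    "steady_state_density",
    "canopy_loss_rate",
    "run_meanfield",
    "detect_oscillations",
    "track_dip",
    "fit_loglog_slope",
    "make_grid",
]


@dataclass
class SizeDistribution:
    """Radius grid with population number density and the sapling pool.

    Attributes
    ----------
    r_grid : ndarray
        Strictly increasing, uniformly spaced radii starting at r0.
    n : ndarray
        Number density per unit radius at each grid point (>= 0).
    n0_pool : float
        Sapling-class count (individuals, >= 0).
    t : float
        Current time.
    """

    r_grid: np.ndarray
    n: np.ndarray
    n0_pool: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.r_grid.ndim != 1 or self.r_grid.size < 2:
            raise ValueError("r_grid must be 1D with at least 2 points")
        dr = np.diff(self.r_grid)
        if np.any(dr <= 0) or not np.allclose(dr, dr[0], rtol=1e-8):
            raise ValueError("r_grid must be strictly increasing and uniform")
        if self.n.shape != self.r_grid.shape:
            raise ValueError("n must match r_grid in shape")
        if np.any(self.n < 0) or self.n0_pool < 0:
            raise ValueError("density and sapling pool must be nonnegative")

    @property
    def dr(self) -> float:
        return float(self.r_grid[1] - self.r_grid[0])

    def total_population(self, include_pool: bool = True) -> float:
        """Integral of n over the grid (finite-volume sum), plus the pool."""
        tot = float(np.sum(self.n) * self.dr)
        return tot + self.n0_pool if include_pool else tot

    def copy(self) -> "SizeDistribution":
        return SizeDistribution(self.r_grid.copy(), self.n.copy(), self.n0_pool, self.t)


@dataclass
class Trajectory:
    """Snapshots of a mean-field run with per-snapshot diagnostics."""

    times: list[float] = field(default_factory=list)
    snapshots: list[SizeDistribution] = field(default_factory=list)
    total_population: list[float] = field(default_factory=list)
    total_canopy_area: list[float] = field(default_factory=list)
    clip_events: int = 0

    def append(self, state: SizeDistribution, comp: CompetitionParams | None) -> None:
        if self.times and state.t <= self.times[-1]:
            raise ValueError("snapshot times must be strictly increasing")
        self.times.append(state.t)
        self.snapshots.append(state.copy())
        self.total_population.append(state.total_population())
        area = 0.0
        if comp is not None:
            area = float(
                np.trapezoid(state.n * comp.canopy_area(state.r_grid), state.r_grid)
            )
        self.total_canopy_area.append(area)

    def band_population(self, r_lo: float, r_hi: float) -> np.ndarray:
        """Population integrated over the radius band [r_lo, r_hi] vs time."""
        out = np.empty(len(self.snapshots))
        for i, snap in enumerate(self.snapshots):
            mask = (snap.r_grid >= r_lo) & (snap.r_grid <= r_hi)
            out[i] = np.sum(snap.n[mask]) * snap.dr
        return out


def make_grid(p: AllometryParams, comp: CompetitionParams | None = None,
              r_top: float | None = None) -> np.ndarray:
    """Uniform radius grid [r0, r_top] with spacing p.dr (default r_top=2*r_max)."""
    if r_top is None:
        r_top = 2.0 * comp.r_max if comp is not None else 20.0 * p.r0
    n_cells = int(round((r_top - p.r0) / p.dr)) + 1
    return p.r0 + p.dr * np.arange(n_cells)


def _attrition_rate(r: np.ndarray, comp: CompetitionParams) -> np.ndarray:
    return comp.s * comp.b_amplitude() * r ** comp.kappa()


def step_discrete_classes(
    state: SizeDistribution,
    p: AllometryParams,
    comp: CompetitionParams | None = None,
    dt: float = 0.01,
) -> SizeDistribution:
    """One explicit Euler step of the discrete size-class chain.

    Class 0 gains recruits at rate g0 and loses members to growth-out and
    mortality; class k gains the growth flux from class k-1 and loses to its
    own growth-out and mortality.  With ``comp`` present each class also
    loses at the attrition rate s*B*r_k^kappa.  Densities are per unit
    radius, so recruitment enters as g0/dr.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    r = state.r_grid
    dr = state.dr
    rdot = allometry.growth_rate(r, p)
    mu = allometry.natural_mortality(r, p)
    loss = rdot / dr + mu
    if comp is not None:
        loss = loss + _attrition_rate(r, comp)
    bad = np.nonzero(dt * loss >= 1.0)[0]
    if bad.size:
        k = int(bad[0])
        raise ValueError(
            f"explicit step unstable: dt*(rdot/dr + mu + attrition) = "
            f"{dt * loss[k]:.3g} >= 1 at class {k} (r = {r[k]:.3g}); reduce dt"
        )
    n_new = state.n * (1.0 - dt * loss)
    n_new[0] += dt * p.g0 / dr
    n_new[1:] += dt * state.n[:-1] * rdot[:-1] / dr
    return SizeDistribution(r, n_new, state.n0_pool, state.t + dt)


def step_pde(
    state: SizeDistribution,
    p: AllometryParams,
    comp: CompetitionParams | None = None,
    canopy: bool = False,
    dt: float = 0.01,
    kernel: Literal["heaviside", "logistic"] = "heaviside",
    kernel_width: float = 0.1,
    clip_log: list | None = None,
) -> SizeDistribution:
    """One upwind finite-volume step of the continuum size-class PDE.

    Transport of the flux n*rdot toward larger r, explicit sink terms
    (natural mortality, symmetric attrition if ``comp``, canopy loss if
    ``canopy``), and the scalar sapling-pool ODE whose outflow
    n0_pool*rdot(r0)/dr enters the first cell as influx.  Mass leaving the
    top of the grid is outflow.  Sinks are clipped so no cell goes negative;
    clip events are appended to ``clip_log`` when provided.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    r = state.r_grid
    dr = state.dr
    rdot = allometry.growth_rate(r, p)
    cfl = dt * float(np.max(rdot)) / dr
    if cfl > 1.0:
        raise ValueError(f"CFL violation: dt*max(rdot)/dr = {cfl:.3g} > 1; reduce dt")
    mu = allometry.natural_mortality(r, p)
    sink = mu.copy() if isinstance(mu, np.ndarray) else np.full_like(r, mu)
    if comp is not None:
        sink = sink + _attrition_rate(r, comp)
    if canopy:
        if comp is None:
            raise ValueError("canopy=True requires CompetitionParams")
        sink = sink + canopy_loss_rate(state, comp, kernel=kernel,
                                       kernel_width=kernel_width)

    # upwind face fluxes: flux[i] enters cell i from below; flux[m] is outflow
    flux = np.empty(r.size + 1)
    flux[1:] = state.n * rdot
    pool_rate = rdot[0] / dr + mu[0]
    if comp is not None:
        pool_rate += _attrition_rate(np.array([r[0]]), comp)[0]
    flux[0] = state.n0_pool * rdot[0] / dr

    n_new = state.n + dt * (flux[:-1] - flux[1:]) / dr
    removal = dt * sink * state.n
    avail = np.maximum(n_new, 0.0)
    clipped = removal > avail
    if np.any(clipped):
        if clip_log is not None:
            clip_log.append((state.t, int(np.count_nonzero(clipped))))
        removal = np.where(clipped, avail, removal)
    n_new = n_new - removal
    if np.any(n_new < -1e-13 * max(1.0, float(np.max(state.n, initial=0.0)))):
        raise AssertionError("negative density after step")
    n_new = np.maximum(n_new, 0.0)

    pool_new = state.n0_pool + dt * (p.g0 - state.n0_pool * pool_rate)
    pool_new = max(pool_new, 0.0)
    return SizeDistribution(r, n_new, pool_new, state.t + dt)


def steady_state_density(
    r,
    p: AllometryParams,
    comp: CompetitionParams,
    n0_tilde: float = 1.0,
) -> np.ndarray:
    """Closed-form stationary density of the generalized size-class model.

    n(r) = n0_tilde * (r/r0)^(-alpha) * exp(-F/(kappa+1-b) * r^(kappa+1-b))
    with F = 8*B*s*c_m^(b-1) / (3*a_bar).  With s = 0 this is the pure power
    law r^(-alpha).
    """
    if p.a_bar == 0:
        raise ValueError("no stationary flux exists with a_bar = 0")
    r = np.asarray(r, dtype=float)
    alpha = allometry.alpha_symmetric(p)
    k = comp.kappa()
    expo = k + 1.0 - p.b
    if expo <= 0:
        raise ValueError(f"kappa + 1 - b must be > 0, got {expo}")
    F = 8.0 * comp.b_amplitude() * comp.s * p.c_m ** (p.b - 1.0) / (3.0 * p.a_bar)
    return n0_tilde * (r / p.r0) ** (-alpha) * np.exp(-F / expo * r**expo)


def canopy_loss_rate(
    state: SizeDistribution,
    c: CompetitionParams,
    kernel: Literal["heaviside", "logistic"] = "heaviside",
    kernel_width: float = 0.1,
) -> np.ndarray:
    """Per-capita loss rate from canopy shading by larger individuals.

    rate(r) = c_comp * a_can(r) * ∫_r^{r_max} n(r') a_can(r') K(r'-r) dr'
    where K is the Heaviside step Theta(r' - r - dr_crit) (default) or a
    logistic ramp of the given width centred at dr_crit.  Trapezoid rule on
    the grid; the caller multiplies by n(r) to get the population loss.
    """
    r = state.r_grid
    if r[-1] < c.r_max:
        raise ValueError("state grid must reach r_max")
    w = state.n * c.canopy_area(r)
    j_max = int(np.searchsorted(r, c.r_max, side="right") - 1)
    if kernel == "heaviside":
        # suffix trapezoid of w over [r_j, r_max] for every j, then pick the
        # first grid point admitted by the step kernel; integrating from
        # that point (rather than masking inside one global trapezoid)
        # avoids a spurious half-cell ramp at the kernel jump
        dr = state.dr
        seg = 0.5 * (w[:j_max] + w[1:j_max + 1]) * dr
        suffix = np.zeros(r.size)
        suffix[:j_max] = np.cumsum(seg[::-1])[::-1]
        k_crit = int(math.ceil(c.dr_crit / dr - 1e-9))
        j0 = np.arange(r.size) + k_crit
        integral = np.where(j0 <= j_max, suffix[np.minimum(j0, j_max)], 0.0)
    elif kernel == "logistic":
        diff = r[None, :] - r[:, None]  # r' - r
        K = 1.0 / (1.0 + np.exp(-(diff - c.dr_crit) / kernel_width))
        K[diff < 0] = 0.0
        integrand = np.where(r[None, :] <= c.r_max, w[None, :], 0.0) * K
        integral = np.trapezoid(integrand, r, axis=1)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return c.c_comp * c.canopy_area(r) * integral


def run_meanfield(
    p: AllometryParams,
    comp: CompetitionParams | None = None,
    mode: Literal["pde", "discrete"] = "pde",
    canopy: bool = False,
    t_max: float = 100.0,
    dt: float | None = None,
    snapshot_every: float = 1.0,
    state0: SizeDistribution | None = None,
    r_top: float | None = None,
    kernel: Literal["heaviside", "logistic"] = "heaviside",
    kernel_width: float = 0.1,
) -> Trajectory:
    """Integrate the size-class model and record snapshots.

    ``dt`` defaults to 0.8 * dr / max(rdot) (CFL with margin).  The initial
    state is empty unless ``state0`` is given.
    """
    if state0 is None:
        grid = make_grid(p, comp, r_top=r_top)
        state = SizeDistribution(grid, np.zeros_like(grid))
    else:
        state = state0.copy()
    rdot_max = float(np.max(allometry.growth_rate(state.r_grid, p))) if p.a_bar else 0.0
    if dt is None:
        dt = 0.8 * state.dr / rdot_max if rdot_max > 0 else snapshot_every / 10.0
    # shrink dt so snapshots fall exactly on the requested cadence
    dt = snapshot_every / math.ceil(snapshot_every / dt)
    traj = Trajectory()
    traj.append(state, comp)
    clip_log: list = []
    n_steps = int(math.ceil(t_max / dt - 1e-9))
    k_snap = max(1, int(round(snapshot_every / dt)))
    for i_step in range(1, n_steps + 1):
        if mode == "pde":
            state = step_pde(state, p, comp, canopy=canopy, dt=dt, kernel=kernel,
                             kernel_width=kernel_width, clip_log=clip_log)
        elif mode == "discrete":
            state = step_discrete_classes(state, p, comp, dt=dt)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        state.t = i_step * dt  # avoid float accumulation drift
        if i_step % k_snap == 0:
            traj.append(state, comp)
    if traj.times[-1] < state.t:
        traj.append(state, comp)
    traj.clip_events = sum(c for _, c in clip_log)
    return traj


def fit_loglog_slope(r, n, window: tuple[float, float]) -> tuple[float, float]:
    """Least-squares slope of log n vs log r restricted to a radius window.

    Returns (slope, stderr).  Requires >= 10 points with n > 0 inside the
    window.
    """
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    lo, hi = window
    mask = (r >= lo) & (r <= hi) & (n > 0)
    if np.count_nonzero(mask) < 10:
        raise ValueError(
            f"need >= 10 positive-density points in window {window}, "
            f"got {np.count_nonzero(mask)}"
        )
    x = np.log(r[mask])
    y = np.log(n[mask])
    A = np.vstack([x, np.ones_like(x)]).T
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    dof = max(x.size - 2, 1)
    resid = y - A @ coef
    s2 = float(resid @ resid) / dof
    sxx = float(np.sum((x - x.mean()) ** 2))
    stderr = math.sqrt(s2 / sxx) if sxx > 0 else math.inf
    return float(coef[0]), stderr


def _autocorr_period(x: np.ndarray, dt: float) -> float | None:
    """Dominant period from the first interior autocorrelation maximum."""
    x = x - x.mean()
    if np.allclose(x, 0):
        return None
    ac = np.correlate(x, x, mode="full")[x.size - 1:]
    ac /= ac[0]
    peaks, _ = find_peaks(ac)
    if peaks.size == 0:
        return None
    k = int(peaks[np.argmax(ac[peaks])])
    if k < 1:
        return None
    # parabolic refinement around the peak
    if 1 <= k < ac.size - 1:
        y0, y1, y2 = ac[k - 1], ac[k], ac[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            k = k + 0.5 * (y0 - y2) / denom
    return float(k * dt)


def detect_oscillations(
    traj: Trajectory,
    size_band: tuple[float, float],
    min_prominence_frac: float = 0.02,
    skip_frac: float = 0.1,
) -> dict:
    """Summarize oscillations of the band-integrated population.

    Detrends P(t) for the radius band with a centred moving average, counts
    interior maxima of the residual exceeding a prominence threshold (a
    fraction of the signal's full range), and estimates the dominant period
    from the autocorrelation peak.  Two or more maxima classify the
    trajectory as "oscillatory".

    Returns a dict with keys ``n_maxima``, ``period``, ``amplitude_decay``
    and ``label`` ("oscillatory" or "monotone").
    """
    if len(traj.times) < 16:
        raise ValueError("trajectory too short for oscillation analysis")
    t = np.asarray(traj.times)
    dts = np.diff(t)
    if not np.allclose(dts, dts[0], rtol=1e-6):
        raise ValueError("oscillation analysis needs uniform snapshot cadence")
    P = traj.band_population(*size_band)
    i0 = int(skip_frac * P.size)
    t, P = t[i0:], P[i0:]
    span = float(P.max() - P.min())
    if span == 0:
        return {"n_maxima": 0, "period": None, "amplitude_decay": None,
                "label": "monotone"}
    win = max(5, P.size // 8) | 1  # odd window
    pad = win // 2
    trend = np.convolve(np.pad(P, pad, mode="edge"), np.ones(win) / win,
                        mode="valid")
    resid = P - trend
    peaks, props = find_peaks(resid, prominence=min_prominence_frac * span)
    period = _autocorr_period(resid, float(dts[0]))
    decay = None
    if peaks.size >= 2:
        prom = props["prominences"]
        decay = float(prom[-1] / prom[0]) if prom[0] > 0 else None
    label = "oscillatory" if peaks.size >= 2 else "monotone"
    return {
        "n_maxima": int(peaks.size),
        "period": period,
        "amplitude_decay": decay,
        "label": label,
    }


def track_dip(
    traj: Trajectory,
    r_range: tuple[float, float] | None = None,
    min_depth: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Locate the travelling population dip in each snapshot.

    For each snapshot, finds the deepest interior local minimum of n(r)
    within ``r_range`` whose depth (relative to the smaller flanking maximum)
    exceeds ``min_depth``.  Returns (times, dip_radii) for snapshots where a
    dip exists; a shock wave shows dip radius increasing with time.
    """
    ts, rs = [], []
    for t, snap in zip(traj.times, traj.snapshots):
        r, n = snap.r_grid, snap.n
        if r_range is not None:
            mask = (r >= r_range[0]) & (r <= r_range[1])
            r, n = r[mask], n[mask]
        if r.size < 5 or np.all(n <= 0):
            continue
        mins, _ = find_peaks(-n)
        best = None
        best_depth = min_depth
        for i in mins:
            left_max = np.max(n[:i]) if i > 0 else n[i]
            right_max = np.max(n[i + 1:]) if i < n.size - 1 else n[i]
            flank = min(left_max, right_max)
            if flank <= 0:
                continue
            depth = (flank - n[i]) / flank
            if depth > best_depth:
                best_depth = depth
                best = i
        if best is not None:
            ts.append(t)
            rs.append(r[best])
    return np.asarray(ts), np.asarray(rs)
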