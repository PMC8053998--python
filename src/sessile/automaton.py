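"""Individual-based 2D spatial simulation on a periodic square plot.

Each individual is a disk-rooted organism with position (x, y) and basal
radius r.  One sweep: draw a single plot-wide scarcity value from the Pareto
tail, recruit Poisson(g0*dt) saplings at uniform positions, grow every
individual allometrically, apply natural mortality, then compute every
survivor's net resource balance

    dQ_i = eps * rho(t) * (a_i - f * sum_j overlap(i, j)) - beta1 * r_i^eta1

with lens overlaps of the resource disks (a_i = c_r * r_i^(2*alpha_r)) under
minimum-image distances; individuals with dQ < 0 die with rate s.  The
extraction efficiency defaults to the calibration that makes the largest
admissible organism marginal at the minimum scarcity, tying the automaton's
stress mortality to the mean-field attrition amplitude B = r_max^(-kappa).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import allometry
from .params import AllometryParams, CompetitionParams

__all__ = [
    "ForestState",
    "ScarcityDraw",
    "sample_scarcity",
    "circle_overlap_area",
    "resource_balance",
    "step_automaton",
    "run_automaton",
    "default_dt",
]


@dataclass
class ScarcityDraw:
    """A realized plot-wide scarcity xi >= xi0 and resource density rho_bar/xi."""

    xi: np.ndarray
    rho: np.ndarray


@dataclass
class ForestState:
    """Set of individuals on a periodic square plot of side L."""

    x: np.ndarray
    y: np.ndarray
    r: np.ndarray
    L: float
    t: float = 0.0
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    next_id: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if not (self.x.shape == self.y.shape == self.r.shape):
            raise ValueError("x, y, r must have identical shapes")
        if self.L <= 0:
            raise ValueError("plot side L must be positive")
        if np.any((self.x < 0) | (self.x >= self.L) | (self.y < 0) | (self.y >= self.L)):
            raise ValueError("positions must lie in [0, L)")
        if self.ids is None:
            self.ids = np.arange(self.x.size, dtype=np.int64)
            self.next_id = self.x.size
        else:
            self.ids = np.asarray(self.ids, dtype=np.int64)

    @property
    def size(self) -> int:
        return int(self.x.size)

    def copy(self) -> "ForestState":
        return ForestState(self.x.copy(), self.y.copy(), self.r.copy(),
                           self.L, self.t, self.ids.copy(), self.next_id)


def sample_scarcity(c: CompetitionParams, count: int, rng: np.random.Generator
                    ) -> ScarcityDraw:
    """Draw scarcity values from the Pareto tail h(xi) = (nu-1) xi0^(nu-1) xi^(-nu).

    Inverse-transform sampling on xi >= xi0.  With the default calibration
    xi0 = (nu-2)/(nu-1) the mean scarcity is exactly 1.
    """
    u = rng.random(count)
    xi = c.xi0 * (1.0 - u) ** (-1.0 / (c.nu - 1.0))
    return ScarcityDraw(xi=xi, rho=c.rho_bar / xi)


def circle_overlap_area(r1, r2, d):
    """Exact lens area of two overlapping circles at centre distance d.

    Symmetric in (r1, r2); equals pi*min(r1, r2)^2 under full containment
    and 0 once d >= r1 + r2.  Vectorized over arrays.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(r1 <= 0) or np.any(r2 <= 0):
        raise ValueError("radii must be positive")
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    r1, r2, d = np.broadcast_arrays(r1, r2, d)
    small = np.minimum(r1, r2)
    big = np.maximum(r1, r2)
    out = np.zeros(d.shape)
    contained = d <= big - small
    out[contained] = math.pi * small[contained] ** 2
    partial = (~contained) & (d < r1 + r2)
    if np.any(partial):
        a, b, dd = r1[partial], r2[partial], d[partial]
        d1 = (dd**2 + a**2 - b**2) / (2.0 * dd)
        d2 = dd - d1
        out[partial] = (
            a**2 * np.arccos(np.clip(d1 / a, -1.0, 1.0))
            - d1 * np.sqrt(np.maximum(a**2 - d1**2, 0.0))
            + b**2 * np.arccos(np.clip(d2 / b, -1.0, 1.0))
            - d2 * np.sqrt(np.maximum(b**2 - d2**2, 0.0))
        )
    return out if out.ndim else float(out)


def _resource_radii(r: np.ndarray, c: CompetitionParams) -> np.ndarray:
    """Radius of the resource-capture disk, sqrt(a(r)/pi)."""
    return np.sqrt(c.resource_area(r) / math.pi)


def _overlap_sums(state: ForestState, c: CompetitionParams) -> np.ndarray:
    """Sum of resource-disk lens overlaps with all neighbours, per individual.

    Periodic minimum-image metric via a KD-tree with box topology.
    """
    n = state.size
    sums = np.zeros(n)
    if n < 2:
        return sums
    rr = _resource_radii(state.r, c)
    rmax = float(rr.max())
    cutoff = min(2.0 * rmax, 0.5 * state.L * (1 - 1e-12))
    pts = np.column_stack([state.x, state.y])
    tree = cKDTree(pts, boxsize=state.L)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if pairs.size == 0:
        return sums
    i, j = pairs[:, 0], pairs[:, 1]
    dx = np.abs(state.x[i] - state.x[j])
    dy = np.abs(state.y[i] - state.y[j])
    dx = np.minimum(dx, state.L - dx)
    dy = np.minimum(dy, state.L - dy)
    d = np.hypot(dx, dy)
    touching = d < rr[i] + rr[j]
    if not np.any(touching):
        return sums
    i, j, d = i[touching], j[touching], d[touching]
    ov = circle_overlap_area(rr[i], rr[j], d)
    np.add.at(sums, i, ov)
    np.add.at(sums, j, ov)
    return sums


def resource_balance_all(state: ForestState, c: CompetitionParams,
                         draw: ScarcityDraw) -> np.ndarray:
    """Net resource balance dQ for every individual under one scarcity draw."""
    rho = float(np.asarray(draw.rho).ravel()[0])
    eps = c.eps_calibrated()
    a = c.resource_area(state.r)
    shared = _overlap_sums(state, c)
    return eps * rho * (a - c.f * shared) - c.basal_need(state.r)


def resource_balance(i: int, state: ForestState, c: CompetitionParams,
                     draw: ScarcityDraw) -> float:
    """Net resource balance dQ of individual ``i`` (see module docstring)."""
    return float(resource_balance_all(state, c, draw)[i])


def default_dt(p: AllometryParams, c: CompetitionParams) -> float:
    """Default sweep duration 0.1 / max(rdot(r_max)/dr, mu(r0), s)."""
    rates = [c.s, allometry.natural_mortality(p.r0, p)]
    if p.a_bar > 0:
        rates.append(allometry.growth_rate(c.r_max, p) / p.dr)
    fastest = max(rates)
    if fastest <= 0:
        return 0.1
    return 0.1 / fastest


def step_automaton(
    state: ForestState,
    p: AllometryParams,
    c: CompetitionParams,
    dt: float,
    rng: np.random.Generator,
    hard_cap: bool = False,
) -> tuple[ForestState, dict]:
    """One sweep of the automaton; returns the new state and an event log.

    Sweep order: scarcity draw; Poisson recruitment at radius r0; allometric
    growth (exact per-step integral of rdot); natural death with probability
    1 - exp(-mu(r) dt); resource balance for every survivor and stress death
    with probability 1 - exp(-s dt) where dQ < 0; optional hard cap of radii
    at r_max.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p_nat_max = 1.0 - math.exp(-allometry.natural_mortality(p.r0, p) * dt)
    p_stress = 1.0 - math.exp(-c.s * dt)
    if p_nat_max > 0.5 or p_stress > 0.5:
        raise ValueError(
            f"per-event probability exceeds 0.5 (natural {p_nat_max:.3g}, "
            f"stress {p_stress:.3g}); reduce dt"
        )
    events = {"births": 0, "natural_deaths": 0, "competitive_deaths": 0,
              "xi": None, "natural_death_radii": np.empty(0),
              "competitive_death_radii": np.empty(0)}

    draw = sample_scarcity(c, 1, rng)
    events["xi"] = float(draw.xi[0])

    st = state.copy()
    k = rng.poisson(p.g0 * dt)
    if k > 0:
        nx = rng.uniform(0.0, st.L, k)
        ny = rng.uniform(0.0, st.L, k)
        st.x = np.concatenate([st.x, nx])
        st.y = np.concatenate([st.y, ny])
        st.r = np.concatenate([st.r, np.full(k, p.r0)])
        st.ids = np.concatenate([st.ids, st.next_id + np.arange(k, dtype=np.int64)])
        st.next_id += k
        events["births"] = int(k)

    if p.a_bar > 0 and st.size:
        # exact increment of dr/dt = k r^b over dt
        one_mb = 1.0 - p.b
        st.r = (st.r**one_mb + one_mb * p.growth_prefactor * dt) ** (1.0 / one_mb)

    if st.size:
        mu = allometry.natural_mortality(st.r, p)
        die_nat = rng.random(st.size) < 1.0 - np.exp(-mu * dt)
        events["natural_deaths"] = int(np.count_nonzero(die_nat))
        events["natural_death_radii"] = st.r[die_nat]
        keep = ~die_nat
        st.x, st.y, st.r, st.ids = st.x[keep], st.y[keep], st.r[keep], st.ids[keep]

    if st.size and c.s > 0:
        dq = resource_balance_all(st, c, draw)
        stressed = dq < 0
        roll = rng.random(st.size)
        die_comp = stressed & (roll < p_stress)
        events["competitive_deaths"] = int(np.count_nonzero(die_comp))
        events["competitive_death_radii"] = st.r[die_comp]
        keep = ~die_comp
        st.x, st.y, st.r, st.ids = st.x[keep], st.y[keep], st.r[keep], st.ids[keep]

    if hard_cap:
        np.minimum(st.r, c.r_max, out=st.r)
    st.t = state.t + dt
    return st, events


def run_automaton(
    p: AllometryParams,
    c: CompetitionParams,
    L: float = 50.0,
    t_max: float = 50.0,
    dt: float | None = None,
    snapshot_every: float = 5.0,
    seed: int = 0,
    hard_cap: bool = False,
    burn_in: float = 0.0,
    population_cap: int = 200_000,
    initial_state: ForestState | None = None,
) -> dict:
    """Run the automaton from an empty plot; return snapshots and a summary.

    Fully reproducible from ``seed``.  Snapshots (taken after ``burn_in``)
    are ForestState copies; the summary holds pooled radii across snapshots,
    event totals, and the population time series.

    Raises RuntimeError if the population exceeds ``population_cap``.
    """
    rng = np.random.default_rng(seed)
    if dt is None:
        dt = default_dt(p, c)
    state = initial_state.copy() if initial_state is not None else ForestState(
        np.empty(0), np.empty(0), np.empty(0), L=L)
    snapshots: list[ForestState] = []
    times: list[float] = []
    pop_series: list[tuple[float, int]] = []
    totals = {"births": 0, "natural_deaths": 0, "competitive_deaths": 0}
    nat_radii: list[np.ndarray] = []
    comp_radii: list[np.ndarray] = []
    pooled: list[np.ndarray] = []
    n_steps = int(math.ceil(t_max / dt))
    next_snap = max(burn_in, snapshot_every)
    for _ in range(n_steps):
        prev_n = state.size
        state, ev = step_automaton(state, p, c, dt, rng, hard_cap=hard_cap)
        # exact event accounting each step
        assert state.size == prev_n + ev["births"] - ev["natural_deaths"] - \
            ev["competitive_deaths"]
        for key in totals:
            totals[key] += ev[key]
        nat_radii.append(ev["natural_death_radii"])
        comp_radii.append(ev["competitive_death_radii"])
        pop_series.append((state.t, state.size))
        if state.size > population_cap:
            raise RuntimeError(
                f"population exploded: {state.size} individuals at t={state.t:.3g} "
                f"(cap {population_cap}); check recruitment/mortality balance"
            )
        if state.t >= next_snap - 1e-9:
            snapshots.append(state.copy())
            times.append(state.t)
            pooled.append(state.r.copy())
            next_snap += snapshot_every
    return {
        "snapshots": snapshots,
        "times": times,
        "pooled_radii": np.concatenate(pooled) if pooled else np.empty(0),
        "population": np.asarray(pop_series),
        "event_totals": totals,
        "natural_death_radii": np.concatenate(nat_radii) if nat_radii else np.empty(0),
        "competitive_death_radii": (np.concatenate(comp_radii) if comp_radii
                                    else np.empty(0)),
        "final_state": state,
        "seed": seed,
        "dt": dt,
        "params": {"L": L, "t_max": t_max, "hard_cap": hard_cap},
    }
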