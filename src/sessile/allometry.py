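"""Individual-level scaling laws and exponent relations.

Pure functions of the allometric demography framework: radial growth
rdot = (3/8) c_m^(1-b) a_bar r^b and its time integral, natural mortality
mu(r) = A_bar r^(b-1), the symmetric population-number exponent
alpha = b + 8 A_bar / (3 a_bar c_m^(1-b)) and its inverse, the competition
exponent kappa = (nu-1)(eta1 - 2 alpha_r), the fatal-fluctuation probability
(r/r_max)^kappa, the asymmetric (canopy) exponent 4 alpha_can + 2 - b, and
the attrition-induced size cutoff.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.integrate import solve_ivp

from .params import AllometryParams, CompetitionParams, ParameterWarning

__all__ = [
    "growth_rate",
    "grow_trajectory",
    "natural_mortality",
    "alpha_symmetric",
    "mortality_coefficient_for_alpha",
    "kappa",
    "fatal_fluctuation_prob",
    "alpha_asymmetric",
    "r_cutoff",
]


def _check_positive_radius(r) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("radius must be positive")
    return r


def growth_rate(r, p: AllometryParams):
    """Radial growth rate rdot(r) = (3/8) c_m^(1-b) a_bar r^b.

    Parameters
    ----------
    r : array_like
        Basal radius, > 0.
    p : AllometryParams

    Returns
    -------
    ndarray or float
        Growth rate, same shape as ``r``; nonnegative.
    """
    r = _check_positive_radius(r)
    out = p.growth_prefactor * r**p.b
    return out if out.ndim else float(out)


def grow_trajectory(r_init: float, p: AllometryParams, t_grid) -> np.ndarray:
    """Integrate dr/dt = growth_rate(r) from r_init over t_grid.

    For long times the trajectory approaches r ~ t^(1/(1-b)).

    Parameters
    ----------
    r_init : float
        Initial radius, > 0.
    t_grid : array_like
        Strictly increasing evaluation times; t_grid[0] is the initial time.

    Returns
    -------
    ndarray
        Radius at each time in ``t_grid``.
    """
    if r_init <= 0:
        raise ValueError("r_init must be positive")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a 1D strictly increasing array")
    if p.a_bar == 0:
        return np.full_like(t_grid, r_init)
    sol = solve_ivp(
        lambda _t, y: p.growth_prefactor * y ** p.b,
        (t_grid[0], t_grid[-1]),
        [r_init],
        t_eval=t_grid,
        rtol=1e-9,
        atol=1e-12,
        method="RK45",
    )
    if not sol.success:
        raise RuntimeError(f"growth integration failed: {sol.message}")
    return sol.y[0]


def natural_mortality(r, p: AllometryParams):
    """Natural (metabolic) mortality rate mu(r) = A_bar * r^(b-1).

    Decreasing in r for b < 1: small organisms die fastest.
    """
    r = _check_positive_radius(r)
    out = p.A_bar * r ** (p.b - 1.0)
    return out if out.ndim else float(out)


def alpha_symmetric(p: AllometryParams) -> float:
    """Population-number exponent alpha = b + 8 A_bar / (3 a_bar c_m^(1-b)).

    Stationarity of the size-class model with n(r) ~ r^(-alpha) fixes this
    exponent from the ratio of mortality to growth coefficients.  At
    a_bar = 0 no organism survives beyond birth and alpha diverges; this is
    returned as ``math.inf`` rather than raised.
    """
    if p.a_bar == 0:
        return math.inf
    return p.b + 8.0 * p.A_bar / (3.0 * p.a_bar * p.c_m ** (1.0 - p.b))


def mortality_coefficient_for_alpha(alpha_target: float, p: AllometryParams) -> float:
    """Mortality coefficient A_bar = (3/8) a_bar c_m^(1-b) (alpha - b).

    Exact algebraic inverse of :func:`alpha_symmetric`.
    """
    if alpha_target < p.b:
        raise ValueError(
            f"alpha_target ({alpha_target}) must be >= growth exponent b ({p.b})"
        )
    return 0.375 * p.a_bar * p.c_m ** (1.0 - p.b) * (alpha_target - p.b)


def kappa(c: CompetitionParams) -> float:
    """Competition exponent kappa = (nu-1)*(eta1 - 2*alpha_r).

    Positive when basal need grows faster than resource area (eta1 > 2 alpha_r),
    so larger organisms sit closer to their resource margin.
    """
    return c.kappa()


def fatal_fluctuation_prob(r, c: CompetitionParams):
    """Probability that a scarcity fluctuation is fatal: B * r^kappa.

    With the single-largest-organism normalization B = r_max^(-kappa) this is
    (r / r_max)^kappa, in [0, 1] and increasing in r for kappa > 0.  Radii
    above r_max are clamped to probability 1 with a warning.  For the
    permitted-but-warned kappa <= 0 regime B = r0^(-kappa), so the smallest
    organism is the one with probability 1.
    """
    r = _check_positive_radius(r)
    k = c.kappa()
    out = c.b_amplitude() * r**k
    if np.any(out > 1.0):
        warnings.warn(
            "fatal_fluctuation_prob clamped to 1 for radii beyond the "
            "normalization anchor",
            ParameterWarning,
            stacklevel=2,
        )
        out = np.minimum(out, 1.0)
    return out if out.ndim else float(out)


def alpha_asymmetric(alpha_can: float, b: float) -> float:
    """Population-number exponent under asymmetric (canopy) competition.

    alpha = 4*alpha_can + 2 - b: free of growth/mortality coefficients, set
    by how canopy area scales with radius and the metabolic growth exponent.
    Generally incompatible with the space-filling value alpha = 2.
    """
    if alpha_can <= 0:
        raise ValueError(f"alpha_can must be > 0, got {alpha_can}")
    if not 0 < b < 1:
        raise ValueError(f"b must satisfy 0 < b < 1, got {b}")
    return 4.0 * alpha_can + 2.0 - b


def r_cutoff(F: float, kappa_val: float, b: float) -> float:
    """Attrition-induced size cutoff [F / (kappa+1-b)]^(-1/(kappa+1-b)).

    The steady-state density decays as exp(-F r^(kappa+1-b)/(kappa+1-b));
    this is the radius scale where that truncation sets in.  Decreasing in F:
    stronger competitive costs push the cutoff to smaller sizes.
    """
    expo = kappa_val + 1.0 - b
    if expo <= 0:
        raise ValueError(f"kappa + 1 - b must be > 0, got {expo}")
    if F <= 0:
        raise ValueError(f"F must be > 0, got {F}")
    return (F / expo) ** (-1.0 / expo)
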