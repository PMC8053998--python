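"""Canonical study configurations.

These presets pin down the conditions under which the package's headline
results are computed, so that tests, the acceptance script, and users all
run the same experiments:

* ``space_filling`` — the demographic-equilibrium benchmark: b = 1/3,
  c_m = 1, growth coefficient 0.8 (growth-rate prefactor 0.3) and mortality
  chosen so the mortality-to-growth ratio 8*A_bar/(3*a_bar*c_m^(2/3)) is
  5/3, giving population exponent alpha = 2.
* ``forest_stand`` — the individual-based stand with weak attrition
  (s = 0.05), where a visible scaling law coexists with a competition
  cutoff near r_max; the basal coefficient beta1 is varied at fixed
  extraction efficiency to move the cutoff.
* the phase trajectory (``phase_random`` / ``phase_liquid`` /
  ``phase_ordered``) — one fixed competition environment (costly sharing
  f = 2, resource-disk radius 2.5 r, extraction efficiency such that an
  isolated sapling is stressed only at scarcity ~30) across which only the
  growth, death, and attrition rates move: significant growth gives random
  spacing; frozen growth and death with moderate attrition a dense liquid;
  lethal attrition the most ordered packing this dynamics reaches.
"""

from __future__ import annotations

import math

from .params import AllometryParams, CompetitionParams

__all__ = [
    "space_filling",
    "forest_stand",
    "phase_random",
    "phase_liquid",
    "phase_ordered",
    "canopy_shock",
    "PHASE_PLOT_SIDE",
]

#: plot side used for desk-scale spatial runs
PHASE_PLOT_SIDE = 50.0

# competition environment shared along the phase trajectory: geometry-
# dominated lethality (isolated sapling stressed only at xi ~ 30) and
# costly sharing so crowding, not scarcity churn, decides who dies
_PHASE_ENV = dict(
    f=2.0,
    c_r=math.pi * 6.25,
    r_max=30.0,
    beta1=1.0,
    eps=30.0 / (math.pi * 6.25),
)


def space_filling(g0: float = 10.0, dr: float = 0.05) -> AllometryParams:
    """Allometry with alpha = 2 (space filling): A_bar/a_bar tuned to 5/3·3/8."""
    a_bar = 0.8
    return AllometryParams(a_bar=a_bar, A_bar=5.0 / 3.0 * 3.0 * a_bar / 8.0,
                           b=1.0 / 3.0, c_m=1.0, g0=g0, r0=1.0, dr=dr)


def forest_stand(beta1: float = 1.0, s: float = 0.05,
                 g0: float = 50.0) -> tuple[AllometryParams, CompetitionParams]:
    """Individual-based stand in the weak-attrition scaling regime.

    The extraction efficiency is calibrated once at beta1 = 1 and held fixed
    while ``beta1`` varies, so raising the basal metabolic coefficient moves
    the size cutoff to smaller radii.
    """
    p = space_filling(g0=g0)
    ref = CompetitionParams(s=s, r_max=10.0, beta1=1.0)
    return p, CompetitionParams(s=s, r_max=10.0, beta1=beta1,
                                eps=ref.eps_calibrated())


def phase_random(s: float = 0.2, g0: float = 150.0
                 ) -> tuple[AllometryParams, CompetitionParams, float]:
    """Significant growth and mortality: spacing statistically random.

    Returns (allometry, competition, dt).
    """
    p = space_filling(g0=g0)
    return p, CompetitionParams(s=s, **_PHASE_ENV), 0.0077


def phase_liquid() -> tuple[AllometryParams, CompetitionParams, float]:
    """Slow growth, no natural death, moderate attrition: dense liquid."""
    p = AllometryParams(a_bar=0.02, A_bar=0.0, g0=100.0, r0=1.0, dr=0.05)
    return p, CompetitionParams(s=1.0, **_PHASE_ENV), 0.01


def phase_ordered() -> tuple[AllometryParams, CompetitionParams, float]:
    """Frozen sizes, lethal attrition: the most ordered packing reached."""
    p = AllometryParams(a_bar=0.0, A_bar=0.0, g0=100.0, r0=1.0, dr=0.05)
    return p, CompetitionParams(s=20.0, **_PHASE_ENV), 0.01


def canopy_shock() -> tuple[AllometryParams, CompetitionParams]:
    """Mean-field canopy-competition regime that excites population waves.

    Strong Heaviside shading (threshold 3 radius units) with growth fast
    enough that the small-size die-off propagates up before canopy cover
    relaxes.
    """
    p = AllometryParams(a_bar=0.8, A_bar=0.2, g0=10.0, r0=1.0, dr=0.05)
    c = CompetitionParams(s=0.0, r_max=10.0, dr_crit=3.0, c_comp=0.02,
                          c_can=math.pi, alpha_can=2.0)
    return p, c
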