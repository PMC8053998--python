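"""Parameter containers for the allometric demography model.

Two dataclasses hold every tunable of the framework: individual-level
allometry (growth, natural mortality, recruitment) and competition
(resource-area scaling, heavy-tailed scarcity, sharing, attrition, canopy
shading).  Validation happens at construction; derived quantities such as
the competition exponent kappa and the fatal-fluctuation amplitude B are
exposed as methods so that every module shares one definition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields, replace


class ParameterWarning(UserWarning):
    """Raised for permitted-but-unusual parameter regimes."""


@dataclass
class AllometryParams:
    """Individual-level scaling laws.

    Parameters
    ----------
    a_bar : float
        Growth coefficient (per unit time).  The radial growth rate is
        (3/8) * c_m**(1-b) * a_bar * r**b.
    b : float
        Metabolic growth exponent, 0 < b < 1 (default 1/3).
    c_m : float
        Mass--radius coefficient in r = c_m * m**(3/8).
    A_bar : float
        Natural-mortality coefficient: mu(r) = A_bar * r**(b-1).
    g0 : float
        Sapling recruitment rate (individuals per unit time).
    r0 : float
        Smallest tracked radius (length).
    dr : float
        Size-class width (length).
    """

    a_bar: float = 0.8
    b: float = 1.0 / 3.0
    c_m: float = 1.0
    A_bar: float = 0.5
    g0: float = 10.0
    r0: float = 1.0
    dr: float = 0.05

    def __post_init__(self) -> None:
        if self.a_bar < 0:
            raise ValueError(f"a_bar must be >= 0, got {self.a_bar}")
        if self.A_bar < 0:
            raise ValueError(f"A_bar must be >= 0, got {self.A_bar}")
        if self.g0 < 0:
            raise ValueError(f"g0 must be >= 0, got {self.g0}")
        if self.r0 <= 0:
            raise ValueError(f"r0 must be > 0, got {self.r0}")
        if self.dr <= 0:
            raise ValueError(f"dr must be > 0, got {self.dr}")
        if not 0 < self.b < 1:
            raise ValueError(f"growth exponent b must satisfy 0 < b < 1, got {self.b}")
        if self.c_m <= 0:
            raise ValueError(f"c_m must be > 0, got {self.c_m}")

    @property
    def growth_prefactor(self) -> float:
        """Coefficient of r**b in the radial growth rate."""
        return 0.375 * self.c_m ** (1.0 - self.b) * self.a_bar

    def replace(self, **kw) -> "AllometryParams":
        return replace(self, **kw)


@dataclass
class CompetitionParams:
    """Resource-area competition and heavy-tailed scarcity.

    The resource area of an individual of radius r is a(r) = c_r * r**(2*alpha_r)
    and its basal need is Q0(r) = beta1 * r**eta1.  Plot-wide scarcity xi is
    Pareto with tail exponent nu on xi >= xi0; realized resource density is
    rho_bar / xi.  Individuals whose net resource balance is negative die with
    rate ``s``.  Canopy (asymmetric) competition uses the shading area
    a_can(r) = c_can * r**(2*alpha_can) with a Heaviside kernel of threshold
    ``dr_crit`` and rate constant ``c_comp``.

    ``eps`` (extraction efficiency) defaults to None, meaning it is calibrated
    jointly with rho_bar so that the mean-field fatal-fluctuation probability
    is exactly 1 for the single largest organism at r_max — the same
    normalization that sets B = r_max**(-kappa).
    """

    beta1: float = 1.0
    eta1: float = 2.5
    alpha_r: float = 1.0
    c_r: float = math.pi
    nu: float = 2.5
    xi0: float | None = None
    eps: float | None = None
    f: float = 0.5
    s: float = 1.0
    rho_bar: float = 1.0
    r_max: float = 10.0
    r0: float = 1.0
    c_can: float = math.pi
    alpha_can: float = 2.0
    dr_crit: float = 3.0
    c_comp: float = 0.0

    def __post_init__(self) -> None:
        if self.nu <= 1:
            raise ValueError(f"scarcity exponent nu must be > 1, got {self.nu}")
        if self.s < 0:
            raise ValueError(f"attrition rate s must be >= 0, got {self.s}")
        if self.r_max <= self.r0:
            raise ValueError(
                f"r_max ({self.r_max}) must exceed the smallest radius r0 ({self.r0})"
            )
        if self.beta1 < 0 or self.c_r <= 0 or self.rho_bar <= 0:
            raise ValueError("beta1 >= 0, c_r > 0, rho_bar > 0 required")
        if not 0 <= self.f:
            raise ValueError(f"sharing fraction f must be >= 0, got {self.f}")
        if self.f > 1:
            warnings.warn(
                f"sharing fraction f={self.f} > 1: competition is costlier than "
                "zero-sum; permitted only if configured deliberately",
                ParameterWarning,
                stacklevel=2,
            )
        if self.xi0 is None:
            if self.nu <= 2:
                raise ValueError(
                    "the mean-1 calibration xi0=(nu-2)/(nu-1) needs nu > 2; for "
                    "1 < nu <= 2 extreme events dominate and the mean diverges — "
                    "supply xi0 explicitly"
                )
            self.xi0 = (self.nu - 2.0) / (self.nu - 1.0)
        elif self.xi0 <= 0:
            raise ValueError(f"xi0 must be > 0, got {self.xi0}")
        elif self.nu <= 2:
            warnings.warn(
                f"nu={self.nu} <= 2: scarcity mean is undefined; using the "
                f"user-supplied xi0={self.xi0}",
                ParameterWarning,
                stacklevel=2,
            )
        if self.kappa() <= 0:
            warnings.warn(
                f"kappa={self.kappa():.4g} <= 0: resource area grows at least as "
                "fast as basal need, so larger organisms are buffered rather than "
                "constrained — outside the expected regime",
                ParameterWarning,
                stacklevel=2,
            )

    def kappa(self) -> float:
        """Competition exponent kappa = (nu-1)*(eta1 - 2*alpha_r)."""
        return (self.nu - 1.0) * (self.eta1 - 2.0 * self.alpha_r)

    def b_amplitude(self) -> float:
        """Amplitude B of the fatal-fluctuation probability B * r**kappa.

        With ``eps`` unset this is the single-largest-organism normalization
        B = r_max**(-kappa) (B = r0**(-kappa) in the warned kappa <= 0 regime,
        so the smallest organism has probability 1).  With an explicit ``eps``
        the amplitude follows from the scarcity tail evaluated at the basal
        threshold, B = (xi0 / C)**(nu-1) with
        C = eps * rho_bar * (1 - f) * c_r / beta1.
        """
        k = self.kappa()
        if self.eps is None:
            anchor = self.r_max if k > 0 else self.r0
            return anchor ** (-k)
        c = self.eps * self.rho_bar * (1.0 - self.f) * self.c_r / self.beta1
        return (self.xi0 / c) ** (self.nu - 1.0)

    def eps_calibrated(self) -> float:
        """Extraction efficiency implied by B = r_max**(-kappa).

        Solves xi_basal(r_max) = xi0, i.e. the largest organism is marginal at
        the minimum scarcity, so that the automaton's stress mortality and the
        mean-field attrition term share one normalization.
        """
        if self.eps is not None:
            return self.eps
        if self.f >= 1:
            raise ValueError("eps calibration requires sharing fraction f < 1")
        return (
            self.xi0
            * self.beta1
            * self.r_max ** (self.eta1 - 2.0 * self.alpha_r)
            / ((1.0 - self.f) * self.c_r * self.rho_bar)
        )

    def resource_area(self, r):
        """Resource-capture area a(r) = c_r * r**(2*alpha_r)."""
        return self.c_r * r ** (2.0 * self.alpha_r)

    def basal_need(self, r):
        """Basal metabolic requirement Q0(r) = beta1 * r**eta1."""
        return self.beta1 * r**self.eta1

    def canopy_area(self, r):
        """Canopy (shading) area a_can(r) = c_can * r**(2*alpha_can)."""
        return self.c_can * r ** (2.0 * self.alpha_can)

    def replace(self, **kw) -> "CompetitionParams":
        kw.setdefault("xi0", self.xi0)
        return replace(self, **kw)


_ALLOMETRY_FIELDS = {f.name for f in fields(AllometryParams)}
_COMPETITION_FIELDS = {f.name for f in fields(CompetitionParams)}


def allometry_from_mapping(section: dict) -> AllometryParams:
    """Build AllometryParams from a flat config section; unknown keys error."""
    unknown = set(section) - _ALLOMETRY_FIELDS
    if unknown:
        raise KeyError(
            f"unknown [allometry] keys: {sorted(unknown)}; "
            f"valid keys are {sorted(_ALLOMETRY_FIELDS)}"
        )
    return AllometryParams(**section)


def competition_from_mapping(section: dict) -> CompetitionParams:
    """Build CompetitionParams from a flat config section; unknown keys error."""
    unknown = set(section) - _COMPETITION_FIELDS
    if unknown:
        raise KeyError(
            f"unknown [competition] keys: {sorted(unknown)}; "
            f"valid keys are {sorted(_COMPETITION_FIELDS)}"
        )
    return CompetitionParams(**section)
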