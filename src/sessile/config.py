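"""Run configuration: flat sectioned TOML in, validated RunConfig out.

Sections: [allometry], [competition], [run], [sweep].  Unknown keys anywhere
are errors (typo protection), a seed is mandatory for stochastic modes, and
inconsistent exponent combinations (a non-normalizable stationary tail with
attrition enabled) are rejected at load time.  ``dump_manifest`` writes the
fully resolved parameter set back out as TOML so a run can be reproduced
from its manifest alone.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

from .params import (
    AllometryParams,
    CompetitionParams,
    allometry_from_mapping,
    competition_from_mapping,
)

__all__ = ["RunConfig", "load_config", "dump_manifest"]

_RUN_KEYS = {
    "mode": "automaton",          # automaton | meanfield
    "meanfield_mode": "pde",      # pde | discrete
    "canopy": False,
    "L": 50.0,
    "t_max": 50.0,
    "dt": None,
    "seed": None,
    "snapshot_every": 5.0,
    "burn_in": 0.0,
    "hard_cap": False,
    "bin_width": 1.0 / 20.0,      # KL histogram bin, in mean-spacing units
}
_SWEEP_KEYS = {
    "a_bar": None,   # list of growth coefficients
    "A_bar": None,   # list of mortality coefficients
    "s": None,       # list of attrition rates
    "max_cells": 64,
}
_STOCHASTIC_MODES = {"automaton"}


@dataclass
class RunConfig:
    """Fully resolved configuration of one experiment."""

    allometry: AllometryParams
    competition: CompetitionParams
    run: dict = field(default_factory=dict)
    sweep: dict = field(default_factory=dict)

    def sweep_axes(self) -> dict[str, list[float]]:
        axes = {}
        for key in ("a_bar", "A_bar", "s"):
            vals = self.sweep.get(key)
            if vals is not None:
                axes[key] = list(vals)
        return axes


def _merge_section(defaults: dict, section: dict, name: str) -> dict:
    unknown = set(section) - set(defaults)
    if unknown:
        raise KeyError(
            f"unknown [{name}] keys: {sorted(unknown)}; "
            f"valid keys are {sorted(defaults)}"
        )
    out = dict(defaults)
    out.update(section)
    return out


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML config file (see module docstring)."""
    path = Path(path)
    with path.open("rb") as fh:
        raw = tomllib.load(fh)
    known_sections = {"allometry", "competition", "run", "sweep"}
    unknown = set(raw) - known_sections
    if unknown:
        raise KeyError(f"unknown config sections: {sorted(unknown)}")
    p = allometry_from_mapping(raw.get("allometry", {}))
    comp_section = dict(raw.get("competition", {}))
    comp_section.setdefault("r0", p.r0)
    c = competition_from_mapping(comp_section)
    run = _merge_section(_RUN_KEYS, raw.get("run", {}), "run")
    sweep = _merge_section(_SWEEP_KEYS, raw.get("sweep", {}), "sweep")
    if run["mode"] not in {"automaton", "meanfield"}:
        raise ValueError(f"run.mode must be automaton or meanfield, got {run['mode']!r}")
    if run["mode"] in _STOCHASTIC_MODES and run["seed"] is None:
        raise ValueError("run.seed is required for stochastic modes")
    if c.s > 0 and c.kappa() + 1.0 - p.b <= 0:
        raise ValueError(
            f"kappa + 1 - b = {c.kappa() + 1.0 - p.b:.4g} <= 0 with attrition "
            "s > 0: the stationary tail is non-normalizable; adjust nu, eta1, "
            "alpha_r or b"
        )
    return RunConfig(allometry=p, competition=c, run=run, sweep=sweep)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def dump_manifest(cfg: RunConfig, path: str | Path) -> None:
    """Write the fully resolved config as TOML; reloads to an equal config."""
    lines = []
    for name, params in (("allometry", cfg.allometry), ("competition", cfg.competition)):
        lines.append(f"[{name}]")
        for f_ in fields(params):
            v = getattr(params, f_.name)
            if v is None:
                continue
            lines.append(f"{f_.name} = {_toml_value(v)}")
        lines.append("")
    for name, section in (("run", cfg.run), ("sweep", cfg.sweep)):
        lines.append(f"[{name}]")
        for k, v in section.items():
            if v is None:
                continue
            lines.append(f"{k} = {_toml_value(v)}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
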