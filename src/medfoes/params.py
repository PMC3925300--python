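"""Domain types and parameter validation for the Medfly extirpation simulator.

The simulator tracks individual female Mediterranean fruit flies (*Ceratitis
capitata*) through their life cycle — egg, larva, pupa, immature adult,
mature adult — under hourly ambient temperatures.  Development follows a
degree-day (thermal unit) model: each stage ``x`` requires ``K_x``
day-degrees above a stage-specific base temperature ``T_min_x``, with
development halted above ``T_max``.  Mortality, reproduction and
human-intervention parameters complete the picture; every symbol used by
the engine has a home in one of the dataclasses below.

Parameter sets serialize to flat YAML mappings keyed by the conventional
symbols (``T_min_l``, ``K_p``, ``M_star_a``, ``r_red``, ...), and
round-trip exactly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "Stage",
    "DevelopmentModel",
    "OffspringPolicy",
    "Termination",
    "StageParams",
    "ReproductionParams",
    "InterventionParams",
    "EngineConfig",
    "Agent",
    "SimulationResult",
    "validate_params",
    "params_to_dict",
    "params_from_dict",
    "save_params",
    "load_params",
]


class Stage(enum.IntEnum):
    """Developmental stages, in the only permitted transition order.

    The life cycle is strictly sequential: EGG -> LARVA -> PUPA ->
    ADULT_IMMATURE -> ADULT_MATURE.  Only mature adults reproduce.
    """

    EGG = 0
    LARVA = 1
    PUPA = 2
    ADULT_IMMATURE = 3
    ADULT_MATURE = 4

    @property
    def suffix(self) -> str:
        """Conventional one-letter subscript: e, l, p, a (both adult substages)."""
        return ("e", "l", "p", "a", "a")[self.value]


class DevelopmentModel(enum.Enum):
    """How stage transitions are decided each hour (the D_m flag).

    THERMAL_UNIT accumulates degree-hours toward an individual threshold;
    HOURLY_PROBABILITY makes the transition a memoryless random event whose
    per-hour probability matches the thermal-unit mode in expectation.
    """

    THERMAL_UNIT = "thermal_unit"
    HOURLY_PROBABILITY = "hourly_probability"


class OffspringPolicy(enum.Enum):
    """Fate of eggs laid after countermeasures start (t_S).

    STERILE: post-intervention offspring are instantiated infertile — they
    live and develop but never reproduce (the default, mimicking fruit
    stripping and SIT pressure).  INHERIT_PARENT_RULES: offspring are
    fertile and subject to the same daily fertility-loss rate as adults.
    """

    STERILE = "sterile"
    INHERIT_PARENT_RULES = "inherit"


class Termination(enum.Enum):
    EXTIRPATED = "extirpated"
    TEMPS_EXHAUSTED = "temps_exhausted"
    CAP_EXCEEDED = "cap_exceeded"


# Literature-range midpoints used as convenience defaults.
_TABLE_MIDPOINTS = {
    "T_min_e": (9.6 + 12.5) / 2,
    "T_min_l": (5.0 + 10.8) / 2,
    "T_min_p": (9.1 + 13.8) / 2,
    "T_min_a": (7.9 + 9.9) / 2,
    "K_e": (27.27 + 33.80) / 2,
    "K_l": (94.50 + 186.78) / 2,
    "K_p": (123.96 + 169.49) / 2,
    "K_a": (58.20 + 105.71) / 2,
    "M_star_e": (0.0198 + 0.1200) / 2,
    "M_star_l": (0.0068 + 0.0946) / 2,
    "M_star_p": (0.0016 + 0.0465) / 2,
    "M_star_a": (0.0245 + 0.1340) / 2,
}


@dataclass
class StageParams:
    """Per-stage thermal constants, base/max temperatures and base mortality.

    ``K_x`` is in day-degrees; individual transition thresholds are stored in
    degree-hours, so a threshold draw uses ``24 * K_x`` (the hourly
    accumulation sums per-hour degree excesses).  For the adult stage, ``K_a``
    is the thermal time from emergence to sexual maturity.  ``M_star_x`` is
    the daily mortality at the thermal optimum, onto which the
    temperature-dependent quadratic is added.  ``gamma`` is the SD of the
    individual development threshold as a proportion of its mean.
    """

    T_min_e: float = _TABLE_MIDPOINTS["T_min_e"]
    T_min_l: float = _TABLE_MIDPOINTS["T_min_l"]
    T_min_p: float = _TABLE_MIDPOINTS["T_min_p"]
    T_min_a: float = _TABLE_MIDPOINTS["T_min_a"]
    K_e: float = _TABLE_MIDPOINTS["K_e"]
    K_l: float = _TABLE_MIDPOINTS["K_l"]
    K_p: float = _TABLE_MIDPOINTS["K_p"]
    K_a: float = _TABLE_MIDPOINTS["K_a"]
    M_star_e: float = _TABLE_MIDPOINTS["M_star_e"]
    M_star_l: float = _TABLE_MIDPOINTS["M_star_l"]
    M_star_p: float = _TABLE_MIDPOINTS["M_star_p"]
    M_star_a: float = _TABLE_MIDPOINTS["M_star_a"]
    T_max: float = 35.0
    gamma: float = 0.05

    def t_min(self, stage: Stage) -> float:
        return getattr(self, f"T_min_{Stage(stage).suffix}")

    def k(self, stage: Stage) -> float:
        return getattr(self, f"K_{Stage(stage).suffix}")

    def m_star(self, stage: Stage) -> float:
        return getattr(self, f"M_star_{Stage(stage).suffix}")

    def t_min_array(self) -> np.ndarray:
        """Base temperature indexed by stage; +inf for the terminal mature
        stage so its thermal increment is always zero."""
        return np.array(
            [self.T_min_e, self.T_min_l, self.T_min_p, self.T_min_a, np.inf]
        )

    def k_array(self) -> np.ndarray:
        """Thermal constant (day-degrees) indexed by stage (mature: +inf)."""
        return np.array([self.K_e, self.K_l, self.K_p, self.K_a, np.inf])

    def m_star_array(self) -> np.ndarray:
        """Optimum-temperature daily mortality indexed by the five stages
        (both adult substages share M_star_a)."""
        return np.array(
            [self.M_star_e, self.M_star_l, self.M_star_p, self.M_star_a, self.M_star_a]
        )


@dataclass
class ReproductionParams:
    """Fecundity of mature females.

    ``r`` is the mean and ``r_var`` the variance of the daily egg draw.
    ``female_fraction`` is the share of laid eggs instantiated as (female)
    agents — the simulator tracks females only, and the literature does not
    state whether reported fecundities count all eggs or daughters, so the
    halving is exposed rather than baked in.
    """

    r: float = 20.0
    r_var: float = 3.57
    female_fraction: float = 0.5


@dataclass
class InterventionParams:
    """Quarantine/eradication countermeasures beginning t_S days after the
    first find: extra daily adult mortality S (bait sprays, mass trapping)
    and a daily probability r_red that a fertile mature female permanently
    loses fertility (sterile-male matings)."""

    t_S: float = 0.0
    S: float = 0.0
    r_red: float = 0.0
    offspring_policy: OffspringPolicy = OffspringPolicy.STERILE


@dataclass
class EngineConfig:
    """Engine-level switches: developmental model D_m, the live-agent cap
    N_m, the RNG seed, and a few behavioral flags.

    ``literal_hourly_exponent`` reproduces the historical per-hour death
    test probability M^(1/24) instead of the survival-compounded
    1-(1-M)^(1/24); see docs.  ``reproduction_hour`` anchors the
    once-per-day egg laying within each simulation-relative 24-h block.
    ``extirpation_fertile_only`` ends a run when no *fertile* agent remains
    rather than when no agent remains (off by default).
    """

    D_m: DevelopmentModel = DevelopmentModel.THERMAL_UNIT
    N_m: int = 1_000_000
    rng_seed: int = 0
    literal_hourly_exponent: bool = False
    reproduction_hour: int = 0
    extirpation_fertile_only: bool = False


@dataclass
class Agent:
    """One female insect.

    ``accumulated`` and ``threshold`` are in degree-hours relative to entry
    into the current stage; ``threshold`` is the individual's own draw of
    24*K_x scaled by the gamma variation.  Agents that are not mature
    adults cannot reproduce regardless of ``fertile``.
    """

    stage: Stage
    accumulated: float
    threshold: float
    fertile: bool
    birth_hour: int = 0


@dataclass
class SimulationResult:
    """Outputs of one run.

    ``t_e`` (days, ceil of the first all-dead hour / 24) is defined only
    when ``terminated_by`` is EXTIRPATED.  ``daily_counts`` has one row per
    simulated day with live-agent counts for the five stages;
    ``daily_temps`` holds (min, mean, max) ambient temperature per day.
    """

    t_e: Optional[float]
    daily_counts: np.ndarray
    daily_temps: np.ndarray
    cumulative_births: int
    cumulative_adult_deaths: int
    terminated_by: Termination
    hours: int
    cap_exceeded: bool = False


def validate_params(
    stage_params: StageParams,
    repro: ReproductionParams,
    interv: InterventionParams,
    engine: EngineConfig,
) -> list[str]:
    """Check every type invariant; return human-readable violations.

    An empty list means all invariants hold.  Each finding names the field
    and the rule it breaks.
    """
    v: list[str] = []
    for s in (Stage.EGG, Stage.LARVA, Stage.PUPA, Stage.ADULT_IMMATURE):
        sfx = s.suffix
        if stage_params.t_min(s) >= stage_params.T_max:
            v.append(f"T_min_{sfx}: T_min >= T_max ({stage_params.t_min(s)} >= {stage_params.T_max})")
        if stage_params.k(s) <= 0:
            v.append(f"K_{sfx}: thermal constant must be > 0")
        if not 0.0 <= stage_params.m_star(s) <= 1.0:
            v.append(f"M_star_{sfx}: daily mortality must lie in [0, 1]")
    if stage_params.gamma < 0:
        v.append("gamma: development-variation SD fraction must be >= 0")
    if repro.r < 0:
        v.append("r: mean eggs per day must be >= 0")
    if repro.r_var < 0:
        v.append("r_var: variance must be >= 0")
    if not 0.0 <= repro.female_fraction <= 1.0:
        v.append("female_fraction: must lie in [0, 1]")
    if interv.t_S < 0:
        v.append("t_S: intervention delay must be >= 0")
    if not 0.0 <= interv.S <= 1.0:
        v.append("S: human-induced daily mortality must lie in [0, 1]")
    if not 0.0 <= interv.r_red <= 1.0:
        v.append("r_red: daily fertility-loss probability must lie in [0, 1]")
    if engine.N_m <= 0:
        v.append("N_m: agent cap must be > 0")
    return v


# --- flat config serialization -------------------------------------------

def params_to_dict(
    stage_params: StageParams,
    repro: ReproductionParams,
    interv: InterventionParams,
    engine: EngineConfig,
) -> dict:
    """Flatten a parameter set to a symbol-keyed mapping (YAML-friendly)."""
    d: dict = {}
    for f in fields(StageParams):
        d[f.name] = getattr(stage_params, f.name)
    d["r"] = repro.r
    d["r_var"] = repro.r_var
    d["female_fraction"] = repro.female_fraction
    d["t_S"] = interv.t_S
    d["S"] = interv.S
    d["r_red"] = interv.r_red
    d["offspring_policy"] = interv.offspring_policy.value
    d["D_m"] = engine.D_m.value
    d["N_m"] = engine.N_m
    d["rng_seed"] = engine.rng_seed
    d["literal_hourly_exponent"] = engine.literal_hourly_exponent
    d["reproduction_hour"] = engine.reproduction_hour
    d["extirpation_fertile_only"] = engine.extirpation_fertile_only
    return d


def params_from_dict(d: dict) -> tuple[StageParams, ReproductionParams, InterventionParams, EngineConfig]:
    """Inverse of :func:`params_to_dict`; missing keys take defaults."""
    sp = StageParams(**{f.name: d[f.name] for f in fields(StageParams) if f.name in d})
    rp = ReproductionParams(
        **{k: d[k] for k in ("r", "r_var", "female_fraction") if k in d}
    )
    ip = InterventionParams(
        **{k: d[k] for k in ("t_S", "S", "r_red") if k in d}
    )
    if "offspring_policy" in d:
        ip.offspring_policy = OffspringPolicy(d["offspring_policy"])
    ec = EngineConfig()
    if "D_m" in d:
        ec.D_m = DevelopmentModel(d["D_m"])
    for k in ("N_m", "rng_seed", "literal_hourly_exponent",
              "reproduction_hour", "extirpation_fertile_only"):
        if k in d:
            setattr(ec, k, d[k])
    return sp, rp, ip, ec


def save_params(path, stage_params, repro, interv, engine) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(stage_params, repro, interv, engine), fh,
                       sort_keys=True)


def load_params(path):
    with open(path) as fh:
        return params_from_dict(yaml.safe_load(fh))
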