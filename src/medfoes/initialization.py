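"""Build an initial agent population from trap-capture facts.

Adult trapping only samples a small fraction of an outbreak population: a
surveillance grid of attractant traps captures roughly 2-3 % of adults per
adult life span.  The flies found in the first three days after detection
are treated as an instantaneous capture, scaled up by the grid sensitivity,
and halved for an even sex ratio to give the adult-female count N_0.  The
unobservable immature stages are then inferred from a published stable age
distribution at 24 degC (proportions e 0.436, l 0.403, p 0.137, immature
adults 0.012, mature adults 0.012); supplying a different AgeStructure
swaps in any alternative distribution with no separate code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import life_history as lh
from .engine import PopulationState
from .params import Stage, StageParams

__all__ = [
    "OutbreakFacts",
    "AgeStructure",
    "PopulationEstimate",
    "estimate_population_size",
    "instantiate_population",
]

#: Stable stage proportions at 24 degC (Medfly cohort projections).
DEFAULT_AGE_STRUCTURE_PROPORTIONS = (0.436, 0.403, 0.137, 0.012, 0.012)


@dataclass
class OutbreakFacts:
    """What the trapping program observed: flies found in the first three
    days, grid sensitivity (proportion captured per adult life span), the
    assumed female share, and the delay t_S to countermeasures (days)."""

    flies_found: int
    trap_sensitivity: float
    sex_ratio_female: float = 0.5
    t_S: float = 0.0

    def __post_init__(self):
        if self.flies_found < 1:
            raise ValueError("flies_found must be >= 1")
        if not 0.0 < self.trap_sensitivity <= 1.0:
            raise ValueError("trap_sensitivity must lie in (0, 1]")


@dataclass
class AgeStructure:
    """Stage proportions (egg, larva, pupa, immature adult, mature adult)."""

    egg: float = DEFAULT_AGE_STRUCTURE_PROPORTIONS[0]
    larva: float = DEFAULT_AGE_STRUCTURE_PROPORTIONS[1]
    pupa: float = DEFAULT_AGE_STRUCTURE_PROPORTIONS[2]
    adult_immature: float = DEFAULT_AGE_STRUCTURE_PROPORTIONS[3]
    adult_mature: float = DEFAULT_AGE_STRUCTURE_PROPORTIONS[4]

    def proportions(self) -> np.ndarray:
        return np.array([self.egg, self.larva, self.pupa,
                         self.adult_immature, self.adult_mature])

    def __post_init__(self):
        p = self.proportions()
        if np.any(p < 0):
            raise ValueError("age-structure proportions must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("age-structure proportions must sum to 1")


@dataclass
class PopulationEstimate:
    """Total population and its per-stage split implied by a trap catch."""

    n0_females: float
    total: int
    counts: np.ndarray  # length 5, sums to total


def estimate_population_size(facts: OutbreakFacts,
                             structure: AgeStructure | None = None
                             ) -> PopulationEstimate:
    """Scale a trap catch up to a whole-population stage census.

    N_0 = (flies_found / trap_sensitivity) * sex_ratio_female adult
    females; total = round(N_0 / mature-adult proportion); per-stage counts
    are rounded proportions with the rounding residual assigned to the
    largest compartment so the counts sum exactly to the total.

    Homogeneous of degree 1 in flies_found and degree -1 in sensitivity.
    """
    structure = structure or AgeStructure()
    p = structure.proportions()
    if p[int(Stage.ADULT_MATURE)] <= 0:
        raise ValueError("mature-adult proportion must be positive")
    n0 = facts.flies_found / facts.trap_sensitivity * facts.sex_ratio_female
    total = int(round(n0 / p[int(Stage.ADULT_MATURE)]))
    counts = np.rint(total * p).astype(np.int64)
    counts[int(np.argmax(p))] += total - counts.sum()
    return PopulationEstimate(n0_females=n0, total=total, counts=counts)


def instantiate_population(counts, stage_params: StageParams,
                           rng: np.random.Generator,
                           N_m: int | None = None) -> PopulationState:
    """Create agents for a per-stage census with uniform within-stage ages.

    Each developing agent draws its own threshold and starts with an
    accumulated fraction Uniform[0, 1) of it — uniform progress through the
    current stage, avoiding the synchronized-molting artifacts a point mass
    at stage entry would cause.  Mature adults start fertile with an
    infinite (terminal) threshold.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.size != 5 or np.any(counts < 0):
        raise ValueError("counts must be 5 non-negative per-stage integers")
    total = int(counts.sum())
    if N_m is not None and total > N_m:
        raise ValueError(f"initial population {total} exceeds cap N_m={N_m}")

    stages = np.repeat(np.arange(5, dtype=np.int8), counts)
    thresholds = np.full(total, np.inf)
    accumulated = np.zeros(total)
    for s in (Stage.EGG, Stage.LARVA, Stage.PUPA, Stage.ADULT_IMMATURE):
        m = stages == int(s)
        c = int(m.sum())
        if c:
            thr = lh.draw_thresholds(np.full(c, stage_params.k(s)),
                                     stage_params.gamma, rng)
            thresholds[m] = thr
            accumulated[m] = rng.random(c) * thr
    fertile = np.ones(total, bool)  # all pre-intervention agents can breed
    return PopulationState(stage=stages, accumulated=accumulated,
                           threshold=thresholds, fertile=fertile,
                           birth_hour=np.zeros(total, np.int64))
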