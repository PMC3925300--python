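"""Top-level outbreak analysis: configuration, orchestration, fixtures.

An outbreak scenario bundles the trap-capture facts, the parameter ranges
to sweep, engine flags and a temperature source.  ``analyze_outbreak``
chains the full pipeline — trap-based initialization, LHS batch, extirpation
statistics, PRCC sensitivity ranking and the degree-day quarantine-length
comparator — into one report whose columns mirror the standard per-outbreak
summary: initial population range N, intervention delay t_S, mean
extirpation time t_m, the 95 %-extirpation day t_0.95, the quarantine
length QL and their difference.

Bundled synthetic fixtures (``warm``, ``cold_snap``, ``leslie_constant``)
provide desk-scale scenarios; real-outbreak replication requires the user
to supply weather-station hourly CSV exports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import life_history as lh
from .engine import ModelParams, run_simulation
from .experiment import (
    ParameterRanges,
    TABLE_RANGES,
    degree_day_quarantine_length,
    extirpation_stats,
    lhs_sample,
    prcc,
    run_batch,
)
from .initialization import (
    AgeStructure,
    OutbreakFacts,
    estimate_population_size,
    instantiate_population,
)
from .leslie import (
    build_stage_structured_model,
    compare_abs_leslie,
    leslie_project,
    stage_proportions,
)
from .params import (
    EngineConfig,
    InterventionParams,
    ReproductionParams,
    Stage,
    StageParams,
)
from .temperature import (
    DailyExtremes,
    TemperatureSeries,
    estimate_hourly,
    read_hourly_csv,
    synthesize_fixture,
)

__all__ = [
    "ScenarioConfig",
    "make_fixture_scenario",
    "make_run_builder",
    "analyze_outbreak",
    "leslie_validation_setup",
    "run_leslie_validation",
    "load_scenario",
    "save_scenario",
]

log = logging.getLogger("medfoes")

# Degree-day comparator defaults: an egg-to-ovipositing-adult generation of
# K_e+K_l+K_p+K_a day-degrees above the mean stage base temperature, both
# taken at the literature-range midpoints.  Configurable per scenario.
DEFAULT_DDQL_K_GENERATION = sum(
    (TABLE_RANGES[k][0] + TABLE_RANGES[k][1]) / 2
    for k in ("K_e", "K_l", "K_p", "K_a"))
DEFAULT_DDQL_T_MIN = float(np.mean(
    [(TABLE_RANGES[k][0] + TABLE_RANGES[k][1]) / 2
     for k in ("T_min_e", "T_min_l", "T_min_p", "T_min_a")]))


@dataclass
class ScenarioConfig:
    """One outbreak's configuration (mirrors one row of an outbreak table)."""

    name: str = "scenario"
    first_find: str = "2009-09-01"
    flies_found: int = 1
    sex_ratio_female: float = 0.5
    t_S: float = 4.0
    runs: int = 100
    q: float = 0.95
    r_var: float = 3.57
    female_fraction: float = 0.5
    gamma: float = 0.05
    T_max: float = 35.0
    N_m: int = 1_000_000
    ddql_t_min: float = DEFAULT_DDQL_T_MIN
    ddql_k_generation: float = DEFAULT_DDQL_K_GENERATION
    ddql_generations: int = 3
    ranges: dict = field(default_factory=lambda: dict(TABLE_RANGES))
    age_structure: dict = field(default_factory=lambda: {
        "e": 0.436, "l": 0.403, "p": 0.137, "a_imm": 0.012, "a_mat": 0.012})
    temperature: dict = field(default_factory=dict)  # {"path": ...} or {"fixture": {...}}

    def __post_init__(self):
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        # normalize YAML lists back to tuples so round-trips compare equal
        self.ranges = {k: tuple(v) for k, v in self.ranges.items()}
        fix = self.temperature.get("fixture")
        if fix and fix.get("cold_snap") is not None:
            fix["cold_snap"] = tuple(fix["cold_snap"])

    def structure(self) -> AgeStructure:
        a = self.age_structure
        return AgeStructure(egg=a["e"], larva=a["l"], pupa=a["p"],
                            adult_immature=a["a_imm"], adult_mature=a["a_mat"])

    def load_temps(self) -> TemperatureSeries:
        if "path" in self.temperature:
            p = Path(self.temperature["path"])
            if not p.exists():
                raise FileNotFoundError(p)
            return read_hourly_csv(p)
        if "fixture" in self.temperature:
            return synthesize_fixture(**self.temperature["fixture"])
        raise ValueError("scenario has no temperature source configured")


def save_scenario(config: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def load_scenario(path) -> ScenarioConfig:
    with open(path) as fh:
        return ScenarioConfig(**yaml.safe_load(fh))


_WARM_TEMP_SEED = 170  # fixed so the bundled fixtures are deterministic


def make_fixture_scenario(name: str, days: int | None = None
                          ) -> tuple[ScenarioConfig, TemperatureSeries]:
    """Bundled desk-scale scenarios: 'warm', 'cold_snap', 'leslie_constant'.

    warm: 120 days with 15/28 degC daily extremes.  cold_snap: the same
    series with a 3-day sub-zero snap starting at day 45.  leslie_constant:
    a constant 24 degC series with the Leslie-validation parameter set.
    """
    if name == "warm":
        spec = dict(days=days or 120, base_tmin=15.0, base_tmax=28.0,
                    seed=_WARM_TEMP_SEED)
    elif name == "cold_snap":
        # depth 28 pushes the snap days' extremes to (-13, 0) degC: a hard
        # freeze with the whole day at or below zero, not just a night frost
        spec = dict(days=days or 120, base_tmin=15.0, base_tmax=28.0,
                    cold_snap=(45, 3, 28.0), seed=_WARM_TEMP_SEED)
    elif name == "leslie_constant":
        d = days or 30
        temps = estimate_hourly(DailyExtremes(
            start_date=datetime(2009, 9, 1),
            tmin=np.full(d, 24.0), tmax=np.full(d, 24.0)))
        cfg = ScenarioConfig(name="leslie_constant", runs=100,
                             temperature={"fixture": dict(
                                 days=d, base_tmin=24.0, base_tmax=24.0,
                                 daily_jitter_sd=0.0, seed=0)})
        return cfg, temps
    else:
        raise ValueError(f"unknown fixture scenario {name!r}")
    cfg = ScenarioConfig(name=name, flies_found=1, t_S=4.0, runs=100,
                         temperature={"fixture": spec})
    return cfg, synthesize_fixture(**spec)


def make_run_builder(config: ScenarioConfig):
    """Return make_run(row, rng) executing one parameter vector end to end.

    The row supplies the sampled stage mortalities, thermal constants, r,
    r_red, S and trap_sensitivity; the scenario supplies everything fixed
    (t_S, gamma, r_var, sex ratio, age structure, engine flags).
    """
    structure = config.structure()

    def make_run(row: dict, rng: np.random.Generator, temps: TemperatureSeries):
        sp = StageParams(
            T_min_e=row["T_min_e"], T_min_l=row["T_min_l"],
            T_min_p=row["T_min_p"], T_min_a=row["T_min_a"],
            K_e=row["K_e"], K_l=row["K_l"], K_p=row["K_p"], K_a=row["K_a"],
            M_star_e=row["M_star_e"], M_star_l=row["M_star_l"],
            M_star_p=row["M_star_p"], M_star_a=row["M_star_a"],
            T_max=config.T_max, gamma=config.gamma,
        )
        params = ModelParams(
            stage=sp,
            repro=ReproductionParams(r=row["r"], r_var=config.r_var,
                                     female_fraction=config.female_fraction),
            interv=InterventionParams(t_S=config.t_S, S=row["S"],
                                      r_red=row["r_red"]),
            engine=EngineConfig(N_m=config.N_m),
        )
        facts = OutbreakFacts(flies_found=config.flies_found,
                              trap_sensitivity=row["trap_sensitivity"],
                              sex_ratio_female=config.sex_ratio_female,
                              t_S=config.t_S)
        est = estimate_population_size(facts, structure)
        state = instantiate_population(est.counts, sp, rng, N_m=config.N_m)
        return run_simulation(state, temps, params, rng)

    return make_run


def analyze_outbreak(config: ScenarioConfig,
                     temps: TemperatureSeries | None = None,
                     seed: int = 0,
                     out_dir=None) -> dict:
    """Full chain: initialization -> LHS batch -> statistics -> comparator.

    Returns a report dict with the standard outbreak-summary columns
    (N range, t_S, t_m, t_0.95, QL, t_0.95 - QL) plus the PRCC table and,
    when ``out_dir`` is given, per-run and PRCC CSVs and a JSON report.
    Fully deterministic for a fixed (config, seed).
    """
    if temps is None:
        temps = config.load_temps()
    ranges = ParameterRanges(dict(config.ranges))
    rng = np.random.default_rng(seed)
    design = lhs_sample(ranges, config.runs, rng)
    log.info("scenario %s: %d runs, %d hourly temperatures",
             config.name, config.runs, len(temps))

    base_run = make_run_builder(config)
    batch = run_batch(design, temps,
                      lambda row, r: base_run(row, r, temps),
                      base_seed=seed + 1)
    t_m, t_q = extirpation_stats(batch, q=config.q)

    # N range across the sampled sensitivity interval
    lo, hi = config.ranges["trap_sensitivity"]
    structure = config.structure()
    n_hi = estimate_population_size(
        OutbreakFacts(config.flies_found, lo, config.sex_ratio_female),
        structure).total
    n_lo = estimate_population_size(
        OutbreakFacts(config.flies_found, hi, config.sex_ratio_female),
        structure).total

    # PRCC on the standard 16 inputs: N_0 (derived from the sampled
    # sensitivity) replaces trap_sensitivity itself.
    prcc_design = batch.design.drop(columns=["trap_sensitivity"]).copy()
    prcc_design["N_0"] = (config.flies_found
                          / batch.design["trap_sensitivity"].to_numpy()
                          * config.sex_ratio_female)
    mask = np.isfinite(batch.t_e)
    try:
        prcc_table = prcc(prcc_design.loc[mask], batch.t_e[mask])
    except ValueError as exc:  # too few extirpated runs for 16 inputs
        log.warning("PRCC skipped: %s", exc)
        prcc_table = None

    ql = degree_day_quarantine_length(temps, config.ddql_t_min,
                                      config.ddql_k_generation,
                                      config.ddql_generations)
    report = {
        "outbreak": config.name,
        "runs": config.runs,
        "n_extirpated": int(mask.sum()),
        "N_range": [n_lo, n_hi],
        "t_S": config.t_S,
        "t_m": t_m,
        f"t_{config.q:g}": t_q,
        "QL": ql,
        "t_q_minus_QL": (t_q - ql) if np.isfinite(t_q) and ql >= 0 else None,
        "seed": seed,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_run = batch.design.copy()
        per_run["seed"] = batch.seeds
        per_run["t_e"] = batch.t_e
        per_run["terminated_by"] = [t.value for t in batch.terminated]
        per_run.to_csv(out / "batch.csv", index=False)
        if prcc_table is not None:
            prcc_table.to_csv(out / "prcc.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        with open(out / "report.txt", "w") as fh:
            for k, v in report.items():
                fh.write(f"{k}: {v}\n")
    report["prcc"] = prcc_table
    report["batch"] = batch
    return report


# --- Leslie validation harness -------------------------------------------

#: Stage parameters for the constant-24-degC validation replication.  The
#: published developmental constants give ~2.3-day eggs, ~9.8-day larvae
#: and ~12.2-day pupae at 24 degC; the pupal constant 124.0 and an adult
#: maturation time of 5 days place the first mature-adult age class at
#: class 30 of 40, matching the reference projection's initial condition.
LESLIE_STAGE_PARAMS = dict(
    T_min_e=9.6, T_min_l=5.0, T_min_p=13.8, T_min_a=8.9,
    K_e=33.4, K_l=186.8, K_p=124.0, K_a=75.5,
    T_max=35.0, gamma=0.05,
)
LESLIE_FIXED_MORTALITY = lh.FixedMortality(M_e=0.00, M_l=0.60, M_p=0.20,
                                           M_a=0.15)
LESLIE_DURATIONS = {Stage.EGG: 2, Stage.LARVA: 10, Stage.PUPA: 12,
                    Stage.ADULT_IMMATURE: 5}
#: Net daily female eggs per mature female.  Deliberately low so total
#: abundance declines monotonically from day 0 (see docs/methods.md);
#: realized in the ABS as r=1 egg/day thinned by female_fraction=0.1, which
#: keeps the per-female draw integer-valued and its mean exact.
LESLIE_FECUNDITY = 0.1


def leslie_validation_setup(initial_mature: int = 100):
    """(ModelParams, initial counts, LeslieModel) for the validation run."""
    sp = StageParams(**LESLIE_STAGE_PARAMS)
    params = ModelParams(
        stage=sp,
        repro=ReproductionParams(r=1.0, r_var=0.0, female_fraction=LESLIE_FECUNDITY),
        interv=InterventionParams(t_S=1e6),  # never intervene
        # Midday laying: the daily Leslie operator treats births as spread
        # through the day, so a noon pulse halves the census-phase offset
        # between the hourly model and the daily projection.
        engine=EngineConfig(reproduction_hour=12),
        fixed_mortality=LESLIE_FIXED_MORTALITY,
    )
    mortality = {Stage.EGG: 0.0, Stage.LARVA: 0.6, Stage.PUPA: 0.2,
                 Stage.ADULT_IMMATURE: 0.15, Stage.ADULT_MATURE: 0.15}
    model = build_stage_structured_model(LESLIE_DURATIONS, mortality,
                                         LESLIE_FECUNDITY, n_classes=40,
                                         initial_mature=float(initial_mature))
    counts = np.array([0, 0, 0, 0, initial_mature], np.int64)
    return params, counts, model


def run_leslie_validation(replicates: int = 100, days: int = 20,
                          seed: int = 0, initial_mature: int = 100) -> dict:
    """Replicate the constant-conditions validation and score the match.

    Runs ``replicates`` agent simulations at constant 24 degC, averages the
    daily stage composition (pooled counts across replicates), projects the
    matched Leslie matrix for the same days, and reports the maximum
    per-stage proportion discrepancy (overall and for days 1-10) plus both
    total-abundance trajectories.
    """
    params, counts, model = leslie_validation_setup(initial_mature)
    cfg, temps = make_fixture_scenario("leslie_constant", days=days + 1)
    rng = np.random.default_rng(seed)

    pooled = np.zeros((days, 5))
    for _ in range(replicates):
        state = instantiate_population(counts, params.stage, rng)
        res = run_simulation(state, temps, params, rng)
        got = res.daily_counts[:days]
        pooled[:got.shape[0]] += got
    abs_totals = pooled.sum(axis=1) / replicates
    abs_props = np.where(pooled.sum(axis=1, keepdims=True) > 0,
                         pooled / np.maximum(pooled.sum(axis=1, keepdims=True), 1),
                         0.0)

    proj = leslie_project(model, days)
    les_props = stage_proportions(proj, model.stage_of_class)[1:]
    les_totals = proj.sum(axis=1)[1:]

    return {
        "abs_props": abs_props,
        "leslie_props": les_props,
        "abs_totals": abs_totals,
        "leslie_totals": les_totals,
        "max_discrepancy": compare_abs_leslie(abs_props, les_props),
        "max_discrepancy_days_1_10": compare_abs_leslie(
            abs_props, les_props, days=slice(0, 10)),
    }
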