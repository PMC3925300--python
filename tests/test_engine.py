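from datetime import datetime

import numpy as np
import pytest

from medfoes.engine import (
    ModelParams,
    PopulationState,
    run_simulation,
    step_hour,
    write_daily_detail,
    write_summary,
)
from medfoes.life_history import FixedMortality, thermal_increment
from medfoes.params import (
    Agent,
    EngineConfig,
    InterventionParams,
    OffspringPolicy,
    ReproductionParams,
    Stage,
    StageParams,
    Termination,
)

from conftest import const_temps, immortal_params, mature_adults


def single_egg(threshold=720.0):
    return PopulationState(stage=[0], accumulated=[0.0],
                           threshold=[threshold], fertile=[True],
                           birth_hour=[0])


class TestStepHour:
    def test_frozen_development_below_base(self, simple_stage_params, rng):
        params = immortal_params(simple_stage_params)
        state = single_egg()
        step_hour(state, 5.0, params, rng)  # below T_min_e = 12
        assert state.hour == 1
        assert state.stage[0] == 0 and state.accumulated[0] == 0.0
        assert state.n_live == 1

    def test_deterministic_fecundity(self, simple_stage_params, rng):
        params = immortal_params(simple_stage_params, r=10.0)
        state = mature_adults(1)
        step_hour(state, 20.0, params, rng)
        assert state.n_live == 11
        assert (state.stage == 0).sum() == 10
        assert state.cum_births == 10

    def test_certain_death_empties_population(self, simple_stage_params, rng):
        params = ModelParams(
            stage=simple_stage_params,
            repro=ReproductionParams(r=0.0, r_var=0.0),
            interv=InterventionParams(t_S=1e6),
            fixed_mortality=FixedMortality(1.0, 1.0, 1.0, 1.0),
        )
        state = PopulationState(stage=[0, 1, 2, 3, 4],
                                accumulated=[0.0] * 5,
                                threshold=[1e9] * 5,
                                fertile=[True] * 5,
                                birth_hour=[0] * 5)
        step_hour(state, 20.0, params, rng)
        assert state.n_live == 0

    def test_conservation_each_hour(self, simple_stage_params):
        sp = simple_stage_params
        params = ModelParams(
            stage=sp,
            repro=ReproductionParams(r=8.0, r_var=2.0, female_fraction=0.5),
            interv=InterventionParams(t_S=2.0, S=0.03, r_red=0.5),
            fixed_mortality=FixedMortality(0.05, 0.05, 0.05, 0.08),
        )
        rng = np.random.default_rng(7)
        state = mature_adults(200)
        prev_live, prev_b = state.n_live, 0
        for h in range(24 * 10):
            step_hour(state, 24.0, params, rng)
            births = state.cum_births - prev_b
            deaths = (state.cum_deaths_natural + state.cum_deaths_human)
            # live(t+1) = live(t) + births - deaths (cumulative form)
            assert state.n_live == 200 + state.cum_births - deaths
            assert births >= 0
            prev_b = state.cum_births
            prev_live = state.n_live

    def test_sterile_offspring_policy_after_intervention(self, simple_stage_params):
        params = immortal_params(simple_stage_params, r=5.0)
        params.repro = ReproductionParams(r=5.0, r_var=0.0, female_fraction=1.0)
        params.interv = InterventionParams(t_S=0.0, S=0.0, r_red=0.0)
        rng = np.random.default_rng(0)
        state = mature_adults(4)
        step_hour(state, 20.0, params, rng)
        eggs = state.stage == 0
        assert eggs.sum() == 20 and not state.fertile[eggs].any()

        params.interv.offspring_policy = OffspringPolicy.INHERIT_PARENT_RULES
        state2 = mature_adults(4)
        step_hour(state2, 20.0, params, np.random.default_rng(0))
        eggs2 = state2.stage == 0
        assert state2.fertile[eggs2].all()

    def test_r_red_sterilizes_all_when_certain(self, simple_stage_params):
        params = immortal_params(simple_stage_params, r=0.0)
        params.interv = InterventionParams(t_S=0.0, S=0.0, r_red=1.0)
        state = mature_adults(50)
        step_hour(state, 20.0, params, np.random.default_rng(0))
        assert not state.fertile.any()
        assert state.n_live == 50  # sterile but alive

    def test_population_cap_truncates_eggs(self, simple_stage_params):
        params = immortal_params(simple_stage_params, r=100.0)
        params.repro = ReproductionParams(r=100.0, r_var=0.0, female_fraction=1.0)
        params.engine = EngineConfig(N_m=120)
        state = mature_adults(100)
        step_hour(state, 20.0, params, np.random.default_rng(0))
        assert state.n_live == 120
        assert state.cap_exceeded


class TestRunSimulation:
    def test_single_egg_reaches_maturity_against_step_oracle(
            self, simple_stage_params):
        sp = simple_stage_params
        params = immortal_params(sp)
        temps = const_temps(40, 26.0)
        state = single_egg(threshold=24.0 * sp.K_e)
        rng = np.random.default_rng(0)
        # independent hand accumulation with carry-over
        acc, stage_idx, oracle_hours = 0.0, 0, None
        thresholds = [24 * sp.K_e, 24 * sp.K_l, 24 * sp.K_p, 24 * sp.K_a]
        for h in range(24 * 40):
            acc += thermal_increment(26.0, 12.0, 35.0)
            while stage_idx < 4 and acc >= thresholds[stage_idx]:
                acc -= thresholds[stage_idx]
                stage_idx += 1
            if stage_idx == 4:
                oracle_hours = h + 1
                break
        assert oracle_hours == 583  # ceil(8160 / 14) with carry-over
        from medfoes.engine import _Kernel
        kernel = _Kernel(params)
        got = None
        for h in range(24 * 40):
            step_hour(state, 26.0, params, rng, _kernel=kernel)
            if state.stage[0] == 4:
                got = h + 1
                break
        assert got == oracle_hours

    def test_constant_population_with_no_rates(self, simple_stage_params):
        params = immortal_params(simple_stage_params)
        state = mature_adults(37)
        res = run_simulation(state, const_temps(10, 20.0), params,
                             np.random.default_rng(0))
        assert res.terminated_by is Termination.TEMPS_EXHAUSTED
        assert res.t_e is None
        assert (res.daily_counts.sum(axis=1) == 37).all()

    def test_binomial_decay_of_fixed_adult_mortality(self, simple_stage_params):
        params = ModelParams(
            stage=simple_stage_params,
            repro=ReproductionParams(r=0.0, r_var=0.0),
            interv=InterventionParams(t_S=1e6),
            fixed_mortality=FixedMortality(0.0, 0.0, 0.0, 0.15),
        )
        rng = np.random.default_rng(11)
        temps = const_temps(5, 26.0)
        total = 0.0
        reps = 300
        for _ in range(reps):
            res = run_simulation(mature_adults(100), temps, params, rng)
            total += (res.daily_counts[-1].sum()
                      if res.daily_counts.shape[0] == 5 else 0.0)
        expected = 100 * 0.85 ** 5  # 44.37
        assert total / reps == pytest.approx(expected, abs=1.0)

    def test_fertile_only_extirpation_variant(self, simple_stage_params):
        params = immortal_params(simple_stage_params)
        params.engine = EngineConfig(extirpation_fertile_only=True)
        state = mature_adults(10)
        state.fertile[:] = False  # alive but all sterile
        res = run_simulation(state, const_temps(2), params,
                             np.random.default_rng(0))
        assert res.terminated_by is Termination.EXTIRPATED
        assert res.t_e == 0.0

    def test_empty_initial_population_is_immediate_extirpation(
            self, simple_stage_params):
        params = immortal_params(simple_stage_params)
        res = run_simulation(PopulationState(), const_temps(2), params,
                             np.random.default_rng(0))
        assert res.t_e == 0.0
        assert res.terminated_by is Termination.EXTIRPATED

    def test_extirpation_day_is_ceiling_of_hours(self, simple_stage_params):
        params = ModelParams(
            stage=simple_stage_params,
            repro=ReproductionParams(r=0.0, r_var=0.0),
            interv=InterventionParams(t_S=1e6),
            fixed_mortality=FixedMortality(1.0, 1.0, 1.0, 1.0),
        )
        res = run_simulation(mature_adults(5), const_temps(3), params,
                             np.random.default_rng(0))
        assert res.terminated_by is Termination.EXTIRPATED
        assert res.t_e == 1.0

    def test_raising_mortality_does_not_lengthen_median_extirpation(
            self, simple_stage_params):
        sp = simple_stage_params
        temps = const_temps(120, 24.0)

        def median_te(m_bump, s):
            tes = []
            for i in range(200):
                params = ModelParams(
                    stage=StageParams(**{
                        **{f.name: getattr(sp, f.name)
                           for f in sp.__dataclass_fields__.values()},
                    }),
                    repro=ReproductionParams(r=0.0, r_var=0.0),
                    interv=InterventionParams(t_S=0.0, S=s, r_red=0.0),
                    fixed_mortality=FixedMortality(
                        0.05 + m_bump, 0.05 + m_bump, 0.05 + m_bump,
                        0.05 + m_bump),
                )
                rng = np.random.default_rng(1000 + i)  # paired seeds
                res = run_simulation(mature_adults(60), temps, params, rng)
                tes.append(res.t_e if res.t_e is not None else np.inf)
            return np.median(tes)

        base = median_te(0.0, 0.005)
        assert median_te(0.05, 0.005) <= base
        assert median_te(0.0, 0.05) <= base


class TestOutputs:
    def _result(self, simple_stage_params, days=10):
        params = ModelParams(
            stage=simple_stage_params,
            repro=ReproductionParams(r=3.0, r_var=1.0),
            interv=InterventionParams(t_S=2.0, S=0.02, r_red=0.6),
            fixed_mortality=FixedMortality(0.05, 0.05, 0.05, 0.1),
        )
        res = run_simulation(mature_adults(50), const_temps(days, 24.0),
                             params, np.random.default_rng(3))
        return res, params

    def test_daily_detail_shape_and_conservation(self, simple_stage_params,
                                                 tmp_path):
        res, _ = self._result(simple_stage_params)
        p = tmp_path / "daily.csv"
        write_daily_detail(res, p)
        import pandas as pd
        df = pd.read_csv(p)
        assert df.shape == (res.daily_counts.shape[0], 9)
        stage_cols = [c for c in df.columns if c.startswith("n_")]
        np.testing.assert_array_equal(
            df[stage_cols].sum(axis=1).to_numpy(),
            res.daily_counts.sum(axis=1))

    def test_output_stops_at_extirpation(self, simple_stage_params):
        params = ModelParams(
            stage=simple_stage_params,
            repro=ReproductionParams(r=0.0, r_var=0.0),
            interv=InterventionParams(t_S=1e6),
            fixed_mortality=FixedMortality(0.0, 0.0, 0.0, 0.9),
        )
        res = run_simulation(mature_adults(10), const_temps(60, 24.0), params,
                             np.random.default_rng(5))
        assert res.terminated_by is Termination.EXTIRPATED
        assert res.daily_counts.shape[0] == int(np.ceil(res.t_e))
        assert res.daily_counts[-1].sum() == 0

    def test_summary_contains_all_parameter_keys(self, simple_stage_params,
                                                 tmp_path):
        res, params = self._result(simple_stage_params)
        p = tmp_path / "summary.txt"
        from datetime import datetime as dt
        write_summary(res, params, p, seed=3, timestamp=dt(2020, 1, 1))
        text = p.read_text()
        for key in ("T_min_e", "K_p", "M_star_a", "r_red", "t_S", "S",
                    "D_m", "N_m", "gamma", "T_max", "r_var",
                    "cumulative_births", "cumulative_adult_deaths"):
            assert f"{key}:" in text
        assert ("t_e:" in text) == (res.terminated_by is Termination.EXTIRPATED)

    def test_summary_reproducible_up_to_timestamp(self, simple_stage_params,
                                                  tmp_path):
        res, params = self._result(simple_stage_params)
        from datetime import datetime as dt
        a, b = tmp_path / "a.txt", tmp_path / "b.txt"
        write_summary(res, params, a, timestamp=dt(2020, 1, 1))
        write_summary(res, params, b, timestamp=dt(2021, 6, 2))
        la = a.read_text().splitlines()
        lb = b.read_text().splitlines()
        diff = [x for x, y in zip(la, lb) if x != y]
        assert len(diff) == 1 and diff[0].startswith("execution_timestamp")


class TestAgentRoundTrip:
    def test_state_agent_round_trip(self):
        agents = [Agent(Stage.EGG, 10.0, 700.0, True, 0),
                  Agent(Stage.ADULT_MATURE, 0.0, np.inf, False, 55)]
        state = PopulationState.from_agents(agents)
        assert state.to_agents() == agents
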