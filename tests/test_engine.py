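"""Generation stepping, tallies, turnover and multi-generation dynamics."""

import numpy as np
import pytest

from defensym import (
    ExtinctionError,
    GridSpec,
    SimulationParams,
    next_generation_infected,
    run_generation,
    run_simulation,
    time_step,
)
from defensym.engine import (
    STATUS_DEAD_NATURAL,
    STATUS_DEAD_PARASITISED,
    GenerationState,
    run_generation_from_state,
)


def make_state(
    positions,
    infected,
    longevity,
    fecundity,
    grid=GridSpec(10, 10),
    wasps=(),
):
    """Hand-built generation state for controlled scenarios."""
    positions = np.asarray(positions)
    n = len(positions)
    infected = np.asarray(infected, dtype=bool)
    longevity = np.asarray(longevity, dtype=float)
    fecundity = np.asarray(fecundity, dtype=np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(longevity > 0, fecundity / np.maximum(longevity, 1e-300), 0.0)
    wasps = list(wasps)
    nw = len(wasps)
    return GenerationState(
        step=0,
        grid=grid,
        x=positions[:, 0].astype(np.int64),
        y=positions[:, 1].astype(np.int64),
        infected=infected,
        alive=np.ones(n, dtype=bool),
        status=np.zeros(n, dtype=np.int8),
        longevity=longevity,
        fecundity=fecundity,
        rate=rate,
        infection_step=np.where(infected, 0, -1).astype(np.int64),
        wx=np.array([w[0] for w in wasps], dtype=float),
        wy=np.array([w[1] for w in wasps], dtype=float),
        w_longevity=np.array([w[2] for w in wasps], dtype=float),
        w_eggs=np.array([w[3] for w in wasps], dtype=np.int64),
        w_alive=np.ones(nw, dtype=bool),
        w_target=np.full(nw, -1, dtype=np.int64),
    )


class TestTimeStep:
    def test_exhaustion_freezes_tallies(self, rng):
        params = SimulationParams(n_hosts=3, grid=GridSpec(10, 10))
        state = make_state(
            [(1, 1), (2, 2), (3, 3)], [False] * 3, [2.0, 2.5, 1.0], [4, 5, 2]
        )
        for _ in range(5):
            time_step(state, params, rng)
        assert not state.alive.any()
        assert (state.status == STATUS_DEAD_NATURAL).all()
        before = (state.progeny_infected, state.progeny_uninfected)
        time_step(state, params, rng)
        assert (state.progeny_infected, state.progeny_uninfected) == before

    def test_unattacked_host_accrues_rate_times_steps(self, rng):
        # rate 0.4 surviving 10 whole steps contributes exactly 4.0
        params = SimulationParams(
            n_hosts=1, grid=GridSpec(10, 10), transmission_enabled=False
        )
        state = make_state([(5, 5)], [False], [10.0], [4])
        for _ in range(12):
            time_step(state, params, rng)
        assert state.progeny_uninfected == pytest.approx(4.0)
        assert state.progeny_infected == 0.0

    def test_fast_forward_matches_stepping(self, rng):
        params = SimulationParams(
            n_hosts=2, grid=GridSpec(10, 10), transmission_enabled=False
        )
        stepped = make_state([(1, 1), (7, 3)], [True, False], [7.3, 11.0], [5, 8])
        while stepped.alive.any():
            time_step(stepped, params, rng)
        forwarded = make_state([(1, 1), (7, 3)], [True, False], [7.3, 11.0], [5, 8])
        res = run_generation_from_state(forwarded, params, rng)
        assert res.progeny_infected == pytest.approx(
            stepped.progeny_infected, rel=1e-12
        )
        assert res.progeny_uninfected == pytest.approx(
            stepped.progeny_uninfected, rel=1e-12
        )

    def test_midlife_infection_splits_tallies(self):
        # a host converted at step t counts as uninfected before t and as
        # infected at the discounted rate afterwards
        params = SimulationParams(
            n_hosts=2, grid=GridSpec(50, 50), c=0.4, h=0.9,
        )
        rng = np.random.default_rng(21)
        state = make_state([(0, 0), (4, 0)], [True, False], [40.0, 30.0], [20, 15])
        original_rate = state.rate[1]
        while state.alive.any():
            time_step(state, params, rng)
        t_inf = state.infection_step[1]
        assert t_inf > 0, "scenario should convert the second host mid-life"
        assert state.rate[1] == pytest.approx(0.6 * original_rate)
        assert state.steps_uninfected[1] == t_inf
        expected_un = state.rate[0] * 0 + original_rate * t_inf
        assert state.progeny_uninfected == pytest.approx(expected_un, rel=1e-12)
        expected_inf = (
            state.rate[0] * state.steps_infected[0]
            + state.rate[1] * state.steps_infected[1]
        )
        assert state.progeny_infected == pytest.approx(expected_inf, rel=1e-12)


class TestRunGeneration:
    def test_no_wasps_all_natural_deaths(self, small_params):
        params = small_params.replace(s_p=0.0)
        res = run_generation(params, 10, np.random.default_rng(2))
        assert res.n_parasitised == 0
        assert res.n_natural_death == params.n_hosts

    def test_host_fate_partition(self, small_params):
        for seed in range(5):
            res = run_generation(small_params, 10, np.random.default_rng(seed))
            assert res.n_parasitised + res.n_natural_death == small_params.n_hosts

    def test_certain_resistance_protects_all(self, small_params):
        params = small_params.replace(r=1.0)
        for seed in range(5):
            res = run_generation(
                params, params.n_hosts, np.random.default_rng(seed)
            )
            assert res.n_parasitised == 0

    def test_no_initial_infection_no_infected_progeny(self, small_params):
        res = run_generation(small_params, 0, np.random.default_rng(3))
        assert res.progeny_infected == 0.0

    def test_egg_conservation(self, small_params):
        rng = np.random.default_rng(17)
        state = GenerationState.initialise(small_params, 10, rng)
        eggs_before = state.w_eggs.sum()
        res = run_generation_from_state(state, small_params, rng)
        assert eggs_before - state.w_eggs.sum() == res.n_parasitised

    def test_expected_progeny_without_parasitoids(self):
        # wasp-free, transmission off: total progeny is a sum of Poisson
        # fecundities discounted by the floor(L)/L step quantisation
        params = SimulationParams(s_p=0.0, transmission_enabled=False, c=0.4)
        totals = [
            run_generation(params, 40, np.random.default_rng(s)).progeny_total
            for s in range(200)
        ]
        # independent quantisation oracle by direct Monte Carlo
        oracle = np.random.default_rng(999)
        q_un = np.mean(
            np.floor(d := oracle.exponential(150.0, 400_000)) / d
        )
        q_in = np.mean(
            np.floor(d := oracle.exponential(0.6 * 150.0, 400_000)) / d
        )
        expected = 160 * 60.0 * q_un + 40 * (0.6 * 60.0) * q_in
        se = np.std(totals, ddof=1) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - expected) < 3 * se

    def test_conservation_identity(self, small_params):
        # accrued tallies equal per-host rate x steps in each infection state
        for seed in range(10):
            rng = np.random.default_rng(seed)
            res = run_generation(small_params, 10, rng)
            un = (res.steps_uninfected * res.rate_uninfected).sum()
            inf = (res.steps_infected * res.rate_final).sum()
            assert res.progeny_uninfected == pytest.approx(un, rel=1e-9)
            assert res.progeny_infected == pytest.approx(inf, rel=1e-9)


class TestNextGeneration:
    def test_absorbing_boundaries(self, rng):
        assert next_generation_infected(0.0, 55.1, 200, rng) == 0
        assert next_generation_infected(31.4, 0.0, 200, rng) == 200

    def test_binomial_mean(self):
        rng = np.random.default_rng(4)
        draws = [
            next_generation_infected(30.0, 70.0, 200, rng) for _ in range(10_000)
        ]
        assert abs(np.mean(draws) - 60.0) < 1.0

    def test_extinction_signal(self, rng):
        with pytest.raises(ExtinctionError):
            next_generation_infected(0.0, 0.0, 200, rng)

    def test_deterministic_rounding(self, rng):
        assert (
            next_generation_infected(30.0, 70.0, 200, rng, deterministic=True)
            == 60
        )


class TestRunSimulation:
    def test_absorbing_states(self, small_params):
        zero = small_params.replace(p0=0.0)
        traj = run_simulation(zero, np.random.default_rng(1))
        assert (traj.fractions == 0.0).all()
        one = small_params.replace(p0=1.0, c=0.0)
        traj = run_simulation(one, np.random.default_rng(1))
        assert (traj.fractions == 1.0).all()

    def test_trajectory_length_and_range(self, small_params):
        traj = run_simulation(small_params, np.random.default_rng(5))
        if not traj.extinct:
            assert len(traj.fractions) == small_params.n_generations + 1
        assert ((traj.fractions >= 0) & (traj.fractions <= 1)).all()

    def test_determinism(self, small_params):
        a = run_simulation(small_params, np.random.default_rng(42))
        b = run_simulation(small_params, np.random.default_rng(42))
        assert np.array_equal(a.fractions, b.fractions)

    def test_cost_only_selection_declines(self):
        # without resistance the infection cost drives the symbiont down
        params = SimulationParams(
            c=0.4, r=0.0, s_p=100.0, h=0.8, a=0.04, n_generations=40
        )
        declined = sum(
            run_simulation(params, np.random.default_rng(s)).fractions[-1] < 0.2
            for s in range(10)
        )
        assert declined >= 9

    def test_to_frame_schema(self, small_params):
        traj = run_simulation(small_params, np.random.default_rng(5))
        df = traj.to_frame(replicate=3)
        assert list(df.columns) == ["replicate", "generation", "infected_fraction"]
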