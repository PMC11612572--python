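"""Generation engine: time steps, generations, and multi-generation runs.

Each generation starts from a fresh spatial layout (hosts do not move) and
advances in discrete time steps until every host has either died naturally
or been successfully parasitised.  Within a step the phases run in a fixed
order:

1. natural host deaths (a host completes step ``t`` iff ``t + 1 <=
   longevity``, i.e. it lives ``floor(longevity)`` whole steps);
2. horizontal transmission among live hosts (synchronous; a host infected
   mid-generation immediately pays the infection cost on its remaining
   longevity and per-step rate, but does not itself become a donor until
   the next generation unless ``chain_transmission`` is enabled);
3. parasitoid phase: wasp deaths (elapsed time or egg exhaustion), then each
   live wasp in randomised order selects a target, moves, and attacks on
   arrival (at most one attack per wasp per step);
4. reproduction: every host still alive adds its per-step rate to the
   progeny tally matching its current infection status.

Because hosts are stationary, all pairwise host distances are fixed within
a generation; the engine caches the per-pair log survival terms
``log(1 - exp(-(1-h) d))`` once and maintains the per-recipient sum
incrementally as the donor set changes, so a transmission round costs O(n)
rather than O(n^2).

When no wasp can ever act again and transmission can no longer fire (no
donor/recipient pair, or transmission disabled), remaining reproduction is
accrued in closed form (rate x remaining whole steps), which is identical
to continued stepping.

Per-step random draws, in order (documented so an independent trace can
reproduce the engine exactly): one uniform per live uninfected recipient
(host-index order, only when live donors exist); one permutation of the live
wasp indices (only when any wasp is alive); then per wasp in that order one
uniform for target choice, Normal step-length draws (redrawn while
negative; skipped when already at the target), and one uniform for attack
resolution only when the attacked host is infected.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

from . import foraging, landscape
from .params import SimulationParams

__all__ = [
    "GenerationState",
    "GenerationResult",
    "Trajectory",
    "ExtinctionError",
    "time_step",
    "run_generation",
    "run_generation_from_state",
    "next_generation_infected",
    "run_simulation",
]

STATUS_ALIVE = 0
STATUS_DEAD_NATURAL = 1
STATUS_DEAD_PARASITISED = 2


class ExtinctionError(RuntimeError):
    """Raised when a generation produces no progeny at all."""


@dataclass
class GenerationState:
    """Mutable state of one generation (struct-of-arrays)."""

    step: int
    grid: landscape.GridSpec
    # hosts
    x: np.ndarray  # int cell coords
    y: np.ndarray
    infected: np.ndarray  # bool
    alive: np.ndarray  # bool
    status: np.ndarray  # int8, STATUS_*
    longevity: np.ndarray  # float, continuous
    fecundity: np.ndarray  # int
    rate: np.ndarray  # float progeny per step
    infection_step: np.ndarray  # int, -1 = never infected
    # wasps
    wx: np.ndarray  # float positions
    wy: np.ndarray
    w_longevity: np.ndarray
    w_eggs: np.ndarray  # int
    w_alive: np.ndarray  # bool
    w_target: np.ndarray  # int host index, -1 = none
    # tallies
    progeny_infected: float = 0.0
    progeny_uninfected: float = 0.0
    n_parasitised: int = 0
    n_natural_death: int = 0
    # audit: steps reproduced in each infection state, and the rate while
    # uninfected (0 for hosts infected from the start)
    steps_uninfected: np.ndarray | None = None
    steps_infected: np.ndarray | None = None
    rate_uninfected: np.ndarray | None = None
    # hosts infected at the start of the generation; within a generation only
    # these act as horizontal-transmission donors unless chain_transmission
    donor_competent: np.ndarray | None = None
    # caches (lazy)
    _fx: np.ndarray | None = field(default=None, repr=False)
    _fy: np.ndarray | None = field(default=None, repr=False)
    _logq: np.ndarray | None = field(default=None, repr=False)
    _log_surv: np.ndarray | None = field(default=None, repr=False)
    _donors_dirty: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        n = len(self.x)
        if self.steps_uninfected is None:
            self.steps_uninfected = np.zeros(n, dtype=np.int64)
        if self.steps_infected is None:
            self.steps_infected = np.zeros(n, dtype=np.int64)
        if self.rate_uninfected is None:
            self.rate_uninfected = np.where(self.infected, 0.0, self.rate)
        if self.donor_competent is None:
            self.donor_competent = self.infected.copy()
        self._fx = self.x.astype(float)
        self._fy = self.y.astype(float)

    # -- construction -----------------------------------------------------

    @classmethod
    def initialise(
        cls,
        params: SimulationParams,
        n_infected_start: int,
        rng: np.random.Generator,
        host_rng: np.random.Generator | None = None,
    ) -> "GenerationState":
        """Draw a fresh generation: layout, infection pattern, life histories.

        ``host_rng`` (defaults to ``rng``) drives every host-side draw, so
        two calls with identical host streams produce byte-identical host
        populations regardless of the wasp count (used for the paired
        efficacy experiment).
        """
        from .demography import draw_host_life

        hrng = rng if host_rng is None else host_rng
        n = params.n_hosts
        positions = landscape.place_hosts(n, params.grid, hrng)
        infected = landscape.assign_infection(
            positions, n_infected_start, params.a, params.grid, hrng
        )
        longevity, fecundity, rate = draw_host_life(infected, params, hrng)
        nw = params.n_parasitoids
        wx = rng.uniform(0.0, params.grid.width, nw)
        wy = rng.uniform(0.0, params.grid.height, nw)
        w_longevity = rng.exponential(scale=params.s_p, size=nw)
        w_eggs = rng.poisson(lam=params.lambda_p, size=nw).astype(np.int64)
        return cls(
            step=0,
            grid=params.grid,
            x=positions[:, 0].copy(),
            y=positions[:, 1].copy(),
            infected=infected.copy(),
            alive=np.ones(n, dtype=bool),
            status=np.zeros(n, dtype=np.int8),
            longevity=np.asarray(longevity, dtype=float),
            fecundity=np.asarray(fecundity, dtype=np.int64),
            rate=np.asarray(rate, dtype=float),
            infection_step=np.where(infected, 0, -1).astype(np.int64),
            wx=wx,
            wy=wy,
            w_longevity=w_longevity,
            w_eggs=w_eggs,
            w_alive=np.ones(nw, dtype=bool),
            w_target=np.full(nw, -1, dtype=np.int64),
        )

    # -- views -------------------------------------------------------------

    def host_fingerprint(self) -> str:
        """Hash of the host-side initial-condition arrays (layout + draws)."""
        hsh = hashlib.sha1()
        for arr in (self.x, self.y, self.infected, self.longevity, self.fecundity):
            hsh.update(np.ascontiguousarray(arr).tobytes())
        return hsh.hexdigest()

    def n_alive(self) -> int:
        return int(self.alive.sum())

    # -- transmission cache ------------------------------------------------

    def _ensure_logq(self, h: float) -> None:
        if self._logq is not None:
            return
        fx = self._fx
        fy = self._fy
        d = np.hypot(fx[:, None] - fx[None, :], fy[:, None] - fy[None, :])
        p = np.exp(-(1.0 - h) * d)
        with np.errstate(divide="ignore"):
            logq = np.log1p(-np.minimum(p, 1.0))
        np.fill_diagonal(logq, 0.0)  # a host is never its own donor
        self._logq = logq

    def _donor_mask(self, params: SimulationParams) -> np.ndarray:
        """Live hosts currently able to transmit horizontally.

        Hosts infected mid-generation only join the donor pool when
        ``chain_transmission`` is on; otherwise donor competence is limited
        to the hosts that started the generation infected (a freshly
        acquired symbiont has not yet established enough to be passed on).
        """
        if params.chain_transmission:
            return self.alive & self.infected
        return self.alive & self.donor_competent

    def _donor_log_survival(self, params: SimulationParams) -> np.ndarray:
        """Per-host sum of log(1 - p_pair) over the current live donors."""
        self._ensure_logq(params.h)
        if self._donors_dirty:
            donors = np.flatnonzero(self._donor_mask(params))
            if donors.size:
                self._log_surv = self._logq[:, donors].sum(axis=1)
            else:
                self._log_surv = np.zeros(len(self.x))
            self._donors_dirty = False
        return self._log_surv


@dataclass(frozen=True)
class GenerationResult:
    """Outcome of one completed generation."""

    progeny_infected: float
    progeny_uninfected: float
    n_parasitised: int
    n_natural_death: int
    duration: int
    host_fingerprint: str
    # per-host audit arrays for conservation checks
    steps_uninfected: np.ndarray
    steps_infected: np.ndarray
    rate_uninfected: np.ndarray
    rate_final: np.ndarray

    @property
    def progeny_total(self) -> float:
        return self.progeny_infected + self.progeny_uninfected


def _steps_alive(longevity: float | np.ndarray):
    """Total integer steps an individual with continuous longevity L lives.

    An individual completes step t iff t + 1 <= L, so it lives floor(L)
    whole steps and its lifetime reproduction rate x floor(L) never exceeds
    its drawn fecundity.  (Granting a partial step a full reproduction tick
    would weight a host by rate x 1 = fecundity / L, whose expectation
    diverges as L -> 0 under the Exponential draw.)
    """
    return np.floor(longevity).astype(np.int64)


def time_step(
    state: GenerationState, params: SimulationParams, rng: np.random.Generator
) -> GenerationState:
    """Advance the generation by one time step (mutates and returns state)."""
    t = state.step
    alive = state.alive
    infected = state.infected

    # -- phase 1: natural host deaths (a host completes step t iff t+1 <= L)
    dying = np.flatnonzero(alive & (state.longevity < t + 1))
    if dying.size:
        alive[dying] = False
        state.status[dying] = STATUS_DEAD_NATURAL
        state.n_natural_death += dying.size
        if state.donor_competent[dying].any() or (
            params.chain_transmission and infected[dying].any()
        ):
            state._donors_dirty = True

    # -- phase 2: horizontal transmission (synchronous)
    if params.transmission_enabled:
        has_donor = bool(state._donor_mask(params).any())
        if has_donor:
            recipients = np.flatnonzero(alive & ~infected)
            if recipients.size:
                u = rng.random(recipients.size)
                log_surv = state._donor_log_survival(params)
                with np.errstate(invalid="ignore"):
                    p = -np.expm1(log_surv[recipients])
                newly = recipients[u < p]
                if newly.size:
                    infected[newly] = True
                    state.infection_step[newly] = t
                    # cost on remaining longevity and per-step rate
                    rem = state.longevity[newly] - t
                    state.longevity[newly] = t + (1.0 - params.c) * rem
                    state.rate[newly] = (1.0 - params.c) * state.rate[newly]
                    if params.chain_transmission:
                        state._donors_dirty = True

    # -- phase 3: parasitoid phase
    newly_dead_wasps = np.flatnonzero(
        state.w_alive & ((state.w_longevity < t + 1) | (state.w_eggs <= 0))
    )
    if newly_dead_wasps.size:
        state.w_alive[newly_dead_wasps] = False
        state.w_target[newly_dead_wasps] = -1
    live_wasps = np.flatnonzero(state.w_alive)
    if live_wasps.size:
        order = live_wasps[rng.permutation(live_wasps.size)]
        fx = state._fx
        fy = state._fy
        cand = np.flatnonzero(alive)
        kappa = params.perception_decay
        for wi in order:
            if cand.size == 0:
                state.w_target[wi] = -1
                continue
            tid = -1
            if params.sticky_target:
                prev = state.w_target[wi]
                if prev >= 0 and alive[prev]:
                    tid = int(prev)
            if tid < 0:
                j = foraging.select_target(
                    (state.wx[wi], state.wy[wi]),
                    fx[cand],
                    fy[cand],
                    kappa,
                    rng,
                )
                tid = int(cand[j])
            state.w_target[wi] = tid
            nx, ny, reached = foraging.move_step(
                state.wx[wi],
                state.wy[wi],
                float(fx[tid]),
                float(fy[tid]),
                params.mu,
                params.sigma,
                rng,
            )
            state.wx[wi] = nx
            state.wy[wi] = ny
            if reached:
                outcome = foraging.resolve_attack(bool(infected[tid]), params.r, rng)
                if outcome is foraging.AttackOutcome.HOST_KILLED_EGG_LAID:
                    alive[tid] = False
                    state.status[tid] = STATUS_DEAD_PARASITISED
                    state.w_eggs[wi] -= 1
                    state.n_parasitised += 1
                    state.w_target[wi] = -1
                    if state.donor_competent[tid] or (
                        params.chain_transmission and infected[tid]
                    ):
                        state._donors_dirty = True
                    cand = np.flatnonzero(alive)

    # -- phase 4: reproduction at the current per-step rate
    live_inf = alive & infected
    live_un = alive & ~infected
    state.progeny_infected += float(state.rate[live_inf].sum())
    state.progeny_uninfected += float(state.rate[live_un].sum())
    state.steps_infected[live_inf] += 1
    state.steps_uninfected[live_un] += 1

    state.step = t + 1
    return state


def _can_change(state: GenerationState, params: SimulationParams) -> bool:
    """True while wasps may still act or transmission may still fire."""
    t = state.step
    wasp_can_act = bool(
        (state.w_alive & (state.w_longevity >= t + 1) & (state.w_eggs > 0)).any()
    )
    if wasp_can_act:
        return True
    if params.transmission_enabled:
        if state._donor_mask(params).any() and (state.alive & ~state.infected).any():
            return True
    return False


def _fast_forward(state: GenerationState) -> None:
    """Accrue all remaining reproduction in closed form and end the generation.

    Only valid once no wasp can act and transmission cannot fire; identical
    to continued stepping because each live host then simply reproduces at
    its fixed rate for its remaining whole steps.
    """
    live = np.flatnonzero(state.alive)
    if live.size == 0:
        return
    t = state.step
    rem = _steps_alive(state.longevity[live]) - t
    rem = np.maximum(rem, 0)
    inf = state.infected[live]
    state.progeny_infected += float((state.rate[live] * rem)[inf].sum())
    state.progeny_uninfected += float((state.rate[live] * rem)[~inf].sum())
    state.steps_infected[live[inf]] += rem[inf]
    state.steps_uninfected[live[~inf]] += rem[~inf]
    state.alive[live] = False
    state.status[live] = STATUS_DEAD_NATURAL
    state.n_natural_death += live.size
    state.step = t + int(rem.max(initial=0))


def run_generation_from_state(
    state: GenerationState, params: SimulationParams, rng: np.random.Generator
) -> GenerationResult:
    """Step an initialised generation to completion."""
    fingerprint = state.host_fingerprint()
    while state.alive.any():
        if not _can_change(state, params):
            _fast_forward(state)
            break
        time_step(state, params, rng)
    return GenerationResult(
        progeny_infected=state.progeny_infected,
        progeny_uninfected=state.progeny_uninfected,
        n_parasitised=state.n_parasitised,
        n_natural_death=state.n_natural_death,
        duration=state.step,
        host_fingerprint=fingerprint,
        steps_uninfected=state.steps_uninfected,
        steps_infected=state.steps_infected,
        rate_uninfected=state.rate_uninfected,
        rate_final=state.rate,
    )


def run_generation(
    params: SimulationParams,
    n_infected_start: int,
    rng: np.random.Generator,
    host_rng: np.random.Generator | None = None,
) -> GenerationResult:
    """Initialise and run one full generation."""
    if not 0 <= n_infected_start <= params.n_hosts:
        raise ValueError(
            f"n_infected_start={n_infected_start} outside [0, {params.n_hosts}]"
        )
    state = GenerationState.initialise(params, n_infected_start, rng, host_rng)
    return run_generation_from_state(state, params, rng)


def next_generation_infected(
    progeny_infected: float,
    progeny_uninfected: float,
    n_hosts: int,
    rng: np.random.Generator,
    deterministic: bool = False,
) -> int:
    """Compose the next generation from the progeny frequencies.

    The infected fraction of the progeny pool, p' = infected / total, seeds
    a Binomial(n_hosts, p') draw (or deterministic rounding).  Raises
    :class:`ExtinctionError` when no progeny were produced at all.
    """
    total = progeny_infected + progeny_uninfected
    if total <= 0.0:
        raise ExtinctionError("generation produced no progeny")
    p_next = progeny_infected / total
    if deterministic:
        return int(math.floor(p_next * n_hosts + 0.5))
    return int(rng.binomial(n_hosts, min(max(p_next, 0.0), 1.0)))


@dataclass(frozen=True)
class Trajectory:
    """Per-generation infected fraction, including the initial level."""

    fractions: np.ndarray  # length n_generations + 1 unless extinct earlier
    extinct: bool = False
    extinction_generation: int | None = None

    def to_frame(self, replicate: int | None = None):
        import pandas as pd

        df = pd.DataFrame(
            {
                "generation": np.arange(len(self.fractions)),
                "infected_fraction": self.fractions,
            }
        )
        if replicate is not None:
            df.insert(0, "replicate", replicate)
        return df


def round_half_up(value: float) -> int:
    return int(math.floor(value + 0.5))


def run_simulation(
    params: SimulationParams, rng: np.random.Generator
) -> Trajectory:
    """Run a multi-generation simulation of the infection dynamics.

    Generation 0 starts with ``round(p0 * n_hosts)`` infected hosts; each
    later generation is seeded from the progeny frequencies of the previous
    one.  The spatial layout and aggregation pattern are redrawn every
    generation at the same aggregation level ``a``.  The trajectory records
    the starting infected fraction of every generation (length
    ``n_generations + 1``) and ends early if the population goes extinct.
    """
    n = params.n_hosts
    n_inf = round_half_up(params.p0 * n)
    fractions = [n_inf / n if n else 0.0]
    for gen in range(params.n_generations):
        result = run_generation(params, n_inf, rng)
        try:
            n_inf = next_generation_infected(
                result.progeny_infected,
                result.progeny_uninfected,
                n,
                rng,
                deterministic=params.deterministic_rounding,
            )
        except ExtinctionError:
            return Trajectory(
                fractions=np.asarray(fractions),
                extinct=True,
                extinction_generation=gen + 1,
            )
        fractions.append(n_inf / n)
    return Trajectory(fractions=np.asarray(fractions))
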