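"""Host life histories and horizontal symbiont transmission.

Uninfected hosts draw longevity from an Exponential distribution with mean
``s_un`` and fecundity from a Poisson with mean ``lambda_un``.  Infected
hosts pay a constitutive cost ``c``: both means are scaled by ``1 - c``.
Reproduction is spread evenly over life as a per-step rate
``fecundity / longevity``.

Horizontal transmission is distance-dependent: each time step, an uninfected
host at distance ``d`` from a live infected donor acquires the symbiont from
that donor with probability ``exp(-(1 - h) * d)``; trials against distinct
donors are independent, so the combined per-step infection probability is
``1 - prod_i(1 - exp(-(1 - h) * d_i))``.  Infection is absorbing: a host
never reverts, and (via 100% vertical transmission) passes the symbiont to
all progeny produced after the infection step.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .params import SimulationParams

__all__ = [
    "HostStatus",
    "HostState",
    "draw_host_life",
    "apply_infection_cost",
    "horizontal_infection_probability",
    "combined_infection_probability",
    "transmission_step",
]


class HostStatus(enum.Enum):
    ALIVE = "alive"
    DEAD_NATURAL = "dead_natural"
    DEAD_PARASITISED = "dead_parasitised"


@dataclass
class HostState:
    """One host individual (a convenience view; the engine stores arrays)."""

    host_id: int
    position: tuple[int, int]
    infected: bool
    longevity: float
    fecundity: int
    rate: float
    status: HostStatus = HostStatus.ALIVE
    infection_step: int | None = None  # 0 if infected at birth, None if never


def draw_host_life(
    infected, params: SimulationParams, rng: np.random.Generator, size=None
):
    """Draw (longevity, fecundity, rate) for one host or an array of hosts.

    ``infected`` may be a scalar bool or a boolean array (then ``size`` is
    implied).  Infected hosts use means scaled by ``1 - c``.  The per-step
    reproduction rate is fecundity / longevity, 0 when longevity is 0.
    """
    infected = np.asarray(infected, dtype=bool)
    if size is None and infected.shape:
        size = infected.shape
    factor = np.where(infected, 1.0 - params.c, 1.0)
    longevity = rng.exponential(scale=factor * params.s_un, size=size)
    fecundity = rng.poisson(lam=factor * params.lambda_un, size=size)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(longevity > 0, fecundity / np.maximum(longevity, 1e-300), 0.0)
    if size is None:
        return float(longevity), int(fecundity), float(rate)
    return longevity, fecundity.astype(np.int64), rate


def apply_infection_cost(remaining_longevity, rate, c: float):
    """Discount a newly infected host's remaining longevity and per-step rate.

    Both are multiplied by ``1 - c``; fecundity already realised is kept.
    """
    return (1.0 - c) * remaining_longevity, (1.0 - c) * rate


def horizontal_infection_probability(d, h):
    """Per-donor, per-step infection probability exp(-(1 - h) * d)."""
    return np.exp(-(1.0 - np.asarray(h)) * np.asarray(d))


def combined_infection_probability(distances, h: float):
    """Probability that at least one of several independent donors transmits.

    ``distances`` is an array of distances to live infected donors; returns
    ``1 - prod(1 - exp(-(1 - h) * d_i))``, computed in log space.
    """
    p = horizontal_infection_probability(distances, h)
    with np.errstate(divide="ignore"):
        log_surv = np.log1p(-p).sum()
    return float(-np.expm1(log_surv))


def transmission_step(
    uninfected_alive,
    infected_alive,
    h: float,
    current_step: int,
    rng: np.random.Generator,
) -> set[int]:
    """One synchronous round of horizontal transmission between HostStates.

    Each live uninfected host runs independent Bernoulli trials against every
    live infected donor; it becomes infected if any trial succeeds.  Newly
    infected hosts get ``infection_step = current_step`` and do not act as
    donors within the same step.  Returns the set of newly infected host ids;
    the caller is responsible for applying the infection cost.
    """
    recipients = sorted(
        (host for host in uninfected_alive if host.status is HostStatus.ALIVE),
        key=lambda host: host.host_id,
    )
    donors = [host for host in infected_alive if host.status is HostStatus.ALIVE]
    if not recipients or not donors:
        return set()
    dpos = np.asarray([d.position for d in donors], dtype=float)
    u = rng.random(len(recipients))
    newly: set[int] = set()
    for ui, host in zip(u, recipients):
        d = np.hypot(dpos[:, 0] - host.position[0], dpos[:, 1] - host.position[1])
        if ui < combined_infection_probability(d, h):
            host.infected = True
            host.infection_step = current_step
            newly.add(host.host_id)
    return newly
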