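"""Parasitoid perception, movement and attack resolution.

A foraging wasp perceives every live host on the grid and picks a target
with probability proportional to exp(-kappa * d), an exponential decay in
distance.  It then moves straight toward the target, each step covering a
distance drawn from Normal(mu, sigma) truncated below at zero (negative
draws are redrawn).  On arrival it attacks: an uninfected host is always
killed and receives one egg; an infected host escapes with probability R
(the symbiont-conferred resistance), in which case no egg is laid and the
host remains alive, perceivable and reproducing.  Dead hosts are never
attacked again (no superparasitism).

Wasps are proovigenic: longevity ~ Exponential(s_p) and egg supply ~
Poisson(lambda_p) are drawn at emergence and eggs never replenish.  A wasp
dies when its elapsed time reaches its longevity or its eggs run out.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .params import SimulationParams

__all__ = [
    "AttackOutcome",
    "ParasitoidState",
    "draw_parasitoid_life",
    "select_target",
    "move_step",
    "resolve_attack",
]


class AttackOutcome(enum.Enum):
    HOST_KILLED_EGG_LAID = "host_killed_egg_laid"
    HOST_RESISTED = "host_resisted"


@dataclass
class ParasitoidState:
    """One parasitoid female (convenience view; the engine stores arrays)."""

    wasp_id: int
    position: tuple[float, float]
    longevity: float
    eggs_remaining: int
    target: int | None = None
    alive: bool = True


def draw_parasitoid_life(params: SimulationParams, rng: np.random.Generator, size=None):
    """Draw (longevity, egg supply) for one wasp or ``size`` wasps."""
    longevity = rng.exponential(scale=params.s_p, size=size)
    eggs = rng.poisson(lam=params.lambda_p, size=size)
    if size is None:
        return float(longevity), int(eggs)
    return longevity, eggs.astype(np.int64)


def select_target(
    wasp_xy,
    host_xs: np.ndarray,
    host_ys: np.ndarray,
    kappa: float,
    rng: np.random.Generator,
) -> int | None:
    """Sample a target index with probability proportional to exp(-kappa*d).

    ``host_xs``/``host_ys`` are the coordinates of the candidate hosts (all
    live hosts); returns an index into them, or None when there are no
    candidates.  One uniform variate is always consumed when candidates
    exist; if every weight underflows to zero the nearest host is chosen.
    """
    n = host_xs.shape[0]
    if n == 0:
        return None
    dx = host_xs - wasp_xy[0]
    dy = host_ys - wasp_xy[1]
    d = np.hypot(dx, dy)
    u = rng.random()
    if n == 1:
        return 0
    w = np.exp(-kappa * d)
    cum = np.cumsum(w)
    total = cum[-1]
    if total <= 0.0:
        return int(np.argmin(d))
    i = int(np.searchsorted(cum, u * total, side="left"))
    return min(i, n - 1)


def move_step(
    x: float,
    y: float,
    tx: float,
    ty: float,
    mu: float,
    sigma: float,
    rng: np.random.Generator,
) -> tuple[float, float, bool]:
    """Advance one movement step toward the target.

    Draws a step length from Normal(mu, sigma), redrawing while negative.
    If the drawn length covers the remaining distance the wasp lands exactly
    on the target (reached=True); a wasp already at its target arrives
    without drawing.  Straight-line movement between two in-grid points
    never leaves the grid, so no boundary clipping is needed.
    """
    ddx = tx - x
    ddy = ty - y
    d = math.hypot(ddx, ddy)
    if d <= 0.0:
        return tx, ty, True
    s = rng.normal(mu, sigma)
    while s < 0.0:
        s = rng.normal(mu, sigma)
    if s >= d:
        return tx, ty, True
    f = s / d
    return x + f * ddx, y + f * ddy, False


def resolve_attack(
    host_infected: bool, resistance: float, rng: np.random.Generator
) -> AttackOutcome:
    """Resolve an attack on a live host.

    Uninfected hosts are always killed (one egg laid, no random draw);
    infected hosts resist with probability ``resistance``.  The caller
    guarantees the host is alive and the wasp has an egg.
    """
    if host_infected and rng.random() < resistance:
        return AttackOutcome.HOST_RESISTED
    return AttackOutcome.HOST_KILLED_EGG_LAID
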