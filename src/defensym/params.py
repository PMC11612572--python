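"""Simulation parameters.

Defaults are the fixed study conditions: 200 hosts and 10 parasitoid females
on a 500 x 500 grid, initial infection level 0.20, mean uninfected host
longevity 150 steps and fecundity 60 progeny, mean parasitoid fecundity 150
eggs, movement steps Normal(10, 5).  Parameters that the study varies over a
range (infection cost c, horizontal-transmission intensity h, mean parasitoid
longevity S_p, resistance R, aggregation a) default to the central anchor
values used when the respective other parameters are varied: c=0.4, h=0.8,
S_p=100, R=0.9, a=0.04.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace, asdict

from .landscape import GridSpec

__all__ = ["SimulationParams"]


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value}")


@dataclass(frozen=True)
class SimulationParams:
    """All tunable parameters of the host-parasitoid-symbiont simulation.

    Attributes
    ----------
    n_hosts, n_parasitoids:
        Population sizes, constant across generations.
    p0:
        Initial proportion of hosts infected by the symbiont.
    a:
        Infected-host spatial aggregation level, a fraction in (0, 1] of the
        infected-host count giving the number of patches.
    s_un, lambda_un:
        Means of the Exponential longevity (time steps) and Poisson fecundity
        (progeny) distributions of uninfected hosts.
    c:
        Constitutive infection cost; infected hosts draw longevity and
        fecundity with means scaled by (1 - c).
    h:
        Horizontal-transmission intensity; per-step per-donor infection
        probability is exp(-(1 - h) * d) at distance d.
    s_p, lambda_p:
        Means of the parasitoid longevity (steps) and egg-supply (Poisson)
        distributions.  Parasitoids are proovigenic: eggs never replenish.
    r:
        Resistance: probability that an infected host survives an attack.
    mu, sigma:
        Mean and SD of the Normal per-step movement distance of a foraging
        parasitoid (cell units; draws truncated below at 0 by redrawing).
    kappa:
        Perception decay per cell unit: a wasp targets host i with weight
        exp(-kappa * d_i).  ``None`` means 1 / mu.
    n_generations, n_replicates, seed:
        Experiment sizes and base random seed.
    transmission_enabled:
        Hard switch for horizontal transmission (h = 0 still allows
        short-range transmission via exp(-d); this disables it entirely).
    chain_transmission:
        If True, hosts infected by horizontal transmission become donors
        from the next time step of the same generation.  Default False: a
        freshly acquired symbiont must establish before it can be passed on,
        so within a generation only hosts infected from birth transmit (all
        infected hosts transmit vertically regardless).
    sticky_target:
        If True a wasp keeps its current target while it stays alive instead
        of re-selecting every step.
    deterministic_rounding:
        If True the next generation's infected count is round(p' * n_hosts)
        instead of a Binomial(n_hosts, p') draw.
    paired:
        If True the efficacy experiment reuses the identical host realisation
        for the control and treatment generations (common random numbers).
    """

    n_hosts: int = 200
    n_parasitoids: int = 10
    p0: float = 0.20
    a: float = 0.04
    s_un: float = 150.0
    lambda_un: float = 60.0
    c: float = 0.4
    h: float = 0.8
    s_p: float = 100.0
    lambda_p: float = 150.0
    r: float = 0.9
    mu: float = 10.0
    sigma: float = 5.0
    grid: GridSpec = field(default_factory=GridSpec)
    kappa: float | None = None
    n_generations: int = 100
    n_replicates: int = 100
    seed: int = 0
    transmission_enabled: bool = True
    chain_transmission: bool = False
    sticky_target: bool = False
    deterministic_rounding: bool = False
    paired: bool = True

    def __post_init__(self) -> None:
        for name in ("p0", "c", "h", "r"):
            _check_fraction(name, getattr(self, name))
        if not 0.0 < self.a <= 1.0:
            raise ValueError(f"a must lie in (0, 1], got {self.a}")
        for name in ("s_un", "lambda_un", "s_p", "lambda_p", "mu", "sigma"):
            _check_nonneg(name, getattr(self, name))
        for name in ("n_hosts", "n_parasitoids", "n_generations", "n_replicates"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.kappa is not None and self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        if self.n_hosts > self.grid.n_cells:
            raise ValueError(
                f"n_hosts={self.n_hosts} exceeds grid capacity {self.grid.n_cells}"
            )

    @property
    def perception_decay(self) -> float:
        """Effective kappa: the explicit value, or 1/mu (0 if mu == 0)."""
        if self.kappa is not None:
            return self.kappa
        return 1.0 / self.mu if self.mu > 0 else 0.0

    def replace(self, **changes) -> "SimulationParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_width"] = self.grid.width
        d["grid_height"] = self.grid.height
        del d["grid"]
        return d

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]
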