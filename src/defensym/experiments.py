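"""Replicate runner, parameter sweeps and the pest-control efficacy experiment.

Steady-state experiments run the full multi-generation simulation across
independently seeded replicates and summarise the final-generation infected
fraction as mean +/- SE.  The efficacy experiment measures biological
control over a single generation: the same host realisation is run once
without parasitoids (control) and once with them (treatment), and efficacy
is the percent reduction in total host progeny.  Pairing the two runs on a
common host realisation (common random numbers) isolates the parasitoid
effect; ``paired=False`` gives fully independent re-runs.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import ExtinctionError, GenerationState, run_generation_from_state, run_simulation, round_half_up
from .params import SimulationParams

__all__ = [
    "ReplicateSummary",
    "EfficacySummary",
    "EfficacyReplicates",
    "UndefinedEfficacyError",
    "params_fingerprint",
    "run_replicates",
    "efficacy_experiment",
    "run_efficacy_replicates",
    "sweep",
    "FIGURE_PRESETS",
]


class UndefinedEfficacyError(RuntimeError):
    """Raised when the control generation produces no progeny."""


def params_fingerprint(params: SimulationParams) -> str:
    """Stable short hash of a parameter set (used for seed derivation)."""
    payload = json.dumps(params.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean +/- SE of the final-generation infected fraction over replicates."""

    final_p_mean: float
    final_p_se: float
    n_replicates: int
    n_extinctions: int
    params_fingerprint: str
    final_values: np.ndarray  # per surviving replicate


@dataclass(frozen=True)
class EfficacySummary:
    """One paired control/treatment generation and its percent reduction."""

    p0: float
    progeny_control: float
    progeny_treatment: float
    efficacy_pct: float


@dataclass(frozen=True)
class EfficacyReplicates:
    """Per-replicate percent reductions, averaged across paired runs."""

    p0: float
    mean_pct: float
    se_pct: float
    n_replicates: int
    n_undefined: int
    values: np.ndarray


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    if values.size == 0:
        return float("nan"), float("nan")
    mean = float(values.mean())
    if values.size < 2:
        return mean, 0.0
    se = float(values.std(ddof=1) / np.sqrt(values.size))
    return mean, se


def run_replicates(
    params: SimulationParams, n_replicates: int, base_seed: int
) -> ReplicateSummary:
    """Run seeded replicates (seeds base_seed+1 .. base_seed+n) and summarise.

    Replicates ending in extinction are excluded from the mean and counted
    separately.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    finals = []
    extinctions = 0
    for i in range(1, n_replicates + 1):
        rng = np.random.default_rng(base_seed + i)
        traj = run_simulation(params, rng)
        if traj.extinct:
            extinctions += 1
        else:
            finals.append(traj.fractions[-1])
    finals = np.asarray(finals)
    mean, se = _mean_se(finals)
    return ReplicateSummary(
        final_p_mean=mean,
        final_p_se=se,
        n_replicates=n_replicates,
        n_extinctions=extinctions,
        params_fingerprint=params_fingerprint(params),
        final_values=finals,
    )


def efficacy_experiment(
    params: SimulationParams, p0: float, rng: np.random.Generator
) -> EfficacySummary:
    """Paired single-generation control (no wasps) vs treatment experiment.

    Both arms share the identical host layout, infection assignment and
    life-history draws when ``params.paired`` (asserted by fingerprint);
    wasp initialisation and within-generation stochasticity use separate
    streams per arm.  Efficacy is 100 x (control - treatment) / control.
    """
    n_inf = round_half_up(p0 * params.n_hosts)
    host_seed = int(rng.integers(0, 2**31 - 1))
    seed_control = int(rng.integers(0, 2**31 - 1))
    seed_treatment = int(rng.integers(0, 2**31 - 1))

    def run_arm(arm_params: SimulationParams, dyn_seed: int, host_seed_arm: int):
        dyn_rng = np.random.default_rng(dyn_seed)
        host_rng = np.random.default_rng(host_seed_arm)
        state = GenerationState.initialise(arm_params, n_inf, dyn_rng, host_rng)
        fp = state.host_fingerprint()
        return run_generation_from_state(state, arm_params, dyn_rng), fp

    control_params = params.replace(n_parasitoids=0, p0=p0)
    treat_params = params.replace(p0=p0)
    if params.paired:
        host_seed_c = host_seed_t = host_seed
    else:
        host_seed_c = seed_control ^ 0x5DEECE
        host_seed_t = seed_treatment ^ 0x5DEECE
    res_c, fp_c = run_arm(control_params, seed_control, host_seed_c)
    res_t, fp_t = run_arm(treat_params, seed_treatment, host_seed_t)
    if params.paired and fp_c != fp_t:
        raise AssertionError("paired arms diverged in host initial conditions")
    control = res_c.progeny_total
    treatment = res_t.progeny_total
    if control <= 0.0:
        raise UndefinedEfficacyError("control generation produced no progeny")
    return EfficacySummary(
        p0=p0,
        progeny_control=control,
        progeny_treatment=treatment,
        efficacy_pct=100.0 * (control - treatment) / control,
    )


def run_efficacy_replicates(
    params: SimulationParams, p0: float, n_replicates: int, base_seed: int
) -> EfficacyReplicates:
    """Average per-replicate percent reductions over paired experiments."""
    values = []
    undefined = 0
    for i in range(1, n_replicates + 1):
        rng = np.random.default_rng(base_seed + i)
        try:
            values.append(efficacy_experiment(params, p0, rng).efficacy_pct)
        except UndefinedEfficacyError:
            undefined += 1
    values = np.asarray(values)
    mean, se = _mean_se(values)
    return EfficacyReplicates(
        p0=p0,
        mean_pct=mean,
        se_pct=se,
        n_replicates=n_replicates,
        n_undefined=undefined,
        values=values,
    )


def _cell_seed(params: SimulationParams, base_seed: int) -> int:
    digest = hashlib.sha256(
        f"{params_fingerprint(params)}:{base_seed}".encode()
    ).hexdigest()
    return int(digest[:8], 16) % (2**31)


def sweep(
    grid_of_params: dict[str, list],
    base_params: SimulationParams,
    n_replicates: int,
    base_seed: int,
    kind: str = "steady",
    p0: float | None = None,
) -> pd.DataFrame:
    """Cross-product sweep over parameter values.

    ``grid_of_params`` maps :class:`SimulationParams` field names to value
    lists.  Each cell gets a deterministic seed derived from the cell's
    parameter fingerprint and ``base_seed``, so any single cell can be rerun
    bit-identically.  ``kind`` selects the steady-state replicate runner or
    the paired efficacy experiment (at ``p0``, defaulting to
    ``base_params.p0``).  Returns a long-format table, one row per cell.
    """
    if not grid_of_params:
        raise ValueError("empty sweep grid")
    names = list(grid_of_params)
    rows = []
    for combo in itertools.product(*(grid_of_params[k] for k in names)):
        cell_params = base_params.replace(**dict(zip(names, combo)))
        seed = _cell_seed(cell_params, base_seed)
        row = dict(zip(names, combo))
        row["seed"] = seed
        if kind == "steady":
            summary = run_replicates(cell_params, n_replicates, seed)
            row.update(
                final_p_mean=summary.final_p_mean,
                final_p_se=summary.final_p_se,
                n_replicates=summary.n_replicates,
                n_extinctions=summary.n_extinctions,
            )
        elif kind == "efficacy":
            eff = run_efficacy_replicates(
                cell_params, p0 if p0 is not None else cell_params.p0,
                n_replicates, seed,
            )
            row.update(
                efficacy_mean_pct=eff.mean_pct,
                efficacy_se_pct=eff.se_pct,
                n_replicates=eff.n_replicates,
                n_undefined=eff.n_undefined,
            )
        else:
            raise ValueError(f"unknown sweep kind {kind!r}")
        rows.append(row)
    return pd.DataFrame(rows)


# Named sweep presets: (kind, swept grid, fixed overrides, p0 values for
# efficacy sweeps).  These encode the fixed-vs-swept parameter combinations
# of the headline experiments: resistance x cost, wasp longevity x cost,
# transmission x aggregation for the steady state; resistance x aggregation
# and resistance x transmission for efficacy at three initial infection
# levels.
FIGURE_PRESETS: dict[int, dict] = {
    2: {
        "kind": "steady",
        "grid": {"r": [round(0.1 * i, 1) for i in range(11)],
                 "c": [0.2, 0.3, 0.4, 0.5, 0.6]},
        "fixed": {"a": 0.04, "h": 0.8, "s_p": 100.0},
    },
    3: {
        "kind": "steady",
        "grid": {"s_p": [float(v) for v in range(0, 301, 20)],
                 "c": [0.2, 0.3, 0.4, 0.5, 0.6]},
        "fixed": {"a": 0.04, "h": 0.8, "r": 0.9},
    },
    4: {
        "kind": "steady",
        # r=0: with strong resistance the selective advantage of infection
        # saturates at fixation for every aggregation level and the
        # transmission-by-aggregation effect is invisible
        "grid": {"h": [0.0, 0.2, 0.4, 0.6, 0.8, 0.9, 1.0],
                 "a": [0.005, 0.04, 1.0]},
        "fixed": {"c": 0.4, "s_p": 100.0, "r": 0.0},
    },
    5: {
        "kind": "efficacy",
        "grid": {"r": [round(0.1 * i, 1) for i in range(11)],
                 "a": [0.005, 0.04, 1.0],
                 "p0": [0.2, 0.5, 0.8]},
        "fixed": {"c": 0.4, "h": 0.8, "s_p": 100.0},
    },
    6: {
        "kind": "efficacy",
        "grid": {"r": [round(0.1 * i, 1) for i in range(11)],
                 "h": [0.0, 0.2, 0.4, 0.6, 0.8, 0.9, 1.0],
                 "p0": [0.2, 0.5, 0.8]},
        "fixed": {"c": 0.4, "a": 0.04, "s_p": 100.0},
    },
}
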