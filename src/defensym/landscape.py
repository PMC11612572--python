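"""Spatial layout of hosts and their symbiont infection pattern.

Hosts (aphids) sit on integer cells of a rectangular grid, at most one host
per cell, and do not move within a generation.  Symbiont infection is
assigned with a controlled level of spatial aggregation: the infected hosts
are grouped into patches around randomly drawn continuous centres, with the
number of patches set by the aggregation level ``a`` (a fraction of the
infected-host count).  Small ``a`` produces a few large clumps; ``a = 1``
gives one patch per infected host, i.e. an effectively random spatial
distribution of infection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GridSpec",
    "PatchLayout",
    "distance",
    "compute_patch_count",
    "split_patch_sizes",
    "plan_patches",
    "place_hosts",
    "assign_infection",
    "layout_frame",
]


@dataclass(frozen=True)
class GridSpec:
    """Rectangular environment measured in cells.

    Host coordinates are integer cell indices in ``[0, width) x [0, height)``;
    patch centres and parasitoid positions are continuous over the same
    extent.
    """

    width: int = 500
    height: int = 500

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(
                f"grid dimensions must be >= 1, got {self.width} x {self.height}"
            )

    @property
    def n_cells(self) -> int:
        return self.width * self.height


@dataclass(frozen=True)
class PatchLayout:
    """Planned grouping of infected hosts into spatial patches."""

    n_patches: int
    patch_centres: np.ndarray  # shape (n_patches, 2), continuous coordinates
    patch_sizes: np.ndarray  # shape (n_patches,), counts summing to n_infected


def distance(p, q) -> float:
    """Euclidean distance between two coordinate pairs, in cell units."""
    return math.hypot(p[0] - q[0], p[1] - q[1])


def compute_patch_count(n_infected: int, a: float) -> int:
    """Number of infection patches for ``n_infected`` hosts at aggregation ``a``.

    ``a`` is a fraction in (0, 1]: the patch count is ``a * n_infected``
    rounded half away from zero, clamped to ``[1, n_infected]``.  Zero
    infected hosts yield zero patches.
    """
    if not 0.0 < a <= 1.0:
        raise ValueError(f"aggregation level a must lie in (0, 1], got {a}")
    if n_infected < 0:
        raise ValueError(f"n_infected must be >= 0, got {n_infected}")
    if n_infected == 0:
        return 0
    k = int(math.floor(a * n_infected + 0.5))
    return min(max(k, 1), n_infected)


def split_patch_sizes(n_infected: int, n_patches: int) -> np.ndarray:
    """Split ``n_infected`` hosts into ``n_patches`` groups differing by <= 1.

    The remainder is given one extra host to the first patches, so the split
    is deterministic.
    """
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    base, rem = divmod(n_infected, n_patches)
    sizes = np.full(n_patches, base, dtype=np.int64)
    sizes[:rem] += 1
    return sizes


def plan_patches(
    n_infected: int, a: float, grid: GridSpec, rng: np.random.Generator
) -> PatchLayout:
    """Draw patch centres uniformly over the grid extent and size the patches."""
    k = compute_patch_count(n_infected, a)
    if k == 0:
        return PatchLayout(0, np.empty((0, 2)), np.empty(0, dtype=np.int64))
    centres = np.column_stack(
        [rng.uniform(0.0, grid.width, k), rng.uniform(0.0, grid.height, k)]
    )
    return PatchLayout(k, centres, split_patch_sizes(n_infected, k))


def place_hosts(
    n_hosts: int, grid: GridSpec, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_hosts`` distinct cells, uniformly without replacement.

    Returns an ``(n_hosts, 2)`` integer array of (x, y) cell coordinates.
    Sampling is draw-until-distinct (exactly equivalent to sampling without
    replacement); when more than half the grid is requested a full
    permutation is used instead so the loop always terminates quickly.
    """
    n_cells = grid.n_cells
    if n_hosts > n_cells:
        raise ValueError(
            f"cannot place {n_hosts} hosts on a grid of {n_cells} cells"
        )
    if n_hosts > n_cells // 2:
        cells = rng.permutation(n_cells)[:n_hosts]
    else:
        seen: set[int] = set()
        out: list[int] = []
        while len(out) < n_hosts:
            for c in rng.integers(0, n_cells, size=n_hosts - len(out)):
                ci = int(c)
                if ci not in seen:
                    seen.add(ci)
                    out.append(ci)
        cells = np.asarray(out, dtype=np.int64)
    x = cells % grid.width
    y = cells // grid.width
    return np.column_stack([x, y]).astype(np.int64)


def assign_infection(
    positions: np.ndarray,
    n_infected: int,
    a: float,
    grid: GridSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Flag exactly ``n_infected`` hosts as infected, clustered into patches.

    Patch centres are drawn uniformly over the continuous grid extent; each
    patch in turn claims its ``patch_size`` nearest not-yet-flagged hosts by
    Euclidean distance (greedy, in patch-index order; ties broken by host
    index).  Returns a boolean array aligned with ``positions``.
    """
    positions = np.asarray(positions)
    n_hosts = len(positions)
    if n_infected > n_hosts:
        raise ValueError(
            f"n_infected={n_infected} exceeds number of hosts {n_hosts}"
        )
    flags = np.zeros(n_hosts, dtype=bool)
    if n_infected == 0:
        return flags
    layout = plan_patches(n_infected, a, grid, rng)
    remaining = np.arange(n_hosts)
    px = positions[:, 0].astype(float)
    py = positions[:, 1].astype(float)
    for (cx, cy), size in zip(layout.patch_centres, layout.patch_sizes):
        d = np.hypot(px[remaining] - cx, py[remaining] - cy)
        order = np.argsort(d, kind="stable")
        take = remaining[order[: int(size)]]
        flags[take] = True
        remaining = remaining[order[int(size):]]
    return flags


def layout_frame(positions: np.ndarray, infected: np.ndarray):
    """Serialise a layout to a DataFrame (host_id, x, y, infected) for debugging."""
    import pandas as pd

    positions = np.asarray(positions)
    return pd.DataFrame(
        {
            "host_id": np.arange(len(positions)),
            "x": positions[:, 0],
            "y": positions[:, 1],
            "infected": np.asarray(infected, dtype=bool),
        }
    )
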