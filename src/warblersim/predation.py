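"""Stage 2 of a model run: predator foraging and nest depredation.

Two predator types forage over the settled landscape for 6400 ticks
(32 days x 200 ticks, time scaled to red fox movement, 1 cell per tick):

* **Wild boar** — an incidental predator: a plain correlated random walk,
  active only for the first ``boar_active_ticks_per_day`` ticks of each
  200-tick day (boars cover roughly half the daily distance of foxes).
* **Red fox** — a responsive predator: a CRW forager that switches to an
  area-restricted search (ARS) after consuming a nest, raising its turning
  SD to ``strength_ars`` for ``duration_ars`` ticks (timer re-armed on each
  new find) so that it concentrates search near the find.

A predator destroys every live nest sharing its (floored) grid cell; nests
never recover, and predators are never satiated.

Two execution paths are provided: scalar per-agent steps
(:func:`boar_step`, :func:`fox_step`, :func:`run_predation_stage`) that make
the update rule explicit, and a replicate-vectorised engine
(:func:`run_predation_batch`) used by the experiment layer.  Because
depredation removes all nests in a cell at once, per-cell occupancy is an
exact sufficient state and the two paths simulate the same process.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

from .settlement import Bird, Nest
from .space import crw_step

__all__ = [
    "PredatorKind",
    "Predator",
    "PredatorParams",
    "SimResult",
    "place_predators",
    "boar_step",
    "fox_step",
    "run_predation_stage",
    "run_predation_batch",
]


class PredatorKind(str, Enum):
    BOAR = "boar"
    FOX = "fox"


@dataclass
class Predator:
    kind: PredatorKind
    pos: np.ndarray
    heading: float
    ars_remaining: int = 0  # ticks of area-restricted search left (foxes only)


@dataclass
class PredatorParams:
    """Movement parameters (degrees / ticks); defaults are the efficient setup.

    ``total_ticks`` must be a multiple of ``ticks_per_day`` (a whole number
    of days; 32 x 200 by default, the length of a nest cycle).
    """

    turning_boar: float = 10.0
    turning_fox: float = 10.0
    strength_ars: float = 55.0
    duration_ars: int = 100
    boar_active_ticks_per_day: int = 100
    ticks_per_day: int = 200
    total_ticks: int = 6400
    side: float = 200.0

    def __post_init__(self) -> None:
        if not (0 < self.boar_active_ticks_per_day <= self.ticks_per_day):
            raise ValueError("boar activity window must lie within the day")
        if self.total_ticks % self.ticks_per_day != 0:
            raise ValueError("total_ticks must be a whole number of days")
        if self.duration_ars < 0:
            raise ValueError("duration_ars must be non-negative")


@dataclass
class SimResult:
    """Per-strategy nest-success tallies for one replicate."""

    successes: dict[str, int]
    totals: dict[str, int]
    nest_alive: np.ndarray
    seed: Optional[int] = None


def place_predators(
    n_boars: int, n_foxes: int, rng, side: float = 200.0
) -> list[Predator]:
    """Place predators uniformly with uniform headings and no ARS state."""
    if n_boars < 0 or n_foxes < 0:
        raise ValueError("predator counts must be non-negative")
    preds = []
    for kind, n in ((PredatorKind.BOAR, n_boars), (PredatorKind.FOX, n_foxes)):
        for _ in range(n):
            preds.append(
                Predator(
                    kind=kind,
                    pos=rng.uniform(0.0, side, size=2),
                    heading=float(rng.uniform(0.0, 360.0)),
                )
            )
    return preds


class _NestIndex:
    """Cell -> live nests lookup; depredation removes whole cells at once."""

    def __init__(self, nests: Iterable[Nest], side: float):
        self.side = side
        self._cells: dict[tuple[int, int], list[Nest]] = defaultdict(list)
        for nest in nests:
            if nest.alive:
                self._cells[self.cell_of(nest.pos)].append(nest)

    def cell_of(self, pos) -> tuple[int, int]:
        return (int(math.floor(pos[0])), int(math.floor(pos[1])))

    def kill_at(self, pos) -> list[Nest]:
        bucket = self._cells.pop(self.cell_of(pos), [])
        for nest in bucket:
            nest.alive = False
        return bucket


def _as_index(nests, side: float) -> _NestIndex:
    return nests if isinstance(nests, _NestIndex) else _NestIndex(nests, side)


def boar_step(p: Predator, t: int, params: PredatorParams, nests, rng) -> list[Nest]:
    """Advance one boar by one tick; returns the nests it destroyed.

    Outside its daily activity window (the first
    ``boar_active_ticks_per_day`` ticks of each day) the boar neither moves
    nor depredates.
    """
    if p.kind != PredatorKind.BOAR:
        raise ValueError("boar_step requires a boar")
    if (t % params.ticks_per_day) >= params.boar_active_ticks_per_day:
        return []
    index = _as_index(nests, params.side)
    p.pos, p.heading = crw_step(
        p.pos, p.heading, params.turning_boar, 1.0, rng, params.side
    )
    p.heading = float(p.heading)
    return index.kill_at(p.pos)


def fox_step(p: Predator, params: PredatorParams, nests, rng) -> list[Nest]:
    """Advance one fox by one tick; returns the nests it destroyed.

    The turning SD is ``strength_ars`` while the ARS timer runs, else
    ``turning_fox``.  Finding (destroying) at least one live nest re-arms the
    timer to ``duration_ars``; otherwise the timer decays toward zero.  Foxes
    are active every tick.
    """
    if p.kind != PredatorKind.FOX:
        raise ValueError("fox_step requires a fox")
    index = _as_index(nests, params.side)
    sd = params.strength_ars if p.ars_remaining > 0 else params.turning_fox
    p.pos, p.heading = crw_step(p.pos, p.heading, sd, 1.0, rng, params.side)
    p.heading = float(p.heading)
    killed = index.kill_at(p.pos)
    if killed:
        p.ars_remaining = params.duration_ars
    elif p.ars_remaining > 0:
        p.ars_remaining -= 1
    return killed


def _tally(nests: Sequence[Nest], birds: Optional[Sequence[Bird]]) -> SimResult:
    alive = np.array([n.alive for n in nests], dtype=bool)
    successes: dict[str, int] = {}
    totals: dict[str, int] = {}
    if birds is not None:
        strat_of = {b.id: str(b.strategy.value) for b in birds}
        for nest in nests:
            s = strat_of[nest.owner]
            totals[s] = totals.get(s, 0) + 1
            successes[s] = successes.get(s, 0) + int(nest.alive)
    return SimResult(successes=successes, totals=totals, nest_alive=alive)


def run_predation_stage(
    nests: Sequence[Nest],
    predators: Sequence[Predator],
    params: PredatorParams,
    rng,
    birds: Optional[Sequence[Bird]] = None,
) -> SimResult:
    """Run the full foraging stage (scalar reference path).

    Before any movement, every predator checks its initial cell (an agent
    standing on a nest consumes it, and a fox arms its ARS timer).  Then for
    each of ``total_ticks`` ticks every predator steps in freshly shuffled
    order.  Depredation is absorbing.  Returns per-strategy tallies when
    ``birds`` is given.
    """
    index = _NestIndex(nests, params.side)
    for i in rng.permutation(len(predators)):
        p = predators[i]
        killed = index.kill_at(p.pos)
        if killed and p.kind == PredatorKind.FOX:
            p.ars_remaining = params.duration_ars
    for t in range(params.total_ticks):
        for i in rng.permutation(len(predators)):
            p = predators[i]
            if p.kind == PredatorKind.BOAR:
                boar_step(p, t, params, index, rng)
            else:
                fox_step(p, params, index, rng)
    return _tally(nests, birds)


def run_predation_batch(
    nest_cells: Sequence[np.ndarray],
    n_boars: int,
    n_foxes: int,
    params: PredatorParams,
    rng,
) -> list[np.ndarray]:
    """Run many independent replicates of the foraging stage at once.

    Parameters
    ----------
    nest_cells : sequence of (n_i, 2) integer arrays
        Floored nest grid cells, one array per replicate.
    n_boars, n_foxes : int
        Predator community, identical across replicates.
    rng : numpy.random.Generator

    Returns
    -------
    list of boolean arrays, one per replicate: nest survival flags aligned
    with the input nests.

    Same process as :func:`run_predation_stage`, vectorised over replicates
    and predators (within-tick kills are simultaneous rather than ordered,
    which is observationally equivalent at cell-level kill granularity).
    """
    side = params.side
    length = int(round(side))
    if abs(side - length) > 1e-9:
        raise ValueError("batch engine requires an integer side length")
    n_rep = len(nest_cells)
    n_pred = n_boars + n_foxes
    alive = np.zeros((n_rep, length * length), dtype=bool)
    for r, cells in enumerate(nest_cells):
        cells = np.asarray(cells, dtype=int)
        alive[r, cells[:, 0] * length + cells[:, 1]] = True
    if n_pred == 0 or n_rep == 0:
        return [alive[r, np.asarray(c, dtype=int)[:, 0] * length + np.asarray(c, dtype=int)[:, 1]]
                for r, c in enumerate(nest_cells)]

    rows = np.arange(n_rep)[:, None]
    pos = rng.uniform(0.0, side, size=(n_rep, n_pred, 2))
    head = rng.uniform(0.0, 360.0, size=(n_rep, n_pred))
    fox = slice(n_boars, n_pred)
    ars = np.zeros((n_rep, n_foxes), dtype=int)

    def strike(p, fox_only: bool):
        """Consume nests under positions ``p``; update fox ARS timers."""
        nonlocal ars
        cells = p.astype(int)
        flat = cells[..., 0] * length + cells[..., 1]
        hit = alive[rows, flat]
        # a visited cell without a live nest is already False
        alive[rows, flat] = False
        if n_foxes:
            fox_hit = hit if fox_only else hit[:, fox]
            ars = np.where(fox_hit, params.duration_ars, np.maximum(ars - 1, 0))
        return hit

    # initial placement check, before any movement (no ARS decay at t=0)
    cells = pos.astype(int)
    flat = cells[..., 0] * length + cells[..., 1]
    hit0 = alive[rows, flat]
    alive[rows, flat] = False
    if n_foxes:
        ars = np.where(hit0[:, fox], params.duration_ars, ars)

    deg = np.empty((n_rep, n_pred))
    for t in range(params.total_ticks):
        boar_active = (t % params.ticks_per_day) < params.boar_active_ticks_per_day
        if boar_active:
            deg[:, :n_boars] = params.turning_boar
            if n_foxes:
                deg[:, fox] = np.where(ars > 0, params.strength_ars, params.turning_fox)
            pos, head = crw_step(pos, head, deg, 1.0, rng, side)
            strike(pos, fox_only=False)
        elif n_foxes:
            sd = np.where(ars > 0, params.strength_ars, params.turning_fox)
            pos[:, fox], head[:, fox] = crw_step(
                pos[:, fox], head[:, fox], sd, 1.0, rng, side
            )
            strike(pos[:, fox], fox_only=True)

    out = []
    for r, c in enumerate(nest_cells):
        c = np.asarray(c, dtype=int)
        out.append(alive[r, c[:, 0] * length + c[:, 1]].copy())
    return out
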