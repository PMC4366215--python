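"""Stage 1 of a model run: bird settlement and nest sprouting.

The bird community consists of three sub-types that differ only in how they
choose a territory:

* **cue-providers** settle first, at random positions mutually at least
  ``min_nn`` cells apart (site-faithful birds relying on personal
  information);
* **cue-users** start at random positions away from all providers, then
  prospect by a correlated random walk until they perceive a settled
  conspecific within ``cue_radius`` cells, at which point they settle on the
  spot and themselves become a social cue;
* **random-settlers** are placed last, mutually at least ``min_nn`` apart and
  at least ``cluster_exclusion`` cells from every settled social bird, as the
  uninformed baseline.

Optionally, settled social birds then revise their decision ("Bayesian
updating"): any bird with more than ``k`` other social birds within
``bayes_radius`` cells wanders in a tight convoluted walk (turning SD
``bayes_sd``) until its neighbourhood is no longer overcrowded.

Finally each settled bird sprouts one nest uniformly on the disc of radius
``nest_radius`` around its territory centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .space import crw_step, pairwise_torus_distance, torus_distance, wrap

__all__ = [
    "Strategy",
    "Bird",
    "Nest",
    "SettlementConfig",
    "PlacementError",
    "ConvergenceError",
    "place_cue_providers",
    "place_cue_users_initial",
    "prospect",
    "prospect_with_updating",
    "bayesian_adjust",
    "place_random_settlers",
    "sprout_nests",
    "run_settlement_stage",
]


class Strategy(str, Enum):
    """Settlement strategy of a bird agent."""

    CUE_PROVIDER = "cue_provider"
    CUE_USER = "cue_user"
    RANDOM_SETTLER = "random_settler"


class PlacementError(RuntimeError):
    """Rejection sampling exhausted its attempt cap: infeasible configuration."""


class ConvergenceError(RuntimeError):
    """A tick-based settlement process did not terminate within the tick cap."""


@dataclass
class Nest:
    """A stationary nest; ``alive`` flips to False on depredation and never back."""

    pos: np.ndarray
    owner: int
    alive: bool = True


@dataclass
class Bird:
    id: int
    strategy: Strategy
    pos: np.ndarray
    heading: float = 0.0
    settled: bool = False
    territory_center: Optional[np.ndarray] = None
    nest: Optional[Nest] = None


@dataclass
class SettlementConfig:
    """Parameters of the settlement stage (distances in cells, 1 cell = 10 m).

    Defaults encode the published community: 80 birds split 8/36/36, a
    10-cell nearest-neighbour spacing, a 10-cell conspecific-cue radius, a
    5-cell territory with nests within 3 cells of its centre, a 20-cell
    exclusion of random-settlers around social clusters, and a 15-cell
    neighbourhood for Bayesian updating.
    """

    side: float = 200.0
    n_cue_providers: int = 8
    n_cue_users: int = 36
    n_random_settlers: int = 36
    min_nn: float = 10.0
    cue_radius: float = 10.0
    territory_radius: float = 5.0
    nest_radius: float = 3.0
    cluster_exclusion: float = 20.0
    bayes_radius: float = 15.0
    k: Optional[int] = None
    prospect_sd: float = 30.0
    bayes_sd: float = 360.0
    max_placement_attempts: int = 100_000
    max_ticks: int = 1_000_000

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError("side must be positive")
        for name in ("cue_radius", "territory_radius", "bayes_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("min_nn", "nest_radius", "cluster_exclusion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("n_cue_providers", "n_cue_users", "n_random_settlers"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1 when Bayesian updating is enabled")


def _reject_sample(n, side, rng, constraint, cap):
    """Draw ``n`` uniform points, each satisfying ``constraint(point, accepted)``.

    ``accepted`` is the (m, 2) array of points accepted so far.  Raises
    :class:`PlacementError` after ``cap`` draws.
    """
    accepted = np.empty((n, 2))
    m = 0
    attempts = 0
    while m < n:
        if attempts >= cap:
            raise PlacementError(
                f"placed {m}/{n} points after {attempts} attempts; "
                "configuration appears infeasible"
            )
        attempts += 1
        p = rng.uniform(0.0, side, size=2)
        if constraint(p, accepted[:m]):
            accepted[m] = p
            m += 1
    return accepted


def place_cue_providers(cfg: SettlementConfig, rng) -> list[Bird]:
    """Place cue-providers uniformly, pairwise at least ``min_nn`` cells apart.

    Providers are settled at creation with territory centre at their position.
    """

    def ok(p, acc):
        return acc.shape[0] == 0 or np.all(
            torus_distance(p, acc, cfg.side) >= cfg.min_nn
        )

    pts = _reject_sample(
        cfg.n_cue_providers, cfg.side, rng, ok, cfg.max_placement_attempts
    )
    return [
        Bird(
            id=i,
            strategy=Strategy.CUE_PROVIDER,
            pos=pts[i].copy(),
            heading=float(rng.uniform(0.0, 360.0)),
            settled=True,
            territory_center=pts[i].copy(),
        )
        for i in range(cfg.n_cue_providers)
    ]


def place_cue_users_initial(
    cfg: SettlementConfig, providers: Sequence[Bird], rng
) -> list[Bird]:
    """Place unsettled cue-users at least ``min_nn`` cells from every provider."""
    ppos = np.array([b.pos for b in providers]).reshape(-1, 2)

    def ok(p, _acc):
        return ppos.shape[0] == 0 or np.all(
            torus_distance(p, ppos, cfg.side) >= cfg.min_nn
        )

    pts = _reject_sample(
        cfg.n_cue_users, cfg.side, rng, ok, cfg.max_placement_attempts
    )
    start = len(providers)
    return [
        Bird(
            id=start + i,
            strategy=Strategy.CUE_USER,
            pos=pts[i].copy(),
            heading=float(rng.uniform(0.0, 360.0)),
            settled=False,
        )
        for i in range(cfg.n_cue_users)
    ]


def prospect(cfg: SettlementConfig, birds: Sequence[Bird], rng) -> Sequence[Bird]:
    """Let unsettled cue-users prospect until all have acquired a social cue.

    Each tick, every still-unsettled cue-user (in freshly shuffled order)
    first checks whether any settled bird lies within ``cue_radius`` cells;
    if so it settles on the spot (and immediately counts as a cue for birds
    later in the same tick's order), otherwise it takes one CRW step with
    turning SD ``prospect_sd``.  Mutates and returns ``birds``.
    """
    settled = [b for b in birds if b.settled]
    users = [b for b in birds if not b.settled]
    if not users:
        return birds
    for u in users:
        if u.strategy != Strategy.CUE_USER:
            raise ValueError("only cue-users may be unsettled when prospecting")
    if not settled:
        raise ValueError("prospecting requires at least one settled bird as a cue")

    side = cfg.side
    settled_pos = np.empty((len(birds), 2))
    for i, b in enumerate(settled):
        settled_pos[i] = b.pos
    n_settled = len(settled)

    pos = np.array([u.pos for u in users], dtype=float)
    head = np.array([u.heading for u in users], dtype=float)
    remaining = list(range(len(users)))

    for _tick in range(cfg.max_ticks):
        order = rng.permutation(len(remaining))
        cur = pos[remaining]
        dmin = pairwise_torus_distance(cur, settled_pos[:n_settled], side).min(axis=1)
        near = dmin <= cfg.cue_radius
        new_this_tick: list[np.ndarray] = []
        still: list[int] = []
        for oi in order:
            ui = remaining[oi]
            found = bool(near[oi])
            if not found:
                for q in new_this_tick:
                    if torus_distance(pos[ui], q, side) <= cfg.cue_radius:
                        found = True
                        break
            if found:
                u = users[ui]
                u.settled = True
                u.pos = pos[ui].copy()
                u.heading = float(head[ui])
                u.territory_center = pos[ui].copy()
                settled_pos[n_settled] = pos[ui]
                n_settled += 1
                new_this_tick.append(pos[ui].copy())
            else:
                still.append(ui)
        if not still:
            return birds
        idx = np.asarray(still)
        pos[idx], head[idx] = crw_step(
            pos[idx], head[idx], cfg.prospect_sd, 1.0, rng, side
        )
        remaining = still
    raise ConvergenceError("prospecting did not converge within the tick cap")


def bayesian_adjust(cfg: SettlementConfig, birds: Sequence[Bird], rng) -> Sequence[Bird]:
    """Let settled social birds revise overcrowded settlement decisions.

    Each tick, every bird (freshly shuffled order) counts the *other* social
    birds within ``bayes_radius`` cells of its current position; while the
    count exceeds ``k`` it takes one CRW step with turning SD ``bayes_sd``
    (a tight convoluted walk) and stops as soon as the count drops to ``k``
    or below.  Updating can re-trigger as neighbours move.  The process
    terminates when a full tick passes with no bird moving; each bird's
    territory centre is then its final position.  Mutates and returns
    ``birds``.
    """
    if cfg.k is None:
        raise ValueError("bayesian_adjust requires cfg.k to be set")
    for b in birds:
        if not b.settled:
            raise ValueError("all birds must be settled before Bayesian updating")
    n = len(birds)
    if n == 0:
        return birds
    pos = np.array([b.pos for b in birds], dtype=float)
    head = np.array([b.heading for b in birds], dtype=float)
    side, r, k = cfg.side, cfg.bayes_radius, cfg.k

    converged = False
    for _tick in range(cfg.max_ticks):
        adj = pairwise_torus_distance(pos, pos, side) <= r
        counts = adj.sum(axis=1) - 1  # exclude self (diagonal is True)
        moved = False
        for i in rng.permutation(n):
            if counts[i] > k:
                pos[i], head[i] = crw_step(pos[i], head[i], cfg.bayes_sd, 1.0, rng, side)
                old = adj[:, i].copy()
                nd = torus_distance(pos[i], pos, side) <= r
                nd[i] = True
                adj[i, :] = nd
                adj[:, i] = nd
                counts += nd.astype(int) - old.astype(int)
                counts[i] = int(nd.sum()) - 1
                moved = True
        if not moved:
            converged = True
            break
    if not converged:
        raise ConvergenceError("Bayesian updating did not converge within the tick cap")
    for i, b in enumerate(birds):
        b.pos = pos[i].copy()
        b.heading = float(head[i])
        b.territory_center = pos[i].copy()
    return birds


def prospect_with_updating(
    cfg: SettlementConfig,
    birds: Sequence[Bird],
    rng,
    count_settled_only: bool = False,
) -> Sequence[Bird]:
    """Stage-1 loop with prospecting and Bayesian updating interleaved.

    Each tick has two sub-steps.  First, still-unsettled cue-users prospect
    exactly as in :func:`prospect`.  Second, every settled social bird (in
    freshly shuffled order) counts the other social birds within
    ``bayes_radius`` of its current position — by default all individuals,
    settled or still prospecting, are counted (``count_settled_only=True``
    restricts the count to settled birds) — and takes one tight convoluted
    CRW step (SD ``bayes_sd``) while the count exceeds ``k``, stopping
    immediately once it does not.  Updating can re-trigger as others arrive
    or move, and wandering birds remain territorial (they still act as
    social cues at their current position).  The stage ends when every
    cue-user is settled and a full tick passes with no bird moving; each
    bird's territory centre is then its final position.

    Mutates and returns ``birds``.
    """
    if cfg.k is None:
        raise ValueError("prospect_with_updating requires cfg.k to be set")
    for b in birds:
        if not b.settled and b.strategy != Strategy.CUE_USER:
            raise ValueError("only cue-users may be unsettled at stage-1 start")
    n = len(birds)
    if n == 0:
        return birds
    pos = np.array([b.pos for b in birds], dtype=float)
    head = np.array([b.heading for b in birds], dtype=float)
    settled = np.array([b.settled for b in birds], dtype=bool)
    if not settled.any() and (~settled).any():
        raise ValueError("prospecting requires at least one settled bird as a cue")
    side, r, k = cfg.side, cfg.bayes_radius, cfg.k

    for _tick in range(cfg.max_ticks):
        # --- prospecting sub-step (sequential with within-tick cues) ---
        unsettled_idx = np.flatnonzero(~settled)
        if unsettled_idx.size:
            settled_idx = np.flatnonzero(settled)
            dmin = pairwise_torus_distance(
                pos[unsettled_idx], pos[settled_idx], side
            ).min(axis=1)
            order = rng.permutation(unsettled_idx.size)
            new_this_tick: list[np.ndarray] = []
            movers: list[int] = []
            for oi in order:
                ui = unsettled_idx[oi]
                found = bool(dmin[oi] <= cfg.cue_radius)
                if not found:
                    for q in new_this_tick:
                        if torus_distance(pos[ui], q, side) <= cfg.cue_radius:
                            found = True
                            break
                if found:
                    settled[ui] = True
                    new_this_tick.append(pos[ui].copy())
                else:
                    movers.append(ui)
            if movers:
                idx = np.asarray(movers)
                pos[idx], head[idx] = crw_step(
                    pos[idx], head[idx], cfg.prospect_sd, 1.0, rng, side
                )
        # --- updating sub-step over settled birds ---
        # neighbour counts are read from an adjacency matrix maintained
        # incrementally as birds move within the pass (sequential semantics:
        # each bird sees the current positions of all others)
        adj = pairwise_torus_distance(pos, pos, side) <= r
        mask = settled.copy() if count_settled_only else np.ones(n, dtype=bool)
        counts = adj[:, mask].sum(axis=1) - 1  # readers are always in mask
        moved = False
        for i in rng.permutation(n):
            if not settled[i]:
                continue
            if counts[i] > k:
                pos[i], head[i] = crw_step(pos[i], head[i], cfg.bayes_sd, 1.0, rng, side)
                old = adj[:, i].copy()
                nd = torus_distance(pos[i], pos, side) <= r
                nd[i] = True
                adj[i, :] = nd
                adj[:, i] = nd
                if mask[i]:
                    counts += nd.astype(int) - old.astype(int)
                counts[i] = int(nd[mask].sum()) - 1
                moved = True
        if settled.all() and not moved and not unsettled_idx.size:
            for i, b in enumerate(birds):
                b.settled = True
                b.pos = pos[i].copy()
                b.heading = float(head[i])
                b.territory_center = pos[i].copy()
            return birds
    raise ConvergenceError("stage-1 settlement with updating did not converge")


def place_random_settlers(
    cfg: SettlementConfig, social_birds: Sequence[Bird], rng
) -> list[Bird]:
    """Place random-settlers away from each other and from social clusters.

    Each settler is at least ``min_nn`` cells from every other random-settler
    and at least ``cluster_exclusion`` cells from every settled social bird
    ("nearest cluster" operationalised as nearest settled social bird).
    """
    for b in social_birds:
        if not b.settled:
            raise ValueError("social birds must be settled before random-settlers")
    spos = np.array([b.pos for b in social_birds]).reshape(-1, 2)

    def ok(p, acc):
        if acc.shape[0] and np.any(torus_distance(p, acc, cfg.side) < cfg.min_nn):
            return False
        if spos.shape[0] and np.any(
            torus_distance(p, spos, cfg.side) < cfg.cluster_exclusion
        ):
            return False
        return True

    pts = _reject_sample(
        cfg.n_random_settlers, cfg.side, rng, ok, cfg.max_placement_attempts
    )
    start = len(social_birds)
    return [
        Bird(
            id=start + i,
            strategy=Strategy.RANDOM_SETTLER,
            pos=pts[i].copy(),
            heading=float(rng.uniform(0.0, 360.0)),
            settled=True,
            territory_center=pts[i].copy(),
        )
        for i in range(cfg.n_random_settlers)
    ]


def sprout_nests(
    birds: Sequence[Bird], nest_radius: float, rng, side: float
) -> list[Nest]:
    """Sprout one nest per settled bird, uniform on the disc around its centre."""
    nests = []
    for b in birds:
        if not b.settled or b.territory_center is None:
            raise ValueError("every bird must be settled before nests sprout")
        radius = nest_radius * math.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * math.pi)
        offset = np.array([radius * math.sin(theta), radius * math.cos(theta)])
        nest = Nest(pos=wrap(b.territory_center + offset, side), owner=b.id)
        b.nest = nest
        nests.append(nest)
    return nests


def run_settlement_stage(
    cfg: SettlementConfig,
    rng,
    bayesian: bool = False,
    updating: str = "sequential",
) -> tuple[list[Bird], list[Nest]]:
    """Run the full settlement stage and return (birds, nests).

    Order of events: cue-providers placed; cue-users placed and prospecting
    to completion; when ``bayesian`` is set, Bayesian updating of settled
    social birds; then random-settlers placed and one nest sprouted per
    bird.  ``updating`` selects how the updating interacts with
    prospecting: ``"sequential"`` (the default) runs :func:`bayesian_adjust`
    once prospecting has finished, ``"concurrent"`` interleaves the two
    within one stage-1 loop (:func:`prospect_with_updating`).
    """
    if updating not in ("sequential", "concurrent"):
        raise ValueError("updating must be 'sequential' or 'concurrent'")
    providers = place_cue_providers(cfg, rng)
    users = place_cue_users_initial(cfg, providers, rng)
    social: list[Bird] = providers + users
    if bayesian and cfg.k is None:
        raise ValueError("bayesian settlement mode requires cfg.k")
    if bayesian and updating == "concurrent":
        prospect_with_updating(cfg, social, rng)
    else:
        if users:
            prospect(cfg, social, rng)
        if bayesian:
            bayesian_adjust(cfg, social, rng)
    randoms = place_random_settlers(cfg, social, rng)
    birds = social + randoms
    nests = sprout_nests(birds, cfg.nest_radius, rng, cfg.side)
    return birds, nests
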