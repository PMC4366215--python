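"""Experiment presets, replicate runners, sweeps, and analysis wrappers.

An experiment is a fully specified stochastic simulation: a bird community
(settlement mode and parameters), a predator community, movement parameters,
a replicate count and a master seed.  :func:`run_replicates` executes the
replicates (settlement per replicate, then the replicate-vectorised
predation engine) and returns a tidy table with one row per replicate and
strategy — the input for the GLM layer in :mod:`warblersim.stats`.

The published experiment suite is reproduced by the preset runners:

* :func:`boar_only` / :func:`fox_only` — 6 predators of one kind, basic
  conspecific attraction, strategy-wise nest success (means model);
* :func:`run_mixed_community` — communities of 6 predators with 0–6 foxes,
  nest success against fox dominance (binomial ANCOVA, pooled refit);
* :func:`run_k_sweep` — Bayesian updating at thresholds k = 2..6 plus a
  naive baseline (effects model);
* :func:`sweep_efficient_predator` / :func:`sweep_predator_density` — the
  staged sensitivity sweeps used to pick the movement parameters and the
  predator count.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .predation import PredatorParams, run_predation_batch
from .settlement import SettlementConfig, Strategy, run_settlement_stage
from .stats import (
    GLMSpec,
    PosteriorSummary,
    contrast,
    fit_ancova,
    fit_effects_model,
    fit_means_model,
    pool_social,
)

__all__ = [
    "ExperimentConfig",
    "run_replicates",
    "boar_only",
    "fox_only",
    "run_mixed_community",
    "run_k_sweep",
    "sweep_predator_param",
    "sweep_efficient_predator",
    "sweep_predator_density",
    "analyze_strategy_means",
    "analyze_mixed_community",
    "analyze_k_sweep",
]

MODES = ("basic", "bayesian", "random_only", "clustered_only")


@dataclass
class ExperimentConfig:
    """One fully specified experiment (replicates of one condition)."""

    name: str
    n_boars: int
    n_foxes: int
    replicates: int = 100
    mode: str = "basic"
    k: Optional[int] = None
    updating: str = "sequential"  # how Bayesian updating interacts with prospecting
    settlement: SettlementConfig = field(default_factory=SettlementConfig)
    predator_params: PredatorParams = field(default_factory=PredatorParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.mode == "bayesian" and (self.k is None or self.k < 1):
            raise ValueError("bayesian mode requires k >= 1")

    def settlement_config(self) -> SettlementConfig:
        """Settlement parameters with counts adjusted for the community mode."""
        cfg = self.settlement
        if self.mode == "random_only":
            total = cfg.n_cue_providers + cfg.n_cue_users + cfg.n_random_settlers
            return dataclasses.replace(
                cfg, n_cue_providers=0, n_cue_users=0, n_random_settlers=total
            )
        if self.mode == "clustered_only":
            users = cfg.n_cue_users + cfg.n_random_settlers
            return dataclasses.replace(cfg, n_cue_users=users, n_random_settlers=0)
        if self.mode == "bayesian":
            return dataclasses.replace(cfg, k=self.k)
        return cfg


def run_replicates(cfg: ExperimentConfig) -> pd.DataFrame:
    """Run all replicates of one experiment and tally nest success.

    Replicate seeds are spawned deterministically from the master seed, so
    identical (config, seed) yields an identical table.  Returns one row per
    (replicate, strategy) with columns: experiment, replicate, seed,
    n_boars, n_foxes, k, mode, strategy, trials, successes.
    """
    scfg = cfg.settlement_config()
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.replicates + 1)
    nest_cells: list[np.ndarray] = []
    owner_strategies: list[np.ndarray] = []
    side = scfg.side
    for i in range(cfg.replicates):
        rng = np.random.default_rng(children[i])
        birds, nests = run_settlement_stage(
            scfg, rng, bayesian=cfg.mode == "bayesian", updating=cfg.updating
        )
        cells = np.floor(np.array([n.pos for n in nests])).astype(int)
        cells %= int(round(side))
        nest_cells.append(cells)
        strat_of = {b.id: b.strategy.value for b in birds}
        owner_strategies.append(np.array([strat_of[n.owner] for n in nests]))

    alive = run_predation_batch(
        nest_cells,
        cfg.n_boars,
        cfg.n_foxes,
        cfg.predator_params,
        np.random.default_rng(children[-1]),
    )

    k_level = cfg.k if cfg.mode == "bayesian" else 0
    rows = []
    order = [s.value for s in Strategy]
    for i in range(cfg.replicates):
        strats = owner_strategies[i]
        for strat in order:
            mask = strats == strat
            if not mask.any():
                continue
            rows.append(
                {
                    "experiment": cfg.name,
                    "replicate": i,
                    "seed": cfg.seed,
                    "n_boars": cfg.n_boars,
                    "n_foxes": cfg.n_foxes,
                    "k": k_level,
                    "mode": cfg.mode,
                    "strategy": strat,
                    "trials": int(mask.sum()),
                    "successes": int(alive[i][mask].sum()),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# presets


def boar_only(seed: int = 0, replicates: int = 100, **overrides) -> ExperimentConfig:
    """6 wild boars, basic conspecific attraction, 8/36/36 birds."""
    return ExperimentConfig(
        name="boar-only", n_boars=6, n_foxes=0, replicates=replicates, seed=seed,
        **overrides,
    )


def fox_only(seed: int = 0, replicates: int = 100, **overrides) -> ExperimentConfig:
    """6 red foxes with area-restricted search, basic conspecific attraction."""
    return ExperimentConfig(
        name="fox-only", n_boars=0, n_foxes=6, replicates=replicates, seed=seed,
        **overrides,
    )


def run_mixed_community(
    seed: int = 0,
    replicates: int = 100,
    total_predators: int = 6,
    boundary_tables: Optional[dict[int, pd.DataFrame]] = None,
    **overrides,
) -> pd.DataFrame:
    """Run the fox-dominance gradient: communities with 0..total foxes.

    The total predator count is held constant, so the number of foxes spans
    landscapes dominated by incidental predators (all boars) to landscapes
    dominated by responsive predators (all foxes).  ``boundary_tables`` may
    supply precomputed tables for given fox counts (the 0- and 6-fox
    communities are exactly the boar-only / fox-only experiments).
    """
    tables = []
    for n_foxes in range(total_predators + 1):
        if boundary_tables and n_foxes in boundary_tables:
            t = boundary_tables[n_foxes].copy()
            t["n_foxes"] = n_foxes
            t["n_boars"] = total_predators - n_foxes
            tables.append(t)
            continue
        cfg = ExperimentConfig(
            name=f"mixed-f{n_foxes}",
            n_boars=total_predators - n_foxes,
            n_foxes=n_foxes,
            replicates=replicates,
            seed=seed + n_foxes,
            **overrides,
        )
        tables.append(run_replicates(cfg))
    return pd.concat(tables, ignore_index=True)


def run_k_sweep(
    kind: str,
    seed: int = 0,
    replicates: int = 100,
    ks: Iterable[int] = range(2, 7),
    naive_table: Optional[pd.DataFrame] = None,
    total_predators: int = 6,
    **overrides,
) -> pd.DataFrame:
    """Run Bayesian-updating experiments over thresholds k plus a naive baseline.

    ``kind`` selects a pure predator community ('boar' or 'fox').  The naive
    baseline (k = 0) is a separate basic-attraction experiment with the same
    predator community unless a precomputed table is supplied.
    """
    if kind not in ("boar", "fox"):
        raise ValueError("kind must be 'boar' or 'fox'")
    n_boars = total_predators if kind == "boar" else 0
    n_foxes = total_predators if kind == "fox" else 0
    tables = []
    if naive_table is None:
        cfg = ExperimentConfig(
            name=f"k-sweep-{kind}-naive",
            n_boars=n_boars,
            n_foxes=n_foxes,
            replicates=replicates,
            seed=seed,
            **overrides,
        )
        tables.append(run_replicates(cfg))
    else:
        tables.append(naive_table)
    for k in ks:
        cfg = ExperimentConfig(
            name=f"k-sweep-{kind}-k{k}",
            n_boars=n_boars,
            n_foxes=n_foxes,
            replicates=replicates,
            mode="bayesian",
            k=int(k),
            seed=seed + 1000 + int(k),
            **overrides,
        )
        tables.append(run_replicates(cfg))
    return pd.concat(tables, ignore_index=True)


# ---------------------------------------------------------------------------
# sensitivity sweeps


def _mean_survival(table: pd.DataFrame) -> float:
    return float(table["successes"].sum() / table["trials"].sum())


def sweep_predator_param(
    param: str,
    values: Sequence[float],
    nest_mode: str,
    predator_kind: str,
    replicates: int = 50,
    seed: int = 0,
    base_params: Optional[PredatorParams] = None,
    total_predators: int = 6,
    settlement: Optional[SettlementConfig] = None,
) -> pd.DataFrame:
    """Mean nest survival over a grid of one movement parameter.

    ``nest_mode`` is 'random_only' (80 random-settlers) or 'clustered_only'
    (8 cue-providers + 72 cue-users); ``predator_kind`` selects a pure
    community of boars or foxes.
    """
    if nest_mode not in ("random_only", "clustered_only"):
        raise ValueError("nest_mode must be 'random_only' or 'clustered_only'")
    base = base_params or PredatorParams()
    rows = []
    for i, v in enumerate(values):
        params = dataclasses.replace(
            base, **{param: int(v) if param == "duration_ars" else float(v)}
        )
        cfg = ExperimentConfig(
            name=f"sweep-{param}-{v}-{predator_kind}-{nest_mode}",
            n_boars=total_predators if predator_kind == "boar" else 0,
            n_foxes=total_predators if predator_kind == "fox" else 0,
            replicates=replicates,
            mode=nest_mode,
            predator_params=params,
            settlement=settlement or SettlementConfig(),
            seed=seed + i,
        )
        table = run_replicates(cfg)
        rows.append(
            {
                "param": param,
                "value": v,
                "predator_kind": predator_kind,
                "nest_mode": nest_mode,
                "replicates": replicates,
                "mean_survival": _mean_survival(table),
            }
        )
    return pd.DataFrame(rows)


def sweep_efficient_predator(
    replicates: int = 50,
    seed: int = 0,
    turning_grid: Sequence[float] = (10, 20, 30, 45, 60, 90),
    strength_grid: Sequence[float] = (10, 25, 40, 55, 70, 85),
    duration_grid: Sequence[int] = (0, 25, 50, 75, 100, 125, 150, 200),
) -> pd.DataFrame:
    """The staged movement-parameter sweeps behind the efficient predator setup.

    Stage 1 varies the turning SD of each predator kind; stage 2 varies the
    ARS turning strength at turning 10 deg and duration 125 ticks; stage 3
    varies the ARS duration at turning 10 deg and strength 55 deg.  Each
    stage is run for both random and clustered nest distributions.
    """
    frames = []
    for nest_mode in ("random_only", "clustered_only"):
        for kind in ("boar", "fox"):
            frames.append(
                sweep_predator_param(
                    "turning_boar" if kind == "boar" else "turning_fox",
                    turning_grid, nest_mode, kind, replicates, seed,
                )
            )
        frames.append(
            sweep_predator_param(
                "strength_ars", strength_grid, nest_mode, "fox", replicates,
                seed + 100,
                base_params=PredatorParams(turning_fox=10.0, duration_ars=125),
            )
        )
        frames.append(
            sweep_predator_param(
                "duration_ars", duration_grid, nest_mode, "fox", replicates,
                seed + 200,
                base_params=PredatorParams(turning_fox=10.0, strength_ars=55.0),
            )
        )
    return pd.concat(frames, ignore_index=True)


def sweep_predator_density(
    counts: Sequence[int] = tuple(range(1, 9)),
    replicates: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean nest survival against predator count, per kind and nest mode."""
    rows = []
    for nest_mode in ("random_only", "clustered_only"):
        for kind in ("boar", "fox"):
            for i, c in enumerate(counts):
                cfg = ExperimentConfig(
                    name=f"density-{kind}-{c}-{nest_mode}",
                    n_boars=c if kind == "boar" else 0,
                    n_foxes=c if kind == "fox" else 0,
                    replicates=replicates,
                    mode=nest_mode,
                    seed=seed + i,
                )
                table = run_replicates(cfg)
                rows.append(
                    {
                        "predator_kind": kind,
                        "count": c,
                        "nest_mode": nest_mode,
                        "replicates": replicates,
                        "mean_survival": _mean_survival(table),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# analysis wrappers


def analyze_strategy_means(
    table: pd.DataFrame, spec: Optional[GLMSpec] = None, rng=None
) -> dict:
    """Means-model fit plus all pairwise probability-scale strategy contrasts."""
    fit = fit_means_model(table, spec, rng)
    levels = [
        name[len("p[") : -1] for name in fit.draws if name.startswith("p[")
    ]
    contrasts = {}
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            contrasts[f"{a} - {b}"] = contrast(fit.flat(f"p[{a}]"), fit.flat(f"p[{b}]"))
    return {"fit": fit, "contrasts": contrasts}


def analyze_mixed_community(
    table: pd.DataFrame, spec: Optional[GLMSpec] = None, rng=None
) -> dict:
    """ANCOVA by strategy, then the pooled social-vs-random refit.

    Returns the unpooled and pooled fits plus the pooled slope contrast
    (social minus random, logit per additional fox).
    """
    rng = rng if rng is not None else np.random.default_rng()
    unpooled = fit_ancova(table, spec, rng)
    pooled = fit_ancova(pool_social(table), spec, rng)
    slope = contrast(
        pooled.flat("beta[social]"), pooled.flat("beta[random_settler]")
    )
    return {"unpooled": unpooled, "pooled": pooled, "slope_contrast": slope}


def analyze_k_sweep(
    table: pd.DataFrame, spec: Optional[GLMSpec] = None, rng=None
) -> dict:
    """Two-way effects fit on social birds, then the k-only refit.

    Only cue-providers and cue-users enter (random-settlers do not take part
    in Bayesian updating).  ``gamma[k=..]`` in the refit is the logit-scale
    fitness gain of updating at threshold k over the naive baseline.
    """
    rng = rng if rng is not None else np.random.default_rng()
    social = table[
        table["strategy"].isin(["cue_provider", "cue_user"])
    ].reset_index(drop=True)
    two_way = fit_effects_model(social, spec, rng, include_strategy=True)
    k_only = fit_effects_model(social, spec, rng, include_strategy=False)
    gammas = {
        name: {
            "mean": k_only.mean(name),
            "ci": k_only.ci(name),
        }
        for name in k_only.draws
        if name.startswith("gamma")
    }
    return {"two_way": two_way, "k_only": k_only, "gammas": gammas}
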