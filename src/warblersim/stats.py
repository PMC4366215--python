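"""Bayesian binomial GLMs over replicate nest-success tables.

Three logit-link binomial models cover the analyses of the simulation
experiments:

* **means model** — ``logit(p_i) = alpha_j(i)``: one logit-scale success
  parameter per settlement strategy (means parameterisation);
* **ancova model** — ``logit(p_i) = alpha_j(i) + beta_j(i) * Nfoxes_i``:
  per-strategy intercepts and slopes against the number of foxes in the
  predator community (binomial ANCOVA);
* **effects model** — ``logit(p_i) = alpha + beta_j(i) + gamma_k(i)``:
  overall mean plus strategy and updating-threshold contrasts, with the
  first level of each factor fixed at zero (effects parameterisation; the
  reference threshold level k = 0 is the naive, non-updating strategy, so
  ``gamma_k`` is the fitness gain of Bayesian updating at threshold k).

All parameters get vague normal priors on the logit scale (SD 100 by
default).  Posteriors are sampled with a component-wise adaptive
random-walk Metropolis algorithm: 3 chains of 10 000 iterations, the first
4 000 discarded as burn-in and every 10th of the remainder stored (600
draws per chain, 1800 total), with a split-chain Gelman-Rubin check
(R-hat < 1.1).  Binomial rows are aggregated by design cell before
sampling, which leaves the likelihood unchanged.

Differences between parameters are assessed by posterior contrasts
(:func:`contrast`); a difference is called significant when its central
95% credible interval excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "GLMSpec",
    "PosteriorSummary",
    "ContrastSummary",
    "fit_means_model",
    "fit_ancova",
    "fit_effects_model",
    "contrast",
    "split_rhat",
    "pool_social",
]


@dataclass
class GLMSpec:
    """Sampler settings: priors, chain layout, and bookkeeping."""

    prior_sd: float = 100.0
    chains: int = 3
    iterations: int = 10_000
    burn_in: int = 4_000
    thin: int = 10
    init_jitter: float = 0.25
    rhat_threshold: float = 1.1

    @property
    def draws_per_chain(self) -> int:
        return (self.iterations - self.burn_in + self.thin - 1) // self.thin


@dataclass
class ContrastSummary:
    """Posterior summary of a difference ``a - b``."""

    mean: float
    se: float
    q2_5: float
    q97_5: float

    @property
    def excludes_zero(self) -> bool:
        return self.q2_5 > 0.0 or self.q97_5 < 0.0


class PosteriorSummary:
    """Named posterior draws with per-parameter summaries and R-hat.

    ``draws[name]`` has shape (chains, draws_per_chain); :meth:`flat` gives
    the pooled vector.  Probability-scale parameters (inverse-logit applied
    draw by draw) are stored alongside logit-scale ones where meaningful.
    """

    def __init__(
        self,
        draws: dict[str, np.ndarray],
        scales: dict[str, str],
        rhat: dict[str, float],
        model: str,
    ):
        self.draws = draws
        self.scales = scales
        self.rhat = rhat
        self.model = model

    def flat(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def mean(self, name: str) -> float:
        return float(self.flat(name).mean())

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        lo = (1.0 - level) / 2.0
        q = np.quantile(self.flat(name), [lo, 1.0 - lo])
        return float(q[0]), float(q[1])

    def table(self) -> pd.DataFrame:
        """Tidy summary: parameter, mean, se, q2.5, q97.5, scale, rhat."""
        rows = []
        for name, d in self.draws.items():
            x = d.reshape(-1)
            q = np.quantile(x, [0.025, 0.975])
            rows.append(
                {
                    "parameter": name,
                    "mean": float(x.mean()),
                    "se": float(x.std(ddof=1)),
                    "q2.5": float(q[0]),
                    "q97.5": float(q[1]),
                    "scale": self.scales.get(name, "logit"),
                    "rhat": self.rhat.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows)


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain Gelman-Rubin statistic for draws of shape (chains, n)."""
    c, n = chains.shape
    half = n // 2
    if half < 2:
        return np.nan
    parts = chains[:, : 2 * half].reshape(c * 2, half)
    within = parts.var(axis=1, ddof=1).mean()
    between = half * parts.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0 if between == 0 else np.inf
    var_plus = (half - 1) / half * within + between / half
    return float(np.sqrt(var_plus / within))


def contrast(draws_a, draws_b) -> ContrastSummary:
    """Posterior summary of the cross difference ``a - b``."""
    a = np.asarray(draws_a, dtype=float).reshape(-1)
    b = np.asarray(draws_b, dtype=float).reshape(-1)
    if a.shape != b.shape:
        raise ValueError("contrast requires equal-length draw vectors")
    d = a - b
    q = np.quantile(d, [0.025, 0.975])
    return ContrastSummary(
        mean=float(d.mean()),
        se=float(d.std(ddof=1)),
        q2_5=float(q[0]),
        q97_5=float(q[1]),
    )


def pool_social(data: pd.DataFrame) -> pd.DataFrame:
    """Relabel cue-providers and cue-users as one pooled 'social' group."""
    mapping = {
        "cue_provider": "social",
        "cue_user": "social",
        "random_settler": "random_settler",
    }
    out = data.copy()
    out["strategy"] = out["strategy"].map(lambda s: mapping.get(str(s), str(s)))
    return out


# ---------------------------------------------------------------------------
# sampler core


def _sample(
    loglik: Callable[[np.ndarray], np.ndarray],
    n_params: int,
    init: np.ndarray,
    spec: GLMSpec,
    rng,
) -> np.ndarray:
    """Component-wise adaptive random-walk Metropolis, chains vectorised.

    ``loglik`` maps a (chains, n_params) parameter block to per-chain log
    likelihoods.  Proposal scales adapt toward ~44% acceptance in batches of
    50 iterations during burn-in only, so the post-burn-in kernel is a fixed
    valid Metropolis kernel.  Returns draws of shape
    (chains, draws_per_chain, n_params).
    """
    c = spec.chains
    theta = init.astype(float).copy()
    prior_var = spec.prior_sd**2

    def logpost(th):
        return loglik(th) - 0.5 * np.sum(th * th, axis=1) / prior_var

    lp = logpost(theta)
    scale = np.full((c, n_params), 0.2)
    accepted = np.zeros((c, n_params))
    batch = 50
    kept = np.empty((c, spec.draws_per_chain, n_params))
    n_kept = 0
    for it in range(spec.iterations):
        for j in range(n_params):
            prop = theta.copy()
            prop[:, j] += scale[:, j] * rng.standard_normal(c)
            lp_prop = logpost(prop)
            take = np.log(rng.uniform(size=c)) < (lp_prop - lp)
            theta[take, j] = prop[take, j]
            lp[take] = lp_prop[take]
            accepted[:, j] += take
        if it < spec.burn_in and (it + 1) % batch == 0:
            rate = accepted / batch
            scale *= np.exp(np.clip(rate - 0.44, -0.5, 0.5))
            accepted[:] = 0.0
        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            kept[:, n_kept, :] = theta
            n_kept += 1
    return kept[:, :n_kept, :]


def _validate(data: pd.DataFrame, required: Sequence[str]) -> pd.DataFrame:
    for col in required:
        if col not in data.columns:
            raise ValueError(f"data is missing required column '{col}'")
    s = data["successes"].to_numpy()
    n = data["trials"].to_numpy()
    if np.any(n <= 0):
        raise ValueError("all trial counts must be positive")
    if np.any((s < 0) | (s > n)):
        raise ValueError("successes must satisfy 0 <= s <= N")
    return data


def _aggregate(data: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    agg = (
        data.groupby(keys, sort=False, observed=True)[["successes", "trials"]]
        .sum()
        .reset_index()
    )
    degenerate = (agg["successes"] == 0) | (agg["successes"] == agg["trials"])
    if degenerate.any():
        warnings.warn(
            "all-success or all-failure design cells present; the posterior "
            "there is dominated by the prior tails",
            stacklevel=3,
        )
    return agg


def _binom_loglik(eta: np.ndarray, s: np.ndarray, n: np.ndarray) -> np.ndarray:
    # sum_i [ s_i * eta_i - N_i * log(1 + exp(eta_i)) ], stable via logaddexp
    return np.sum(s * eta - n * np.logaddexp(0.0, eta), axis=-1)


def _initial_logit(s: float, n: float) -> float:
    return float(np.log((s + 0.5) / (n - s + 0.5)))


def _finish(
    raw: np.ndarray,
    names: list[str],
    scales: dict[str, str],
    extra: dict[str, np.ndarray],
    spec: GLMSpec,
    model: str,
) -> PosteriorSummary:
    draws = {name: raw[:, :, j] for j, name in enumerate(names)}
    draws.update(extra)
    rhat = {name: split_rhat(d) for name, d in draws.items()}
    bad = {k: v for k, v in rhat.items() if np.isfinite(v) and v > spec.rhat_threshold}
    if bad:
        warnings.warn(
            f"MCMC convergence check failed (R-hat > {spec.rhat_threshold}): {bad}",
            stacklevel=3,
        )
    return PosteriorSummary(draws=draws, scales=scales, rhat=rhat, model=model)


def _levels(values: pd.Series) -> list:
    """Factor levels in a deterministic, canonical order."""
    vals = list(pd.unique(values))
    canonical = ["cue_provider", "cue_user", "random_settler", "social"]
    key = {v: i for i, v in enumerate(canonical)}
    if all(str(v) in key for v in vals):
        return sorted(vals, key=lambda v: key[str(v)])
    return vals


# ---------------------------------------------------------------------------
# model fits


def fit_means_model(
    data: pd.DataFrame, spec: Optional[GLMSpec] = None, rng=None
) -> PosteriorSummary:
    """Fit ``logit(p) = alpha_strategy`` to per-replicate success counts.

    ``data`` needs columns ``successes``, ``trials``, ``strategy``.  Reports
    ``alpha[level]`` on the logit scale and ``p[level]`` on the probability
    scale (inverse-logit applied to each draw before summarising).
    """
    spec = spec or GLMSpec()
    rng = rng if rng is not None else np.random.default_rng()
    data = _validate(data, ["successes", "trials", "strategy"])
    agg = _aggregate(data, ["strategy"])
    levels = _levels(agg["strategy"])
    idx = agg["strategy"].map({lv: i for i, lv in enumerate(levels)}).to_numpy()
    s = agg["successes"].to_numpy(dtype=float)
    n = agg["trials"].to_numpy(dtype=float)
    k = len(levels)

    def loglik(theta):
        return _binom_loglik(theta[:, idx], s, n)

    init0 = np.array([_initial_logit(s[idx == i].sum(), n[idx == i].sum()) for i in range(k)])
    init = init0 + spec.init_jitter * rng.standard_normal((spec.chains, k))
    raw = _sample(loglik, k, init, spec, rng)
    names = [f"alpha[{lv}]" for lv in levels]
    scales = {name: "logit" for name in names}
    extra = {}
    for j, lv in enumerate(levels):
        extra[f"p[{lv}]"] = expit(raw[:, :, j])
        scales[f"p[{lv}]"] = "probability"
    return _finish(raw, names, scales, extra, spec, "means")


def fit_ancova(
    data: pd.DataFrame, spec: Optional[GLMSpec] = None, rng=None
) -> PosteriorSummary:
    """Fit ``logit(p) = alpha_strategy + beta_strategy * n_foxes``.

    ``data`` needs columns ``successes``, ``trials``, ``strategy`` and
    ``n_foxes``.  To reproduce the pooled refit, relabel strategies first
    (:func:`pool_social`).  Reports per-strategy intercepts ``alpha[level]``
    and slopes ``beta[level]`` (logit per additional fox), plus the
    intercept success probability ``p0[level]``.
    """
    spec = spec or GLMSpec()
    rng = rng if rng is not None else np.random.default_rng()
    data = _validate(data, ["successes", "trials", "strategy", "n_foxes"])
    if data["n_foxes"].nunique() < 2:
        raise ValueError("slope is unidentifiable with a single n_foxes value")
    agg = _aggregate(data, ["strategy", "n_foxes"])
    levels = _levels(agg["strategy"])
    idx = agg["strategy"].map({lv: i for i, lv in enumerate(levels)}).to_numpy()
    x = agg["n_foxes"].to_numpy(dtype=float)
    s = agg["successes"].to_numpy(dtype=float)
    n = agg["trials"].to_numpy(dtype=float)
    k = len(levels)

    def loglik(theta):
        eta = theta[:, idx] + theta[:, k + idx] * x
        return _binom_loglik(eta, s, n)

    init0 = np.concatenate(
        [
            [_initial_logit(s[idx == i].sum(), n[idx == i].sum()) for i in range(k)],
            np.zeros(k),
        ]
    )
    init = init0 + spec.init_jitter * rng.standard_normal((spec.chains, 2 * k))
    raw = _sample(loglik, 2 * k, init, spec, rng)
    names = [f"alpha[{lv}]" for lv in levels] + [f"beta[{lv}]" for lv in levels]
    scales = {name: "logit" for name in names}
    extra = {}
    for j, lv in enumerate(levels):
        extra[f"p0[{lv}]"] = expit(raw[:, :, j])
        scales[f"p0[{lv}]"] = "probability"
    return _finish(raw, names, scales, extra, spec, "ancova")


def fit_effects_model(
    data: pd.DataFrame,
    spec: Optional[GLMSpec] = None,
    rng=None,
    include_strategy: bool = True,
) -> PosteriorSummary:
    """Fit ``logit(p) = alpha + beta_strategy + gamma_k`` (effects coding).

    ``data`` needs columns ``successes``, ``trials``, ``strategy`` and ``k``
    (updating threshold; level 0 = naive is the required reference).  The
    first strategy level (cue-providers, when present) and the k = 0 level
    are fixed at zero, so ``gamma[k]`` is the logit-scale fitness gain of
    Bayesian updating at threshold k relative to naive birds.  With
    ``include_strategy=False`` the strategy term is dropped (the single-
    predictor refit used once strategies prove indistinguishable).
    """
    spec = spec or GLMSpec()
    rng = rng if rng is not None else np.random.default_rng()
    data = _validate(data, ["successes", "trials", "strategy", "k"])
    keys = ["strategy", "k"] if include_strategy else ["k"]
    agg = _aggregate(data, keys)
    k_levels = sorted(pd.unique(agg["k"]))
    if 0 not in k_levels:
        raise ValueError("effects model requires the naive reference level k=0")
    k_idx = agg["k"].map({kv: i for i, kv in enumerate(k_levels)}).to_numpy()
    s = agg["successes"].to_numpy(dtype=float)
    n = agg["trials"].to_numpy(dtype=float)
    n_gamma = len(k_levels) - 1

    if include_strategy:
        strat_levels = _levels(agg["strategy"])
        s_idx = agg["strategy"].map(
            {lv: i for i, lv in enumerate(strat_levels)}
        ).to_numpy()
        n_beta = len(strat_levels) - 1
    else:
        strat_levels = []
        s_idx = np.zeros(len(agg), dtype=int)
        n_beta = 0

    n_params = 1 + n_beta + n_gamma

    def loglik(theta):
        c = theta.shape[0]
        beta = np.concatenate([np.zeros((c, 1)), theta[:, 1 : 1 + n_beta]], axis=1)
        gamma = np.concatenate([np.zeros((c, 1)), theta[:, 1 + n_beta :]], axis=1)
        eta = theta[:, [0]] + beta[:, s_idx] + gamma[:, k_idx]
        return _binom_loglik(eta, s, n)

    init0 = np.zeros(n_params)
    init0[0] = _initial_logit(s.sum(), n.sum())
    init = init0 + spec.init_jitter * rng.standard_normal((spec.chains, n_params))
    raw = _sample(loglik, n_params, init, spec, rng)
    names = ["alpha"]
    names += [f"beta[{lv}]" for lv in strat_levels[1:]]
    names += [f"gamma[k={kv}]" for kv in k_levels[1:]]
    scales = {name: "logit" for name in names}
    return _finish(raw, names, scales, {}, spec, "effects")
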