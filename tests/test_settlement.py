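"""Settlement stage: placements, prospecting, Bayesian updating, nests."""

import dataclasses

import numpy as np
import pytest

from warblersim.settlement import (
    Bird,
    ConvergenceError,
    PlacementError,
    SettlementConfig,
    Strategy,
    bayesian_adjust,
    place_cue_providers,
    place_cue_users_initial,
    place_random_settlers,
    prospect,
    prospect_with_updating,
    run_settlement_stage,
    sprout_nests,
)
from warblersim.space import pairwise_torus_distance, torus_distance

L = 200.0


def _pairwise_min(points):
    d = pairwise_torus_distance(points, points, L)
    np.fill_diagonal(d, np.inf)
    return d.min()


def _positions(birds):
    return np.array([b.pos for b in birds]).reshape(-1, 2)


class TestPlacements:
    def test_cue_providers_spacing(self, rng):
        birds = place_cue_providers(SettlementConfig(), rng)
        assert len(birds) == 8
        assert all(b.settled for b in birds)
        assert all(b.strategy is Strategy.CUE_PROVIDER for b in birds)
        assert _pairwise_min(_positions(birds)) >= 10.0

    @pytest.mark.parametrize("n", [0, 1])
    def test_cue_providers_small_counts(self, rng, n):
        birds = place_cue_providers(
            dataclasses.replace(SettlementConfig(), n_cue_providers=n), rng
        )
        assert len(birds) == n

    def test_infeasible_placement_raises(self, rng):
        cfg = dataclasses.replace(
            SettlementConfig(),
            n_cue_providers=50,
            min_nn=60.0,
            max_placement_attempts=5000,
        )
        with pytest.raises(PlacementError):
            place_cue_providers(cfg, rng)

    def test_cue_users_away_from_providers(self, rng):
        cfg = SettlementConfig()
        providers = place_cue_providers(cfg, rng)
        users = place_cue_users_initial(cfg, providers, rng)
        assert len(users) == 36
        assert not any(u.settled for u in users)
        d = pairwise_torus_distance(_positions(users), _positions(providers), L)
        assert d.min() >= 10.0

    def test_cue_users_unconstrained_cases(self, rng):
        cfg = SettlementConfig()
        assert len(place_cue_users_initial(cfg, [], rng)) == 36
        cfg0 = dataclasses.replace(cfg, min_nn=0.0)
        providers = place_cue_providers(cfg0, rng)
        assert len(place_cue_users_initial(cfg0, providers, rng)) == 36

    def test_random_settlers_constraints(self, rng):
        cfg = SettlementConfig()
        social = place_cue_providers(cfg, rng)
        settlers = place_random_settlers(cfg, social, rng)
        assert len(settlers) == 36
        pts = _positions(settlers)
        assert _pairwise_min(pts) >= 10.0
        assert pairwise_torus_distance(pts, _positions(social), L).min() >= 20.0

    def test_random_settlers_without_social_birds(self, rng):
        settlers = place_random_settlers(SettlementConfig(), [], rng)
        assert _pairwise_min(_positions(settlers)) >= 10.0

    def test_random_settlers_infeasible_exclusion(self, rng):
        cfg = dataclasses.replace(
            SettlementConfig(),
            cluster_exclusion=150.0,  # > L/sqrt(2): no admissible point remains
            max_placement_attempts=5000,
        )
        social = place_cue_providers(cfg, rng)
        with pytest.raises(PlacementError):
            place_random_settlers(cfg, social, rng)


def _bird(i, strategy, pos, heading=0.0, settled=False):
    b = Bird(id=i, strategy=strategy, pos=np.array(pos, dtype=float), heading=heading)
    b.settled = settled
    if settled:
        b.territory_center = b.pos.copy()
    return b


class TestProspect:
    def test_straight_approach_settles_on_entering_cue_radius(self, rng):
        """A user 10.5 cells away heading straight at a provider settles
        right after its first step takes it inside the 10-cell radius."""
        cfg = dataclasses.replace(SettlementConfig(), prospect_sd=0.0)
        provider = _bird(0, Strategy.CUE_PROVIDER, (100.0, 110.5), settled=True)
        user = _bird(1, Strategy.CUE_USER, (100.0, 100.0), heading=0.0)
        prospect(cfg, [provider, user], rng)
        assert user.settled
        assert np.allclose(user.pos, [100.0, 101.0])
        assert torus_distance(user.pos, provider.pos, L) <= 10.0

    def test_unbounded_cue_radius_settles_everyone_in_place(self, rng):
        cfg = dataclasses.replace(SettlementConfig(), cue_radius=1.5 * L)
        providers = place_cue_providers(cfg, rng)
        users = place_cue_users_initial(cfg, providers, rng)
        initial = _positions(users)
        prospect(cfg, providers + users, rng)
        assert all(u.settled for u in users)
        assert np.allclose(_positions(users), initial)

    def test_every_settled_user_has_a_cue_within_radius(self, rng):
        cfg = SettlementConfig()
        providers = place_cue_providers(cfg, rng)
        users = place_cue_users_initial(cfg, providers, rng)
        birds = providers + users
        prospect(cfg, birds, rng)
        pos = _positions(birds)
        d = pairwise_torus_distance(pos, pos, L)
        np.fill_diagonal(d, np.inf)
        # cue-providers never move during basic attraction, so the cue that
        # triggered each settlement is still within the radius at the end
        assert (d[len(providers):].min(axis=1) <= cfg.cue_radius).all()

    def test_prospect_requires_a_cue_source(self, rng):
        users = [_bird(0, Strategy.CUE_USER, (5.0, 5.0))]
        with pytest.raises(ValueError):
            prospect(SettlementConfig(), users, rng)

    def test_social_birds_cluster_tighter_than_random_settlers(self, rng):
        """Conspecific attraction aggregates: mean nearest-neighbour
        distance among social birds is below that of random-settlers."""
        social_nn, random_nn = [], []
        for _ in range(30):
            birds, _ = run_settlement_stage(SettlementConfig(), rng)
            pos = _positions(birds)
            social = np.array([b.strategy is not Strategy.RANDOM_SETTLER for b in birds])
            d = pairwise_torus_distance(pos, pos, L)
            np.fill_diagonal(d, np.inf)
            social_nn.append(d[social][:, social].min(axis=1).mean())
            random_nn.append(d[~social][:, ~social].min(axis=1).mean())
        assert np.mean(social_nn) < np.mean(random_nn) - 1.0


class TestBayesianUpdating:
    def test_high_threshold_is_a_no_op(self, rng):
        cfg = dataclasses.replace(SettlementConfig(), k=7)  # n - 1 birds
        birds = [
            _bird(i, Strategy.CUE_PROVIDER, p, settled=True)
            for i, p in enumerate(rng.uniform(0, L, size=(8, 2)))
        ]
        before = _positions(birds)
        bayesian_adjust(cfg, birds, rng)
        assert np.allclose(_positions(birds), before)

    def test_stacked_birds_disperse_to_threshold(self, rng):
        cfg = dataclasses.replace(SettlementConfig(), k=2)
        birds = [
            _bird(i, Strategy.CUE_USER, (100.0, 100.0), settled=True)
            for i in range(5)
        ]
        bayesian_adjust(cfg, birds, rng)
        pos = _positions(birds)
        d = pairwise_torus_distance(pos, pos, L)
        counts = (d <= cfg.bayes_radius).sum(axis=1) - 1
        assert (counts <= 2).all()
        assert all(np.allclose(b.territory_center, b.pos) for b in birds)

    def test_requires_threshold_and_settled_birds(self, rng):
        birds = [_bird(0, Strategy.CUE_PROVIDER, (1.0, 1.0), settled=True)]
        with pytest.raises(ValueError):
            bayesian_adjust(SettlementConfig(), birds, rng)  # k unset
        cfg = dataclasses.replace(SettlementConfig(), k=2)
        with pytest.raises(ValueError):
            bayesian_adjust(cfg, [_bird(0, Strategy.CUE_USER, (1.0, 1.0))], rng)

    @pytest.mark.parametrize("updating", ["sequential", "concurrent"])
    def test_updating_reduces_peak_crowding(self, rng, updating):
        """With k=2 the adjusted community never exceeds 2 neighbours
        within the updating radius, while naive settlement routinely does."""
        cfg = SettlementConfig()
        cfg_k = dataclasses.replace(cfg, k=2)
        naive_max, adjusted_max = [], []
        for _ in range(15):
            birds, _ = run_settlement_stage(cfg, rng)
            naive_max.append(_max_crowding(birds, cfg))
            birds, _ = run_settlement_stage(
                cfg_k, rng, bayesian=True, updating=updating
            )
            adjusted_max.append(_max_crowding(birds, cfg))
        assert max(adjusted_max) <= 2
        assert np.mean(naive_max) > np.mean(adjusted_max)

    def test_concurrent_loop_settles_and_respects_threshold(self, rng):
        cfg = dataclasses.replace(SettlementConfig(), k=3)
        providers = place_cue_providers(cfg, rng)
        users = place_cue_users_initial(cfg, providers, rng)
        birds = providers + users
        prospect_with_updating(cfg, birds, rng)
        assert all(b.settled for b in birds)
        assert _max_crowding(birds, cfg) <= 3


def _max_crowding(birds, cfg):
    social = [b for b in birds if b.strategy is not Strategy.RANDOM_SETTLER]
    pos = _positions(social)
    d = pairwise_torus_distance(pos, pos, L)
    counts = (d <= cfg.bayes_radius).sum(axis=1) - 1
    return int(counts.max())


class TestNests:
    def test_sprout_within_radius_and_linked(self, rng):
        birds, nests = run_settlement_stage(SettlementConfig(), rng)
        assert len(nests) == 80
        by_id = {b.id: b for b in birds}
        for nest in nests:
            owner = by_id[nest.owner]
            assert owner.nest is nest
            assert nest.alive
            assert torus_distance(nest.pos, owner.territory_center, L) <= 3.0

    def test_zero_radius_puts_nest_at_centre(self, rng):
        b = _bird(0, Strategy.CUE_PROVIDER, (40.0, 40.0), settled=True)
        (nest,) = sprout_nests([b], 0.0, rng, L)
        assert np.allclose(nest.pos, b.pos)

    def test_mean_nest_distance_matches_uniform_disc(self, rng):
        """Uniform on a disc of radius R has mean radius 2R/3 (= 2 cells)."""
        birds = [
            _bird(i, Strategy.CUE_PROVIDER, (100.0, 100.0), settled=True)
            for i in range(10_000)
        ]
        nests = sprout_nests(birds, 3.0, rng, L)
        dist = np.array(
            [torus_distance(n.pos, np.array([100.0, 100.0]), L) for n in nests]
        )
        assert dist.max() <= 3.0
        assert dist.mean() == pytest.approx(2.0, abs=0.05)

    def test_unsettled_bird_rejected(self, rng):
        with pytest.raises(ValueError):
            sprout_nests([_bird(0, Strategy.CUE_USER, (1.0, 1.0))], 3.0, rng, L)


def test_stage_is_deterministic_under_a_fixed_seed():
    cfg = SettlementConfig()
    runs = []
    for _ in range(2):
        birds, nests = run_settlement_stage(cfg, np.random.default_rng(123))
        runs.append(
            (
                np.array([b.pos for b in birds]),
                np.array([n.pos for n in nests]),
            )
        )
    assert np.array_equal(runs[0][0], runs[1][0])
    assert np.array_equal(runs[0][1], runs[1][1])


def test_tick_cap_raises_convergence_error(rng):
    cfg = dataclasses.replace(SettlementConfig(), max_ticks=3)
    providers = [_bird(0, Strategy.CUE_PROVIDER, (0.0, 0.0), settled=True)]
    users = [_bird(1, Strategy.CUE_USER, (100.0, 100.0))]
    with pytest.raises(ConvergenceError):
        prospect(cfg, providers + users, rng)
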