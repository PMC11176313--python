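"""NSGA-II primitives, variation operators, and the evolution loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wirevo as wv
from wirevo.evolution import (
    EvolutionConfig,
    _random_block_values,
    _tile_blend,
    expected_pattern_count,
    select_survivors,
    rank_population,
    EvaluatedPattern,
)


def brute_force_fronts(points):
    """Independent O(n^2) dominance ranking."""
    pts = [np.asarray(p) for p in points]
    n = len(pts)
    remaining = set(range(n))
    fronts = []
    while remaining:
        front = [
            i
            for i in remaining
            if not any(
                j != i
                and np.all(pts[j] <= pts[i])
                and np.any(pts[j] < pts[i])
                for j in remaining
            )
        ]
        fronts.append(sorted(front))
        remaining -= set(front)
    return fronts


class TestNonDominatedSort:
    def test_hand_case(self):
        fronts = wv.non_dominated_sort([(1, 2), (2, 1), (3, 3)])
        assert [sorted(f) for f in fronts] == [[0, 1], [2]]

    def test_singleton(self):
        assert wv.non_dominated_sort([(5.0,)]) == [[0]]

    def test_all_identical(self):
        fronts = wv.non_dominated_sort([(1, 1)] * 4)
        assert [sorted(f) for f in fronts] == [[0, 1, 2, 3]]

    def test_empty(self):
        assert wv.non_dominated_sort([]) == []

    @settings(deadline=None, max_examples=60)
    @given(
        data=st.data(),
        n=st.integers(1, 50),
        m=st.integers(1, 3),
    )
    def test_matches_brute_force_oracle(self, data, n, m):
        pts = [
            tuple(data.draw(st.integers(0, 5)) for _ in range(m))
            for _ in range(n)
        ]
        got = [sorted(f) for f in wv.non_dominated_sort(pts)]
        assert got == brute_force_fronts(pts)
        assert sorted(i for f in got for i in f) == list(range(n))


class TestCrowdingDistance:
    def test_two_points_all_infinite(self):
        d = wv.crowding_distance([(0, 1), (1, 0)])
        assert np.isinf(d).all()

    def test_collinear_hand_case(self):
        d = wv.crowding_distance([(0, 2), (1, 1), (2, 0)])
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert d[1] == pytest.approx(2.0)

    def test_duplicate_values_no_division_error(self):
        d = wv.crowding_distance([(1, 1), (1, 1), (1, 1)])
        assert np.isfinite(d[1:-1]).all() or np.isinf(d).any()
        assert (d >= 0).all()


class TestCrossover:
    def test_identical_parents_reproduce_parent(self, pattern, params):
        rng = np.random.default_rng(0)
        child = wv.crossover(pattern, pattern, 2, rng)
        np.testing.assert_allclose(child.W, pattern.W, atol=1e-12)

    def test_every_tile_from_one_parent(self, params, layout):
        a = wv.init_pattern(params, 1, layout=layout)
        b = wv.init_pattern(params, 2, layout=layout)
        rng = np.random.default_rng(3)
        child, tile_mask = _tile_blend(a.W, b.W, 2, rng)
        for bi in range(24):
            for bj in range(24):
                sl = (slice(bi * 2, bi * 2 + 2), slice(bj * 2, bj * 2 + 2))
                src = a.W[sl] if tile_mask[bi, bj] else b.W[sl]
                np.testing.assert_array_equal(child[sl], src)

    def test_inheritance_ratio_near_half(self, params, layout):
        a = wv.init_pattern(params, 1, layout=layout)
        b = wv.init_pattern(params, 2, layout=layout)
        rng = np.random.default_rng(4)
        frac = np.mean(
            [_tile_blend(a.W, b.W, 2, rng)[1].mean() for _ in range(20)]
        )
        assert 0.47 <= frac <= 0.53

    def test_child_is_normalized(self, params, layout):
        a = wv.init_pattern(params, 5, layout=layout)
        b = wv.init_pattern(params, 6, layout=layout)
        child = wv.crossover(a, b, 2, np.random.default_rng(7))
        assert abs(wv.spectral_radius(child.W) - 1) < 1e-9

    def test_metadata_preserved(self, params, layout):
        a = wv.init_pattern(params, 5, layout=layout)
        b = wv.init_pattern(params, 6, layout=layout)
        child = wv.crossover(a, b, 2, np.random.default_rng(8))
        np.testing.assert_array_equal(child.coords, a.coords)
        assert list(child.subtype) == list(a.subtype)

    def test_dimension_mismatch_rejected(self, pattern):
        small = wv.WiringPattern(
            W=np.eye(4), subtype=pattern.subtype, coords=pattern.coords, id="s"
        )
        with pytest.raises(ValueError):
            wv.crossover(pattern, small, 2, np.random.default_rng(0))


class TestMutate:
    def test_deletion_branch_zeroes_block(self, pattern, params):
        cfg = EvolutionConfig(p_delete=1.0)
        rng = np.random.default_rng(1)
        child = wv.mutate(pattern, cfg, params, rng)
        # exactly one 2x2 block was zeroed before re-normalization: the set
        # of zero entries must grow by the block's previously nonzero cells
        grew = (child.W == 0) & (pattern.W != 0)
        rows = np.unique(np.argwhere(grew)[:, 0]) if grew.any() else []
        assert grew.sum() <= 4
        assert len(rows) <= 2

    def test_refill_statistics(self):
        rng = np.random.default_rng(2)
        blocks = np.array(
            [_random_block_values((2, 2), 0.2, rng) for _ in range(10_000)]
        )
        nz = blocks != 0
        assert 0.17 <= nz.mean() <= 0.23
        assert np.abs(blocks).max() <= 0.5

    def test_mutant_is_normalized(self, pattern, params):
        cfg = EvolutionConfig()
        child = wv.mutate(pattern, cfg, params, np.random.default_rng(3))
        assert abs(wv.spectral_radius(child.W) - 1) < 1e-9


class TestSelection:
    @staticmethod
    def _pop(vectors):
        return [
            EvaluatedPattern(pattern=None, objectives_vector=np.asarray(v, float),
                             record={"i": i})
            for i, v in enumerate(vectors)
        ]

    def test_elitism_front_zero_survives(self):
        # front 0 = {(0,3), (3,0)}; they must outlive all dominated points
        pop = self._pop([(0, 3), (3, 0), (2, 2), (4, 4), (5, 5), (6, 6)])
        chosen = select_survivors(pop, 3)
        chosen_ids = {p.record["i"] for p in chosen}
        assert {0, 1} <= chosen_ids
        assert 5 not in chosen_ids

    def test_splitting_front_resolved_by_crowding(self):
        # one front of four collinear points; the two boundary points carry
        # infinite crowding and must be chosen first
        pop = self._pop([(0, 3), (1, 2), (2, 1), (3, 0)])
        chosen = select_survivors(pop, 2)
        assert {p.record["i"] for p in chosen} == {0, 3}

    def test_rank_assignment(self):
        pop = self._pop([(1, 1), (2, 2)])
        rank_population(pop)
        assert pop[0].rank == 0 and pop[1].rank == 1


@pytest.fixture(scope="module")
def smoke_history():
    imgs = [wv.generate_surrogate_landscape(21, 32, 32)]
    train = wv.make_saccade_series(imgs, n_scenes=10, n_clips=10, seed=1)
    cfg = EvolutionConfig(generations=2, n_survivors=6, n_offspring=6)
    return (
        wv.evolve(cfg, wv.ReservoirParams(), wv.HebbParams(),
                  wv.InfoEstimatorConfig(), train, seed=1),
        cfg,
        train,
    )


class TestEvolve:
    def test_population_bookkeeping(self, smoke_history):
        history, cfg, _ = smoke_history
        assert len(history.population) == cfg.n_survivors + cfg.n_offspring
        assert len(history.survivors) == cfg.n_survivors
        assert len(history.summary) == cfg.generations + 1
        assert len(history.archive) == expected_pattern_count(
            cfg.generations + 1, cfg.n_survivors, cfg.n_offspring
        )

    def test_deterministic_in_seed(self, smoke_history):
        history, cfg, train = smoke_history
        again = wv.evolve(cfg, wv.ReservoirParams(), wv.HebbParams(),
                          wv.InfoEstimatorConfig(), train, seed=1)
        assert history.summary.equals(again.summary)
        for a, b in zip(history.population, again.population):
            np.testing.assert_array_equal(a.pattern.W, b.pattern.W)

    def test_every_pattern_entered_normalized(self, smoke_history):
        history, _, _ = smoke_history
        assert (np.abs(history.archive["rho"] - 1) < 1e-6).all()

    def test_metadata_propagates(self, smoke_history):
        history, _, _ = smoke_history
        for ev in history.population:
            assert ev.pattern.W.shape == (48, 48)
            assert list(np.unique(ev.pattern.subtype)) == [
                "hidden", "input", "rc_readout"
            ]

    def test_cost_declines_under_pure_cost_objective(self):
        imgs = [wv.generate_surrogate_landscape(22, 32, 32)]
        train = wv.make_saccade_series(imgs, n_scenes=8, n_clips=10, seed=2)
        cfg = EvolutionConfig(
            generations=8, n_survivors=8, n_offspring=8,
            objectives=("minimize_cost",),
        )
        history = wv.evolve(cfg, wv.ReservoirParams(), wv.HebbParams(),
                            wv.InfoEstimatorConfig(), train, seed=1)
        cost = history.summary["cost_mean"].to_numpy()
        assert cost[-1] < cost[0]
        # monotone in trend: fitted slope over generations is negative
        slope = np.polyfit(np.arange(cost.size), cost, 1)[0]
        assert slope < 0

    def test_invalid_objectives_rejected(self):
        with pytest.raises(ValueError):
            EvolutionConfig(objectives=())
        with pytest.raises(ValueError):
            EvolutionConfig(objectives=("maximize_fun",))


def test_pattern_count_identity():
    # the published full-scale accounting: initial 500 plus 99 cycles of 250
    assert expected_pattern_count(100, 250, 250) == 25_250
    assert expected_pattern_count(11, 25, 25) == 300
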