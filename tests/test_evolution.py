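"""Gene-order evolution: rearrangement operators, fitness, cluster detection."""

import numpy as np
import pytest

from replicluster.evolution import (
    ORI,
    SENTINEL_FITNESS,
    TER,
    EvoConfig,
    EvoGenome,
    GeneOrderEvolution,
    apply_inversion,
    apply_translocation,
    detect_clusters,
    genome_fitness,
    target_positions,
)
from replicluster.optimize import HomeostasisObjective, ObjectiveConfig
from replicluster.synth import random_linlog


@pytest.fixture(scope="module")
def small():
    return random_linlog(3, 5, seed=21)


def _arrangement(n_loci, target_slots, n_targets, ter_at=None):
    """Build an arrangement with ori at 0 and targets at given indices."""
    ter_at = n_loci // 2 if ter_at is None else ter_at
    arr = np.full(n_loci, -1, dtype=np.int32)
    arr[0] = ORI
    arr[ter_at] = TER
    for code, slot in enumerate(target_slots, start=2):
        arr[slot] = code
    rest = [i for i in range(n_loci) if arr[i] == -1]
    arr[rest] = np.arange(2 + n_targets, n_loci)
    return arr


class TestRearrangements:
    def test_multiset_conserved_and_markers_fixed(self):
        rng = np.random.default_rng(0)
        g = EvoGenome.initial(100, 10, rng)
        arr = g.arrangement
        for _ in range(50):
            arr = apply_inversion(arr, rng)
            assert np.array_equal(np.sort(arr), np.arange(100))
        # inversions never move the markers
        assert np.flatnonzero(arr == ORI)[0] == np.flatnonzero(g.arrangement == ORI)[0]
        assert np.flatnonzero(arr == TER)[0] == np.flatnonzero(g.arrangement == TER)[0]
        for _ in range(50):
            arr = apply_translocation(arr, rng)
            assert np.array_equal(np.sort(arr), np.arange(100))

    def test_blocks_exclude_markers(self):
        rng = np.random.default_rng(1)
        g = EvoGenome.initial(30, 5, rng)
        for _ in range(200):
            arr = apply_inversion(g.arrangement, rng, mean=8, sd=4)
            assert ORI in arr and TER in arr
            assert np.array_equal(np.sort(arr), np.arange(30))


class TestTargetPositions:
    def test_initial_genome_positions_in_unit_interval(self):
        rng = np.random.default_rng(2)
        g = EvoGenome.initial(600, 34, rng)
        p = target_positions(g.arrangement, 34)
        assert p.shape == (34,)
        assert np.all((p > 0) & (p <= 1.0))

    def test_known_layout(self):
        # 10 loci, ori at 0, ter at 5; target code 2 at index 1 (p = 1/5 on
        # arm 1), code 3 at index 9 (one step from ori on arm 2: p = 1/5).
        arr = _arrangement(10, [1, 9], 2)
        p = target_positions(arr, 2)
        assert p[0] == pytest.approx(0.2)
        assert p[1] == pytest.approx(0.2)


class TestGenomeFitness:
    def test_identical_genomes_identical_fitness(self, small):
        cfg = EvoConfig(pop_size=10, generations=1, n_loci=100)
        eng = HomeostasisObjective(small, ObjectiveConfig(taus=cfg.taus))
        rng = np.random.default_rng(3)
        g = EvoGenome.initial(100, small.n_reactions, rng)
        f1 = genome_fitness(g, eng, cfg)
        f2 = genome_fitness(EvoGenome(g.arrangement.copy(), small.n_reactions), eng, cfg)
        assert f1 == f2 > 0

    def test_broken_oriter_structure_is_lethal(self, small):
        cfg = EvoConfig(pop_size=10, generations=1, n_loci=100)
        eng = HomeostasisObjective(small, ObjectiveConfig(taus=cfg.taus))
        # ter dragged to 25% of the circle: min arc 25 < 0.75 * 50
        arr = _arrangement(100, [10, 60, 70], 3, ter_at=25)
        assert genome_fitness(arr, eng, cfg, n_targets=3) == SENTINEL_FITNESS

    def test_contiguous_targets_beat_random_layouts(self, small):
        cfg = EvoConfig(pop_size=10, generations=1, n_loci=100)
        eng = HomeostasisObjective(small, ObjectiveConfig(taus=cfg.taus))
        nt = small.n_reactions
        clustered = _arrangement(100, list(range(10, 10 + nt)), nt)
        f_clustered = genome_fitness(clustered, eng, cfg, n_targets=nt)
        rng = np.random.default_rng(4)
        f_random = []
        for _ in range(200):
            g = EvoGenome.initial(100, nt, rng)
            f_random.append(genome_fitness(g, eng, cfg))
        assert f_clustered > np.quantile(f_random, 0.99)


class TestDetectClusters:
    def test_scattered_targets_no_clusters(self):
        arr = _arrangement(40, [4, 10, 16, 25], 4)
        rep = detect_clusters(arr, 4)
        assert rep.n_pure == 0 and rep.n_mixed == 0

    def test_pure_run_of_three(self):
        arr = _arrangement(40, [7, 8, 9], 3)
        rep = detect_clusters(arr, 3)
        assert rep.pure_sizes == [3]
        assert rep.n_mixed == 0

    def test_mixed_and_pure_combination(self):
        # layout around indices 3..11: T N N T N N N T T
        arr = _arrangement(40, [3, 6, 10, 11], 4)
        rep = detect_clusters(arr, 4)
        assert rep.pure_sizes == [2]
        assert rep.mixed_sizes == [4]  # T..T with an internal gap of 2

    def test_worked_example_t_t_n_t(self):
        arr = _arrangement(40, [3, 4, 6], 3)  # T T N T
        rep = detect_clusters(arr, 3)
        assert rep.pure_sizes == [2]
        assert rep.mixed_sizes == [4]

    def test_run_may_span_the_ter_gap(self):
        # targets immediately on both sides of ter: with the marker removed
        # from the order, they form a pure pair (both are ter-proximal).
        arr = _arrangement(40, [19, 21], 2, ter_at=20)
        rep = detect_clusters(arr, 2)
        assert rep.pure_sizes == [2]


class TestEvolve:
    def test_zero_mutation_rate_is_static(self, small):
        cfg = EvoConfig(pop_size=50, generations=10, n_loci=80, p_inv=0.0, p_transl=0.0)
        res = GeneOrderEvolution(small, cfg).run(seed=0)
        t = res.trajectory
        assert t["best_fitness"].nunique() == 1
        assert t["mean_fitness"].nunique() == 1

    def test_reproducible_from_seed(self, small):
        cfg = EvoConfig(pop_size=100, generations=30, n_loci=80, p_inv=0.02)
        r1 = GeneOrderEvolution(small, cfg).run(seed=7)
        r2 = GeneOrderEvolution(small, cfg).run(seed=7)
        assert r1.trajectory.equals(r2.trajectory)
        assert np.array_equal(r1.best_genome.arrangement, r2.best_genome.arrangement)

    def test_selection_improves_fitness(self, small):
        cfg = EvoConfig(pop_size=200, generations=150, n_loci=80, p_inv=0.02)
        res = GeneOrderEvolution(small, cfg).run(seed=3)
        assert res.final_fitness > res.initial_fitness
        assert "fittest-strain fitness" in res.summary()
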