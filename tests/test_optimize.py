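"""Homeostasis objective, position/promoter optimization, cluster summary."""

import numpy as np
import pytest

from replicluster.optimize import (
    SENTINEL_F,
    GeneLayout,
    GenePositionModel,
    HomeostasisObjective,
    ObjectiveConfig,
    cluster_summary,
    enzymes_from_positions,
    objective_F,
)
from replicluster.replication import ReplicationParams, average_copy_number
from replicluster.synth import random_linlog


@pytest.fixture(scope="module")
def small():
    return random_linlog(4, 6, seed=11)


class TestEnzymesFromPositions:
    def test_all_at_origin_doubles_reference(self, small):
        cfg = ObjectiveConfig(taus=(40.0,), C=40.0, D=0.0)
        layout = GeneLayout(np.zeros(small.n_reactions))
        np.testing.assert_allclose(
            enzymes_from_positions(layout, small, cfg, tau=40.0), 2.0 * small.E0
        )

    def test_terminus_with_no_division_delay_is_reference(self, small):
        cfg = ObjectiveConfig(C=40.0, D=0.0)
        layout = GeneLayout(np.ones(small.n_reactions))
        for tau in (20.0, 77.0):
            np.testing.assert_allclose(
                enzymes_from_positions(layout, small, cfg, tau=tau), small.E0
            )

    def test_mixed_positions_match_per_gene_oracle(self, small):
        cfg = ObjectiveConfig(C=40.0, D=20.0)
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, small.n_reactions)
        k = rng.uniform(0.5, 2.0, small.n_reactions)
        E = enzymes_from_positions(GeneLayout(p), small, cfg, tau=35.0, k=k)
        rep = ReplicationParams(cfg.C, cfg.D, 35.0)
        for i in range(small.n_reactions):
            expected = small.E0[i] * average_copy_number(rep, p[i]) * k[i]
            assert E[i] == pytest.approx(expected, rel=1e-12)


class TestObjectiveF:
    def test_colocated_genes_give_zero(self, small):
        cfg = ObjectiveConfig()
        for p in (0.0, 0.37, 1.0):
            F = objective_F(np.full(small.n_reactions, p), small, cfg)
            assert F <= 1e-12

    def test_single_tau_gives_zero(self, small):
        cfg = ObjectiveConfig(taus=(40.0,))
        rng = np.random.default_rng(1)
        F = objective_F(rng.uniform(0, 1, small.n_reactions), small, cfg)
        assert F <= 1e-15

    def test_scattered_layout_is_positive(self, small):
        rng = np.random.default_rng(2)
        F = objective_F(rng.uniform(0, 1, small.n_reactions), small, ObjectiveConfig())
        assert 0 < F < SENTINEL_F

    def test_promoter_mode_requires_positions(self, small):
        cfg = ObjectiveConfig(mode="promoters")
        with pytest.raises(ValueError):
            objective_F(np.ones(small.n_reactions), small, cfg)

    def test_gene_relabeling_at_identical_positions_is_invariant(self, small):
        """Swapping two genes that sit at the same locus cannot change F."""
        cfg = ObjectiveConfig()
        p = np.linspace(0, 1, small.n_reactions)
        p[1] = p[0]
        F1 = objective_F(p, small, cfg)
        q = p.copy()
        q[0], q[1] = q[1], q[0]
        assert objective_F(q, small, cfg) == pytest.approx(F1, rel=1e-12)

    def test_matches_unbatched_reference_implementation(self, small):
        """Oracle: per-tau loop over the plain steady-state solver."""
        from replicluster.linlog import derive_parameters, steady_state

        cfg = ObjectiveConfig()
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, small.n_reactions)
        par = derive_parameters(small)
        X = []
        for tau in cfg.taus:
            rep = ReplicationParams(cfg.C, cfg.D, tau)
            E = small.E0 * average_copy_number(rep, p)
            X.append(steady_state(small, par, E))
        X = np.array(X)
        expected = float(np.mean(X.std(axis=0) / X.mean(axis=0)))
        assert objective_F(p, small, cfg) == pytest.approx(expected, rel=1e-10)


class TestGenePositionModel:
    def test_position_fit_descends_and_colocates_two_genes(self):
        """On the two-enzyme chain, co-location is the F = 0 optimum."""
        m = random_linlog(1, 2, seed=5)
        fit = GenePositionModel(m, ObjectiveConfig()).fit(n_runs=3, seed=0)
        assert (fit.runs["final_F"] <= fit.runs["start_F"] + 1e-15).all()
        gaps = np.abs(fit.layouts[:, 0] - fit.layouts[:, 1])
        assert (fit.runs["final_F"] < 1e-8).all()
        assert (gaps < 0.05).all()

    def test_promoter_fit_descends(self, small):
        fit = GenePositionModel(small, ObjectiveConfig(mode="promoters")).fit(
            n_runs=2, seed=1, maxiter=300
        )
        assert (fit.runs["final_F"] <= fit.runs["start_F"] + 1e-15).all()
        assert fit.fixed_positions.shape == fit.layouts.shape
        assert (fit.layouts > 0).all()

    def test_matched_runs_share_starting_layouts(self, small):
        pos = GenePositionModel(small, ObjectiveConfig()).fit(n_runs=2, seed=9, maxiter=20)
        pro = GenePositionModel(small, ObjectiveConfig(mode="promoters")).fit(
            n_runs=2, seed=9, maxiter=20
        )
        np.testing.assert_allclose(pos.start_layouts, pro.fixed_positions)

    def test_pathway_members_colocate_on_carbon_model(self, carbon):
        """After position optimization, genes of the same pathway end up
        closer together than a random relabeling of the layout predicts."""
        import itertools

        pathways = [
            ["pts", "pgi", "pfk", "fba", "tpi", "gapdh", "pgk", "gpm", "eno", "pyk", "pdh"],
            ["zwf", "gnd", "rpe", "rpi", "tkt1", "tal", "tkt2"],
            ["cs", "acn", "icd", "akgdh", "sucoas", "sdh", "fum", "mdh"],
            ["icl", "ms"],
            ["pta_ack", "acs"],
        ]
        idx = {r: i for i, r in enumerate(carbon.reactions)}
        within = np.array(
            [
                (idx[a], idx[b])
                for members in pathways
                for a, b in itertools.combinations(members, 2)
            ]
        )
        fit = GenePositionModel(carbon, ObjectiveConfig()).fit(
            n_runs=4, seed=3, maxiter=600
        )
        rng = np.random.default_rng(0)
        wins = 0
        for layout in fit.layouts:
            d_within = np.abs(layout[within[:, 0]] - layout[within[:, 1]]).mean()
            perm_means = []
            for _ in range(100):
                perm_layout = layout[rng.permutation(layout.size)]
                perm_means.append(
                    np.abs(perm_layout[within[:, 0]] - perm_layout[within[:, 1]]).mean()
                )
            wins += d_within < np.mean(perm_means)
        assert wins >= 3

    def test_summary_renders(self, small):
        fit = GenePositionModel(small, ObjectiveConfig()).fit(n_runs=1, seed=2, maxiter=50)
        assert "Homeostasis optimization" in fit.summary()
        assert len(fit.trajectories[0]) >= 1


class TestClusterSummary:
    def test_single_cluster_when_identical(self):
        labels = cluster_summary(np.full(5, 0.4), 0.05)
        assert set(labels) == {0}

    def test_two_separated_pairs(self):
        labels = cluster_summary(np.array([0.1, 0.12, 0.8, 0.82]), 0.05)
        assert list(labels) == [0, 0, 1, 1]

    def test_matches_bruteforce_single_linkage(self):
        def oracle(p, thr):
            n = len(p)
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    i = parent[i]
                return i

            for i in range(n):
                for j in range(i + 1, n):
                    if abs(p[i] - p[j]) <= thr:
                        parent[find(i)] = find(j)
            roots = {find(i) for i in range(n)}
            return len(roots)

        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.uniform(0, 1, 12)
            thr = rng.uniform(0.02, 0.3)
            labels = cluster_summary(p, thr)
            assert labels.max() + 1 == oracle(p, thr)

    def test_labels_ordered_by_mean_position(self):
        labels = cluster_summary(np.array([0.9, 0.1, 0.5]), 0.05)
        assert list(labels) == [2, 0, 1]
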