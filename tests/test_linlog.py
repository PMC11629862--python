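"""Linlog parameter derivation, rate evaluation, analytic steady state, IO."""

import numpy as np
import pytest

from replicluster.linlog import (
    LinlogModel,
    LoadError,
    derive_parameters,
    load_network,
    rates,
    save_network,
    steady_state,
)
from replicluster.synth import random_linlog


def _random_model_state(seed):
    rng = np.random.default_rng(seed)
    m = random_linlog(3, 5, seed=seed)
    E = rng.uniform(0.5, 2.0, m.n_reactions)
    x = rng.uniform(0.5, 2.0, m.n_metabolites)
    c = rng.uniform(0.5, 2.0, m.n_external)
    return m, E, x, c


class TestDeriveParameters:
    def test_unit_reference_concentrations(self):
        m = random_linlog(3, 5, seed=0)  # x0 = c0 = 1 by construction
        par = derive_parameters(m)
        np.testing.assert_allclose(par.Ap, m.J0 / m.E0)
        np.testing.assert_allclose(par.Bp, (m.J0 / m.E0)[:, None] * m.Bx)
        np.testing.assert_allclose(par.Cp, (m.J0 / m.E0)[:, None] * m.Bc)

    def test_elementwise_oracle_nonunit_reference(self):
        rng = np.random.default_rng(42)
        m = random_linlog(3, 5, seed=1)
        m.x0 = rng.uniform(0.5, 3.0, m.n_metabolites)
        m.c0 = rng.uniform(0.5, 3.0, m.n_external)
        par = derive_parameters(m)
        for i in range(m.n_reactions):
            scale = m.J0[i] / m.E0[i]
            a = scale * (
                1.0
                - sum(m.Bx[i, j] * np.log(m.x0[j]) for j in range(m.n_metabolites))
                - sum(m.Bc[i, k] * np.log(m.c0[k]) for k in range(m.n_external))
            )
            assert par.Ap[i] == pytest.approx(a, rel=1e-12)
            for j in range(m.n_metabolites):
                assert par.Bp[i, j] == pytest.approx(scale * m.Bx[i, j], rel=1e-12)


class TestRates:
    def test_reference_returns_J0(self):
        m = random_linlog(4, 7, seed=2)
        par = derive_parameters(m)
        np.testing.assert_allclose(rates(m, par, m.E0, m.x0, m.c0), m.J0, rtol=1e-12)

    def test_zero_enzyme_zero_rate(self):
        m, E, x, c = _random_model_state(3)
        par = derive_parameters(m)
        E[2] = 0.0
        assert rates(m, par, E, x, c)[2] == 0.0

    def test_termwise_oracle(self):
        m, E, x, c = _random_model_state(4)
        par = derive_parameters(m)
        v = rates(m, par, E, x, c)
        for i in range(m.n_reactions):
            expected = E[i] * (
                par.Ap[i]
                + sum(par.Bp[i, j] * np.log(x[j]) for j in range(m.n_metabolites))
                + sum(par.Cp[i, k] * np.log(c[k]) for k in range(m.n_external))
            )
            assert v[i] == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_concentration_rejected(self):
        m, E, x, c = _random_model_state(5)
        par = derive_parameters(m)
        x[0] = 0.0
        with pytest.raises(ValueError):
            rates(m, par, E, x, c)


class TestSteadyState:
    def test_reference_recovery(self, small_models):
        for m in small_models:
            par = derive_parameters(m)
            np.testing.assert_allclose(
                steady_state(m, par, m.E0), m.x0, rtol=1e-9, atol=1e-12
            )

    def test_uniform_scaling_perfect_homeostasis(self, small_models):
        """E = r E0 leaves x unchanged and scales every flux by r."""
        for m in small_models:
            par = derive_parameters(m)
            for r in (0.5, 3.0):
                x = steady_state(m, par, r * m.E0)
                np.testing.assert_allclose(x, m.x0, rtol=1e-9, atol=1e-12)
                np.testing.assert_allclose(
                    rates(m, par, r * m.E0, x), r * m.J0, rtol=1e-9
                )

    def test_random_enzymes_give_zero_net_production(self, small_models):
        rng = np.random.default_rng(0)
        for m in small_models:
            par = derive_parameters(m)
            E = m.E0 * rng.uniform(0.5, 2.0, m.n_reactions)
            x = steady_state(m, par, E)
            v = rates(m, par, E, x)
            assert np.abs(m.N @ v).max() <= 1e-8 * max(1.0, np.abs(v).max())

    def test_concentration_unit_invariance(self):
        """Rescaling x0 and c0 (with re-derived parameters) rescales x_ss."""
        m = random_linlog(4, 7, seed=8)
        par = derive_parameters(m)
        rng = np.random.default_rng(1)
        E = m.E0 * rng.uniform(0.5, 2.0, m.n_reactions)
        x = steady_state(m, par, E)
        factor = 3.7
        m2 = LinlogModel(
            N=m.N, E0=m.E0, J0=m.J0, x0=factor * m.x0, c0=factor * m.c0,
            Bx=m.Bx, Bc=m.Bc, reactions=list(m.reactions),
            externals=list(m.externals), output_reaction=m.output_reaction,
        )
        par2 = derive_parameters(m2)
        x2 = steady_state(m2, par2, E, factor * m.c0)
        np.testing.assert_allclose(x2, factor * x, rtol=1e-9)


class TestIO:
    def test_carbon_fixture_dimensions(self, carbon):
        assert carbon.n_reactions == 34
        assert carbon.n_metabolites == 26
        assert carbon.externals == ["glucose", "acetate"]

    def test_json_tsv_round_trip_bit_equivalent(self, tmp_path, carbon):
        save_network(carbon, tmp_path / "model.json", dialect="json")
        save_network(carbon, tmp_path / "model_tsv", dialect="tsv")
        mj = load_network(tmp_path / "model.json")
        mt = load_network(tmp_path / "model_tsv")
        for attr in ("N", "E0", "J0", "x0", "c0", "Bx", "Bc"):
            np.testing.assert_array_equal(getattr(mj, attr), getattr(mt, attr))
            np.testing.assert_array_equal(getattr(mj, attr), getattr(carbon, attr))
        assert mj.reactions == mt.reactions == carbon.reactions
        assert mj.output_reaction == mt.output_reaction == carbon.output_reaction

    def test_unbalanced_reference_flux_rejected(self, tmp_path, carbon):
        import json

        from replicluster.linlog import _model_to_dict

        data = _model_to_dict(carbon)
        data["reference"]["J0"][0] *= 2.0
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(data))
        with pytest.raises(LoadError):
            load_network(path)

    def test_small_chain_behaves_like_toy_pathway(self):
        """One-metabolite chain: s rises with E1, falls with E2, co-scales freely."""
        m = random_linlog(1, 2, seed=3)
        par = derive_parameters(m)
        s_ref = steady_state(m, par, np.array([1.0, 1.0]))[0]
        s_up = steady_state(m, par, np.array([2.0, 1.0]))[0]
        s_down = steady_state(m, par, np.array([1.0, 2.0]))[0]
        s_both = steady_state(m, par, np.array([2.0, 2.0]))[0]
        assert s_up > s_ref > s_down
        assert s_both == pytest.approx(s_ref, rel=1e-9)
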