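"""Circuit model: Hill inputs, generalized regulatory kinetics, steady states."""

import numpy as np
import pytest

from bifdesign.model import CircuitModel, ParameterSet, Topology, build_rhs, signal_input, steady_states


def two_gene_model(edges=((0, -1), (-1, 0)), mask=(True, True), **over):
    vals = dict(p=(361.0, 411.0), l=(30.0, 30.0), k=9.04e-2, R=(143.0, 300.0),
                K=(10.0, 137.0), d=(1.0, 1.38))
    vals.update(over)
    return CircuitModel(
        Topology(edges, mask),
        ParameterSet(promoter=vals["p"], leak=vals["l"], interaction=vals["k"],
                     tf_total=vals["R"], dissociation=vals["K"], degradation=vals["d"]),
    )


class TestSignalInput:
    def test_half_saturation(self):
        assert signal_input(10.0, 143.0, 10.0) == pytest.approx(143.0 / 2)

    def test_zero_signal(self):
        assert signal_input(0.0, 5.0, 2.0) == 0.0

    def test_printed_biosensor_values(self):
        # R1 = 143, K1 = 10 at S = K gives half the TF total
        assert signal_input(10.0, 143.0, 10.0, 2) == pytest.approx(71.5)

    def test_monotone_and_bounded(self):
        S = np.linspace(0, 500, 200)
        q = signal_input(S, 143.0, 10.0)
        assert np.all(np.diff(q) >= 0)
        assert np.all(q <= 143.0)

    @pytest.mark.parametrize("bad", [dict(S=-1.0), dict(R=0.0), dict(K=-2.0)])
    def test_domain_errors(self, bad):
        kw = dict(S=1.0, R=1.0, K=1.0)
        kw.update(bad)
        with pytest.raises(ValueError):
            signal_input(kw["S"], kw["R"], kw["K"])


class TestGeneralizedKinetics:
    def test_printed_three_gene_system(self):
        """The generalized rule restricted to the printed cascade topology
        reproduces the three displayed rate equations term by term."""
        import sympy as sp

        u, v, w, S = sp.symbols("u v w S", positive=True)
        p0, p1, p2, p3, p4, p5, k = sp.symbols("p0 p1 p2 p3 p4 p5 k", positive=True)
        R1, R2, K1, K2 = sp.symbols("R1 R2 K1 K2", positive=True)
        du, dv, dw = sp.symbols("du dv dw", positive=True)
        q1 = R1 * S**2 / (K1**2 + S**2)
        q2 = R2 * S**2 / (K2**2 + S**2)
        printed = [
            p0 * (p1 + q1) / (1 + p1 + q1 + k * v**2) - du * u,
            p2 * (p3 + q2) / (1 + p3 + q2 + k * u**2 + k * w**2) - dv * v,
            p4 * p5 / (1 + p5 + k * v**2) - dw * w,
        ]
        # v represses u; u and w repress v; v represses w
        edges = ((0, -1, 0), (-1, 0, -1), (0, -1, 0))
        subs = {p0: 3.0, p1: 0.5, p2: 7.0, p3: 1.5, p4: 2.0, p5: 0.25, k: 0.1,
                R1: 11.0, R2: 5.0, K1: 2.0, K2: 3.0, du: 1.0, dv: 0.7, dw: 1.3}
        model = CircuitModel(
            Topology(edges, (True, True, False)),
            ParameterSet(promoter=(3.0, 7.0, 2.0), leak=(0.5, 1.5, 0.25), interaction=0.1,
                         tf_total=(11.0, 5.0, 9.0), dissociation=(2.0, 3.0, 4.0),
                         degradation=(1.0, 0.7, 1.3)),
        )
        rng = np.random.default_rng(0)
        for _ in range(10):
            uu, vv, ww, ss = rng.uniform(0.1, 5.0, size=4)
            expected = [
                float(e.subs(subs).subs({u: uu, v: vv, w: ww, S: ss})) for e in printed
            ]
            got = model.rhs(np.array([uu, vv, ww]), ss)
            np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_uncoupled_genes(self):
        model = two_gene_model(edges=((0, 0), (0, 0)), mask=(False, False))
        w = np.array([2.0, 3.0])
        p = np.array(model.params.promoter)
        l = np.array(model.params.leak)
        d = np.array(model.params.degradation)
        np.testing.assert_allclose(model.rhs(w, 5.0), p * l / (1 + l) - d * w, rtol=1e-13)

    def test_cross_repression_positive_at_origin(self):
        model = two_gene_model()
        f = build_rhs(model)
        rate = f(np.zeros(2), 7.0)
        q = signal_input(7.0, np.array(model.params.tf_total), np.array(model.params.dissociation))
        l = np.array(model.params.leak)
        p = np.array(model.params.promoter)
        np.testing.assert_allclose(rate, p * (l + q) / (1 + l + q), rtol=1e-13)
        assert np.all(rate > 0)

    def test_self_edges_enter_numerator_and_denominator(self):
        act = two_gene_model(edges=((1, 0), (0, 0)), mask=(False, False))
        rep = two_gene_model(edges=((-1, 0), (0, 0)), mask=(False, False))
        none = two_gene_model(edges=((0, 0), (0, 0)), mask=(False, False))
        w = np.array([2.0, 1.0])
        k = none.params.interaction
        l0, p0_, _ = none.params.leak[0], none.params.promoter[0], none.params.degradation[0]
        expected_act = p0_ * (l0 + k * 4.0) / (1 + l0 + k * 4.0)
        expected_rep = p0_ * l0 / (1 + l0 + k * 4.0)
        assert act.rhs(w, 0.0)[0] + 2.0 == pytest.approx(expected_act, rel=1e-12)
        assert rep.rhs(w, 0.0)[0] + 2.0 == pytest.approx(expected_rep, rel=1e-12)

    def test_analytic_jacobians_match_finite_differences(self):
        model = two_gene_model(edges=((-1, -1), (-1, 1)))
        rng = np.random.default_rng(1)
        for _ in range(5):
            w = rng.uniform(0.5, 50.0, size=2)
            S = rng.uniform(0.5, 80.0)
            J = model.jacobian_state(w[None], np.array([S]))[0]
            fS = model.jacobian_signal(w[None], np.array([S]))[0]
            eps = 1e-6
            for j in range(2):
                dw = np.zeros(2)
                dw[j] = eps * max(w[j], 1.0)
                fd = (model.rhs(w + dw, S) - model.rhs(w - dw, S)) / (2 * dw[j])
                np.testing.assert_allclose(J[:, j], fd, rtol=1e-5)
            hS = eps * max(S, 1.0)
            fd_S = (model.rhs(w, S + hS) - model.rhs(w, S - hS)) / (2 * hS)
            np.testing.assert_allclose(fS, fd_S, rtol=1e-5)


class TestSteadyStates:
    def test_uncoupled_closed_form(self):
        model = two_gene_model(edges=((0, 0), (0, 0)), mask=(False, False))
        roots = steady_states(model, 5.0)
        assert len(roots) == 1
        w, stable = roots[0]
        p = np.array(model.params.promoter)
        l = np.array(model.params.leak)
        d = np.array(model.params.degradation)
        np.testing.assert_allclose(w, p * l / (d * (1 + l)), rtol=1e-8)
        assert stable

    def test_bistable_range_has_three_equilibria(self):
        # the printed biosensor set is bistable at the baseline signal S = 10
        from bifdesign.fixtures import fig5_A1

        roots = steady_states(fig5_A1().model, 10.0)
        assert len(roots) == 3
        assert sum(stable for _, stable in roots) == 2

    def test_monostable_far_above_the_mushroom(self):
        from bifdesign.fixtures import fig5_A1

        roots = steady_states(fig5_A1().model, 250.0)
        assert len(roots) == 1 and roots[0][1]

    def test_residuals_and_second_polish(self):
        from bifdesign.fixtures import fig5_A1

        model = fig5_A1().model
        for w, _ in steady_states(model, 10.0, tol=1e-9):
            assert np.max(np.abs(model.rhs(w, 10.0))) <= 1e-9
            tight = steady_states(model, 10.0, seeds=[w], tol=1e-12)
            assert any(np.max(np.abs(w - w2) / np.maximum(w, 1)) < 1e-6 for w2, _ in tight)

    def test_forward_invariance_of_nonnegative_box(self):
        from scipy.integrate import solve_ivp

        rng = np.random.default_rng(3)
        for _ in range(5):
            edges = rng.integers(-1, 2, size=(2, 2))
            model = two_gene_model(edges=tuple(map(tuple, edges.tolist())))
            ceiling = model.state_ceiling
            w0 = rng.uniform(0, ceiling)
            sol = solve_ivp(lambda t, w: model.rhs(np.clip(w, 0, None), 15.0),
                            (0, 50.0), w0, rtol=1e-8, atol=1e-10)
            assert np.min(sol.y) >= -1e-7
            assert np.max(sol.y.T / ceiling) <= 1.0 + 1e-6


class TestTopology:
    def test_vector_round_trip_uses_printed_ordering(self):
        edges = ((0, -1, 0), (-1, 0, -1), (0, -1, 0))
        topo = Topology(edges, (True, True, False))
        vec = topo.to_vector()
        # (y_uu, y_vu, y_wu, y_uv, y_vv, y_wv, y_uw, y_vw, y_ww)
        assert vec.tolist() == [0, -1, 0, -1, 0, -1, 0, -1, 0]
        assert Topology.from_vector(vec, (True, True, False)) == topo

    def test_invariants(self):
        with pytest.raises(ValueError):
            Topology(((0, 2), (0, 0)), (True, True))
        topo = Topology(((1, 0), (0, -1)), (True, True))
        assert topo.n_connections == 2
        assert not topo.is_connected  # self-edges only
        assert Topology(((0, 1), (0, 0)), (True, True)).is_connected

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ParameterSet(promoter=(1.0, -1.0), leak=(0.0, 0.0), interaction=0.1,
                         tf_total=(1.0, 1.0), dissociation=(1.0, 1.0), degradation=(1.0, 1.0))
        with pytest.raises(ValueError):
            ParameterSet(promoter=(1.0,), leak=(0.0, 0.0), interaction=0.1,
                         tf_total=(1.0,), dissociation=(1.0,), degradation=(1.0,))

    def test_tying_rules(self):
        model = two_gene_model()
        tied = CircuitModel(model.topology, model.params,
                            assumptions={"leak[1]": "leak[0]", "degradation[0]": 1.0})
        assert tied.params.leak[1] == tied.params.leak[0]
        assert tied.params.degradation[0] == 1.0
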