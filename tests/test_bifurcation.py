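"""Extended Jacobian, fold detection, diagram tracing and classification."""

import numpy as np
import pytest

from bifdesign.bifurcation import (
    Branch,
    BifurcationDiagram,
    DegeneratePointError,
    classify_diagram,
    extended_jacobian,
    isola_curvature_check,
    phase_map,
    saddle_node_objective,
    tangent_vector,
    trace_diagram,
    with_params,
)
from bifdesign.model import steady_states


class FoldNormalForm:
    """1-state toy f(w, S) = S - w^2: a fold at (w, S) = (0, 0)."""

    def rhs(self, omega, S):
        omega = np.atleast_1d(np.asarray(omega, dtype=float))
        return np.atleast_1d(S - omega[..., 0] ** 2)[..., None] if omega.ndim > 1 else np.array(
            [S - omega[0] ** 2]
        )


class TestExtendedJacobian:
    def test_fold_normal_form(self):
        toy = FoldNormalForm()
        Q = extended_jacobian(toy, np.array([1.0]), 1.0)
        np.testing.assert_allclose(Q, [[-2.0, 1.0]], atol=1e-6)
        Q0 = extended_jacobian(toy, np.array([0.0]), 0.0)
        np.testing.assert_allclose(Q0, [[0.0, 1.0]], atol=1e-6)

    def test_matches_symbolic_jacobian(self, mushroom_fixture):
        """Analytic Q equals the sympy-differentiated Jacobian of the circuit."""
        import sympy as sp

        model = mushroom_fixture.model
        u, v, S = sp.symbols("u v S", positive=True)
        p = model.params
        q1 = p.tf_total[0] * S**2 / (p.dissociation[0] ** 2 + S**2)
        q2 = p.tf_total[1] * S**2 / (p.dissociation[1] ** 2 + S**2)
        k = p.interaction
        # wiring: u self-represses, u and v mutually repress
        f1 = p.promoter[0] * (p.leak[0] + q1) / (1 + p.leak[0] + q1 + k * u**2 + k * v**2) - p.degradation[0] * u
        f2 = p.promoter[1] * (p.leak[1] + q2) / (1 + p.leak[1] + q2 + k * u**2) - p.degradation[1] * v
        sym_Q = sp.Matrix([f1, f2]).jacobian([u, v, S])
        rng = np.random.default_rng(2)
        for _ in range(5):
            uu, vv, ss = rng.uniform(0.5, 60.0, size=3)
            expected = np.array(sym_Q.subs({u: uu, v: vv, S: ss}), dtype=float)
            got = extended_jacobian(model, np.array([uu, vv]), ss)
            np.testing.assert_allclose(got, expected, rtol=1e-9)

    def test_shape(self, phase_base_fixture):
        Q = extended_jacobian(phase_base_fixture.model, np.array([1.0, 1.0]), 2.0)
        assert Q.shape == (2, 3)


class TestTangentVector:
    def test_axis_cases(self):
        np.testing.assert_allclose(tangent_vector(np.array([[0.0, 1.0]])), [1.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(tangent_vector(np.array([[1.0, 0.0]])), [0.0, 1.0], atol=1e-12)

    def test_random_full_rank_matrices(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            Q = rng.standard_normal((3, 4))
            beta = tangent_vector(Q)
            assert np.linalg.norm(beta) == pytest.approx(1.0)
            assert np.max(np.abs(Q @ beta)) <= 1e-8 * np.linalg.norm(Q)
            assert beta[np.argmax(np.abs(beta))] > 0

    def test_rank_deficient_raises(self):
        Q = np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])  # two-dimensional null space
        with pytest.raises(DegeneratePointError):
            tangent_vector(Q)


class TestSaddleNodeObjective:
    def test_normal_form_values(self):
        toy = FoldNormalForm()
        assert saddle_node_objective(toy, np.array([0.0]), 0.0) == pytest.approx(0.0, abs=1e-10)
        assert saddle_node_objective(toy, np.array([1.0]), 1.0) == pytest.approx(0.8, abs=1e-8)

    def test_requires_near_equilibrium(self):
        with pytest.raises(ValueError):
            saddle_node_objective(FoldNormalForm(), np.array([5.0]), 0.0)

    def test_zero_at_every_traced_fold(self, mushroom_diagram, mushroom_fixture):
        for sn in mushroom_diagram.saddle_nodes:
            assert sn.J <= 1e-8
            assert saddle_node_objective(mushroom_fixture.model, sn.omega, sn.S) <= 1e-8


class TestTraceDiagram:
    def test_uncoupled_is_monostable(self, s_grid):
        from bifdesign.fixtures import fig5_A1
        from bifdesign.model import CircuitModel, Topology

        base = fig5_A1().model
        model = CircuitModel(Topology(((0, 0), (0, 0)), (False, False)), base.params)
        diagram = trace_diagram(model, s_grid)
        assert diagram.label == "monostable"
        assert len(diagram.saddle_nodes) == 0
        assert len(diagram.branches) == 1

    def test_fold_invariants(self, mushroom_diagram, mushroom_fixture):
        """Every fold satisfies equilibrium + fold conditions to tight tolerance."""
        model = mushroom_fixture.model
        for sn in mushroom_diagram.saddle_nodes:
            assert np.max(np.abs(model.rhs(sn.omega, sn.S))) <= 1e-8
            assert sn.J <= 1e-8
            eig = np.linalg.eigvals(model.jacobian_state(sn.omega[None], np.array([sn.S]))[0])
            assert np.min(np.abs(eig.real)) <= 1e-4
            assert np.linalg.norm(sn.beta) == pytest.approx(1.0)

    def test_fold_pairing_alternates_stability(self, mushroom_diagram):
        for b1, b2 in mushroom_diagram.fold_branches:
            assert b1 is not None and b2 is not None
            assert mushroom_diagram.branches[b1].stable != mushroom_diagram.branches[b2].stable

    def test_equilibrium_counts_match_dense_root_sweep(self, mushroom_diagram, mushroom_fixture):
        """Oracle equivalence: branch coverage equals an independent root sweep."""
        rng = np.random.default_rng(7)
        lo, hi = mushroom_diagram.s_range
        for S in rng.uniform(lo + 1.0, hi - 1.0, size=10):
            n_oracle = len(steady_states(mushroom_fixture.model, S, points_per_axis=11))
            n_diagram = sum(1 for b in mushroom_diagram.branches if b.s_min <= S <= b.s_max)
            assert n_diagram == n_oracle

    def test_symmetric_model_gives_symmetric_diagram(self, s_grid):
        from bifdesign.model import CircuitModel, ParameterSet, Topology

        params = ParameterSet(promoter=(400.0, 400.0), leak=(30.0, 30.0), interaction=0.1,
                              tf_total=(200.0, 200.0), dissociation=(50.0, 50.0),
                              degradation=(1.0, 1.0))
        model = CircuitModel(Topology(((0, -1), (-1, 0)), (True, True)), params)
        diagram = trace_diagram(model, s_grid)
        for sn in diagram.saddle_nodes:
            # the swapped state is a fold of the same diagram at the same signal
            mirrored = sn.omega[::-1]
            assert any(
                abs(o.S - sn.S) <= 1e-6 * sn.S + 1e-9
                and np.max(np.abs(o.omega - mirrored)) <= 1e-4 * (1 + np.max(mirrored))
                for o in diagram.saddle_nodes
            )

    def test_grid_validation(self, mushroom_fixture):
        with pytest.raises(ValueError):
            trace_diagram(mushroom_fixture.model, np.linspace(1, 10, 10))


def _circle_diagram(s0=10.0, u0=5.0, r=3.0):
    """A synthetic closed branch: (S - s0)^2 + (u - u0)^2 = r^2."""
    theta = np.linspace(0.02, np.pi - 0.02, 60)
    S_top = s0 - r * np.cos(theta)
    top = Branch(S=S_top, states=(u0 + r * np.sin(theta))[:, None], stable=True)
    bottom = Branch(S=S_top, states=(u0 - r * np.sin(theta))[:, None], stable=False)
    outer = Branch(S=np.linspace(0.0, 25.0, 80), states=np.full((80, 1), 0.2), stable=True)
    from bifdesign.bifurcation import SaddleNodePoint

    folds = [
        SaddleNodePoint(S=s0 - r, omega=np.array([u0]), beta=np.array([1.0, 0.0]), J=0.0),
        SaddleNodePoint(S=s0 + r, omega=np.array([u0]), beta=np.array([1.0, 0.0]), J=0.0),
    ]
    return BifurcationDiagram(
        branches=[top, bottom, outer],
        saddle_nodes=folds,
        s_range=(0.0, 25.0),
        bistable_ranges=[(s0 - r, s0 + r)],
        components=[0, 0, 2],
        fold_branches=[(0, 1), (0, 1)],
    )


def _scurve_diagram():
    """A synthetic toggle S-curve: u^3 - u = S - 5 style hysteresis."""
    u = np.linspace(-1.8, 1.8, 120)
    S = (u**3 - u) + 5.0
    lower = u <= -1 / np.sqrt(3)
    upper = u >= 1 / np.sqrt(3)
    middle = ~(lower | upper)
    mk = lambda m, st: Branch(S=S[m][np.argsort(S[m])],  # noqa: E731
                              states=(u[m][np.argsort(S[m])] + 2.0)[:, None], stable=st)
    from bifdesign.bifurcation import SaddleNodePoint

    s1 = float((1 / np.sqrt(3)) ** 3 - 1 / np.sqrt(3) + 5.0)  # fold at u = +1/sqrt(3)... S low
    s2 = float((-1 / np.sqrt(3)) ** 3 + 1 / np.sqrt(3) + 5.0)
    folds = [
        SaddleNodePoint(S=s1, omega=np.array([1 / np.sqrt(3) + 2.0]), beta=np.array([1.0, 0.0]), J=0.0),
        SaddleNodePoint(S=s2, omega=np.array([-1 / np.sqrt(3) + 2.0]), beta=np.array([1.0, 0.0]), J=0.0),
    ]
    folds.sort(key=lambda sn: sn.S)
    return BifurcationDiagram(
        branches=[mk(lower, True), mk(middle, False), mk(upper, True)],
        saddle_nodes=folds,
        s_range=(float(S.min()), float(S.max())),
        bistable_ranges=[(folds[0].S, folds[1].S)],
        components=[0, 0, 0],
        fold_branches=[(1, 2), (0, 1)],
    )


class TestCurvatureCheck:
    def test_circle_branch_is_isola_shaped(self):
        assert isola_curvature_check(_circle_diagram()) is True

    def test_toggle_scurve_has_reversed_signs(self):
        assert isola_curvature_check(_scurve_diagram()) is False

    def test_traced_isola_branch(self, isola_diagram):
        assert isola_curvature_check(isola_diagram) is True

    def test_requires_two_folds(self, s_grid):
        from bifdesign.bifurcation import NotApplicableError
        from bifdesign.fixtures import fig5_A1
        from bifdesign.model import CircuitModel, Topology

        base = fig5_A1().model
        mono = CircuitModel(Topology(((0, 0), (0, 0)), (False, False)), base.params)
        with pytest.raises(NotApplicableError):
            isola_curvature_check(trace_diagram(mono, s_grid))


class TestClassification:
    def test_fixture_labels(self, mushroom_diagram, isola_diagram, open_mushroom_diagram):
        assert mushroom_diagram.label == "mushroom"
        assert isola_diagram.label == "isola"
        assert open_mushroom_diagram.label == "mushroom"

    def test_isola_has_closed_branch_and_open_branch(self, isola_diagram):
        closed = [c for c in set(isola_diagram.components) if isola_diagram.component_is_closed(c)]
        assert len(closed) == 1
        assert len(isola_diagram.component_folds(closed[0])) == 2

    def test_mushroom_has_two_disjoint_bistable_ranges(self, mushroom_diagram):
        (a1, b1), (a2, b2) = mushroom_diagram.bistable_ranges
        assert b1 < a2
        # the two ranges are delimited by the four folds
        fold_s = sorted(sn.S for sn in mushroom_diagram.saddle_nodes)
        assert [a1, b1, a2, b2] == pytest.approx(fold_s)

    def test_neck_pinching_under_falling_degradation(self, mushroom_fixture, s_grid):
        """Pushing d_v along the pinch direction turns the mushroom into an
        isola and finally monostable, without touching the wiring."""
        labels = [
            trace_diagram(with_params(mushroom_fixture.model, dv=dv), s_grid).label
            for dv in (1.38, 1.1, 0.4)
        ]
        assert labels == ["mushroom", "isola", "monostable"]


class TestPhaseMap:
    def test_degenerate_grid_reproduces_fixture_cell(self, mushroom_fixture, s_grid):
        labels = phase_map(mushroom_fixture.model, ("dv", [1.38]), ("k", [9.04e-2]), s_grid)
        assert labels.shape == (1, 1)
        assert labels[0, 0] == "mushroom"

    def test_zero_interaction_is_monostable(self, mushroom_fixture, s_grid):
        labels = phase_map(mushroom_fixture.model, ("dv", [1.38]), ("k", [1e-9]), s_grid)
        assert labels[0, 0] == "monostable"

    def test_unknown_parameter_rejected(self, mushroom_fixture, s_grid):
        with pytest.raises(KeyError):
            phase_map(mushroom_fixture.model, ("nope", [1.0]), ("k", [0.1]), s_grid)
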