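"""Mixed-integer design of circuits with prescribed saddle-node locations.

The design problem: find a signed wiring ``y``, kinetic parameters ``x`` and
fold coordinates ``(S_k, omega_k)`` minimizing the fold objective

    Psi = sum_k J_k,    J_k = beta_{k, N+1}^2,

subject to the equilibrium constraints ``f(omega_k, x, y, S_k) = 0``, bounds
on ``x`` and ``y``, and rectangular target boxes for each fold location.
``Psi = 0`` with four distinct folds is a mushroom; with two folds and the
isola curvature signature, an isola.

The mixed-integer search is a seeded multistart: each start samples a wiring
uniformly within the integer bounds and the continuous variables
log-uniformly within theirs, then runs a gradient-based constrained local
solve (SLSQP) over the continuous variables at fixed wiring.  Accepted
solutions (``Psi <= 1e-6``) are post-verified by tracing and classifying the
full bifurcation diagram -- Psi alone can also vanish at coincident folds
(a cusp), which verification rejects.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .model import CircuitModel, ParameterSet, Topology, _apply_assumptions
from .bifurcation import (
    DegeneratePointError,
    EmptyDiagramError,
    PARAM_ALIASES,
    extended_jacobian,
    tangent_vector,
    trace_diagram,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TargetBox",
    "DesignProblem",
    "DesignSolution",
    "DesignFailure",
    "SolutionSet",
    "CapabilityError",
    "mushroom_objective",
    "solve_single",
    "multistart_search",
    "enumerate_topologies",
    "pareto_front",
    "epsilon_constraint_scan",
    "epsilon_constraint_sweep",
    "isola_design",
    "two_gene_mushroom_problem",
    "three_gene_mushroom_problem",
    "default_search_grid",
]

PSI_SUCCESS_TOL = 1e-6
DEGENERATE_PENALTY = 1e6


class CapabilityError(ValueError):
    """Requested exhaustive operation is beyond the supported problem size."""


# ----------------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetBox:
    """Rectangular target region for one (or one pair of) saddle nodes."""

    s_interval: tuple
    omega_box: tuple  # per-gene (low, high)

    def __post_init__(self):
        lo, hi = self.s_interval
        if not lo < hi:
            raise ValueError("S interval must have positive length")
        for wl, wh in self.omega_box:
            if not wl <= wh:
                raise ValueError("omega box bounds must be ordered")

    def contains(self, S, omega, rel_slack: float = 0.0) -> bool:
        lo, hi = self.s_interval
        slack_s = rel_slack * (hi - lo)
        if not (lo - slack_s <= S <= hi + slack_s):
            return False
        for w, (wl, wh) in zip(omega, self.omega_box):
            slack_w = rel_slack * (wh - wl)
            if not (wl - slack_w <= w <= wh + slack_w):
                return False
        return True


@dataclass(frozen=True)
class DesignProblem:
    """Bounds, fold target boxes and objectives of a circuit-design task.

    ``x_names`` are the free continuous parameters (short aliases such as
    ``p0``, ``k``, ``dv``); ``tying`` holds the dimensionality-reduction
    rules applied to every candidate (by default the two leakiness values
    are tied and the first degradation rate is fixed to one).  When
    ``boxes`` has length 2 and ``n_folds`` is 4 the folds are constrained
    pairwise (the two low-signal folds share the first box).
    """

    n_genes: int
    signal_mask: tuple
    y_lower: tuple
    y_upper: tuple
    x_names: tuple
    x_bounds: tuple  # (low, high) per name
    boxes: tuple
    n_folds: int = 4
    tying: tuple = (("leak[1]", "leak[0]"), ("degradation[0]", 1.0))
    target_labels: tuple = ("mushroom", "inverted_mushroom")
    objectives: tuple = ("psi",)
    extra_conditions: tuple = ()
    s_window: tuple = (0.1, 330.0)
    multistart: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 1 or self.multistart < 1:
            raise ValueError("n_folds and multistart must be >= 1")
        if len(self.boxes) not in (self.n_folds, 2):
            raise ValueError("boxes must have one entry per fold, or exactly 2 (pairwise mode)")
        if len(self.x_names) != len(self.x_bounds):
            raise ValueError("x_bounds must align with x_names")
        for lo, hi in self.x_bounds:
            if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo < hi):
                raise ValueError("x bounds must be finite, positive and ordered")
        yl = np.asarray(self.y_lower)
        yu = np.asarray(self.y_upper)
        if yl.shape != (self.n_genes, self.n_genes) or yu.shape != yl.shape:
            raise ValueError("y bounds must be n_genes x n_genes matrices")
        if np.any(yl > yu) or yl.min() < -1 or yu.max() > 1:
            raise ValueError("y bounds must satisfy -1 <= y_lower <= y_upper <= 1")

    def box_for_fold(self, k: int) -> TargetBox:
        if len(self.boxes) == self.n_folds:
            return self.boxes[k]
        return self.boxes[0] if k < self.n_folds // 2 else self.boxes[1]

    def build_model(self, topology: Topology, x: np.ndarray) -> CircuitModel:
        base = ParameterSet(
            promoter=(1.0,) * self.n_genes,
            leak=(1.0,) * self.n_genes,
            interaction=1.0,
            tf_total=(1.0,) * self.n_genes,
            dissociation=(1.0,) * self.n_genes,
            degradation=(1.0,) * self.n_genes,
        )
        rules = {PARAM_ALIASES.get(n, n): v for n, v in zip(self.x_names, x)}
        rules.update({k: v for k, v in self.tying})
        params = _apply_assumptions(base, rules)
        return CircuitModel(topology, params)


@dataclass
class DesignSolution:
    """A verified design: wiring, parameters, fold coordinates and residual."""

    topology: Topology
    params: ParameterSet
    x: np.ndarray
    folds: list  # (S_k, omega_k)
    psi: float
    verified_label: str
    start_seed: int
    objective_values: dict = field(default_factory=dict)


@dataclass
class DesignFailure:
    """A non-convergent or rejected start, with diagnostics (never raised)."""

    reason: str
    start_seed: int
    psi: float = np.inf
    topology: Topology | None = None


@dataclass
class SolutionSet:
    """Verified designs aggregated over a multistart run."""

    solutions: list
    n_runs: int
    seed: int

    def by_topology(self) -> dict:
        groups: dict = {}
        for sol in self.solutions:
            groups.setdefault(tuple(int(v) for v in sol.topology.to_vector()), []).append(sol)
        return groups

    def frequency_table(self):
        """Per-topology hit counts, most frequent first (the A1..A7 ordering)."""
        import pandas as pd

        groups = self.by_topology()
        rows = [
            {
                "topology": key,
                "n_connections": sols[0].topology.n_connections,
                "n_hits": len(sols),
                "best_psi": min(s.psi for s in sols),
            }
            for key, sols in groups.items()
        ]
        return (
            pd.DataFrame(rows, columns=["topology", "n_connections", "n_hits", "best_psi"])
            .sort_values("n_hits", ascending=False, kind="stable")
            .reset_index(drop=True)
        )

    def parameter_matrix(self, topology_key) -> np.ndarray:
        sols = self.by_topology()[tuple(topology_key)]
        return np.array([s.x for s in sols])


# ----------------------------------------------------------------------------
# objective
# ----------------------------------------------------------------------------

def mushroom_objective(model: CircuitModel, folds) -> float:
    """``Psi = sum_k J_k`` over prescribed fold coordinates.

    Equilibrium violation is handled by the solver's constraints, not here.
    A degenerate extended Jacobian contributes a large finite penalty so the
    local solver can retreat from cusps.
    """
    psi = 0.0
    for S_k, omega_k in folds:
        try:
            beta = tangent_vector(extended_jacobian(model, np.asarray(omega_k, float), S_k))
            psi += float(beta[-1] ** 2)
        except (DegeneratePointError, ValueError):
            logger.warning("degenerate fold point at S=%.4g; penalizing", S_k)
            psi += DEGENERATE_PENALTY
    return psi


# ----------------------------------------------------------------------------
# single local solve
# ----------------------------------------------------------------------------

def _sample_start(problem: DesignProblem, rng: np.random.Generator):
    yl = np.asarray(problem.y_lower)
    yu = np.asarray(problem.y_upper)
    y = rng.integers(yl, yu + 1)
    topo = Topology(tuple(map(tuple, y.tolist())), problem.signal_mask)
    lo = np.log(np.array([b[0] for b in problem.x_bounds]))
    hi = np.log(np.array([b[1] for b in problem.x_bounds]))
    x = np.exp(rng.uniform(lo, hi))
    s_list, w_list = [], []
    for k in range(problem.n_folds):
        box = problem.box_for_fold(k)
        s_list.append(rng.uniform(*box.s_interval))
        w_list.append(np.array([rng.uniform(wl, wh) for wl, wh in box.omega_box]))
    order = np.argsort(s_list)
    return topo, x, [s_list[i] for i in order], [w_list[i] for i in order]


def _omega_scales(problem):
    """Per-fold, per-gene state scales (the target-box ceilings)."""
    return np.array(
        [[max(hi, 1.0) for _, hi in problem.box_for_fold(k).omega_box] for k in range(problem.n_folds)]
    )


def _pack(problem, x, s_folds, w_folds):
    scales = _omega_scales(problem)
    w = np.asarray(w_folds, dtype=float) / scales
    return np.concatenate([np.log(x), np.log(np.asarray(s_folds, dtype=float)), w.ravel()])


def _unpack(problem, z):
    P = len(problem.x_names)
    n, K = problem.n_genes, problem.n_folds
    x = np.exp(z[:P])
    s_folds = np.exp(z[P : P + K])
    w_folds = z[P + K :].reshape(K, n) * _omega_scales(problem)
    return x, s_folds, np.clip(w_folds, 0.0, None)


#: minimum relative separation between consecutive fold signal values; keeps
#: the local solver away from coincident-fold (cusp) minima of Psi
MIN_FOLD_SEP = 0.3


def _bounds_and_constraints(problem: DesignProblem, topo: Topology):
    K = problem.n_folds
    scales = _omega_scales(problem)
    bounds = [(np.log(lo), np.log(hi)) for lo, hi in problem.x_bounds]
    for k in range(K):
        lo, hi = problem.box_for_fold(k).s_interval
        bounds.append((np.log(max(lo, 1e-6)), np.log(hi)))
    for k in range(K):
        for (wl, wh), sc in zip(problem.box_for_fold(k).omega_box, scales[k]):
            bounds.append((wl / sc, wh / sc))
    def eq_f(z):
        # equilibrium residuals normalized by promoter strength, so every
        # constraint component is O(1) regardless of expression scale
        x, s_folds, w_folds = _unpack(problem, z)
        model = problem.build_model(topo, x)
        return (np.asarray(model.rhs(w_folds, s_folds)) / np.asarray(model.params.promoter)).ravel()

    def ineq_sep(z):
        P = len(problem.x_names)
        log_s = z[P : P + K]
        return np.diff(log_s) - np.log1p(MIN_FOLD_SEP)

    cons = [{"type": "eq", "fun": eq_f}]
    if K > 1:
        cons.append({"type": "ineq", "fun": ineq_sep})
    return bounds, cons, eq_f


def _sweep_roots(model, s_vals, points_per_axis: int = 5, tol: float = 1e-9):
    """Fast dense root sweep (no stability, no refinement) for diversification."""
    from .model import _dedupe, _lattice_seeds, _newton_polish

    lattice = _lattice_seeds(model, points_per_axis)
    ns = len(lattice)
    W = np.tile(lattice, (len(s_vals), 1))
    S = np.repeat(s_vals, ns)
    W, ok = _newton_polish(model, W, S, tol, max_iter=50)
    scale = np.maximum(model.state_ceiling, 1.0)
    return [
        _dedupe(W[t * ns : (t + 1) * ns][ok[t * ns : (t + 1) * ns]], scale)
        for t in range(len(s_vals))
    ]


def _profile_transitions(s_vals, roots, scale):
    """Fold seeds from equilibrium-count changes: (S midpoint, annihilating-pair midpoint)."""
    counts = np.array([len(r) for r in roots])
    out = []
    for t in np.nonzero(np.diff(counts))[0]:
        many = roots[t] if counts[t] > counts[t + 1] else roots[t + 1]
        if len(many) < 2:
            continue
        pts = np.array(many)
        best, pair = np.inf, None
        for a in range(len(pts)):
            for b in range(a + 1, len(pts)):
                d = np.max(np.abs(pts[a] - pts[b]) / scale)
                if d < best:
                    best, pair = d, 0.5 * (pts[a] + pts[b])
        out.append((0.5 * (s_vals[t] + s_vals[t + 1]), pair))
    return out, counts


def _diversify(problem, topo, rng, n_draws):
    """Global phase of one start: score log-uniform parameter draws by their
    equilibrium-count profile and keep the draw whose diagram already shows
    the most fold transitions (up to the prescribed number)."""
    lo = np.log([b[0] for b in problem.x_bounds])
    hi = np.log([b[1] for b in problem.x_bounds])
    s_lo = min(problem.box_for_fold(k).s_interval[0] for k in range(problem.n_folds))
    s_hi = max(problem.box_for_fold(k).s_interval[1] for k in range(problem.n_folds))
    s_vals = np.concatenate(
        [
            np.geomspace(max(0.5 * s_lo, 1e-3), 0.1 * s_hi, 18, endpoint=False),
            np.linspace(0.1 * s_hi, 1.1 * s_hi, 22),
        ]
    )
    best = None
    draw = 0
    budget = n_draws
    while draw < budget:
        if draw >= 20 and best is None:
            break  # topology shows no multistability at all; move on
        draw += 1
        x = np.exp(rng.uniform(lo, hi))
        model = problem.build_model(topo, x)
        roots = _sweep_roots(model, s_vals)
        scale = np.maximum(model.state_ceiling, 1.0)
        transitions, counts = _profile_transitions(s_vals, roots, scale)
        if not transitions:
            continue
        interior = counts[0] < max(counts) and counts[-1] < max(counts)
        score = (min(len(transitions), problem.n_folds), int(interior))
        if best is None or score > best[0]:
            best = (score, x, transitions)
            if score == (problem.n_folds, 1):
                break
        if best[0] >= (2, 1):
            # interior multistability found: this wiring is promising, so
            # spend a larger draw budget on it (diversification intensifies)
            budget = 3 * n_draws

    def evaluate(x):
        model = problem.build_model(topo, x)
        roots = _sweep_roots(model, s_vals)
        scale = np.maximum(model.state_ceiling, 1.0)
        transitions, counts = _profile_transitions(s_vals, roots, scale)
        if not transitions:
            return None
        interior = counts[0] < max(counts) and counts[-1] < max(counts)
        return (min(len(transitions), problem.n_folds), int(interior)), transitions

    if best is not None and (2, 1) <= best[0] < (problem.n_folds, 1):
        # intensification: log-space mutation hill climb on the profile score;
        # a second bistable range (the neck) often opens under small moves
        score, x, transitions = best
        for _ in range(40):
            x_try = x.copy()
            idx = rng.choice(len(x), size=rng.integers(1, 4), replace=False)
            x_try[idx] *= np.exp(0.4 * rng.standard_normal(len(idx)))
            x_try = np.clip(x_try, np.exp(lo), np.exp(hi))
            out = evaluate(x_try)
            if out is not None and out[0] >= score:
                score, transitions = out
                x = x_try
                best = (score, x, transitions)
                if score == (problem.n_folds, 1):
                    break
    return best


def _presolve_folds(model, s_folds, w_folds, n_iter: int = 25):
    """Pull the sampled fold states toward nearby equilibria (Newton warm start)."""
    W = np.array(w_folds, dtype=float)
    S = np.array(s_folds, dtype=float)
    ceil = np.max(model.state_ceiling)
    for _ in range(n_iter):
        F = model.rhs(W, S)
        J = model.jacobian_state(W, S)
        try:
            step = np.linalg.solve(J, F[..., None])[..., 0]
        except np.linalg.LinAlgError:
            break
        W = np.clip(W - np.clip(step, -ceil, ceil), 0.0, None)
    return [w for w in W]


def verification_grid(problem_or_window, n_low: int = 80, n_high: int = 100) -> np.ndarray:
    """Signal grid for post-verification: log-spaced at low signal, linear above."""
    window = getattr(problem_or_window, "s_window", problem_or_window)
    lo, hi = window
    split = min(20.0, 0.2 * hi)
    return np.concatenate([np.geomspace(max(lo, 1e-3), split, n_low, endpoint=False), np.linspace(split, hi, n_high)])


def _verify(problem: DesignProblem, topo: Topology, x, psi, start_seed, objective_values=None):
    model = problem.build_model(topo, x)
    try:
        diagram = trace_diagram(model, verification_grid(problem))
    except EmptyDiagramError:
        return DesignFailure("empty diagram during verification", start_seed, psi, topo)
    if diagram.label not in problem.target_labels:
        return DesignFailure(f"verified label {diagram.label!r} not in targets", start_seed, psi, topo)
    if len(diagram.saddle_nodes) != problem.n_folds:
        return DesignFailure(
            f"{len(diagram.saddle_nodes)} folds traced, {problem.n_folds} prescribed", start_seed, psi, topo
        )
    folds = sorted(((sn.S, sn.omega) for sn in diagram.saddle_nodes), key=lambda f: f[0])
    if psi is None:
        # fold coordinates are the traced ones; Psi is evaluated there
        psi = float(sum(sn.J for sn in diagram.saddle_nodes))
        if psi > PSI_SUCCESS_TOL:
            return DesignFailure(f"traced folds not exact (psi={psi:.3g})", start_seed, psi, topo)
    for k, (S_k, w_k) in enumerate(folds):
        if not problem.box_for_fold(k).contains(S_k, w_k, rel_slack=0.02):
            return DesignFailure(f"traced fold {k} outside its target box", start_seed, psi, topo)
    return DesignSolution(
        topology=topo,
        params=model.params,
        x=np.asarray(x, dtype=float),
        folds=folds,
        psi=float(psi),
        verified_label=diagram.label,
        start_seed=start_seed,
        objective_values=objective_values or {},
    )


def _assign_fold_seeds(problem, transitions, s_sampled, w_sampled):
    """Initial fold coordinates: detected count transitions where available
    (clipped into their target boxes), sampled box points otherwise."""
    transitions = sorted(transitions, key=lambda t: t[0])
    if len(transitions) > problem.n_folds:
        pick = np.round(np.linspace(0, len(transitions) - 1, problem.n_folds)).astype(int)
        transitions = [transitions[i] for i in pick]
    s0, w0 = [], []
    for k in range(problem.n_folds):
        box = problem.box_for_fold(k)
        if k < len(transitions):
            s_k, w_k = transitions[k]
            s0.append(float(np.clip(s_k, *box.s_interval)))
            w0.append(np.array([np.clip(w, wl, wh) for w, (wl, wh) in zip(w_k, box.omega_box)]))
        else:
            s0.append(s_sampled[k])
            w0.append(w_sampled[k])
    return s0, w0


def solve_single(problem: DesignProblem, start_seed: int, maxiter: int = 100, n_draws: int = 40):
    """One start of the hybrid search; deterministic given the seed.

    A start samples a wiring, then runs a short global (diversification)
    phase -- scoring log-uniform parameter draws by the fold transitions of
    their equilibrium-count profile -- and a local phase: an SLSQP solve of
    the constrained fold-placement problem from the best draw, with fold
    coordinates initialized at the detected transitions.

    Returns a :class:`DesignSolution` on verified success, otherwise a
    :class:`DesignFailure` with diagnostics (never an exception).
    """
    rng = np.random.default_rng(start_seed)
    topo, x0, s0, w0 = _sample_start(problem, rng)
    if not topo.is_connected:
        return DesignFailure("unconnected topology sampled", start_seed, topology=topo)
    best = _diversify(problem, topo, rng, n_draws)
    if best is None:
        return DesignFailure("no fold-bearing parameter draw found", start_seed, topology=topo)
    score, x0, transitions = best
    if score[0] < problem.n_folds:
        return DesignFailure(
            f"best draw shows only {score[0]} fold transitions of {problem.n_folds} prescribed",
            start_seed,
            topology=topo,
        )
    if score == (problem.n_folds, 1):
        # the draw's diagram already shows the prescribed fold structure:
        # verify it directly (the tracer's bisection + Moore-Spence pipeline
        # locates the exact folds) before any parameter movement
        fast = _verify(problem, topo, x0, None, start_seed)
        if isinstance(fast, DesignSolution):
            return fast
    s0, w0 = _assign_fold_seeds(problem, transitions, s0, w0)
    model0 = problem.build_model(topo, x0)
    z0 = _pack(problem, x0, s0, w0)
    bounds, cons, eq_f = _bounds_and_constraints(problem, topo)
    z0 = np.clip(z0, [b[0] for b in bounds], [b[1] for b in bounds])

    def objective(z):
        x, s_folds, w_folds = _unpack(problem, z)
        model = problem.build_model(topo, x)
        return mushroom_objective(model, list(zip(s_folds, w_folds)))

    # iterated local solve: SLSQP's quasi-Newton model is reset on each
    # restart, which reliably finishes off nearly-converged runs; starts
    # that stall at a large Psi are abandoned early
    z = z0
    psi = feas = np.inf
    for round_idx in range(6):
        try:
            with np.errstate(all="ignore"):
                res = minimize(
                    objective,
                    z,
                    method="SLSQP",
                    bounds=bounds,
                    constraints=cons,
                    options={"maxiter": maxiter, "ftol": 1e-12},
                )
        except (ValueError, np.linalg.LinAlgError) as exc:
            return DesignFailure(f"local solver error: {exc}", start_seed, topology=topo)
        z = res.x
        prev_psi = psi
        psi = objective(z)
        feas = float(np.max(np.abs(eq_f(z))))
        if (psi <= PSI_SUCCESS_TOL and feas <= 1e-8) or psi > 0.05 or psi > 0.3 * prev_psi:
            break
    x, s_folds, w_folds = _unpack(problem, z)
    if PSI_SUCCESS_TOL < psi < 0.05 and feas <= 1e-3:
        # the local solve has essentially placed the folds; finish each one
        # exactly with a Moore-Spence solve at fixed parameters (the result
        # satisfies the equilibrium constraints to the polish residual)
        finished = _finish_folds(problem, topo, x, s_folds, w_folds)
        if finished is not None:
            psi, s_folds, w_folds = finished
            feas = float(np.max(np.abs(problem.build_model(topo, x).rhs(np.asarray(w_folds), np.asarray(s_folds)))))
    if psi > PSI_SUCCESS_TOL or feas > 1e-8:
        return DesignFailure(f"not converged (psi={psi:.3g}, |f|/p={feas:.3g})", start_seed, psi, topo)
    return _verify(problem, topo, x, psi, start_seed)


def _finish_folds(problem, topo, x, s_folds, w_folds):
    from .bifurcation import _moore_spence_polish

    model = problem.build_model(topo, x)
    new_s, new_w = [], []
    for k, (s_k, w_k) in enumerate(zip(s_folds, w_folds)):
        J = model.jacobian_state(np.asarray(w_k)[None], np.array([s_k]))[0]
        _, _, Vt = np.linalg.svd(J)
        polished = _moore_spence_polish(model, np.asarray(w_k, dtype=float), float(s_k), Vt[-1])
        if polished is None or not problem.box_for_fold(k).contains(polished[1], polished[0], rel_slack=0.02):
            return None
        new_w.append(polished[0])
        new_s.append(polished[1])
    # all polished folds must be distinct diagram folds, not a shared cusp point
    for a in range(len(new_s)):
        for b in range(a + 1, len(new_s)):
            if abs(new_s[a] - new_s[b]) < 0.05 * min(new_s[a], new_s[b]):
                return None
    new_psi = mushroom_objective(model, list(zip(new_s, new_w)))
    if new_psi > PSI_SUCCESS_TOL:
        return None
    return new_psi, new_s, new_w


# ----------------------------------------------------------------------------
# multistart search
# ----------------------------------------------------------------------------

def _start_seeds(seed: int, n_runs: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_runs)


def multistart_search(problem: DesignProblem, n_runs: int, seed: int | None = None) -> SolutionSet:
    """Seeded multistart over random wirings and parameter starts.

    Aggregates verified solutions and groups them by the canonical wiring
    vector; raw vector equality is used (mirror-symmetric structures count
    as distinct).  Fully replayable: run ``i`` uses the ``i``-th child seed
    of the master seed.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seed = problem.seed if seed is None else seed
    solutions = []
    for child in _start_seeds(seed, n_runs):
        result = solve_single(problem, int(child))
        if isinstance(result, DesignSolution):
            solutions.append(result)
    logger.info("multistart: %d/%d verified successes", len(solutions), n_runs)
    return SolutionSet(solutions=solutions, n_runs=n_runs, seed=seed)


# ----------------------------------------------------------------------------
# enumeration and Pareto analysis
# ----------------------------------------------------------------------------

def enumerate_topologies(n_genes: int, allow_self: bool = True, require_connected: bool = True):
    """All distinct sign assignments over the n^2 edges, optionally filtered.

    ``require_connected`` drops wirings with no gene-to-gene (off-diagonal)
    edge.  Exhaustive enumeration is supported for up to three genes.
    """
    if n_genes > 3:
        raise CapabilityError("exhaustive enumeration supported for n_genes <= 3")
    mask = tuple([True, True, False][:n_genes])
    positions = list(itertools.product(range(n_genes), repeat=2))
    choices = []
    for i, j in positions:
        choices.append((-1, 0, 1) if (i != j or allow_self) else (0,))
    out = []
    for signs in itertools.product(*choices):
        e = np.zeros((n_genes, n_genes), dtype=int)
        for (i, j), s in zip(positions, signs):
            e[i, j] = s
        topo = Topology(tuple(map(tuple, e.tolist())), mask)
        if require_connected and not topo.is_connected:
            continue
        out.append(topo)
    return out


def pareto_front(points, orientation=None):
    """Non-dominated subset of ``(objective_vector, payload)`` pairs.

    ``orientation`` lists ``"min"``/``"max"`` per objective (default: all
    minimized).  Returns the payloads of the front, ordered by the first
    objective (in its stated orientation).
    """
    points = list(points)
    if not points:
        return []
    dim = len(points[0][0])
    orientation = orientation or ("min",) * dim
    if any(len(v) != dim for v, _ in points):
        raise ValueError("all objective vectors must have the same length")
    sign = np.array([1.0 if o == "min" else -1.0 for o in orientation])
    vals = np.array([np.asarray(v, dtype=float) * sign for v, _ in points])
    order = np.lexsort(vals.T[::-1])
    kept_vals, kept_payloads = [], []
    for idx in order:
        v = vals[idx]
        if not any(np.all(u <= v) and np.any(u < v) for u in kept_vals):
            kept_vals.append(v)
            kept_payloads.append(points[idx][1])
    return kept_payloads


# ----------------------------------------------------------------------------
# epsilon-constraint multiobjective scalarization
# ----------------------------------------------------------------------------

def epsilon_constraint_scan(solver, epsilon_grid):
    """Generic epsilon-constraint sweep.

    ``solver(eps)`` must return ``(objective_vector, payload)`` for a
    feasible constrained solve or ``None`` when infeasible.  Returns the
    non-dominated union (all objectives minimized) and the infeasible
    epsilon levels.
    """
    results, infeasible = [], []
    for eps in epsilon_grid:
        out = solver(eps)
        if out is None:
            infeasible.append(eps)
        else:
            results.append(out)
    return pareto_front(results), infeasible


_OBJECTIVES = {
    # protein production burden of a design
    "burden": lambda model: float(np.sum(model.params.promoter)),
    # fold objective itself (constraint-style objective)
    "psi": None,
}


def _objective_value(name: str, model: CircuitModel) -> float:
    try:
        fn = _OBJECTIVES[name]
    except KeyError:
        raise KeyError(f"unknown objective {name!r}; known: {sorted(_OBJECTIVES)}") from None
    if fn is None:
        raise ValueError("psi is imposed as a constraint, not evaluated as a scalar objective")
    return fn(model)


def epsilon_constraint_sweep(
    problem: DesignProblem,
    objective_index: int,
    epsilon_grid,
    n_starts_per_level: int = 25,
    seed: int | None = None,
) -> SolutionSet:
    """Scalarize a multiobjective design problem over a grid of bounds.

    The fold condition ``Psi = 0`` is always imposed as a constraint
    (success tolerance 1e-6); the selected secondary objective is minimized
    while every other secondary objective is bounded by the epsilon level.
    Each level is solved by a short seeded multistart; infeasible levels
    are recorded and the sweep continues.  Returns the non-dominated union.
    """
    secondary = [o for o in problem.objectives if o != "psi"]
    if len(problem.objectives) < 2 or not secondary:
        raise ValueError("epsilon-constraint sweep needs at least two objectives (psi plus one more)")
    sel = secondary[objective_index]
    others = [o for o in secondary if o != sel]
    seed = problem.seed if seed is None else seed

    picked: list[DesignSolution] = []
    for level, eps in enumerate(epsilon_grid):
        best = None
        for child in _start_seeds(seed + level + 1, n_starts_per_level):
            result = solve_single(problem, int(child))
            if not isinstance(result, DesignSolution):
                continue
            model = problem.build_model(result.topology, result.x)
            vals = {o: _objective_value(o, model) for o in secondary}
            if any(vals[o] > eps for o in others):
                continue
            result = replace(result, objective_values=vals)
            if best is None or vals[sel] < best.objective_values[sel]:
                best = result
        if best is None:
            logger.info("epsilon level %g infeasible", eps)
        else:
            picked.append(best)
    front = pareto_front([(tuple(s.objective_values[o] for o in secondary), s) for s in picked])
    return SolutionSet(solutions=front, n_runs=len(epsilon_grid) * n_starts_per_level, seed=seed)


def isola_design(problem: DesignProblem, n_runs: int | None = None, seed: int | None = None) -> SolutionSet:
    """Multistart search targeting an isola (or, with flipped curvature signs,
    a bistable switch).

    Requires ``n_folds = 2`` and curvature-sign conditions in
    ``extra_conditions``: ``("curvature", "+-")`` demands positive inverse
    curvature at the low fold and negative at the high fold (the isola
    signature); ``"-+"`` is the bistable-switch signature.
    """
    if problem.n_folds != 2:
        raise ValueError("isola design requires exactly 2 prescribed folds")
    conds = dict(problem.extra_conditions)
    signs = conds.get("curvature")
    if signs not in ("+-", "-+"):
        raise ValueError('extra_conditions must include ("curvature", "+-") or ("curvature", "-+")')
    target = ("isola",) if signs == "+-" else ("bistable_switch",)
    problem = replace(problem, target_labels=target)
    return multistart_search(problem, n_runs or problem.multistart, seed)


# ----------------------------------------------------------------------------
# default problem configurations (versioned defaults)
# ----------------------------------------------------------------------------

#: default continuous bounds; values in the printed reference sets span
#: roughly 1e-2 .. 1e3, and every printed value lies inside these bands.
DEFAULT_X_BOUNDS = {
    "p0": (10.0, 2000.0),
    "p1": (1.0, 500.0),
    "p2": (10.0, 2000.0),
    "p4": (10.0, 2000.0),
    "p5": (1.0, 500.0),
    "k": (1e-3, 1.0),
    "R1": (50.0, 500.0),
    "R2": (50.0, 500.0),
    "dv": (0.1, 10.0),
    "dw": (0.1, 10.0),
    "K1": (1.0, 300.0),
    "K2": (1.0, 300.0),
}


def _default_boxes(n_genes: int):
    # generous pairwise boxes covering where mushroom folds fall for circuits
    # drawn from the default parameter bands; the low- and high-signal pairs
    # overlap in S (the ordering constraint keeps the folds sorted)
    w_hi = (500.0, 1000.0, 2000.0)[:n_genes]
    box = lambda s: TargetBox(s, tuple((0.0, h) for h in w_hi))  # noqa: E731
    return (box((0.1, 40.0)), box((2.0, 300.0)))


def two_gene_mushroom_problem(multistart: int = 2000, seed: int = 0, **overrides) -> DesignProblem:
    """The two-gene mushroom screen: free signed wiring, signal on both genes."""
    names = ("p0", "p1", "p2", "k", "R1", "R2", "dv", "K1", "K2")
    kw = dict(
        n_genes=2,
        signal_mask=(True, True),
        y_lower=((-1, -1), (-1, -1)),
        y_upper=((1, 1), (1, 1)),
        x_names=names,
        x_bounds=tuple(DEFAULT_X_BOUNDS[n] for n in names),
        boxes=_default_boxes(2),
        n_folds=4,
        multistart=multistart,
        seed=seed,
    )
    kw.update(overrides)
    return DesignProblem(**kw)


def three_gene_mushroom_problem(multistart: int = 10000, seed: int = 0, **overrides) -> DesignProblem:
    """The three-gene mushroom screen (gene W receives no signal input)."""
    names = ("p0", "p1", "p2", "p4", "p5", "k", "R1", "R2", "dv", "dw", "K1", "K2")
    kw = dict(
        n_genes=3,
        signal_mask=(True, True, False),
        y_lower=tuple((-1,) * 3 for _ in range(3)),
        y_upper=tuple((1,) * 3 for _ in range(3)),
        x_names=names,
        x_bounds=tuple(DEFAULT_X_BOUNDS[n] for n in names),
        boxes=_default_boxes(3),
        n_folds=4,
        tying=(("leak[1]", "leak[0]"), ("degradation[0]", 1.0)),
        multistart=multistart,
        seed=seed,
    )
    kw.update(overrides)
    return DesignProblem(**kw)


def default_search_grid(problem: DesignProblem) -> np.ndarray:
    """The verification signal grid for a problem's window."""
    return verification_grid(problem)
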