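"""Saddle-node detection, diagram tracing and classification.

The bifurcation parameter is the signal concentration S.  At an equilibrium
``f(omega, S) = 0`` the extended Jacobian

    Q = [ D_omega f , D_S f ]            (shape N x (N+1))

has, at a fold, a null vector beta (the branch tangent) whose last entry
vanishes: the branch is locally vertical in S.  The scalar objective

    J = beta_{N+1}^2

is therefore zero exactly at a saddle-node point, and is the quantity the
design optimizer drives to zero.

Diagrams are traced by a dense root sweep over a signal grid (not by
pseudo-arclength continuation: isola branches are disconnected from every
boundary equilibrium, so continuation alone cannot find them), linked into
branches by nearest-neighbor matching, and folds are refined by bisection on
the equilibrium count followed by a Moore-Spence root polish.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root as _scipy_root

from .model import CircuitModel, ParameterSet, steady_states, _lattice_seeds, _newton_polish, _dedupe

logger = logging.getLogger(__name__)

__all__ = [
    "DegeneratePointError",
    "EmptyDiagramError",
    "NotApplicableError",
    "SaddleNodePoint",
    "Branch",
    "BifurcationDiagram",
    "extended_jacobian",
    "tangent_vector",
    "saddle_node_objective",
    "trace_diagram",
    "isola_curvature_check",
    "classify_diagram",
    "phase_map",
    "PARAM_ALIASES",
    "with_params",
]


class DegeneratePointError(ValueError):
    """The extended Jacobian does not have a one-dimensional null space."""


class EmptyDiagramError(RuntimeError):
    """No equilibrium was found at any grid signal value."""


class NotApplicableError(ValueError):
    """The requested check does not apply to this diagram."""


# ----------------------------------------------------------------------------
# extended Jacobian, tangent vector, fold objective
# ----------------------------------------------------------------------------

def extended_jacobian(model, omega, S) -> np.ndarray:
    """``[D_omega f, D_S f]`` at ``(omega, S)``, shape ``N x (N+1)``.

    Uses the model's analytic Jacobians when available, otherwise central
    finite differences on ``model.rhs``.
    """
    omega = np.asarray(omega, dtype=float)
    S = float(S)
    if hasattr(model, "jacobian_state") and hasattr(model, "jacobian_signal"):
        J = np.asarray(model.jacobian_state(omega[None], np.array([S])))[0]
        fS = np.asarray(model.jacobian_signal(omega[None], np.array([S])))[0]
    else:
        J, fS = _fd_jacobians(model.rhs, omega, S)
    Q = np.hstack([J, np.asarray(fS, dtype=float)[:, None]])
    if not np.all(np.isfinite(Q)):
        raise ValueError("non-finite extended Jacobian entries at the requested point")
    return Q


def _fd_jacobians(rhs, omega, S, rel_step: float = 1e-6):
    n = omega.shape[-1]
    f0 = np.asarray(rhs(omega, S), dtype=float)
    J = np.empty((n, n))
    for j in range(n):
        h = rel_step * max(abs(omega[j]), 1.0)
        wp, wm = omega.copy(), omega.copy()
        wp[j] += h
        wm[j] -= h
        J[:, j] = (np.asarray(rhs(wp, S)) - np.asarray(rhs(wm, S))) / (2 * h)
    hS = rel_step * max(abs(S), 1.0)
    if S - hS < 0:
        fS = (np.asarray(rhs(omega, S + hS)) - f0) / hS
    else:
        fS = (np.asarray(rhs(omega, S + hS)) - np.asarray(rhs(omega, S - hS))) / (2 * hS)
    return J, fS


def tangent_vector(Q: np.ndarray, gate: float = 1e3) -> np.ndarray:
    """Unit null vector of the extended Jacobian (the branch tangent).

    Computed by SVD.  The null space must be one-dimensional: all N
    singular values of the N x (N+1) matrix must stay above the degeneracy
    gate (relative condition 1/gate^2), otherwise a second null direction
    has opened (e.g. at a cusp).  The sign is fixed so the largest-magnitude
    entry is positive.
    """
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    _, s, Vt = np.linalg.svd(Q)
    if Q.shape[0] >= Q.shape[1]:
        raise DegeneratePointError("extended Jacobian must have shape N x (N+1)")
    # an N x (N+1) matrix has a structural one-dimensional null space only at
    # full row rank: if the smallest of the N singular values also collapses
    # (relative to the gate) the null space is two-dimensional (e.g. a cusp)
    if s[0] <= 0.0 or s[-1] <= s[0] / gate**2:
        raise DegeneratePointError("null space of the extended Jacobian is not one-dimensional")
    beta = Vt[-1]
    imax = int(np.argmax(np.abs(beta)))
    if beta[imax] < 0:
        beta = -beta
    return beta


def saddle_node_objective(model, omega, S, residual_gate: float = 1e-3) -> float:
    """Fold objective ``J = beta_{N+1}^2`` at a (near-)equilibrium point.

    Zero exactly when the equilibrium is a saddle-node with respect to S.
    The point must satisfy the equilibrium residual loosely (``residual_gate``);
    the design optimizer enforces ``f = 0`` as a separate constraint.
    """
    omega = np.asarray(omega, dtype=float)
    res = np.max(np.abs(np.asarray(model.rhs(omega, float(S)))))
    if res > residual_gate:
        raise ValueError(f"point is not near an equilibrium (|f|_inf = {res:.3g})")
    beta = tangent_vector(extended_jacobian(model, omega, S))
    return float(beta[-1] ** 2)


# ----------------------------------------------------------------------------
# diagram data structures
# ----------------------------------------------------------------------------

@dataclass
class SaddleNodePoint:
    """A fold: signal location, state, unit branch tangent and residual J."""

    S: float
    omega: np.ndarray
    beta: np.ndarray
    J: float


@dataclass
class Branch:
    """An ordered sequence of equilibria of constant stability."""

    S: np.ndarray
    states: np.ndarray
    stable: bool

    def interp(self, S: float) -> np.ndarray:
        """Linear interpolation of the branch state at signal ``S`` (within range)."""
        return np.array([np.interp(S, self.S, self.states[:, j]) for j in range(self.states.shape[1])])

    @property
    def s_min(self) -> float:
        return float(self.S[0])

    @property
    def s_max(self) -> float:
        return float(self.S[-1])


@dataclass
class BifurcationDiagram:
    """Traced equilibrium structure over a signal window."""

    branches: list
    saddle_nodes: list
    s_range: tuple
    label: str | None = None
    bistable_ranges: list = field(default_factory=list)
    # component id per branch (branches joined through folds), fold -> branch ids
    components: list = field(default_factory=list)
    fold_branches: list = field(default_factory=list)

    def component_branches(self, cid: int):
        return [b for b, c in zip(self.branches, self.components) if c == cid]

    def component_is_closed(self, cid: int, rel: float = 1e-9) -> bool:
        """A component is closed iff none of its branches reaches the window edge."""
        lo, hi = self.s_range
        span = hi - lo
        for b in self.component_branches(cid):
            if b.s_min <= lo + rel * span or b.s_max >= hi - rel * span:
                return False
        return True

    def component_folds(self, cid: int):
        return [
            sn
            for sn, (b1, b2) in zip(self.saddle_nodes, self.fold_branches)
            if (b1 is not None and self.components[b1] == cid)
            or (b2 is not None and self.components[b2] == cid)
        ]

    def stable_branches_at(self, S: float):
        """Stable branches covering signal ``S`` with their interpolated states."""
        out = []
        for i, b in enumerate(self.branches):
            if b.stable and b.s_min <= S <= b.s_max:
                out.append((i, b.interp(S)))
        return out


# ----------------------------------------------------------------------------
# tracing
# ----------------------------------------------------------------------------

def _equilibria_on_grid(
    model: CircuitModel, s_grid: np.ndarray, points_per_axis: int, tol: float, passes: int = 4
):
    """Dense-seeded equilibria at every grid signal value.

    One Newton batch over the full (grid x lattice) product, followed by
    neighbor-seeding refinement passes: every root found at a grid value
    also seeds its neighboring values.  Equilibria vary continuously along
    a branch, so this recovers roots whose Newton basins are too small for
    the lattice alone and keeps the per-slice counts consistent.
    """
    T = len(s_grid)
    lattice = _lattice_seeds(model, points_per_axis)
    n_seed = len(lattice)
    W = np.tile(lattice, (T, 1))
    S = np.repeat(s_grid, n_seed)
    W, ok = _newton_polish(model, W, S, tol)
    scale = np.maximum(model.state_ceiling, 1.0)
    roots = [
        _dedupe(W[t * n_seed : (t + 1) * n_seed][ok[t * n_seed : (t + 1) * n_seed]], scale)
        for t in range(T)
    ]
    for _ in range(passes):
        seeds, owners = [], []
        for t in range(T):
            for tn in (t - 1, t + 1):
                if 0 <= tn < T:
                    seeds.extend(roots[tn])
                    owners.extend([t] * len(roots[tn]))
        if not seeds:
            break
        Wp, okp = _newton_polish(model, np.asarray(seeds), s_grid[np.asarray(owners)], tol)
        added = False
        for w, good, t in zip(Wp, okp, owners):
            if good and not any(np.max(np.abs(w - u) / scale) < 1e-4 for u in roots[t]):
                roots[t].append(w)
                added = True
        if not added:
            break
    slices = []
    for t in range(T):
        entries = []
        for w in roots[t]:
            J = model.jacobian_state(w[None], np.array([s_grid[t]]))[0]
            entries.append((w, bool(np.all(np.linalg.eigvals(J).real < 0.0))))
        entries.sort(key=lambda e: e[0][0])
        slices.append(entries)
    return slices


def _link_branches(s_grid, slices, scale):
    """Greedy nearest-neighbor continuation of slice equilibria into branches."""
    from scipy.optimize import linear_sum_assignment

    branches: list[dict] = []  # {"S": [...], "W": [...], "stable": bool, "open": bool}
    active: list[int] = []
    for t, entries in enumerate(slices):
        pts = [e[0] for e in entries]
        stb = [e[1] for e in entries]
        if not active:
            matched_pts = set()
        else:
            cost = np.full((len(active), len(pts)), 1e6)
            for a, bi in enumerate(active):
                w_prev = branches[bi]["W"][-1]
                for j, w in enumerate(pts):
                    if stb[j] == branches[bi]["stable"]:
                        d = np.max(np.abs(w - w_prev) / scale)
                        if d < 0.5:
                            cost[a, j] = d
            row, col = linear_sum_assignment(cost)
            matched_pts = set()
            still_active = []
            for a, j in zip(row, col):
                if cost[a, j] < 1e6:
                    bi = active[a]
                    branches[bi]["S"].append(s_grid[t])
                    branches[bi]["W"].append(pts[j])
                    matched_pts.add(j)
                    still_active.append(bi)
            active = still_active
        for j in range(len(pts)):
            if j not in matched_pts:
                branches.append({"S": [s_grid[t]], "W": [pts[j]], "stable": stb[j]})
                active.append(len(branches) - 1)
    return [
        Branch(np.asarray(b["S"], dtype=float), np.asarray(b["W"], dtype=float), b["stable"])
        for b in branches
    ]


def _count_at(model, S, points_per_axis, tol, seeds):
    return len(steady_states(model, S, seeds=seeds, tol=tol, points_per_axis=points_per_axis))


def _bisect_fold(model, s_lo, s_hi, points_per_axis, tol, rel_ds, seeds):
    """Bisection on the equilibrium-count change; returns (s_fold, side_with_more)."""
    c_lo = _count_at(model, s_lo, points_per_axis, tol, seeds)
    c_hi = _count_at(model, s_hi, points_per_axis, tol, seeds)
    while s_hi - s_lo > rel_ds:
        mid = 0.5 * (s_lo + s_hi)
        c_mid = _count_at(model, mid, points_per_axis, tol, seeds)
        if c_mid == c_lo:
            s_lo = mid
        else:
            s_hi, c_hi = mid, c_mid
    more_side = s_lo if c_lo > c_hi else s_hi
    return 0.5 * (s_lo + s_hi), more_side, max(c_lo, c_hi)


def _moore_spence_polish(model, w0, s0, phi0):
    """Solve the fold system f = 0, J phi = 0, |phi|^2 = 1 for (omega, S, phi).

    S is parametrized as exp(sigma) so the root-finder cannot wander into
    negative signal concentrations.
    """
    n = len(w0)

    def system(z):
        w, S, phi = z[:n], np.exp(z[n]), z[n + 1 :]
        f = np.asarray(model.rhs(w[None], np.array([S])))[0]
        J = np.asarray(model.jacobian_state(w[None], np.array([S])))[0]
        return np.concatenate([f, J @ phi, [phi @ phi - 1.0]])

    z0 = np.concatenate([w0, [np.log(max(s0, 1e-12))], phi0])
    with np.errstate(over="ignore"):
        sol = _scipy_root(system, z0, method="hybr")
        residual = np.max(np.abs(system(sol.x)))
    if residual > 1e-9:
        return None
    w, S, _ = sol.x[:n], np.exp(sol.x[n]), sol.x[n + 1 :]
    if not np.isfinite(S) or np.any(w < -1e-8):
        return None
    return np.clip(w, 0.0, None), float(S)


def _make_saddle_node(model, w, S):
    beta = tangent_vector(extended_jacobian(model, w, S))
    return SaddleNodePoint(S=float(S), omega=np.asarray(w, dtype=float), beta=beta, J=float(beta[-1] ** 2))


def _dedupe_folds(saddle_nodes, span, scale, rel_s: float = 1e-3, rel_w: float = 2e-2):
    kept = []
    for sn in saddle_nodes:
        dup = any(
            abs(sn.S - other.S) <= rel_s * span
            and np.max(np.abs(sn.omega - other.omega) / scale) <= rel_w
            for other in kept
        )
        if not dup:
            kept.append(sn)
    return kept


def trace_diagram(
    model: CircuitModel,
    s_grid,
    points_per_axis: int = 8,
    tol: float = 1e-9,
    classify: bool = True,
) -> BifurcationDiagram:
    """Trace all equilibrium branches of ``model`` over a signal grid.

    At every grid S the dense-seeded equilibria are recorded; points are
    linked into branches by nearest-neighbor continuation; every change in
    the equilibrium count is refined by bisection to 1e-6 of the grid span
    and polished into an exact fold by a Moore-Spence solve.  Disconnected
    closed branches (isolas) are retained by construction.
    """
    s_grid = np.asarray(s_grid, dtype=float)
    if len(s_grid) < 50:
        raise ValueError("s_grid must have at least 50 points")
    if np.any(np.diff(s_grid) <= 0):
        raise ValueError("s_grid must be strictly increasing")
    slices = _equilibria_on_grid(model, s_grid, points_per_axis, tol)
    if all(len(s) == 0 for s in slices):
        raise EmptyDiagramError("no equilibrium found at any signal value")
    scale = np.maximum(model.state_ceiling, 1.0)
    branches = _link_branches(s_grid, slices, scale)

    span = s_grid[-1] - s_grid[0]
    rel_ds = 1e-6 * span
    counts = np.array([len(s) for s in slices])
    saddle_nodes = []
    for t in np.nonzero(np.diff(counts))[0]:
        local_seeds = np.array([w for w, _ in slices[t] + slices[t + 1]])
        s_fold, s_more, _ = _bisect_fold(
            model, s_grid[t], s_grid[t + 1], points_per_axis, tol, rel_ds, local_seeds
        )
        # the two annihilating equilibria: closest pair on the many-equilibria side
        eq = steady_states(model, s_more, seeds=local_seeds, tol=tol, points_per_axis=points_per_axis)
        if len(eq) < 2:
            continue
        pts = np.array([w for w, _ in eq])
        best, w_pair = np.inf, None
        for a in range(len(pts)):
            for b in range(a + 1, len(pts)):
                d = np.max(np.abs(pts[a] - pts[b]) / scale)
                if d < best:
                    best, w_pair = d, (pts[a], pts[b])
        w0 = 0.5 * (w_pair[0] + w_pair[1])
        J = model.jacobian_state(w0[None], np.array([s_fold]))[0]
        _, _, Vt = np.linalg.svd(J)
        polished = _moore_spence_polish(model, w0, s_fold, Vt[-1])
        if polished is not None:
            w_f, s_f = polished
            if abs(s_f - s_fold) < 0.05 * span + 1e-9:
                try:
                    saddle_nodes.append(_make_saddle_node(model, w_f, s_f))
                    continue
                except DegeneratePointError:
                    pass
        logger.warning("fold polish failed near S=%.6g; keeping bisection estimate", s_fold)
        saddle_nodes.append(_make_saddle_node(model, w0, s_fold))
    saddle_nodes.sort(key=lambda sn: sn.S)
    saddle_nodes = _dedupe_folds(saddle_nodes, span, scale)

    fold_branches = [_attach_fold(sn, branches, s_grid, scale) for sn in saddle_nodes]
    components = _components(len(branches), fold_branches)
    bistable = _bistable_ranges(s_grid, slices, saddle_nodes)
    diagram = BifurcationDiagram(
        branches=branches,
        saddle_nodes=saddle_nodes,
        s_range=(float(s_grid[0]), float(s_grid[-1])),
        bistable_ranges=bistable,
        components=components,
        fold_branches=fold_branches,
    )
    if classify:
        classify_diagram(diagram)
    return diagram


def _local_step(s_grid, s):
    """Grid spacing in the neighborhood of ``s`` (grids may be nonuniform)."""
    idx = int(np.clip(np.searchsorted(s_grid, s), 1, len(s_grid) - 1))
    return float(s_grid[idx] - s_grid[idx - 1])


def _attach_fold(sn, branches, s_grid, scale):
    """The two branches whose endpoints terminate at this fold."""
    step = _local_step(s_grid, sn.S)
    cands = []
    for i, b in enumerate(branches):
        for s_end, w_end in ((b.s_min, b.states[0]), (b.s_max, b.states[-1])):
            if abs(s_end - sn.S) <= 1.5 * step:
                cands.append((np.max(np.abs(w_end - sn.omega) / scale), i))
    cands.sort()
    picked = []
    for d, i in cands:
        if d < 0.3 and i not in picked:
            picked.append(i)
        if len(picked) == 2:
            break
    while len(picked) < 2:
        picked.append(None)
    return tuple(picked)


def _components(n_branches, fold_branches):
    parent = list(range(n_branches))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for b1, b2 in fold_branches:
        if b1 is not None and b2 is not None:
            parent[find(b1)] = find(b2)
    return [find(i) for i in range(n_branches)]


def _bistable_ranges(s_grid, slices, saddle_nodes):
    """S-intervals with >= 2 coexisting stable equilibria, edges snapped to folds."""
    stable_counts = np.array([sum(1 for _, st in s if st) for s in slices])
    fold_s = [sn.S for sn in saddle_nodes]
    ranges = []
    in_range = False
    start = None
    for t, c in enumerate(stable_counts):
        if c >= 2 and not in_range:
            in_range, start = True, s_grid[t]
        elif c < 2 and in_range:
            in_range = False
            ranges.append((_snap(start, fold_s, s_grid), _snap(s_grid[t - 1], fold_s, s_grid)))
    if in_range:
        ranges.append((_snap(start, fold_s, s_grid), float(s_grid[-1])))
    return ranges


def _snap(s, fold_s, s_grid):
    step = _local_step(s_grid, s)
    for f in fold_s:
        if abs(f - s) <= 1.5 * step:
            return float(f)
    return float(s)


# ----------------------------------------------------------------------------
# curvature check and classification
# ----------------------------------------------------------------------------

def _closed_two_fold_component(diagram: BifurcationDiagram):
    for cid in set(diagram.components):
        if diagram.component_is_closed(cid) and len(diagram.component_folds(cid)) == 2:
            return cid
    return None


def _local_curvature(branch_pts_S, branch_pts_w, s_fold, w_fold, n_pts: int = 5):
    """Quadratic-fit curvature d^2 S / d w^2 of the branch near a fold."""
    d = np.abs(branch_pts_S - s_fold)
    idx = np.argsort(d)[:n_pts]
    w = branch_pts_w[idx]
    S = branch_pts_S[idx]
    if len(set(np.round(w, 12))) < 3:
        return 0.0
    coeff = np.polyfit(w - w_fold, S - s_fold, 2)
    return 2.0 * coeff[0]


def isola_curvature_check(diagram: BifurcationDiagram, readout: int | None = None) -> bool:
    """Curvature signature distinguishing an isola from a bistable S-curve.

    On an isola the two folds are the signal extremes of one closed
    equilibrium curve: S is locally a minimum of the branch at the low fold
    S1 (inverse-function curvature d^2 S / d w^2 > 0) and a maximum at the
    high fold S2 (< 0), and the whole curve lies inside [S1, S2].  A
    bistable switch fails the signature: its branch curve continues beyond
    the fold signal values instead of closing between them.
    """
    cid = _closed_two_fold_component(diagram)
    if cid is not None:
        folds = sorted(diagram.component_folds(cid), key=lambda sn: sn.S)
        pool = diagram.component_branches(cid)
    else:
        if len(diagram.saddle_nodes) < 2:
            raise NotApplicableError("curvature check requires two saddle nodes")
        folds = sorted(diagram.saddle_nodes, key=lambda sn: sn.S)
        folds = [folds[0], folds[-1]]
        pool = [
            b
            for i, b in enumerate(diagram.branches)
            if any(i in fb for fb in diagram.fold_branches)
        ] or diagram.branches
    s1, s2 = folds[0].S, folds[1].S
    tol = 0.02 * (s2 - s1) + 1e-12
    s_lo = min(b.s_min for b in pool)
    s_hi = max(b.s_max for b in pool)
    if s_lo < s1 - tol or s_hi > s2 + tol:
        return False  # the fold-bearing curve extends beyond its folds: not a closed loop
    signs = []
    for sn in folds:
        S_all = np.concatenate([b.S for b in pool])
        W_all = np.vstack([b.states for b in pool])
        if readout is None:
            # pick the state coordinate with most variation near the fold
            near = np.argsort(np.abs(S_all - sn.S))[: max(5, len(S_all) // 10)]
            j = int(np.argmax(np.ptp(W_all[near], axis=0)))
        else:
            j = readout
        signs.append(np.sign(_local_curvature(S_all, W_all[:, j], sn.S, sn.omega[j])))
    return bool(signs[0] > 0 and signs[1] < 0)


def _unique_state_at(diagram, slices_cache, model, S, points_per_axis, tol):
    eq = steady_states(model, S, tol=tol, points_per_axis=points_per_axis)
    return eq


def classify_diagram(diagram: BifurcationDiagram, readout: int = 0) -> str:
    """Assign a taxonomy label to a traced diagram.

    mushroom: four folds producing two disjoint interior bistable signal
    ranges with an intermediate branch between them; inverted_mushroom when
    that branch sits at lower expression than the outer locus; isola: a
    closed two-fold branch (passing the curvature signature) coexisting with
    a fold-free open branch; bistable_switch: two interior folds, one
    bistable range, open branches; incomplete_mushroom_*: a head truncated
    by the signal window; monostable: a unique equilibrium everywhere.
    Anything ambiguous is labeled ``other``.
    """
    lo, hi = diagram.s_range
    span = hi - lo
    F = len(diagram.saddle_nodes)
    n_br = len(diagram.branches)
    label = "other"
    fold_s = [sn.S for sn in diagram.saddle_nodes]

    def touches(rng, side):
        # a bistable range is truncated on a side iff that edge is not anchored
        # to a fold (the tracer snaps interior edges exactly onto fold locations)
        edge = rng[0] if side == "left" else rng[1]
        return not any(abs(edge - f) <= 1e-9 * max(span, 1.0) for f in fold_s)

    closed_cid = _closed_two_fold_component(diagram)
    open_foldfree = any(
        not any(i in fb for fb in diagram.fold_branches)
        and b.s_min <= lo + 1e-9 * span
        and b.s_max >= hi - 1e-9 * span
        for i, b in enumerate(diagram.branches)
    )
    if F == 0:
        if n_br == 1:
            label = "monostable"
    elif closed_cid is not None and open_foldfree:
        try:
            label = "isola" if isola_curvature_check(diagram) else "other"
        except NotApplicableError:
            label = "other"
    elif F == 4 and len(diagram.bistable_ranges) == 2:
        r1, r2 = diagram.bistable_ranges
        if touches(r1, "left") or touches(r2, "right"):
            label = "incomplete_mushroom_left" if touches(r1, "left") else "incomplete_mushroom_right"
        else:
            neck = _neck_readouts(diagram, r1, r2, readout)
            if neck is not None:
                mid_val, outer_val = neck
                label = "mushroom" if mid_val > outer_val else "inverted_mushroom"
    elif F in (2, 3) and len(diagram.bistable_ranges) >= 1:
        left_trunc = any(touches(r, "left") for r in diagram.bistable_ranges)
        right_trunc = any(touches(r, "right") for r in diagram.bistable_ranges)
        if left_trunc and not right_trunc:
            label = "incomplete_mushroom_left"
        elif right_trunc and not left_trunc:
            label = "incomplete_mushroom_right"
        elif F == 2 and len(diagram.bistable_ranges) == 1 and not (left_trunc or right_trunc):
            label = "bistable_switch"
    diagram.label = label
    return label


def _neck_readouts(diagram, r1, r2, readout):
    """Readout value of the sole intermediate-branch state in the neck vs the outer locus."""
    s_neck = 0.5 * (r1[1] + r2[0])
    lo, hi = diagram.s_range
    at_neck = diagram.stable_branches_at(s_neck)
    if len(at_neck) != 1:
        return None
    neck_branch, neck_state = at_neck[0]
    outer_vals = []
    for s_edge in (lo, hi):
        here = diagram.stable_branches_at(s_edge)
        if len(here) != 1:
            return None
        bid, state = here[0]
        if bid == neck_branch:
            return None  # intermediate locus must be a different branch than the outer one
        outer_vals.append(state[readout])
    return float(neck_state[readout]), float(np.mean(outer_vals))


# ----------------------------------------------------------------------------
# parameter sweeps
# ----------------------------------------------------------------------------

PARAM_ALIASES = {
    "p0": "promoter[0]",
    "p1": "leak[0]",
    "p2": "promoter[1]",
    "p3": "leak[1]",
    "p4": "promoter[2]",
    "p5": "leak[2]",
    "k": "interaction",
    "R1": "tf_total[0]",
    "R2": "tf_total[1]",
    "R3": "tf_total[2]",
    "K1": "dissociation[0]",
    "K2": "dissociation[1]",
    "K3": "dissociation[2]",
    "du": "degradation[0]",
    "dv": "degradation[1]",
    "dw": "degradation[2]",
}


def with_params(model: CircuitModel, **overrides) -> CircuitModel:
    """A copy of ``model`` with named parameters replaced.

    Accepts canonical keys (``degradation[1]``, ``interaction``) or the
    conventional short aliases (``dv``, ``k``, ``p0``, ``R1``...).
    """
    from .model import _apply_assumptions

    rules = {PARAM_ALIASES.get(k, k): v for k, v in overrides.items()}
    params = _apply_assumptions(model.params, rules)
    return CircuitModel(model.topology, params)


def phase_map(model_template: CircuitModel, axis1, axis2, s_grid, **trace_kw):
    """Diagram taxonomy over a 2-D parameter grid.

    ``axis1`` and ``axis2`` are ``(name, grid)`` pairs; the returned matrix of
    labels has shape ``(len(grid1), len(grid2))`` aligned to the grids.
    Per-cell tracing failures are recorded as ``"error"`` labels and never
    abort the sweep.
    """
    name1, grid1 = axis1
    name2, grid2 = axis2
    for name in (name1, name2):
        key = PARAM_ALIASES.get(name, name)
        base = key.split("[")[0]
        if base != "interaction" and not hasattr(model_template.params, base):
            raise KeyError(f"unknown parameter {name!r}")
    labels = np.empty((len(grid1), len(grid2)), dtype=object)
    for i, v1 in enumerate(grid1):
        for j, v2 in enumerate(grid2):
            try:
                m = with_params(model_template, **{name1: v1, name2: v2})
                labels[i, j] = trace_diagram(m, s_grid, **trace_kw).label
            except Exception as exc:  # noqa: BLE001 - sweep must not abort
                logger.warning("phase-map cell (%s=%g, %s=%g) failed: %s", name1, v1, name2, v2, exc)
                labels[i, j] = "error"
    return labels
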