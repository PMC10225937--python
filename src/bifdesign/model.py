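"""Gene-circuit superstructure model.

A circuit is a set of ``n`` genes whose protein concentrations
``omega = (omega_1, ..., omega_n)`` evolve under thermodynamic
(promoter-occupancy) kinetics,

    d omega_i / dt = p_i * N_i / D_i - d_i * omega_i,

with regulatory numerator and denominator

    N_i = l_i + [i receives the signal] * q_i(S) + sum_{j activates i} k * omega_j^m,
    D_i = 1 + N_i + sum_{j represses i} k * omega_j^m.

``q_i(S) = R_i S^h / (K_i^h + S^h)`` is the Hill-type concentration of
signal-bound activating transcription factor (cooperativity ``h = 2`` by
default), regulators bind as dimers (``m = 2``), and a single shared rate
constant ``k`` sets the strength of every active regulatory edge.

Wiring is a signed integer matrix ``y`` with ``y[i][j] = +1`` (gene j
activates gene i), ``-1`` (represses) or ``0`` (no regulation).  All model
evaluations are vectorized over batches of states so that dense root sweeps
(needed to find disconnected equilibrium branches) stay cheap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Topology",
    "ParameterSet",
    "CircuitModel",
    "signal_input",
    "build_rhs",
    "steady_states",
]


# ----------------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class Topology:
    """Signed wiring of a gene circuit.

    Parameters
    ----------
    edges
        ``(n, n)`` integer matrix, ``edges[i][j] in {-1, 0, +1}``: the effect
        of gene ``j`` on gene ``i``.
    signal_mask
        Boolean vector marking the genes that receive the activating input
        signal S.  The superstructure default is signal on genes U and V
        (and not on W for three-gene circuits).
    """

    edges: tuple
    signal_mask: tuple

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=int)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError("edges must be a square matrix")
        if not np.isin(e, (-1, 0, 1)).all():
            raise ValueError("edge entries must be -1, 0 or +1")
        m = np.asarray(self.signal_mask, dtype=bool)
        if m.shape != (e.shape[0],):
            raise ValueError("signal_mask length must equal the gene count")
        object.__setattr__(self, "edges", tuple(map(tuple, e.tolist())))
        object.__setattr__(self, "signal_mask", tuple(m.tolist()))

    @property
    def n_genes(self) -> int:
        return len(self.edges)

    @property
    def edge_matrix(self) -> np.ndarray:
        return np.asarray(self.edges, dtype=int)

    @property
    def n_connections(self) -> int:
        return int(np.count_nonzero(self.edge_matrix))

    @property
    def is_connected(self) -> bool:
        """True iff at least one off-diagonal (gene-to-gene) edge is present."""
        e = self.edge_matrix
        return bool(np.count_nonzero(e - np.diag(np.diag(e))))

    def to_vector(self) -> np.ndarray:
        """Flatten to the 9-vector convention ``(y_uu, y_vu, y_wu, y_uv, ...)``.

        The vector lists target genes fastest (column-major in ``edges``),
        i.e. first the effects of gene u on u, v, w, then of gene v, etc.
        """
        return self.edge_matrix.flatten(order="F")

    @classmethod
    def from_vector(cls, vec, signal_mask) -> "Topology":
        vec = np.asarray(vec, dtype=int)
        n = int(round(len(vec) ** 0.5))
        if n * n != len(vec):
            raise ValueError("topology vector length must be a square number")
        return cls(tuple(map(tuple, vec.reshape((n, n), order="F").tolist())), tuple(signal_mask))


@dataclass(frozen=True)
class ParameterSet:
    """Kinetic parameters of a circuit.

    ``promoter`` (p_i, concentration/time), ``leak`` (l_i, dimensionless),
    ``interaction`` (shared k, 1/concentration^m), ``tf_total`` (R_i,
    concentration), ``dissociation`` (K_i, concentration) and ``degradation``
    (d_i, 1/time) are per-gene arrays except the shared ``interaction``.
    ``hill_n`` is the signal cooperativity and ``dimer_exponent`` the
    regulator binding multiplicity; both default to 2.
    """

    promoter: tuple
    leak: tuple
    interaction: float
    tf_total: tuple
    dissociation: tuple
    degradation: tuple
    hill_n: int = 2
    dimer_exponent: int = 2

    def __post_init__(self):
        for name in ("promoter", "leak", "tf_total", "dissociation", "degradation"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, tuple(arr.tolist()))
        n = len(self.promoter)
        for name in ("leak", "tf_total", "dissociation", "degradation"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one entry per gene")
        if min(self.promoter) <= 0 or min(self.degradation) <= 0:
            raise ValueError("promoter strengths and degradation rates must be positive")
        if min(self.tf_total) <= 0 or min(self.dissociation) <= 0:
            raise ValueError("TF totals and dissociation constants must be positive")
        if min(self.leak) < 0:
            raise ValueError("leakiness must be nonnegative")
        if self.interaction < 0:
            raise ValueError("interaction strength must be nonnegative")
        if self.hill_n < 1 or self.dimer_exponent < 1:
            raise ValueError("hill_n and dimer_exponent must be >= 1")

    @property
    def n_genes(self) -> int:
        return len(self.promoter)


def _apply_assumptions(params: ParameterSet, assumptions: dict) -> ParameterSet:
    """Apply tying rules such as ``{"leak[1]": "leak[0]", "degradation[0]": 1.0}``.

    A value may be a number (fixed) or a string naming another entry
    (tied).  Ties are resolved against the already-updated arrays, in
    insertion order.
    """
    arrays = {
        name: list(getattr(params, name))
        for name in ("promoter", "leak", "tf_total", "dissociation", "degradation")
    }
    scalars = {"interaction": params.interaction}

    def parse(key):
        if "[" in key:
            name, idx = key[:-1].split("[")
            return name, int(idx)
        return key, None

    for key, value in assumptions.items():
        name, idx = parse(key)
        if isinstance(value, str):
            src, sidx = parse(value)
            value = arrays[src][sidx] if sidx is not None else scalars[src]
        if idx is None:
            if name not in scalars:
                raise KeyError(f"unknown scalar parameter {key!r}")
            scalars[name] = float(value)
        else:
            if name not in arrays:
                raise KeyError(f"unknown parameter array {key!r}")
            arrays[name][idx] = float(value)

    return replace(
        params,
        interaction=scalars["interaction"],
        **{k: tuple(v) for k, v in arrays.items()},
    )


@dataclass(frozen=True)
class CircuitModel:
    """A wired, parametrized circuit: right-hand side and Jacobians.

    ``assumptions`` are tying rules applied once at construction (the
    default search space ties the two leakiness values and fixes the first
    degradation rate to one).
    """

    topology: Topology
    params: ParameterSet
    assumptions: dict | None = None

    # caches of dense arrays, built in __post_init__
    _act: np.ndarray = field(init=False, repr=False, compare=False)
    _rep: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.params.n_genes != self.topology.n_genes:
            raise ValueError("parameter arrays and topology disagree on the gene count")
        if self.assumptions:
            object.__setattr__(self, "params", _apply_assumptions(self.params, self.assumptions))
        e = self.topology.edge_matrix
        object.__setattr__(self, "_act", (e == 1).astype(float))
        object.__setattr__(self, "_rep", (e == -1).astype(float))

    @property
    def n_genes(self) -> int:
        return self.topology.n_genes

    @property
    def state_ceiling(self) -> np.ndarray:
        """Componentwise bound p_i/d_i that trajectories cannot exceed (production <= p_i)."""
        return np.asarray(self.params.promoter) / np.asarray(self.params.degradation)

    # -- vectorized kinetics ------------------------------------------------

    def _terms(self, omega, S):
        p = self.params
        omega = np.asarray(omega, dtype=float)
        S = np.asarray(S, dtype=float)
        q = np.where(
            np.asarray(self.topology.signal_mask),
            signal_input(S[..., None], np.asarray(p.tf_total), np.asarray(p.dissociation), p.hill_n),
            0.0,
        )
        wm = omega ** p.dimer_exponent
        act = p.interaction * wm @ self._act.T
        rep = p.interaction * wm @ self._rep.T
        N = np.asarray(p.leak) + q + act
        D = 1.0 + N + rep
        return N, D, q

    def rhs(self, omega, S):
        """dω/dt; ``omega`` may be ``(..., n)``-batched, with broadcastable S."""
        p = self.params
        N, D, _ = self._terms(omega, S)
        return np.asarray(p.promoter) * N / D - np.asarray(p.degradation) * np.asarray(omega, dtype=float)

    def jacobian_state(self, omega, S):
        """Analytic ∂f/∂ω with shape ``(..., n, n)``."""
        p = self.params
        omega = np.asarray(omega, dtype=float)
        N, D, _ = self._terms(omega, S)
        m = p.dimer_exponent
        dwm = m * p.interaction * omega ** (m - 1)  # d(k w_j^m)/dw_j
        Np = self._act * dwm[..., None, :]
        Dp = (self._act + self._rep) * dwm[..., None, :]
        J = np.asarray(p.promoter)[:, None] * (Np * D[..., :, None] - N[..., :, None] * Dp) / D[..., :, None] ** 2
        return J - np.eye(self.n_genes) * np.asarray(p.degradation)[:, None]

    def jacobian_signal(self, omega, S):
        """Analytic ∂f/∂S with shape ``(..., n)``."""
        p = self.params
        S = np.asarray(S, dtype=float)
        N, D, _ = self._terms(omega, S)
        R = np.asarray(p.tf_total)
        K = np.asarray(p.dissociation)
        h = p.hill_n
        with np.errstate(divide="ignore", invalid="ignore"):
            qp = R * h * K ** h * S[..., None] ** (h - 1) / (K ** h + S[..., None] ** h) ** 2
        qp = np.where(np.asarray(self.topology.signal_mask), np.nan_to_num(qp), 0.0)
        return np.asarray(p.promoter) * qp * (D - N) / D ** 2


# ----------------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------------

def signal_input(S, R, K, n: int = 2):
    """Hill response ``R * S^n / (K^n + S^n)`` of the signal-bound activator.

    Monotone nondecreasing in S and bounded by the total TF concentration R.
    """
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("signal concentration must be nonnegative")
    if np.any(np.asarray(R, dtype=float) <= 0) or np.any(np.asarray(K, dtype=float) <= 0):
        raise ValueError("R and K must be positive")
    R = np.asarray(R, dtype=float)
    with np.errstate(over="ignore", invalid="ignore"):
        Sn = S ** n
        out = R * Sn / (np.asarray(K, dtype=float) ** n + Sn)
    # saturated limit: S^n overflows to inf, where the response equals R
    return np.where(np.isnan(out) & np.isinf(np.broadcast_to(Sn, np.shape(out))), np.broadcast_to(R, np.shape(out)), out)


def build_rhs(model: CircuitModel):
    """Return the vector field ``f(omega, S)`` of the circuit as a callable."""
    return model.rhs


def _lattice_seeds(model: CircuitModel, points_per_axis: int = 8) -> np.ndarray:
    hi = model.state_ceiling
    axes = [np.linspace(0.0, h, points_per_axis) for h in hi]
    return np.array(list(itertools.product(*axes)))


def _newton_polish(model: CircuitModel, W: np.ndarray, S, tol: float, max_iter: int = 60):
    """Damped Newton iteration on a batch of states; returns (states, converged)."""
    W = np.array(W, dtype=float)
    S = np.broadcast_to(np.asarray(S, dtype=float), W.shape[:-1]).copy()
    ceil = np.max(model.state_ceiling)
    active = np.ones(W.shape[:-1], dtype=bool)
    for _ in range(max_iter):
        F = model.rhs(W, S)
        active = np.max(np.abs(F), axis=-1) > 0.1 * tol
        if not active.any():
            break
        J = model.jacobian_state(W[active], S[active])
        try:
            step = np.linalg.solve(J, F[active][..., None])[..., 0]
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -ceil, ceil)
        W[active] = np.clip(W[active] - step, -1e-12, None)
    F = model.rhs(W, S)
    ok = np.all(np.isfinite(F), axis=-1) & (np.max(np.abs(F), axis=-1) <= tol)
    return np.clip(W, 0.0, None), ok


def _dedupe(states: np.ndarray, scale: np.ndarray, rel_tol: float = 1e-4):
    out: list[np.ndarray] = []
    for w in states:
        if not any(np.max(np.abs(w - u) / scale) < rel_tol for u in out):
            out.append(w)
    return out


def steady_states(
    model: CircuitModel,
    S: float,
    seeds=None,
    tol: float = 1e-9,
    points_per_axis: int = 8,
):
    """All nonnegative equilibria of the circuit at signal level ``S``.

    A fixed lattice of Newton seeds over ``[0, p_i/d_i]`` per coordinate
    (optionally augmented with user seeds) is polished to ``|f|_inf <= tol``
    and deduplicated at relative distance 1e-4.  Dense seeding is essential:
    isola branches are disconnected from every boundary equilibrium, so
    continuation from a single start cannot find them.

    Returns a list of ``(omega, stable)`` pairs, ``stable`` from the
    eigenvalues of the state Jacobian (all real parts negative).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    lattice = _lattice_seeds(model, points_per_axis)
    if seeds is not None:
        seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
        lattice = np.vstack([lattice, seeds])
    W, ok = _newton_polish(model, lattice, float(S), tol)
    scale = np.maximum(model.state_ceiling, 1.0)
    roots = _dedupe(W[ok], scale)
    result = []
    for w in roots:
        J = model.jacobian_state(w[None], np.array([float(S)]))[0]
        eig = np.linalg.eigvals(J)
        result.append((w, bool(np.all(eig.real < 0.0))))
    return result
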