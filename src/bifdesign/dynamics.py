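"""Dynamic simulation of circuits under time-varying signals.

Demonstrates the functional behaviors of the designed diagrams: the
mushroom as a pulse-intensity sensor and timer (activation only for
intermediate pulse heights, delayed by the saddle-node ghost), and the
isola as an irreversible extreme-value detector under noisy signals.

ON/OFF assignment is by branch identity, not by an expression threshold:
the intermediate (head or isola) stable branch is ON, the outer open
stable locus is OFF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .bifurcation import BifurcationDiagram, trace_diagram, with_params
from .design import verification_grid
from .model import CircuitModel

logger = logging.getLogger(__name__)

__all__ = [
    "SignalProgram",
    "Trajectory",
    "simulate",
    "classify_final_state",
    "activation_map",
    "isola_memory_demo",
]


@dataclass(frozen=True)
class SignalProgram:
    """A time-varying signal S(t).

    kinds: ``constant`` (level ``s_min``); ``gaussian_pulse``,
    ``S(t) = s_min + (s_max - s_min) exp(-((t - center)/tau)^2 / 2)``;
    ``wiener``, a driftless random walk with diffusion ``sigma`` started at
    the midpoint of ``(s_min, s_max)``, precomputed at fixed steps ``dt``
    (seeded), held piecewise-constant between steps and clamped at S >= 0.
    """

    kind: str = "constant"
    s_min: float = 10.0
    s_max: float = 100.0
    center: float = 100.0
    tau: float = 20.0
    dt: float = 0.01
    sigma: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("constant", "gaussian_pulse", "wiener"):
            raise ValueError(f"unknown signal kind {self.kind!r}")
        if self.s_min < 0:
            raise ValueError("signal must be nonnegative")

    def path(self, t_span):
        """Return a callable S(t) over ``t_span``."""
        if self.kind == "constant":
            level = self.s_min
            return lambda t: level
        if self.kind == "gaussian_pulse":
            return lambda t: self.s_min + (self.s_max - self.s_min) * np.exp(
                -0.5 * ((t - self.center) / self.tau) ** 2
            )
        t0, t1 = t_span
        n_steps = int(np.ceil((t1 - t0) / self.dt)) + 1
        rng = np.random.default_rng(self.seed)
        increments = self.sigma * np.sqrt(self.dt) * rng.standard_normal(n_steps)
        s = 0.5 * (self.s_min + self.s_max) + np.concatenate([[0.0], np.cumsum(increments)])
        s = np.maximum(_reflect_at_zero(s), 0.0)

        def S(t):
            idx = np.clip(((np.asarray(t) - t0) / self.dt).astype(int), 0, n_steps)
            return s[idx]

        return S


def _reflect_at_zero(s):
    # reflecting the walk keeps the signal a nonnegative diffusion rather than absorbing it at 0
    return np.abs(s)


@dataclass
class Trajectory:
    """An integrated path: times, per-gene states, signal and detected events."""

    times: np.ndarray
    states: np.ndarray  # (time, genes)
    signal: np.ndarray
    events: list = field(default_factory=list)

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    @property
    def final_signal(self) -> float:
        return float(self.signal[-1])


def simulate(
    model: CircuitModel,
    signal: SignalProgram,
    t_span=(0.0, 200.0),
    initial_state=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_out: int = 400,
) -> Trajectory:
    """Integrate the circuit ODEs under ``signal`` with a stiff-capable solver.

    For Wiener signals the path is precomputed at fixed steps (seeded) and
    held piecewise-constant, so the run is exactly reproducible; the solver
    step is then capped at the signal step scale.
    """
    if initial_state is None:
        raise ValueError("initial_state is required")
    w0 = np.asarray(initial_state, dtype=float)
    if np.any(w0 < 0):
        raise ValueError("initial state must be nonnegative")
    S_of_t = signal.path(t_span)

    def rhs(t, w):
        return model.rhs(np.clip(w, 0.0, None), float(np.asarray(S_of_t(t))))

    kwargs = {}
    if signal.kind == "wiener":
        # the signal path is noise-dominated; resolving it below half a time
        # unit costs far more accuracy than the state dynamics possess
        kwargs["max_step"] = 0.5
        rtol, atol = max(rtol, 1e-6), max(atol, 1e-8)
    sol = solve_ivp(rhs, t_span, w0, method="LSODA", rtol=rtol, atol=atol,
                    t_eval=np.linspace(*t_span, n_out), **kwargs)
    if not sol.success:
        raise RuntimeError(f"integration failed at t={sol.t[-1] if len(sol.t) else t_span[0]:.4g}: {sol.message}")
    states = np.clip(sol.y.T, 0.0, None)
    sig = np.asarray([float(np.asarray(S_of_t(t))) for t in sol.t])
    return Trajectory(times=sol.t, states=states, signal=sig)


# ----------------------------------------------------------------------------
# branch-identity classification
# ----------------------------------------------------------------------------

def _branch_roles(diagram: BifurcationDiagram):
    """ON = stable branches interior to the window (head/isola); OFF = boundary-touching."""
    lo, hi = diagram.s_range
    tol = 1e-9 * (hi - lo)
    on, off = [], []
    for i, b in enumerate(diagram.branches):
        if not b.stable:
            continue
        touches = b.s_min <= lo + tol or b.s_max >= hi - tol
        (off if touches else on).append(i)
    return on, off


def classify_final_state(trajectory: Trajectory, diagram: BifurcationDiagram, rel_tol: float = 0.05) -> str:
    """Assign the trajectory's final state to ON, OFF or other.

    The final state is matched to the nearest stable branch of the diagram
    at the final signal value (relative distance at most ``rel_tol``); the
    branch's identity (intermediate locus vs outer locus) gives the label.
    """
    s_f = trajectory.final_signal
    lo, hi = diagram.s_range
    if not (lo <= s_f <= hi):
        raise ValueError(f"final signal {s_f:.4g} outside the diagram window [{lo:.4g}, {hi:.4g}]")
    on, off = _branch_roles(diagram)
    scale = np.maximum(np.vstack([b.states for b in diagram.branches]).max(axis=0), 1.0)
    w_f = trajectory.final_state
    best = (np.inf, "other")
    for bid, state in diagram.stable_branches_at(s_f):
        d = float(np.max(np.abs(state - w_f) / scale))
        role = "ON" if bid in on else ("OFF" if bid in off else "other")
        if d < best[0]:
            best = (d, role)
    return best[1] if best[0] <= rel_tol else "other"


def _off_state_at(diagram: BifurcationDiagram, S: float) -> np.ndarray:
    _, off = _branch_roles(diagram)
    for bid, state in diagram.stable_branches_at(S):
        if bid in off:
            return state
    raise ValueError(f"no outer (OFF) stable branch at S={S:.4g}")


def _on_state_at(diagram: BifurcationDiagram, S: float) -> np.ndarray:
    on, _ = _branch_roles(diagram)
    for bid, state in diagram.stable_branches_at(S):
        if bid in on:
            return state
    raise ValueError(f"no intermediate (ON) stable branch at S={S:.4g}")


def activation_map(
    model: CircuitModel,
    tau_grid,
    smax_grid,
    s_min: float = 10.0,
    diagram: BifurcationDiagram | None = None,
) -> np.ndarray:
    """Stable-activation map of a mushroom under Gaussian signal pulses.

    Entry ``[i, j]`` is True when a pulse of duration ``tau_grid[i]`` and
    peak ``smax_grid[j]`` leaves the circuit on the intermediate (ON)
    branch.  The circuit starts on the outer (OFF) branch at the baseline
    signal.  Per-cell simulation failures are recorded as False and logged;
    the sweep never aborts.
    """
    if diagram is None:
        diagram = trace_diagram(model, verification_grid((min(0.1, s_min / 10), 330.0)))
    if diagram.label not in ("mushroom", "inverted_mushroom"):
        raise ValueError(f"activation map requires a mushroom diagram, got {diagram.label!r}")
    w0 = _off_state_at(diagram, s_min)
    out = np.zeros((len(tau_grid), len(smax_grid)), dtype=bool)
    for i, tau in enumerate(tau_grid):
        for j, smax in enumerate(smax_grid):
            sig = SignalProgram(kind="gaussian_pulse", s_min=s_min, s_max=float(smax), tau=float(tau))
            t_end = sig.center + max(6.0 * tau, 100.0) + 100.0
            try:
                traj = simulate(model, sig, t_span=(0.0, t_end), initial_state=w0)
                out[i, j] = classify_final_state(traj, diagram) == "ON"
            except (RuntimeError, ValueError) as exc:
                logger.warning("activation-map cell (tau=%g, smax=%g) failed: %s", tau, smax, exc)
    return out


def isola_memory_demo(
    model: CircuitModel,
    signal: SignalProgram,
    reset_rule: dict,
    t_span=(0.0, 200.0),
    diagram: BifurcationDiagram | None = None,
):
    """Irreversible extreme-value detection on an isola.

    The initial state is placed on the isola via ``reset_rule``: the
    parameter override (e.g. lowering the leakiness) reopens the mushroom,
    whose intermediate branch continuously deforms into the isola branch;
    its ON state at the initial signal is the reset state.  The Wiener
    signal is then integrated; ``events`` record each onset of an excursion
    of the signal outside the isola's fold range ``[S1, S2]``.  Once any
    excursion has occurred the system relaxes to the outer branch and, the
    transition being irreversible, never reoccupies the isola branch.
    """
    if signal.kind != "wiener":
        raise ValueError("the memory demo drives the circuit with a wiener signal")
    if diagram is None:
        diagram = trace_diagram(model, verification_grid((0.1, 330.0)))
    if diagram.label != "isola":
        raise ValueError(f"model must classify as isola, got {diagram.label!r}")
    s1, s2 = sorted(sn.S for sn in diagram.saddle_nodes)

    opened = with_params(model, **reset_rule)
    opened_diagram = trace_diagram(opened, verification_grid((0.1, 330.0)))
    S0 = float(np.asarray(signal.path(t_span)(t_span[0])))
    w0 = _on_state_at(opened_diagram, S0)

    traj = simulate(model, signal, t_span=t_span, initial_state=w0)
    outside = (traj.signal < s1) | (traj.signal > s2)
    events = []
    for t_idx in np.nonzero(np.diff(outside.astype(int)) == 1)[0]:
        t = float(traj.times[t_idx + 1])
        events.append((t, "low" if traj.signal[t_idx + 1] < s1 else "high"))
    if outside[0]:
        events.insert(0, (float(traj.times[0]), "low" if traj.signal[0] < s1 else "high"))
    traj.events = events
    return traj, events
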