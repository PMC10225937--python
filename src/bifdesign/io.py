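"""Configuration files, result tables and run manifests.

Problems are stored as JSON or YAML with a versioned schema and strict key
validation.  Every run report includes a manifest (master seed, config
hash, package and library versions) sufficient to replay the run exactly:
all randomness in the package flows from a single master seed through
deterministic child-seed derivation.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bifurcation import BifurcationDiagram
from .design import DesignProblem, SolutionSet, TargetBox
from .dynamics import Trajectory
from .robustness import RobustnessReport

SCHEMA_VERSION = 1

_PROBLEM_KEYS = {
    "schema_version",
    "n_genes",
    "signal_mask",
    "y_lower",
    "y_upper",
    "x_names",
    "x_bounds",
    "boxes",
    "n_folds",
    "tying",
    "target_labels",
    "objectives",
    "extra_conditions",
    "s_window",
    "multistart",
    "seed",
}

__all__ = ["load_problem", "save_problem", "problem_to_dict", "run_report", "SCHEMA_VERSION"]


def _tupled(obj):
    if isinstance(obj, (list, tuple)):
        return tuple(_tupled(v) for v in obj)
    return obj


def problem_to_dict(problem: DesignProblem) -> dict:
    d = asdict(problem)
    d["boxes"] = [
        {"s_interval": list(b.s_interval), "omega_box": [list(w) for w in b.omega_box]}
        for b in problem.boxes
    ]
    d["schema_version"] = SCHEMA_VERSION
    return json.loads(json.dumps(d))  # plain JSON types throughout


def _problem_from_dict(data: dict) -> DesignProblem:
    data = dict(data)
    version = data.pop("schema_version", None)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unrecognized schema_version {version!r} (expected {SCHEMA_VERSION})")
    unknown = set(data) - _PROBLEM_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    missing = _PROBLEM_KEYS - {"schema_version"} - set(data)
    if missing:
        raise ValueError(f"missing configuration keys: {sorted(missing)}")
    boxes = []
    for b in data.pop("boxes"):
        extra = set(b) - {"s_interval", "omega_box"}
        if extra:
            raise ValueError(f"unknown box keys: {sorted(extra)}")
        boxes.append(TargetBox(_tupled(b["s_interval"]), _tupled(b["omega_box"])))
    kwargs = {k: _tupled(v) if isinstance(v, list) else v for k, v in data.items()}
    return DesignProblem(boxes=tuple(boxes), **kwargs)


def load_problem(path) -> DesignProblem:
    """Read and validate a design-problem configuration (JSON or YAML)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError("problem configuration must be a mapping")
    return _problem_from_dict(data)


def save_problem(problem: DesignProblem, path) -> Path:
    path = Path(path)
    data = problem_to_dict(problem)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(data, sort_keys=True))
    else:
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    return path


# ----------------------------------------------------------------------------
# result writers
# ----------------------------------------------------------------------------

def _config_hash(config) -> str:
    canon = json.dumps(config, sort_keys=True) if config is not None else ""
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _manifest(out_dir: Path, name: str, seed, config) -> Path:
    import scipy

    from . import __version__

    manifest = {
        "name": name,
        "seed": seed,
        "config_hash": _config_hash(config),
        "config": config,
        "versions": {
            "bifdesign": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "python": platform.python_version(),
        },
    }
    path = out_dir / f"{name}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _write_solution_set(result: SolutionSet, out_dir: Path, name: str):
    rows = []
    for sol in result.solutions:
        row = {"topology": "".join(f"{v:+d}" for v in sol.topology.to_vector()), "psi": sol.psi,
               "label": sol.verified_label, "start_seed": sol.start_seed,
               "n_connections": sol.topology.n_connections}
        row.update({f"x{j}": v for j, v in enumerate(sol.x)})
        for k, (S_k, w_k) in enumerate(sol.folds):
            row[f"fold{k}_S"] = S_k
            for g, w in enumerate(w_k):
                row[f"fold{k}_w{g}"] = w
        rows.append(row)
    paths = []
    sol_path = out_dir / f"{name}_solutions.csv"
    pd.DataFrame(rows).to_csv(sol_path, index=False)
    paths.append(sol_path)
    freq = result.frequency_table()
    freq["topology"] = freq["topology"].map(lambda t: "".join(f"{v:+d}" for v in t))
    freq_path = out_dir / f"{name}_frequency.csv"
    freq.to_csv(freq_path, index=False)
    paths.append(freq_path)
    return paths


def _write_diagram(result: BifurcationDiagram, out_dir: Path, name: str):
    rows = []
    for bid, b in enumerate(result.branches):
        for s, w in zip(b.S, b.states):
            row = {"branch_id": bid, "S": s, "stable": b.stable}
            row.update({f"w{g}": v for g, v in enumerate(w)})
            rows.append(row)
    branches_path = out_dir / f"{name}_branches.csv"
    pd.DataFrame(rows).to_csv(branches_path, index=False)
    folds = [
        {"S": sn.S, "J": sn.J, **{f"w{g}": v for g, v in enumerate(sn.omega)}}
        for sn in result.saddle_nodes
    ]
    folds_path = out_dir / f"{name}_folds.csv"
    pd.DataFrame(folds, columns=["S", "J"] + [f"w{g}" for g in range(len(result.branches[0].states[0]))]).to_csv(
        folds_path, index=False
    )
    return [branches_path, folds_path]


def _write_trajectory(result: Trajectory, out_dir: Path, name: str):
    df = pd.DataFrame({"time": result.times, "S": result.signal})
    for g in range(result.states.shape[1]):
        df[f"w{g}"] = result.states[:, g]
    path = out_dir / f"{name}_trajectory.csv"
    df.to_csv(path, index=False)
    paths = [path]
    if result.events:
        ev_path = out_dir / f"{name}_events.csv"
        pd.DataFrame(result.events, columns=["time", "direction"]).to_csv(ev_path, index=False)
        paths.append(ev_path)
    return paths


def _write_phase_map(result, out_dir: Path, name: str, axes=None):
    labels = np.asarray(result, dtype=object)
    if axes is None:
        axes = (("axis1", np.arange(labels.shape[0])), ("axis2", np.arange(labels.shape[1])))
    (n1, g1), (n2, g2) = axes
    rows = [
        {n1: g1[i], n2: g2[j], "label": labels[i, j]}
        for i in range(labels.shape[0])
        for j in range(labels.shape[1])
    ]
    path = out_dir / f"{name}_phasemap.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return [path]


def _write_robustness(result, out_dir: Path, name: str):
    if isinstance(result, RobustnessReport):
        df = pd.DataFrame([asdict(result)])
    else:
        df = result
    path = out_dir / f"{name}_robustness.csv"
    df.to_csv(path, index=False)
    return [path]


def run_report(result, out_dir, name: str = "run", seed=None, config=None, axes=None):
    """Write a result object and its replay manifest to ``out_dir``.

    Dispatches on the result type (solution sets, diagrams, trajectories,
    phase maps, robustness tables).  Returns the list of written paths,
    manifest last.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(result, SolutionSet):
        paths = _write_solution_set(result, out_dir, name)
        seed = result.seed if seed is None else seed
    elif isinstance(result, BifurcationDiagram):
        paths = _write_diagram(result, out_dir, name)
    elif isinstance(result, Trajectory):
        paths = _write_trajectory(result, out_dir, name)
    elif isinstance(result, (RobustnessReport, pd.DataFrame)):
        paths = _write_robustness(result, out_dir, name)
    elif isinstance(result, np.ndarray) and result.dtype == object:
        paths = _write_phase_map(result, out_dir, name, axes)
    else:
        raise TypeError(f"no writer for result type {type(result).__name__}")
    paths.append(_manifest(out_dir, name, seed, config))
    return paths
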