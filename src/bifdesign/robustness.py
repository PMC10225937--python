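"""Robustness scoring of successful topologies.

A topology is the more robust the larger the region of parameter space its
verified solutions occupy.  Two scores are used, both computed on parameter
vectors standardized against the pooled solution set of all topologies:

* ``logdet``: natural log-determinant of the sample covariance of a
  topology's solution vectors (a hypervolume proxy);
* ``iqr``: the sum over parameters of the interquartile range
  (linear-interpolation quantiles).

Uncertainty is reported as the median and quartiles over bootstrap
resamples of the solution rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SolutionSet",
    "RobustnessReport",
    "SingularCovarianceError",
    "standardize",
    "robustness_logdet",
    "robustness_iqr",
    "bootstrap_scores",
    "robustness_vs_complexity",
]


class SingularCovarianceError(ValueError):
    """The sample covariance is numerically singular; the log-det score is undefined."""


@dataclass(frozen=True)
class SolutionSet:
    """Successful parameter vectors of one topology (rows = solutions)."""

    topology_key: tuple
    param_rows: np.ndarray
    parameter_names: tuple
    n_connections: int = 0

    def __post_init__(self):
        rows = np.atleast_2d(np.asarray(self.param_rows, dtype=float))
        if rows.shape[1] != len(self.parameter_names):
            raise ValueError("column count must match parameter_names")
        object.__setattr__(self, "param_rows", rows)

    @property
    def n_solutions(self) -> int:
        return self.param_rows.shape[0]


@dataclass(frozen=True)
class Scaler:
    mean: np.ndarray
    std: np.ndarray

    def transform(self, rows):
        return (np.asarray(rows, dtype=float) - self.mean) / self.std

    def inverse(self, rows):
        return np.asarray(rows, dtype=float) * self.std + self.mean


@dataclass
class RobustnessReport:
    """Point scores plus bootstrap medians and quartiles for one topology."""

    logdet_score: float
    iqr_score: float
    bootstrap: dict  # score name -> (q25, median, q75)
    n_solutions: int
    n_boot: int
    seed: int
    quantile_method: str = "linear"
    log_base: str = "natural"


def standardize(all_sets):
    """Center and scale each parameter by the pooled mean/std over all sets.

    Pooling regularizes the scores so that spread is measured on a common
    scale across topologies.  Zero-variance pooled columns keep scale 1
    (with a warning).  Returns ``(transformed_sets, scaler)``.
    """
    all_sets = list(all_sets)
    names = all_sets[0].parameter_names
    if any(s.parameter_names != names for s in all_sets):
        raise ValueError("all sets must share parameter_names in the same order")
    pooled = np.vstack([s.param_rows for s in all_sets])
    if pooled.shape[0] < 2:
        raise ValueError("standardization needs at least two pooled solutions")
    mean = pooled.mean(axis=0)
    std = pooled.std(axis=0, ddof=0)
    zero = std == 0.0
    if zero.any():
        logger.warning("zero pooled variance in columns %s; scale set to 1", np.nonzero(zero)[0].tolist())
        std = np.where(zero, 1.0, std)
    scaler = Scaler(mean=mean, std=std)
    return [replace(s, param_rows=scaler.transform(s.param_rows)) for s in all_sets], scaler


def robustness_logdet(solution_set: SolutionSet) -> float:
    """Natural log-determinant of the sample covariance of the solution rows.

    Larger values mean the solutions fill a larger parameter hypervolume.
    Requires more solutions than parameters; a numerically singular
    covariance is an explicit error, not silently ``-inf`` (silent ``-inf``
    would corrupt bootstrap quartiles downstream).
    """
    rows = solution_set.param_rows
    n, d = rows.shape
    if n < d + 1:
        raise ValueError(f"need at least {d + 1} solutions for {d} parameters, got {n}")
    cov = np.cov(rows, rowvar=False)
    sign, logdet = np.linalg.slogdet(np.atleast_2d(cov))
    if sign <= 0 or not np.isfinite(logdet):
        raise SingularCovarianceError("sample covariance is singular; log-det score undefined")
    return float(logdet)


def robustness_iqr(solution_set: SolutionSet) -> float:
    """Sum over parameters of the interquartile range of the solution rows."""
    rows = solution_set.param_rows
    if rows.shape[0] < 4:
        raise ValueError("IQR score needs at least 4 solutions")
    q1, q3 = np.quantile(rows, [0.25, 0.75], axis=0, method="linear")
    return float(np.sum(q3 - q1))


def bootstrap_scores(solution_set: SolutionSet, n_boot: int = 1000, seed: int = 0) -> RobustnessReport:
    """Bootstrap (resample rows with replacement) both robustness scores.

    Replicates whose covariance is singular contribute only to the IQR
    statistics (logged).  Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    rows = solution_set.param_rows
    n = rows.shape[0]
    logdets, iqrs = [], []
    n_singular = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        rep = replace(solution_set, param_rows=rows[idx])
        try:
            logdets.append(robustness_logdet(rep))
        except (SingularCovarianceError, ValueError):
            n_singular += 1
        iqrs.append(robustness_iqr(rep))
    if n_singular:
        logger.warning("%d/%d bootstrap replicates had singular covariance", n_singular, n_boot)
    boot = {
        "logdet": tuple(np.quantile(logdets, [0.25, 0.5, 0.75])) if logdets else (np.nan,) * 3,
        "iqr": tuple(np.quantile(iqrs, [0.25, 0.5, 0.75])),
    }
    return RobustnessReport(
        logdet_score=robustness_logdet(solution_set),
        iqr_score=robustness_iqr(solution_set),
        bootstrap=boot,
        n_solutions=n,
        n_boot=n_boot,
        seed=seed,
    )


def robustness_vs_complexity(sets, n_boot: int = 1000, seed: int = 0, score: str = "iqr"):
    """Robustness-versus-connection-count table and its Pareto front.

    Sets are standardized against their pooled rows, scored, and the front
    (maximize robustness, minimize connections) is computed.  Returns
    ``(table, front_keys)`` where the table is one row per topology.
    """
    from .design import pareto_front

    sets = list(sets)
    if len(sets) < 2:
        raise ValueError("need at least two topologies to compare")
    transformed, _ = standardize(sets)
    rows = []
    for original, tset in zip(sets, transformed):
        report_kwargs = {"n_boot": n_boot, "seed": seed}
        try:
            report = bootstrap_scores(tset, **report_kwargs)
            logdet, iqr = report.logdet_score, report.iqr_score
            boot = report.bootstrap
        except (SingularCovarianceError, ValueError):
            logdet, iqr, boot = np.nan, robustness_iqr(tset), None
        rows.append(
            {
                "topology": original.topology_key,
                "n_connections": original.n_connections,
                "logdet": logdet,
                "iqr": iqr,
                "boot_logdet_q25": boot["logdet"][0] if boot else np.nan,
                "boot_logdet_median": boot["logdet"][1] if boot else np.nan,
                "boot_logdet_q75": boot["logdet"][2] if boot else np.nan,
                "boot_iqr_q25": boot["iqr"][0] if boot else np.nan,
                "boot_iqr_median": boot["iqr"][1] if boot else np.nan,
                "boot_iqr_q75": boot["iqr"][2] if boot else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    points = [
        ((row["n_connections"], row[score]), row["topology"])
        for _, row in table.iterrows()
        if np.isfinite(row[score])
    ]
    front = pareto_front(points, orientation=("min", "max"))
    return table, front
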