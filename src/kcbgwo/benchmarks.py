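"""Classical continuous benchmark functions and the trial protocol.

Ten standard test functions (Sphere, the three Schwefel problems 2.22/1.2/2.21,
Generalized Rosenbrock, Schwefel 2.26, Rastrigin, Ackley, Griewank and the
first Generalized Penalized function) with their conventional box domains,
plus a seeded multi-run protocol that records per-run best fitness and
summarizes mean/std across runs for optimizer comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ObjectiveSpec",
    "TrialSummary",
    "evaluate",
    "get_suite",
    "get_objective",
    "run_trials",
    "summarize_comparison",
]


@dataclass(frozen=True)
class ObjectiveSpec:
    """A benchmark (or user-supplied) objective to be minimized.

    Attributes
    ----------
    id : str
        Short identifier, ``f1`` .. ``f10`` for the built-in suite.
    name : str
        Display name of the function.
    dim : int
        Number of decision variables ``D``.
    lower, upper : ndarray of shape (D,)
        Per-dimension box bounds; ``lower < upper`` everywhere.
    modality : str
        ``"unimodal"`` or ``"multimodal"``.
    f_min : float
        Known global minimum value.
    x_min : ndarray of shape (D,) or None
        One known minimizer, when available in closed form.
    fn : callable
        Vector -> float evaluator; deterministic and pure.
    """

    id: str
    name: str
    dim: int
    lower: np.ndarray
    upper: np.ndarray
    modality: str
    f_min: float
    x_min: np.ndarray | None
    fn: Callable[[np.ndarray], float]

    def __post_init__(self) -> None:
        if not np.all(self.lower < self.upper):
            raise ValueError("every lower bound must be strictly below its upper bound")


@dataclass
class TrialSummary:
    """Mean/std of per-run best fitness for one (objective, optimizer) pair."""

    objective_id: str
    optimizer_id: str
    runs: int
    pop_size: int
    iterations: int
    base_seed: int
    best_per_run: list[float] = field(default_factory=list)
    mean_best: float = float("nan")
    std_best: float = float("nan")

    def recompute(self) -> None:
        arr = np.asarray(self.best_per_run, dtype=float)
        self.runs = arr.size
        self.mean_best = float(arr.mean())
        self.std_best = float(arr.std(ddof=0))


# ---------------------------------------------------------------------------
# Function definitions (minimization, standard forms)
# ---------------------------------------------------------------------------

def _sphere(x: np.ndarray) -> float:
    return float(np.sum(x * x))


def _schwefel_222(x: np.ndarray) -> float:
    a = np.abs(x)
    return float(np.sum(a) + np.prod(a))


def _schwefel_12(x: np.ndarray) -> float:
    # rotated hyper-ellipsoid: sum over i of (sum_{j<=i} x_j)^2
    return float(np.sum(np.cumsum(x) ** 2))


def _schwefel_221(x: np.ndarray) -> float:
    return float(np.max(np.abs(x)))


def _rosenbrock(x: np.ndarray) -> float:
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (x[:-1] - 1.0) ** 2))


def _schwefel_226(x: np.ndarray) -> float:
    # shifted so the global minimum is ~0 and values are positive
    return float(418.9829 * x.size - np.sum(x * np.sin(np.sqrt(np.abs(x)))))


def _rastrigin(x: np.ndarray) -> float:
    return float(np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x) + 10.0))


def _ackley(x: np.ndarray) -> float:
    d = x.size
    s1 = np.sum(x * x) / d
    s2 = np.sum(np.cos(2.0 * np.pi * x)) / d
    return float(-20.0 * np.exp(-0.2 * np.sqrt(s1)) - np.exp(s2) + 20.0 + np.e)


def _griewank(x: np.ndarray) -> float:
    i = np.arange(1, x.size + 1, dtype=float)
    return float(np.sum(x * x) / 4000.0 - np.prod(np.cos(x / np.sqrt(i))) + 1.0)


def _penalty_u(x: np.ndarray, a: float, k: float, m: float) -> np.ndarray:
    out = np.zeros_like(x)
    out = np.where(x > a, k * (x - a) ** m, out)
    out = np.where(x < -a, k * (-x - a) ** m, out)
    return out


def _penalized1(x: np.ndarray) -> float:
    y = 1.0 + (x + 1.0) / 4.0
    d = x.size
    term = (
        10.0 * np.sin(np.pi * y[0]) ** 2
        + np.sum((y[:-1] - 1.0) ** 2 * (1.0 + 10.0 * np.sin(np.pi * y[1:]) ** 2))
        + (y[-1] - 1.0) ** 2
    )
    return float(np.pi / d * term + np.sum(_penalty_u(x, 10.0, 100.0, 4.0)))


# id -> (name, fn, bound, modality, minimizer coordinate)
# Schwefel 2.26 has its minimizer at 420.9687... in every dimension, with a
# small residual from the 418.9829 offset; all others have exact optima.
_SUITE = [
    ("f1", "Sphere", _sphere, 100.0, "unimodal", 0.0),
    ("f2", "Schwefel 2.22", _schwefel_222, 10.0, "unimodal", 0.0),
    ("f3", "Schwefel 1.2", _schwefel_12, 100.0, "unimodal", 0.0),
    ("f4", "Schwefel 2.21", _schwefel_221, 100.0, "unimodal", 0.0),
    ("f5", "Generalized Rosenbrock", _rosenbrock, 30.0, "unimodal", 1.0),
    ("f6", "Generalized Schwefel 2.26", _schwefel_226, 500.0, "multimodal", 420.968746),
    ("f7", "Rastrigin", _rastrigin, 5.12, "multimodal", 0.0),
    ("f8", "Ackley", _ackley, 32.0, "multimodal", 0.0),
    ("f9", "Griewank", _griewank, 600.0, "multimodal", 0.0),
    ("f10", "Generalized Penalized 1", _penalized1, 50.0, "multimodal", -1.0),
]


def get_suite(dim: int = 30) -> list[ObjectiveSpec]:
    """Return the ten benchmark specs f1..f10 at dimension ``dim``.

    Parameters
    ----------
    dim : int
        Problem dimension, at least 2 (several functions couple adjacent
        coordinates and degenerate below that).
    """
    if dim < 2:
        raise ValueError(f"suite dimension must be >= 2, got {dim}")
    specs = []
    for fid, name, fn, bound, modality, xm in _SUITE:
        specs.append(
            ObjectiveSpec(
                id=fid,
                name=name,
                dim=dim,
                lower=np.full(dim, -bound),
                upper=np.full(dim, bound),
                modality=modality,
                f_min=0.0,
                x_min=np.full(dim, xm),
                fn=fn,
            )
        )
    return specs


def get_objective(fid: str, dim: int = 30) -> ObjectiveSpec:
    """Look up one suite member by id (``f1`` .. ``f10``)."""
    for spec in get_suite(dim):
        if spec.id == fid:
            return spec
    raise KeyError(f"unknown objective id {fid!r}; expected f1..f10")


def evaluate(spec: ObjectiveSpec, x: Sequence[float] | np.ndarray) -> float:
    """Evaluate ``spec`` at point ``x``.

    Validates dimension and finiteness only; staying inside the box is the
    caller's (the optimizer's) responsibility.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (spec.dim,):
        raise ValueError(
            f"dimension mismatch: objective {spec.id} expects length {spec.dim}, "
            f"got shape {x.shape}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("input vector contains non-finite values")
    return spec.fn(x)


# ---------------------------------------------------------------------------
# Trial protocol
# ---------------------------------------------------------------------------

def run_trials(
    optimizer: str,
    spec: ObjectiveSpec,
    runs: int = 30,
    base_seed: int = 0,
    pop_size: int = 30,
    iterations: int = 500,
    **optimizer_kwargs,
) -> TrialSummary:
    """Run an optimizer ``runs`` times on ``spec`` and summarize best fitness.

    Run ``i`` is seeded with ``base_seed + i``, so the whole summary is
    reproducible from ``base_seed`` alone. Registered optimizer ids:
    ``kcbgwo`` (clustered GWO, continuous), ``gwo`` (plain GWO),
    ``bgwo`` (binary-coded GWO; positions are bit vectors fed to the
    objective as 0/1 coordinates), ``pso``.
    """
    from . import gwo as _gwo
    from .optimizer import KCBGWOConfig, minimize as _kcbgwo_minimize

    if runs < 1:
        raise ValueError("runs must be >= 1")

    def _one(seed: int) -> float:
        if optimizer == "kcbgwo":
            cfg = KCBGWOConfig(
                pop_size=pop_size,
                iterations=iterations,
                mode="continuous",
                seed=seed,
                **optimizer_kwargs,
            )
            return _kcbgwo_minimize(spec, cfg).best_fitness
        if optimizer == "bgwo":
            cfg = KCBGWOConfig(
                pop_size=pop_size,
                iterations=iterations,
                n_clusters=1,
                mode="binary",
                seed=seed,
                **optimizer_kwargs,
            )
            return _kcbgwo_minimize(spec, cfg).best_fitness
        if optimizer == "gwo":
            res = _gwo.gwo_minimize(
                spec, pop_size=pop_size, iterations=iterations, seed=seed
            )
            return res.best_fitness
        if optimizer == "pso":
            res = _gwo.pso_minimize(
                spec, pop_size=pop_size, iterations=iterations, seed=seed
            )
            return res.best_fitness
        raise ValueError(f"unknown optimizer id {optimizer!r}")

    summary = TrialSummary(
        objective_id=spec.id,
        optimizer_id=optimizer,
        runs=runs,
        pop_size=pop_size,
        iterations=iterations,
        base_seed=base_seed,
        best_per_run=[_one(base_seed + i) for i in range(runs)],
    )
    summary.recompute()
    return summary


def summarize_comparison(summaries: Sequence[TrialSummary]) -> pd.DataFrame:
    """Pivot a list of trial summaries into an objectives x optimizers grid.

    One row per objective; an ``Av``/``Std`` column pair per optimizer.
    All summaries must share the same protocol (runs, pop size, iterations).
    """
    if not summaries:
        return pd.DataFrame()
    protos = {(s.runs, s.pop_size, s.iterations) for s in summaries}
    if len(protos) > 1:
        raise ValueError(f"mixed trial protocols cannot be compared: {sorted(protos)}")
    rows = [
        {
            "objective": s.objective_id,
            "optimizer": s.optimizer_id,
            "Av": s.mean_best,
            "Std": s.std_best,
        }
        for s in summaries
    ]
    long = pd.DataFrame(rows)
    wide = long.pivot(index="objective", columns="optimizer", values=["Av", "Std"])
    wide = wide.swaplevel(axis=1).sort_index(axis=1)
    wide.columns = [f"{opt}_{stat}" for opt, stat in wide.columns]
    return wide.reset_index()
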