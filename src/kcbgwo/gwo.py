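"""Grey-wolf update mechanics shared by the plain and clustered optimizers.

The grey wolf optimizer moves each wolf toward the pack's three best
solutions (alpha, beta, delta).  For each leader p the attraction is

    K = |C * X_p - X|,    candidate = X_p - A * K,

with stochastic coefficients A = 2*a*r1 - a and C = 2*r2 (r1, r2 uniform in
[0, 1] per dimension) and a control parameter ``a`` that decays linearly
from 2 to 0 over the iteration budget.  Continuous mode averages the three
leader candidates and clamps to the box; binary mode squashes the average
through a sigmoid and samples each bit with that probability.

Randomness convention (shared with :mod:`kcbgwo.optimizer` so that the
clustered optimizer with a single cluster reproduces plain GWO draw for
draw): per update step, one uniform block of shape (N, 3, D) for r1, then
one for r2, then — binary mode only — one (N, D) block of bit-acceptance
draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .benchmarks import ObjectiveSpec, evaluate

__all__ = [
    "ControlCoefficients",
    "LeaderStep",
    "OptimizationResult",
    "control_parameter",
    "sample_coefficients",
    "leader_component",
    "blend_components",
    "sigmoid_transfer",
    "binary_bit_update",
    "pack_step",
    "gwo_minimize",
    "pso_minimize",
]


@dataclass(frozen=True)
class ControlCoefficients:
    """Per-dimension stochastic attraction coefficients for one leader."""

    a: float
    r1: np.ndarray
    r2: np.ndarray
    A: np.ndarray
    C: np.ndarray


@dataclass(frozen=True)
class LeaderStep:
    """One leader-guided update component for a single wolf."""

    leader_position: np.ndarray
    prey_distance: np.ndarray
    candidate: np.ndarray
    role: str = "alpha"


@dataclass
class OptimizationResult:
    """Outcome of a single optimization run."""

    best_position: np.ndarray
    best_fitness: float
    history: list[float] = field(default_factory=list)
    n_evaluations: int = 0
    seed: int | None = None
    config: dict = field(default_factory=dict)


def control_parameter(iteration: int, total_iterations: int) -> float:
    """Linearly decaying control parameter a(t) = 2 - 2*t/T."""
    if total_iterations < 1:
        raise ValueError("total_iterations must be >= 1")
    if iteration < 0 or iteration > total_iterations:
        raise ValueError(
            f"iteration {iteration} outside [0, {total_iterations}]"
        )
    return 2.0 - 2.0 * iteration / total_iterations


def sample_coefficients(
    a: float, dim: int, rng: np.random.Generator
) -> ControlCoefficients:
    """Draw fresh r1, r2 per dimension and form A = 2*a*r1 - a, C = 2*r2."""
    if not 0.0 <= a <= 2.0:
        raise ValueError(f"control parameter a must lie in [0, 2], got {a}")
    r1 = rng.random(dim)
    r2 = rng.random(dim)
    return ControlCoefficients(a=a, r1=r1, r2=r2, A=2.0 * a * r1 - a, C=2.0 * r2)


def leader_component(
    x: np.ndarray, x_p: np.ndarray, coeffs: ControlCoefficients, role: str = "alpha"
) -> LeaderStep:
    """Prey distance K = |C∘X_p - X| and candidate X_p - A∘K, element-wise."""
    x = np.asarray(x, dtype=float)
    x_p = np.asarray(x_p, dtype=float)
    if not (x.shape == x_p.shape == coeffs.A.shape == coeffs.C.shape):
        raise ValueError(
            f"dimension mismatch: x {x.shape}, x_p {x_p.shape}, "
            f"A {coeffs.A.shape}, C {coeffs.C.shape}"
        )
    prey_distance = np.abs(coeffs.C * x_p - x)
    candidate = x_p - coeffs.A * prey_distance
    return LeaderStep(
        leader_position=x_p,
        prey_distance=prey_distance,
        candidate=candidate,
        role=role,
    )


def blend_components(
    c_alpha: np.ndarray, c_beta: np.ndarray, c_delta: np.ndarray
) -> np.ndarray:
    """Element-wise mean of the three leader-guided candidates."""
    c_alpha = np.asarray(c_alpha, dtype=float)
    c_beta = np.asarray(c_beta, dtype=float)
    c_delta = np.asarray(c_delta, dtype=float)
    if not (c_alpha.shape == c_beta.shape == c_delta.shape):
        raise ValueError("leader components must share one shape")
    return (c_alpha + c_beta + c_delta) / 3.0


def sigmoid_transfer(v: float | np.ndarray) -> float | np.ndarray:
    """Logistic transfer 1/(1 + e^-v), saturating without overflow."""
    out = expit(v)
    return float(out) if np.isscalar(v) else out


def binary_bit_update(
    c_alpha: float, c_beta: float, c_delta: float, rng: np.random.Generator
) -> int:
    """Sample one bit: 1 iff u < sigmoid(mean of the three components)."""
    p = sigmoid_transfer((c_alpha + c_beta + c_delta) / 3.0)
    return int(rng.random() < p)


def pack_step(
    positions: np.ndarray,
    leader_positions: np.ndarray,
    a: float,
    rng: np.random.Generator,
    mode: str = "continuous",
    lower: np.ndarray | None = None,
    upper: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized one-iteration update of a whole pack.

    Parameters
    ----------
    positions : (N, D) array
        Current wolf positions.
    leader_positions : (N, 3, D) array
        For each wolf, the positions of its alpha, beta and delta leaders
        (identical across wolves for plain GWO; per-cluster for KCBGWO).
    a : float
        Current control parameter.
    mode : {"continuous", "binary"}
        Continuous: mean of candidates, clamped to [lower, upper].
        Binary: sigmoid of the mean, one acceptance draw per bit.
    """
    n, d = positions.shape
    if leader_positions.shape != (n, 3, d):
        raise ValueError(
            f"leader_positions must be (N, 3, D) = ({n}, 3, {d}), "
            f"got {leader_positions.shape}"
        )
    r1 = rng.random((n, 3, d))
    r2 = rng.random((n, 3, d))
    coef_a = 2.0 * a * r1 - a
    coef_c = 2.0 * r2
    prey_dist = np.abs(coef_c * leader_positions - positions[:, None, :])
    candidates = leader_positions - coef_a * prey_dist
    blended = candidates.mean(axis=1)
    if mode == "continuous":
        if lower is None or upper is None:
            raise ValueError("continuous mode requires bounds")
        return np.clip(blended, lower, upper)
    if mode == "binary":
        u = rng.random((n, d))
        return (u < expit(blended)).astype(float)
    raise ValueError(f"unknown mode {mode!r}")


def _evaluate_pack(spec: ObjectiveSpec, positions: np.ndarray) -> np.ndarray:
    return np.array([evaluate(spec, row) for row in positions])


def gwo_minimize(
    spec: ObjectiveSpec,
    pop_size: int = 30,
    iterations: int = 500,
    seed: int = 0,
    mode: str = "continuous",
) -> OptimizationResult:
    """Plain grey wolf optimizer with global alpha/beta/delta leaders."""
    if pop_size < 4:
        raise ValueError("pop_size must be >= 4")
    rng = np.random.default_rng(seed)
    d = spec.dim
    if mode == "continuous":
        positions = rng.uniform(spec.lower, spec.upper, size=(pop_size, d))
    else:
        positions = (rng.random((pop_size, d)) < 0.5).astype(float)
    fitness = _evaluate_pack(spec, positions)
    n_evals = pop_size

    best_idx = int(np.argmin(fitness))
    best_pos = positions[best_idx].copy()
    best_fit = float(fitness[best_idx])
    history = [best_fit]

    for it in range(iterations):
        a = control_parameter(it, iterations)
        order = np.argsort(fitness, kind="stable")
        leaders = positions[order[:3]]  # alpha, beta, delta
        leader_positions = np.broadcast_to(
            leaders[None, :, :], (pop_size, 3, d)
        )
        positions = pack_step(
            positions,
            leader_positions,
            a,
            rng,
            mode=mode,
            lower=spec.lower,
            upper=spec.upper,
        )
        fitness = _evaluate_pack(spec, positions)
        n_evals += pop_size
        it_best = int(np.argmin(fitness))
        if fitness[it_best] < best_fit:
            best_fit = float(fitness[it_best])
            best_pos = positions[it_best].copy()
        history.append(best_fit)

    return OptimizationResult(
        best_position=best_pos,
        best_fitness=best_fit,
        history=history,
        n_evaluations=n_evals,
        seed=seed,
        config={"optimizer": "gwo", "pop_size": pop_size, "iterations": iterations},
    )


def pso_minimize(
    spec: ObjectiveSpec,
    pop_size: int = 30,
    iterations: int = 500,
    seed: int = 0,
    inertia: float = 0.729,
    c1: float = 1.49445,
    c2: float = 1.49445,
) -> OptimizationResult:
    """Standard global-best particle swarm baseline.

    Constriction-style inertia weight, velocities clamped to half the box
    width, positions clamped to the box.
    """
    if pop_size < 1 or iterations < 1:
        raise ValueError("pop_size and iterations must be >= 1")
    rng = np.random.default_rng(seed)
    d = spec.dim
    span = spec.upper - spec.lower
    v_max = span / 2.0

    positions = rng.uniform(spec.lower, spec.upper, size=(pop_size, d))
    velocities = rng.uniform(-v_max, v_max, size=(pop_size, d))
    fitness = _evaluate_pack(spec, positions)
    n_evals = pop_size

    p_best = positions.copy()
    p_best_fit = fitness.copy()
    g_idx = int(np.argmin(fitness))
    g_best = positions[g_idx].copy()
    g_best_fit = float(fitness[g_idx])
    history = [g_best_fit]

    for _ in range(iterations):
        r1 = rng.random((pop_size, d))
        r2 = rng.random((pop_size, d))
        velocities = (
            inertia * velocities
            + c1 * r1 * (p_best - positions)
            + c2 * r2 * (g_best - positions)
        )
        velocities = np.clip(velocities, -v_max, v_max)
        positions = np.clip(positions + velocities, spec.lower, spec.upper)
        fitness = _evaluate_pack(spec, positions)
        n_evals += pop_size
        improved = fitness < p_best_fit
        p_best[improved] = positions[improved]
        p_best_fit[improved] = fitness[improved]
        g_idx = int(np.argmin(p_best_fit))
        if p_best_fit[g_idx] < g_best_fit:
            g_best_fit = float(p_best_fit[g_idx])
            g_best = p_best[g_idx].copy()
        history.append(g_best_fit)

    return OptimizationResult(
        best_position=g_best,
        best_fitness=g_best_fit,
        history=history,
        n_evaluations=n_evals,
        seed=seed,
        config={"optimizer": "pso", "pop_size": pop_size, "iterations": iterations},
    )
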