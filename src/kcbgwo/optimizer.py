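"""K-means-clustered grey wolf optimizer (KCBGWO).

The pack is partitioned by k-means in position space; each cluster gets its
own fitness-ordered alpha/beta/delta leadership, and every wolf is updated
against its *own* cluster's leaders rather than the global trio.  The
partition is refreshed every ``recluster_period`` iterations.  Continuous
mode blends the three leader candidates and clamps to the box; binary mode
pushes the blend through a sigmoid transfer and samples bits.

Two independent random streams are derived from the run seed: one drives
initialization and position updates (identical to the plain-GWO stream, so
a single-cluster run reproduces plain GWO draw for draw), the other drives
k-means centroid seeding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

from .benchmarks import ObjectiveSpec
from .gwo import OptimizationResult, control_parameter

__all__ = [
    "Wolf",
    "Pack",
    "KCBGWOConfig",
    "ClusterModel",
    "RoleTable",
    "initialize_population",
    "kmeans_partition",
    "assign_roles",
    "minimize",
    "encode_search_space",
    "decode_candidate",
    "SearchSpaceEncoding",
]


@dataclass(frozen=True)
class Wolf:
    position: np.ndarray
    fitness: float | None
    id: int


class Pack:
    """A wolf population: positions matrix plus per-wolf fitness."""

    def __init__(self, positions: np.ndarray, fitness: np.ndarray | None = None):
        self.positions = np.asarray(positions, dtype=float)
        self.fitness = fitness

    def __len__(self) -> int:
        return self.positions.shape[0]

    def __getitem__(self, i: int) -> Wolf:
        fit = None if self.fitness is None else float(self.fitness[i])
        return Wolf(position=self.positions[i], fitness=fit, id=i)


@dataclass
class KCBGWOConfig:
    """Run configuration.

    Defaults follow the published protocol: population 30, 500 iterations,
    3 clusters, k-means capped at 100 Lloyd iterations, reclustering every
    iteration.  ``threshold`` (optional) stops the run early once the global
    best fitness falls to or below it.  ``leader_blend_weights`` optionally
    replaces the plain three-leader mean with a weighted mean (off by
    default).
    """

    pop_size: int = 30
    iterations: int = 500
    n_clusters: int = 3
    kmeans_max_iter: int = 100
    mode: str = "continuous"
    bounds: tuple[float, float] | None = None
    threshold: float | None = None
    seed: int = 0
    recluster_period: int = 1
    dim: int | None = None
    leader_blend_weights: tuple[float, float, float] | None = None

    def validate(self) -> None:
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4 (alpha/beta/delta/omega)")
        if not 1 <= self.n_clusters <= self.pop_size:
            raise ValueError("need 1 <= n_clusters <= pop_size")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.mode not in ("continuous", "binary"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.threshold is not None and not math.isfinite(self.threshold):
            raise ValueError("threshold must be finite when set")
        if self.recluster_period < 1:
            raise ValueError("recluster_period must be >= 1")


@dataclass
class ClusterModel:
    """Result of one k-means partition of the pack."""

    n_clusters: int
    centroids: np.ndarray  # (K, D)
    assignments: np.ndarray  # (N,) cluster index per wolf
    inertia: float  # within-cluster sum of squared distances


@dataclass
class RoleTable:
    """Per-cluster alpha/beta/delta/omega roles plus the global best."""

    alpha: np.ndarray  # (K,) wolf index of each cluster's alpha
    beta: np.ndarray
    delta: np.ndarray
    omega: list[np.ndarray]  # per-cluster omega member indices
    global_best_index: int
    global_best_fitness: float


def initialize_population(
    config: KCBGWOConfig, dim: int, rng: np.random.Generator
) -> Pack:
    """Draw the initial pack: fair coins (binary) or uniform-in-box reals."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if config.mode == "binary":
        positions = (rng.random((config.pop_size, dim)) < 0.5).astype(float)
    else:
        if config.bounds is None:
            raise ValueError("continuous mode requires bounds")
        lo, hi = config.bounds
        positions = rng.uniform(lo, hi, size=(config.pop_size, dim))
    return Pack(positions)


def kmeans_partition(
    positions: np.ndarray,
    n_clusters: int,
    max_iter: int = 100,
    rng: np.random.Generator | None = None,
    trace: list | None = None,
) -> ClusterModel:
    """Lloyd's algorithm on the wolf positions.

    Centroids are seeded by sampling ``n_clusters`` distinct wolves; the
    loop stops at an assignment fixpoint or after ``max_iter`` sweeps.  An
    emptied cluster is re-seeded from a randomly chosen wolf.  When a
    ``trace`` list is supplied, the within-cluster sum of squares after
    each sweep is appended to it.
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if n_clusters > n:
        raise ValueError(f"n_clusters {n_clusters} exceeds population {n}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if rng is None:
        rng = np.random.default_rng()

    centroids = positions[rng.choice(n, size=n_clusters, replace=False)].copy()
    assignments = np.full(n, -1, dtype=int)
    for _ in range(max_iter):
        d2 = ((positions[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_assignments = np.argmin(d2, axis=1)
        for k in range(n_clusters):
            members = new_assignments == k
            if members.any():
                centroids[k] = positions[members].mean(axis=0)
            else:
                centroids[k] = positions[rng.integers(n)]
        if trace is not None:
            trace.append(
                float(((positions - centroids[new_assignments]) ** 2).sum())
            )
        if np.array_equal(new_assignments, assignments):
            break
        assignments = new_assignments

    d2 = ((positions - centroids[assignments]) ** 2).sum(axis=1)
    return ClusterModel(
        n_clusters=n_clusters,
        centroids=centroids,
        assignments=assignments,
        inertia=float(d2.sum()),
    )


def assign_roles(pack: Pack, clusters: ClusterModel) -> RoleTable:
    """Fitness-order each cluster and designate alpha/beta/delta/omega.

    Ties break by wolf index (stable sort).  Clusters with fewer than four
    members reuse their best wolf for the missing roles.
    """
    if pack.fitness is None:
        raise RuntimeError("pack fitness must be evaluated before role assignment")
    fitness = np.asarray(pack.fitness, dtype=float)
    k = clusters.n_clusters
    alpha = np.zeros(k, dtype=int)
    beta = np.zeros(k, dtype=int)
    delta = np.zeros(k, dtype=int)
    omega: list[np.ndarray] = []
    for c in range(k):
        members = np.flatnonzero(clusters.assignments == c)
        if members.size == 0:
            # degenerate: empty cluster falls back to the global best wolf
            g = int(np.argmin(fitness))
            alpha[c] = beta[c] = delta[c] = g
            omega.append(np.array([], dtype=int))
            continue
        order = members[np.argsort(fitness[members], kind="stable")]
        alpha[c] = order[0]
        beta[c] = order[1] if order.size > 1 else order[0]
        delta[c] = order[2] if order.size > 2 else order[0]
        omega.append(order[3:])
    g = int(np.argmin(fitness))
    return RoleTable(
        alpha=alpha,
        beta=beta,
        delta=delta,
        omega=omega,
        global_best_index=g,
        global_best_fitness=float(fitness[g]),
    )


def _resolve_objective(
    objective: ObjectiveSpec | Callable[[np.ndarray], float],
    config: KCBGWOConfig,
) -> tuple[Callable[[np.ndarray], float], int, np.ndarray, np.ndarray]:
    if isinstance(objective, ObjectiveSpec):
        lo, hi = objective.lower, objective.upper
        if config.bounds is not None:
            lo = np.full(objective.dim, config.bounds[0])
            hi = np.full(objective.dim, config.bounds[1])
        return objective.fn, objective.dim, lo, hi
    if config.dim is None:
        raise ValueError("config.dim is required for a bare callable objective")
    d = config.dim
    if config.mode == "continuous":
        if config.bounds is None:
            raise ValueError("continuous mode requires bounds")
        lo = np.full(d, config.bounds[0])
        hi = np.full(d, config.bounds[1])
    else:
        lo = np.zeros(d)
        hi = np.ones(d)
    return objective, d, lo, hi


def minimize(
    objective: ObjectiveSpec | Callable[[np.ndarray], float],
    config: KCBGWOConfig,
) -> OptimizationResult:
    """Run the clustered grey wolf optimizer.

    Each iteration: update the control parameter, move every wolf against
    its own cluster's alpha/beta/delta, re-evaluate, refresh roles, and
    recluster on schedule.  Stops at the iteration budget or as soon as the
    global best fitness reaches ``config.threshold`` (when set).
    """
    config.validate()
    fn, dim, lower, upper = _resolve_objective(objective, config)

    rng = np.random.default_rng(config.seed)
    rng_cluster = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    if config.mode == "continuous" and config.bounds is None and not isinstance(
        objective, ObjectiveSpec
    ):
        raise ValueError("continuous mode requires bounds")

    if config.mode == "binary":
        positions = (rng.random((config.pop_size, dim)) < 0.5).astype(float)
    else:
        positions = rng.uniform(lower, upper, size=(config.pop_size, dim))

    def eval_all(pos: np.ndarray) -> np.ndarray:
        return np.array([float(fn(row)) for row in pos])

    fitness = eval_all(positions)
    n_evals = config.pop_size
    pack = Pack(positions, fitness)

    clusters = kmeans_partition(
        positions, config.n_clusters, config.kmeans_max_iter, rng_cluster
    )
    roles = assign_roles(pack, clusters)

    best_fit = roles.global_best_fitness
    best_pos = positions[roles.global_best_index].copy()
    history = [best_fit]

    if config.leader_blend_weights is not None:
        w = np.asarray(config.leader_blend_weights, dtype=float)
        blend_w = (w / w.sum())[None, :, None]
    else:
        blend_w = None

    stopped_early = False
    if config.threshold is not None and best_fit <= config.threshold:
        stopped_early = True

    for it in range(config.iterations):
        if stopped_early:
            break
        a = control_parameter(it, config.iterations)

        leader_idx = np.stack(
            [roles.alpha, roles.beta, roles.delta], axis=1
        )  # (K, 3)
        leader_positions = positions[leader_idx[clusters.assignments]]  # (N, 3, D)

        n = config.pop_size
        r1 = rng.random((n, 3, dim))
        r2 = rng.random((n, 3, dim))
        coef_a = 2.0 * a * r1 - a
        coef_c = 2.0 * r2
        prey_dist = np.abs(coef_c * leader_positions - positions[:, None, :])
        candidates = leader_positions - coef_a * prey_dist
        if blend_w is None:
            blended = candidates.mean(axis=1)
        else:
            blended = (candidates * blend_w).sum(axis=1)

        if config.mode == "continuous":
            positions = np.clip(blended, lower, upper)
        else:
            u = rng.random((n, dim))
            positions = (u < expit(blended)).astype(float)

        fitness = eval_all(positions)
        n_evals += n
        pack = Pack(positions, fitness)

        if (it + 1) % config.recluster_period == 0:
            clusters = kmeans_partition(
                positions, config.n_clusters, config.kmeans_max_iter, rng_cluster
            )
        else:
            d2 = (
                (positions[:, None, :] - clusters.centroids[None, :, :]) ** 2
            ).sum(axis=2)
            clusters.assignments = np.argmin(d2, axis=1)
        roles = assign_roles(pack, clusters)

        if roles.global_best_fitness < best_fit:
            best_fit = roles.global_best_fitness
            best_pos = positions[roles.global_best_index].copy()
        history.append(best_fit)

        if config.threshold is not None and best_fit <= config.threshold:
            stopped_early = True

    return OptimizationResult(
        best_position=best_pos,
        best_fitness=best_fit,
        history=history,
        n_evaluations=n_evals,
        seed=config.seed,
        config={
            "optimizer": "kcbgwo",
            "pop_size": config.pop_size,
            "iterations": config.iterations,
            "n_clusters": config.n_clusters,
            "mode": config.mode,
            "recluster_period": config.recluster_period,
            "stopped_early": stopped_early,
        },
    )


# ---------------------------------------------------------------------------
# Binary encoding of hyperparameter search spaces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchSpaceEncoding:
    """Bit layout for a list of finite parameter domains."""

    names: tuple[str, ...]
    domains: tuple[tuple, ...]
    bit_widths: tuple[int, ...]

    @property
    def total_bits(self) -> int:
        return sum(self.bit_widths)


def encode_search_space(
    space: Sequence[tuple[str, Sequence]] | dict,
) -> SearchSpaceEncoding:
    """Lay out ceil(log2(|domain|)) bits per parameter.

    Every bit string decodes to a valid setting: the bit integer indexes
    the domain modulo its cardinality.
    """
    items = list(space.items()) if isinstance(space, dict) else list(space)
    names, domains, widths = [], [], []
    for name, domain in items:
        domain = tuple(domain)
        if len(domain) == 0:
            raise ValueError(f"parameter {name!r} has an empty domain")
        names.append(name)
        domains.append(domain)
        widths.append(max(1, math.ceil(math.log2(len(domain)))))
    return SearchSpaceEncoding(
        names=tuple(names), domains=tuple(domains), bit_widths=tuple(widths)
    )


def decode_candidate(
    bits: Sequence[int] | np.ndarray, encoding: SearchSpaceEncoding
) -> dict:
    """Map a bit string onto a parameter setting (total: never fails).

    Bits are consumed parameter by parameter, most significant bit first;
    the resulting integer indexes the domain modulo its size.
    """
    bits = np.asarray(bits).astype(int)
    if bits.shape != (encoding.total_bits,):
        raise ValueError(
            f"expected {encoding.total_bits} bits, got shape {bits.shape}"
        )
    if not np.isin(bits, (0, 1)).all():
        raise ValueError("bit string must contain only 0/1")
    setting = {}
    pos = 0
    for name, domain, width in zip(
        encoding.names, encoding.domains, encoding.bit_widths
    ):
        chunk = bits[pos : pos + width]
        value = int("".join(map(str, chunk)), 2)
        setting[name] = domain[value % len(domain)]
        pos += width
    return setting
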