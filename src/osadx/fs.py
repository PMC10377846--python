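"""Binary particle-swarm wrapper feature selection.

A swarm of bit-vector particles searches the feature-subset lattice.
Real-valued velocities evolve by the classic inertia + cognitive +
social rule; an S-shaped transfer function turns each velocity into a
bit probability; subsets are scored by a weighted sum of the wrapped
classifier's cross-validated error rate and the selected-feature
fraction (lower is better).  An exhaustive-enumeration oracle over all
nonempty subsets is provided for small dimensions to validate the
search.

Two polarity conventions for the binary position update are supported:
``standard`` sets a bit to 1 with probability S(v) (the convention of
the S-shaped binary-swarm literature); ``as_printed`` applies the
inverted rule (bit 0 when rand < S(v)) found in some write-ups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy.special import expit

from .evaluation import CVConfig, error_rate, make_folds
from .masks import as_mask, popcount
from .table import LabeledTable

__all__ = [
    "TF_SCALES",
    "SwarmConfig",
    "ParticleState",
    "FitnessWeights",
    "FitnessValue",
    "FSResult",
    "transfer_value",
    "inertia_at",
    "update_velocity",
    "update_position_binary",
    "fitness",
    "run_bpso",
    "exhaustive_best_subset",
    "save_result",
]

# velocity multiplier inside the sigmoid: S(v) = expit(scale * v)
TF_SCALES = {"S1": 2.0, "S2": 1.0, "S3": 0.5, "S4": 1.0 / 3.0}

POLARITIES = ("standard", "as_printed")


@dataclass(frozen=True)
class SwarmConfig:
    """Swarm hyperparameters.

    ``inertia`` is either a constant or a ``(start, end)`` pair decayed
    linearly over the iteration budget.
    """

    n_particles: int = 10
    n_iterations: int = 100
    inertia: object = (0.9, 0.4)
    c1: float = 2.0
    c2: float = 2.0
    velocity_clamp: float = 6.0
    tf_id: str = "S1"
    polarity: str = "standard"
    seed: int = 0

    def __post_init__(self):
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("acceleration coefficients must be >= 0")
        if self.velocity_clamp <= 0:
            raise ValueError("velocity_clamp must be positive")
        if self.tf_id not in TF_SCALES:
            raise ValueError(f"unknown transfer function {self.tf_id!r}")
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")


@dataclass
class ParticleState:
    """One particle: position bits, velocity, personal best."""

    position: np.ndarray
    velocity: np.ndarray
    pbest: np.ndarray
    pbest_fitness: "FitnessValue"
    generation: int = 0


@dataclass(frozen=True)
class FitnessWeights:
    """Error-rate vs subset-size trade-off weights (sum to 1)."""

    alpha: float = 0.99
    beta: float = 0.01

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.alpha + self.beta - 1.0) > 1e-9:
            raise ValueError("alpha + beta must equal 1")


class FitnessValue(NamedTuple):
    value: float
    error_rate: float
    n_selected: int
    n_total: int


@dataclass
class FSResult:
    """Outcome of one swarm run."""

    mask: np.ndarray
    fitness: FitnessValue
    accuracy: float
    trace: np.ndarray          # best-so-far fitness, one entry per iteration
    seed: int
    fold_seed: int
    n_evaluations: int = 0


# ----------------------------------------------------------------------
# primitive updates
# ----------------------------------------------------------------------

def transfer_value(tf_id: str, v):
    """S-shaped transfer: monotone map from velocity to (0, 1)."""
    if tf_id not in TF_SCALES:
        raise ValueError(f"unknown transfer function {tf_id!r}")
    return expit(TF_SCALES[tf_id] * np.asarray(v, dtype=float))


def inertia_at(config: SwarmConfig, generation: int) -> float:
    """Inertia weight at a given generation (linear schedule)."""
    w = config.inertia
    if np.isscalar(w):
        return float(w)
    start, end = w
    if config.n_iterations == 1:
        return float(start)
    frac = min(generation, config.n_iterations - 1) / (config.n_iterations - 1)
    return float(start + (end - start) * frac)


def update_velocity(state: ParticleState, gbest, config: SwarmConfig, rng) -> np.ndarray:
    """Inertia + cognitive + social velocity update, clamped symmetrically."""
    x = state.position.astype(float)
    pbest = state.pbest.astype(float)
    gbest = as_mask(gbest, x.size).astype(float)
    n = x.size
    r1 = rng.random(n)
    r2 = rng.random(n)
    w = inertia_at(config, state.generation)
    v = (
        w * state.velocity
        + config.c1 * r1 * (pbest - x)
        + config.c2 * r2 * (gbest - x)
    )
    return np.clip(v, -config.velocity_clamp, config.velocity_clamp)


def update_position_binary(velocity, tf_id: str, polarity: str, rng) -> np.ndarray:
    """Draw a bit per dimension against the transfer probability."""
    if polarity not in POLARITIES:
        raise ValueError(f"polarity must be one of {POLARITIES}")
    p = transfer_value(tf_id, velocity)
    draw = rng.random(np.asarray(velocity).shape) < p
    return draw if polarity == "standard" else ~draw


# ----------------------------------------------------------------------
# fitness
# ----------------------------------------------------------------------

def fitness(mask, table: LabeledTable, classifier_spec, weights: FitnessWeights,
            cv=CVConfig(), folds=None) -> FitnessValue:
    """alpha * cv-error + beta * selected-fraction; empty mask -> 1.0.

    ``folds`` may carry precomputed (train, test) index pairs so that
    every subset in a search is scored on identical splits.
    """
    mask = as_mask(mask, table.n_features)
    n_total = mask.size
    n_sel = popcount(mask)
    if n_sel == 0:
        return FitnessValue(1.0, 1.0, 0, n_total)
    y = np.asarray(table.y)
    if folds is None:
        folds = make_folds(y, cv)
    X = table.to_matrix()[:, mask]
    er = error_rate(X, y, classifier_spec, folds)
    value = weights.alpha * er + weights.beta * (n_sel / n_total)
    return FitnessValue(float(value), er, n_sel, n_total)


def _rank_key(fit: FitnessValue, mask) -> tuple:
    # total order: fitness, then fewer features, then lexicographic bits
    return (fit.value, fit.n_selected, tuple(int(b) for b in mask))


# ----------------------------------------------------------------------
# the search
# ----------------------------------------------------------------------

def run_bpso(table: LabeledTable, swarm: SwarmConfig, classifier_spec,
             weights: FitnessWeights = FitnessWeights(),
             cv: CVConfig = CVConfig()) -> FSResult:
    """Run the binary swarm and return the best subset found.

    Positions start uniformly at random, velocities at zero.  Fold
    assignment is fixed for the whole run (seeded from the swarm seed),
    so the fitness of a mask is deterministic and memoized.
    """
    y = np.asarray(table.y)
    if np.unique(y).size < 2:
        raise ValueError("table must contain both classes")
    n = table.n_features
    rng = np.random.default_rng(swarm.seed)
    fold_seed = int(rng.integers(0, 2**31 - 1))
    folds = make_folds(y, CVConfig(cv.k, cv.stratified, fold_seed))

    cache: dict = {}

    def evaluate(mask) -> FitnessValue:
        key = mask.tobytes()
        if key not in cache:
            cache[key] = fitness(mask, table, classifier_spec, weights, folds=folds)
        return cache[key]

    positions = rng.random((swarm.n_particles, n)) < 0.5
    particles = []
    gbest_mask, gbest_fit = None, None
    for i in range(swarm.n_particles):
        fit = evaluate(positions[i])
        particles.append(
            ParticleState(
                position=positions[i].copy(),
                velocity=np.zeros(n),
                pbest=positions[i].copy(),
                pbest_fitness=fit,
            )
        )
        if gbest_fit is None or _rank_key(fit, positions[i]) < _rank_key(gbest_fit, gbest_mask):
            gbest_mask, gbest_fit = positions[i].copy(), fit

    trace = [gbest_fit.value]
    for m in range(swarm.n_iterations):
        for p in particles:
            p.generation = m
            p.velocity = update_velocity(p, gbest_mask, swarm, rng)
            p.position = update_position_binary(
                p.velocity, swarm.tf_id, swarm.polarity, rng
            )
            fit = evaluate(p.position)
            if _rank_key(fit, p.position) < _rank_key(p.pbest_fitness, p.pbest):
                p.pbest = p.position.copy()
                p.pbest_fitness = fit
            if _rank_key(fit, p.position) < _rank_key(gbest_fit, gbest_mask):
                gbest_mask, gbest_fit = p.position.copy(), fit
        trace.append(gbest_fit.value)

    return FSResult(
        mask=gbest_mask,
        fitness=gbest_fit,
        accuracy=1.0 - gbest_fit.error_rate,
        trace=np.asarray(trace),
        seed=swarm.seed,
        fold_seed=fold_seed,
        n_evaluations=len(cache),
    )


def exhaustive_best_subset(table: LabeledTable, classifier_spec,
                           weights: FitnessWeights = FitnessWeights(),
                           cv: CVConfig = CVConfig(),
                           folds=None, max_features: int = 12):
    """Enumerate every nonempty subset and return the fitness minimizer.

    Refuses above ``max_features`` dimensions (2^N evaluations).  Ties
    break toward fewer features, then the lexicographically smallest
    mask.  Returns ``(mask, FitnessValue)``.
    """
    n = table.n_features
    if n > max_features:
        raise ValueError(f"exhaustive search limited to {max_features} features, got {n}")
    y = np.asarray(table.y)
    if folds is None:
        folds = make_folds(y, cv)
    best_mask, best_fit = None, None
    for bits in range(1, 2**n):
        mask = np.array([(bits >> j) & 1 for j in range(n)], dtype=bool)
        fit = fitness(mask, table, classifier_spec, weights, folds=folds)
        if best_fit is None or _rank_key(fit, mask) < _rank_key(best_fit, best_mask):
            best_mask, best_fit = mask, fit
    return best_mask, best_fit


# ----------------------------------------------------------------------
# serialization
# ----------------------------------------------------------------------

def save_result(result: FSResult, out_dir, feature_names, prefix: str = "fs") -> None:
    """Write mask CSV (one 0/1 row), JSON summary, and trace CSV."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = list(feature_names)
    bits = [str(int(b)) for b in result.mask]
    (out / f"{prefix}_mask.csv").write_text(
        ",".join(names) + "\n" + ",".join(bits) + "\n"
    )
    summary = {
        "fitness": result.fitness.value,
        "error_rate": result.fitness.error_rate,
        "accuracy": result.accuracy,
        "n_selected": result.fitness.n_selected,
        "n_total": result.fitness.n_total,
        "seed": result.seed,
        "fold_seed": result.fold_seed,
        "n_evaluations": result.n_evaluations,
    }
    (out / f"{prefix}_summary.json").write_text(json.dumps(summary, indent=2))
    lines = ["iteration,best_fitness"] + [
        f"{i},{v}" for i, v in enumerate(result.trace)
    ]
    (out / f"{prefix}_trace.csv").write_text("\n".join(lines) + "\n")
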