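"""Decision fusion via the Levy-Flight Honey Badger Algorithm (LFHBA).

Several classifiers emit row-stochastic probability matrices; fusion
takes their convex combination ``F = sum_i w_i C_i(X)`` with a simplex
weight vector ``w``.  The weights are found by a population metaheuristic
built from two moves:

* an attraction move toward the incumbent best ``P`` with exponentially
  decaying step, ``X' = X + r (P - X) e^{-t/T}`` with ``r`` a random
  moving factor, and
* a heavy-tailed Levy-flight move, ``X' = X + S * (P - X)`` elementwise,
  where ``S`` is a stable-law step from Mantegna's Gaussian-ratio
  construction, enabling occasional long jumps out of local optima.

Candidates keep a move only when it improves their own fitness (greedy
selection) and the global best is tracked with elitism, so the recorded
best-fitness trace is nonincreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import gamma as _gamma

import numpy as np

from .synthetic import ValidationError

# --------------------------------------------------------------------------
# types


def check_probability_matrix(values: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError(f"probability matrix must be 2-D, got {arr.ndim}-D")
    if (arr < -tol).any():
        raise ValidationError("probability matrix has negative entries")
    if np.abs(arr.sum(axis=1) - 1.0).max() > tol:
        raise ValidationError("probability matrix rows must sum to 1")
    return arr


@dataclass
class LFHBAConfig:
    population_size: int = 20
    iterations: int = 100
    bounds: tuple[float, float] = (-5.0, 5.0)
    r_scale: float = 1.0
    levy_beta: float = 1.5
    # the Levy step multiplies the attraction vector (P - X), so a unit
    # multiplier is the coherent default; sub-unit scales strangle the
    # jumps and the search stalls on the incumbent best
    levy_scale: float = 1.0
    levy_probability: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise ValidationError("population_size must be >= 2")
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if not 0.0 < self.levy_beta <= 2.0:
            raise ValidationError("levy_beta must be in (0, 2]")
        if not 0.0 <= self.levy_probability <= 1.0:
            raise ValidationError("levy_probability must be in [0, 1]")
        lo, hi = self.bounds
        if lo >= hi:
            raise ValidationError("bounds must satisfy low < high")


@dataclass
class OptimizerTrace:
    best_position: list[np.ndarray] = field(default_factory=list)
    best_fitness: list[float] = field(default_factory=list)
    evaluations: int = 0


@dataclass
class FusionWeights:
    w: np.ndarray

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=np.float64)
        if (self.w < 0).any() or abs(self.w.sum() - 1.0) > 1e-9:
            raise ValidationError("fusion weights must lie on the simplex")


# --------------------------------------------------------------------------
# Levy flight


def levy_sigma(beta: float) -> float:
    """Mantegna scale of the Gaussian numerator:
    sigma_u^beta = Gamma(1+beta) sin(pi beta / 2) /
                   [Gamma((1+beta)/2) beta 2^((beta-1)/2)]."""
    num = _gamma(1.0 + beta) * np.sin(np.pi * beta / 2.0)
    den = _gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return float((num / den) ** (1.0 / beta))


def levy_step(beta: float, scale: float, count, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed steps ``S = scale * u / |v|^(1/beta)`` with
    u ~ N(0, sigma_u^2), v ~ N(0, 1); symmetric about zero with tail
    exponent ``beta``."""
    if not 0.0 < beta <= 2.0:
        raise ValidationError(f"levy beta must be in (0, 2], got {beta}")
    u = rng.normal(0.0, levy_sigma(beta), size=count)
    v = rng.normal(0.0, 1.0, size=count)
    return scale * u / np.abs(v) ** (1.0 / beta)


# --------------------------------------------------------------------------
# Honey Badger updates


def hba_update(position: np.ndarray, best: np.ndarray, t: int, T: int,
               rng: np.random.Generator, config: LFHBAConfig) -> np.ndarray:
    """One candidate update: attraction move with probability
    ``1 - levy_probability``, else a Levy move; result clipped to bounds."""
    if not 1 <= t <= T:
        raise ValidationError(f"iteration t={t} outside [1, T={T}]")
    x = np.asarray(position, dtype=np.float64)
    p = np.asarray(best, dtype=np.float64)
    lo, hi = config.bounds
    if (x < lo).any() or (x > hi).any():
        import logging
        logging.getLogger(__name__).warning("hba_update: clipping out-of-bounds input")
        x = np.clip(x, lo, hi)
    if rng.random() >= config.levy_probability:
        r = rng.uniform(0.0, config.r_scale)
        new = x + r * (p - x) * np.exp(-t / T)
    else:
        s = levy_step(config.levy_beta, config.levy_scale, x.shape, rng)
        new = x + s * (p - x)
    return np.clip(new, lo, hi)


def lfhba_optimize(fitness, dimension: int, config: LFHBAConfig):
    """Minimize ``fitness`` over the bounded box.

    Population initialized uniformly in bounds; each candidate is updated
    by :func:`hba_update` toward the incumbent best and replaces itself
    only on improvement; the global best is tracked with elitism.
    Returns ``(best_position, trace)``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds
    pop = rng.uniform(lo, hi, size=(config.population_size, dimension))
    fit = np.empty(config.population_size)
    trace = OptimizerTrace()
    for i in range(config.population_size):
        fit[i] = _eval_fitness(fitness, pop[i])
        trace.evaluations += 1
    best_i = int(fit.argmin())
    best_x, best_f = pop[best_i].copy(), float(fit[best_i])
    for t in range(1, config.iterations + 1):
        for i in range(config.population_size):
            cand = hba_update(pop[i], best_x, t, config.iterations, rng, config)
            f = _eval_fitness(fitness, cand)
            trace.evaluations += 1
            if f < fit[i]:                    # greedy per-candidate selection
                pop[i], fit[i] = cand, f
                if f < best_f:                # global elitism
                    best_x, best_f = cand.copy(), float(f)
        trace.best_position.append(best_x.copy())
        trace.best_fitness.append(best_f)
    return best_x, trace


def _eval_fitness(fitness, x: np.ndarray) -> float:
    f = float(fitness(x))
    if not np.isfinite(f):
        raise ValidationError(f"non-finite fitness at position {x}")
    return f


# --------------------------------------------------------------------------
# fusion


def fuse_predictions(outputs: list[np.ndarray], weights: FusionWeights) -> np.ndarray:
    """Rowwise convex combination ``F = sum_i w_i C_i``; rows stay on the
    simplex when inputs do."""
    w = weights.w if isinstance(weights, FusionWeights) else FusionWeights(weights).w
    if len(outputs) != len(w):
        raise ValidationError(
            f"{len(outputs)} matrices but {len(w)} weights")
    mats = [check_probability_matrix(o) for o in outputs]
    shape = mats[0].shape
    for m in mats:
        if m.shape != shape:
            raise ValidationError("probability matrices must share shape")
    return np.tensordot(w, np.stack(mats), axes=1)


def fused_accuracy(outputs: list[np.ndarray], labels: np.ndarray,
                   weights: FusionWeights) -> float:
    """Argmax accuracy of the fused matrix; argmax ties break toward the
    lowest class index."""
    fused = fuse_predictions(outputs, weights)
    return float((fused.argmax(axis=1) == np.asarray(labels)).mean())


def softmax_simplex(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


def optimize_fusion_weights(outputs: list[np.ndarray], labels: np.ndarray,
                            config: LFHBAConfig, fitness_kind: str = "accuracy"):
    """Search fusion weights with LFHBA.

    The optimizer works in an unconstrained box; each candidate is mapped
    to the simplex by softmax before evaluation.  Fitness is the negative
    validation argmax-accuracy of the fused predictions (or mean
    cross-entropy with ``fitness_kind='cross_entropy'``).  Returns
    ``(FusionWeights, trace)``.
    """
    labels = np.asarray(labels)
    if len(outputs) < 2:
        raise ValidationError("need at least 2 classifiers to fuse")
    if len(np.unique(labels)) < 2:
        raise ValidationError("labels must contain at least two classes")
    mats = [check_probability_matrix(o) for o in outputs]
    for m in mats:
        if m.shape[0] != len(labels):
            raise ValidationError("labels length must match n_samples")
    stacked = np.stack(mats)

    if fitness_kind == "accuracy":
        def fitness(z):
            w = softmax_simplex(z)
            fused = np.tensordot(w, stacked, axes=1)
            return -float((fused.argmax(axis=1) == labels).mean())
    elif fitness_kind == "cross_entropy":
        idx = np.arange(len(labels))

        def fitness(z):
            w = softmax_simplex(z)
            fused = np.tensordot(w, stacked, axes=1)
            return float(-np.log(fused[idx, labels] + 1e-12).mean())
    else:
        raise ValidationError(f"unknown fitness_kind '{fitness_kind}'")

    best_z, trace = lfhba_optimize(fitness, len(outputs), config)
    return FusionWeights(softmax_simplex(best_z)), trace


def uniform_fusion_accuracy(outputs: list[np.ndarray], labels: np.ndarray) -> float:
    """Baseline: plain average of the classifier outputs."""
    n = len(outputs)
    return fused_accuracy(outputs, labels, FusionWeights(np.full(n, 1.0 / n)))


def majority_vote_accuracy(outputs: list[np.ndarray], labels: np.ndarray) -> float:
    """Baseline: per-sample majority over the classifiers' argmax votes
    (ties toward the lowest class index)."""
    votes = np.stack([check_probability_matrix(o).argmax(axis=1) for o in outputs])
    n_classes = outputs[0].shape[1]
    counts = np.zeros((votes.shape[1], n_classes), dtype=int)
    for row in votes:
        np.add.at(counts, (np.arange(len(row)), row), 1)
    return float((counts.argmax(axis=1) == np.asarray(labels)).mean())
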