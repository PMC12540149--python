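"""Osprey Optimisation Algorithm: a bounded continuous metaheuristic.

A population of candidate positions ("ospreys") is initialized uniformly in
a box.  Each iteration, every member performs two greedily accepted moves:

* exploration - move toward a randomly chosen strictly better member (a
  "fish"), ``x' = x + r * (fish - I * x)`` with ``r ~ U[0,1]`` per dimension
  and ``I`` a random integer in {1, 2},
* exploitation - a decaying local perturbation,
  ``x' = x + (LB + r * (UB - LB)) / t`` with ``t`` the 1-based iteration.

Candidates are clipped to the bounds and accepted only if strictly better,
so per-member and population-best fitness are non-increasing.  The module
also provides the wrapper that tunes the autoencoder classifier's
hyperparameters by validation fitness (macro precision TP/(TP+FP) by
default, plain accuracy by switch).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence
import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, precision_score

from .autoencoder import AEHyperparams, AutoencoderClassifier


@dataclass
class SearchSpace:
    """Box constraints; ``integer_dims`` are rounded when decoded."""

    lb: np.ndarray
    ub: np.ndarray
    integer_dims: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        if self.lb.shape != self.ub.shape or self.lb.ndim != 1:
            raise ValueError("lb and ub must be 1-D arrays of equal length")
        if not np.all(self.lb < self.ub):
            raise ValueError("every lower bound must be strictly below its upper bound")

    @property
    def m(self) -> int:
        return self.lb.size

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lb, self.ub)


@dataclass
class FitnessSpec:
    objective: Callable[[np.ndarray], float]
    direction: str = "minimize"

    def __post_init__(self) -> None:
        if self.direction not in ("minimize", "maximize"):
            raise ValueError(f"direction must be minimize or maximize, got {self.direction!r}")

    def evaluate(self, x: np.ndarray) -> float:
        """Internal minimization value (maximization handled by negation)."""
        v = float(self.objective(x))
        if not np.isfinite(v):
            raise ValueError(f"objective returned non-finite value {v} at position {x}")
        return -v if self.direction == "maximize" else v


@dataclass
class OOAState:
    os: np.ndarray                 # (n, m) population
    ff: np.ndarray                 # (n,) fitness (internal minimization scale)
    os_best: np.ndarray
    ff_best: float
    t: int
    T: int
    space: SearchSpace
    fitness: FitnessSpec
    rng: np.random.Generator
    i_mode: str = "integer"        # exploration multiplier: {1,2} or U[1,2]


def init_population(fitness: FitnessSpec, space: SearchSpace, n: int,
                    seed: int | np.random.Generator = 0, T: int = 1,
                    i_mode: str = "integer") -> OOAState:
    """Uniform initialization ``LB + r * (UB - LB)`` plus fitness evaluation."""
    if n < 2:
        raise ValueError(f"population size must be >= 2, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    os = space.lb + rng.random((n, space.m)) * (space.ub - space.lb)
    ff = np.array([fitness.evaluate(x) for x in os])
    best = int(np.argmin(ff))
    return OOAState(os=os, ff=ff, os_best=os[best].copy(), ff_best=float(ff[best]),
                    t=1, T=T, space=space, fitness=fitness, rng=rng, i_mode=i_mode)


def fish_set(state: OOAState, i: int) -> np.ndarray:
    """Indices of strictly better members plus the best member.

    For the best osprey itself this is just the best index; ties are
    excluded by the strict inequality.
    """
    better = np.flatnonzero(state.ff < state.ff[i])
    best = int(np.argmin(state.ff))
    return np.unique(np.append(better, best))


def _accept(state: OOAState, i: int, candidate: np.ndarray) -> None:
    candidate = state.space.clip(candidate)
    f = state.fitness.evaluate(candidate)
    if f < state.ff[i]:
        state.os[i] = candidate
        state.ff[i] = f
        if f < state.ff_best:
            state.ff_best = float(f)
            state.os_best = candidate.copy()


def exploration_step(state: OOAState, i: int) -> None:
    """Move toward a randomly chosen fish; clip; accept if strictly better.

    RNG consumption order: fish choice (one integer), ``r`` (m uniforms),
    ``I`` (m draws: integers in {1,2} or uniforms on [1,2]).
    """
    fs = fish_set(state, i)
    cf = state.os[fs[state.rng.integers(0, len(fs))]]
    r = state.rng.random(state.space.m)
    if state.i_mode == "integer":
        I = state.rng.integers(1, 3, size=state.space.m).astype(float)
    else:
        I = 1.0 + state.rng.random(state.space.m)
    candidate = state.os[i] + r * (cf - I * state.os[i])
    _accept(state, i, candidate)


def exploitation_step(state: OOAState, i: int) -> None:
    """Decaying local perturbation ``x + (LB + r (UB - LB)) / t``; greedy.

    RNG consumption order: ``r`` (m uniforms).  ``t`` is the 1-based
    iteration counter, so the step magnitude decays over the run.
    """
    if state.t < 1:
        raise ValueError(f"iteration counter must be >= 1, got {state.t}")
    r = state.rng.random(state.space.m)
    sp = state.space
    candidate = state.os[i] + (sp.lb + r * (sp.ub - sp.lb)) / state.t
    _accept(state, i, candidate)


@dataclass
class OOAResult:
    best_position: np.ndarray
    best_fitness: float            # on the caller's scale (un-negated)
    history: pd.DataFrame          # iteration, best_fitness, mean_fitness
    state: OOAState = field(repr=False, default=None)


def optimize(fitness: FitnessSpec | Callable[[np.ndarray], float], space: SearchSpace,
             n: int = 20, T: int = 100, seed: int = 0, i_mode: str = "integer") -> OOAResult:
    """Run the full optimizer: init, then per iteration each member explores
    then exploits.  Best-so-far fitness is non-increasing in ``t``."""
    if not isinstance(fitness, FitnessSpec):
        fitness = FitnessSpec(fitness)
    if T < 1:
        raise ValueError(f"iteration budget T must be >= 1, got {T}")
    state = init_population(fitness, space, n, seed, T=T, i_mode=i_mode)
    sign = -1.0 if fitness.direction == "maximize" else 1.0
    rows = []
    for t in range(1, T + 1):
        state.t = t
        for i in range(n):
            exploration_step(state, i)
            exploitation_step(state, i)
        rows.append((t, sign * state.ff_best, sign * float(np.mean(state.ff))))
    history = pd.DataFrame(rows, columns=["iteration", "best_fitness", "mean_fitness"])
    return OOAResult(best_position=state.os_best.copy(),
                     best_fitness=sign * state.ff_best, history=history, state=state)


# ---------------------------------------------------------------------------
# hyperparameter tuning wrapper

#: default search space over the autoencoder classifier's hyperparameters
DEFAULT_AE_SPACE: list[dict] = [
    {"name": "latent_dim", "low": 8, "high": 64, "type": "int"},
    {"name": "learning_rate", "low": 1e-4, "high": 1e-2, "type": "float"},
    {"name": "batch_size", "low": 8, "high": 64, "type": "int"},
    {"name": "dropout", "low": 0.0, "high": 0.5, "type": "float"},
]


def _space_from_dims(dims: Sequence[dict]) -> tuple[SearchSpace, list[str]]:
    names = [d["name"] for d in dims]
    lb = np.array([d["low"] for d in dims], dtype=float)
    ub = np.array([d["high"] for d in dims], dtype=float)
    integer_dims = tuple(j for j, d in enumerate(dims) if d.get("type") == "int")
    return SearchSpace(lb, ub, integer_dims), names


def decode_position(x: np.ndarray, space: SearchSpace, names: list[str],
                    epochs: int) -> AEHyperparams:
    """Map a continuous position to hyperparameters (integer dims rounded)."""
    values = {}
    for j, name in enumerate(names):
        v = float(np.clip(x[j], space.lb[j], space.ub[j]))
        values[name] = int(round(v)) if j in space.integer_dims else v
    return AEHyperparams(epochs=epochs, **values)


def tune_ae_hyperparams(
    X_train: np.ndarray, y_train: np.ndarray,
    X_val: np.ndarray, y_val: np.ndarray,
    dims: Sequence[dict] | None = None,
    n: int = 6, T: int = 4, seed: int = 0,
    fitness_metric: str = "precision",
    ae_epochs: int = 40,
    n_classes: int = 4,
) -> tuple[AEHyperparams, OOAResult]:
    """Tune the autoencoder classifier's hyperparameters with the optimizer.

    The objective trains the classifier on the train split and scores the
    validation split with macro precision TP/(TP+FP) (``fitness_metric=
    'accuracy'`` switches to plain accuracy); the optimizer maximizes it via
    internal negation.  Per-candidate training uses reduced ``ae_epochs``
    and a seed derived from (master seed, candidate index), so the search is
    deterministic.  A candidate whose training fails scores worst-possible
    and the search continues.
    """
    if fitness_metric not in ("precision", "accuracy"):
        raise ValueError(f"fitness_metric must be precision or accuracy, got {fitness_metric!r}")
    dims = list(dims) if dims is not None else DEFAULT_AE_SPACE
    space, names = _space_from_dims(dims)
    counter = {"i": 0}

    def objective(x: np.ndarray) -> float:
        idx = counter["i"]
        counter["i"] += 1
        try:
            h = decode_position(x, space, names, epochs=ae_epochs)
            clf = AutoencoderClassifier(h, n_classes=n_classes)
            clf.fit(X_train, y_train, seed=int((seed * 100003 + idx) % 2**31))
            y_pred = clf.predict(X_val)
            if fitness_metric == "accuracy":
                return float(accuracy_score(y_val, y_pred))
            return float(precision_score(y_val, y_pred, average="macro", zero_division=0))
        except (ValueError, FloatingPointError, RuntimeError) as exc:
            warnings.warn(f"candidate {idx} failed ({exc}); scored worst-possible")
            return 0.0

    result = optimize(FitnessSpec(objective, direction="maximize"), space, n=n, T=T, seed=seed)
    best = decode_position(result.best_position, space, names, epochs=ae_epochs)
    return best, result
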