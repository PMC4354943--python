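"""Derringer-Suich desirability functions and multi-response profile optimization.

Each response is mapped to a desirability d in [0, 1] by a piecewise-linear
ramp (maximize / minimize / target), and responses are combined by an
importance-weighted geometric mean.  The profile optimizer maximizes the
overall desirability of model predictions over the coded factor cube with
a seeded multi-start local search, and checkpoint analysis quantifies
prediction-versus-observation percent error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .errors import ConfigurationError, DomainError
from .rsm import FittedModel

MAXIMIZE = "maximize"
MINIMIZE = "minimize"
TARGET = "target"


@dataclass(frozen=True)
class ResponseGoal:
    """Goal for one response: direction, anchor values and relative importance.

    Under ``maximize`` the desirability ramps linearly from 0 at ``lower``
    to 1 at ``upper``; ``minimize`` is the mirror image; ``target`` is a
    triangle peaking at ``target``.
    """

    name: str
    goal: str
    lower: float | None = None
    upper: float | None = None
    target: float | None = None
    importance: float = 1.0

    def __post_init__(self) -> None:
        if self.goal not in (MAXIMIZE, MINIMIZE, TARGET):
            raise ConfigurationError(f"unknown goal {self.goal!r} for {self.name!r}")
        if self.importance <= 0:
            raise ConfigurationError(f"importance must be > 0 for {self.name!r}")
        if self.goal in (MAXIMIZE, MINIMIZE):
            if self.lower is None or self.upper is None or not self.lower < self.upper:
                raise ConfigurationError(
                    f"{self.goal} goal for {self.name!r} needs anchors lower < upper"
                )
        else:
            if None in (self.lower, self.upper, self.target) or not (
                self.lower < self.target < self.upper
            ):
                raise ConfigurationError(
                    f"target goal for {self.name!r} needs lower < target < upper"
                )


def d_individual(value, goal: ResponseGoal):
    """Desirability of a response value (vectorized over ``value``)."""
    v = np.asarray(value, dtype=float)
    if goal.goal == MAXIMIZE:
        d = (v - goal.lower) / (goal.upper - goal.lower)
    elif goal.goal == MINIMIZE:
        d = (goal.upper - v) / (goal.upper - goal.lower)
    else:
        left = (v - goal.lower) / (goal.target - goal.lower)
        right = (goal.upper - v) / (goal.upper - goal.target)
        d = np.where(v <= goal.target, left, right)
    d = np.clip(d, 0.0, 1.0)
    return float(d) if np.ndim(value) == 0 else d


def d_overall(ds, importances=None) -> float:
    """Importance-weighted geometric mean of individual desirabilities."""
    ds = np.asarray(ds, dtype=float)
    if ds.size == 0:
        raise ConfigurationError("at least one desirability component is required")
    if importances is None:
        w = np.ones(ds.size)
    else:
        w = np.asarray(importances, dtype=float)
        if w.size != ds.size:
            raise ConfigurationError("importances and desirabilities differ in length")
        if np.any(w <= 0):
            raise ConfigurationError("importances must be positive")
    if np.any(ds == 0):
        return 0.0
    return float(np.exp(np.sum(w * np.log(ds)) / np.sum(w)))


def desirability_of_point(
    point, models: dict[str, FittedModel], goals: list[ResponseGoal]
) -> float:
    preds = [models[g.name].predict(point) for g in goals]
    ds = [d_individual(p, g) for p, g in zip(preds, goals)]
    return d_overall(ds, [g.importance for g in goals])


def optimize_profile(
    models: dict[str, FittedModel],
    goals: list[ResponseGoal],
    bounds: list[tuple[float, float]] | None = None,
    n_starts_per_dim: int = 5,
    seed: int = 0,
    tol: float = 1e-6,
):
    """Maximize overall desirability of predicted responses over the coded cube.

    Multi-start Nelder-Mead from a regular grid of seeds (jittered
    deterministically) with L-BFGS-free local refinement; returns
    ``(optimal coded point, {response: prediction}, overall desirability,
    degenerate_flag)``.  ``degenerate_flag`` is True when every start ends
    at zero desirability (goals unreachable anywhere in the cube).
    """
    if not goals:
        raise ConfigurationError("at least one response goal is required")
    names = {g.name for g in goals}
    missing = names - set(models)
    if missing:
        raise ConfigurationError(f"no fitted model for goal(s): {sorted(missing)}")
    k = next(iter(models.values())).n_factors
    if any(m.n_factors != k for m in models.values()):
        raise ConfigurationError("all models must share one factor space")
    if bounds is None:
        bounds = [(-1.0, 1.0)] * k
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def neg_d(x):
        x = np.clip(x, lo, hi)
        return -desirability_of_point(x, models, goals)

    # Seeded grid of starting points (n_starts_per_dim per axis).
    axes = [np.linspace(b[0], b[1], n_starts_per_dim) for b in bounds]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, k)
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-0.01, 0.01, size=grid.shape) * (hi - lo)
    starts = np.clip(grid + jitter, lo, hi)

    best_x, best_f = starts[0], neg_d(starts[0])
    for x0 in starts:
        res = scipy.optimize.minimize(
            neg_d, x0, method="Nelder-Mead",
            options={"xatol": tol, "fatol": tol, "maxiter": 400},
        )
        if res.fun < best_f:
            best_x, best_f = np.clip(res.x, lo, hi), res.fun

    d_best = -best_f
    degenerate = d_best <= 0.0
    preds = {g.name: float(models[g.name].predict(best_x)) for g in goals}
    return best_x, preds, d_best, degenerate


def checkpoint_error(predicted: float, observed: float) -> float:
    """Percent error between model prediction and a confirmation run: 100*|obs-pred|/|obs|."""
    if observed == 0:
        raise DomainError("percent error is undefined for observed = 0")
    return 100.0 * abs(observed - predicted) / abs(observed)
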