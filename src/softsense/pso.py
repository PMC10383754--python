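"""Particle swarm optimisation of kinetic parameters against trajectory data.

The kinetic model has many parameters and the RMSE criterion surface is
multimodal, so a population-based global search is used: standard global-best
PSO with inertia/cognitive/social updates

    v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x),

reflecting positions at the box bounds.  The fit criterion is a weighted mean
of per-variable RMSEs, each variable pre-normalised by the standard deviation
of its observations so that cell counts, g/L and mmol/L signals are
commensurable.  A failed simulation maps to a large finite penalty, never an
exception, so the swarm can keep moving.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinetics import FeedSchedule, KineticParams, KineticState, simulate
from .pls import r2 as _r2
from .pls import rmse as _rmse

__all__ = ["FitProblem", "PSOConfig", "FitResult", "criterion", "pso_minimize",
           "fit_kinetics", "PENALTY"]

PENALTY = 1e6  # criterion value assigned to unsimulable parameter sets


@dataclass
class PSOConfig:
    """Swarm hyperparameters (constriction-style defaults)."""

    n_particles: int = 30
    n_iterations: int = 300
    inertia: float = 0.729
    cognitive: float = 1.494
    social: float = 1.494
    velocity_clamp: float = 0.5  # fraction of box range
    seed: int | None = 0
    stall_iterations: int | None = None  # stop early after this many non-improving iters

    def __post_init__(self):
        if self.n_particles < 1:
            raise ValueError("need at least 1 particle")
        if self.inertia <= 0 or self.cognitive < 0 or self.social < 0:
            raise ValueError("inertia must be positive, c1/c2 non-negative")


@dataclass
class FitResult:
    """Best point found, its criterion value, and the gbest convergence trace."""

    best_x: np.ndarray
    best_value: float
    trace: np.ndarray
    seed: int | None
    best_params: KineticParams | None = None
    per_variable: dict = field(default_factory=dict)

    @property
    def n_iterations(self) -> int:
        return self.trace.size


@dataclass
class FitProblem:
    """A kinetic-parameter estimation problem.

    ``free`` maps parameter names to finite (lower, upper) bounds;
    ``observations`` is a tidy frame with columns variable/time_h/value and an
    optional weight column.  Observable names follow
    :func:`softsense.kinetics.observables` (glucose, glutamine, lactate,
    ammonium, vcc, tcc, mab, f_g0).
    """

    free: dict
    base_params: KineticParams
    state0: KineticState
    observations: pd.DataFrame
    schedule: FeedSchedule | None = None
    t_end: float = 336.0
    grid_h: float = 1.0
    rtol: float = 1e-6
    atol: float = 1e-9

    def __post_init__(self):
        self.observations = pd.DataFrame(self.observations)
        required = {"variable", "time_h", "value"}
        if not required <= set(self.observations.columns):
            raise ValueError(f"observations need columns {sorted(required)}")
        if "weight" not in self.observations.columns:
            self.observations["weight"] = 1.0
        for name, (lo, hi) in self.free.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name!r} must be finite with lower < upper")
        tmax = self.observations["time_h"].max()
        if tmax > self.t_end:
            raise ValueError("observations extend beyond the simulation horizon")

    @property
    def names(self) -> list[str]:
        return list(self.free)

    @property
    def bounds(self) -> np.ndarray:
        return np.array([self.free[n] for n in self.names], dtype=float)

    def params_from_vector(self, x) -> KineticParams:
        return self.base_params.replace(**dict(zip(self.names, map(float, x))))


def _per_variable_errors(problem: FitProblem, params: KineticParams) -> dict:
    traj = simulate(problem.state0, params, problem.schedule, t_end=problem.t_end,
                    grid_h=problem.grid_h, rtol=problem.rtol, atol=problem.atol)
    obs_frame = traj.observables()
    result = {}
    for variable, group in problem.observations.groupby("variable"):
        if variable not in obs_frame.columns:
            raise KeyError(f"unknown observable {variable!r}")
        sim = np.interp(group["time_h"].to_numpy(), obs_frame["time_h"].to_numpy(),
                        obs_frame[variable].to_numpy())
        y = group["value"].to_numpy(dtype=float)
        result[variable] = {
            "rmse": _rmse(y, sim),
            "r2": _r2(y, sim) if np.std(y) > 0 else float("nan"),
            "scale": float(np.std(y)) or 1.0,
            "weight": float(group["weight"].mean()),
        }
    return result


def criterion(x, problem: FitProblem) -> float:
    """Combined weighted RMSE of a candidate parameter vector (penalty on failure)."""
    try:
        per_var = _per_variable_errors(problem, problem.params_from_vector(x))
    except (RuntimeError, ValueError, FloatingPointError, OverflowError):
        return PENALTY
    num = sum(v["weight"] * v["rmse"] / v["scale"] for v in per_var.values())
    den = sum(v["weight"] for v in per_var.values())
    value = num / den
    return float(value) if np.isfinite(value) else PENALTY


def pso_minimize(f, bounds, config: PSOConfig | None = None) -> FitResult:
    """Global-best PSO over a box; deterministic per seed.

    ``bounds`` is an (n_dim, 2) array of finite (lower, upper) pairs.
    Positions leaving the box are reflected and their velocity component
    negated.  Returns the best-ever point with a non-increasing gbest trace.
    """
    config = config or PSOConfig()
    bounds = np.atleast_2d(np.asarray(bounds, dtype=float))
    lo, hi = bounds[:, 0], bounds[:, 1]
    if not np.all(np.isfinite(bounds)) or not np.all(lo < hi):
        raise ValueError("bounds must be finite with lower < upper")
    span = hi - lo
    vmax = config.velocity_clamp * span
    rng = np.random.default_rng(config.seed)
    n, dim = config.n_particles, bounds.shape[0]

    x = lo + span * rng.random((n, dim))
    v = (rng.random((n, dim)) - 0.5) * span * 0.1
    pbest_x = x.copy()
    pbest_f = np.array([f(xi) for xi in x], dtype=float)
    g = int(np.argmin(pbest_f))
    gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])

    trace = [gbest_f]
    stall = 0
    for _ in range(config.n_iterations):
        r1 = rng.random((n, dim))
        r2_ = rng.random((n, dim))
        v = (config.inertia * v + config.cognitive * r1 * (pbest_x - x)
             + config.social * r2_ * (gbest_x - x))
        v = np.clip(v, -vmax, vmax)
        x = x + v
        # reflect at the box walls
        for _ in range(3):  # a large step can overshoot both walls
            below, above = x < lo, x > hi
            if not (below.any() or above.any()):
                break
            x = np.where(below, 2 * lo - x, x)
            x = np.where(above, 2 * hi - x, x)
            v = np.where(below | above, -v, v)
        x = np.clip(x, lo, hi)

        fx = np.array([f(xi) for xi in x], dtype=float)
        improved = fx < pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = fx[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])
            stall = 0
        else:
            stall += 1
        trace.append(gbest_f)
        if config.stall_iterations is not None and stall >= config.stall_iterations:
            break
    return FitResult(best_x=gbest_x, best_value=gbest_f,
                     trace=np.array(trace), seed=config.seed)


def fit_kinetics(problem: FitProblem, config: PSOConfig | None = None) -> FitResult:
    """PSO fit of the free kinetic parameters; reports per-variable RMSE and R2."""
    config = config or PSOConfig()
    if not problem.free:
        value = criterion(np.array([]), problem)
        result = FitResult(best_x=np.array([]), best_value=value,
                           trace=np.array([value]), seed=config.seed,
                           best_params=problem.base_params)
    else:
        result = pso_minimize(lambda x: criterion(x, problem), problem.bounds, config)
        result.best_params = problem.params_from_vector(result.best_x)
    try:
        result.per_variable = {
            k: {"rmse": v["rmse"], "r2": v["r2"]}
            for k, v in _per_variable_errors(problem, result.best_params).items()
        }
    except (RuntimeError, ValueError):
        result.per_variable = {}
    return result
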