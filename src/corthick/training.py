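"""Two-stage network training and validation-driven hidden-size selection.

Each region's network is trained in two steps.  Simulated annealing first
explores the weight space globally: the temperature steps linearly from 15
down to 0.001 over 100 levels with 100 candidate perturbations per level,
Metropolis acceptance on the MSE, and best-so-far bookkeeping.  The annealed
weights then seed Levenberg-Marquardt, a damped Gauss-Newton least-squares
refinement that only ever accepts steps that strictly decrease the MSE and
stops at 1,000 iterations or when the MSE reaches the 1e-5 goal.

The number of hidden neurons H is chosen on a seeded 80/20 train/validation
split: H grows from 0 and the search stops at the first H whose validation
MSE fails to improve on the previous one; the previous H wins.  Final models
are then refit on all samples at the chosen H.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .neuralnet import Dataset, MLPModel, mse, weight_gradient


@dataclass
class SAConfig:
    """Simulated-annealing schedule (defaults follow the study settings)."""

    t_initial: float = 15.0
    t_final: float = 0.001
    n_temperatures: int = 100
    iters_per_temperature: int = 100
    cooling: str = "linear"
    perturb_scale: float = 1.0
    init_half_range: float = 0.5
    weight_bound: float = 8.0

    def __post_init__(self) -> None:
        if not (self.t_initial > self.t_final > 0):
            raise ValueError("need t_initial > t_final > 0")
        if self.n_temperatures < 1 or self.iters_per_temperature < 1:
            raise ValueError("temperature and iteration counts must be >= 1")
        if self.cooling != "linear":
            raise ValueError(f"unsupported cooling schedule: {self.cooling!r}")

    def temperatures(self) -> np.ndarray:
        return np.linspace(self.t_initial, self.t_final, self.n_temperatures)


@dataclass
class LMConfig:
    """Levenberg-Marquardt stopping and damping controls."""

    max_iterations: int = 1000
    goal_mse: float = 1e-5
    lambda_init: float = 1e-3
    lambda_up: float = 10.0
    lambda_down: float = 10.0
    lambda_max: float = 1e12

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.goal_mse <= 0 or self.lambda_init <= 0:
            raise ValueError("goal_mse and lambda_init must be positive")


@dataclass
class TrainResult:
    model: MLPModel
    train_mse: float
    n_lm_iterations_used: int
    converged_by_goal: bool
    validation_mse: Optional[float] = None
    mse_trace: list = field(default_factory=list)


@dataclass
class SelectionResult:
    chosen_h: int
    trace: list  # (H, train_mse, validation_mse)


class SingularSystemError(RuntimeError):
    """LM normal equations unsolvable even at maximal damping."""


def anneal(
    data: Dataset,
    n_hidden: int,
    config: SAConfig,
    rng: np.random.Generator,
) -> MLPModel:
    """Global weight search by simulated annealing; returns the best model.

    The perturbation draws Gaussian noise for every weight jointly, with
    standard deviation shrinking proportionally to the temperature, so moves
    start large and become local as the system cools.  Candidates are kept
    inside the box [-weight_bound, weight_bound]: with inputs scaled to
    [-1, 1], weights beyond a few units only push tanh deeper into
    saturation, so an unbounded walk would diffuse into a flat, redundant
    region of the error surface during the hot phase and never return.
    """
    template = MLPModel.zeros(n_hidden)
    p = template.n_params
    current = rng.uniform(-config.init_half_range, config.init_half_range, size=p)
    current_mse = mse(template.with_params(current), data)
    best, best_mse = current.copy(), current_mse
    for temp in config.temperatures():
        sd = config.perturb_scale * temp / config.t_initial
        for _ in range(config.iters_per_temperature):
            cand = np.clip(
                current + rng.normal(0.0, sd, size=p),
                -config.weight_bound,
                config.weight_bound,
            )
            cand_mse = mse(template.with_params(cand), data)
            delta = cand_mse - current_mse
            if delta <= 0 or rng.random() < math.exp(-delta / temp):
                current, current_mse = cand, cand_mse
                if current_mse < best_mse:
                    best, best_mse = current.copy(), current_mse
    model = template.with_params(best)
    model.training_metadata["sa_mse"] = best_mse
    return model


def levenberg_marquardt(
    model: MLPModel, data: Dataset, config: LMConfig
) -> TrainResult:
    """Damped Gauss-Newton refinement of a model's weights.

    Accepted steps strictly decrease the MSE, so the accepted-MSE sequence
    is monotone non-increasing; rejected steps only raise the damping.
    Stops on the MSE goal, the iteration cap, or damping overflow (stall).
    """
    params = model.to_params()
    current = model.with_params(params)
    current_mse = mse(current, data)
    trace = [current_mse]
    lam = config.lambda_init
    n_iter = 0
    eye = np.eye(params.size)
    while current_mse > config.goal_mse and n_iter < config.max_iterations:
        n_iter += 1
        r = current.forward(data.x) - data.t
        _, jac = weight_gradient(current, data)
        jtj = jac.T @ jac
        jtr = jac.T @ r
        try:
            delta = np.linalg.solve(jtj + lam * eye, -jtr)
        except np.linalg.LinAlgError:
            lam *= config.lambda_up
            if lam > config.lambda_max:
                raise SingularSystemError(
                    "normal equations singular at maximal damping"
                )
            continue
        cand = current.with_params(params + delta)
        cand_mse = mse(cand, data)
        if cand_mse < current_mse:
            params = params + delta
            current, current_mse = cand, cand_mse
            trace.append(current_mse)
            lam = max(lam / config.lambda_down, 1e-15)
        else:
            lam *= config.lambda_up
            if lam > config.lambda_max:
                break  # stalled: no descent direction at any damping
    current.training_metadata["lm_mse"] = current_mse
    return TrainResult(
        model=current,
        train_mse=current_mse,
        n_lm_iterations_used=n_iter,
        converged_by_goal=current_mse <= config.goal_mse,
        mse_trace=trace,
    )


def train_region(
    data: Dataset,
    n_hidden: int,
    sa_config: SAConfig,
    lm_config: LMConfig,
    rng: np.random.Generator,
    n_restarts: int = 1,
) -> TrainResult:
    """Two-stage training: annealing for initial weights, then LM polish.

    ``n_restarts`` repeats the whole two-stage run and keeps the result
    with the lowest training MSE, guarding against occasional poor local
    optima on multi-inflection targets; the default is a single run.
    """
    best: TrainResult | None = None
    for _ in range(max(1, n_restarts)):
        annealed = anneal(data, n_hidden, sa_config, rng)
        result = levenberg_marquardt(annealed, data, lm_config)
        result.model.training_metadata["sa_mse"] = annealed.training_metadata["sa_mse"]
        if best is None or result.train_mse < best.train_mse:
            best = result
    return best


def split_dataset(
    data: Dataset, train_fraction: float, rng: np.random.Generator
) -> tuple[Dataset, Dataset]:
    """Seeded uniform random split into training and validation parts."""
    n = len(data)
    n_train = int(round(train_fraction * n))
    if n_train < 1 or n - n_train < 1:
        raise ValueError(
            f"cannot split {n} samples into nonempty "
            f"{train_fraction:.0%}/{1 - train_fraction:.0%} parts"
        )
    perm = rng.permutation(n)
    tr, va = perm[:n_train], perm[n_train:]
    return Dataset(data.x[tr], data.t[tr]), Dataset(data.x[va], data.t[va])


def select_hidden_size(
    data: Dataset,
    sa_config: SAConfig,
    lm_config: LMConfig,
    rng: np.random.Generator,
    train_fraction: float = 0.8,
    max_hidden: int = 10,
    min_rel_improvement: float = 0.05,
) -> SelectionResult:
    """Grow H from 0 until the validation MSE stops decreasing.

    The same seeded split is reused for every H so validation errors are
    comparable.  Continuation requires a material improvement: the search
    ends at the first H whose validation MSE fails to drop by more than
    ``min_rel_improvement`` (relative) below the previous H's, and the
    previous H is returned.  The threshold exists because with a finite
    validation set, sub-percent "improvements" are statistically
    indistinguishable from split noise and a strict comparison inflates H
    spuriously; pass 0.0 for the strict rule.
    """
    if len(data) < 10:
        raise ValueError("hidden-size selection needs at least 10 samples")
    train, val = split_dataset(data, train_fraction, rng)
    return select_hidden_size_presplit(
        train,
        val,
        sa_config,
        lm_config,
        rng,
        max_hidden=max_hidden,
        min_rel_improvement=min_rel_improvement,
    )


def select_hidden_size_presplit(
    train: Dataset,
    val: Dataset,
    sa_config: SAConfig,
    lm_config: LMConfig,
    rng: np.random.Generator,
    max_hidden: int = 10,
    min_rel_improvement: float = 0.05,
) -> SelectionResult:
    """Hidden-size search on an externally prepared train/validation split.

    Lets callers scale the two parts with a scaler fitted on the training
    portion only, avoiding validation leakage.
    """
    trace = []
    prev_val = None
    for h in range(max_hidden + 1):
        res = train_region(train, h, sa_config, lm_config, rng)
        val_mse = mse(res.model, val)
        trace.append((h, res.train_mse, val_mse))
        if prev_val is not None and val_mse >= prev_val * (1.0 - min_rel_improvement):
            return SelectionResult(chosen_h=h - 1, trace=trace)
        prev_val = val_mse
    return SelectionResult(chosen_h=max_hidden, trace=trace)
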