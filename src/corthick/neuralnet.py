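"""The 1-H-1 all-tanh multilayer perceptron used to model one region.

Each network maps a scaled age x in [-1, 1] to a scaled thickness:

    y = tanh( b_out + sum_j w_j * tanh(b_j + h_j * x) ),   j = 1..H

where h_j are input weights, w_j output weights, and every neuron (hidden
and output) carries a bias.  H = 0 degenerates to a single tanh output
neuron on an affine input, y = tanh(b_out + v * x), the minimal all-tanh
network.  Because the output activation is tanh, |y| < 1 strictly, which is
why targets are min-max scaled (see :mod:`corthick.preprocess`).

Parameters are exposed as a flat vector in the fixed order
(h_1..h_H, b_1..b_H, w_1..w_H, b_out), or (v, b_out) when H = 0, so the
optimizers in :mod:`corthick.training` can treat the model generically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .preprocess import ScalingTransform


@dataclass
class MLPModel:
    n_hidden: int
    input_weights: np.ndarray  # h_j, shape (H,)
    input_biases: np.ndarray  # b_j, shape (H,)
    output_weights: np.ndarray  # w_j, shape (H,)
    output_bias: float
    direct_weight: float = 0.0  # v, used only when H == 0
    input_scaler: Optional[ScalingTransform] = None
    output_scaler: Optional[ScalingTransform] = None
    region: Optional[str] = None
    hemisphere: Optional[str] = None
    training_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        h = self.n_hidden
        self.input_weights = np.asarray(self.input_weights, dtype=float).reshape(h)
        self.input_biases = np.asarray(self.input_biases, dtype=float).reshape(h)
        self.output_weights = np.asarray(self.output_weights, dtype=float).reshape(h)
        self.output_bias = float(self.output_bias)
        self.direct_weight = float(self.direct_weight)
        for arr in (self.input_weights, self.input_biases, self.output_weights):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite network parameter")
        if not np.isfinite(self.output_bias) or not np.isfinite(self.direct_weight):
            raise ValueError("non-finite network parameter")

    # ---- parameter vector interface -------------------------------------

    @property
    def n_params(self) -> int:
        return 2 if self.n_hidden == 0 else 3 * self.n_hidden + 1

    def to_params(self) -> np.ndarray:
        if self.n_hidden == 0:
            return np.array([self.direct_weight, self.output_bias])
        return np.concatenate(
            [
                self.input_weights,
                self.input_biases,
                self.output_weights,
                [self.output_bias],
            ]
        )

    def with_params(self, params: np.ndarray) -> "MLPModel":
        """A copy of this model with its free parameters replaced."""
        params = np.asarray(params, dtype=float)
        if params.size != self.n_params:
            raise ValueError(
                f"expected {self.n_params} parameters, got {params.size}"
            )
        h = self.n_hidden
        if h == 0:
            return MLPModel(
                n_hidden=0,
                input_weights=np.empty(0),
                input_biases=np.empty(0),
                output_weights=np.empty(0),
                output_bias=params[1],
                direct_weight=params[0],
                input_scaler=self.input_scaler,
                output_scaler=self.output_scaler,
                region=self.region,
                hemisphere=self.hemisphere,
                training_metadata=dict(self.training_metadata),
            )
        return MLPModel(
            n_hidden=h,
            input_weights=params[:h],
            input_biases=params[h : 2 * h],
            output_weights=params[2 * h : 3 * h],
            output_bias=params[3 * h],
            input_scaler=self.input_scaler,
            output_scaler=self.output_scaler,
            region=self.region,
            hemisphere=self.hemisphere,
            training_metadata=dict(self.training_metadata),
        )

    @classmethod
    def zeros(cls, n_hidden: int, **kwargs) -> "MLPModel":
        return cls(
            n_hidden=n_hidden,
            input_weights=np.zeros(n_hidden),
            input_biases=np.zeros(n_hidden),
            output_weights=np.zeros(n_hidden),
            output_bias=0.0,
            **kwargs,
        )

    # ---- evaluation ------------------------------------------------------

    def forward(self, x):
        """Scaled thickness prediction for scaled age(s) ``x``; |y| < 1."""
        x = np.asarray(x, dtype=float)
        if self.n_hidden == 0:
            z = self.output_bias + self.direct_weight * x
        else:
            a = np.tanh(
                self.input_biases + np.multiply.outer(x, self.input_weights)
            )
            z = self.output_bias + a @ self.output_weights
        y = np.tanh(z)
        return float(y) if y.ndim == 0 else y

    # ---- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "hemisphere": self.hemisphere,
            "n_hidden": self.n_hidden,
            "parameters": {
                "input_weights": self.input_weights.tolist(),
                "input_biases": self.input_biases.tolist(),
                "output_weights": self.output_weights.tolist(),
                "output_bias": self.output_bias,
                "direct_weight": self.direct_weight,
            },
            "scalers": {
                "input": self.input_scaler.to_dict() if self.input_scaler else None,
                "output": self.output_scaler.to_dict()
                if self.output_scaler
                else None,
            },
            "training_metadata": self.training_metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPModel":
        p = d["parameters"]
        sc = d.get("scalers") or {}
        return cls(
            n_hidden=int(d["n_hidden"]),
            input_weights=np.asarray(p["input_weights"], dtype=float),
            input_biases=np.asarray(p["input_biases"], dtype=float),
            output_weights=np.asarray(p["output_weights"], dtype=float),
            output_bias=float(p["output_bias"]),
            direct_weight=float(p.get("direct_weight", 0.0)),
            input_scaler=ScalingTransform.from_dict(sc["input"])
            if sc.get("input")
            else None,
            output_scaler=ScalingTransform.from_dict(sc["output"])
            if sc.get("output")
            else None,
            region=d.get("region"),
            hemisphere=d.get("hemisphere"),
            training_metadata=d.get("training_metadata", {}),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "MLPModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class Dataset:
    """Scaled training pairs: ages x and targets t, both in [-1, 1]."""

    x: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        t = np.asarray(self.t, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "t", t)
        if x.ndim != 1 or t.ndim != 1 or x.size != t.size:
            raise ValueError("x and t must be 1-d arrays of equal length")
        if x.size < 1:
            raise ValueError("dataset must be nonempty")

    def __len__(self) -> int:
        return self.x.size


def mse(model: MLPModel, data: Dataset) -> float:
    """Mean squared error of the model's scaled predictions."""
    r = model.forward(data.x) - data.t
    return float(np.mean(np.square(r)))


def residuals(model: MLPModel, data: Dataset) -> np.ndarray:
    return model.forward(data.x) - data.t


def weight_gradient(model: MLPModel, data: Dataset):
    """Analytic per-sample Jacobian of the residuals and the MSE gradient.

    Returns
    -------
    grad : ndarray, shape (n_params,)
        Gradient of the MSE with respect to the flat parameter vector.
    jac : ndarray, shape (n_samples, n_params)
        d residual_i / d theta_k (residual = prediction - target, so this is
        also the Jacobian of the predictions).
    """
    x = data.x
    n = x.size
    if model.n_hidden == 0:
        z = model.output_bias + model.direct_weight * x
        y = np.tanh(z)
        dy_dz = 1.0 - y**2
        jac = np.column_stack([dy_dz * x, dy_dz])
    else:
        pre = model.input_biases + np.multiply.outer(x, model.input_weights)
        a = np.tanh(pre)  # (n, H)
        z = model.output_bias + a @ model.output_weights
        y = np.tanh(z)
        dy_dz = 1.0 - y**2  # (n,)
        da = 1.0 - a**2  # (n, H)
        common = dy_dz[:, None] * model.output_weights[None, :] * da  # (n, H)
        jac = np.concatenate(
            [common * x[:, None], common, dy_dz[:, None] * a, dy_dz[:, None]],
            axis=1,
        )
    r = y - data.t
    grad = (2.0 / n) * (jac.T @ r)
    return grad, jac
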