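"""Single-hidden-layer feed-forward network for log event-timing regression.

Architecture: binary species/event indicators in, logistic hidden units,
a linear output unit, and an optional skip layer of direct linear
input-to-output connections (with zero hidden contribution the skip layer
alone is an ordinary linear regression). The response is ln(PC day); no
offset is subtracted, so predictions back-transform with a plain exp.

Training minimizes the penalized least-squares loss

    sum_n (y_n - f(x_n))^2 + lambda * sum(all parameters squared)

with a full-batch quasi-Newton optimizer (L-BFGS-B with an analytic
gradient) from small random initial weights. Networks converge to local
optima, so callers typically train several random restarts and average
predictions or errors across them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .design_matrix import DesignMatrix, encode_query


@dataclass(frozen=True)
class FFNNArch:
    n_inputs: int
    hidden_units: int = 1
    skip: bool = False
    decay: float = 0.0  # weight-decay strength lambda

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("need at least one hidden unit")
        if self.decay < 0:
            raise ValueError("decay must be nonnegative")

    @property
    def n_params(self) -> int:
        return count_params(self.n_inputs, self.hidden_units, self.skip)


@dataclass
class FFNNParams:
    arch: FFNNArch
    input_to_hidden: np.ndarray  # (h, n_inputs)
    hidden_biases: np.ndarray  # (h,)
    hidden_to_output: np.ndarray  # (h,)
    output_bias: float
    skip_weights: np.ndarray | None = None  # (n_inputs,) iff arch.skip
    converged: bool = True
    seed: int | None = None
    loss: float = np.nan

    def flat(self) -> np.ndarray:
        parts = [
            self.input_to_hidden.ravel(),
            self.hidden_biases,
            self.hidden_to_output,
            [self.output_bias],
        ]
        if self.arch.skip:
            parts.append(self.skip_weights)
        return np.concatenate([np.asarray(p, dtype=float) for p in parts])

    @classmethod
    def from_flat(cls, arch: FFNNArch, theta: np.ndarray, **kw) -> "FFNNParams":
        h, d = arch.hidden_units, arch.n_inputs
        if theta.size != arch.n_params:
            raise ValueError(f"expected {arch.n_params} parameters, got {theta.size}")
        W = theta[: h * d].reshape(h, d)
        b = theta[h * d : h * d + h]
        v = theta[h * d + h : h * d + 2 * h]
        b0 = float(theta[h * d + 2 * h])
        u = theta[h * d + 2 * h + 1 :] if arch.skip else None
        return cls(arch, W, b, v, b0, u, **kw)

    def to_json(self, column_labels: list[str] | None = None) -> str:
        doc = {
            "model": "ffnn",
            "arch": {
                "n_inputs": self.arch.n_inputs,
                "hidden_units": self.arch.hidden_units,
                "skip": self.arch.skip,
                "decay": self.arch.decay,
            },
            "seed": self.seed,
            "converged": self.converged,
            "input_to_hidden": self.input_to_hidden.tolist(),
            "hidden_biases": self.hidden_biases.tolist(),
            "hidden_to_output": self.hidden_to_output.tolist(),
            "output_bias": self.output_bias,
            "skip_weights": None if self.skip_weights is None else self.skip_weights.tolist(),
        }
        if column_labels is not None:
            doc["column_labels"] = column_labels
        return json.dumps(doc, indent=2)


def count_params(n_inputs: int, h: int, skip: bool) -> int:
    """Total free parameters: h*(n_inputs+1) hidden weights and biases,
    h+1 output weights and bias, plus n_inputs skip weights if present.

    For the empirical 10-species, 95-event table (105 inputs), one hidden
    unit and no skip layer this gives 108 — comparable to the FD model's
    107 (106 regression coefficients plus the separately estimated k).
    """
    if h < 1:
        raise ValueError("need at least one hidden unit")
    return h * (n_inputs + 1) + (h + 1) + (n_inputs if skip else 0)


def forward(params: FFNNParams, rows: np.ndarray) -> np.ndarray:
    """Network output for each row: b0 + v . logistic(b + W x) [+ u . x]."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[1] != params.arch.n_inputs:
        raise ValueError(
            f"row width {rows.shape[1]} != n_inputs {params.arch.n_inputs}"
        )
    hidden = expit(rows @ params.input_to_hidden.T + params.hidden_biases)
    out = params.output_bias + hidden @ params.hidden_to_output
    if params.arch.skip:
        out = out + rows @ params.skip_weights
    return out


def penalized_loss(params: FFNNParams, rows: np.ndarray, targets: np.ndarray,
                   decay: float | None = None) -> float:
    """Sum of squared log-scale errors plus decay * sum of squared parameters
    (biases included in the penalty)."""
    if decay is None:
        decay = params.arch.decay
    targets = np.asarray(targets, dtype=float)
    resid = forward(params, rows) - targets
    theta = params.flat()
    return float(resid @ resid + decay * theta @ theta)


def _loss_and_grad(theta: np.ndarray, arch: FFNNArch, rows: np.ndarray,
                   targets: np.ndarray) -> tuple[float, np.ndarray]:
    h, d = arch.hidden_units, arch.n_inputs
    W = theta[: h * d].reshape(h, d)
    b = theta[h * d : h * d + h]
    v = theta[h * d + h : h * d + 2 * h]
    b0 = theta[h * d + 2 * h]
    u = theta[h * d + 2 * h + 1 :] if arch.skip else None

    act = expit(rows @ W.T + b)  # (n, h)
    out = b0 + act @ v
    if arch.skip:
        out = out + rows @ u
    r = out - targets
    lam = arch.decay
    loss = r @ r + lam * theta @ theta

    two_r = 2.0 * r
    d_v = act.T @ two_r  # (h,)
    d_b0 = two_r.sum()
    # back through the logistic: s'(z) = s(z)(1 - s(z))
    delta = (two_r[:, None] * act * (1.0 - act)) * v  # (n, h)
    d_b = delta.sum(axis=0)
    d_W = delta.T @ rows  # (h, d)
    parts = [d_W.ravel(), d_b, d_v, [d_b0]]
    if arch.skip:
        parts.append(rows.T @ two_r)
    grad = np.concatenate([np.asarray(p, dtype=float) for p in parts])
    grad += 2.0 * lam * theta
    return float(loss), grad


def penalized_loss_grad(params: FFNNParams, rows: np.ndarray,
                        targets: np.ndarray) -> np.ndarray:
    """Analytic gradient of :func:`penalized_loss` w.r.t. the flat
    parameter vector (checked against finite differences in the tests)."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    _, g = _loss_and_grad(params.flat(), params.arch, rows,
                          np.asarray(targets, dtype=float))
    return g


INIT_RANGE = 0.5  # initial weights uniform in [-0.5, 0.5]


def train(
    rows: np.ndarray,
    targets: np.ndarray,
    arch: FFNNArch,
    seed: int,
    max_iter: int = 2000,
    tol: float = 1e-8,
    bounds=None,
) -> FFNNParams:
    """Train the network from a seeded random initialization.

    Deterministic given (rows, targets, arch, seed). Non-convergence
    within ``max_iter`` iterations raises a warning and returns the best
    parameters found. ``bounds`` (per-parameter (lo, hi) pairs in flat
    order) can clamp individual weights, e.g. pinning the hidden output
    weight to 0 to reduce the model to its linear skip part.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    targets = np.asarray(targets, dtype=float)
    if rows.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if rows.shape[0] != targets.size:
        raise ValueError("rows and targets are misaligned")
    rng = np.random.default_rng(seed)
    theta0 = rng.uniform(-INIT_RANGE, INIT_RANGE, size=arch.n_params)
    if bounds is not None:
        theta0 = np.clip(theta0, [lo if lo is not None else -np.inf for lo, _ in bounds],
                         [hi if hi is not None else np.inf for _, hi in bounds])
    res = minimize(
        _loss_and_grad,
        theta0,
        args=(arch, rows, targets),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
    )
    converged = bool(res.success)
    if not converged:
        warnings.warn(
            f"FFNN training did not converge in {max_iter} iterations "
            f"(seed {seed}): {res.message}",
            RuntimeWarning,
            stacklevel=2,
        )
    return FFNNParams.from_flat(arch, res.x, converged=converged, seed=seed,
                                loss=float(res.fun))


def predict_ffnn(params: FFNNParams, design: DesignMatrix, species: str,
                 event: str) -> float:
    """Predict a PC day for a query cell: exp of the network output."""
    x = encode_query(design, species, event)
    return float(np.exp(forward(params, x[None, :])[0]))
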