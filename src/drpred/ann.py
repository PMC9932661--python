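"""Alternative regression head: feed-forward network with tanh + dropout.

A plain numpy multilayer perceptron matching the architecture contract of
the method's neural head: four hidden layers (1000, 800, 500, 100 by
default) with hyperbolic-tangent activation, dropout on the hidden layers
during training, and root-mean-square error as the reported loss.  Training
is seeded mini-batch gradient descent with momentum; dropout is disabled at
inference, so prediction is deterministic.

RMSE is a strictly increasing function of the mean squared error, so the
gradient step uses the MSE gradient (same minimizer, better-conditioned
scale) while the trace reports RMSE.  Inputs and targets are standardized
internally and predictions mapped back to the response scale.  This head
produces point predictions only; intervals are the gamma GLM's contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import FeatureTable, ResponseVector
from .glm import impute_median

DEFAULT_WIDTHS = (1000, 800, 500, 100)


@dataclass
class MLPModel:
    """Weights and normalization of a fitted feed-forward regressor."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    widths: tuple[int, ...]
    dropout_rate: float
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    impute_medians: np.ndarray | None
    rmse_trace: list[float] = field(default_factory=list)
    seed: int = 0

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[0]

    @property
    def final_rmse(self) -> float:
        return self.rmse_trace[-1] if self.rmse_trace else float("nan")


def _prepare_x(x: np.ndarray | FeatureTable) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(x, FeatureTable):
        x = np.where(x.missing_mask, np.nan, x.values)
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        return impute_median(x)
    return x, None


def _forward(model_w, model_b, z, dropout_rate=0.0, rng=None):
    """Forward pass; returns post-dropout activations, pre-dropout tanh
    outputs (for the derivative), and dropout masks."""
    acts = [z]
    raws = []
    masks = []
    a = z
    n_layers = len(model_w)
    for li, (w, b) in enumerate(zip(model_w, model_b)):
        pre = a @ w + b
        if li < n_layers - 1:
            raw = np.tanh(pre)
            raws.append(raw)
            if rng is not None and dropout_rate > 0.0:
                keep = rng.random(raw.shape) >= dropout_rate
                a = raw * keep / (1.0 - dropout_rate)
                masks.append(keep)
            else:
                a = raw
                masks.append(None)
        else:
            a = pre[:, 0]
        acts.append(a)
    return acts, raws, masks


def fit_mlp(
    x: np.ndarray | FeatureTable,
    y: np.ndarray | ResponseVector,
    widths: tuple[int, ...] = DEFAULT_WIDTHS,
    dropout_rate: float = 0.1,
    epochs: int = 200,
    batch_size: int = 32,
    learning_rate: float = 0.01,
    momentum: float = 0.9,
    seed: int = 0,
) -> MLPModel:
    """Train the tanh-with-dropout regressor by mini-batch SGD with momentum.

    ``epochs=0`` returns the seeded initialization (predictions near the
    target mean under standardized targets).  Divergence (non-finite loss)
    raises with advice to lower the learning rate.
    """
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError("dropout_rate must be in [0, 1)")
    if any(w < 1 for w in widths):
        raise ValueError("all hidden widths must be >= 1")
    xv, medians = _prepare_x(x)
    yv = y.values if isinstance(y, ResponseVector) else np.asarray(y, dtype=float)
    n = xv.shape[0]
    batch_size = min(batch_size, n)

    x_mean = xv.mean(axis=0)
    x_std = np.where(xv.std(axis=0) > 0, xv.std(axis=0), 1.0)
    y_mean = float(yv.mean())
    y_std = float(yv.std()) or 1.0
    z = (xv - x_mean) / x_std
    t = (yv - y_mean) / y_std

    rng = np.random.default_rng(seed)
    dims = [xv.shape[1], *widths, 1]
    ws = [
        rng.normal(0.0, 1.0 / np.sqrt(dims[i]), size=(dims[i], dims[i + 1]))
        for i in range(len(dims) - 1)
    ]
    bs = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
    vel_w = [np.zeros_like(w) for w in ws]
    vel_b = [np.zeros_like(b) for b in bs]

    trace: list[float] = []
    for _ in range(epochs):
        perm = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = perm[start:start + batch_size]
            zb, tb = z[idx], t[idx]
            acts, raws, masks = _forward(ws, bs, zb, dropout_rate, rng)
            pred = acts[-1]
            err = pred - tb
            delta = (2.0 * err / err.size)[:, None]
            for li in range(len(ws) - 1, -1, -1):
                a_prev = acts[li]
                g_w = a_prev.T @ delta
                g_b = delta.sum(axis=0)
                if li > 0:
                    d_a = delta @ ws[li].T
                    if masks[li - 1] is not None:
                        d_a = d_a * masks[li - 1] / (1.0 - dropout_rate)
                    delta = d_a * (1.0 - raws[li - 1] ** 2)
                vel_w[li] = momentum * vel_w[li] - learning_rate * g_w
                vel_b[li] = momentum * vel_b[li] - learning_rate * g_b
                ws[li] += vel_w[li]
                bs[li] += vel_b[li]
        acts, _, _ = _forward(ws, bs, z)
        rmse = float(np.sqrt(np.mean((acts[-1] - t) ** 2)))
        if not np.isfinite(rmse):
            raise FloatingPointError(
                "training diverged (non-finite RMSE); lower the learning rate"
            )
        trace.append(rmse)
    if not trace:  # epochs == 0: report RMSE of the untrained net
        acts, _, _ = _forward(ws, bs, z)
        trace.append(float(np.sqrt(np.mean((acts[-1] - t) ** 2))))

    return MLPModel(
        weights=ws, biases=bs, widths=tuple(widths), dropout_rate=dropout_rate,
        x_mean=x_mean, x_std=x_std, y_mean=y_mean, y_std=y_std,
        impute_medians=medians, rmse_trace=trace, seed=seed,
    )


def predict_mlp(model: MLPModel, x_new: np.ndarray | FeatureTable) -> np.ndarray:
    """Deterministic forward pass with dropout disabled (inference mode)."""
    if isinstance(x_new, FeatureTable):
        xv = np.where(x_new.missing_mask, np.nan, x_new.values)
    else:
        xv = np.atleast_2d(np.asarray(x_new, dtype=float))
    if xv.shape[1] != model.n_inputs:
        raise ValueError(
            f"expected {model.n_inputs} features, got {xv.shape[1]}"
        )
    if np.isnan(xv).any():
        med = model.impute_medians
        if med is None:
            med = model.x_mean
        xv = np.where(np.isnan(xv), med, xv)
    z = (xv - model.x_mean) / model.x_std
    acts, _, _ = _forward(model.weights, model.biases, z)
    return acts[-1] * model.y_std + model.y_mean
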