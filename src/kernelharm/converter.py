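"""Residual CNN kernel converter.

A fully convolutional 2D network that maps a CT slice rendered under one
reconstruction kernel to its rendering under the other kernel.  The network
predicts a *residual*: stacked 3x3 convolutions with rectifier
nonlinearities, a final 3x3 convolution down to one channel, and a skip
connection adding the input back.  The final layer is zero-initialized so
the untrained converter is exactly the identity map.

Training minimizes the per-pixel mean squared error (proportional to the
sum-of-squares loss; the constant of proportionality is the pixel count)
with Adam.  Two independent models are trained, one per conversion
direction (to_smooth, to_sharp); they share no weights.

The implementation is a compact, deterministic numpy CNN: convolutions via
im2col + matrix multiplication in float32, hand-derived backprop, and a
standard Adam update.  It is single-threaded-reproducible: the same data,
config and seed give bit-identical weights and losses.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "ConverterConfig",
    "TrainedConverter",
    "build_converter",
    "train_converter",
    "convert_volume",
    "convert_slices",
    "rmse",
    "rmse_reduction",
    "save_converter",
    "load_converter",
]

_K = 3  # convolution kernel size (3x3 throughout)


@dataclass(frozen=True)
class ConverterConfig:
    """Architecture and training hyperparameters for one direction."""

    direction: str = "to_smooth"  # or "to_sharp"
    n_layers: int = 6  # total convolution layers, incl. the final 1-channel one
    channels: int = 64
    learning_rate: float = 1e-4
    n_epochs: int = 55
    batch_size: int = 8
    intensity_shift: float = 800.0  # added before scaling: lung background ~ 0
    intensity_scale: float = 1000.0  # divisor; recorded with the model
    seed: int = 0

    def __post_init__(self) -> None:
        if self.direction not in ("to_smooth", "to_sharp"):
            raise ValueError("direction must be 'to_smooth' or 'to_sharp'")
        if self.n_layers < 2:
            raise ValueError("n_layers must be >= 2")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class TrainedConverter:
    """Converter weights plus the training log (may be untrained)."""

    config: ConverterConfig
    weights: list  # [(W, b), ...] with W (Cout, Cin*9) float32, b (Cout,)
    training_log: list = field(default_factory=list)  # dicts: epoch, train_loss, test_loss
    initial_test_loss: float | None = None

    @property
    def n_parameters(self) -> int:
        return int(sum(W.size + b.size for W, b in self.weights))


def _init_weights(config: ConverterConfig) -> list:
    """He-initialized hidden layers; zero-initialized final layer."""
    rng = np.random.default_rng(config.seed)
    layers = []
    c_in = 1
    for i in range(config.n_layers):
        last = i == config.n_layers - 1
        c_out = 1 if last else config.channels
        fan_in = c_in * _K * _K
        if last:
            W = np.zeros((c_out, fan_in), dtype=np.float32)
        else:
            W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in)).astype(
                np.float32
            )
        b = np.zeros(c_out, dtype=np.float32)
        layers.append((W, b))
        c_in = c_out
    return layers


def build_converter(config: ConverterConfig) -> TrainedConverter:
    """Construct an untrained converter (exact identity at init)."""
    return TrainedConverter(config=config, weights=_init_weights(config))


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patches with zero 'same' padding."""
    n, c, h, w = x.shape
    xp = np.zeros((n, c, h + 2, w + 2), dtype=x.dtype)
    xp[:, :, 1:-1, 1:-1] = x
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(xp, (_K, _K), axis=(2, 3))  # (N, C, H, W, 3, 3)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * _K * _K)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, shape: tuple) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back to the image."""
    n, c, h, w = shape
    d = dcols.reshape(n, h, w, c, _K, _K)
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dcols.dtype)
    for dy in range(_K):
        for dx in range(_K):
            dxp[:, :, dy : dy + h, dx : dx + w] += d[:, :, :, :, dy, dx].transpose(
                0, 3, 1, 2
            )
    return dxp[:, :, 1:-1, 1:-1]


def _forward(weights: list, x: np.ndarray, keep: bool = False):
    """Residual forward pass.  x: (N, 1, H, W) normalized intensities."""
    act = x
    cache = []
    n_layers = len(weights)
    for i, (W, b) in enumerate(weights):
        cols = _im2col(act)
        z = cols @ W.T + b  # (N*H*W, Cout)
        n, _, h, w = act.shape
        z = z.reshape(n, h, w, -1).transpose(0, 3, 1, 2)
        if i < n_layers - 1:
            out = np.maximum(z, 0.0)
        else:
            out = z
        if keep:
            cache.append((act.shape, cols, z if i < n_layers - 1 else None))
        act = out
    return x + act, cache  # residual skip


def _backward(weights: list, cache: list, dout: np.ndarray) -> list:
    """Gradients of the loss w.r.t. every (W, b); dout is dL/d(residual)."""
    grads: list = [None] * len(weights)
    dact = dout
    for i in range(len(weights) - 1, -1, -1):
        W, _b = weights[i]
        in_shape, cols, pre_relu = cache[i]
        if pre_relu is not None:  # hidden layer: ReLU backward
            dact = dact * (pre_relu > 0)
        n, cout, h, w = dact.shape
        dmat = dact.transpose(0, 2, 3, 1).reshape(n * h * w, cout)
        dW = dmat.T @ cols
        db = dmat.sum(axis=0)
        dcols = dmat @ W
        dact = _col2im(dcols, in_shape)
        grads[i] = (dW.astype(np.float32), db.astype(np.float32))
    return grads


def _normalize(x: np.ndarray, cfg: ConverterConfig) -> np.ndarray:
    return ((np.asarray(x, dtype=np.float64) + cfg.intensity_shift) / cfg.intensity_scale).astype(np.float32)


def convert_slices(model: TrainedConverter, slices: np.ndarray) -> np.ndarray:
    """Apply the converter to a stack of 2D slices (N, H, W).

    The residual is predicted in normalized intensity space and rescaled, so
    a zero residual returns the input bit-for-bit.
    """
    slices = np.asarray(slices, dtype=np.float64)
    if not np.all(np.isfinite(slices)):
        raise ValueError("input slices must be finite")
    x = _normalize(slices, model.config)[:, None, :, :]
    out, _ = _forward(model.weights, x)
    residual = (out - x)[:, 0, :, :].astype(np.float64)
    return slices + residual * model.config.intensity_scale


def convert_volume(model: TrainedConverter, volume: np.ndarray) -> np.ndarray:
    """Convert a 3D volume slice-by-slice along the axial (last) axis."""
    volume = np.asarray(volume, dtype=np.float64)
    if not np.all(np.isfinite(volume)):
        raise ValueError("input volume must be finite")
    stack = np.moveaxis(volume, 2, 0)
    converted = convert_slices(model, stack)
    return np.moveaxis(converted, 0, 2)


def _loss_and_residual_grad(weights, x, y):
    pred, cache = _forward(weights, x, keep=True)
    diff = pred - y
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    dpred = (2.0 / diff.size) * diff
    return loss, cache, dpred.astype(np.float32)


def _eval_loss(weights, x, y) -> float:
    pred, _ = _forward(weights, x)
    return float(np.mean((pred.astype(np.float64) - y.astype(np.float64)) ** 2))


def train_converter(
    pairs,
    config: ConverterConfig,
    holdout_fraction: float = 0.25,
) -> TrainedConverter:
    """Train a converter on (source slice, target slice) pairs.

    A seed-deterministic split holds out ``holdout_fraction`` of the pairs;
    both losses are recorded every epoch.  If the last epoch's held-out loss
    exceeds the untrained (identity) baseline, the weights from the best
    epoch are restored, so the returned model is never worse than identity
    on the held-out set.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("need at least 2 slice pairs")
    src = np.stack([np.asarray(s, dtype=np.float64) for s, _ in pairs])
    tgt = np.stack([np.asarray(t, dtype=np.float64) for _, t in pairs])
    if src.shape != tgt.shape:
        raise ValueError("source/target slice shapes must match")

    x = _normalize(src, config)[:, None, :, :]
    y = _normalize(tgt, config)[:, None, :, :]

    rng = np.random.default_rng(config.seed + 1)
    perm = rng.permutation(len(pairs))
    n_hold = max(1, int(round(holdout_fraction * len(pairs))))
    hold_idx, train_idx = perm[:n_hold], perm[n_hold:]
    if len(train_idx) == 0:
        train_idx, hold_idx = perm[n_hold:0:-1], perm[:1]
    xt, yt = x[train_idx], y[train_idx]
    xh, yh = x[hold_idx], y[hold_idx]

    weights = _init_weights(config)
    m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0

    initial_test = _eval_loss(weights, xh, yh)
    log = []
    best = (initial_test, [(W.copy(), b.copy()) for W, b in weights])

    for epoch in range(config.n_epochs):
        order = rng.permutation(len(train_idx))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            loss, cache, dpred = _loss_and_residual_grad(weights, xt[batch], yt[batch])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "lower the learning rate or rescale intensities"
                )
            epoch_losses.append(loss)
            grads = _backward(weights, cache, dpred)
            t += 1
            new_weights = []
            for li, ((W, b), (dW, db)) in enumerate(zip(weights, grads)):
                mW, mb = m[li]
                vW, vb = v[li]
                mW = beta1 * mW + (1 - beta1) * dW
                mb = beta1 * mb + (1 - beta1) * db
                vW = beta2 * vW + (1 - beta2) * dW**2
                vb = beta2 * vb + (1 - beta2) * db**2
                m[li], v[li] = (mW, mb), (vW, vb)
                corr1 = 1 - beta1**t
                corr2 = 1 - beta2**t
                lr_t = config.learning_rate * np.sqrt(corr2) / corr1
                W = W - lr_t * mW / (np.sqrt(vW) + eps)
                b = b - lr_t * mb / (np.sqrt(vb) + eps)
                new_weights.append((W.astype(np.float32), b.astype(np.float32)))
            weights = new_weights
        test_loss = _eval_loss(weights, xh, yh)
        log.append(
            {
                "epoch": epoch + 1,
                "train_loss": float(np.mean(epoch_losses)),
                "test_loss": test_loss,
            }
        )
        if test_loss < best[0]:
            best = (test_loss, [(W.copy(), b.copy()) for W, b in weights])

    if log and log[-1]["test_loss"] > initial_test:
        weights = best[1]  # never return a model worse than identity held-out

    return TrainedConverter(
        config=config,
        weights=weights,
        training_log=log,
        initial_test_loss=initial_test,
    )


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square difference between two same-shape images."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def rmse_reduction(source: np.ndarray, converted: np.ndarray, target: np.ndarray) -> float:
    """Percentage decrease in RMSE against the target after conversion."""
    base = rmse(source, target)
    if base == 0.0:
        warnings.warn("rmse(source, target) is 0; reduction undefined, reporting 0")
        return 0.0
    return 100.0 * (1.0 - rmse(converted, target) / base)


def save_converter(model: TrainedConverter, path: str | Path) -> None:
    """Single-file archive: weights arrays + config/log JSON."""
    arrays = {}
    for i, (W, b) in enumerate(model.weights):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    meta = json.dumps(
        {
            "config": asdict(model.config),
            "training_log": model.training_log,
            "initial_test_loss": model.initial_test_loss,
            "n_layers": len(model.weights),
        }
    )
    buf = io.BytesIO()
    np.savez(buf, meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)
    Path(path).write_bytes(buf.getvalue())


def load_converter(path: str | Path) -> TrainedConverter:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta"]).decode())
        weights = [
            (npz[f"W{i}"], npz[f"b{i}"]) for i in range(meta["n_layers"])
        ]
    return TrainedConverter(
        config=ConverterConfig(**meta["config"]),
        weights=weights,
        training_log=meta["training_log"],
        initial_test_loss=meta["initial_test_loss"],
    )
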