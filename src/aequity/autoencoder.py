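"""Compressive autoencoder head trained with full-batch Adam.

The head is deliberately simple: one tanh bottleneck layer and a linear
output, trained to minimise the reconstruction MSE ``E[(x - g(f(x)))^2]``.
Its purpose is not representation learning but *learnability probing*: the
validation reconstruction loss as a function of training-set size traces a
learning curve whose convergence point is the quantity of interest.

Implementation note: all bootstrap replicates at one sample size share
shapes, so they are trained simultaneously as a stacked ``(R, n, d)``
tensor with ``(R, d, k)`` weight banks. One Python-level epoch loop then
advances every replicate at once, which makes 50-replicate bootstraps
cheap on a single CPU. Training is full-batch, so given a seed the result
is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AutoencoderConfig", "train_replicates"]


@dataclass(frozen=True)
class AutoencoderConfig:
    """Training configuration for the compressive head.

    bottleneck_dim defaults to ``max(2, input_dim // 4)`` (capped at
    ``input_dim - 1`` so the head is always compressive).
    """

    bottleneck_dim: int | None = None
    max_epochs: int = 150
    learning_rate: float = 0.02
    patience: int = 10  # early-stop patience, in validation checks
    val_every: int = 2  # epochs between validation checks
    min_delta: float = 1e-6

    def resolve_bottleneck(self, input_dim: int) -> int:
        if input_dim < 2:
            raise ValueError("autoencoder input must have >= 2 features to be compressive")
        k = self.bottleneck_dim if self.bottleneck_dim is not None else max(2, input_dim // 4)
        k = min(k, input_dim - 1)
        if k < 1:
            raise ValueError(f"bottleneck_dim must be >= 1, got {k}")
        return k


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def train_replicates(
    train_sets: np.ndarray,
    val_set: np.ndarray,
    config: AutoencoderConfig,
    seed: int,
) -> np.ndarray:
    """Train one autoencoder per replicate; return each replicate's best
    validation MSE (early-stopped loss).

    Parameters
    ----------
    train_sets : (R, n, d) array — R independent bootstrap training sets.
    val_set : (v, d) or (R, v, d) array — held-out validation examples;
        a 3-D array gives each replicate its own validation resample
        (fixed across grid sizes by the caller so curves are comparable).
    seed : seeds weight initialisation (per replicate, independent).

    Returns
    -------
    (R,) array of best validation losses; NaN marks a replicate whose
    training produced non-finite values.
    """
    # float32 keeps the full pipeline fast on one CPU; loss resolution
    # (~1e-3 of the loss scale) is far above single-precision rounding
    train_sets = np.asarray(train_sets, dtype=np.float32)
    val_set = np.asarray(val_set, dtype=np.float32)
    if train_sets.ndim != 3:
        raise ValueError("train_sets must be (R, n, d)")
    R, n, d = train_sets.shape
    k = config.resolve_bottleneck(d)
    rng = np.random.default_rng(seed)

    # Independent Glorot init per replicate.
    W1 = _glorot(rng, (R, d, k), d, k).astype(np.float32)
    b1 = np.zeros((R, 1, k), dtype=np.float32)
    W2 = _glorot(rng, (R, k, d), k, d).astype(np.float32)
    b2 = np.zeros((R, 1, d), dtype=np.float32)
    params = [W1, b1, W2, b2]
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate

    if val_set.ndim == 2:
        Xv = np.broadcast_to(val_set, (R,) + val_set.shape)
    elif val_set.ndim == 3 and val_set.shape[0] == R:
        Xv = val_set
    else:
        raise ValueError("val_set must be (v, d) or (R, v, d)")
    best = np.full(R, np.inf)
    alive = np.ones(R, dtype=bool)
    stale = 0

    for t in range(1, config.max_epochs + 1):
        X = train_sets
        Z1 = X @ W1 + b1
        H = np.tanh(Z1)
        Y = H @ W2 + b2
        err = Y - X

        # validation loss (early-stopping criterion, and the reported value)
        if t % config.val_every == 0 or t == config.max_epochs:
            Hv = np.tanh(Xv @ W1 + b1)
            val_err = Hv @ W2 + b2 - Xv
            val_loss = np.mean(val_err * val_err, axis=(1, 2), dtype=np.float64)
            finite = np.isfinite(val_loss)
            alive &= finite
            improved = finite & (val_loss < best - config.min_delta)
            best = np.where(finite & (val_loss < best), val_loss, best)
            stale = 0 if improved.any() else stale + 1
            if stale >= config.patience or not alive.any():
                break

        dY = (2.0 / (n * d)) * err
        gW2 = np.swapaxes(H, 1, 2) @ dY
        gb2 = dY.sum(axis=1, keepdims=True)
        dH = dY @ np.swapaxes(W2, 1, 2)
        dZ1 = dH * (1.0 - H * H)
        gW1 = np.swapaxes(X, 1, 2) @ dZ1
        gb1 = dZ1.sum(axis=1, keepdims=True)

        bc1 = 1.0 - beta1**t
        bc2 = 1.0 - beta2**t
        for p, m, v, g in zip(params, m_t, v_t, [gW1, gb1, gW2, gb2]):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * (g * g)
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + eps)

    out = np.where(np.isfinite(best), best, np.nan)
    out[~alive & ~np.isfinite(best)] = np.nan
    return out
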