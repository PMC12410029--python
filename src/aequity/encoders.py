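"""Frozen-embedder contracts.

AEq is always computed *through* an encoder: a frozen map ``f: X -> h`` whose
latent space the compressive autoencoder head reconstructs from. For tabular
data the encoder is the identity; for image-scale data the user supplies a
frozen backbone (a plain callable) and wraps it with :func:`wrap_frozen_model`.
The contract guarantees determinism and immutability, which AEq requires:
a drifting encoder would confound the learning curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "Encoder",
    "EncoderContractError",
    "identity_encoder",
    "wrap_frozen_model",
]


class EncoderContractError(ValueError):
    """Raised when an embedder violates the frozen-encoder contract."""


@dataclass(frozen=True)
class Encoder:
    """A frozen embedder ``f: R^input_dim -> R^latent_dim``.

    ``frozen`` must be True before any AEq computation uses the encoder;
    the constructor enforces it. ``embed`` accepts a 2-D array of shape
    ``(n, input_dim)`` and returns ``(n, latent_dim)``.
    """

    input_dim: int
    latent_dim: int
    _fn: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    frozen: bool = True
    name: str = "encoder"

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise EncoderContractError(f"input_dim must be >= 1, got {self.input_dim}")
        if self.latent_dim < 1:
            raise EncoderContractError(f"latent_dim must be >= 1, got {self.latent_dim}")
        if not self.frozen:
            raise EncoderContractError("encoder must be frozen before use")

    def embed(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        squeeze = x.ndim == 1
        if squeeze:
            x = x[None, :]
        if x.shape[1] != self.input_dim:
            raise EncoderContractError(
                f"{self.name}: expected input of width {self.input_dim}, got {x.shape[1]}"
            )
        h = np.asarray(self._fn(x), dtype=np.float64)
        if h.ndim == 1:
            h = h[None, :] if squeeze else h[:, None]
        if h.shape != (x.shape[0], self.latent_dim):
            raise EncoderContractError(
                f"{self.name}: embedder returned shape {h.shape}, "
                f"contract requires ({x.shape[0]}, {self.latent_dim})"
            )
        return h[0] if squeeze else h


def identity_encoder(input_dim: int) -> Encoder:
    """The identity map — the default encoder for raw tabular features.

    The compressive head then reconstructs the (standardized) features
    directly, i.e. AEq on raw features equals AEq on "embeddings" exactly.
    """
    if input_dim < 1:
        raise EncoderContractError(f"input_dim must be >= 1, got {input_dim}")
    return Encoder(
        input_dim=input_dim,
        latent_dim=input_dim,
        _fn=lambda x: x,
        name="identity",
    )


def wrap_frozen_model(
    model: Callable[[np.ndarray], np.ndarray],
    input_dim: int,
    latent_dim: int,
    name: str = "frozen-model",
) -> Encoder:
    """Wrap an opaque embed-callable (e.g. a pretrained backbone's forward
    pass) as a frozen :class:`Encoder`.

    The wrapper exposes no weight access, so nothing downstream can update
    the wrapped model; shape violations surface on the first call.
    """
    return Encoder(input_dim=input_dim, latent_dim=latent_dim, _fn=model, name=name)
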