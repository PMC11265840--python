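"""Backbone networks for channel-stacked PSS inputs.

The backbone contract is minimal: take a ``patch_size x patch_size x D_in``
array (``D_in`` = 3 x number of patches in the sampling configuration) and
return a softmax probability vector over the 4 HER2 classes. Any model
honoring that contract can stand behind the training and inference
protocols.

Two backbones are defined:

* :class:`SmallConvNet` — the desk-scale default: four conv-ReLU-pool
  blocks, global average pooling and a linear 4-way head, implemented in
  numpy so it trains on one CPU in minutes. Batch normalization is omitted;
  at this depth it is unnecessary and its absence keeps the backward pass
  simple and exactly reproducible.
* :func:`densenet201_reference_spec` — the documented full-scale layout
  (initial 7x7xD_in convolution, dense blocks of 6/12/48/32 layers, 1x1
  conv + 2x2 average-pool transitions, 4-way softmax head). Instantiating
  it requires a GPU deep-learning framework and is out of scope for the
  CPU test environment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Conv2D, Dense, GlobalAveragePool, MaxPool2, ReLU

__all__ = ["SmallConvNet", "DenseNet201Spec", "densenet201_reference_spec", "softmax"]

N_CLASSES = 4


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class SmallConvNet:
    """Four-block convnet accepting an arbitrary stacked channel depth.

    ``forward`` returns logits; ``predict_proba`` applies softmax. In eval
    mode (``train=False``) no caches are written and the output is a
    deterministic function of the parameters.
    """

    def __init__(
        self,
        d_in: int,
        patch_size: int,
        channels: tuple[int, ...] = (8, 16, 16, 16),
        seed: int = 0,
    ) -> None:
        if patch_size % (2 ** len(channels)):
            raise ValueError(
                f"patch_size {patch_size} must be divisible by {2 ** len(channels)}"
            )
        self.d_in = int(d_in)
        self.patch_size = int(patch_size)
        self.channels = tuple(channels)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.layers: list = []
        c_prev = d_in
        for c in channels:
            self.layers += [
                Conv2D(c_prev, c, rng=rng),
                ReLU(),
                MaxPool2(),
            ]
            c_prev = c
        self.gap = GlobalAveragePool()
        self.head = Dense(c_prev, N_CLASSES, rng=rng)
        self._all = self.layers + [self.gap, self.head]

    # -- parameter access -------------------------------------------------
    def params(self) -> list[np.ndarray]:
        return [p for layer in self._all for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self._all for g in layer.grads()]

    def set_params(self, values: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), values, strict=True):
            p[...] = v

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Logits for a batch ``(B, patch_size, patch_size, d_in)``."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[3] != self.d_in:
            raise ValueError(
                f"input depth {x.shape[3]} does not match model D_in={self.d_in} "
                "(check the pyramid configuration the model was trained with)"
            )
        for layer in self._all:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits.astype(np.float32)
        for layer in reversed(self._all):
            d = layer.backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))


@dataclass(frozen=True)
class DenseNet201Spec:
    """Documented full-scale reference backbone layout.

    A 201-layer densely connected convnet: an initial convolution of kernel
    ``7 x 7 x D_in`` with batch norm, ReLU and stride-2 3x3 max pooling;
    four dense blocks whose layers each receive all preceding feature maps;
    transitions of a 1x1 convolution followed by 2x2 average pooling; and a
    softmax head over the 4 HER2 classes.
    """

    initial_kernel: int = 7
    initial_pool: str = "3x3 max, stride 2"
    block_layers: tuple[int, int, int, int] = (6, 12, 48, 32)
    transition: str = "1x1 conv + 2x2 average pool"
    growth_rate: int = 32
    n_classes: int = N_CLASSES


def densenet201_reference_spec() -> DenseNet201Spec:
    """Return the documented DenseNet-201 layout (not instantiable here).

    Training this backbone at full scale requires a GPU framework (the
    original used PyTorch); this package keeps it as an interface-level
    contract and uses :class:`SmallConvNet` as the runnable default.
    """
    return DenseNet201Spec()
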