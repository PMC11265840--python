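"""Training of the 4-class HER2 scorer on channel-stacked PSS inputs.

The trainer follows the protocol used at full scale: balanced-class
weighted cross-entropy (class weights inversely proportional to training
frequency), dihedral data augmentation (horizontal/vertical flips and 90°
rotations), and AdamW with a learning rate reduced on a validation-loss
plateau. A fresh PSS is sampled for every core at every epoch, so the
stochastic patch sampler doubles as a regularizer.

The backbone is pluggable (see :mod:`her2pss.nn.network`): the desk-scale
default is a small numpy convnet; the documented full-scale reference is
DenseNet-201. Swapping backbones changes nothing else in the pipeline.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image as PILImage

from .labels import CLASS_NAMES, ScoreLabel, parse_score
from .nn import AdamW, SmallConvNet, softmax
from .pyramid import PyramidConfig, PyramidSamplingSet, sample_pss, stack_channels
from .types import CoreImage

__all__ = [
    "class_weights",
    "weighted_cross_entropy",
    "augment",
    "apply_dihedral",
    "invert_dihedral",
    "TrainConfig",
    "TrainedModel",
    "train",
    "forward",
    "save_model",
    "load_model",
]

N_CLASSES = 4
LOG_CLAMP = 1e-12


def class_weights(class_counts) -> np.ndarray:
    """Inverse-frequency class weights, w_c = M / (C * n_c).

    With M the total count and C = 4 classes, balanced counts give unit
    weights, and the identity sum_c w_c * n_c = M holds for any counts.
    """
    counts = np.asarray(class_counts, dtype=np.float64)
    if counts.shape != (N_CLASSES,):
        raise ValueError(f"expected 4 class counts, got shape {counts.shape}")
    if np.any(counts <= 0):
        empty = int(np.argmin(counts))
        raise ValueError(
            f"class {CLASS_NAMES[empty]} has no training examples; "
            "weights are undefined for empty classes"
        )
    return counts.sum() / (N_CLASSES * counts)


def weighted_cross_entropy(probs, labels_onehot, weights) -> float:
    """L = -(1/m) sum_i sum_c w_c y_ic log p_ic.

    ``probs`` rows must be probability vectors; with unit weights this is
    the mean negative log-likelihood. Zero probabilities at the true class
    are clamped at 1e-12 (with a warning) for numerical safety.
    """
    p = np.asarray(probs, dtype=np.float64)
    y = np.asarray(labels_onehot, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    if p.ndim == 1:
        p, y = p[None], y[None]
    if p.shape != y.shape or p.shape[1] != N_CLASSES:
        raise ValueError(f"probs {p.shape} and labels {y.shape} must both be (m, 4)")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    if np.any((p * y) [y > 0] < LOG_CLAMP):
        warnings.warn("true-class probability below 1e-12 clamped", RuntimeWarning)
    m = p.shape[0]
    return float(-(y * w * np.log(np.clip(p, LOG_CLAMP, None))).sum() / m)


# -- dihedral augmentation -------------------------------------------------

#: Inverse transform index for each of the 8 dihedral transforms.
_DIHEDRAL_INVERSE = (0, 3, 2, 1, 4, 5, 6, 7)


def apply_dihedral(patch: np.ndarray, transform: int) -> np.ndarray:
    """Apply dihedral transform ``transform`` in 0..7 to a square patch.

    0..3 are counterclockwise rotations by 90*t degrees; 4..7 first flip
    horizontally, then rotate. All transforms permute pixels, preserving
    every pixel value exactly.
    """
    if patch.shape[0] != patch.shape[1]:
        raise ValueError(f"augmentation requires a square patch, got {patch.shape[:2]}")
    if not 0 <= transform < 8:
        raise ValueError(f"transform index must be in 0..7, got {transform}")
    out = patch[:, ::-1] if transform >= 4 else patch
    return np.ascontiguousarray(np.rot90(out, k=transform % 4))


def invert_dihedral(transform: int) -> int:
    """Index of the inverse dihedral transform."""
    return _DIHEDRAL_INVERSE[transform]


def augment(patch: np.ndarray, rng, return_transform: bool = False):
    """One of the 8 flip/rotation transforms, chosen uniformly at random."""
    t = int(np.random.default_rng(rng).integers(0, 8)) if isinstance(rng, int) else int(
        rng.integers(0, 8)
    )
    out = apply_dihedral(patch, t)
    return (out, t) if return_transform else out


# -- training --------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule settings.

    Defaults mirror the full-scale protocol (AdamW, initial learning rate
    1e-5, batch size 12, rate reduced when the validation loss plateaus).
    The small desk-scale backbone converges faster at a larger rate; tests
    pass ``learning_rate=3e-3`` explicitly.
    """

    learning_rate: float = 1e-5
    batch_size: int = 12
    max_epochs: int = 30
    weight_decay: float = 1e-4
    lr_patience: int = 5
    lr_factor: float = 0.5
    min_lr: float = 1e-7
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainedModel:
    """Fitted backbone plus the sampling configuration it was trained for."""

    network: SmallConvNet
    pyramid_config: PyramidConfig
    train_config: TrainConfig
    history: pd.DataFrame
    class_order: tuple[str, ...] = CLASS_NAMES


def _prepare_input(stacked: np.ndarray) -> np.ndarray:
    """Shared input normalization: uint8 [0,255] -> float32 in [-0.5, 0.5]."""
    return stacked.astype(np.float32) / 255.0 - 0.5


def _load_manifest_images(manifest: pd.DataFrame, images) -> list[CoreImage]:
    out = []
    for _, row in manifest.iterrows():
        if images is not None:
            core = images[row["core_id"]]
            if not isinstance(core, CoreImage):
                core = CoreImage(image=core, core_id=str(row["core_id"]))
        else:
            arr = np.asarray(PILImage.open(row["path"]).convert("RGB"))
            core = CoreImage(image=arr, core_id=str(row["core_id"]))
        out.append(core)
    return out


def _epoch_batch(cores, labels, config, rng, do_augment):
    """Sample one fresh PSS per core, augment per patch, stack to a batch."""
    xs = np.empty(
        (len(cores), config.patch_size, config.patch_size, config.d_in),
        dtype=np.float32,
    )
    for i, core in enumerate(cores):
        pss = sample_pss(core, config, seed=int(rng.integers(0, 2**31)))
        patches = pss.patches
        if do_augment:
            patches = np.stack([augment(p, rng) for p in patches])
        pss = dataclasses.replace(pss, patches=patches)
        xs[i] = _prepare_input(stack_channels(pss))
    return xs, np.asarray(labels, dtype=np.int64)


def _loss_and_grad(logits, labels, weights):
    """Weighted CE loss on softmax(logits) and its gradient w.r.t. logits."""
    p = softmax(logits.astype(np.float64))
    m = logits.shape[0]
    w_i = weights[labels]
    nll = -np.log(np.clip(p[np.arange(m), labels], LOG_CLAMP, None))
    loss = float((w_i * nll).sum() / m)
    d = p.copy()
    d[np.arange(m), labels] -= 1.0
    d *= (w_i / m)[:, None]
    return loss, d.astype(np.float32)


def train(
    manifest: pd.DataFrame,
    pyramid_config: PyramidConfig,
    train_config: TrainConfig = TrainConfig(),
    images: dict | None = None,
    backbone: str = "small",
    channels: tuple[int, ...] = (8, 16, 16, 16),
) -> TrainedModel:
    """Fit the classifier on a labeled, split manifest.

    ``manifest`` needs columns ``core_id, score, split`` and either a
    ``path`` column (PNG/TIFF files) or an ``images`` mapping from core_id
    to :class:`~her2pss.types.CoreImage`. Each epoch samples a fresh PSS
    per training core (new derived seed), augments each patch with a random
    dihedral transform, and optimizes the class-weighted cross-entropy with
    AdamW. Validation PSSs use fixed seeds so the validation loss is
    comparable across epochs; the returned parameters are those of the best
    validation epoch. Fully deterministic given ``train_config.seed``.
    """
    if backbone != "small":
        raise ValueError(
            f"backbone {backbone!r} is not runnable in this environment; "
            "'small' is the trainable default (DenseNet-201 is documented "
            "as the full-scale reference only)"
        )
    for split in ("train", "val"):
        if not (manifest["split"] == split).any():
            raise ValueError(f"manifest has no cores in the {split!r} split")

    tr = manifest[manifest["split"] == "train"].reset_index(drop=True)
    va = manifest[manifest["split"] == "val"].reset_index(drop=True)
    tr_cores = _load_manifest_images(tr, images)
    va_cores = _load_manifest_images(va, images)
    tr_labels = np.array([int(parse_score(s)) for s in tr["score"]])
    va_labels = np.array([int(parse_score(s)) for s in va["score"]])

    counts = np.bincount(tr_labels, minlength=N_CLASSES)
    weights = class_weights(counts)

    master = np.random.SeedSequence(train_config.seed)
    init_seed, val_seed, *epoch_seeds = [
        int(s.generate_state(1)[0] % 2**31)
        for s in master.spawn(2 + train_config.max_epochs)
    ]

    net = SmallConvNet(
        d_in=pyramid_config.d_in,
        patch_size=pyramid_config.patch_size,
        channels=channels,
        seed=init_seed,
    )
    opt = AdamW(
        net.params(),
        lr=train_config.learning_rate,
        weight_decay=train_config.weight_decay,
    )

    # Fixed validation PSSs: same patches every epoch.
    val_rng = np.random.default_rng(val_seed)
    x_val, y_val = _epoch_batch(va_cores, va_labels, pyramid_config, val_rng, False)

    history_rows = []
    best_val = np.inf
    best_params = [p.copy() for p in net.params()]
    plateau = 0
    lr = train_config.learning_rate

    for epoch in range(train_config.max_epochs):
        rng = np.random.default_rng(epoch_seeds[epoch])
        order = rng.permutation(len(tr_cores))
        x_tr, y_tr = _epoch_batch(
            [tr_cores[i] for i in order],
            tr_labels[order],
            pyramid_config,
            rng,
            train_config.augment,
        )
        losses = []
        for start in range(0, len(order), train_config.batch_size):
            xb = x_tr[start : start + train_config.batch_size]
            yb = y_tr[start : start + train_config.batch_size]
            logits = net.forward(xb, train=True)
            loss, dlogits = _loss_and_grad(logits, yb, weights)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            net.backward(dlogits)
            opt.step(net.grads())
            losses.append(loss * len(yb))
        train_loss = float(np.sum(losses) / len(order))

        val_logits = net.forward(x_val, train=False)
        val_loss, _ = _loss_and_grad(val_logits, y_val, weights)
        val_acc = float((val_logits.argmax(axis=1) == y_val).mean())
        history_rows.append(
            {
                "epoch": epoch,
                "train_loss": train_loss,
                "val_loss": val_loss,
                "val_acc": val_acc,
                "lr": lr,
            }
        )

        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = [p.copy() for p in net.params()]
            plateau = 0
        else:
            plateau += 1
            if plateau >= train_config.lr_patience and lr > train_config.min_lr:
                lr = max(lr * train_config.lr_factor, train_config.min_lr)
                opt.lr = lr
                plateau = 0

    net.set_params(best_params)
    return TrainedModel(
        network=net,
        pyramid_config=pyramid_config,
        train_config=train_config,
        history=pd.DataFrame(history_rows),
    )


def forward(model: TrainedModel, pss: PyramidSamplingSet) -> np.ndarray:
    """Class-probability 4-vector for one PSS (eval mode, deterministic)."""
    if pss.d_in != model.network.d_in:
        raise ValueError(
            f"PSS stacked depth {pss.d_in} does not match the model's "
            f"D_in={model.network.d_in}; expected pyramid config "
            f"{model.pyramid_config.levels} (hash {model.pyramid_config.config_hash})"
        )
    x = _prepare_input(stack_channels(pss))
    return model.network.predict_proba(x)[0]


def save_model(path, model: TrainedModel) -> None:
    """Single-file checkpoint: parameters + pyramid/training metadata."""
    meta = {
        "class_order": list(model.class_order),
        "patch_size": model.pyramid_config.patch_size,
        "levels": [list(l) for l in model.pyramid_config.levels],
        "include_whole_core": model.pyramid_config.include_whole_core,
        "config_hash": model.pyramid_config.config_hash,
        "channels": list(model.network.channels),
        "d_in": model.network.d_in,
        "net_seed": model.network.seed,
        "train_config": dataclasses.asdict(model.train_config),
    }
    arrays = {f"param_{i}": p for i, p in enumerate(model.network.params())}
    np.savez_compressed(path, meta=np.array(json.dumps(meta)), **arrays)
    hist_path = Path(str(path)).with_suffix(".history.csv")
    model.history.to_csv(hist_path, index=False)


def load_model(path) -> TrainedModel:
    with np.load(path) as z:
        meta = json.loads(str(z["meta"]))
        params = [z[f"param_{i}"] for i in range(len(z.files) - 1)]
    config = PyramidConfig(
        patch_size=meta["patch_size"],
        levels=tuple(tuple(l) for l in meta["levels"]),
        include_whole_core=meta["include_whole_core"],
    )
    net = SmallConvNet(
        d_in=meta["d_in"],
        patch_size=meta["patch_size"],
        channels=tuple(meta["channels"]),
        seed=meta["net_seed"],
    )
    net.set_params(params)
    hist_path = Path(str(path)).with_suffix(".history.csv")
    history = pd.read_csv(hist_path) if hist_path.exists() else pd.DataFrame()
    return TrainedModel(
        network=net,
        pyramid_config=config,
        train_config=TrainConfig(**meta["train_config"]),
        history=history,
        class_order=tuple(meta["class_order"]),
    )
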