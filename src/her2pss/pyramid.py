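"""Pyramid-Sampling Sets (PSS).

A PSS is a fixed-size collection of square RGB patches drawn from one core
image at multiple scales — patches at the original resolution capture
membrane-level detail, patches from downsampled copies capture tissue
architecture, and one patch holds the entire core resized to the patch
size. The patches are stacked along the channel axis into a single
``patch_size x patch_size x 3*n`` classifier input, so one forward pass
sees all scales jointly.

The default configuration is 40 full-resolution patches + 10 patches from
a 2x-downsampled copy + the whole-core patch: 51 patches, 153 stacked
channels. Three reduced presets (``a``, ``b``, ``c``) are provided for
ablation comparisons.

Sampling conventions (documented contracts, exercised by tests):

* patch top-left positions are drawn uniformly **with replacement** over
  all valid positions of the (possibly padded) level image;
* downsampling by an integer factor is block averaging; the whole-core
  resize uses the same area-style reduction after white padding;
* cores smaller than the patch size at some level are centered and padded
  with white (bright-field background), never rejected;
* no tissue-content filtering: patches may fall on background;
* coordinates are 0-based, half-open ``[top, top + patch_size)``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .types import CoreImage

__all__ = [
    "PyramidConfig",
    "PyramidSamplingSet",
    "sample_pss",
    "stack_channels",
    "unstack_channels",
    "ablation_configs",
    "save_pss",
    "load_pss",
]

WHITE = 255

#: Provenance level recorded for the whole-core resized patch.
WHOLE_CORE_LEVEL = 0


@dataclass(frozen=True)
class PyramidConfig:
    """Multi-scale sampling plan.

    ``levels`` is an ordered tuple of ``(downsample_factor, n_patches)``
    with strictly increasing integer factors; ``include_whole_core``
    appends one patch holding the full core resized to ``patch_size``.
    """

    patch_size: int = 512
    levels: tuple[tuple[int, int], ...] = ((1, 40), (2, 10))
    include_whole_core: bool = True

    def __post_init__(self) -> None:
        if self.patch_size < 8:
            raise ValueError("patch_size must be >= 8")
        factors = [f for f, _ in self.levels]
        if any(f < 1 for f in factors):
            raise ValueError("downsample factors must be integers >= 1")
        if any(b <= a for a, b in zip(factors, factors[1:])):
            raise ValueError("downsample factors must be strictly increasing")
        if any(n < 0 for _, n in self.levels):
            raise ValueError("per-level patch counts must be >= 0")
        if self.n_patches == 0:
            raise ValueError("configuration yields an empty patch set")

    @property
    def n_patches(self) -> int:
        return sum(n for _, n in self.levels) + int(self.include_whole_core)

    @property
    def d_in(self) -> int:
        """Stacked channel depth: 3 x patch count."""
        return 3 * self.n_patches

    @property
    def config_hash(self) -> str:
        text = f"{self.patch_size}|{tuple(self.levels)}|{self.include_whole_core}"
        return hashlib.sha1(text.encode()).hexdigest()[:12]


@dataclass
class PyramidSamplingSet:
    """One sampled PSS: ordered patches plus per-patch provenance.

    ``patches`` is ``(n, patch_size, patch_size, 3)`` uint8;
    ``provenance`` is ``(n, 3)`` int with columns
    ``(level_factor, top_row, top_col)`` in the coordinates of that level's
    (padded) image. The whole-core patch carries level
    :data:`WHOLE_CORE_LEVEL`.
    """

    core_id: str
    patches: np.ndarray
    provenance: np.ndarray
    rng_seed: int
    config: PyramidConfig = field(default_factory=PyramidConfig)

    @property
    def n_patches(self) -> int:
        return self.patches.shape[0]

    @property
    def d_in(self) -> int:
        return 3 * self.n_patches


def _pad_to_multiple(image: np.ndarray, factor: int) -> np.ndarray:
    h, w = image.shape[:2]
    ph = (-h) % factor
    pw = (-w) % factor
    if ph == 0 and pw == 0:
        return image
    return np.pad(
        image, ((0, ph), (0, pw), (0, 0)), mode="constant", constant_values=WHITE
    )


def _block_downsample(image: np.ndarray, factor: int) -> np.ndarray:
    """Area (block-mean) downsampling by an integer factor, white-padded."""
    if factor == 1:
        return image
    img = _pad_to_multiple(image, factor).astype(np.float64)
    h, w, c = img.shape
    img = img.reshape(h // factor, factor, w // factor, factor, c).mean(axis=(1, 3))
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _pad_center_to(image: np.ndarray, size: int) -> np.ndarray:
    """Center an image on a white size x size canvas (no-op if large enough)."""
    h, w = image.shape[:2]
    if h >= size and w >= size:
        return image
    ch, cw = max(h, size), max(w, size)
    canvas = np.full((ch, cw, 3), WHITE, dtype=image.dtype)
    y0 = (ch - h) // 2
    x0 = (cw - w) // 2
    canvas[y0 : y0 + h, x0 : x0 + w] = image
    return canvas


def _resize_whole(image: np.ndarray, size: int) -> np.ndarray:
    """Resize the full core to size x size by block averaging.

    The core is white-padded up to the next multiple of ``size`` along its
    longer side (keeping it centered), then block-reduced — the same area
    interpolation used between pyramid levels.
    """
    h, w = image.shape[:2]
    factor = max(1, -(-max(h, w) // size))  # ceil division
    target = factor * size
    canvas = np.full((target, target, 3), WHITE, dtype=image.dtype)
    y0 = (target - h) // 2
    x0 = (target - w) // 2
    canvas[y0 : y0 + h, x0 : x0 + w] = image
    return _block_downsample(canvas, factor)


def sample_pss(
    core: CoreImage | np.ndarray,
    config: PyramidConfig = PyramidConfig(),
    seed: int = 0,
) -> PyramidSamplingSet:
    """Draw one Pyramid-Sampling Set from a core image.

    For each level the core is block-downsampled by the level's factor and
    ``n_patches`` top-left positions are drawn uniformly at random (with
    replacement) over valid positions; the whole-core resized patch, when
    configured, is appended last. Identical ``(core, config, seed)``
    reproduce the identical PSS.
    """
    if isinstance(core, CoreImage):
        image, core_id = core.image, core.core_id
    else:
        image, core_id = np.asarray(core), "core"
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB (H, W, 3) core image, got {image.shape}")

    ps = config.patch_size
    rng = np.random.default_rng(seed)
    patches: list[np.ndarray] = []
    provenance: list[tuple[int, int, int]] = []

    for factor, n in config.levels:
        level_img = _pad_center_to(_block_downsample(image, factor), ps)
        max_top = level_img.shape[0] - ps
        max_left = level_img.shape[1] - ps
        tops = rng.integers(0, max_top + 1, size=n)
        lefts = rng.integers(0, max_left + 1, size=n)
        for t, l in zip(tops, lefts):
            patches.append(level_img[t : t + ps, l : l + ps])
            provenance.append((factor, int(t), int(l)))

    if config.include_whole_core:
        patches.append(_resize_whole(image, ps))
        provenance.append((WHOLE_CORE_LEVEL, 0, 0))

    return PyramidSamplingSet(
        core_id=core_id,
        patches=np.ascontiguousarray(np.stack(patches)),
        provenance=np.asarray(provenance, dtype=np.int64),
        rng_seed=int(seed),
        config=config,
    )


def stack_channels(pss: PyramidSamplingSet) -> np.ndarray:
    """Concatenate patches along the channel axis.

    Returns ``(patch_size, patch_size, 3 * n)`` with RGB triplets contiguous
    in patch order; :func:`unstack_channels` inverts this exactly.
    """
    n, h, w, c = pss.patches.shape
    if h != w or c != 3:
        raise ValueError(f"patches must be square RGB, got {pss.patches.shape}")
    return np.ascontiguousarray(pss.patches.transpose(1, 2, 0, 3).reshape(h, w, n * 3))


def unstack_channels(stacked: np.ndarray) -> np.ndarray:
    """Invert :func:`stack_channels` back to ``(n, H, W, 3)`` patches."""
    h, w, d = stacked.shape
    if d % 3:
        raise ValueError(f"stacked depth {d} is not a multiple of 3")
    return np.ascontiguousarray(
        stacked.reshape(h, w, d // 3, 3).transpose(2, 0, 1, 3)
    )


def ablation_configs(patch_size: int = 512) -> dict[str, PyramidConfig]:
    """Named sampling presets used for configuration comparisons.

    ``a``: a single full-resolution patch (1 patch);
    ``b``: 20 full-resolution + 6 from 2x-downsampled + whole core (27);
    ``c``: as ``b`` plus 2 patches from a 4x-downsampled copy (29);
    ``default``: 40 + 10 + whole core (51).
    """
    return {
        "a": PyramidConfig(patch_size, ((1, 1),), include_whole_core=False),
        "b": PyramidConfig(patch_size, ((1, 20), (2, 6))),
        "c": PyramidConfig(patch_size, ((1, 20), (2, 6), (4, 2))),
        "default": PyramidConfig(patch_size, ((1, 40), (2, 10))),
    }


def save_pss(path, pss: PyramidSamplingSet) -> None:
    """Cache a PSS as an NPZ bundle with provenance and config attributes."""
    np.savez_compressed(
        path,
        patches=pss.patches,
        provenance=pss.provenance,
        core_id=np.array(pss.core_id),
        seed=np.array(pss.rng_seed),
        config_hash=np.array(pss.config.config_hash),
        patch_size=np.array(pss.config.patch_size),
        levels=np.array(pss.config.levels, dtype=np.int64),
        include_whole_core=np.array(pss.config.include_whole_core),
    )


def load_pss(path) -> PyramidSamplingSet:
    with np.load(path) as z:
        config = PyramidConfig(
            patch_size=int(z["patch_size"]),
            levels=tuple(map(tuple, z["levels"].tolist())),
            include_whole_core=bool(z["include_whole_core"]),
        )
        return PyramidSamplingSet(
            core_id=str(z["core_id"]),
            patches=z["patches"],
            provenance=z["provenance"],
            rng_seed=int(z["seed"]),
            config=config,
        )
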