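"""Shared lightweight containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CoreImage:
    """One circular tissue core as an RGB raster plus provenance.

    Attributes
    ----------
    image:
        ``(H, W, 3)`` uint8 RGB array, bright-field convention
        (light background, dark stain).
    core_id:
        Stable identifier of the core (e.g. patient/position code).
    pixel_size_um:
        Physical pixel size, if known. Purely informational.
    """

    image: np.ndarray
    core_id: str = "core"
    pixel_size_um: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError(
                f"CoreImage expects an (H, W, 3) RGB array, got shape {img.shape}"
            )
        self.image = img

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.image.shape
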