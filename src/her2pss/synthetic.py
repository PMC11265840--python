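"""Synthetic IHC-like tissue cores and TMA-slide mosaics.

Emulates bright-field HER2 immunohistochemistry at patch scale: a circular
tissue core on a light background, populated with cell-like objects — a
hematoxylin-toned nucleus disk surrounded by a DAB-brown membrane ring.
The HER2 class controls the mean intensity and the angular completeness of
the membrane ring, mirroring the clinical reading ("complete and intense
membrane staining" for 3+, faint and partial for 1+). Intratumoral
heterogeneity is modeled as one contiguous angular sector of the core whose
cells express one class lower than the core's label, so a random patch
sampler can plausibly miss it.

The generator is fully deterministic: identical ``(spec, seed)`` produce
bit-identical images. Closed-form expectations of its own stain statistics
are exposed (:func:`expected_mean_dab_signal`) so tests can verify the
rendered images against an analytic oracle rather than against themselves.

Non-goals: optics, scanner noise models, stain deconvolution, nuclei
ground truth. Images are plain RGB with no color normalization.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .labels import ScoreLabel
from .types import CoreImage

__all__ = [
    "StainParams",
    "DEFAULT_STAIN_PARAMS",
    "CoreSpec",
    "SlideSpec",
    "generate_core",
    "generate_core_with_masks",
    "generate_dataset",
    "generate_tma_slide",
    "expected_mean_dab_signal",
    "mean_dab_signal",
]

# Bright-field palette (R, G, B). DAB is brown (high R, low B); hematoxylin
# counterstain is blue-violet (B above R); slide background is near-white.
BACKGROUND_RGB = np.array([247.0, 246.0, 244.0])
TISSUE_RGB = np.array([229.0, 222.0, 232.0])
NUCLEUS_RGB = np.array([74.0, 62.0, 132.0])
DAB_RGB = np.array([96.0, 60.0, 18.0])

TISSUE_ALPHA = 0.90  # blend of tissue tone over background inside the core
NUCLEUS_ALPHA = 0.85
NUCLEUS_RADIUS_FRACTION = 0.55  # nucleus radius relative to cell radius


@dataclass(frozen=True)
class StainParams:
    """Membrane staining parameters for one HER2 class.

    ``membrane_intensity`` is the blend weight of DAB brown over the
    underlying pixel (0 = unstained, 1 = saturated chromogen);
    ``membrane_completeness`` is the fraction of the cell perimeter that
    carries the ring.
    """

    membrane_intensity: float
    membrane_completeness: float


#: Default per-class staining. Mean membrane DAB signal is strictly
#: increasing in class: both intensity and completeness grow with score.
DEFAULT_STAIN_PARAMS: dict[ScoreLabel, StainParams] = {
    ScoreLabel.ZERO: StainParams(0.05, 0.10),
    ScoreLabel.ONE_PLUS: StainParams(0.30, 0.40),
    ScoreLabel.TWO_PLUS: StainParams(0.60, 0.75),
    ScoreLabel.THREE_PLUS: StainParams(0.95, 1.00),
}


@dataclass(frozen=True)
class CoreSpec:
    """Recipe for one synthetic tissue core.

    Parameters
    ----------
    diameter_px:
        Core diameter in pixels. 2,048 is the desk-scale stand-in for
        full-resolution cores (~10,000 px); configurable up to that scale.
    score:
        Ground-truth HER2 class of the core.
    heterogeneity:
        Fraction in [0, 1] of the core area (one contiguous sector)
        rendered with the staining of class ``max(score - 1, 0)``.
    cell_density:
        Cells per 10^4 px^2 of tissue. The default of 12 gives a cell area
        fraction near 0.3 at the default cell radius, a plausible epithelial
        packing that keeps ring overlap modest.
    cell_radius_px:
        Mean cell radius in pixels; fixed (not scaled with diameter), i.e.
        magnification is constant and core size varies, as on a scanner.
    stain_params:
        Per-class staining table; defaults to :data:`DEFAULT_STAIN_PARAMS`.
    seed:
        Seed fully determining the rendered image.
    """

    diameter_px: int = 2048
    score: ScoreLabel = ScoreLabel.ZERO
    heterogeneity: float = 0.0
    cell_density: float = 12.0
    cell_radius_px: float = 9.0
    stain_params: dict[ScoreLabel, StainParams] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.score, ScoreLabel):
            object.__setattr__(self, "score", ScoreLabel(int(self.score)))
        if self.diameter_px < 64:
            raise ValueError(f"diameter_px must be >= 64, got {self.diameter_px}")
        if not 0.0 <= self.heterogeneity <= 1.0:
            raise ValueError(
                f"heterogeneity must lie in [0, 1], got {self.heterogeneity}"
            )
        if self.cell_density < 0:
            raise ValueError("cell_density must be non-negative")

    @property
    def params(self) -> dict[ScoreLabel, StainParams]:
        return self.stain_params if self.stain_params is not None else DEFAULT_STAIN_PARAMS


def _ring_thickness(cell_radius: float) -> float:
    return max(2.0, cell_radius / 4.5)


def _tissue_radius(diameter_px: int) -> float:
    return diameter_px / 2.0 - 2.0


def _render(spec: CoreSpec) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Render one core; returns float image and internal masks."""
    rng = np.random.default_rng(spec.seed)
    d = spec.diameter_px
    center = (d - 1) / 2.0
    radius = _tissue_radius(d)

    yy, xx = np.mgrid[0:d, 0:d].astype(np.float64)
    dist = np.hypot(yy - center, xx - center)
    tissue = dist <= radius

    img = np.empty((d, d, 3), dtype=np.float64)
    img[:] = BACKGROUND_RGB
    img += rng.normal(0.0, 1.5, size=(d, d, 1))

    # Tissue disk: counterstain tone with mild texture.
    texture = rng.normal(0.0, 4.0, size=(d, d))
    blend = TISSUE_ALPHA * np.clip(radius + 0.5 - dist, 0.0, 1.0)
    img += blend[..., None] * (TISSUE_RGB - img) + (blend * texture)[..., None]

    # Heterogeneous sector: angular wedge of area fraction `heterogeneity`.
    sector_start = rng.uniform(0.0, 2 * np.pi)
    sector_span = 2 * np.pi * spec.heterogeneity
    angle = np.mod(np.arctan2(yy - center, xx - center) - sector_start, 2 * np.pi)
    sector = tissue & (angle < sector_span)

    params = spec.params
    low_class = ScoreLabel(max(int(spec.score) - 1, 0))

    # Cell positions: uniform over the disk (sqrt-radial), fixed count so the
    # analytic expectations are exact in the cell number.
    cell_r = spec.cell_radius_px
    tissue_area = np.pi * radius**2
    n_cells = int(round(spec.cell_density * tissue_area / 1e4))
    r_eff = max(radius - cell_r - 2.0, 1.0)
    pos_r = r_eff * np.sqrt(rng.random(n_cells))
    pos_t = rng.uniform(0.0, 2 * np.pi, n_cells)
    cy = center + pos_r * np.sin(pos_t)
    cx = center + pos_r * np.cos(pos_t)
    radii = np.clip(
        rng.normal(cell_r, 0.12 * cell_r, n_cells), 0.7 * cell_r, 1.3 * cell_r
    )
    ring_phase = rng.uniform(0.0, 2 * np.pi, n_cells)
    in_sector = np.mod(pos_t - sector_start, 2 * np.pi) < sector_span

    membrane_alpha = np.zeros((d, d), dtype=np.float64)
    thick = _ring_thickness(cell_r)
    for i in range(n_cells):
        sp = params[low_class] if in_sector[i] else params[spec.score]
        r_i = radii[i]
        half = r_i + thick
        y0, y1 = int(np.floor(cy[i] - half)), int(np.ceil(cy[i] + half)) + 1
        x0, x1 = int(np.floor(cx[i] - half)), int(np.ceil(cx[i] + half)) + 1
        y0, x0 = max(y0, 0), max(x0, 0)
        y1, x1 = min(y1, d), min(x1, d)
        ly, lx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
        ld = np.hypot(ly - cy[i], lx - cx[i])

        # Nucleus: antialiased hematoxylin disk.
        nuc_aa = np.clip(NUCLEUS_RADIUS_FRACTION * r_i + 0.5 - ld, 0.0, 1.0)
        a = NUCLEUS_ALPHA * nuc_aa
        img[y0:y1, x0:x1] += a[..., None] * (NUCLEUS_RGB - img[y0:y1, x0:x1])

        # Membrane: antialiased DAB arc of angular span 2*pi*completeness.
        ring_aa = np.clip(thick / 2.0 + 0.5 - np.abs(ld - r_i), 0.0, 1.0)
        arc = (
            np.mod(np.arctan2(ly - cy[i], lx - cx[i]) - ring_phase[i], 2 * np.pi)
            < 2 * np.pi * sp.membrane_completeness
        )
        a = sp.membrane_intensity * ring_aa * arc
        img[y0:y1, x0:x1] += a[..., None] * (DAB_RGB - img[y0:y1, x0:x1])
        membrane_alpha[y0:y1, x0:x1] = np.maximum(
            membrane_alpha[y0:y1, x0:x1], a
        )

    masks = {
        "tissue": tissue,
        "sector": sector,
        "membrane_alpha": membrane_alpha,
    }
    return np.clip(np.round(img), 0, 255).astype(np.uint8), masks


def generate_core_with_masks(
    spec: CoreSpec, core_id: str = "core"
) -> tuple[CoreImage, ScoreLabel, dict[str, np.ndarray]]:
    """As :func:`generate_core`, additionally returning internal masks.

    ``masks['tissue']`` is the core disk, ``masks['sector']`` the
    lower-class heterogeneity wedge, ``masks['membrane_alpha']`` the
    per-pixel DAB blend weight actually applied.
    """
    image, masks = _render(spec)
    core = CoreImage(image=image, core_id=core_id, meta={"spec": spec})
    return core, spec.score, masks


def generate_core(spec: CoreSpec, core_id: str = "core") -> tuple[CoreImage, ScoreLabel]:
    """Render one synthetic core. Deterministic in ``(spec, spec.seed)``."""
    core, label, _ = generate_core_with_masks(spec, core_id=core_id)
    return core, label


def mean_dab_signal(image: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Measured DAB signal: mean of (R - B)/255 over ``mask``.

    DAB brown has R well above B while the hematoxylin counterstain has the
    opposite sign, so this contrast grows monotonically with membrane
    staining and is insensitive to overall brightness.
    """
    img = np.asarray(image, dtype=np.float64)
    rb = (img[..., 0] - img[..., 2]) / 255.0
    if mask is not None:
        rb = rb[mask]
    return float(rb.mean())


def _class_signal(spec: CoreSpec, score: ScoreLabel, base_rb: float) -> float:
    """Expected membrane contribution of one class to the (R-B)/255 mean."""
    sp = spec.params[score]
    radius = _tissue_radius(spec.diameter_px)
    disk_area = np.pi * radius**2
    n_cells = round(spec.cell_density * disk_area / 1e4)
    ring_area = 2 * np.pi * spec.cell_radius_px * _ring_thickness(spec.cell_radius_px)
    f_mem = n_cells * ring_area * sp.membrane_completeness / disk_area
    dab_rb = (DAB_RGB[0] - DAB_RGB[2]) / 255.0
    return f_mem * sp.membrane_intensity * (dab_rb - base_rb)


def expected_mean_dab_signal(spec: CoreSpec) -> float:
    """Closed-form expectation of :func:`mean_dab_signal` over the core disk.

    Derived from the generator's own palette and geometry, ignoring
    cell–cell overlap (a few percent at the default density): the disk is a
    mixture of counterstained tissue, nucleus disks, and membrane arcs whose
    expected area fractions follow directly from ``cell_density``,
    ``cell_radius_px`` and the per-class staining table.
    """
    bg_rb = (BACKGROUND_RGB[0] - BACKGROUND_RGB[2]) / 255.0
    tis_rb = (TISSUE_RGB[0] - TISSUE_RGB[2]) / 255.0
    base_rb = bg_rb + TISSUE_ALPHA * (tis_rb - bg_rb)

    radius = _tissue_radius(spec.diameter_px)
    disk_area = np.pi * radius**2
    n_cells = round(spec.cell_density * disk_area / 1e4)
    nuc_area = np.pi * (NUCLEUS_RADIUS_FRACTION * spec.cell_radius_px) ** 2
    f_nuc = n_cells * nuc_area / disk_area
    nuc_rb = (NUCLEUS_RGB[0] - NUCLEUS_RGB[2]) / 255.0
    expected = base_rb + f_nuc * NUCLEUS_ALPHA * (nuc_rb - base_rb)

    h = spec.heterogeneity
    low = ScoreLabel(max(int(spec.score) - 1, 0))
    expected += (1.0 - h) * _class_signal(spec, spec.score, base_rb)
    expected += h * _class_signal(spec, low, base_rb)
    return float(expected)


def _derived_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def generate_dataset(
    n_per_class: int,
    template: CoreSpec = CoreSpec(),
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[tuple[CoreImage, ScoreLabel]], pd.DataFrame]:
    """Generate ``4 * n_per_class`` labeled cores from a template spec.

    Per-core seeds are derived deterministically from ``seed``; two runs
    with the same master seed produce identical manifests and images. When
    ``out_dir`` is given, cores are written as PNG and a ``manifest.csv``
    with columns ``core_id, path, score, heterogeneity, seed`` is saved.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    seeds = _derived_seeds(seed, 4 * n_per_class)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    cores: list[tuple[CoreImage, ScoreLabel]] = []
    rows = []
    for ci, score in enumerate(ScoreLabel):
        for j in range(n_per_class):
            k = ci * n_per_class + j
            spec = dataclasses.replace(template, score=score, seed=seeds[k])
            core_id = f"core_{int(score)}_{j:03d}"
            core, label = generate_core(spec, core_id=core_id)
            cores.append((core, label))
            path = ""
            if out is not None:
                path = str(out / f"{core_id}.png")
                Image.fromarray(core.image).save(path)
            rows.append(
                {
                    "core_id": core_id,
                    "path": path,
                    "score": str(label),
                    "heterogeneity": spec.heterogeneity,
                    "seed": spec.seed,
                }
            )
    manifest = pd.DataFrame(rows)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    return cores, manifest


@dataclass(frozen=True)
class SlideSpec:
    """Recipe for a TMA-slide mosaic: a grid of cores on a light slide.

    ``core_specs`` may list one :class:`CoreSpec` per grid position
    (row-major); ``None`` entries leave an empty slot, emulating missing
    cores. When the whole list is ``None``, classes are drawn uniformly at
    random. ``spacing_px`` is the center-to-center distance and must exceed
    the core diameter.
    """

    grid_rows: int = 3
    grid_cols: int = 3
    core_radius_px: int = 100
    spacing_px: int = 260
    core_specs: tuple[CoreSpec | None, ...] | None = None
    background_level: int = 246
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.spacing_px <= 2 * self.core_radius_px:
            raise ValueError(
                "spacing_px must exceed the core diameter "
                f"(spacing {self.spacing_px} <= 2 x radius {self.core_radius_px})"
            )
        if self.core_specs is not None and len(self.core_specs) != (
            self.grid_rows * self.grid_cols
        ):
            raise ValueError("core_specs length must equal grid_rows * grid_cols")


def generate_tma_slide(spec: SlideSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a TMA mosaic plus its ground-truth circle table.

    Returns the slide as an ``(H, W, 3)`` uint8 array and a DataFrame with
    columns ``core_id, center_row, center_col, radius, score`` in 0-based
    pixel coordinates; ``radius`` is the rendered tissue radius.
    """
    rng = np.random.default_rng(spec.seed)
    margin = spec.core_radius_px + 24
    height = spec.spacing_px * (spec.grid_rows - 1) + 2 * margin
    width = spec.spacing_px * (spec.grid_cols - 1) + 2 * margin

    slide = np.empty((height, width, 3), dtype=np.float64)
    slide[:] = spec.background_level
    slide += rng.normal(0.0, 1.5, size=(height, width, 1))

    seeds = _derived_seeds(spec.seed + 1, spec.grid_rows * spec.grid_cols)
    rows = []
    for r in range(spec.grid_rows):
        for c in range(spec.grid_cols):
            idx = r * spec.grid_cols + c
            if spec.core_specs is not None:
                core_spec = spec.core_specs[idx]
                if core_spec is None:
                    continue
            else:
                core_spec = CoreSpec(
                    diameter_px=2 * spec.core_radius_px,
                    score=ScoreLabel(int(rng.integers(0, 4))),
                    seed=seeds[idx],
                )
            if core_spec.diameter_px != 2 * spec.core_radius_px:
                core_spec = dataclasses.replace(
                    core_spec, diameter_px=2 * spec.core_radius_px
                )
            img, masks = _render(core_spec)
            d = core_spec.diameter_px
            cy = margin + r * spec.spacing_px
            cx = margin + c * spec.spacing_px
            y0, x0 = cy - d // 2, cx - d // 2
            tissue = masks["tissue"]
            region = slide[y0 : y0 + d, x0 : x0 + d]
            region[tissue] = img[tissue]
            rows.append(
                {
                    "core_id": f"r{r}c{c}",
                    "center_row": cy,
                    "center_col": cx,
                    "radius": _tissue_radius(d),
                    "score": str(core_spec.score),
                }
            )
    truth = pd.DataFrame(rows)
    return np.clip(np.round(slide), 0, 255).astype(np.uint8), truth
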