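"""Detection and cropping of circular tissue cores on TMA slides.

TMA cores are near-circular disks of tissue on a bright background, so a
circular Hough transform on an edge map is the natural detector. The
pipeline: downsample the slide (detection needs no full resolution),
Canny edge detection, circular Hough accumulation over the requested
radius range, peak extraction with non-maximum suppression at the
requested minimum separation, and rescaling of centers and radii back to
full resolution. Detections are returned sorted by accumulator score.

Crops are square, centered on the detected circle, with an optional
margin; regions falling outside the slide are filled with white (the
bright-field background) rather than reflected, to avoid fabricating
tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.color import rgb2gray
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from .types import CoreImage

__all__ = ["DetectedCircle", "detect_cores", "crop_core", "extract_all"]

#: Accumulator fraction below which peaks are discarded (relative to a
#: perfect circle response of 1.0); rejects blank or structureless slides.
MIN_ACCUMULATOR = 0.15


@dataclass(frozen=True)
class DetectedCircle:
    """One detected core: 0-based center, radius, Hough accumulator score."""

    center_row: float
    center_col: float
    radius: float
    detection_score: float


def _refine_circle(
    gray: np.ndarray, row: float, col: float, radius: float
) -> tuple[float, float, float]:
    """Refine a Hough proposal at full resolution.

    Within a window around the proposal, tissue is darker than the slide
    background; Otsu-thresholding the window and restricting to a disk
    slightly larger than the proposed radius isolates the core's pixel
    mask, whose centroid and equivalent-area radius give subpixel center
    and radius estimates (the coarse Hough grid alone quantizes both).
    """
    for _ in range(3):  # centroid updates converge in 2-3 passes
        half = int(round(1.45 * radius))
        y0, y1 = max(int(row) - half, 0), min(int(row) + half + 1, gray.shape[0])
        x0, x1 = max(int(col) - half, 0), min(int(col) + half + 1, gray.shape[1])
        window = gray[y0:y1, x0:x1]
        if window.size < 16 or window.max() - window.min() < 1e-3:
            return row, col, radius
        # background level from the window border; tissue (counterstained,
        # even without chromogen) sits clearly below it
        border = np.r_[window[0], window[-1], window[:, 0], window[:, -1]]
        mask = window < np.median(border) - 0.03
        mask = ndi.binary_fill_holes(mask)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        mask &= np.hypot(yy - row, xx - col) <= 1.35 * radius
        area = int(mask.sum())
        if area < 16:
            return row, col, radius
        row = float(yy[mask].mean())
        col = float(xx[mask].mean())
        radius = float(np.sqrt(area / np.pi))
    return row, col, radius


def detect_cores(
    slide: np.ndarray,
    radius_range: tuple[int, int],
    min_separation_px: int,
    downsample: int = 4,
) -> list[DetectedCircle]:
    """Find circular cores on a slide image via a circular Hough transform.

    Proposals come from a Hough accumulator on a downsampled edge map and
    are refined at full resolution (threshold + centroid) to subpixel
    precision. ``radius_range`` is (min, max) radius in full-resolution
    pixels; no two returned centers are closer than ``min_separation_px``.
    An image without circular structure yields an empty list.
    Deterministic.
    """
    r_min, r_max = radius_range
    if not 0 < r_min < r_max:
        raise ValueError(f"invalid radius_range {radius_range}: need 0 < min < max")
    if min_separation_px < 1:
        raise ValueError("min_separation_px must be >= 1")
    slide = np.asarray(slide)
    if slide.size == 0:
        return []
    gray = rgb2gray(slide) if slide.ndim == 3 else slide.astype(np.float64) / 255.0

    ds = max(1, int(downsample))
    small = gray[::ds, ::ds]
    edges = canny(small, sigma=2.0)
    if not edges.any():
        return []

    radii = np.arange(max(2, r_min // ds), max(3, -(-r_max // ds) + 1))
    accum = hough_circle(edges, radii)
    min_dist = max(1, min_separation_px // ds)
    scores, cxs, cys, rs = hough_circle_peaks(
        accum,
        radii,
        min_xdistance=min_dist,
        min_ydistance=min_dist,
        threshold=MIN_ACCUMULATOR,
        num_peaks=np.inf,
        total_num_peaks=np.inf,
    )

    # hough_circle_peaks suppresses in x and y independently; enforce true
    # euclidean separation, keeping the stronger detection.
    circles: list[DetectedCircle] = []
    for s, cx, cy, r in sorted(zip(scores, cxs, cys, rs), key=lambda t: -t[0]):
        row, col = float(cy * ds + ds / 2 - 0.5), float(cx * ds + ds / 2 - 0.5)
        row, col, radius = _refine_circle(gray, row, col, float(r * ds))
        if any(
            np.hypot(row - c.center_row, col - c.center_col) < min_separation_px
            for c in circles
        ):
            continue
        circles.append(
            DetectedCircle(
                center_row=row,
                center_col=col,
                radius=radius,
                detection_score=float(s),
            )
        )
    return circles


def crop_core(
    slide: np.ndarray,
    circle: DetectedCircle,
    margin_fraction: float = 0.1,
    core_id: str = "core",
) -> CoreImage:
    """Square crop around a detected circle, white-filling out-of-bounds.

    The crop side is ``round(2 * radius * (1 + margin_fraction))`` and the
    circle center is preserved at the crop center; pixel ranges are
    half-open. Portions outside the slide become white background.
    """
    if margin_fraction < 0:
        raise ValueError("margin_fraction must be >= 0")
    slide = np.asarray(slide)
    side = int(round(2 * circle.radius * (1 + margin_fraction)))
    side = max(side, 2)
    y0 = int(round(circle.center_row - side / 2 + 0.5))
    x0 = int(round(circle.center_col - side / 2 + 0.5))
    out = np.full((side, side, 3), 255, dtype=np.uint8)
    ys0, xs0 = max(y0, 0), max(x0, 0)
    ys1, xs1 = min(y0 + side, slide.shape[0]), min(x0 + side, slide.shape[1])
    if ys1 > ys0 and xs1 > xs0:
        out[ys0 - y0 : ys1 - y0, xs0 - x0 : xs1 - x0] = slide[ys0:ys1, xs0:xs1]
    return CoreImage(
        image=out,
        core_id=core_id,
        meta={"center_row": circle.center_row, "center_col": circle.center_col,
              "radius": circle.radius},
    )


def extract_all(
    slide: np.ndarray,
    radius_range: tuple[int, int],
    min_separation_px: int,
    margin_fraction: float = 0.1,
    out_dir: str | Path | None = None,
) -> tuple[list[CoreImage], pd.DataFrame]:
    """Detect and crop every core on a slide; optionally write PNG + CSV."""
    from PIL import Image

    circles = detect_cores(slide, radius_range, min_separation_px)
    cores = []
    rows = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for i, c in enumerate(circles):
        cid = f"core_{i:03d}"
        core = crop_core(slide, c, margin_fraction, core_id=cid)
        cores.append(core)
        path = ""
        if out is not None:
            path = str(out / f"{cid}.png")
            Image.fromarray(core.image).save(path)
        rows.append(
            {
                "core_id": cid,
                "center_row": c.center_row,
                "center_col": c.center_col,
                "radius": c.radius,
                "path": path,
            }
        )
    table = pd.DataFrame(rows)
    if out is not None:
        table.to_csv(out / "cores.csv", index=False)
    return cores, table
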