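"""Image-derived traits: projected areas, estimated biovolume, height, hue.

Traits follow the conventions of conveyor-greenhouse RGB phenotyping:

* **EB** (estimated biovolume, voxel = pixel^3):
  ``sqrt((mean side area)^2 * top area)``, i.e. the mean of the three
  side-view projected areas times the square root of the top-view area;
  reported after division by a downscaling factor of 1e6.
* **PH** (plant height, mm): pot-rim row minus topmost plant row in a side
  view, times the mm-per-pixel calibration.
* **CVa** (color value, hue): plant-pixel hues pooled over the side views,
  binned into a 20-bin histogram, and summarized as the count-weighted mean
  of bin centers.  A healthy green plant sits near 0.23 on this scale.

Segmentation is a hue-window/saturation threshold with small-component
removal — adequate for the synthetic renderer this package ships and for any
imagery with a similarly controlled background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv
from skimage.morphology import remove_small_objects

DOWNSCALE = 1e6
N_HUE_BINS = 20


@dataclass(frozen=True)
class SegmentationConfig:
    hue_window: tuple[float, float] = (0.04, 0.45)
    min_saturation: float = 0.25
    min_component_px: int = 4
    pot_rows: int = 20  # bottom rows excluded in side views

    def __post_init__(self) -> None:
        lo, hi = self.hue_window
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("hue window must satisfy 0 <= lo < hi <= 1")
        if self.min_component_px < 1:
            raise ValueError("min component size must be >= 1")


@dataclass
class ImageTraits:
    plant_id: str
    das: int
    side_areas: tuple[int, int, int]
    top_area: int | None  # None when the top view is unavailable
    eb_raw: float | None
    eb_reported: float | None
    ph_mm: float | None
    cva: float | None


def _as_float_rgb(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) color raster")
    if img.dtype == np.uint8:
        return img / 255.0
    return img.astype(float)


def segment_plant(
    image: np.ndarray,
    config: SegmentationConfig | None = None,
    side_view: bool = False,
) -> np.ndarray:
    """Boolean mask of plant pixels.

    A pixel is plant iff its hue lies in the configured window and its
    saturation meets the threshold; connected components smaller than the
    minimum size are dropped, and for side views the pot rows at the bottom
    of the frame are excluded.  An empty mask is a valid result.
    """
    config = config or SegmentationConfig()
    hsv = rgb2hsv(_as_float_rgb(image))
    lo, hi = config.hue_window
    mask = (hsv[..., 0] >= lo) & (hsv[..., 0] <= hi)
    mask &= hsv[..., 1] >= config.min_saturation
    if side_view and config.pot_rows > 0:
        mask[mask.shape[0] - config.pot_rows:, :] = False
    if config.min_component_px > 1:
        # remove_small_objects' max_size removes components <= the threshold
        mask = remove_small_objects(mask, max_size=config.min_component_px - 1)
    return mask


def projected_areas(
    side_masks: list[np.ndarray],
    top_mask: np.ndarray | None,
) -> tuple[tuple[int, int, int], int | None]:
    """True-pixel counts per view; the top count is None when missing."""
    if len(side_masks) != 3:
        raise ValueError("expected exactly three side-view masks")
    sides = tuple(int(np.count_nonzero(m)) for m in side_masks)
    top = None if top_mask is None else int(np.count_nonzero(top_mask))
    return sides, top


def estimated_biovolume(
    side_areas: tuple[int, int, int] | list[int],
    top_area: float,
    downscale: float = DOWNSCALE,
) -> tuple[float, float]:
    """EB from projected areas: ``sqrt(mean_side^2 * top)`` voxels.

    Returns ``(eb_raw, eb_reported)`` with the reported value divided by
    ``downscale``.
    """
    sides = [float(a) for a in side_areas]
    if any(a < 0 for a in sides) or top_area < 0:
        raise ValueError("projected areas must be non-negative")
    mean_side = sum(sides) / len(sides)
    eb_raw = math.sqrt(mean_side**2 * top_area)
    return eb_raw, eb_raw / downscale


def plant_height(
    side_mask: np.ndarray,
    baseline_row: int,
    mm_per_pixel: float,
) -> float | None:
    """Height in mm from a side-view mask: (pot-rim row - topmost plant row)
    scaled by the calibration, floored at zero.  None for an empty mask."""
    if not 0 <= baseline_row < side_mask.shape[0]:
        raise ValueError("baseline_row outside the image")
    if mm_per_pixel <= 0:
        raise ValueError("mm_per_pixel must be positive")
    rows = np.nonzero(side_mask.any(axis=1))[0]
    if rows.size == 0:
        return None
    return max(0.0, float(baseline_row - rows[0]) * mm_per_pixel)


def hue_histogram(
    image: np.ndarray,
    mask: np.ndarray,
    n_bins: int = N_HUE_BINS,
) -> np.ndarray:
    """Counts of plant-pixel hues in ``n_bins`` equal-width bins over [0, 1)."""
    hsv = rgb2hsv(_as_float_rgb(image))
    hues = hsv[..., 0][np.asarray(mask, dtype=bool)]
    counts, _ = np.histogram(hues, bins=n_bins, range=(0.0, 1.0))
    return counts


def cva_from_histogram(counts: np.ndarray) -> float | None:
    """Count-weighted mean of bin centers; None for an all-zero histogram."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return None
    centers = (np.arange(counts.size) + 0.5) / counts.size
    return float(np.dot(counts, centers) / total)


def color_value_cva(
    image: np.ndarray,
    mask: np.ndarray,
    n_bins: int = N_HUE_BINS,
) -> float | None:
    """CVa of one view: binned-hue weighted mean over the mask.

    Hue is treated as a plain [0, 1) scale without circular averaging; plant
    hues (green to yellow) stay far from the red wrap point, so this is safe
    for the intended imagery.
    """
    return cva_from_histogram(hue_histogram(image, mask, n_bins))


def qy_lh_ratio(qy_low: float, qy_high: float) -> float:
    """Ratio of the quantum yield after the low-light flash to the one after
    the high-light flash — a plasticity measure of photosystem II."""
    if qy_high <= 0:
        raise ValueError("qy_high must be positive")
    return qy_low / qy_high


def extract_traits(
    image_set,
    config: SegmentationConfig | None = None,
    downscale: float = DOWNSCALE,
    top_missing: bool = False,
) -> ImageTraits:
    """All image traits of one imaging event (a ``PlantImageSet``).

    When the top view is unavailable (``top_missing``), EB is emitted as
    missing while PH and CVa are still computed from the side views — the
    behaviour required when a top camera outage hits part of a time series.
    """
    config = config or SegmentationConfig()
    side_masks = [segment_plant(img, config, side_view=True) for img in image_set.sides]
    top_mask = None if top_missing else segment_plant(image_set.top, config)
    sides, top = projected_areas(side_masks, top_mask)

    if top is None:
        eb_raw = eb_rep = None
    else:
        eb_raw, eb_rep = estimated_biovolume(sides, top, downscale)

    baseline = image_set.sides[0].shape[0] - config.pot_rows - 1
    heights = [
        plant_height(m, baseline, image_set.mm_per_pixel) for m in side_masks
    ]
    heights = [h for h in heights if h is not None]
    ph = max(heights) if heights else None

    pooled = np.zeros(N_HUE_BINS, dtype=float)
    for img, m in zip(image_set.sides, side_masks):
        pooled += hue_histogram(img, m)
    cva = cva_from_histogram(pooled)

    return ImageTraits(
        plant_id=image_set.plant_id,
        das=image_set.das,
        side_areas=sides,
        top_area=top,
        eb_raw=eb_raw,
        eb_reported=eb_rep,
        ph_mm=ph,
        cva=cva,
    )


def extract_experiment(
    image_sets,
    config: SegmentationConfig | None = None,
    downscale: float = DOWNSCALE,
    genotype_of: dict[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Long-format trait table (EB, PH, CVa) from a list of image sets.

    ``genotype_of`` maps plant_id -> (genotype, treatment); when omitted the
    ids are parsed as ``<genotype>_<treatment>_r<rep>`` (the synthetic
    layout).  Missing EB days yield rows with an empty value.
    """
    rows = []
    for s in image_sets:
        t = extract_traits(s, config, downscale)
        if genotype_of is not None:
            genotype, treatment = genotype_of[s.plant_id]
        else:
            genotype, treatment, _ = s.plant_id.rsplit("_", 2)
        rows.append((s.plant_id, genotype, treatment, s.das, "EB", t.eb_reported))
        rows.append((s.plant_id, genotype, treatment, s.das, "PH", t.ph_mm))
        rows.append((s.plant_id, genotype, treatment, s.das, "CVa", t.cva))
    return pd.DataFrame(
        rows, columns=["plant_id", "genotype", "treatment", "das", "trait", "value"]
    )
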