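"""Ground-truthed synthetic HTP experiments.

This module generates the kind of data the analysis pipeline expects from a
conveyor greenhouse phenotyping platform: per-plant daily trajectories of
estimated biovolume (EB), plant height (PH) and mean hue (CVa), harvest
records, and (optionally) procedurally rendered top/side-view images with
exact ground-truth masks.

The generative model, per genotype x treatment:

* EB follows a logistic curve ``A / (1 + exp(-r (t - m)))``; under drought a
  smooth multiplier ramps in after the watering step-down plus a
  genotype-specific lag (the lag is the biologically interesting, recoverable
  parameter), and after ripening starts an exponential decline sets in as the
  visible plant area shrinks.
* PH follows its own logistic and saturates shortly after heading.
* CVa sits at a green hue (0.23 by default) and decays logistically to a
  mature yellow hue; the decay midpoint is the senescence-onset parameter
  that stay-green detection must recover.
* Replicates share genotype parameters up to multiplicative noise on the
  asymptotes, and each plant leaves the platform on its own maturity day.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb

from .design import (
    CONTROL,
    STRESS,
    ExperimentDesign,
    build_default_design,
    imaging_days,
    stress_onset,
)

GREEN_HUE = 0.23  # 20-bin hue model value of a healthy green plant
MATURE_HUE = 0.12  # fully senesced (yellow); chosen for contrast with green

TRAIT_EB = "EB"
TRAIT_PH = "PH"
TRAIT_CVA = "CVa"


@dataclass
class GrowthParams:
    """Trajectory parameters for one genotype in one treatment.

    ``stress_onset_das`` is ``None`` in the control treatment; when set, the
    drought multiplier ramps in smoothly over ``drought_ramp_days`` starting
    ``drought_lag`` days after it.
    """

    eb_asymptote: float  # voxel scale
    eb_rate: float  # 1/day
    eb_inflection: float  # DAS
    ripening_start: float  # DAS
    ripening_decline: float  # 1/day
    ph_asymptote: float  # mm
    ph_rate: float = 0.25
    ph_inflection: float = 40.0
    heading_das: float = 48.0
    hue_green: float = GREEN_HUE
    hue_mature: float = MATURE_HUE
    senescence_onset: float = 85.0  # DAS, logistic midpoint of hue decay
    senescence_rate: float = 0.25  # 1/day
    stress_onset_das: int | None = None
    drought_multiplier: float = 1.0  # asymptotic stress/control ratio, (0, 1]
    drought_lag: int = 0  # days
    drought_ramp_days: float = 14.0
    ph_drought_frac: float = 0.3  # PH feels this fraction of the EB drought effect
    maturity_mean: float = 110.0  # DAS
    maturity_sd: float = 4.0
    replicate_cv: float = 0.08
    eb_noise_cv: float = 0.03  # day-to-day measurement noise
    ph_noise_cv: float = 0.015
    cva_noise_sd: float = 0.004
    yield_means: dict[str, float] = field(default_factory=dict)
    yield_sds: dict[str, float] = field(default_factory=dict)
    yield_coupling: float = 0.0  # 0 = independent yield draws, 1 = fully size-coupled

    def __post_init__(self) -> None:
        if self.eb_asymptote < 0 or self.eb_rate < 0 or self.ph_asymptote < 0:
            raise ValueError("asymptotes and rates must be non-negative")
        if not self.hue_mature < self.hue_green:
            raise ValueError("hue_mature must be below hue_green")
        if not 0.0 < self.drought_multiplier <= 1.0:
            raise ValueError("drought_multiplier must lie in (0, 1]")
        if self.drought_lag < 0:
            raise ValueError("drought_lag must be non-negative")


@dataclass
class PlantState:
    """One simulated plant: realized parameters and its platform lifetime."""

    plant_id: str
    genotype: str
    treatment: str
    params: GrowthParams  # per-plant realized copy
    removal_das: int


@dataclass
class PlantImageSet:
    """One imaging event: top view plus three side views (0, 45, 90 degrees)."""

    plant_id: str
    das: int
    top: np.ndarray  # (H, W, 3) uint8
    sides: list[np.ndarray]  # three (H, W, 3) uint8
    truth_masks: dict[str, np.ndarray] | None  # keys: top, side000, side045, side090
    mm_per_pixel: float


# ---------------------------------------------------------------------------
# Deterministic trajectory model


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def _smoothstep(u: float) -> float:
    u = min(max(u, 0.0), 1.0)
    return u * u * (3.0 - 2.0 * u)


def drought_factor(params: GrowthParams, das: float) -> float:
    """Multiplicative drought effect on EB at ``das`` (1.0 = no effect)."""
    if params.stress_onset_das is None or params.drought_multiplier >= 1.0:
        return 1.0
    start = params.stress_onset_das + params.drought_lag
    if das <= start:
        return 1.0
    ramp = _smoothstep((das - start) / params.drought_ramp_days)
    return 1.0 - (1.0 - params.drought_multiplier) * ramp


def true_biovolume(params: GrowthParams, das: float) -> float:
    """Noise-free EB (voxel scale) at ``das`` under the growth model."""
    if das < 0:
        raise ValueError("das must be non-negative")
    eb = params.eb_asymptote * _logistic(params.eb_rate * (das - params.eb_inflection))
    eb *= drought_factor(params, das)
    if das > params.ripening_start:
        eb *= math.exp(-params.ripening_decline * (das - params.ripening_start))
    return max(eb, 0.0)


def true_height(params: GrowthParams, das: float) -> float:
    """Noise-free plant height in mm at ``das``."""
    if das < 0:
        raise ValueError("das must be non-negative")
    ph = params.ph_asymptote * _logistic(params.ph_rate * (das - params.ph_inflection))
    f = drought_factor(params, das)
    ph *= 1.0 - params.ph_drought_frac * (1.0 - f)
    return max(ph, 0.0)


def true_cva(params: GrowthParams, das: float) -> float:
    """Noise-free mean hue at ``das``: green, decaying logistically with
    senescence.  The decay midpoint sits at ``senescence_onset``."""
    if das < 0:
        raise ValueError("das must be non-negative")
    span = params.hue_green - params.hue_mature
    return params.hue_mature + span * _logistic(
        -params.senescence_rate * (das - params.senescence_onset)
    )


# ---------------------------------------------------------------------------
# Default parameterization of the reference experiment

# Per-genotype values: EB asymptote (voxel), PH asymptote control/stress (mm),
# heading DAS control/stress, drought multiplier and response lag (days),
# senescence-onset DAS control/stress, maturity-day mean control/stress.
_GENOTYPE_TABLE: dict[str, dict] = {
    "BarNir": dict(eb=2.2e6, ph=(477, 448), head=(46.6, 45.2), dmult=0.43, lag=0,
                   sen=(84, 66), mat=(108, 90), hue_shift=0.000),
    "NIL-B-7A-2": dict(eb=2.8e6, ph=(726, 672), head=(47.0, 46.2), dmult=0.48, lag=6,
                       sen=(84, 72), mat=(110, 94), hue_shift=-0.004),
    "Zahir": dict(eb=2.4e6, ph=(727, 687), head=(55.6, 52.6), dmult=0.37, lag=0,
                  sen=(88, 70), mat=(115, 97), hue_shift=0.000),
    "NIL-Z-7A-5": dict(eb=2.2e6, ph=(748, 678), head=(54.0, 52.8), dmult=0.44, lag=7,
                       sen=(90, 75), mat=(116, 98), hue_shift=0.000),
    "Uzan": dict(eb=2.3e6, ph=(625, 581), head=(50.0, 48.3), dmult=0.48, lag=0,
                 sen=(85, 67), mat=(110, 92), hue_shift=0.004),
    "NIL-U-2B-3": dict(eb=2.5e6, ph=(547, 480), head=(49.8, 47.5), dmult=0.51, lag=2,
                       sen=(84, 66), mat=(109, 91), hue_shift=0.000),
}

# Harvest traits: (control mean, control sd, stress mean, stress sd).
_YIELD_TABLE: dict[str, dict[str, tuple]] = {
    "BarNir": {
        "plant_biomass_g": (12.51, 2.02, 5.42, 0.55),
        "grain_weight_g": (7.60, 1.24, 4.00, 0.34),
        "straw_weight_g": (6.35, 1.02, 3.02, 0.31),
        "tkw_g": (37.30, 2.16, 33.05, 3.33),
        "watersum_l": (8.14, 0.99, 2.82, 0.14),
    },
    "NIL-B-7A-2": {
        "plant_biomass_g": (16.94, 5.89, 8.09, 1.39),
        "grain_weight_g": (10.50, 3.95, 5.70, 0.91),
        "straw_weight_g": (8.42, 2.24, 4.48, 0.60),
        "tkw_g": (44.60, 6.55, 39.29, 2.11),
        "watersum_l": (9.91, 2.25, 3.73, 0.43),
    },
    "Zahir": {
        "plant_biomass_g": (13.27, 4.00, 4.97, 0.76),
        "grain_weight_g": (8.70, 2.34, 4.00, 0.62),
        "straw_weight_g": (7.61, 1.80, 3.34, 0.32),
        "tkw_g": (47.43, 4.75, 38.17, 6.32),
        "watersum_l": (8.96, 1.68, 2.92, 0.17),
    },
    "NIL-Z-7A-5": {
        "plant_biomass_g": (11.76, 1.85, 5.12, 0.86),
        "grain_weight_g": (7.50, 1.08, 4.00, 0.63),
        "straw_weight_g": (6.97, 1.00, 3.39, 0.30),
        "tkw_g": (47.55, 2.18, 44.01, 5.27),
        "watersum_l": (8.20, 0.71, 2.85, 0.21),
    },
    "Uzan": {
        "plant_biomass_g": (11.69, 1.83, 5.66, 0.75),
        "grain_weight_g": (6.90, 1.70, 3.90, 0.55),
        "straw_weight_g": (6.86, 0.59, 3.63, 0.35),
        "tkw_g": (50.05, 5.70, 46.85, 4.21),
        "watersum_l": (9.21, 1.10, 3.31, 0.30),
    },
    "NIL-U-2B-3": {
        "plant_biomass_g": (12.51, 3.22, 6.43, 1.16),
        "grain_weight_g": (7.40, 1.99, 4.40, 0.78),
        "straw_weight_g": (6.97, 1.56, 3.69, 0.53),
        "tkw_g": (48.32, 3.05, 46.71, 3.48),
        "watersum_l": (9.28, 1.62, 3.34, 0.38),
    },
}


def default_growth_params(
    design: ExperimentDesign | None = None,
) -> dict[tuple[str, str], GrowthParams]:
    """Default parameters for every genotype x treatment of ``design``.

    Asymptotes and harvest-trait distributions differ by genotype; heading,
    senescence onset and maturity are earlier under drought (about 2, 18 and
    18 days respectively); the drought multiplier reaches roughly half of the
    control biomass and the NILs respond with a lag of several days.
    """
    design = design or build_default_design()
    onset = stress_onset(design) if STRESS in design.watering else None
    out: dict[tuple[str, str], GrowthParams] = {}
    for g in design.genotypes:
        row = _GENOTYPE_TABLE.get(g.name)
        if row is None:
            raise KeyError(f"no default parameters for genotype {g.name!r}")
        yields = _YIELD_TABLE[g.name]
        head_c, head_s = row["head"]
        ph_c, ph_s = row["ph"]
        for treatment in design.treatments:
            stressed = treatment == STRESS
            idx = 1 if stressed else 0
            head = row["head"][idx]
            # both treatments share the pre-drought trajectory (same
            # asymptotes/inflections anchored on the control heading); the
            # stress reduction comes entirely from the drought ramp, with
            # ph_drought_frac sized so the asymptotic PH matches the
            # genotype's observed stress/control height ratio
            ph_frac = (1.0 - ph_s / ph_c) / (1.0 - row["dmult"])
            out[(g.name, treatment)] = GrowthParams(
                eb_asymptote=row["eb"],
                eb_rate=0.18,
                eb_inflection=head_c - 2.0,
                ripening_start=head + 5.0,
                ripening_decline=0.03,
                # shallower logistic than EB: seedlings already have a few
                # cm of height while final PH settles shortly after heading
                ph_asymptote=ph_c,
                ph_rate=0.12,
                ph_inflection=head_c - 12.0,
                heading_das=head,
                hue_green=GREEN_HUE + row["hue_shift"],
                senescence_onset=row["sen"][idx],
                stress_onset_das=onset if stressed else None,
                drought_multiplier=row["dmult"] if stressed else 1.0,
                drought_lag=row["lag"] if stressed else 0,
                ph_drought_frac=ph_frac,
                maturity_mean=row["mat"][idx],
                maturity_sd=4.0 if not stressed else 6.0,
                yield_means={k: v[2 * idx] for k, v in yields.items()},
                yield_sds={k: v[2 * idx + 1] for k, v in yields.items()},
            )
    return out


# ---------------------------------------------------------------------------
# Sampling plants


def _positive_factor(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    return float(np.clip(rng.normal(1.0, cv), 0.05, None))


def sample_plants(
    design: ExperimentDesign,
    params: dict[tuple[str, str], GrowthParams],
    seed: int,
) -> list[PlantState]:
    """Draw ``n_rep`` plants per genotype x treatment.

    Per plant, multiplicative noise (CV ``replicate_cv``) is applied to the
    EB and PH asymptotes and the removal day is drawn from
    Normal(maturity_mean, maturity_sd), clipped to [1, last_das].
    """
    rng = np.random.default_rng(seed)
    plants: list[PlantState] = []
    for g in design.genotypes:
        for treatment in design.treatments:
            base = params[(g.name, treatment)]
            for rep in range(1, design.n_rep + 1):
                f_eb = _positive_factor(rng, base.replicate_cv)
                f_ph = _positive_factor(rng, base.replicate_cv / 2.0)
                if base.maturity_sd > 0:
                    removal = rng.normal(base.maturity_mean, base.maturity_sd)
                else:
                    removal = base.maturity_mean
                removal = int(np.clip(round(removal), 1, design.last_das))
                realized = replace(
                    base,
                    eb_asymptote=base.eb_asymptote * f_eb,
                    ph_asymptote=base.ph_asymptote * f_ph,
                    yield_means=dict(base.yield_means),
                    yield_sds=dict(base.yield_sds),
                )
                plants.append(
                    PlantState(
                        plant_id=f"{g.name}_{treatment}_r{rep:02d}",
                        genotype=g.name,
                        treatment=treatment,
                        params=realized,
                        removal_das=removal,
                    )
                )
    return plants


# ---------------------------------------------------------------------------
# Image rendering


@dataclass(frozen=True)
class RenderConfig:
    width: int = 150
    height: int = 200
    mm_per_pixel: float = 5.0
    pot_rows: int = 20  # bottom rows occupied by the pot in side views
    side_area_scale: float = 0.09  # side pixels per voxel^(2/3)
    top_area_scale: float = 0.07
    hue_noise: float = 0.008
    background_noise: float = 0.01

    @property
    def baseline_row(self) -> int:
        return self.height - self.pot_rows - 1


_VIEWS = ("top", "side000", "side045", "side090")


def _plant_rng(seed: int, plant_id: str, das: int, view: int) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(plant_id.encode()), das, view])


def _paint(shape: tuple[int, int], mask: np.ndarray, hue: float,
           cfg: RenderConfig, rng: np.random.Generator,
           pot_rows: int = 0) -> np.ndarray:
    """Compose an HSV image: light low-saturation background, an optional
    low-saturation pot band, and plant pixels with hue jitter around ``hue``."""
    h, w = shape
    hsv = np.empty((h, w, 3), dtype=float)
    hsv[..., 0] = 0.60
    hsv[..., 1] = 0.05
    hsv[..., 2] = 0.85
    if cfg.background_noise > 0:
        hsv[..., 2] += rng.normal(0.0, cfg.background_noise, size=(h, w))
    if pot_rows > 0:
        hsv[h - pot_rows:, :, 0] = 0.07
        hsv[h - pot_rows:, :, 1] = 0.12
        hsv[h - pot_rows:, :, 2] = 0.35
    n = int(mask.sum())
    if n:
        hsv[..., 0][mask] = np.clip(
            hue + rng.normal(0.0, cfg.hue_noise, size=n), 0.02, 0.97
        )
        hsv[..., 1][mask] = rng.uniform(0.55, 0.85, size=n)
        hsv[..., 2][mask] = rng.uniform(0.35, 0.75, size=n)
    hsv = np.clip(hsv, 0.0, 1.0)
    return (hsv2rgb(hsv) * 255).round().astype(np.uint8)


def _side_mask(cfg: RenderConfig, n_pixels: int, height_px: float,
               heading: bool, view: int) -> np.ndarray:
    """Exactly ``n_pixels`` plant pixels: the pixels nearest (in the image
    plane) to a fan of culm segments rooted at the pot rim.  Exact pixel
    counts make truth areas strictly monotone in the target area."""
    h, w = cfg.height, cfg.width
    mask = np.zeros((h, w), dtype=bool)
    if n_pixels < 1 or height_px < 1:
        return mask
    base_r, base_c = cfg.baseline_row, w / 2.0
    height_px = min(height_px, base_r - 2)
    n_tillers = min(8, 1 + n_pixels // 300)
    # culm tips: main culm vertical, side tillers splayed; view angle shifts
    # the splay so that the three side views differ but areas stay close
    segs = []
    for t in range(n_tillers):
        side = (-1) ** t
        rank = (t + 1) // 2
        tip_h = height_px * (1.0 - 0.08 * rank)
        splay = 0.22 * rank * side * (1.0 + 0.15 * math.sin(1.3 * view + t))
        tip_c = base_c + splay * tip_h
        segs.append((base_r, base_c, base_r - tip_h, tip_c))
        if heading and rank == 0:
            # spike: a second segment thickening the top of the main culm
            # (kept below the tip so drawn height stays the modelled height)
            segs.append((base_r - tip_h + 6.0, tip_c, base_r - tip_h, tip_c))
    rows, cols = np.mgrid[0:base_r + 1, 0:w]
    pts_r = rows.ravel().astype(float)
    pts_c = cols.ravel().astype(float)
    # keep the canopy below the culm tip: pixels above it are heavily
    # penalised so the drawn height stays the modelled height
    top_row = base_r - height_px
    dist = np.where(pts_r < top_row, (top_row - pts_r) * 1e3, 0.0)
    seg_dist = np.full(pts_r.shape, np.inf)
    for r0, c0, r1, c1 in segs:
        dr, dc = r1 - r0, c1 - c0
        denom = dr * dr + dc * dc
        if denom == 0:
            d = np.hypot(pts_r - r0, pts_c - c0)
        else:
            u = np.clip(((pts_r - r0) * dr + (pts_c - c0) * dc) / denom, 0.0, 1.0)
            d = np.hypot(pts_r - (r0 + u * dr), pts_c - (c0 + u * dc))
        np.minimum(seg_dist, d, out=seg_dist)
    dist += seg_dist
    n_pixels = min(n_pixels, dist.size)
    order = np.argsort(dist, kind="stable")[:n_pixels]
    mask[pts_r[order].astype(int), pts_c[order].astype(int)] = True
    return mask


def _top_mask(cfg: RenderConfig, n_pixels: int, view_rng: np.random.Generator) -> np.ndarray:
    """Exactly ``n_pixels`` pixels forming a lobed rosette around the centre."""
    h, w = cfg.height, cfg.width
    mask = np.zeros((h, w), dtype=bool)
    if n_pixels < 1:
        return mask
    rows, cols = np.mgrid[0:h, 0:w]
    dr = rows - h / 2.0
    dc = cols - w / 2.0
    theta = np.arctan2(dr, dc)
    phase = view_rng.uniform(0.0, 2.0 * math.pi)
    # seedlings are compact rosettes; lobes develop with size (and small
    # lobed blobs would shed disconnected tip pixels)
    amp = 0.25 * min(1.0, n_pixels / 300.0)
    metric = np.hypot(dr, dc) * (1.0 + amp * np.cos(6.0 * theta + phase))
    n_pixels = min(n_pixels, metric.size)
    order = np.argsort(metric.ravel(), kind="stable")[:n_pixels]
    mask[np.unravel_index(order, (h, w))] = True
    return mask


def render_views(
    state: PlantState,
    das: int,
    seed: int,
    cfg: RenderConfig | None = None,
) -> PlantImageSet:
    """Render one imaging event of ``state`` at ``das``.

    Truth-mask areas are exact functions of the modelled biovolume
    (``side_area_scale * EB^(2/3)`` pixels per side view and the analogous
    top-view count), so extracted areas can be validated against the model.
    """
    if das > state.removal_das:
        raise ValueError("plant was removed from the platform before this DAS")
    cfg = cfg or RenderConfig()
    p = state.params
    eb = true_biovolume(p, das)
    ph_px = true_height(p, das) / cfg.mm_per_pixel
    n_side = int(round(cfg.side_area_scale * eb ** (2.0 / 3.0)))
    n_top = int(round(cfg.top_area_scale * eb ** (2.0 / 3.0)))
    heading = das >= p.heading_das
    hue = true_cva(p, das)

    masks: dict[str, np.ndarray] = {}
    images: dict[str, np.ndarray] = {}
    for v, view in enumerate(_VIEWS):
        rng = _plant_rng(seed, state.plant_id, das, v)
        if view == "top":
            m = _top_mask(cfg, n_top, rng)
            img = _paint((cfg.height, cfg.width), m, hue, cfg, rng, pot_rows=0)
        else:
            m = _side_mask(cfg, n_side, ph_px, heading, v)
            img = _paint((cfg.height, cfg.width), m, hue, cfg, rng,
                         pot_rows=cfg.pot_rows)
        masks[view] = m
        images[view] = img
    return PlantImageSet(
        plant_id=state.plant_id,
        das=das,
        top=images["top"],
        sides=[images["side000"], images["side045"], images["side090"]],
        truth_masks=masks,
        mm_per_pixel=cfg.mm_per_pixel,
    )


# ---------------------------------------------------------------------------
# Whole experiments


def generate_experiment(
    design: ExperimentDesign,
    params: dict[tuple[str, str], GrowthParams] | None = None,
    seed: int = 0,
    with_images: bool = False,
    render_config: RenderConfig | None = None,
    day_stride: int = 1,
) -> tuple[pd.DataFrame, list[PlantImageSet], pd.DataFrame]:
    """Simulate a full experiment.

    Returns ``(traits, image_sets, maturity)``:

    * ``traits`` — long-format table (plant_id, genotype, treatment, das,
      trait, value) with one EB/PH/CVa record per plant and imaging day up to
      the plant's removal day; EB is on the reported scale (voxel / 1e6).
    * ``image_sets`` — rendered views (empty unless ``with_images``).
    * ``maturity`` — one row per plant with harvest traits drawn from the
      genotype's yield distributions plus the heading day and removal day.

    ``day_stride`` keeps every ``day_stride``-th imaging day (1 = all), which
    makes desk-scale rendered experiments cheap without changing the design.
    """
    params = params or default_growth_params(design)
    plants = sample_plants(design, params, seed)
    days = imaging_days(design)[::day_stride]
    rng = np.random.default_rng([seed, 1])

    rows = []
    image_sets: list[PlantImageSet] = []
    for plant in plants:
        p = plant.params
        for das in days:
            if das > plant.removal_das:
                break
            eb = true_biovolume(p, das) * _positive_factor(rng, p.eb_noise_cv)
            ph = true_height(p, das) * _positive_factor(rng, p.ph_noise_cv)
            cva = true_cva(p, das) + rng.normal(0.0, p.cva_noise_sd)
            for trait, value in ((TRAIT_EB, eb / 1e6), (TRAIT_PH, ph),
                                 (TRAIT_CVA, cva)):
                rows.append((plant.plant_id, plant.genotype, plant.treatment,
                             das, trait, value))
            if with_images:
                image_sets.append(render_views(plant, das, seed, render_config))
    traits = pd.DataFrame(
        rows, columns=["plant_id", "genotype", "treatment", "das", "trait", "value"]
    )

    mat_rows = []
    for plant in plants:
        p = plant.params
        size = p.eb_asymptote / params[(plant.genotype, plant.treatment)].eb_asymptote
        rec: dict = {
            "plant_id": plant.plant_id,
            "genotype": plant.genotype,
            "treatment": plant.treatment,
            "removal_das": plant.removal_das,
            "bbch55_das": float(np.clip(round(rng.normal(p.heading_das, 1.0)), 1,
                                        design.last_das)),
        }
        for trait_name, mean in p.yield_means.items():
            sd = p.yield_sds.get(trait_name, 0.0)
            value = rng.normal(mean, sd) if sd > 0 else mean
            if p.yield_coupling > 0:
                value *= size ** p.yield_coupling
            rec[trait_name] = max(value, 0.0)
        mat_rows.append(rec)
    maturity = pd.DataFrame(mat_rows)
    return traits, image_sets, maturity


def sample_one_way_table(
    v_g: float,
    v_e: float,
    n_genotypes: int,
    n_rep: int,
    rng: np.random.Generator,
    mean: float = 0.0,
) -> pd.DataFrame:
    """A single balanced one-way layout with known variance components.

    Genotype effects are drawn from Normal(0, v_g) and residuals from
    Normal(0, v_e); used for variance-component recovery checks.
    """
    g_eff = rng.normal(0.0, math.sqrt(v_g), size=n_genotypes)
    rows = []
    for i, g in enumerate(g_eff):
        values = mean + g + rng.normal(0.0, math.sqrt(v_e), size=n_rep)
        rows += [(f"g{i}", v) for v in values]
    return pd.DataFrame(rows, columns=["genotype", "value"])
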