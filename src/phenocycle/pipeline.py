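"""The four-stage analysis pipeline: simulate -> extract -> stats -> report.

Each stage is a plain function over DataFrames/paths so the CLI stays a thin
shell.  ``run_pipeline`` chains them, writes every artifact under one output
directory and records a manifest; identical config + seed give byte-identical
trait and stats files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import design as design_mod
from . import io as io_mod
from . import stats as stats_mod
from .image_traits import SegmentationConfig, extract_experiment
from .maturity import nil_parent_table, treatment_effect_summary
from .synthetic import RenderConfig, default_growth_params, generate_experiment

MATURITY_TRAITS = ["plant_biomass_g", "grain_weight_g", "straw_weight_g",
                   "tkw_g", "watersum_l", "bbch55_das"]


def simulate_stage(design, seed: int, out_dir: Path, with_images: bool,
                   day_stride: int = 1, render_config: RenderConfig | None = None):
    traits, image_sets, maturity = generate_experiment(
        design, default_growth_params(design), seed,
        with_images=with_images, render_config=render_config,
        day_stride=day_stride,
    )
    out_dir.mkdir(parents=True, exist_ok=True)
    io_mod.write_trait_table(traits, out_dir / "traits_truth.csv")
    maturity.to_csv(out_dir / "maturity.csv", index=False, float_format="%.10g")
    if with_images:
        io_mod.write_images(image_sets, out_dir / "images")
    return traits, image_sets, maturity


def extract_stage(image_sets, out_dir: Path,
                  config: SegmentationConfig | None = None) -> pd.DataFrame:
    extracted = extract_experiment(image_sets, config)
    out_dir.mkdir(parents=True, exist_ok=True)
    io_mod.write_trait_table(extracted, out_dir / "traits_extracted.csv")
    return extracted


def stats_stage(traits: pd.DataFrame, design, out_dir: Path,
                alpha: float = stats_mod.ALPHA, sustain_k: int = 3):
    out_dir.mkdir(parents=True, exist_ok=True)
    daily = stats_mod.compute_daily_stats(traits, n_rep=design.n_rep)
    daily.to_csv(out_dir / "daily_stats.csv", index=False, float_format="%.10g")

    trait_names = sorted(traits.trait.unique())
    pair_rows = []
    for parent, nil in design.pairs():
        for treatment in design.treatments:
            for trait in trait_names:
                pvals = stats_mod.pairwise_pvalues(
                    traits,
                    {"genotype": parent, "treatment": treatment},
                    {"genotype": nil, "treatment": treatment},
                    trait, alpha,
                )
                onset = stats_mod.divergence_onset(pvals, alpha, sustain_k)
                for das, p in pvals.items():
                    pair_rows.append((parent, nil, treatment, trait, das, p,
                                      p <= alpha, onset))
    pairwise = pd.DataFrame(pair_rows, columns=[
        "parent", "nil", "treatment", "trait", "das", "p", "significant",
        "pair_onset_das",
    ])
    pairwise.to_csv(out_dir / "pairwise_tests.csv", index=False,
                    float_format="%.10g")

    min_das = design_mod.stress_onset(design) if "stress" in design.watering else None
    div_rows = []
    for g in design.genotypes:
        for trait in trait_names:
            onset = stats_mod.treatment_divergence(
                traits, g.name, trait, alpha=alpha, sustain_k=sustain_k,
                min_das=min_das,
            )
            div_rows.append((g.name, trait, onset))
    divergence = pd.DataFrame(div_rows, columns=["genotype", "trait", "onset_das"])
    divergence.to_csv(out_dir / "divergence.csv", index=False)
    return daily, pairwise, divergence


def report_stage(daily: pd.DataFrame, divergence: pd.DataFrame,
                 maturity: pd.DataFrame, design, out_dir: Path,
                 alpha: float = stats_mod.ALPHA) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    for trait in [t for t in MATURITY_TRAITS if t in maturity.columns
                  and t != "bbch55_das"]:
        summary[f"effect_pct_{trait}"] = treatment_effect_summary(maturity, trait)
    if "bbch55_das" in maturity.columns:
        means = maturity.groupby(["treatment", "genotype"])["bbch55_das"].mean()
        summary["bbch55_shift_days"] = float(
            means.loc["control"].mean() - means.loc["stress"].mean()
        )
    growth = daily[(daily.trait != "CVa") & daily.repeatability.notna()]
    if len(growth):
        summary["mean_repeatability_growth_traits"] = float(
            growth.repeatability.mean()
        )
    mat_table = nil_parent_table(
        maturity, design.pairs(),
        [t for t in MATURITY_TRAITS if t in maturity.columns], alpha,
    )
    mat_table.to_csv(out_dir / "maturity_comparisons.csv", index=False,
                     float_format="%.10g")
    pd.Series(summary, name="value").rename_axis("quantity").to_csv(
        out_dir / "summary.csv", float_format="%.10g"
    )
    return summary


def run_pipeline(config_path, seed: int, out_dir, with_images: bool = False,
                 alpha: float = stats_mod.ALPHA, sustain_k: int = 3,
                 day_stride: int = 1) -> dict:
    """Run simulate -> (extract) -> stats -> report and write a manifest.

    ``config_path`` is a YAML design file (None for the default design).
    In traits-only mode (no images) the ground-truth trait table feeds the
    stats stage directly.
    """
    out_dir = Path(out_dir)
    design = (design_mod.design_from_yaml(config_path) if config_path
              else design_mod.build_default_design())
    status = "ok"
    try:
        traits, image_sets, maturity = simulate_stage(
            design, seed, out_dir, with_images, day_stride
        )
        if with_images:
            analysed = extract_stage(image_sets, out_dir)
        else:
            analysed = traits
        daily, pairwise, divergence = stats_stage(
            analysed, design, out_dir, alpha, sustain_k
        )
        summary = report_stage(daily, divergence, maturity, design, out_dir, alpha)
    except Exception:
        io_mod.write_manifest(out_dir / "manifest.json", seed=seed,
                              config_path=config_path, status="failed")
        raise
    outputs = sorted(str(p.relative_to(out_dir))
                     for p in out_dir.rglob("*.csv"))
    io_mod.write_manifest(out_dir / "manifest.json", seed=seed,
                          config_path=config_path, outputs=outputs,
                          status=status)
    return summary
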