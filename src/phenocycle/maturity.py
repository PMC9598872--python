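"""Harvest-time derived traits, treatment-effect summaries and NIL-vs-parent
comparison tables.

Beyond the simple derived traits (water use efficiency, harvest index, flag
leaf area, tiller gain), this module builds the comparison tables a pot
phenotyping study reports: per-treatment parent-vs-NIL rows with means,
standard deviations and Student's t p-values, treatment-effect percentages
across genotypes, and cross-environment NIL/parent percentage ratios.

The package also ships transcriptions of a published wheat parent/NIL
comparison (traits before maturity and at maturity, mean +/- sd of n = 10
plants per cell with two-decimal p-values); these serve as reference inputs
for the summary-statistics t-test and the treatment-effect summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .stats import ALPHA, summary_ttest, two_sample_ttest

PRINTED_N = 10  # replicates behind every transcribed table cell


def wue(biomass_g: float, watersum_l: float) -> float:
    """Water use efficiency: final above-ground biomass per litre watered."""
    if watersum_l <= 0:
        raise ValueError("watersum must be positive")
    return biomass_g / watersum_l


def harvest_index(grain_g: float, biomass_g: float) -> float | None:
    """Grain weight as a fraction of above-ground biomass; None when the
    biomass is zero."""
    if biomass_g == 0:
        return None
    return grain_g / biomass_g


def flag_leaf_area(length_cm: float, width_mm: float) -> float:
    """Flag leaf area in cm^2 as length x width x 0.75, width in mm
    converted to cm first."""
    if length_cm < 0 or width_mm < 0:
        raise ValueError("leaf dimensions must be non-negative")
    return length_cm * (width_mm / 10.0) * 0.75


def tiller_gain(tn_early: float, tn_late: float) -> float:
    """Change in tiller number between two counting days."""
    return tn_late - tn_early


def env_ratio(nil_mean: float, parent_mean: float) -> float:
    """NIL/parent x 100 — percentage used for cross-environment comparison."""
    if parent_mean == 0:
        raise ValueError("parent mean must be non-zero")
    return 100.0 * nil_mean / parent_mean


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (reporting rule
    for percent summaries)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def treatment_effect_summary(
    records: pd.DataFrame,
    trait: str,
    control: str = "control",
    stress: str = "stress",
    value_col: str | None = None,
) -> float:
    """Percent change of a trait under stress relative to control.

    Genotypes are weighted equally: the summary is
    ``100 * (mean of stress genotype means - mean of control genotype means)
    / mean of control genotype means``.  ``records`` may hold per-plant rows
    or already-aggregated genotype means (one row per genotype x treatment);
    both give the same answer for balanced data.
    """
    col = value_col or trait
    sub = records.dropna(subset=[col])
    means = sub.groupby(["treatment", "genotype"], sort=True)[col].mean()
    m_control = means.loc[control].mean()
    m_stress = means.loc[stress].mean()
    if m_control == 0:
        return float("nan")
    return 100.0 * (m_stress - m_control) / m_control


@dataclass
class ComparisonRow:
    trait: str
    treatment: str
    parent: str
    parent_mean: float
    parent_sd: float
    nil: str
    nil_mean: float
    nil_sd: float
    p: float | None
    significant: bool


def nil_parent_table(
    records: pd.DataFrame,
    pairings: list[tuple[str, str]],
    traits: list[str],
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Parent-vs-NIL comparison rows (one per trait x treatment x pair).

    ``records`` holds one row per plant with trait columns; cells with fewer
    than two values per group get a missing p-value.
    """
    rows: list[ComparisonRow] = []
    for treatment, part in records.groupby("treatment", sort=True):
        for parent, nil in pairings:
            for trait in traits:
                a = part.loc[part.genotype == parent, trait].dropna().to_numpy(float)
                b = part.loc[part.genotype == nil, trait].dropna().to_numpy(float)
                stats_ok = a.size >= 2 and b.size >= 2
                if stats_ok:
                    _, _, p, sig = two_sample_ttest(a, b, alpha)
                else:
                    p, sig = None, False
                rows.append(ComparisonRow(
                    trait=trait, treatment=str(treatment),
                    parent=parent,
                    parent_mean=float(a.mean()) if a.size else np.nan,
                    parent_sd=float(a.std(ddof=1)) if a.size > 1 else np.nan,
                    nil=nil,
                    nil_mean=float(b.mean()) if b.size else np.nan,
                    nil_sd=float(b.std(ddof=1)) if b.size > 1 else np.nan,
                    p=p, significant=sig,
                ))
    return pd.DataFrame([r.__dict__ for r in rows])


def render_comparison_table(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering, two-decimal p-values, bold (``**``)
    marking significance — the display convention of the printed tables."""
    lines = []
    for treatment, part in table.groupby("treatment", sort=True):
        lines.append(f"== {treatment} ==")
        for row in part.itertuples():
            if row.p is None or not np.isfinite(row.p):
                p_txt = "  NA"
            else:
                p_txt = f"{row.p:.2f}"
                if row.significant:
                    p_txt = f"**{p_txt}**"
            lines.append(
                f"{row.trait:<32s} {row.parent_mean:8.2f} ± {row.parent_sd:5.2f}"
                f"  {row.nil_mean:8.2f} ± {row.nil_sd:5.2f}  {p_txt}"
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Printed-table transcriptions


def repair_decimal_artifacts(values: pd.Series) -> pd.Series:
    """Fix misprinted decimal separators in a numeric column.

    Printed tables occasionally drop the decimal point (``1,251`` standing
    for 12.51).  A value more than 50x the column median is divided by 100,
    repeatedly if needed — magnitudes that large are physically impossible
    for the traits concerned.
    """
    vals = values.astype(float).copy()
    finite = vals[np.isfinite(vals)]
    med = float(np.median(np.abs(finite))) if len(finite) else np.nan
    if not np.isfinite(med) or med == 0:
        return vals
    for idx, v in vals.items():
        while np.isfinite(v) and abs(v) > 50.0 * med:
            v /= 100.0
        vals.at[idx] = v
    return vals


def _load_printed(name: str, repair: bool = True) -> pd.DataFrame:
    path = resources.files("phenocycle.data") / name
    with path.open("rb") as fh:
        df = pd.read_csv(fh, thousands=",")
    df["repaired"] = False
    if repair:
        for col in ("parent_mean", "parent_sd", "nil_mean", "nil_sd"):
            fixed = df.groupby("trait", group_keys=False)[col].apply(
                repair_decimal_artifacts
            )
            df["repaired"] |= ~np.isclose(fixed, df[col].astype(float))
            df[col] = fixed
    df["n"] = PRINTED_N
    return df


def load_printed_pre_maturity(repair: bool = True) -> pd.DataFrame:
    """Transcribed parent/NIL summaries of traits measured before maturity
    (tiller counts, heading day, flag leaf, osmotic potential, quantum
    yields)."""
    return _load_printed("printed_pre_maturity.csv", repair)


def load_printed_maturity(repair: bool = True) -> pd.DataFrame:
    """Transcribed parent/NIL summaries of harvest traits (heights, yield
    components, water sums, WUE)."""
    return _load_printed("printed_maturity.csv", repair)


def printed_genotype_means(printed: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Tidy (treatment, genotype, value) genotype means of one printed
    trait, suitable for :func:`treatment_effect_summary`."""
    sub = printed[printed.trait == trait]
    rows = []
    for r in sub.itertuples():
        rows.append((r.treatment, r.parent, r.parent_mean))
        rows.append((r.treatment, r.nil, r.nil_mean))
    return pd.DataFrame(rows, columns=["treatment", "genotype", trait])


#: Print quantum of the transcribed tables (two decimals).
PRINT_QUANTUM = 0.01


def printed_significance_agreement(
    printed: pd.DataFrame,
    alpha: float = ALPHA,
    skip_ambiguous: bool = True,
) -> pd.DataFrame:
    """Re-test every printed cell pair with the summary-statistics t-test
    and compare against the printed bold/non-bold significance marking.

    Cells that the printed precision cannot decide are skipped by default:
    a p-value printed exactly as 0.05 may sit on either side of alpha; a
    repaired (misprinted) cell has unreliable inputs; and when the standard
    error of the mean difference implied by the printed sds is below four
    print quanta, two-decimal rounding of the means dominates the
    t-statistic and the printed p cannot be recomputed from the summaries.
    Returns the tested rows with computed p and an ``agrees`` flag.
    """
    rows = []
    for r in printed.itertuples():
        if skip_ambiguous:
            se_diff = np.sqrt((r.parent_sd**2 + r.nil_sd**2) / r.n)
            if (abs(r.printed_p - alpha) < 1e-9 or r.repaired
                    or se_diff < 4 * PRINT_QUANTUM):
                continue
        _, _, p, sig = summary_ttest(
            r.parent_mean, r.parent_sd, r.n, r.nil_mean, r.nil_sd, r.n, alpha
        )
        rows.append((r.treatment, r.trait, r.parent, r.printed_p,
                     bool(r.printed_sig), p, sig, sig == bool(r.printed_sig)))
    return pd.DataFrame(rows, columns=[
        "treatment", "trait", "parent", "printed_p", "printed_sig",
        "p", "significant", "agrees",
    ])
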