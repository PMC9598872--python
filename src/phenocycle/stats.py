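"""Day-wise statistics for longitudinal phenotyping trait tables.

Each imaging day and treatment is analysed independently (the design has no
repeated-measures structure worth modelling across days at this replication
level): Tukey outlier fences per genotype group, genotype BLUEs from the
fixed-effect one-way model Y = mu + G + e (cell means, so the BLUE of a
genotype is its group mean), variance components from the random-effect
model Y = G + e fitted by REML, and repeatability

    R = vG / (vG + ve / nRep).

On top of the per-day fits sit the longitudinal summaries: pairwise t-tests
(NIL vs parent, control vs stress), confidence bands with the non-overlap
rule, divergence-onset and response-lag estimation, the maturity-day quorum
rule, senescence onset and a stay-green score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


# ---------------------------------------------------------------------------
# Outlier filtering


def tukey_filter(values) -> np.ndarray:
    """Keep-flags under the Tukey rule: a value is kept iff it lies within
    [Q1 - 1.5 IQR, Q3 + 1.5 IQR], quartiles by linear interpolation.
    Lists with fewer than 4 values are kept whole."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        return np.ones(arr.size, dtype=bool)
    q1, q3 = np.percentile(arr, [25, 75], method="linear")
    iqr = q3 - q1
    return (arr >= q1 - 1.5 * iqr) & (arr <= q3 + 1.5 * iqr)


# ---------------------------------------------------------------------------
# BLUEs and variance components


@dataclass
class DayGroupData:
    """Replicate values per genotype for one day x treatment x trait cell."""

    das: int
    treatment: str
    trait: str
    groups: dict[str, np.ndarray]

    @classmethod
    def from_table(cls, table: pd.DataFrame, das: int, treatment: str,
                   trait: str, apply_tukey: bool = True) -> "DayGroupData":
        sub = table[(table.das == das) & (table.treatment == treatment)
                    & (table.trait == trait)].dropna(subset=["value"])
        groups = {}
        for genotype, part in sub.groupby("genotype", sort=True):
            vals = part["value"].to_numpy(dtype=float)
            if apply_tukey:
                vals = vals[tukey_filter(vals)]
            groups[str(genotype)] = vals
        return cls(das=das, treatment=treatment, trait=trait, groups=groups)


def daily_blues(data: DayGroupData) -> pd.DataFrame:
    """Per-genotype BLUE and standard error for one day cell.

    With genotype fixed, the one-way model is a cell-means model, so each
    BLUE is the genotype's arithmetic mean.  The SE uses the pooled residual
    standard deviation: SE_i = s_pooled / sqrt(n_i).
    """
    names, means, ns = [], [], []
    sse = 0.0
    for genotype, vals in data.groups.items():
        if vals.size == 0:
            names.append(genotype)
            means.append(np.nan)
            ns.append(0)
            continue
        names.append(genotype)
        means.append(float(vals.mean()))
        ns.append(int(vals.size))
        sse += float(((vals - vals.mean()) ** 2).sum())
    n_total = sum(ns)
    n_groups = sum(1 for n in ns if n > 0)
    df_resid = n_total - n_groups
    s_pooled = math.sqrt(sse / df_resid) if df_resid > 0 else np.nan
    se = [s_pooled / math.sqrt(n) if n > 0 else np.nan for n in ns]
    return pd.DataFrame({"genotype": names, "blue": means, "se": se, "n": ns,
                         "df_resid": df_resid})


def _reml_criterion(lam: float, n_i: np.ndarray, means: np.ndarray,
                    ssw: float) -> float:
    """-2 x (profiled restricted log-likelihood + const) of the one-way
    random model at variance ratio lam = vG/ve."""
    u = n_i / (1.0 + n_i * lam)
    su = u.sum()
    q = ssw + float(np.dot(u, means**2)) - float(np.dot(u, means)) ** 2 / su
    n = int(n_i.sum())
    return ((n - 1) * math.log(q) + float(np.log1p(n_i * lam).sum())
            + math.log(su))


def _reml_score(lam: float, n_i: np.ndarray, means: np.ndarray,
                ssw: float) -> float:
    """d/d(lam) of :func:`_reml_criterion` — zero at the REML optimum."""
    u = n_i / (1.0 + n_i * lam)
    u2 = u * u
    s = u.sum()
    a = float(np.dot(u, means))
    b = float(np.dot(u, means**2))
    q = ssw + b - a * a / s
    ds = -float(u2.sum())
    da = -float(np.dot(u2, means))
    db = -float(np.dot(u2, means**2))
    dq = db - (2.0 * a * da * s - a * a * ds) / (s * s)
    n = int(n_i.sum())
    return (n - 1) * dq / q + float((n_i / (1.0 + n_i * lam)).sum()) + ds / s


_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def _golden_section(f, a: float, b: float, iters: int = 140) -> float:
    """Golden-section minimum of a unimodal ``f`` on [a, b]."""
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(iters):
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
        if b - a <= 1e-14 * max(1.0, abs(a)):
            break
    return 0.5 * (a + b)


def variance_components(data: DayGroupData) -> tuple[float, float]:
    """REML estimates (vG, ve) of the one-way random-effects model.

    The restricted likelihood is profiled down to the variance ratio
    lam = vG/ve, located by golden-section search, polished by a root find
    on the analytic score (the golden bracket alone stalls at the float
    noise floor of the flat criterion), and truncated at zero; ve then
    follows in closed form.  Requires at least two genotypes with two
    retained values each.
    """
    groups = {g: v for g, v in data.groups.items() if v.size > 0}
    if len(groups) < 2:
        raise ValueError("variance components need at least two genotypes")
    if any(v.size < 2 for v in groups.values()):
        raise ValueError("each genotype needs at least two retained values")
    n_i = np.array([v.size for v in groups.values()], dtype=float)
    means = np.array([v.mean() for v in groups.values()])
    ssw = float(sum(((v - v.mean()) ** 2).sum() for v in groups.values()))
    n = int(n_i.sum())

    if ssw == 0.0 and np.ptp(means) == 0.0:
        return 0.0, 0.0

    if _reml_score(0.0, n_i, means, ssw) >= 0.0:
        lam = 0.0  # boundary solution: no genotypic variance
    else:
        lam = _golden_section(
            lambda x: _reml_criterion(x, n_i, means, ssw), 0.0, 1e7
        )
        lo, hi = lam / 2.0, lam * 2.0
        while _reml_score(lo, n_i, means, ssw) > 0.0 and lo > 1e-300:
            lo /= 2.0
        while _reml_score(hi, n_i, means, ssw) < 0.0 and hi < 1e12:
            hi *= 2.0
        try:
            from scipy.optimize import brentq

            lam = float(brentq(_reml_score, lo, hi, args=(n_i, means, ssw),
                               xtol=1e-300, rtol=8.9e-16))
        except ValueError:
            pass  # no sign change at float precision: keep the golden result
    u = n_i / (1.0 + n_i * lam)
    q = ssw + float(np.dot(u, means**2)) - float(np.dot(u, means)) ** 2 / u.sum()
    ve = q / (n - 1)
    return max(lam * ve, 0.0), max(ve, 0.0)


def balanced_anova_components(data: DayGroupData) -> tuple[float, float]:
    """Closed-form ANOVA/REML solution for a *balanced* layout:
    ve = MSE, vG = max(0, (MSB - MSE)/n).  Used as an independent oracle."""
    sizes = {v.size for v in data.groups.values()}
    if len(sizes) != 1:
        raise ValueError("closed form requires a balanced layout")
    n = sizes.pop()
    if n < 2:
        raise ValueError("need at least two replicates per genotype")
    arr = np.stack([v for v in data.groups.values()])
    g = arr.shape[0]
    mse = float(((arr - arr.mean(axis=1, keepdims=True)) ** 2).sum()) / (g * (n - 1))
    msb = n * float(((arr.mean(axis=1) - arr.mean()) ** 2).sum()) / (g - 1)
    return max(0.0, (msb - mse) / n), mse


def repeatability(v_g: float, v_e: float, n_rep: int) -> float:
    """R = vG / (vG + ve/nRep); the fraction of variance among replicate
    means attributable to genotype.  NaN when both components vanish."""
    if v_g < 0 or v_e < 0 or n_rep < 1:
        raise ValueError("variances must be non-negative and n_rep >= 1")
    denom = v_g + v_e / n_rep
    if denom == 0:
        return float("nan")
    return v_g / denom


# ---------------------------------------------------------------------------
# Pairwise tests and confidence bands


def two_sample_ttest(a, b, alpha: float = ALPHA, welch: bool = False):
    """Student's two-sample t-test (pooled variance by default; Welch behind
    the flag).  Returns (t, df, p, significant).  Two identical
    zero-variance groups give t=0, p=1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        df = a.size + b.size - 2
        return 0.0, df, 1.0, False
    res = sps.ttest_ind(a, b, equal_var=not welch)
    t, p = float(res.statistic), float(res.pvalue)
    df = float(res.df)
    return t, df, p, bool(p <= alpha)


def summary_ttest(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                  alpha: float = ALPHA, welch: bool = False):
    """Same contract as :func:`two_sample_ttest`, computed from sufficient
    statistics (mean, sd, n) per group — lets printed summary tables be
    re-tested without the raw data."""
    if sd_a < 0 or sd_b < 0 or n_a < 2 or n_b < 2:
        raise ValueError("sds must be non-negative and ns >= 2")
    if sd_a == 0 and sd_b == 0 and mean_a == mean_b:
        return 0.0, n_a + n_b - 2, 1.0, False
    res = sps.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                   equal_var=not welch)
    t, p = float(res.statistic), float(res.pvalue)
    if welch:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    else:
        df = n_a + n_b - 2
    return t, df, p, bool(p <= alpha)


def confidence_band(blue: float, se: float, df: int,
                    alpha: float = ALPHA) -> tuple[float, float]:
    """blue +/- t(1-alpha/2, df) * se."""
    if se < 0:
        raise ValueError("se must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    half = sps.t.ppf(1.0 - alpha / 2.0, df) * se
    return blue - half, blue + half


def ci_overlap_significant(band_a: tuple[float, float],
                           band_b: tuple[float, float]) -> bool:
    """Non-overlap rule: disjoint confidence bands are read as a significant
    difference (the converse is *not* implied)."""
    (lo_a, hi_a), (lo_b, hi_b) = band_a, band_b
    return hi_a < lo_b or hi_b < lo_a


# ---------------------------------------------------------------------------
# Longitudinal summaries


def divergence_onset(p_series: dict[int, float], alpha: float = ALPHA,
                     sustain_k: int = 3) -> int | None:
    """Earliest imaging day from which significance is sustained.

    The onset is the first day d with p <= alpha on d and on the next
    sustain_k - 1 imaging days; None when no such run exists.  Days are the
    keys of ``p_series`` in increasing order (NaN counts as not significant).
    """
    days = sorted(p_series)
    sig = [(p_series[d] <= alpha) if np.isfinite(p_series[d]) else False
           for d in days]
    for i in range(len(days) - sustain_k + 1):
        if all(sig[i:i + sustain_k]):
            return days[i]
    return None


def response_lag(onset_a: int | None, onset_b: int | None) -> int | None:
    """Signed difference onset_b - onset_a in days; None if either onset is
    undefined."""
    if onset_a is None or onset_b is None:
        return None
    return onset_b - onset_a


def maturity_day(presence_last_das, quorum: float = 0.7) -> int:
    """Final-maturity day: the largest DAS on which at least
    ceil(quorum * n) replicates were still on the platform."""
    last = np.asarray(list(presence_last_das), dtype=int)
    if last.size == 0:
        raise ValueError("need at least one replicate")
    need = math.ceil(quorum * last.size)
    candidates = np.sort(last)[::-1]
    for das in candidates:
        if int((last >= das).sum()) >= need:
            return int(das)
    return int(candidates[-1])


def senescence_onset(cva_series: dict[int, float], baseline_window: int = 10,
                     delta: float = 0.02) -> int | None:
    """First day at which a centred 3-point median of CVa drops below the
    early-season baseline by ``delta`` and never recovers; None if absent.

    The baseline is the mean CVa over the first ``baseline_window`` imaging
    days of the series.
    """
    days = sorted(cva_series)
    if len(days) < baseline_window:
        raise ValueError("series shorter than the baseline window")
    vals = np.array([cva_series[d] for d in days], dtype=float)
    baseline = vals[:baseline_window].mean()
    padded = np.concatenate([vals[:1], vals, vals[-1:]])
    smooth = np.array([np.median(padded[i:i + 3]) for i in range(len(vals))])
    below = smooth < baseline - delta
    for i in range(len(days)):
        if below[i] and below[i:].all():
            return days[i]
    return None


def stay_green_score(cva_a: dict[int, np.ndarray], cva_b: dict[int, np.ndarray],
                     window: tuple[int, int], alpha: float = ALPHA):
    """Mean CVa advantage of genotype b over genotype a across a late-season
    window, plus the days with a significant per-day replicate t-test.

    ``cva_a``/``cva_b`` map DAS -> replicate CVa values.  Returns
    (mean difference of daily group means, list of significant days)."""
    lo, hi = window
    days = [d for d in sorted(set(cva_a) & set(cva_b)) if lo <= d <= hi]
    if not days:
        raise ValueError("empty comparison window")
    diffs, sig_days = [], []
    for d in days:
        a, b = np.asarray(cva_a[d], float), np.asarray(cva_b[d], float)
        diffs.append(b.mean() - a.mean())
        if a.size >= 2 and b.size >= 2:
            _, _, p, significant = two_sample_ttest(a, b, alpha)
            if significant:
                sig_days.append(d)
    return float(np.mean(diffs)), sig_days


# ---------------------------------------------------------------------------
# Whole-table drivers


def compute_daily_stats(table: pd.DataFrame, n_rep: int | None = None,
                        apply_tukey: bool = True) -> pd.DataFrame:
    """Per day x treatment x trait x genotype: BLUE, SE, vG, ve and R.

    ``n_rep`` defaults to the modal group size of each cell.  Cells where the
    variance model is not estimable (fewer than two genotypes with two
    retained replicates) carry NaN components.
    """
    out = []
    cells = table.dropna(subset=["value"]).groupby(
        ["das", "treatment", "trait"], sort=True
    )
    for (das, treatment, trait), _ in cells:
        data = DayGroupData.from_table(table, das, treatment, trait, apply_tukey)
        blues = daily_blues(data)
        try:
            v_g, v_e = variance_components(data)
            n = n_rep or int(blues.loc[blues.n > 0, "n"].mode().iat[0])
            r = repeatability(v_g, v_e, n)
        except ValueError:
            v_g = v_e = r = np.nan
        for row in blues.itertuples():
            out.append((das, treatment, trait, row.genotype, row.blue, row.se,
                        row.n, v_g, v_e, r))
    return pd.DataFrame(out, columns=["das", "treatment", "trait", "genotype",
                                      "blue", "se", "n", "v_g", "v_e",
                                      "repeatability"])


def pairwise_pvalues(table: pd.DataFrame, group_a: dict, group_b: dict,
                     trait: str, alpha: float = ALPHA,
                     apply_tukey: bool = True) -> dict[int, float]:
    """Per-day p-values comparing two plant groups on one trait.

    ``group_a``/``group_b`` are column->value filters (e.g. genotype and/or
    treatment); outlier filtering is applied within each group and day.
    Days where either group has fewer than two values are skipped.
    """
    sub = table[table.trait == trait].dropna(subset=["value"])

    def select(filters):
        m = pd.Series(True, index=sub.index)
        for col, val in filters.items():
            m &= sub[col] == val
        return sub[m]

    sa, sb = select(group_a), select(group_b)
    pvals: dict[int, float] = {}
    for das in sorted(set(sa.das) & set(sb.das)):
        a = sa.loc[sa.das == das, "value"].to_numpy(float)
        b = sb.loc[sb.das == das, "value"].to_numpy(float)
        if apply_tukey:
            a, b = a[tukey_filter(a)], b[tukey_filter(b)]
        if a.size < 2 or b.size < 2:
            continue
        _, _, p, _ = two_sample_ttest(a, b, alpha)
        pvals[int(das)] = p
    return pvals


def treatment_divergence(table: pd.DataFrame, genotype: str, trait: str,
                         control: str = "control", stress: str = "stress",
                         alpha: float = ALPHA, sustain_k: int = 3,
                         min_das: int | None = None) -> int | None:
    """Onset day of sustained control-vs-stress divergence for one genotype.

    ``min_das`` restricts the scan, typically to the first day of reduced
    watering — before it the two treatments are the same condition and a
    "divergence" would be spurious.
    """
    pvals = pairwise_pvalues(
        table,
        {"genotype": genotype, "treatment": control},
        {"genotype": genotype, "treatment": stress},
        trait, alpha,
    )
    if min_das is not None:
        pvals = {d: p for d, p in pvals.items() if d >= min_das}
    return divergence_onset(pvals, alpha, sustain_k)
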