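"""Two-group aging statistics and the mosaic effect-size analysis.

A cohort is a tidy table with one value per (subject, group, region,
marker), where markers are regional aging measures: MDM derivatives
(dR1/dMTV, dMTsat/dMTV, ...), MTV, R2*, region volume, or raw qMRI medians.
Group differences (young vs old) use the independent-sample t-test
(equal-variance by default, Welch by flag), two-sided, with
Benjamini-Hochberg FDR correction over the explicitly passed family of
(region, marker) tests.  Effect sizes are Cohen's d with pooled SD; per
region the *dominant* marker is the one with the largest |d|, and regions
whose largest effect is below the small-effect floor (d = 0.2) are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError, DegenerateVarianceError

__all__ = [
    "GroupComparison",
    "EffectProfile",
    "SMALL_EFFECT_FLOOR",
    "cohens_d",
    "ttest_groups",
    "compare_groups",
    "run_group_comparisons",
    "fdr_adjust",
    "effect_profile",
    "correlate_effect_profiles",
    "significance_stars",
    "validate_cohort",
]

SMALL_EFFECT_FLOOR = 0.2

COHORT_COLUMNS = ("subject", "group", "region", "marker", "value")


def validate_cohort(cohort: pd.DataFrame, groups=("young", "old")) -> pd.DataFrame:
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise DataError(f"cohort table missing columns: {sorted(missing)}")
    present = set(cohort["group"].unique())
    if not set(groups) <= present:
        raise DataError(f"cohort lacks groups {set(groups) - present}")
    dup = cohort.duplicated(subset=["subject", "region", "marker"])
    if dup.any():
        raise DataError("duplicate (subject, region, marker) rows in cohort")
    return cohort


def cohens_d(group_a, group_b) -> tuple[float, float]:
    """Cohen's d = (mean_a - mean_b) / pooled SD, plus its sampling SD.

    Pooled SD weights each group's variance by (n - 1).  The sd of d uses
    the standard large-sample formula
    sqrt((n_a + n_b)/(n_a * n_b) + d^2 / (2 (n_a + n_b))).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise DataError("each group needs n >= 2")
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise DegenerateVarianceError("pooled SD is zero; d undefined")
    d = float((a.mean() - b.mean()) / np.sqrt(pooled_var))
    sd_d = float(np.sqrt((na + nb) / (na * nb) + d**2 / (2 * (na + nb))))
    return d, sd_d


def ttest_groups(a, b, equal_var: bool = True, axis: int = -1):
    """Independent two-sample t-test (two-sided); thin scipy wrapper.

    Vectorized over ``axis`` so simulation studies can test thousands of
    replicate cohorts in one call.
    """
    res = stats.ttest_ind(a, b, axis=axis, equal_var=equal_var)
    return res.statistic, res.pvalue


@dataclass
class GroupComparison:
    """One (region, marker) young-vs-old comparison.

    ``q`` is NaN until the comparison is adjusted within a declared family
    (see :func:`run_group_comparisons`) — FDR needs the whole family.
    """

    region: str
    marker: str
    t: float
    p: float
    d: float
    sd_d: float
    n_young: int
    n_old: int
    q: float = float("nan")


def _group_values(cohort, region, marker, group):
    sel = (
        (cohort["region"] == region)
        & (cohort["marker"] == marker)
        & (cohort["group"] == group)
    )
    return cohort.loc[sel, "value"].to_numpy(dtype=float)


def compare_groups(
    cohort: pd.DataFrame, region: str, marker: str, equal_var: bool = True
) -> GroupComparison:
    """t-test and Cohen's d for one (region, marker) cell, young vs old."""
    validate_cohort(cohort)
    young = _group_values(cohort, region, marker, "young")
    old = _group_values(cohort, region, marker, "old")
    if len(young) < 2 or len(old) < 2:
        raise DataError(
            f"({region!r}, {marker!r}): both groups need n >= 2, "
            f"got {len(young)}/{len(old)}"
        )
    t, p = ttest_groups(young, old, equal_var=equal_var)
    try:
        d, sd_d = cohens_d(young, old)
    except DegenerateVarianceError:
        d, sd_d = float("nan"), float("nan")
    return GroupComparison(
        region=region, marker=marker, t=float(t), p=float(p),
        d=d, sd_d=sd_d, n_young=len(young), n_old=len(old),
    )


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    The family is exactly the vector passed in — family membership is an
    explicit caller decision, never global state.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a nonempty 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_group_comparisons(
    cohort: pd.DataFrame,
    regions=None,
    markers=None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """All (region, marker) comparisons with FDR over that joint family.

    The FDR family is every cell tested in this call, mirroring per-figure
    correction; pass subsets to declare a narrower family.
    """
    validate_cohort(cohort)
    regions = sorted(cohort["region"].unique()) if regions is None else list(regions)
    markers = sorted(cohort["marker"].unique()) if markers is None else list(markers)
    rows = []
    for region in regions:
        for marker in markers:
            c = compare_groups(cohort, region, marker, equal_var=equal_var)
            rows.append(vars(c))
    out = pd.DataFrame(rows)
    out["q"] = fdr_adjust(out["p"].to_numpy())
    out["stars"] = [significance_stars(q) for q in out["q"]]
    return out


def significance_stars(q: float) -> str:
    """Conventional significance stars, applied to FDR-adjusted values."""
    if q < 0.001:
        return "***"
    if q < 0.01:
        return "**"
    if q < 0.05:
        return "*"
    return ""


@dataclass
class EffectProfile:
    """Per-region, per-marker Cohen's d with dominant-marker assignment."""

    d: pd.DataFrame  # index regions, columns markers
    sd_d: pd.DataFrame
    dominant: pd.Series  # region -> marker with largest |d|
    below_floor: pd.Series  # region -> bool, max |d| < floor
    floor: float = SMALL_EFFECT_FLOOR


def effect_profile(
    cohort: pd.DataFrame, markers=None, floor: float = SMALL_EFFECT_FLOOR
) -> EffectProfile:
    """Cohen's d per (region, marker); dominant marker by |d| per region."""
    validate_cohort(cohort)
    regions = sorted(cohort["region"].unique())
    if len(regions) < 2:
        raise DataError("need >= 2 regions for an effect profile")
    markers = sorted(cohort["marker"].unique()) if markers is None else list(markers)
    d = pd.DataFrame(index=regions, columns=markers, dtype=float)
    sd = pd.DataFrame(index=regions, columns=markers, dtype=float)
    for region in regions:
        for marker in markers:
            young = _group_values(cohort, region, marker, "young")
            old = _group_values(cohort, region, marker, "old")
            try:
                # old - young: positive d = increase with age
                d.loc[region, marker], sd.loc[region, marker] = cohens_d(old, young)
            except DegenerateVarianceError:
                d.loc[region, marker] = np.nan
                sd.loc[region, marker] = np.nan
    dominant = d.abs().idxmax(axis=1)
    below = d.abs().max(axis=1) < floor
    return EffectProfile(d=d, sd_d=sd, dominant=dominant, below_floor=below, floor=floor)


def correlate_effect_profiles(profile_a, profile_b) -> tuple[float, float, float]:
    """Spatial correlation of two markers' effect sizes across regions.

    Simple regression of profile_b on profile_a over aligned regions;
    returns ``(slope, adjusted R^2, F-test p)``.
    """
    a = pd.Series(profile_a).astype(float)
    b = pd.Series(profile_b).astype(float).reindex(a.index)
    if b.isna().any() or a.isna().any():
        raise DataError("profiles not aligned over regions")
    if len(a) < 3:
        raise DataError("need >= 3 regions")
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        raise DataError("zero-variance profile")
    res = stats.linregress(a.to_numpy(), b.to_numpy())
    n = len(a)
    r2 = res.rvalue**2
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return float(res.slope), float(r2_adj), float(res.pvalue)
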