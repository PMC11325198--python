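"""Cohort-level statistics of the turnover table.

Implements the study's statistical program on a table with one row per
annotated object (its ratio-of-sums ^15N/^14N, morphometry, region, age
group and image id):

* per-class contrasts against the per-image whole-area baseline
  (Mann-Whitney rank-sum, Bonferroni-corrected over the classes tested);
* young/aged contrasts after whole-organ normalization, so global
  age-related shifts cancel before comparison;
* extreme-turnover subsets (top-k / bottom-k by ratio) whose morphometry
  distributions are compared by two-sample Wilcoxon rank-sum tests;
* nascent-zone percentages contrasted by a paired signed-rank test across
  region x age strata;
* paired pre/post-synaptic regressions (OLS slope, R^2, slope-t p).

Rank-sum p-values use exhaustive permutation enumeration for small pooled
samples (exact even under ties), the exact no-tie distribution for moderate
group sizes, and the tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import STRUCTURE_CLASSES

__all__ = [
    "TURNOVER_COLUMNS",
    "SYNAPTIC_CLASSES",
    "ContrastResult",
    "AgeContrast",
    "MorphologyComparison",
    "NascentContrast",
    "PairedRegression",
    "DegenerateRegressionError",
    "bonferroni",
    "rank_sum_test",
    "compare_to_whole",
    "whole_organ_average",
    "normalize_and_contrast_ages",
    "extreme_subsets",
    "compare_morphology",
    "nascent_fraction_contrast",
    "paired_regression",
]

#: canonical turnover-table columns (one row per object)
TURNOVER_COLUMNS = [
    "object_id",
    "structure",
    "region",
    "age_group",
    "image_id",
    "ratio",
    "whole_area_ratio",
    "area_um2",
    "length_um",
    "vesicle_count",
    "thickness_nm",
    "nascent_zone",
    "in_presynapse",
    "pair_id",
]

SYNAPTIC_CLASSES = ("presynapse", "postsynapse", "active_zone", "PSD")

#: pooled-sample size up to which rank-sum p-values are computed by
#: exhaustive enumeration (exact even with ties)
_ENUMERATION_LIMIT = 16
#: per-group size up to which the exact no-tie distribution is used
_EXACT_LIMIT = 25


class DegenerateRegressionError(ValueError):
    """Zero variance in the regressor."""


def bonferroni(raw_p: float, m: int) -> float:
    """corrected p = min(1, m * raw_p)."""
    return min(1.0, m * raw_p)


# ----------------------------------------------------------------------
# rank-sum machinery
# ----------------------------------------------------------------------


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x vs y with midrank tie handling."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return r1 - len(x) * (len(x) + 1) / 2.0


def _enumerated_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """Exhaustive permutation p-value of the U statistic (exact with ties)."""
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(x) + len(y)
    ranks = stats.rankdata(pooled)
    mu = n1 * (n - n1) / 2.0
    offset = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - offset
    us = np.array(
        [sum(ranks[i] for i in idx) - offset for idx in combinations(range(n), n1)]
    )
    eps = 1e-9
    if alternative == "two-sided":
        hits = np.abs(us - mu) >= abs(u_obs - mu) - eps
    elif alternative == "greater":
        hits = us >= u_obs - eps
    elif alternative == "less":
        hits = us <= u_obs + eps
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(hits.mean())


def rank_sum_test(
    x, y, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    Returns ``(U, p)``. Method selection: exhaustive enumeration for pooled
    n <= 16; exact no-tie distribution for group sizes <= 25 without ties;
    tie-corrected normal approximation (with continuity correction)
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= _ENUMERATION_LIMIT:
        return u, _enumerated_p(x, y, alternative)
    if not has_ties and min(len(x), len(y)) <= _EXACT_LIMIT:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return u, float(res.pvalue)


# ----------------------------------------------------------------------
# structure vs whole-area contrasts
# ----------------------------------------------------------------------


@dataclass
class ContrastResult:
    structure: str
    raw_p: float
    corrected_p: float
    n_objects: int
    n_whole: int
    effect_direction: int  # sign of median(class) - median(whole areas)
    correction_m: int


def compare_to_whole(
    table: pd.DataFrame,
    region: str | None = None,
    age_group: str | None = None,
    classes: tuple[str, ...] | None = None,
    *,
    correction_m: int | None = None,
) -> list[ContrastResult]:
    """Mann-Whitney contrasts of each class against the whole-area baseline.

    The comparison population is the set of per-image whole-area ratios (one
    per image in the stratum). The Bonferroni factor defaults to the number
    of classes actually tested; classes with fewer than 2 objects are
    excluded with a warning.
    """
    sub = _stratum(table, region, age_group)
    whole = (
        sub.drop_duplicates("image_id")["whole_area_ratio"].to_numpy(dtype=float)
    )
    if len(whole) == 0:
        raise ValueError("no whole-area ratios present in the stratum")
    classes = classes or tuple(
        c for c in STRUCTURE_CLASSES if (sub["structure"] == c).any()
    )
    tested = []
    for cls in classes:
        vals = sub.loc[sub["structure"] == cls, "ratio"].to_numpy(dtype=float)
        if len(vals) < 2:
            warnings.warn(f"class {cls} has < 2 objects; excluded", stacklevel=2)
            continue
        tested.append((cls, vals))
    m = correction_m or len(tested)
    out = []
    for cls, vals in tested:
        _, p = rank_sum_test(vals, whole)
        out.append(
            ContrastResult(
                structure=cls,
                raw_p=p,
                corrected_p=bonferroni(p, m),
                n_objects=len(vals),
                n_whole=len(whole),
                effect_direction=int(np.sign(np.median(vals) - np.median(whole))),
                correction_m=m,
            )
        )
    return out


def _stratum(table, region, age_group) -> pd.DataFrame:
    sub = table
    if region is not None:
        sub = sub[sub["region"] == region]
    if age_group is not None:
        sub = sub[sub["age_group"] == age_group]
    return sub


# ----------------------------------------------------------------------
# young vs aged, whole-organ normalized
# ----------------------------------------------------------------------


@dataclass
class AgeContrast:
    structure: str
    normalized_by_region: dict[str, float]
    mean_over_regions: float
    raw_p: float
    corrected_p: float
    correction_m: int


def whole_organ_average(table: pd.DataFrame) -> float:
    """Whole-organ average ratio of a cohort stratum.

    Computed as the ratio of summed counts over all analyzed images when the
    per-image sums are available; otherwise the mean of per-image whole-area
    ratios (per-image normalization variant).
    """
    imgs = table.drop_duplicates("image_id")
    if {"image_sum15", "image_sum14"}.issubset(imgs.columns) and not (
        imgs[["image_sum15", "image_sum14"]].isna().any().any()
    ):
        return float(imgs["image_sum15"].sum() / imgs["image_sum14"].sum())
    return float(imgs["whole_area_ratio"].mean())


def normalize_and_contrast_ages(
    young: pd.DataFrame,
    aged: pd.DataFrame,
    classes: tuple[str, ...] = SYNAPTIC_CLASSES,
    *,
    correction_m: int | None = None,
) -> list[AgeContrast]:
    """Whole-organ-normalized aged/young contrast per synaptic class.

    For each region and age the ratios are divided by that stratum's
    whole-organ average; the per-class per-region normalized means of the
    aged cohort are divided by the young ones, and each class is tested with
    a two-sided one-sample t-test of the per-region values against 1,
    Bonferroni-corrected over the classes tested. A global multiplicative
    shift of one cohort cancels exactly.
    """
    regions = sorted(set(young["region"]) & set(aged["region"]))
    skipped = set(young["region"]) ^ set(aged["region"])
    for r in sorted(skipped):
        warnings.warn(f"region {r} present in only one age; excluded", stacklevel=2)
    if not regions:
        raise ValueError("no region is present in both cohorts")
    m = correction_m or len(classes)
    out = []
    for cls in classes:
        per_region = {}
        for region in regions:
            vals = []
            for tab in (young, aged):
                sub = tab[tab["region"] == region]
                organ = whole_organ_average(sub)
                ratios = sub.loc[sub["structure"] == cls, "ratio"].to_numpy(float)
                if len(ratios) == 0:
                    break
                vals.append(float(np.mean(ratios / organ)))
            if len(vals) == 2:
                per_region[region] = vals[1] / vals[0]
        values = np.array(list(per_region.values()))
        if len(values) == 0:
            warnings.warn(f"class {cls} missing from a cohort; skipped", stacklevel=2)
            continue
        # a numerically constant vector (identical cohorts up to rounding)
        # carries no evidence against 1
        if len(values) >= 2 and np.ptp(values) > 1e-9 * abs(values.mean()):
            p = float(stats.ttest_1samp(values, 1.0).pvalue)
        else:
            p = 1.0
        out.append(
            AgeContrast(
                structure=cls,
                normalized_by_region=per_region,
                mean_over_regions=float(values.mean()),
                raw_p=p,
                corrected_p=bonferroni(p, m),
                correction_m=m,
            )
        )
    return out


# ----------------------------------------------------------------------
# extreme-turnover subsets and their morphology
# ----------------------------------------------------------------------


def extreme_subsets(
    table: pd.DataFrame,
    structure: str,
    region: str | None = None,
    age_group: str | None = None,
    k: int = 18,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k and bottom-k objects of a class by ratio (ties by object_id).

    Returns ``(high, low)``; the groups are disjoint. Raises when the
    stratum holds fewer than 2k objects.
    """
    sub = _stratum(table, region, age_group)
    sub = sub[sub["structure"] == structure]
    n = len(sub)
    if n < 2 * k:
        raise ValueError(
            f"stratum holds {n} {structure} objects; need >= {2 * k} "
            f"(choose k <= {n // 2})"
        )
    ordered = sub.sort_values(["ratio", "object_id"], kind="mergesort")
    return ordered.iloc[-k:].copy(), ordered.iloc[:k].copy()


@dataclass
class MorphologyComparison:
    parameter: str
    p_value: float
    u_statistic: float
    n_high: int
    n_low: int
    median_high: float
    median_low: float
    alternative: str


def compare_morphology(
    high: pd.DataFrame,
    low: pd.DataFrame,
    parameter: str,
    alternative: str = "two-sided",
) -> MorphologyComparison:
    """Wilcoxon rank-sum comparison of a morphometry parameter between the
    high- and low-turnover groups."""
    for name, grp in (("high", high), ("low", low)):
        if len(grp) == 0:
            raise ValueError(f"{name} group is empty")
        missing = grp[grp[parameter].isna()]
        if len(missing):
            oid = missing.iloc[0]["object_id"]
            raise ValueError(
                f"parameter {parameter!r} missing for object {oid} in the "
                f"{name} group"
            )
    x = high[parameter].to_numpy(dtype=float)
    y = low[parameter].to_numpy(dtype=float)
    u, p = rank_sum_test(x, y, alternative)
    return MorphologyComparison(
        parameter=parameter,
        p_value=p,
        u_statistic=u,
        n_high=len(x),
        n_low=len(y),
        median_high=float(np.median(x)),
        median_low=float(np.median(y)),
        alternative=alternative,
    )


# ----------------------------------------------------------------------
# nascent-zone fractions
# ----------------------------------------------------------------------


@dataclass
class NascentContrast:
    strata: list[tuple[str, str]]  # (region, age_group)
    high_pct: list[float]
    low_pct: list[float]
    p_value: float
    degenerate: bool = False  # all per-stratum differences were zero


def nascent_fraction_contrast(
    high: pd.DataFrame, low: pd.DataFrame
) -> NascentContrast:
    """Percentage of nascent-zone PSDs in high vs low groups, per stratum,
    with a paired Wilcoxon signed-rank test across the strata."""
    for grp in (high, low):
        if grp["nascent_zone"].isna().any():
            raise ValueError("nascent_zone flag missing for some PSDs")
    strata = sorted(
        set(map(tuple, high[["region", "age_group"]].drop_duplicates().to_numpy()))
        & set(map(tuple, low[["region", "age_group"]].drop_duplicates().to_numpy()))
    )
    if len(strata) < 2:
        raise ValueError("need >= 2 region x age strata for the paired test")
    high_pct, low_pct = [], []
    for region, age in strata:
        for grp, store in ((high, high_pct), (low, low_pct)):
            sub = grp[(grp["region"] == region) & (grp["age_group"] == age)]
            store.append(100.0 * sub["nascent_zone"].astype(bool).mean())
    diffs = np.asarray(high_pct) - np.asarray(low_pct)
    if np.all(diffs == 0):
        return NascentContrast(strata, high_pct, low_pct, 1.0, degenerate=True)
    p = float(stats.wilcoxon(high_pct, low_pct, zero_method="zsplit").pvalue)
    return NascentContrast(strata, high_pct, low_pct, p)


# ----------------------------------------------------------------------
# paired pre/post regressions
# ----------------------------------------------------------------------


@dataclass
class PairedRegression:
    x_structure: str
    y_structure: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_pairs: int
    degenerate: bool = False  # zero variance in y


def paired_regression(
    table: pd.DataFrame, x_class: str, y_class: str
) -> PairedRegression:
    """OLS of the y-class ratio on the x-class ratio over shared pair_ids.

    R^2 is the squared Pearson correlation; p comes from the slope t-test.
    Constant y is reported as a degenerate fit (slope 0, R^2 0, p 1);
    constant x raises :class:`DegenerateRegressionError`.
    """
    xs = table[(table["structure"] == x_class) & table["pair_id"].notna()]
    ys = table[(table["structure"] == y_class) & table["pair_id"].notna()]
    merged = xs.merge(ys, on="pair_id", suffixes=("_x", "_y"))
    n = len(merged)
    if n < 3:
        raise ValueError(f"need >= 3 complete {x_class}-{y_class} pairs, got {n}")
    x = merged["ratio_x"].to_numpy(dtype=float)
    y = merged["ratio_y"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateRegressionError(f"zero variance in {x_class} ratios")
    if np.ptp(y) == 0:
        return PairedRegression(
            x_class, y_class, 0.0, float(y[0]), 0.0, 1.0, n, degenerate=True
        )
    fit = stats.linregress(x, y)
    return PairedRegression(
        x_structure=x_class,
        y_structure=y_class,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n_pairs=n,
    )
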