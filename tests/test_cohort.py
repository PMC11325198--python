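"""Cohort statistics: exactness, cancellation, extremes, pairing."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emsims.cohort import (
    DegenerateRegressionError,
    bonferroni,
    compare_morphology,
    compare_to_whole,
    extreme_subsets,
    nascent_fraction_contrast,
    normalize_and_contrast_ages,
    paired_regression,
    rank_sum_test,
    whole_organ_average,
)
from emsims.simdata import SceneSpec, sample_cohort


# ---------------------------------------------------------------- oracle


def _u_by_pairwise_comparison(x, y):
    """Independent U formula: count of (x_i > y_j) pairs plus half-ties."""
    x, y = np.asarray(x), np.asarray(y)
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return gt + 0.5 * eq


def _enumerated_p_oracle(x, y, alternative="two-sided"):
    """Exhaustive permutation p of the U statistic, built from the pairwise
    comparison formula (independent of the implementation's rank route)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    idx = range(len(pooled))
    mu = n1 * len(y) / 2.0
    u_obs = _u_by_pairwise_comparison(x, y)
    hits = total = 0
    for chosen in combinations(idx, n1):
        mask = np.zeros(len(pooled), bool)
        mask[list(chosen)] = True
        u = _u_by_pairwise_comparison(pooled[mask], pooled[~mask])
        total += 1
        if alternative == "two-sided":
            hits += abs(u - mu) >= abs(u_obs - mu) - 1e-9
        elif alternative == "greater":
            hits += u >= u_obs - 1e-9
        else:
            hits += u <= u_obs + 1e-9
    return hits / total


@pytest.mark.parametrize(
    "x,y",
    [
        ([1.2, 3.4, 0.1, 5.0], [2.2, 2.3, 7.7, 0.5]),
        ([1, 2, 3], [4, 5, 6, 7]),
        ([1, 1, 2, 3], [1, 2, 2, 4]),  # ties across and within groups
        ([5.0, 5.0, 5.0], [5.0, 5.0]),  # fully tied
        (list(range(8)), list(range(4, 12))),
    ],
)
@pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
def test_small_sample_rank_sum_equals_exhaustive_enumeration(x, y, alternative):
    _, p = rank_sum_test(x, y, alternative)
    assert p == pytest.approx(
        _enumerated_p_oracle(np.asarray(x, float), np.asarray(y, float), alternative),
        abs=1e-12,
    )


def test_rank_sum_matches_scipy_exact_without_ties(rng):
    x = rng.normal(size=7)
    y = rng.normal(0.5, size=6)
    _, p = rank_sum_test(x, y)
    expected = stats.mannwhitneyu(x, y, method="exact").pvalue
    assert p == pytest.approx(expected, abs=1e-12)


def test_large_sample_rank_sum_uses_tie_corrected_normal(rng):
    x = rng.integers(0, 10, size=40).astype(float)
    y = rng.integers(2, 12, size=45).astype(float)
    _, p = rank_sum_test(x, y)
    expected = stats.mannwhitneyu(x, y, method="asymptotic").pvalue
    assert p == pytest.approx(expected, rel=1e-12)


def test_bonferroni_arithmetic_and_cap():
    assert bonferroni(0.01, 8) == pytest.approx(0.08)
    assert bonferroni(0.4, 8) == 1.0


# ---------------------------------------------------------------- tables


def _table(rows):
    return pd.DataFrame(rows)


def _mk_rows(structure, ratios, region="CA1", age="young", image="i0", whole=0.01,
             start_id=0, **extra):
    return [
        {
            "object_id": f"{image}:{start_id + k}",
            "structure": structure,
            "region": region,
            "age_group": age,
            "image_id": image,
            "ratio": r,
            "whole_area_ratio": whole,
            "area_um2": 0.3,
            "length_um": 0.4,
            "vesicle_count": 20,
            "thickness_nm": None,
            "nascent_zone": None,
            "in_presynapse": None,
            "pair_id": None,
            **extra,
        }
        for k, r in enumerate(ratios)
    ]


def test_compare_to_whole_identical_multiset_is_capped_at_one():
    whole_vals = [0.010, 0.011, 0.012, 0.013]
    rows = []
    for i, w in enumerate(whole_vals):
        rows += _mk_rows("presynapse", [w], image=f"i{i}", whole=w, start_id=i)
    table = _table(rows)
    res = compare_to_whole(table)
    assert len(res) == 1
    assert res[0].corrected_p == 1.0


def test_compare_to_whole_small_case_matches_enumeration():
    cls_vals = np.array([0.021, 0.025, 0.030, 0.034])
    whole_vals = np.array([0.010, 0.012, 0.013, 0.015])
    rows = []
    for i, w in enumerate(whole_vals):
        rows += _mk_rows(
            "PSD", [cls_vals[i]], image=f"i{i}", whole=w, start_id=i
        )
    res = compare_to_whole(_table(rows))[0]
    expected = _enumerated_p_oracle(cls_vals, whole_vals)
    assert res.raw_p == pytest.approx(expected, abs=1e-12)
    assert res.corrected_p == pytest.approx(min(1.0, res.raw_p * res.correction_m))
    assert res.effect_direction == 1


def test_compare_to_whole_excludes_singleton_classes():
    rows = _mk_rows("presynapse", [0.02, 0.03, 0.04]) + _mk_rows(
        "myelin", [0.005], start_id=10
    )
    with pytest.warns(UserWarning, match="myelin"):
        res = compare_to_whole(_table(rows))
    assert {r.structure for r in res} == {"presynapse"}


# --------------------------------------------------- age normalization


def _cohort_table(scale=1.0, presyn_extra=1.0, regions=("CA1", "cortex", "DG")):
    rng = np.random.default_rng(77)
    rows = []
    for region in regions:
        whole = 0.010 * rng.uniform(0.9, 1.1)
        for cls in ("presynapse", "postsynapse", "active_zone", "PSD"):
            base = {"presynapse": 0.014, "postsynapse": 0.015,
                    "active_zone": 0.018, "PSD": 0.018}[cls]
            extra = presyn_extra if cls == "presynapse" else 1.0
            ratios = base * extra * scale * rng.uniform(0.8, 1.2, size=12)
            rows += _mk_rows(
                cls, ratios, region=region, image=f"{region}-img",
                whole=whole * scale, start_id=len(rows),
            )
    return _table(rows)


def test_identity_cohorts_normalize_to_exactly_one():
    young = _cohort_table()
    res = normalize_and_contrast_ages(young, young.copy())
    for r in res:
        for v in r.normalized_by_region.values():
            assert v == pytest.approx(1.0, abs=1e-12)


def test_global_scaling_cancels_algebraically():
    young = _cohort_table()
    aged = young.copy()
    aged["ratio"] *= 0.8
    aged["whole_area_ratio"] *= 0.8
    res = normalize_and_contrast_ages(young, aged)
    for r in res:
        assert r.mean_over_regions == pytest.approx(1.0, rel=1e-12)


def test_planted_presynaptic_slowdown_is_recovered():
    young = _cohort_table()
    aged = young.copy()
    aged["ratio"] *= 0.8
    aged["whole_area_ratio"] *= 0.8
    pre = aged["structure"] == "presynapse"
    aged.loc[pre, "ratio"] *= 0.95
    res = {r.structure: r for r in normalize_and_contrast_ages(young, aged)}
    assert res["presynapse"].mean_over_regions == pytest.approx(0.95, rel=1e-9)
    assert res["PSD"].mean_over_regions == pytest.approx(1.0, rel=1e-9)


def test_whole_organ_average_prefers_count_sums():
    rows = _mk_rows("presynapse", [0.02], image="a", whole=0.010)
    rows += _mk_rows("presynapse", [0.02], image="b", whole=0.020, start_id=5)
    t = _table(rows)
    t["image_sum15"] = [100, 400]
    t["image_sum14"] = [10000, 20000]
    assert whole_organ_average(t) == pytest.approx(500 / 30000)
    t2 = t.drop(columns=["image_sum15", "image_sum14"])
    assert whole_organ_average(t2) == pytest.approx(0.015)


def test_region_in_single_age_is_excluded_with_warning():
    young = _cohort_table(regions=("CA1", "cortex"))
    aged = _cohort_table(regions=("CA1",))
    with pytest.warns(UserWarning, match="cortex"):
        res = normalize_and_contrast_ages(young, aged)
    assert all(set(r.normalized_by_region) == {"CA1"} for r in res)


# ---------------------------------------------------------------- extremes


def test_extreme_subsets_match_full_sort_head_and_tail(rng):
    ratios = rng.uniform(0.005, 0.03, size=53)
    rows = _mk_rows("presynapse", ratios)
    table = _table(rows)
    high, low = extreme_subsets(table, "presynapse", k=15)
    ordered = np.sort(ratios)
    np.testing.assert_allclose(np.sort(high["ratio"]), ordered[-15:])
    np.testing.assert_allclose(np.sort(low["ratio"]), ordered[:15])
    assert not set(high["object_id"]) & set(low["object_id"])


def test_extreme_subsets_partition_with_exactly_2k_objects(rng):
    rows = _mk_rows("PSD", rng.uniform(0.01, 0.03, size=30))
    high, low = extreme_subsets(_table(rows), "PSD", k=15)
    assert set(high["object_id"]) | set(low["object_id"]) == set(
        r["object_id"] for r in rows
    )


def test_extreme_subsets_tie_break_is_deterministic():
    rows = _mk_rows("PSD", [0.01] * 10)
    t = _table(rows)
    high1, low1 = extreme_subsets(t, "PSD", k=5)
    high2, low2 = extreme_subsets(t.sample(frac=1, random_state=3), "PSD", k=5)
    assert list(high1["object_id"]) == list(high2["object_id"])
    assert high1["ratio"].min() >= low1["ratio"].max()


def test_extreme_subsets_insufficient_objects_raise():
    rows = _mk_rows("PSD", [0.01, 0.02, 0.03])
    with pytest.raises(ValueError, match="k <= 1"):
        extreme_subsets(_table(rows), "PSD", k=2)


def test_compare_morphology_symmetry_and_missing_parameter():
    rng = np.random.default_rng(5)
    high = _table(_mk_rows("presynapse", rng.uniform(size=8)))
    low = _table(_mk_rows("presynapse", rng.uniform(size=8), start_id=20))
    high["area_um2"] = rng.uniform(0.2, 0.5, size=8)
    low["area_um2"] = rng.uniform(0.3, 0.6, size=8)
    p_hl = compare_morphology(high, low, "area_um2").p_value
    p_lh = compare_morphology(low, high, "area_um2").p_value
    assert p_hl == pytest.approx(p_lh, abs=1e-12)
    low.loc[low.index[2], "area_um2"] = np.nan
    with pytest.raises(ValueError, match=str(low.iloc[2]["object_id"])):
        compare_morphology(high, low, "area_um2")


# ---------------------------------------------------------------- nascent


def _nascent_groups(flags_high, flags_low):
    highs, lows = [], []
    strata = [("CA1", "young"), ("CA1", "aged"), ("DG", "young")]
    for (region, age), fh, fl in zip(strata, flags_high, flags_low):
        h = _mk_rows("PSD", [0.02] * len(fh), region=region, age=age)
        l = _mk_rows("PSD", [0.01] * len(fl), region=region, age=age, start_id=50)
        for row, f in zip(h, fh):
            row["nascent_zone"] = f
        for row, f in zip(l, fl):
            row["nascent_zone"] = f
        highs += h
        lows += l
    return _table(highs), _table(lows)


def test_nascent_percentages_equal_brute_force_counts():
    high, low = _nascent_groups(
        [[True, True, False, False], [True, False], [True, True, True]],
        [[False, False, False, True], [False, False], [False, True, False]],
    )
    res = nascent_fraction_contrast(high, low)
    by_stratum = dict(zip(res.strata, zip(res.high_pct, res.low_pct)))
    assert by_stratum[("CA1", "young")] == pytest.approx((50.0, 25.0))
    assert by_stratum[("CA1", "aged")] == pytest.approx((50.0, 0.0))
    assert by_stratum[("DG", "young")] == pytest.approx((100.0, 100.0 / 3))


def test_nascent_all_unflagged_is_degenerate_no_difference():
    high, low = _nascent_groups(
        [[False] * 4, [False] * 3, [False] * 5],
        [[False] * 4, [False] * 3, [False] * 5],
    )
    res = nascent_fraction_contrast(high, low)
    assert res.degenerate and res.p_value == 1.0
    assert res.high_pct == res.low_pct == [0.0, 0.0, 0.0]


def test_planted_nascent_coupling_separates_high_and_low_strata():
    """With a strong enrichment-nascent coupling, the high-turnover PSD
    subset shows a higher nascent percentage in nearly every stratum."""
    wins = ties = 0
    strata = [(r, a) for r in ("CA1", "cortex", "DG") for a in ("young", "aged")]
    for i, (region, age) in enumerate(strata):
        spec = SceneSpec(
            structure_counts={"postsynapse": 40, "PSD": 40},
            nascent_logit_slope=2.0,
            seed=300 + i,
        )
        df = sample_cohort(spec, region=region, age_group=age, image_id=f"s{i}")
        psd = df[df.structure == "PSD"]
        high, low = extreme_subsets(psd, "PSD", k=15)
        diff = high["nascent_zone"].mean() - low["nascent_zone"].mean()
        wins += diff > 0
        ties += diff == 0
    assert wins >= 5


# ---------------------------------------------------------------- pairing


def _paired_table(x, y, x_cls="presynapse", y_cls="postsynapse"):
    rows = []
    for i, (a, b) in enumerate(zip(x, y)):
        rows += _mk_rows(x_cls, [a], start_id=2 * i, pair_id=i)
        rows += _mk_rows(y_cls, [b], start_id=2 * i + 1, pair_id=i)
    return _table(rows)


def test_paired_regression_perfect_line():
    x = np.linspace(0.01, 0.02, 10)
    res = paired_regression(_paired_table(x, x), "presynapse", "postsynapse")
    assert res.r_squared == pytest.approx(1.0)
    assert res.slope == pytest.approx(1.0)
    assert res.n_pairs == 10


def test_paired_regression_constant_y_is_degenerate():
    x = np.linspace(0.01, 0.02, 8)
    res = paired_regression(
        _paired_table(x, np.full(8, 0.015)), "presynapse", "postsynapse"
    )
    assert res.degenerate and res.r_squared == 0.0 and res.p_value == 1.0


def test_paired_regression_error_cases():
    x = np.array([0.01, 0.02])
    with pytest.raises(ValueError, match=">= 3"):
        paired_regression(_paired_table(x, x), "presynapse", "postsynapse")
    const_x = np.full(5, 0.01)
    with pytest.raises(DegenerateRegressionError):
        paired_regression(
            _paired_table(const_x, np.linspace(0.01, 0.02, 5)),
            "presynapse",
            "postsynapse",
        )


def test_paired_regression_p_matches_permutation_test(rng):
    x = rng.uniform(0.01, 0.03, size=10)
    y = 0.6 * x + rng.normal(0, 0.004, size=10)
    res = paired_regression(_paired_table(x, y), "presynapse", "postsynapse")

    def statistic(ys):
        return abs(stats.pearsonr(x, ys).statistic)

    perm = stats.permutation_test(
        (y,),
        statistic,
        permutation_type="pairings",
        n_resamples=2000,
        random_state=np.random.default_rng(8),
    )
    mc_se = np.sqrt(perm.pvalue * (1 - perm.pvalue) / 2000)
    assert abs(res.p_value - perm.pvalue) < 4 * mc_se + 0.01
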