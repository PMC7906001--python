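"""Correlation selection, strength labeling and Mann-Whitney comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from gazehand.stats import (
    choose_method,
    classify_strength,
    correlate_pair,
    mann_whitney,
    run_correlation_battery,
)

from _oracles import exact_mannwhitney_min_u_p


# ------------------------------------------------------------------- strength

@pytest.mark.parametrize(
    "r, label",
    [
        (0.06, "small"), (-0.29, "small"), (0.0, "small"),
        (0.3, "moderate"), (0.448, "moderate"), (-0.443, "moderate"),
        (0.5, "strong"), (-0.836, "strong"), (1.0, "strong"),
    ],
)
def test_strength_bands(r, label):
    assert classify_strength(r) == label


def test_strength_rejects_out_of_range():
    with pytest.raises(ValueError):
        classify_strength(1.2)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(min_value=-1.0, max_value=1.0), st.floats(min_value=-1.0, max_value=1.0))
def test_strength_monotone_in_magnitude(a, b):
    order = {"small": 0, "moderate": 1, "strong": 2}
    if abs(a) <= abs(b):
        assert order[classify_strength(a)] <= order[classify_strength(b)]


# ------------------------------------------------------------- method selection

def test_choose_method_normal_data_pearson(rng):
    x, y = rng.normal(size=50), rng.normal(size=50)
    method, px, py = choose_method(x, y)
    assert (px > 0.05) and (py > 0.05)  # seeded draw is comfortably normal
    assert method == "pearson"
    assert px == pytest.approx(sps.shapiro(x).pvalue)


def test_choose_method_outlier_forces_spearman(rng):
    x = rng.normal(size=30)
    x[0] = 40.0  # single extreme heavy-tail outlier
    y = rng.normal(size=30)
    method, px, _ = choose_method(x, y)
    assert px < 0.05 and method == "spearman"


def test_choose_method_small_n_errors(rng):
    with pytest.raises(ValueError):
        choose_method([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


def test_choose_method_constant_vector_warns_spearman():
    with pytest.warns(UserWarning, match="constant"):
        method, *_ = choose_method(np.ones(10), np.arange(10.0))
    assert method == "spearman"


# ---------------------------------------------------------------- correlation

def test_perfect_correlations():
    x = np.arange(10.0)
    up = correlate_pair(x, x, "pearson")
    dn = correlate_pair(x, -x, "pearson")
    assert (up.coefficient, up.strength, up.sign) == (pytest.approx(1.0), "strong", "+")
    assert (dn.coefficient, dn.strength, dn.sign) == (pytest.approx(-1.0), "strong", "-")


def test_pearson_matches_direct_formula():
    x = np.array([3.1, 4.7, 2.2, 5.9, 4.1, 3.3, 6.2, 1.8, 4.9, 5.5])
    y = np.array([9.4, 8.1, 11.0, 6.3, 8.8, 9.9, 5.7, 11.8, 7.6, 7.2])
    r = correlate_pair(x, y, "pearson").coefficient
    # brute-force evaluation of the product-moment formula
    xc, yc = x - x.mean(), y - y.mean()
    want = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
    assert r == pytest.approx(want, abs=1e-12)


def test_spearman_is_pearson_on_midranks():
    x = np.array([1.0, 2.0, 2.0, 5.0, 9.0, 3.0, 3.0, 7.0])
    y = np.array([4.0, 1.0, 6.0, 6.0, 2.0, 8.0, 5.0, 3.0])
    rs = correlate_pair(x, y, "spearman").coefficient
    want = correlate_pair(sps.rankdata(x), sps.rankdata(y), "pearson").coefficient
    assert rs == pytest.approx(want, abs=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_spearman_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    x, y = rng.normal(size=12), rng.normal(size=12)
    base = correlate_pair(x, y, "spearman").coefficient
    warped = correlate_pair(np.exp(x), y**3, "spearman").coefficient
    assert warped == pytest.approx(base, abs=1e-12)


def test_pearson_zero_variance_errors():
    with pytest.raises(ValueError):
        correlate_pair(np.ones(10), np.arange(10.0), "pearson")


# --------------------------------------------------------------- mann-whitney

def test_complete_separation_worked_example():
    """3 values all above 8 values: U = 0, mean ranks 10.0 and 4.5."""
    a = np.array([4.8, 4.6, 4.9])
    b = np.array([2.0, 1.5, 2.2, 1.8, 2.5, 1.2, 2.8, 1.9])
    res = mann_whitney(a, b)
    assert res.U == 0.0
    assert res.mean_rank_1 == pytest.approx(10.0)
    assert res.mean_rank_2 == pytest.approx(4.5)
    assert res.p < 0.05


def test_single_tied_pair():
    res = mann_whitney([1.0], [1.0])
    assert res.U == 0.5
    assert res.mean_rank_1 == res.mean_rank_2 == 1.5


def test_u_bounds_and_exchange_symmetry(rng):
    a, b = rng.integers(0, 10, 6).astype(float), rng.integers(0, 10, 7).astype(float)
    r1, r2 = mann_whitney(a, b), mann_whitney(b, a)
    assert 0 <= r1.U <= a.size * b.size
    assert r1.U == r2.U and r1.p == pytest.approx(r2.p)
    assert r1.mean_rank_1 == r2.mean_rank_2


def test_normal_approx_close_to_exact_permutation(rng):
    for _ in range(5):
        a = rng.integers(0, 8, 3).astype(float)
        b = rng.integers(0, 8, 4).astype(float)
        approx = mann_whitney(a, b, exact=False)
        want = exact_mannwhitney_min_u_p(a, b)
        assert mann_whitney(a, b, exact=True).p == pytest.approx(want)
        # the tie-corrected normal approximation tracks the exact value
        assert approx.p == pytest.approx(want, abs=0.17)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_mw_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    a, b = rng.normal(size=5), rng.normal(size=6)
    base = mann_whitney(a, b)
    warped = mann_whitney(np.exp(a), np.exp(b))
    assert warped.U == base.U and warped.p == pytest.approx(base.p)


def test_empty_group_errors():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


# -------------------------------------------------------------------- battery

def _metric_df(rng, n=12, participant_prefix="p"):
    rows = []
    for i in range(n):
        rows.append(
            {
                "participant": f"{participant_prefix}{i}", "scenario": "s1", "task": 0,
                "FD_ms": rng.normal(450, 40), "FN": rng.integers(5, 15),
                "SN": rng.integers(2, 10), "SSD_ms": rng.normal(550, 40),
                "SSN": rng.integers(4, 12), "SSM": rng.integers(1, 8),
            }
        )
    return pd.DataFrame(rows)


def test_battery_produces_six_cells(rng):
    df = pd.concat([_metric_df(rng, 8, "a"), _metric_df(rng, 8, "b")])
    groups = {f"a{i}": "g1" for i in range(8)} | {f"b{i}": "g2" for i in range(8)}
    results = run_correlation_battery(df, groups)
    assert len(results) == 6
    for r in results:
        assert r.strength == classify_strength(r.coefficient)
        assert r.method in ("pearson", "spearman")


def test_battery_identical_groups_identical_rows(rng):
    df1 = _metric_df(rng, 8, "a")
    df2 = df1.copy()
    df2["participant"] = df2["participant"].str.replace("a", "b")
    groups = {f"a{i}": "g1" for i in range(8)} | {f"b{i}": "g2" for i in range(8)}
    results = run_correlation_battery(pd.concat([df1, df2]), groups)
    by_group = {}
    for r in results:
        by_group.setdefault(r.group, []).append((r.pair, r.method, r.coefficient))
    assert by_group["g1"] == by_group["g2"]


def test_battery_constant_metric_uses_spearman(rng):
    df = _metric_df(rng, 8, "a")
    df["SSM"] = 3
    with pytest.warns(UserWarning, match="constant"):
        results = run_correlation_battery(df, {f"a{i}": "g" for i in range(8)})
    cell = [r for r in results if r.pair == "SN-SSM"][0]
    assert cell.method == "spearman"


def test_battery_too_few_units_errors(rng):
    df = _metric_df(rng, 3, "a")
    with pytest.raises(ValueError, match=">= 4"):
        run_correlation_battery(df, {f"a{i}": "g" for i in range(3)})
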