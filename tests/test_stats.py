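"""Contingency tests, gated comparisons, ICC, OLS/VIF, blood loss.

Printed-table checks use the published contingency tables and summary
statistics of a 90-patient two-arm lumbar-fusion cohort; simulation
checks use seeded generators at the stated operating conditions.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.special import comb

from paramuscle import (
    estimate_blood_loss,
    fisher_exact,
    icc_a_k,
    mann_whitney_u,
    multivariable_ols,
    pearson_chi2,
    shapiro_wilk_gate,
    significance_flag,
    two_sample_t,
)
from paramuscle import test_selector_categorical as selector_categorical
from paramuscle.exceptions import CollinearityError
from paramuscle.stats import compare_continuous, expected_counts, icc_band

# published 2x2/3x2 baseline tables: (name, table, chi2)
PRINTED_TABLES = [
    ("sex", [[24, 24], [19, 23]], 0.204),
    ("diabetes", [[6, 42], [6, 36]], 0.062),
    ("smoking", [[17, 31], [13, 29]], 0.201),
    ("spondylolisthesis", [[15, 33], [16, 26]], 0.465),
    ("asa", [[21, 17], [22, 21], [5, 4]], 0.156),
    ("myofascitis_fu", [[17, 31], [25, 17]], 5.230),
]


# ---------------------------------------------------------------------------
# chi2 / Fisher


@pytest.mark.parametrize("name,table,chi2", PRINTED_TABLES)
def test_chi2_reproduces_published_tables(name, table, chi2):
    res = pearson_chi2(table, continuity_correction=False)
    assert res.statistic == pytest.approx(chi2, abs=5e-4)


def test_chi2_zero_for_proportional_table():
    assert pearson_chi2([[10, 20], [5, 10]]).statistic == pytest.approx(0.0, abs=1e-12)


def test_chi2_zero_margin_is_error():
    with pytest.raises(ValueError, match="zero margin"):
        pearson_chi2([[0, 0], [5, 10]])


@settings(max_examples=100, deadline=None)
@given(st.lists(st.integers(1, 40), min_size=4, max_size=4))
def test_chi2_closed_form_on_2x2(cells):
    a, b, c, d = cells
    res = pearson_chi2([[a, b], [c, d]])
    n = a + b + c + d
    closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    assert res.statistic == pytest.approx(closed, abs=1e-10)
    # Cramér's V from its definition
    assert res.effect["cramers_v"] == pytest.approx(np.sqrt(closed / n), abs=1e-10)


def fisher_p_by_enumeration(table):
    """Oracle: sum hypergeometric probabilities of all tables with the
    observed margins whose probability is <= that of the observed table."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    def prob(x):
        return (comb(r1, x, exact=True) * comb(n - r1, c1 - x, exact=True)) / comb(n, c1, exact=True)
    p_obs = prob(a)
    return sum(p for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1)
               if (p := prob(x)) <= p_obs * (1 + 1e-9))


@pytest.mark.parametrize("table", [
    [[3, 45], [3, 39]],       # osteoporosis-style sparse table
    [[0, 10], [10, 0]],
    [[5, 5], [5, 5]],
    [[2, 7], [8, 3]],
    [[1, 12], [4, 2]],
])
def test_fisher_matches_enumeration_oracle(table):
    assert fisher_exact(table).p_value == pytest.approx(fisher_p_by_enumeration(table), abs=1e-10)


@settings(max_examples=60, deadline=None)
@given(st.lists(st.integers(0, 15), min_size=4, max_size=4))
def test_fisher_enumeration_on_random_small_tables(cells):
    a, b, c, d = cells
    t = [[a, b], [c, d]]
    if min(a + b, c + d, a + c, b + d) == 0:
        return  # degenerate margins: p = 1 by convention, skip
    assert fisher_exact(t).p_value == pytest.approx(fisher_p_by_enumeration(t), abs=1e-9)


def test_balanced_table_fisher_p_is_one():
    assert fisher_exact([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)


def test_selector_uses_expected_cell_rule():
    assert selector_categorical([[24, 24], [19, 23]]) == "chi2"
    assert selector_categorical([[3, 45], [3, 39]]) == "fisher"
    assert expected_counts([[3, 45], [3, 39]]).min() == pytest.approx(6 * 42 / 90)
    with pytest.raises(ValueError, match="zero margin"):
        selector_categorical([[0, 0], [5, 10]])


# ---------------------------------------------------------------------------
# continuous comparisons


def test_pooled_t_from_printed_summaries():
    """Functional-disability scores at day 3: 39.1±6.6 (n=48) vs 47.9±4.7
    (n=42) give the published pooled t = −7.188 (within rounding)."""
    res = two_sample_t(39.1, 6.6, 48, 47.9, 4.7, 42)
    assert res.statistic == pytest.approx(-7.188, rel=1e-3)
    assert res.df == 88


def test_t_zero_for_equal_groups_and_linearity():
    assert two_sample_t(5.0, 1.0, 20, 5.0, 1.0, 20).statistic == 0.0
    t1 = two_sample_t(5.0, 1.0, 20, 6.0, 1.0, 20).statistic
    t2 = two_sample_t(5.0, 1.0, 20, 7.0, 1.0, 20).statistic
    assert t2 == pytest.approx(2 * t1)


def test_t_rejects_degenerate_inputs():
    with pytest.raises(ValueError, match="pooled variance"):
        two_sample_t(5.0, 0.0, 20, 5.0, 0.0, 20)
    with pytest.raises(ValueError, match="n >= 2"):
        two_sample_t(5.0, 1.0, 1, 5.0, 1.0, 20)


def test_mann_whitney_enumerated_example():
    res = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert res.effect["U"] == 0.0  # every pairwise comparison lost


def test_mann_whitney_symmetry_and_complement():
    rng = np.random.default_rng(4)
    a, b = rng.random(12), rng.random(15)
    res_ab, res_ba = mann_whitney_u(a, b), mann_whitney_u(b, a)
    assert res_ab.effect["U"] + res_ba.effect["U"] == pytest.approx(12 * 15)
    assert res_ab.statistic == pytest.approx(-res_ba.statistic)
    same = mann_whitney_u(a, a)
    assert same.effect["U"] == pytest.approx(12 * 12 / 2)
    assert same.statistic == pytest.approx(0.0)


def test_mann_whitney_all_identical_is_error():
    with pytest.raises(ValueError, match="identical"):
        mann_whitney_u([2.0, 2.0], [2.0, 2.0])


def test_mann_whitney_tie_corrected_z():
    a, b = [1, 2, 2, 3], [2, 3, 3, 4]
    res = mann_whitney_u(a, b)
    # manual tie-corrected normal approximation, no continuity correction
    pooled = np.array(a + b, float)
    ranks = sps.rankdata(pooled)
    u = ranks[:4].sum() - 4 * 5 / 2
    _, t = np.unique(pooled, return_counts=True)
    var = 4 * 4 / 12 * (9 - np.sum(t**3 - t) / (8 * 7))
    assert res.statistic == pytest.approx((u - 8) / np.sqrt(var), abs=1e-12)


def test_shapiro_gate_routes_by_distribution():
    t_count = mw_count = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        t_count += shapiro_wilk_gate(rng.normal(size=40), rng.normal(size=40)) == "t_test"
        mw_count += shapiro_wilk_gate(rng.exponential(size=40), rng.exponential(size=40)) == "mann_whitney"
    assert t_count >= 85  # both normal samples must pass SW at 0.05 jointly
    assert mw_count >= 95
    with pytest.raises(ValueError, match="n >= 3"):
        shapiro_wilk_gate([1.0, 2.0], [1.0, 2.0, 3.0])


def test_gated_comparison_type_one_error():
    """Normal data, equal means, n=45/group: the gated test's rejection
    rate at α=0.01 stays within 3 SE of nominal over 2000 simulations."""
    rng = np.random.default_rng(2024)
    rejections = 0
    n_sim = 2000
    for _ in range(n_sim):
        res = compare_continuous(rng.normal(size=45), rng.normal(size=45))
        rejections += significance_flag(res.p_value)
    rate = rejections / n_sim
    se = np.sqrt(0.01 * 0.99 / n_sim)
    assert abs(rate - 0.01) <= 3 * se


# ---------------------------------------------------------------------------
# ICC


def anova_icc_oracle(x):
    """Independently coded two-way ANOVA table and ICC(A,k) for k=2,
    accumulating sums of squares cell by cell."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ssr = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ssc = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    sse = 0.0
    for i in range(n):
        for j in range(k):
            sse += (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
    msr, msc, mse = ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)


def test_icc_perfect_agreement():
    x = np.column_stack([np.arange(10.0), np.arange(10.0)])
    res = icc_a_k(x)
    assert res.icc == pytest.approx(1.0)
    assert res.band == "excellent"


def test_icc_matches_anova_oracle_to_1e10():
    rng = np.random.default_rng(11)
    subj = rng.normal(0.0, 1.0, 90)
    x = subj[:, None] + rng.normal(0.0, 1.0, (90, 2))
    assert icc_a_k(x).icc == pytest.approx(anova_icc_oracle(x), abs=1e-10)


def test_icc_matches_pingouin_reference():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(3)
    x = rng.normal(0.0, 1.0, 40)[:, None] + rng.normal(0.0, 0.4, (40, 2))
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(40), 2),
        "rater": np.tile(["r1", "r2"], 40),
        "score": x.ravel(),
    })
    ref = pingouin.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    ref["Type"] = ref["Type"].astype(str)
    row = ref.set_index("Type").loc["ICC(A,k)"] if "ICC(A,k)" in set(ref["Type"]) else ref.set_index("Type").loc["ICC2k"]
    ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
    mine = icc_a_k(x)
    assert mine.icc == pytest.approx(row["ICC"], abs=1e-8)
    assert mine.f_value == pytest.approx(row["F"], abs=1e-8)
    # pingouin rounds the reported interval to 2 decimals
    assert mine.ci_low == pytest.approx(row[ci_col][0], abs=5.1e-3)
    assert mine.ci_high == pytest.approx(row[ci_col][1], abs=5.1e-3)


def test_icc_near_zero_under_pure_noise():
    vals = []
    for seed in range(200):
        rng = np.random.default_rng(seed)
        vals.append(icc_a_k(rng.normal(size=(90, 2))).icc)
    assert abs(np.mean(vals)) <= 0.05


def test_icc_shift_invariance_and_bands():
    rng = np.random.default_rng(9)
    x = rng.normal(0.0, 1.0, 30)[:, None] + rng.normal(0.0, 0.3, (30, 2))
    assert icc_a_k(x).icc == pytest.approx(icc_a_k(x + 100.0).icc, abs=1e-12)
    assert icc_band(0.95) == "excellent"
    assert icc_band(0.85) == "good"
    assert icc_band(0.75) == "acceptable"
    assert icc_band(0.5) == "poor"


def test_icc_rejects_missing_cells():
    x = np.random.default_rng(0).normal(size=(10, 2))
    x[3, 1] = np.nan
    with pytest.raises(ValueError, match="missing"):
        icc_a_k(x)


# ---------------------------------------------------------------------------
# regression


def test_orthogonal_design_has_unit_vif():
    X = pd.DataFrame({"a": [1, 1, -1, -1, 1, 1, -1, -1.0], "b": [1, -1, 1, -1, 1, -1, 1, -1.0]})
    y = np.arange(8.0)
    res = multivariable_ols(y, X)
    assert res.row("a").diagnostics["vif"] == pytest.approx(1.0, abs=1e-10)
    assert res.row("b").diagnostics["vif"] == pytest.approx(1.0, abs=1e-10)


def test_duplicated_covariate_raises_collinearity():
    rng = np.random.default_rng(0)
    X = pd.DataFrame({"a": rng.normal(size=30)})
    X["b"] = X["a"]
    with pytest.raises(CollinearityError) as err:
        multivariable_ols(rng.normal(size=30), X)
    assert set(err.value.columns) == {"a", "b"}


def test_vif_from_pairwise_correlation():
    """Two covariates with sample correlation r have VIF = 1/(1−r²); the
    oracle computes R²_j directly from the correlation."""
    rng = np.random.default_rng(5)
    a = rng.normal(size=400)
    b = 0.8 * a + np.sqrt(1 - 0.64) * rng.normal(size=400)
    X = pd.DataFrame({"a": a, "b": b})
    r = np.corrcoef(a, b)[0, 1]
    res = multivariable_ols(rng.normal(size=400), X)
    assert res.row("a").diagnostics["vif"] == pytest.approx(1.0 / (1.0 - r**2), rel=1e-10)
    assert res.row("a").diagnostics["tolerance"] == pytest.approx(1.0 - r**2, rel=1e-10)


def test_standardized_beta_definition():
    rng = np.random.default_rng(6)
    X = pd.DataFrame({"a": rng.normal(2.0, 3.0, 200)})
    y = 1.5 * X["a"].to_numpy() + rng.normal(size=200)
    res = multivariable_ols(y, X)
    row = res.row("a")
    expected = row.effect["beta"] * X["a"].std(ddof=1) / np.std(y, ddof=1)
    assert row.effect["standardized_beta"] == pytest.approx(expected, rel=1e-12)


def test_residual_diagnostics_exported():
    rng = np.random.default_rng(7)
    X = pd.DataFrame({"a": rng.normal(size=50)})
    res = multivariable_ols(rng.normal(size=50), X)
    diag = res.residual_diagnostics
    assert {"fitted", "std_residual", "pp_observed", "pp_expected"} <= set(diag.columns)
    assert len(diag) == 50
    assert diag["pp_observed"].between(0, 1).all()


# ---------------------------------------------------------------------------
# blood loss & significance


@pytest.mark.parametrize("suction,irrigation,gauze,expected", [
    (300.0, 250.0, 18.0, 60.08),
    (100.0, 100.0, 0.0, 0.0),
    (0.0, 0.0, 1.0, 0.56),
])
def test_blood_loss_estimator(suction, irrigation, gauze, expected):
    assert estimate_blood_loss(suction, irrigation, gauze) == pytest.approx(expected)


def test_blood_loss_rejects_inconsistent_inputs():
    with pytest.raises(ValueError, match="exceeds"):
        estimate_blood_loss(100.0, 150.0, 0.0)
    with pytest.raises(ValueError, match="non-negative"):
        estimate_blood_loss(100.0, 50.0, -1.0)


@pytest.mark.parametrize("p,flag", [(0.009, True), (0.01, False), (0.5, False), (0.0, True)])
def test_significance_strictly_below_alpha(p, flag):
    assert significance_flag(p) is flag
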