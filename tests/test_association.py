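"""Association-statistics tests: exact tests against enumeration oracles,
logistic fits against closed forms and a hand-rolled IRLS, screening logic."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bcrisk.association import (
    SeparationError,
    compare_baseline,
    covariate_design,
    fit_logistic,
    genotype_table_test,
    hwe_exact_test,
    select_markers,
    snp_association,
    two_stage_screen,
)
from bcrisk.datatypes import GenotypeCounts
from bcrisk.studydata import (
    FIVE_SNP_PANEL,
    GENOTYPE_COUNTS,
    SCREENING_PVALUES,
    VALIDATED_SNP_IDS,
)
from conftest import dataset_from_counts


# ---------------------------------------------------------------------------
# independent enumeration oracles (exact rational arithmetic)


def hwe_oracle(hom_major: int, het: int, hom_minor: int) -> float:
    """Exact HWE p by enumerating heterozygote counts with Fractions.

    Conditional genotype probability given the allele count nm:
    P(h) = n! 2^h / (n_hom_major! h! n_hom_minor!) / C(2n, nm).
    """
    from math import factorial

    n = hom_major + het + hom_minor
    nm = 2 * hom_minor + het

    def exact_prob(h: int) -> Fraction:
        lo = (nm - h) // 2
        hi_ = n - h - lo
        return Fraction(
            factorial(n) * 2**h, factorial(hi_) * factorial(h) * factorial(lo)
        ) / Fraction(comb(2 * n, nm))

    p_obs = exact_prob(het)
    total = sum(
        exact_prob(h)
        for h in range(nm % 2, min(nm, 2 * n - nm) + 1, 2)
        if exact_prob(h) <= p_obs
    )
    return float(min(Fraction(1), total))


def ffh_oracle(row_a, row_b) -> float:
    """Exact FFH p for a 2x3 table by full enumeration with Fractions."""
    from math import factorial

    cols = [a + b for a, b in zip(row_a, row_b)]
    r1 = sum(row_a)
    n = sum(cols)

    def prob(cells) -> Fraction:
        num = Fraction(factorial(r1) * factorial(n - r1))
        for c in cols:
            num *= factorial(c)
        den = Fraction(factorial(n))
        for x, c in zip(cells, cols):
            den *= factorial(x) * factorial(c - x)
        return num / den

    p_obs = prob(row_a)
    total = Fraction(0)
    for a in range(min(cols[0], r1) + 1):
        for b in range(min(cols[1], r1 - a) + 1):
            c = r1 - a - b
            if 0 <= c <= cols[2]:
                p = prob((a, b, c))
                if p <= p_obs:
                    total += p
    return float(min(Fraction(1), total))


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


@pytest.mark.parametrize(
    "counts,expected",
    [
        ((387, 393, 110), 0.50),  # testing-stage controls of the 6q25.1 marker
        ((695, 188, 9), 0.41),    # 2q35 marker controls
    ],
)
def test_hwe_matches_published_control_values(counts, expected):
    p = hwe_exact_test(GenotypeCounts(*counts))
    assert round(p, 2) == expected


def test_hwe_monomorphic_is_one():
    assert hwe_exact_test(GenotypeCounts(50, 0, 0)) == 1.0


def test_hwe_equals_enumeration_oracle_on_small_tables():
    rng = np.random.default_rng(0)
    for _ in range(40):
        counts = rng.integers(0, 18, size=3)
        if counts.sum() == 0:
            continue
        p = hwe_exact_test(GenotypeCounts(*map(int, counts)))
        assert p == pytest.approx(hwe_oracle(*map(int, counts)), abs=1e-10)


def test_hwe_pvalues_conservative_under_null():
    """Under HWE genotypes the exact test rejects at most ~5% at alpha=.05."""
    rng = np.random.default_rng(2)
    rejections = 0
    reps = 400
    for _ in range(reps):
        g = rng.binomial(2, 0.3, size=300)
        counts = GenotypeCounts(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))
        rejections += hwe_exact_test(counts) <= 0.05
    assert rejections / reps <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / reps)


# ---------------------------------------------------------------------------
# Fisher-Freeman-Halton / chi-square on 2x3 tables


PUBLISHED_TABLES = {
    "rs2981582": 0.037,
    "rs2180341": 0.040,
    "rs2307032": 0.017,
    "rs13387042": 0.039,
}


@pytest.mark.parametrize("snp_id,expected", list(PUBLISHED_TABLES.items()))
def test_ffh_reproduces_published_screening_pvalues(snp_id, expected):
    tc = GENOTYPE_COUNTS[snp_id]["testing"]
    p = genotype_table_test(tc["case"], tc["control"], "ffh_exact")
    assert round(p, 3) == expected


def test_ffh_reproduces_strongest_marker_pvalue():
    tc = GENOTYPE_COUNTS["rs2046210"]["testing"]
    p = genotype_table_test(tc["case"], tc["control"], "ffh_exact")
    assert p == pytest.approx(1.26e-5, rel=0.02)


def test_ffh_equals_enumeration_oracle_on_small_tables():
    rng = np.random.default_rng(1)
    for _ in range(30):
        a = rng.integers(0, 8, size=3)
        b = rng.integers(0, 8, size=3)
        if a.sum() == 0 or b.sum() == 0 or np.any((a + b) == 0):
            continue
        p = genotype_table_test(list(map(int, a)), list(map(int, b)), "ffh_exact")
        assert p == pytest.approx(ffh_oracle(list(a), list(b)), abs=1e-9)


def test_chi2_matches_hand_pearson_and_agrees_with_ffh_when_dense():
    a = np.array([423, 373, 54])
    b = np.array([480, 334, 66])
    exp = np.outer([a.sum(), b.sum()], a + b) / (a.sum() + b.sum())
    obs = np.vstack([a, b])
    stat = ((obs - exp) ** 2 / exp).sum()
    p_hand = stats.chi2.sf(stat, 2)
    p = genotype_table_test(list(a), list(b), "chi2")
    assert p == pytest.approx(p_hand, abs=1e-12)
    p_ffh = genotype_table_test(list(a), list(b), "ffh_exact")
    # dense tables: the two tests agree to 2 significant figures
    assert float(f"{p:.2g}") == float(f"{p_ffh:.2g}")


def test_identical_proportions_give_p_one():
    assert genotype_table_test([10, 20, 10], [20, 40, 20], "chi2") == pytest.approx(1.0)


def test_zero_margin_column_dropped_and_df_reduced():
    p = genotype_table_test([10, 20, 0], [20, 10, 0], "chi2")
    expected = stats.chi2_contingency([[10, 20], [20, 10]], correction=False)[1]
    assert p == pytest.approx(expected)


def test_empty_group_rejected():
    with pytest.raises(ValueError):
        genotype_table_test([0, 0, 0], [1, 2, 3])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 10), min_size=6, max_size=6))
def test_ffh_is_valid_probability_and_at_least_point_prob(cells):
    a, b = cells[:3], cells[3:]
    if sum(a) == 0 or sum(b) == 0 or any(x + y == 0 for x, y in zip(a, b)):
        return
    p = genotype_table_test(a, b, "ffh_exact")
    assert 0 < p <= 1
    assert p >= ffh_oracle(a, b) - 1e-9  # never below the enumeration value


# ---------------------------------------------------------------------------
# logistic regression


def irls_oracle(y, X, iters=50):
    """Minimal hand-rolled IRLS for cross-checking fit_logistic."""
    X = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        eta = X @ beta
        mu = 1 / (1 + np.exp(-eta))
        W = mu * (1 - mu)
        z = eta + (y - mu) / W
        beta = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (W * z))
    return beta


def test_fit_logistic_matches_2x2_cross_product():
    # combined carrier table of the 6q25.1 marker: 1186/582 cases, 1083/767 controls
    y = np.concatenate([np.ones(1186 + 582), np.zeros(1083 + 767)])
    x = np.concatenate([np.ones(1186), np.zeros(582), np.ones(1083), np.zeros(767)])
    fit = fit_logistic(y, pd.DataFrame({"carrier": x}))
    or_, *_ = fit.or_ci("carrier")
    assert or_ == pytest.approx((1186 * 767) / (582 * 1083), rel=1e-6)


def test_fit_logistic_matches_hand_irls_on_random_designs():
    rng = np.random.default_rng(3)
    for _ in range(5):
        X = rng.normal(size=(200, 3))
        beta_true = rng.normal(scale=0.5, size=3)
        y = (rng.random(200) < 1 / (1 + np.exp(-(X @ beta_true)))).astype(float)
        fit = fit_logistic(y, pd.DataFrame(X, columns=list("abc")))
        ref = irls_oracle(y, X)
        assert np.allclose(fit.coef, ref, atol=1e-6)


def test_fit_logistic_rescaling_compensates_in_beta():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(300, 2))
    y = (rng.random(300) < 0.4).astype(float)
    fit1 = fit_logistic(y, pd.DataFrame(X, columns=["a", "b"]))
    fit2 = fit_logistic(y, pd.DataFrame(X * [10.0, 0.1], columns=["a", "b"]))
    assert fit2.coef[1] == pytest.approx(fit1.coef[1] / 10.0, rel=1e-6)
    assert fit2.coef[2] == pytest.approx(fit1.coef[2] * 10.0, rel=1e-6)


def test_fit_logistic_detects_separation():
    y = np.array([0.0] * 10 + [1.0] * 10)
    x = np.array([0.0] * 10 + [1.0] * 10)
    with pytest.raises(SeparationError):
        fit_logistic(y, pd.DataFrame({"x": x}))


def test_fit_logistic_null_coefficients_near_zero():
    rng = np.random.default_rng(5)
    x = rng.normal(size=2000)
    y = (rng.random(2000) < 0.5).astype(float)
    fit = fit_logistic(y, pd.DataFrame({"x": x}))
    assert abs(fit.coef[1]) < 3 * fit.se[1] + 0.15


# ---------------------------------------------------------------------------
# snp_association and the two-stage workflow


def test_dominant_association_without_covariates_equals_closed_form(panel):
    snp = panel[3]  # the 6q25.1 marker
    combined_cases = GenotypeCounts(582, 873, 313)   # testing + validation
    combined_controls = GenotypeCounts(767, 836, 247)
    ds = dataset_from_counts(snp, combined_cases, combined_controls)
    res = snp_association(ds, snp, "dominant", (), "combined")
    carriers_case = 873 + 313
    carriers_ctrl = 836 + 247
    expected = (carriers_case * 767) / (582 * carriers_ctrl)
    assert res.or_point == pytest.approx(expected, rel=1e-6)
    assert res.ci_low <= res.or_point <= res.ci_high


def test_genotype_coding_returns_het_and_hom_contrasts(panel):
    snp = panel[3]
    tc = GENOTYPE_COUNTS[snp.snp_id]["testing"]
    ds = dataset_from_counts(snp, tc["case"], tc["control"])
    res = snp_association(ds, snp, "genotype", (), "combined")
    assert len(res) == 2
    # hom-minor contrast equals its 2x2 cross-product (ref = hom-major)
    expected = (158 * 387) / (290 * 110)
    assert res[1].or_point == pytest.approx(expected, rel=1e-6)


def test_two_stage_screen_alpha_extremes(study):
    testing = study.stratum("testing")
    assert two_stage_screen(testing, study.panel, alpha=1e-12) == []
    assert len(two_stage_screen(testing, study.panel, alpha=0.9999)) == 5


def test_screening_rule_on_published_pvalues_selects_the_five_markers():
    chosen = select_markers(SCREENING_PVALUES, alpha=0.05)
    assert set(chosen) == set(VALIDATED_SNP_IDS)
    assert select_markers(SCREENING_PVALUES, alpha=0.0) == []
    assert len(select_markers(SCREENING_PVALUES, alpha=1.0)) == 15


def test_covariate_design_expansion():
    df = pd.DataFrame(
        {
            "age": [40.0, 60.0],
            "menarche": ["early", "late"],
            "menopause": ["pre", "post"],
            "first_birth": ["late", "early"],
        }
    )
    design = covariate_design(df, ("age", "menarche", "menopause", "first_birth"))
    assert list(design.columns) == [
        "age",
        "menarche_early",
        "menarche_normal",
        "menopause_post",
        "first_birth_late",
    ]
    assert design.iloc[0].tolist() == [40.0, 1.0, 0.0, 0.0, 1.0]
    assert design.iloc[1].tolist() == [60.0, 0.0, 0.0, 1.0, 0.0]


# ---------------------------------------------------------------------------
# baseline comparisons


def test_compare_baseline_identical_samples_p_one():
    x = [1.0, 2.0, 3.0, 4.0]
    assert compare_baseline(x, x, "continuous") == pytest.approx(1.0)


def test_compare_baseline_distinguishes_shifted_normals():
    rng = np.random.default_rng(6)
    a = rng.normal(0, 1, 1000)
    b = rng.normal(1, 1, 1000)
    assert compare_baseline(a, b, "continuous") < 1e-10


def test_compare_baseline_2x2_equals_classic_fisher():
    cases = ["yes"] * 12 + ["no"] * 5
    controls = ["yes"] * 4 + ["no"] * 11
    p = compare_baseline(cases, controls, "categorical")
    expected = stats.fisher_exact([[12, 5], [4, 11]], alternative="two-sided")[1]
    assert p == pytest.approx(expected, rel=1e-9)


def test_compare_baseline_single_category_errors():
    with pytest.raises(ValueError):
        compare_baseline(["a", "a"], ["a"], "categorical")
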