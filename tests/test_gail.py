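"""Modified Gail chain: RR conversion, population normalisation, the
piecewise-hazard projection against a quadrature oracle, classification."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from bcrisk.datatypes import GenotypeCounts, HazardBand, HazardSchedule
from bcrisk.gail import (
    build_rr_tables,
    classify_high_risk,
    cohort_absolute_risk,
    combined_relative_risk,
    genotype_rr_from_allelic_or,
    population_normalize,
    project_absolute_risk,
)
from bcrisk.risk import bin_counts, count_risk_alleles
from bcrisk.studydata import (
    COMBINED_ADDITIVE_OR,
    clinical_crude_ors,
    synthetic_hazard_schedule,
)


# ---------------------------------------------------------------------------
# relative-risk construction


@pytest.mark.parametrize(
    "or_,expected",
    [(1.0, (1, 1, 1)), (1.33, (1, 1.33, 1.7689)), (0.8, (1, 0.8, 0.64))],
)
def test_genotype_rr_multiplicative(or_, expected):
    assert genotype_rr_from_allelic_or(or_) == pytest.approx(expected)
    with pytest.raises(ValueError):
        genotype_rr_from_allelic_or(0.0)


def test_population_normalize_against_weighted_average_oracle():
    # pooled control genotypes of the 6q25.1 marker: 767/836/247 of 1850
    freqs = {0: 767 / 1850, 1: 836 / 1850, 2: 247 / 1850}
    rr = dict(zip((0, 1, 2), genotype_rr_from_allelic_or(1.33)))
    mean_rr = sum(freqs[g] * rr[g] for g in rr)
    assert mean_rr == pytest.approx(1.2518, abs=2e-4)
    r = population_normalize(rr, freqs)
    assert r[0] == pytest.approx(0.7988, abs=2e-4)
    assert r[1] == pytest.approx(1.0624, abs=2e-4)
    assert r[2] == pytest.approx(1.4131, abs=2e-4)
    assert sum(freqs[g] * r[g] for g in r) == pytest.approx(1.0, abs=1e-10)


def test_population_normalize_trivials_and_errors():
    assert population_normalize({0: 1.0, 1: 1.0}, {0: 0.3, 1: 0.7}) == {0: 1.0, 1: 1.0}
    assert population_normalize({0: 1.0, 1: 3.0}, {0: 0.5, 1: 0.5}) == {0: 0.5, 1: 1.5}
    with pytest.raises(ValueError, match="sum"):
        population_normalize({0: 1.0, 1: 2.0}, {0: 0.5, 1: 0.6})


def test_rr_tables_average_to_one_for_every_factor(study):
    tables = build_rr_tables(study, COMBINED_ADDITIVE_OR, clinical_crude_ors())
    assert set(tables) == set(COMBINED_ADDITIVE_OR) | {"menarche", "first_birth"}
    for table in tables.values():
        mean = sum(table.level_freqs[l] * table.r_by_level[l] for l in table.r_by_level)
        assert mean == pytest.approx(1.0, abs=1e-10)


def test_combined_rr_product_oracle(study):
    tables = build_rr_tables(study, COMBINED_ADDITIVE_OR, clinical_crude_ors())
    rr = combined_relative_risk(study, tables)
    row = study.subjects.dropna(subset=study.snp_ids).iloc[0]
    expected = 1.0
    for sid in study.snp_ids:
        expected *= tables[sid].r_by_level[row[sid]]
    expected *= tables["menarche"].r_by_level[row["menarche"]]
    expected *= tables["first_birth"].r_by_level[row["first_birth"]]
    assert rr.loc[row.name] == pytest.approx(expected, rel=1e-12)


def test_population_mean_combined_rr_near_one(cohort):
    tables = build_rr_tables(cohort, COMBINED_ADDITIVE_OR, clinical_crude_ors())
    rr = combined_relative_risk(cohort, tables)
    # independent factors, each averaging to 1 in controls; cohort mean ~ 1
    assert rr.mean() == pytest.approx(1.0, abs=0.05)


# ---------------------------------------------------------------------------
# absolute-risk projection


def flat_schedule(h1, h2, start=20.0, end=85.0):
    return HazardSchedule((HazardBand(start, end, h1, h2),))


def ar_quadrature_oracle(r, schedule, age_start=20.0, age_end=85.0):
    """Numerically integrate r*h1(t) * S(t) over the span."""

    def h1(t):
        for b in schedule.bands:
            if b.age_start <= t < b.age_end:
                return b.incidence
        return 0.0

    def h2(t):
        for b in schedule.bands:
            if b.age_start <= t < b.age_end:
                return b.mortality
        return 0.0

    def cumhaz(t):
        total = 0.0
        for b in schedule.bands:
            lo, hi = max(b.age_start, age_start), min(b.age_end, t)
            if hi > lo:
                total += (r * b.incidence + b.mortality) * (hi - lo)
        return total

    total = 0.0
    for b in schedule.bands:
        lo, hi = max(b.age_start, age_start), min(b.age_end, age_end)
        if hi > lo:
            val, _ = quad(
                lambda t: r * h1(t) * np.exp(-cumhaz(t)), lo, hi, epsabs=1e-12
            )
            total += val
    return total


def test_projection_closed_form_no_competing_mortality():
    ar = project_absolute_risk(1.0, flat_schedule(0.01, 0.0))
    assert ar == pytest.approx(1 - np.exp(-0.65), abs=1e-12)


def test_projection_zero_incidence_gives_zero():
    assert project_absolute_risk(2.0, flat_schedule(0.0, 0.02)) == 0.0


def test_projection_agrees_with_quadrature_oracle():
    sched = synthetic_hazard_schedule()
    for r in (0.3, 1.0, 2.7):
        ar = project_absolute_risk(r, sched)
        assert ar == pytest.approx(ar_quadrature_oracle(r, sched), abs=1e-8)


def test_projection_partial_span_and_coverage_errors():
    sched = synthetic_hazard_schedule()
    ar_mid = project_absolute_risk(1.0, sched, age_start=42.5, age_end=60.0)
    assert ar_mid == pytest.approx(
        ar_quadrature_oracle(1.0, sched, 42.5, 60.0), abs=1e-8
    )
    with pytest.raises(ValueError, match="covers"):
        project_absolute_risk(1.0, sched, age_start=10, age_end=60)
    with pytest.raises(ValueError):
        project_absolute_risk(-1.0, sched)


def test_projection_monotone_in_r_and_decreasing_in_mortality():
    sched = synthetic_hazard_schedule()
    rs = np.linspace(0.2, 5.0, 30)
    ars = project_absolute_risk(rs, sched)
    assert np.all(np.diff(ars) > 0)
    low_mort = flat_schedule(0.002, 0.001)
    high_mort = flat_schedule(0.002, 0.05)
    assert project_absolute_risk(1.0, high_mort) < project_absolute_risk(1.0, low_mort)


def test_projection_low_hazard_linear_limit():
    sched = flat_schedule(1e-5, 1e-5)
    r = 1.4
    ar = project_absolute_risk(r, sched)
    linear = r * 1e-5 * 65
    assert ar == pytest.approx(linear, rel=0.01)


# ---------------------------------------------------------------------------
# cohort-level behaviour and classification


def test_median_rr_and_ar_increase_over_allele_bins(cohort):
    tables = build_rr_tables(cohort, COMBINED_ADDITIVE_OR, clinical_crude_ors())
    res = cohort_absolute_risk(cohort, tables, synthetic_hazard_schedule())
    bins, _ = bin_counts(count_risk_alleles(cohort), first_upper=1, last_lower=6)
    med = res.assign(b=bins).groupby("b")[["combined_rr", "absolute_risk"]].median()
    assert med["combined_rr"].is_monotonic_increasing
    assert med["absolute_risk"].is_monotonic_increasing
    assert med["combined_rr"].iloc[0] < 1 < med["combined_rr"].iloc[-1]


def test_classify_high_risk_thresholds():
    ars = pd.Series([0.05, 0.06, 0.07, 0.08, 0.2])
    flags, thr = classify_high_risk(ars, 2.0)
    assert thr == pytest.approx(0.14)
    assert flags.tolist() == [False, False, False, False, True]
    flags, thr = classify_high_risk(ars, 3.0)
    assert thr == pytest.approx(0.21)
    all_equal = pd.Series([0.07] * 5)
    flags, _ = classify_high_risk(all_equal, 1.0)
    assert flags.all()
    with pytest.raises(ValueError):
        classify_high_risk(ars, 0.0)
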