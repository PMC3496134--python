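"""Counting vs OR-weighted risk models on a simulated study.

The counting model sums risk alleles (0-10) plus one point each for early
menarche and late first birth; the weighted model sums dosage * log(OR)
and is grouped by its quartiles among controls. Grouped odds ratios show
the dose-response pattern.
"""

from bcrisk import (
    bin_counts,
    build_risk_score,
    count_risk_factors,
    default_config,
    grouped_or_analysis,
    quartile_groups,
    score_subjects,
    simulate_two_stage_study,
)
from bcrisk.studydata import COMBINED_ADDITIVE_OR, clinical_crude_ors

study = simulate_two_stage_study(default_config(seed=42))

# counting model: risk-factor bins 0-2, 3, 4, 5, 6, >=7
factor_counts = count_risk_factors(study)
bins, labels = bin_counts(factor_counts, first_upper=2, last_lower=7)
counting = grouped_or_analysis(bins, study, ("age", "menopause"), labels)

# weighted model: published ORs as weights, control-quartile groups
model = build_risk_score(COMBINED_ADDITIVE_OR, clinical_crude_ors())
scores = score_subjects(model, study, include_clinical=True)
groups = quartile_groups(scores, scores[~study.case_mask])
weighted = grouped_or_analysis(groups, study, ("age", "menopause"),
                               ["<Q25", "Q25-Q50", "Q50-Q75", ">=Q75"])

for name, res in (("risk-factor counting", counting), ("weighted score quartiles", weighted)):
    print(f"\n{name} (adjusted for age, menopausal status):")
    print(f"  {'group':<10} {'cases':>6} {'controls':>9} {'OR':>6} {'95% CI':>16}")
    for i, lab in enumerate(res.labels):
        ci = f"({res.ci_low[i]:.2f}-{res.ci_high[i]:.2f})" if i else "(ref.)"
        print(f"  {lab:<10} {res.case_counts[i]:>6} {res.control_counts[i]:>9} "
              f"{res.or_point[i]:>6.2f} {ci:>16}")
    print(f"  P for trend: {res.trend_p:.2e}")

print(
    "\nOdds ratios rise monotonically across groups in both models — the "
    "dose-response the cumulative-risk construction is designed to show."
)
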