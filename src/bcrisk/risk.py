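"""Cumulative OR-based risk models: counting and OR-weighted scoring.

Two ways of combining validated markers and clinical factors into a single
risk measure. The counting model treats every risk allele/factor equally:
the sum of risk-allele dosages over the panel (0-10 for five SNPs), plus
one point each for early menarche (< 15 y) and late first live birth
(>= 25 y). The weighted model is the log-odds score sum(dosage * log OR)
(+ category log-ORs), grouped by its quartiles among controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import covariate_design, fit_logistic
from .datatypes import SnpDef, StudyDataset

logger = logging.getLogger(__name__)

__all__ = [
    "RiskScoreModel",
    "GroupedRiskResult",
    "count_risk_alleles",
    "count_risk_factors",
    "bin_counts",
    "build_risk_score",
    "score_subjects",
    "quartile_groups",
    "grouped_or_analysis",
]


def _risk_dosage(dataset: StudyDataset, snp: SnpDef) -> pd.Series:
    """Dosage of the designated risk allele (flips when risk = major)."""
    d = dataset.subjects[snp.snp_id].astype(float)
    return d if snp.risk_is_minor else 2.0 - d


def count_risk_alleles(dataset: StudyDataset, panel: Sequence[SnpDef] | None = None) -> pd.Series:
    """Per-subject risk-allele count over the panel (NaN if any genotype missing)."""
    panel = list(dataset.panel if panel is None else panel)
    total = sum(_risk_dosage(dataset, snp) for snp in panel)
    return total


def count_risk_factors(
    dataset: StudyDataset,
    panel: Sequence[SnpDef] | None = None,
    menarche_ordinal: bool = False,
) -> pd.Series:
    """Risk-allele count plus clinical risk-factor points.

    Default: +1 for early menarche and +1 for late first birth (range 0-12
    for five SNPs). With ``menarche_ordinal`` the menarche contribution is
    graded 2/1/0 for early/normal/late instead of the binary indicator.
    """
    alleles = count_risk_alleles(dataset, panel)
    men = dataset.subjects["menarche"].replace("", np.nan)
    fb = dataset.subjects["first_birth"].replace("", np.nan)
    if menarche_ordinal:
        men_pts = men.map({"early": 2.0, "normal": 1.0, "late": 0.0})
    else:
        men_pts = men.map({"early": 1.0, "normal": 0.0, "late": 0.0})
    fb_pts = fb.map({"late": 1.0, "early": 0.0})
    return alleles + men_pts + fb_pts


def bin_counts(
    counts: pd.Series, first_upper: int, last_lower: int
) -> tuple[pd.Series, list[str]]:
    """Group integer counts into ordinal bins [0..first_upper], single values,
    and [last_lower..inf), returning (bin index per subject, bin labels)."""
    if last_lower <= first_upper:
        raise ValueError("last_lower must exceed first_upper")
    labels = [f"0-{first_upper}" if first_upper > 0 else "0"]
    labels += [str(v) for v in range(first_upper + 1, last_lower)]
    labels += [f">={last_lower}"]
    idx = (counts - first_upper).clip(lower=0).clip(upper=last_lower - first_upper)
    return idx, labels


@dataclass
class RiskScoreModel:
    """Log-OR weights per SNP and per clinical category, with control quartiles."""

    snp_weights: dict[str, float]
    clinical_weights: dict[str, dict[str, float]] = field(default_factory=dict)
    quartile_cutpoints: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        for w in self.snp_weights.values():
            if not np.isfinite(w):
                raise ValueError("non-finite SNP weight")
        if self.quartile_cutpoints is not None:
            q = self.quartile_cutpoints
            if not (q[0] <= q[1] <= q[2]):
                raise ValueError("quartile cutpoints must be non-decreasing")


def build_risk_score(
    snp_ors: Mapping[str, float],
    clinical_ors: Mapping[str, Mapping[str, float]] | None = None,
) -> RiskScoreModel:
    """Turn per-allele and per-category odds ratios into log-OR weights.

    ``snp_ors`` maps snp_id to the additive (per minor allele) OR;
    ``clinical_ors`` maps factor to {level: OR vs reference} (reference
    level OR = 1 gives weight 0).
    """
    for sid, or_ in snp_ors.items():
        if or_ <= 0:
            raise ValueError(f"{sid}: OR must be positive")
    snp_w = {sid: float(np.log(or_)) for sid, or_ in snp_ors.items()}
    clin_w: dict[str, dict[str, float]] = {}
    for factor, levels in (clinical_ors or {}).items():
        for lvl, or_ in levels.items():
            if or_ <= 0:
                raise ValueError(f"{factor}/{lvl}: OR must be positive")
        clin_w[factor] = {lvl: float(np.log(or_)) for lvl, or_ in levels.items()}
    return RiskScoreModel(snp_weights=snp_w, clinical_weights=clin_w)


def score_subjects(
    model: RiskScoreModel, dataset: StudyDataset, include_clinical: bool = False
) -> pd.Series:
    """Per-subject weighted log-odds score; NaN where any needed input is missing."""
    score = pd.Series(0.0, index=dataset.subjects.index)
    for sid, w in model.snp_weights.items():
        snp = dataset.snp(sid)
        score = score + _risk_dosage(dataset, snp) * w
    if include_clinical:
        for factor, weights in model.clinical_weights.items():
            lvl = dataset.subjects[factor].replace("", np.nan)
            score = score + lvl.map(weights)
    n_excluded = int(score.isna().sum())
    if n_excluded:
        logger.info("score_subjects: %d subject(s) excluded for missing data", n_excluded)
    return score


def quartile_groups(
    scores: pd.Series | np.ndarray, control_scores: pd.Series | np.ndarray
) -> pd.Series:
    """Quartile group (0-3) of each score relative to the control distribution.

    Cutpoints are the control 25th/50th/75th percentiles under the
    linear-interpolation definition; a score equal to a cutpoint joins the
    upper group. NaN scores stay NaN.
    """
    ctrl = np.asarray(control_scores, dtype=float)
    ctrl = ctrl[~np.isnan(ctrl)]
    if len(np.unique(ctrl)) < 4:
        raise ValueError("need at least 4 distinct control scores for quartiles")
    cuts = np.percentile(ctrl, [25, 50, 75])
    s = pd.Series(np.asarray(scores, dtype=float),
                  index=scores.index if isinstance(scores, pd.Series) else None)
    groups = pd.Series(
        np.searchsorted(cuts, s.to_numpy(), side="right").astype(float), index=s.index
    )
    groups[s.isna()] = np.nan
    return groups


@dataclass
class GroupedRiskResult:
    """Per-group case/control counts and adjusted ORs vs the lowest group."""

    labels: list[str]
    case_counts: list[int]
    control_counts: list[int]
    or_point: list[float]  # reference group = 1.0
    ci_low: list[float]
    ci_high: list[float]
    p_value: list[float]  # reference group = NaN
    trend_p: float
    covariates: list[str] = field(default_factory=list)


def grouped_or_analysis(
    groups: pd.Series,
    dataset: StudyDataset,
    covariates: Sequence[str] = ("age", "menopause"),
    labels: Sequence[str] | None = None,
) -> GroupedRiskResult:
    """Adjusted odds ratios across ordinal risk groups, plus a trend test.

    Groups enter as indicators against the lowest group; the trend p-value
    refits with the group index as a single ordinal covariate. Empty groups
    are collapsed into their lower neighbour (logged). The default
    adjustment (age, menopausal status) omits menarche/first-birth for use
    with scores that already contain them; pass the full covariate list
    when the score is genetic-only.
    """
    sub = dataset.subjects
    g = pd.Series(groups, index=sub.index).astype(float)
    cov = covariate_design(sub, covariates)
    keep = g.notna() & cov.notna().all(axis=1)
    g, cov, sub = g[keep], cov[keep], sub[keep]
    y = (sub["status"] == "case").astype(float)

    present = sorted(g.unique())
    # collapse empty-in-either-status groups downward
    relabel = {}
    kept_levels: list[float] = []
    for lvl in present:
        mask = g == lvl
        if y[mask].nunique() < 2 and kept_levels:
            relabel[lvl] = kept_levels[-1]
            logger.info("grouped_or_analysis: collapsing group %s into %s", lvl, kept_levels[-1])
        else:
            kept_levels.append(lvl)
    if relabel:
        g = g.replace(relabel)
        present = sorted(g.unique())

    if labels is None:
        labels = [str(int(lvl)) for lvl in present]
    else:
        labels = [labels[int(lvl)] for lvl in present]

    design = pd.DataFrame(
        {f"grp_{int(lvl)}": (g == lvl).astype(float) for lvl in present[1:]},
        index=g.index,
    )
    fit = fit_logistic(y.to_numpy(), pd.concat([design, cov], axis=1))
    ors, los, his, ps = [1.0], [1.0], [1.0], [np.nan]
    for lvl in present[1:]:
        or_, lo, hi, p = fit.or_ci(f"grp_{int(lvl)}")
        ors.append(or_)
        los.append(lo)
        his.append(hi)
        ps.append(p)

    trend_design = pd.concat([pd.DataFrame({"group_index": g}), cov], axis=1)
    trend_fit = fit_logistic(y.to_numpy(), trend_design)
    trend_p = trend_fit.or_ci("group_index")[3]

    case_counts = [int(((g == lvl) & (y == 1)).sum()) for lvl in present]
    control_counts = [int(((g == lvl) & (y == 0)).sum()) for lvl in present]
    return GroupedRiskResult(
        labels=list(labels),
        case_counts=case_counts,
        control_counts=control_counts,
        or_point=ors,
        ci_low=los,
        ci_high=his,
        p_value=ps,
        trend_p=trend_p,
        covariates=list(covariates),
    )
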