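"""Case-control association statistics for biallelic markers.

Implements the screening stage of a two-stage replication design: the exact
conditional Hardy-Weinberg test among controls, the Fisher-Freeman-Halton
exact test (and Pearson chi-square) on 2xk genotype-by-status tables,
covariate-adjusted logistic odds ratios under additive / dominant /
recessive / genotype codings, and baseline-characteristic comparisons.

Exact tests use probability ordering: the two-sided p-value sums the null
probabilities of all outcomes no more probable than the observed one, with
a relative tie tolerance of 1e-7 to keep the "no more probable" comparison
stable in floating point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln

from .datatypes import GenotypeCounts, SnpDef, StudyDataset

__all__ = [
    "AssociationResult",
    "LogisticFit",
    "SeparationError",
    "hwe_exact_test",
    "genotype_table_test",
    "fit_logistic",
    "snp_association",
    "two_stage_screen",
    "select_markers",
    "validate_markers",
    "compare_baseline",
    "DEFAULT_COVARIATES",
]

#: Adjustment set used throughout the study: age, age at menarche,
#: menopausal status and age at first live birth.
DEFAULT_COVARIATES = ("age", "menarche", "menopause", "first_birth")

_TIE_RTOL = 1e-7


class SeparationError(RuntimeError):
    """Raised when a logistic fit shows complete or quasi-complete separation."""


# ---------------------------------------------------------------------------
# exact tests


def hwe_exact_test(counts: GenotypeCounts) -> float:
    """Exact conditional test of Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and sums, over all attainable
    heterozygote counts (same parity as the minor-allele count), the
    probabilities of those no larger than the observed one. Returns the
    two-sided p-value, capped at 1.
    """
    n = counts.total
    if n == 0:
        raise ValueError("empty genotype table")
    n_minor = counts.minor_allele_count
    hets = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)

    def logprob(h: np.ndarray) -> np.ndarray:
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        return (
            gammaln(n + 1)
            - gammaln(hom_maj + 1)
            - gammaln(h + 1)
            - gammaln(hom_min + 1)
            + h * np.log(2)
            + gammaln(n_minor + 1)
            + gammaln(2 * n - n_minor + 1)
            - gammaln(2 * n + 1)
        )

    probs = np.exp(logprob(hets))
    p_obs = np.exp(logprob(np.array([counts.n_het])))[0]
    p = probs[probs <= p_obs * (1 + _TIE_RTOL)].sum()
    return float(min(1.0, p))


def _ffh_exact_2xk(row_a: np.ndarray, row_b: np.ndarray) -> float:
    """Fisher-Freeman-Halton exact p for a 2xk table by full enumeration.

    Enumerates every table with the observed margins (vectorised over the
    second-to-last cell, python loops over the remaining free cells), so it
    is intended for k <= 4; the 2x3 genotype tables of a thousand-subject
    study enumerate in well under a second.
    """
    cols = row_a + row_b
    r1 = int(row_a.sum())
    n = int(cols.sum())
    const = (
        gammaln(r1 + 1)
        + gammaln(n - r1 + 1)
        + gammaln(cols + 1).sum()
        - gammaln(n + 1)
    )

    def logp(cells: np.ndarray) -> np.ndarray:
        return const - (
            gammaln(cells + 1).sum(axis=-1)
            + gammaln(cols - cells + 1).sum(axis=-1)
        )

    p_obs = np.exp(logp(row_a.astype(float)))
    k = len(cols)
    total = 0.0

    def recurse(prefix: list[int], used: int, idx: int) -> None:
        nonlocal total
        if idx == k - 2:
            # vectorise the last two cells
            last_but = np.arange(0, min(cols[k - 2], r1 - used) + 1)
            last = r1 - used - last_but
            ok = last <= cols[k - 1]
            if not ok.any():
                return
            cells = np.zeros((ok.sum(), k))
            cells[:, : k - 2] = prefix
            cells[:, k - 2] = last_but[ok]
            cells[:, k - 1] = last[ok]
            p = np.exp(logp(cells))
            total += p[p <= p_obs * (1 + _TIE_RTOL)].sum()
            return
        for v in range(0, min(cols[idx], r1 - used) + 1):
            recurse(prefix + [v], used + v, idx + 1)

    if k < 2:
        raise ValueError("need at least two categories")
    recurse([], 0, 0)
    return float(min(1.0, total))


def genotype_table_test(
    case_counts: GenotypeCounts | Sequence[int],
    control_counts: GenotypeCounts | Sequence[int],
    method: Literal["ffh_exact", "chi2"] = "ffh_exact",
) -> float:
    """Two-sided test of genotype-frequency difference on a 2x3 table.

    ``ffh_exact`` is the Fisher-Freeman-Halton exact test (probability
    ordering over all tables with the observed margins). ``chi2`` is the
    Pearson statistic on 2 df; columns with a zero margin are dropped and
    the degrees of freedom reduced accordingly.
    """
    a = (
        case_counts.as_array()
        if isinstance(case_counts, GenotypeCounts)
        else np.asarray(case_counts)
    )
    b = (
        control_counts.as_array()
        if isinstance(control_counts, GenotypeCounts)
        else np.asarray(control_counts)
    )
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("both groups must be non-empty")
    keep = (a + b) > 0
    a, b = a[keep], b[keep]
    if len(a) < 2:
        raise ValueError("table has no residual degrees of freedom")
    if method == "ffh_exact":
        return _ffh_exact_2xk(a, b)
    if method == "chi2":
        stat, p, _, _ = stats.chi2_contingency(np.vstack([a, b]), correction=False)
        return float(p)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# logistic regression


@dataclass
class LogisticFit:
    """A fitted logistic model: coefficient table and covariance."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    n_used: int
    converged: bool

    def or_ci(self, name: str, z: float = 1.96) -> tuple[float, float, float, float]:
        """(OR, ci_low, ci_high, wald_p) for one coefficient."""
        i = self.names.index(name)
        b, s = self.coef[i], self.se[i]
        p = 2 * stats.norm.sf(abs(b / s)) if s > 0 else 1.0
        return float(np.exp(b)), float(np.exp(b - z * s)), float(np.exp(b + z * s)), float(p)


def fit_logistic(outcome: np.ndarray, design: pd.DataFrame) -> LogisticFit:
    """Maximum-likelihood logistic fit (IRLS) with an intercept prepended.

    Raises :class:`SeparationError` when any non-intercept coefficient
    diverges past |beta| = 15 (complete or quasi-complete separation) and
    ``RuntimeError`` on non-convergence within 100 iterations.
    """
    y = np.asarray(outcome, dtype=float)
    X = sm.add_constant(design.astype(float), has_constant="add")
    if len(y) <= X.shape[1]:
        raise ValueError("more parameters than observations")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=100)
    coef = np.asarray(res.params)
    names = list(X.columns)
    for name, b in zip(names, coef):
        if name != "const" and abs(b) > 15:
            raise SeparationError(f"separation detected on predictor {name!r}")
    if not res.converged:
        raise RuntimeError("logistic fit did not converge in 100 iterations")
    return LogisticFit(
        names=names,
        coef=coef,
        se=np.asarray(res.bse),
        cov=np.asarray(res.cov_params()),
        n_used=len(y),
        converged=bool(res.converged),
    )


# ---------------------------------------------------------------------------
# genetic codings and covariate design


def _genetic_columns(dosage: pd.Series, coding: str, snp_id: str) -> pd.DataFrame:
    d = dosage.astype(float)
    if d.nunique(dropna=True) < 2:
        raise ValueError(f"{snp_id}: monomorphic in this stratum; {coding} coding undefined")
    if coding == "additive":
        return pd.DataFrame({snp_id: d})
    if coding == "dominant":
        return pd.DataFrame({snp_id: (d >= 1).astype(float)})
    if coding == "recessive":
        return pd.DataFrame({snp_id: (d == 2).astype(float)})
    if coding == "genotype":
        return pd.DataFrame(
            {f"{snp_id}_het": (d == 1).astype(float), f"{snp_id}_hom": (d == 2).astype(float)}
        )
    raise ValueError(f"unknown coding {coding!r}")


def covariate_design(subjects: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Expand clinical covariates into model columns.

    age -> continuous; menarche -> early/normal indicators (reference:
    late); menopause -> postmenopausal indicator; first_birth -> late
    (>= 25 y) indicator. Missing values are left as NaN for the caller's
    complete-case filter.
    """
    cols: dict[str, pd.Series] = {}
    for cov in covariates:
        if cov == "age":
            cols["age"] = subjects["age"].astype(float)
        elif cov == "menarche":
            m = subjects["menarche"].replace("", np.nan)
            cols["menarche_early"] = (m == "early").astype(float).where(m.notna())
            cols["menarche_normal"] = (m == "normal").astype(float).where(m.notna())
        elif cov == "menopause":
            m = subjects["menopause"].replace("", np.nan)
            cols["menopause_post"] = (m == "post").astype(float).where(m.notna())
        elif cov == "first_birth":
            m = subjects["first_birth"].replace("", np.nan)
            cols["first_birth_late"] = (m == "late").astype(float).where(m.notna())
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    return pd.DataFrame(cols, index=subjects.index)


@dataclass
class AssociationResult:
    """Per-SNP effect estimate under a stated coding and adjustment."""

    snp_id: str
    coding: str
    stratum: str
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    covariates: list[str] = field(default_factory=list)
    n_used: int = 0
    term: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_point <= self.ci_high):
            raise ValueError("CI does not bracket the point estimate")


def snp_association(
    dataset: StudyDataset,
    snp: SnpDef,
    coding: str = "additive",
    covariates: Sequence[str] = (),
    stratum: str = "combined",
) -> AssociationResult | list[AssociationResult]:
    """Covariate-adjusted logistic odds ratio for one SNP.

    Complete-case on the genotype and every listed covariate. For the
    two-parameter ``genotype`` coding a list of two results (het and
    hom-minor vs hom-major) is returned; the single-parameter codings
    return one result.
    """
    sub = dataset.stratum(stratum).subjects
    gen = _genetic_columns(sub[snp.snp_id], coding, snp.snp_id)
    design = pd.concat([gen, covariate_design(sub, covariates)], axis=1)
    keep = design.notna().all(axis=1)
    design, y = design[keep], (sub["status"] == "case").astype(float)[keep]
    if design.empty:
        raise ValueError(f"no complete cases in stratum {stratum!r}")
    fit = fit_logistic(y.to_numpy(), design)

    def result(term: str) -> AssociationResult:
        or_, lo, hi, p = fit.or_ci(term)
        return AssociationResult(
            snp_id=snp.snp_id,
            coding=coding,
            stratum=stratum,
            or_point=or_,
            ci_low=lo,
            ci_high=hi,
            p_value=p,
            covariates=list(covariates),
            n_used=fit.n_used,
            term=term,
        )

    if coding == "genotype":
        return [result(f"{snp.snp_id}_het"), result(f"{snp.snp_id}_hom")]
    return result(snp.snp_id)


# ---------------------------------------------------------------------------
# two-stage workflow


def two_stage_screen(
    testing: StudyDataset, panel: Sequence[SnpDef], alpha: float = 0.05
) -> list[SnpDef]:
    """Stage-1 screen: keep SNPs whose testing-set exact 2x3 p < alpha."""
    chosen = []
    for snp in panel:
        cases = testing.genotype_counts(snp.snp_id, "case")
        controls = testing.genotype_counts(snp.snp_id, "control")
        if genotype_table_test(cases, controls, "ffh_exact") < alpha:
            chosen.append(snp)
    return chosen


def select_markers(pvalues: Mapping[str, float], alpha: float = 0.05) -> list[str]:
    """Screening rule applied to precomputed per-SNP p-values."""
    return [sid for sid, p in pvalues.items() if p < alpha]


def validate_markers(
    dataset: StudyDataset,
    screened: Sequence[SnpDef],
    alpha: float = 0.05,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    coding: str = "additive",
) -> list[SnpDef]:
    """Stage-2 confirmation of screened markers.

    A marker validates when its validation-stage effect lies on the same
    side of OR = 1 as in the testing stage and the combined-stage adjusted
    p-value is below ``alpha`` — the weakest reading of "consistent
    association with significant combined evidence".
    """
    kept = []
    for snp in screened:
        rt = snp_association(dataset, snp, coding, covariates, "testing")
        rv = snp_association(dataset, snp, coding, covariates, "validation")
        rc = snp_association(dataset, snp, coding, covariates, "combined")
        same_direction = (rt.or_point - 1) * (rv.or_point - 1) >= 0
        if same_direction and rc.p_value < alpha:
            kept.append(snp)
    return kept


# ---------------------------------------------------------------------------
# baseline comparisons


def compare_baseline(
    cases: Sequence, controls: Sequence, kind: Literal["continuous", "categorical"]
) -> float:
    """Case-control comparison of one baseline characteristic.

    Continuous: Student t with pooled variance when an F-test of variance
    equality is non-significant at 0.05, otherwise Welch t'. Categorical:
    Fisher-Freeman-Halton exact test on the 2xk level table.
    """
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both groups must be non-empty")
    if kind == "continuous":
        a = np.asarray(cases, dtype=float)
        b = np.asarray(controls, dtype=float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        va, vb = a.var(ddof=1), b.var(ddof=1)
        f = va / vb if va >= vb else vb / va
        dfn = (len(a) - 1, len(b) - 1) if va >= vb else (len(b) - 1, len(a) - 1)
        p_var = 2 * min(stats.f.sf(f, *dfn), 1 - stats.f.sf(f, *dfn))
        equal_var = p_var >= 0.05
        return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
    if kind == "categorical":
        levels = sorted(set(cases) | set(controls))
        if len(levels) < 2:
            raise ValueError("need at least two categories")
        a = np.array([sum(c == lvl for c in cases) for lvl in levels])
        b = np.array([sum(c == lvl for c in controls) for lvl in levels])
        keep = (a + b) > 0
        return _ffh_exact_2xk(a[keep], b[keep])
    raise ValueError(f"unknown kind {kind!r}")
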