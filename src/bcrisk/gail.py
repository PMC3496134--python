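"""Modified Gail model: absolute risk from odds ratios and registry hazards.

The chain is: per-allele OR -> genotype relative risks (1, OR, OR^2) under
a multiplicative model -> risks relative to the population (rescaled so the
frequency-weighted average over genotypes is exactly 1) -> one combined
relative risk per woman as the product over the five SNPs and the two
clinical factors -> absolute risk over an age span, integrating the
piecewise-constant disease hazard r*h1(t) against competing mortality
h2(t).

Because every factor's population-relative risks average to 1, the
population-average projected hazard equals the registry incidence without
any further attributable-risk deflation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import HazardSchedule, SnpDef, StudyDataset

__all__ = [
    "RelativeRiskTable",
    "genotype_rr_from_allelic_or",
    "population_normalize",
    "build_rr_tables",
    "combined_relative_risk",
    "project_absolute_risk",
    "cohort_absolute_risk",
    "classify_high_risk",
]


def genotype_rr_from_allelic_or(allelic_or: float) -> tuple[float, float, float]:
    """Genotype relative risks (rr0, rr1, rr2) = (1, OR, OR^2)."""
    if allelic_or <= 0:
        raise ValueError("allelic OR must be positive")
    return 1.0, float(allelic_or), float(allelic_or**2)


def population_normalize(
    rr_by_level: Mapping[object, float], level_freqs: Mapping[object, float]
) -> dict[object, float]:
    """Rescale relative risks so their frequency-weighted mean is exactly 1."""
    if set(rr_by_level) != set(level_freqs):
        raise ValueError("rr and frequency maps must share levels")
    freq_sum = sum(level_freqs.values())
    if abs(freq_sum - 1.0) > 1e-8:
        raise ValueError(f"level frequencies sum to {freq_sum}, not 1")
    for lvl, rr in rr_by_level.items():
        if rr <= 0:
            raise ValueError(f"level {lvl!r}: relative risk must be positive")
    mean_rr = sum(level_freqs[lvl] * rr_by_level[lvl] for lvl in rr_by_level)
    r = {lvl: rr / mean_rr for lvl, rr in rr_by_level.items()}
    assert abs(sum(level_freqs[lvl] * r[lvl] for lvl in r) - 1.0) < 1e-10
    return r


@dataclass(frozen=True)
class RelativeRiskTable:
    """Population-relative risks and normalisation frequencies for one factor."""

    factor: str
    r_by_level: dict
    level_freqs: dict

    def __post_init__(self) -> None:
        mean = sum(self.level_freqs[lvl] * self.r_by_level[lvl] for lvl in self.r_by_level)
        if abs(mean - 1.0) > 1e-10:
            raise ValueError(f"{self.factor}: population-relative risks do not average to 1")


def build_rr_tables(
    dataset: StudyDataset,
    snp_ors: Mapping[str, float],
    clinical_ors: Mapping[str, Mapping[str, float]] | None = None,
) -> dict[str, RelativeRiskTable]:
    """Population-relative risk tables for each SNP and clinical factor.

    Normalisation frequencies come from the control sample (the standard
    population stand-in available in a case-control study): genotype
    frequencies of pooled controls for SNPs, category frequencies of
    pooled controls for clinical factors.
    """
    controls = dataset.subjects[dataset.subjects["status"] == "control"]
    tables: dict[str, RelativeRiskTable] = {}
    for sid, or_ in snp_ors.items():
        snp = dataset.snp(sid)
        counts = dataset.genotype_counts(sid, status="control")
        if counts.total == 0:
            raise ValueError(f"{sid}: no genotyped controls for normalisation")
        freqs_minor = {
            0: counts.n_hom_major / counts.total,
            1: counts.n_het / counts.total,
            2: counts.n_hom_minor / counts.total,
        }
        rr_minor_level = dict(zip((0, 1, 2), genotype_rr_from_allelic_or(or_)))
        if not snp.risk_is_minor:
            # OR is per risk allele; re-express on the minor-allele dosage axis
            rr_minor_level = {d: rr_minor_level[2 - d] for d in (0, 1, 2)}
        tables[sid] = RelativeRiskTable(
            sid, population_normalize(rr_minor_level, freqs_minor), freqs_minor
        )
    for factor, levels in (clinical_ors or {}).items():
        obs = controls[factor].replace("", np.nan).dropna()
        if obs.empty:
            raise ValueError(f"{factor}: no control data for normalisation")
        freqs = obs.value_counts(normalize=True).to_dict()
        missing = set(freqs) - set(levels)
        if missing:
            raise ValueError(f"{factor}: no OR supplied for level(s) {sorted(missing)}")
        rr = {lvl: float(levels[lvl]) for lvl in freqs}
        tables[factor] = RelativeRiskTable(factor, population_normalize(rr, freqs), freqs)
    return tables


def combined_relative_risk(
    dataset: StudyDataset, tables: Mapping[str, RelativeRiskTable]
) -> pd.Series:
    """Per-subject product of population-relative risks over all factors.

    Subjects missing any factor level get NaN (complete-case exclusion).
    """
    out = pd.Series(1.0, index=dataset.subjects.index)
    snp_ids = set(dataset.snp_ids)
    for name, table in tables.items():
        if name in snp_ids:
            level = dataset.subjects[name].astype(float)
        else:
            level = dataset.subjects[name].replace("", np.nan)
        out = out * level.map(table.r_by_level)
    return out


def project_absolute_risk(
    r: float | np.ndarray | pd.Series,
    schedule: HazardSchedule,
    age_start: float = 20.0,
    age_end: float = 85.0,
) -> float | np.ndarray | pd.Series:
    """Absolute disease risk over [age_start, age_end) with competing mortality.

    Piecewise-constant-hazard closed form: within each band of width dt
    with disease hazard r*h1 and competing hazard h2, the contribution is
    S * r*h1/(r*h1+h2) * (1 - exp(-(r*h1+h2) dt)), where S is the
    probability of having escaped both causes so far. Vectorised over r.
    """
    if age_start >= age_end:
        raise ValueError("age_start must precede age_end")
    if not schedule.covers(age_start, age_end):
        raise ValueError(
            f"schedule covers [{schedule.age_start}, {schedule.age_end}) but "
            f"[{age_start}, {age_end}) requested"
        )
    rv = np.asarray(r, dtype=float)
    if np.any(rv[~np.isnan(rv)] <= 0):
        raise ValueError("relative risk must be positive")
    ar = np.zeros_like(rv, dtype=float)
    surv = np.ones_like(rv, dtype=float)
    for band in schedule.bands:
        lo = max(band.age_start, age_start)
        hi = min(band.age_end, age_end)
        if hi <= lo:
            continue
        dt = hi - lo
        h1 = rv * band.incidence
        h_tot = h1 + band.mortality
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(h_tot > 0, h1 / np.where(h_tot > 0, h_tot, 1.0), 0.0)
            ar = ar + surv * frac * (1.0 - np.exp(-h_tot * dt))
            surv = surv * np.exp(-h_tot * dt)
    if isinstance(r, pd.Series):
        return pd.Series(ar, index=r.index)
    if np.isscalar(r):
        return float(ar)
    return ar


def cohort_absolute_risk(
    dataset: StudyDataset,
    tables: Mapping[str, RelativeRiskTable],
    schedule: HazardSchedule,
    age_start: float = 20.0,
    age_end: float = 85.0,
) -> pd.DataFrame:
    """Combined relative risk and projected absolute risk for every subject."""
    rr = combined_relative_risk(dataset, tables)
    ar = pd.Series(np.nan, index=rr.index)
    ok = rr.notna()
    ar[ok] = project_absolute_risk(rr[ok], schedule, age_start, age_end)
    return pd.DataFrame(
        {
            "subject_id": dataset.subjects["subject_id"],
            "status": dataset.subjects["status"],
            "combined_rr": rr,
            "absolute_risk": ar,
        }
    )


def classify_high_risk(
    ars: pd.Series | np.ndarray, k: float
) -> tuple[pd.Series | np.ndarray, float]:
    """Flag subjects whose absolute risk reaches k times the cohort median."""
    if k <= 0:
        raise ValueError("multiple k must be positive")
    a = np.asarray(ars, dtype=float)
    valid = a[~np.isnan(a)]
    if valid.size == 0:
        raise ValueError("no absolute risks to classify")
    threshold = float(k * np.median(valid))
    flags = a >= threshold
    if isinstance(ars, pd.Series):
        return pd.Series(flags, index=ars.index), threshold
    return flags, threshold
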