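"""Synthetic two-stage case-control studies with known risk structure.

The generator draws genotypes independently per SNP under Hardy-Weinberg
equilibrium at configured minor allele frequencies, clinical categories
from configured population frequencies, and disease status from a logistic
model whose linear predictor is additive in minor-allele dosage (log
per-allele OR per copy) and in clinical category log-ORs. The intercept is
solved by bisection so the marginal prevalence matches the configured
baseline. Case-control ascertainment then samples fixed numbers of cases
and controls per stage, mirroring the two-stage design (878/900 testing,
914/967 validation by default).

Default parameters are the published study conditions: control MAFs and
combined-stage additive ORs of the five validated markers, control
category frequencies of the two clinical factors, and crude clinical ORs
derived from the published combined counts. Baseline prevalence defaults
to 0.05 — a deliberately low, documented knob (the study never states a
population prevalence), chosen so odds ratios approximate relative risks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .datatypes import SnpDef, StudyDataset
from .studydata import (
    COMBINED_ADDITIVE_OR,
    CONTROL_MAF,
    FIVE_SNP_PANEL,
    clinical_control_freqs,
    clinical_crude_ors,
)

__all__ = [
    "SimulationConfig",
    "default_config",
    "simulate_population",
    "sample_case_control",
    "inject_missingness",
    "simulate_two_stage_study",
]


@dataclass
class SimulationConfig:
    """Parameters of the generating model; see module docstring for defaults."""

    panel: list[SnpDef]
    snp_mafs: list[float]
    snp_allelic_ors: list[float]
    #: {factor: {level: frequency}}; frequencies sum to 1 per factor.
    clinical_category_freqs: dict[str, dict[str, float]]
    #: {factor: {level: OR vs the factor's reference level}}.
    clinical_ors: dict[str, dict[str, float]]
    baseline_prevalence: float = 0.05
    n_cases_ts: int = 878
    n_controls_ts: int = 900
    n_cases_vs: int = 914
    n_controls_vs: int = 967
    call_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.snp_mafs) != len(self.panel) or len(self.snp_allelic_ors) != len(self.panel):
            raise ValueError("snp_mafs and snp_allelic_ors must match the panel length")
        for maf in self.snp_mafs:
            if not 0 < maf <= 0.5:
                raise ValueError(f"MAF {maf} outside (0, 0.5]")
        for or_ in self.snp_allelic_ors:
            if or_ <= 0:
                raise ValueError("allelic ORs must be positive")
        for factor, freqs in self.clinical_category_freqs.items():
            if abs(sum(freqs.values()) - 1.0) > 1e-8:
                raise ValueError(f"{factor}: category frequencies must sum to 1")
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline prevalence must lie in (0, 1)")
        for n in (self.n_cases_ts, self.n_controls_ts, self.n_cases_vs, self.n_controls_vs):
            if n <= 0:
                raise ValueError("stage sample sizes must be positive")
        if not 0 < self.call_rate <= 1:
            raise ValueError("call_rate must lie in (0, 1]")


def default_config(seed: int = 0) -> SimulationConfig:
    """The published-study conditions as a simulation configuration."""
    return SimulationConfig(
        panel=list(FIVE_SNP_PANEL),
        snp_mafs=[CONTROL_MAF[s.snp_id] for s in FIVE_SNP_PANEL],
        snp_allelic_ors=[COMBINED_ADDITIVE_OR[s.snp_id] for s in FIVE_SNP_PANEL],
        clinical_category_freqs=clinical_control_freqs(),
        clinical_ors=clinical_crude_ors(),
        seed=seed,
    )


def _solve_intercept(lp: np.ndarray, prevalence: float) -> float:
    """Bisection for the intercept making mean expit(a + lp) = prevalence."""
    lo, hi = -40.0, 40.0
    f = lambda a: float(expit(a + lp).mean() - prevalence)
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(f"prevalence {prevalence} unattainable under this model")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
        if abs(f(mid)) < 1e-9:
            break
    return 0.5 * (lo + hi)


def simulate_population(
    config: SimulationConfig, n: int, seed: int | None = None
) -> StudyDataset:
    """Draw a cross-sectional population of size ``n`` from the generating model.

    The returned dataset carries two true-risk annotation columns:
    ``true_lp`` (the linear predictor excluding the intercept) and
    ``true_prob`` (the individual disease probability).
    """
    if n <= 0:
        raise ValueError("population size must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    mafs = np.asarray(config.snp_mafs)
    log_ors = np.log(config.snp_allelic_ors)
    genotypes = rng.binomial(2, mafs, size=(n, len(mafs))).astype(float)
    lp = genotypes @ log_ors

    clinical: dict[str, np.ndarray] = {}
    for factor, freqs in config.clinical_category_freqs.items():
        levels = list(freqs)
        draws = rng.choice(len(levels), size=n, p=[freqs[l] for l in levels])
        labels = np.array(levels, dtype=object)[draws]
        clinical[factor] = labels
        factor_lor = np.log([config.clinical_ors[factor][l] for l in levels])
        lp = lp + factor_lor[draws]

    alpha = _solve_intercept(lp, config.baseline_prevalence)
    prob = expit(alpha + lp)
    status = np.where(rng.random(n) < prob, "case", "control")

    age = np.clip(rng.normal(50.0, 11.5, size=n), 25, 85).round(1)
    menopause_age = rng.normal(49.0, 4.2, size=n)
    menopause = np.where(age >= menopause_age, "post", "pre")

    subjects = pd.DataFrame(
        {
            "subject_id": [f"S{i:07d}" for i in range(n)],
            "status": status,
            "stage": "",
            "age": age,
            "menarche": clinical.get("menarche", np.full(n, "", dtype=object)),
            "first_birth": clinical.get("first_birth", np.full(n, "", dtype=object)),
            "menopause": menopause,
        }
    )
    for j, snp in enumerate(config.panel):
        subjects[snp.snp_id] = genotypes[:, j]
    subjects["true_lp"] = lp
    subjects["true_prob"] = prob
    return StudyDataset(list(config.panel), subjects)


def sample_case_control(
    population: StudyDataset,
    n_cases: int,
    n_controls: int,
    seed: int,
    stage: str = "testing",
) -> StudyDataset:
    """Ascertain a case-control sample, uniformly within each status stratum."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("n_cases and n_controls must be positive")
    rng = np.random.default_rng(seed)
    df = population.subjects
    cases = df.index[df["status"] == "case"].to_numpy()
    controls = df.index[df["status"] == "control"].to_numpy()
    if len(cases) < n_cases:
        raise ValueError(f"case pool short by {n_cases - len(cases)}")
    if len(controls) < n_controls:
        raise ValueError(f"control pool short by {n_controls - len(controls)}")
    take = np.concatenate(
        [
            rng.choice(cases, size=n_cases, replace=False),
            rng.choice(controls, size=n_controls, replace=False),
        ]
    )
    sample = df.loc[take].copy()
    sample["stage"] = stage
    return StudyDataset(list(population.panel), sample.reset_index(drop=True))


def inject_missingness(
    dataset: StudyDataset, call_rate: float, seed: int
) -> StudyDataset:
    """Set each genotype independently missing with probability 1 - call_rate."""
    if not 0 < call_rate <= 1:
        raise ValueError("call_rate must lie in (0, 1]")
    if call_rate == 1.0:
        return dataset
    rng = np.random.default_rng(seed)
    df = dataset.subjects.copy()
    for sid in dataset.snp_ids:
        miss = rng.random(len(df)) > call_rate
        col = df[sid].to_numpy(dtype=float, copy=True)
        col[miss] = np.nan
        df[sid] = col
    return StudyDataset(list(dataset.panel), df)


def simulate_two_stage_study(config: SimulationConfig) -> StudyDataset:
    """Simulate the full two-stage study: population, ascertainment, missingness.

    The population pool is sized so both stage samples can be drawn
    (expected case yield plus a 30% margin, grown deterministically if a
    draw still falls short).
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) for s in ss.generate_state(5) % (2**31)]
    need_cases = config.n_cases_ts + config.n_cases_vs
    need_controls = config.n_controls_ts + config.n_controls_vs
    n = int(
        max(
            need_cases / config.baseline_prevalence,
            need_controls / (1 - config.baseline_prevalence),
        )
        * 1.3
    )
    for attempt in range(5):
        pop = simulate_population(config, n, seed=seeds[0] + attempt)
        n_case_pool = pop.n_cases()
        if n_case_pool >= need_cases and pop.n_controls() >= need_controls:
            break
        n *= 2
    else:
        raise RuntimeError("could not draw enough cases/controls")

    testing = sample_case_control(
        pop, config.n_cases_ts, config.n_controls_ts, seeds[1], stage="testing"
    )
    remaining = pop.subjects.drop(
        pop.subjects[pop.subjects["subject_id"].isin(testing.subjects["subject_id"])].index
    )
    validation = sample_case_control(
        StudyDataset(list(config.panel), remaining.reset_index(drop=True)),
        config.n_cases_vs,
        config.n_controls_vs,
        seeds[2],
        stage="validation",
    )
    combined = pd.concat(
        [testing.subjects, validation.subjects], ignore_index=True
    )
    study = StudyDataset(list(config.panel), combined)
    return inject_missingness(study, config.call_rate, seeds[3])
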