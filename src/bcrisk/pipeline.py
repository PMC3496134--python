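"""Config-driven end-to-end orchestration of the full analysis.

Runs the study workflow on either a simulated or a user-supplied dataset:
baseline comparison -> QC/HWE -> two-stage screening and validation ->
combined association -> counting and weighted risk models with grouped
ORs -> absolute-risk projection -> ROC/AUC, DeLong comparison and
cross-validated AUCs. All randomness flows from the single config seed via
``numpy.random.SeedSequence`` spawning; rerunning with the same config is
byte-identical in the machine-readable summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    DEFAULT_COVARIATES,
    compare_baseline,
    hwe_exact_test,
    snp_association,
    two_stage_screen,
    validate_markers,
)
from .datatypes import SnpDef, StudyDataset
from .gail import build_rr_tables, classify_high_risk, cohort_absolute_risk
from .io import qc_summary, read_genotype_table, read_hazard_schedule, write_results
from .risk import (
    bin_counts,
    build_risk_score,
    count_risk_alleles,
    count_risk_factors,
    grouped_or_analysis,
    quartile_groups,
    score_subjects,
)
from .roc import cv_auc, delong_paired_test, roc_analysis
from .simulate import default_config, simulate_two_stage_study
from .studydata import clinical_crude_ors, synthetic_hazard_schedule

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str = "bcrisk_out"
    genotype_table: str | None = None  # None -> simulate
    hazard_schedule: str | None = None  # None -> bundled synthetic schedule
    alpha: float = 0.05
    coding: str = "additive"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    cutoff_multiples: tuple[float, ...] = (2.0, 3.0)
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("covariates", "cutoff_multiples"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _score_model_builder(panel: Sequence[SnpDef], include_clinical: bool):
    """Model builder for cv_auc: refit additive ORs on the training fold."""

    def build(train: StudyDataset):
        snp_ors = {}
        for snp in panel:
            res = snp_association(train, snp, "additive", (), "combined")
            snp_ors[snp.snp_id] = res.or_point
        clin = clinical_crude_ors() if include_clinical else None
        model = build_risk_score(snp_ors, clin)

        def scorer(test: StudyDataset) -> np.ndarray:
            return score_subjects(model, test, include_clinical).to_numpy()

        return scorer

    return build


def _clinical_model_builder():
    def build(train: StudyDataset):
        model = build_risk_score({}, clinical_crude_ors())

        def scorer(test: StudyDataset) -> np.ndarray:
            return score_subjects(model, test, include_clinical=True).to_numpy()

        return scorer

    return build


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, persist result tables, return the summary dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": dataclasses.asdict(config), "stages": []}
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) for s in ss.generate_state(4) % (2**31)]
    log_lines = [
        f"bcrisk {__version__} on python {platform.python_version()}",
        f"seed {config.seed}",
    ]

    def stage(name: str):
        summary["stages"].append(name)
        log_lines.append(f"stage: {name}")

    try:
        stage("load")
        if config.genotype_table is None:
            sim = default_config(seed=seeds[0])
            dataset = simulate_two_stage_study(sim)
            log_lines.append("input: simulated two-stage study (default config)")
        else:
            from .studydata import FIVE_SNP_PANEL

            dataset = read_genotype_table(config.genotype_table, FIVE_SNP_PANEL)
            log_lines.append(f"input: {config.genotype_table}")
        schedule = (
            synthetic_hazard_schedule()
            if config.hazard_schedule is None
            else read_hazard_schedule(config.hazard_schedule)
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("load", exc) from exc

    try:
        stage("baseline")
        sub = dataset.subjects
        cases, controls = sub[dataset.case_mask], sub[~dataset.case_mask]
        baseline = {
            "age": compare_baseline(cases["age"], controls["age"], "continuous"),
            "menarche": compare_baseline(
                list(cases["menarche"]), list(controls["menarche"]), "categorical"
            ),
            "first_birth": compare_baseline(
                list(cases["first_birth"]), list(controls["first_birth"]), "categorical"
            ),
        }
        summary["baseline_p"] = baseline
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("baseline", exc) from exc

    try:
        stage("qc")
        qc_rows = []
        for snp in dataset.panel:
            call_rate, maf = qc_summary(dataset, snp)
            controls_counts = dataset.stratum("testing").genotype_counts(
                snp.snp_id, "control"
            )
            qc_rows.append(
                {
                    "snp_id": snp.snp_id,
                    "call_rate": call_rate,
                    "control_maf": maf,
                    "hwe_p_controls": hwe_exact_test(controls_counts),
                }
            )
        pd.DataFrame(qc_rows).to_csv(outdir / "qc.tsv", sep="\t", index=False)
        summary["qc"] = qc_rows
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("qc", exc) from exc

    try:
        stage("association")
        testing = dataset.stratum("testing")
        screened = two_stage_screen(testing, dataset.panel, config.alpha)
        validated = validate_markers(
            dataset, screened, config.alpha, config.covariates, config.coding
        )
        summary["screened"] = [s.snp_id for s in screened]
        summary["validated"] = [s.snp_id for s in validated]
        assoc_rows = []
        for snp in validated:
            for stratum in ("testing", "validation", "combined"):
                res = snp_association(
                    dataset, snp, config.coding, config.covariates, stratum
                )
                assoc_rows.append(res)
        write_results(assoc_rows, outdir / "association.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("association", exc) from exc

    if not validated:
        log_lines.append("no validated markers; skipping genetic risk models")
        summary["skipped"] = "risk_models_and_downstream"
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        _write_summary(summary, outdir)
        return summary

    try:
        stage("risk_models")
        vpanel = validated
        snp_ors = {
            s.snp_id: snp_association(
                dataset, s, "additive", config.covariates, "combined"
            ).or_point
            for s in vpanel
        }
        clin_ors = clinical_crude_ors()
        model = build_risk_score(snp_ors, clin_ors)

        allele_counts = count_risk_alleles(dataset, vpanel)
        factor_counts = count_risk_factors(dataset, vpanel)
        n_bins = 2 * len(vpanel)
        allele_bins, allele_labels = bin_counts(
            allele_counts, first_upper=1, last_lower=min(6, n_bins - 1)
        )
        factor_bins, factor_labels = bin_counts(
            factor_counts, first_upper=2, last_lower=min(7, n_bins)
        )
        grouped = {
            "allele_counting": grouped_or_analysis(
                allele_bins, dataset, ("age", "menopause", "menarche", "first_birth"),
                allele_labels,
            ),
            "factor_counting": grouped_or_analysis(
                factor_bins, dataset, ("age", "menopause"), factor_labels
            ),
        }
        gscore = score_subjects(model, dataset, include_clinical=False)
        cscore = score_subjects(model, dataset, include_clinical=True)
        ctrl = ~dataset.case_mask
        ggroups = quartile_groups(gscore, gscore[ctrl])
        cgroups = quartile_groups(cscore, cscore[ctrl])
        grouped["genetic_score"] = grouped_or_analysis(
            ggroups, dataset, ("age", "menopause", "menarche", "first_birth")
        )
        grouped["genetic_clinical_score"] = grouped_or_analysis(
            cgroups, dataset, ("age", "menopause")
        )
        for name, res in grouped.items():
            write_results(res, outdir / f"grouped_{name}.tsv")
        summary["grouped_or"] = {
            name: {"or": res.or_point, "trend_p": res.trend_p}
            for name, res in grouped.items()
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("risk_models", exc) from exc

    try:
        stage("absolute_risk")
        tables = build_rr_tables(dataset, snp_ors, clin_ors)
        ar = cohort_absolute_risk(dataset, tables, schedule)
        ar.to_csv(outdir / "absolute_risk.tsv", sep="\t", index=False)
        ar_summary = {
            "median_rr": float(ar["combined_rr"].median()),
            "median_ar": float(ar["absolute_risk"].median()),
            "deciles": [
                float(v)
                for v in np.nanpercentile(ar["absolute_risk"], np.arange(10, 100, 10))
            ],
        }
        for mult in config.cutoff_multiples:
            flags, thr = classify_high_risk(ar["absolute_risk"], mult)
            ar_summary[f"high_risk_frac_{mult:g}x"] = float(np.nanmean(flags))
            ar_summary[f"threshold_{mult:g}x"] = thr
        summary["absolute_risk"] = ar_summary
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("absolute_risk", exc) from exc

    try:
        stage("discrimination")
        labels = dataset.subjects["status"].to_numpy()
        ok = cscore.notna() & factor_counts.notna() & ar["absolute_risk"].notna()
        weighted = roc_analysis(cscore[ok], labels[ok])
        counting = roc_analysis(factor_counts[ok], labels[ok])
        absrisk = roc_analysis(ar.loc[ok, "absolute_risk"], labels[ok])
        _, _, delong_p = delong_paired_test(
            cscore[ok], factor_counts[ok], labels[ok]
        )
        cv = {
            "snps_only": cv_auc(
                dataset, _score_model_builder(vpanel, False), config.cv_folds, seeds[1]
            ),
            "clinical_only": cv_auc(
                dataset, _clinical_model_builder(), config.cv_folds, seeds[2]
            ),
            "snps_plus_clinical": cv_auc(
                dataset, _score_model_builder(vpanel, True), config.cv_folds, seeds[3]
            ),
        }
        summary["discrimination"] = {
            "weighted_score": dataclasses.asdict(weighted),
            "counting": dataclasses.asdict(counting),
            "absolute_risk": dataclasses.asdict(absrisk),
            "delong_p_weighted_vs_counting": delong_p,
            "cv_auc": cv,
        }
        write_results([weighted, counting, absrisk], outdir / "roc.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("discrimination", exc) from exc

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    _write_summary(summary, outdir)
    return summary


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _write_summary(summary: dict, outdir: Path) -> None:
    (outdir / "summary.json").write_text(
        json.dumps(_round_floats(summary), indent=2, sort_keys=True, allow_nan=True)
        + "\n"
    )
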