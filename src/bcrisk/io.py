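"""Readers and writers for genotype/covariate tables and hazard schedules.

Genotype tables are delimited text with one row per subject; genotype cells
may be unordered allele pairs (``"GA"``), integer minor-allele dosages, or a
missing token (empty, ``NA``, ``NN``). Dosage orientation always follows the
panel's designated minor allele.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import (
    FIRST_BIRTH_LEVELS,
    MENARCHE_LEVELS,
    HazardBand,
    HazardSchedule,
    SnpDef,
    StudyDataset,
    categorize_first_birth,
    categorize_menarche,
)

logger = logging.getLogger(__name__)

MISSING_TOKENS = {"", "NA", "NN", "nan", "NaN", "."}

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "read_hazard_schedule",
    "write_hazard_schedule",
    "read_vcf_genotypes",
    "qc_summary",
    "write_results",
]


def _parse_genotype_cell(cell: object, snp: SnpDef, row: int) -> float:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return np.nan
    text = str(cell).strip()
    if text in MISSING_TOKENS:
        return np.nan
    # integer dosage?
    try:
        dosage = float(text)
    except ValueError:
        pass
    else:
        if dosage not in (0.0, 1.0, 2.0):
            raise ValueError(
                f"row {row}, column {snp.snp_id}: dosage {text!r} not in 0/1/2"
            )
        return dosage
    if len(text) != 2:
        raise ValueError(
            f"row {row}, column {snp.snp_id}: cannot parse genotype {text!r}"
        )
    try:
        return snp.dosage_from_alleles(text)
    except ValueError as exc:
        raise ValueError(f"row {row}, column {snp.snp_id}: {exc}") from exc


def _parse_clinical(sub: pd.DataFrame) -> pd.DataFrame:
    sub = sub.copy()
    if "menarche" in sub.columns:
        vals = sub["menarche"].astype(str).str.strip()
        numeric = pd.to_numeric(vals, errors="coerce")
        cat = numeric.map(categorize_menarche)
        cat[numeric.isna()] = vals[numeric.isna()].str.lower()
        cat = cat.replace(dict.fromkeys(MISSING_TOKENS, ""))
        bad = set(cat.unique()) - set(MENARCHE_LEVELS) - {""}
        if bad:
            raise ValueError(f"unknown menarche categories {sorted(bad)}")
        sub["menarche"] = cat
    if "first_birth" in sub.columns:
        vals = sub["first_birth"].astype(str).str.strip()
        numeric = pd.to_numeric(vals, errors="coerce")
        cat = numeric.map(categorize_first_birth)
        cat[numeric.isna()] = vals[numeric.isna()].str.lower()
        cat = cat.replace(dict.fromkeys(MISSING_TOKENS, ""))
        bad = set(cat.unique()) - set(FIRST_BIRTH_LEVELS) - {""}
        if bad:
            raise ValueError(f"unknown first_birth categories {sorted(bad)}")
        sub["first_birth"] = cat
    return sub


def read_genotype_table(path: str | Path, panel: list[SnpDef]) -> StudyDataset:
    """Read a delimited subject table into a :class:`StudyDataset`.

    The header must name every panel SNP; clinical columns ``menarche`` and
    ``first_birth`` accept either category labels or ages in years (then
    binned on the half-open category boundaries). Unknown SNP columns (any
    column that is neither a known subject field nor a panel id) raise.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    known = {
        "subject_id",
        "status",
        "stage",
        "age",
        "menarche",
        "first_birth",
        "menopause",
    }
    panel_ids = {s.snp_id for s in panel}
    for col in raw.columns:
        if col not in known and col not in panel_ids:
            raise ValueError(f"unknown SNP column {col!r} (not in panel)")
    absent = panel_ids - set(raw.columns)
    if absent:
        raise ValueError(f"panel SNP(s) missing from table: {sorted(absent)}")

    out = pd.DataFrame()
    out["subject_id"] = raw.get("subject_id", pd.Series(range(len(raw)))).astype(str)
    out["status"] = raw["status"].str.strip().str.lower()
    bad_status = set(out["status"].unique()) - {"case", "control"}
    if bad_status:
        raise ValueError(f"unknown status values {sorted(bad_status)}")
    out["stage"] = (
        raw["stage"].str.strip().str.lower()
        if "stage" in raw
        else pd.Series(["testing"] * len(raw))
    )
    out["age"] = (
        pd.to_numeric(raw["age"], errors="coerce") if "age" in raw else np.nan
    )
    out["menarche"] = raw.get("menarche", pd.Series([""] * len(raw)))
    out["first_birth"] = raw.get("first_birth", pd.Series([""] * len(raw)))
    out["menopause"] = (
        raw["menopause"].str.strip().str.lower()
        if "menopause" in raw
        else pd.Series([""] * len(raw))
    )
    out = _parse_clinical(out)

    for snp in panel:
        col = raw[snp.snp_id]
        out[snp.snp_id] = [
            _parse_genotype_cell(col.iloc[i], snp, i) for i in range(len(col))
        ]
        n_missing = int(pd.isna(out[snp.snp_id]).sum())
        if n_missing:
            logger.info("%s: %d missing genotype(s)", snp.snp_id, n_missing)
    return StudyDataset(panel, out)


def write_genotype_table(dataset: StudyDataset, path: str | Path) -> None:
    """Write a StudyDataset back to delimited text (dosage-coded genotypes)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    keep = [
        "subject_id", "status", "stage", "age", "menarche", "first_birth", "menopause",
    ] + dataset.snp_ids
    df = dataset.subjects[keep].copy()
    for sid in dataset.snp_ids:
        df[sid] = df[sid].map(lambda d: "NA" if pd.isna(d) else str(int(d)))
    df.to_csv(path, sep=sep, index=False)


def read_hazard_schedule(path: str | Path) -> HazardSchedule:
    """Read an age-banded hazard table (rates given per 100,000 person-years).

    Columns: ``age_start, age_end, incidence_per_100k, mortality_per_100k``.
    Rates are converted to per-person-year; bands are validated contiguous.
    """
    df = pd.read_csv(path)
    required = {"age_start", "age_end", "incidence_per_100k", "mortality_per_100k"}
    if not required <= set(df.columns):
        raise ValueError(f"hazard schedule lacks columns {sorted(required - set(df.columns))}")
    if df.empty:
        raise ValueError("hazard schedule has no bands")
    df = df.sort_values("age_start")
    bands = [
        HazardBand(
            float(r.age_start),
            float(r.age_end),
            float(r.incidence_per_100k) / 1e5,
            float(r.mortality_per_100k) / 1e5,
        )
        for r in df.itertuples()
    ]
    return HazardSchedule(tuple(bands))


def write_hazard_schedule(schedule: HazardSchedule, path: str | Path) -> None:
    df = schedule.to_frame()
    df["incidence_per_100k"] = df.pop("incidence") * 1e5
    df["mortality_per_100k"] = df.pop("mortality") * 1e5
    df.to_csv(path, index=False)


def read_vcf_genotypes(path: str | Path, panel: list[SnpDef]) -> pd.DataFrame:
    """Read minor-allele dosages for panel SNPs from a VCF's GT field.

    Only biallelic records whose ID matches a panel SNP are used; REF/ALT
    must equal the panel's two alleles (either orientation). Returns a frame
    of dosage columns indexed by VCF sample name. Requires :mod:`cyvcf2`.
    """
    from cyvcf2 import VCF  # optional dependency

    by_id = {s.snp_id: s for s in panel}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    data: dict[str, np.ndarray] = {}
    for var in vcf:
        snp = by_id.get(var.ID)
        if snp is None:
            continue
        if len(var.ALT) != 1:
            raise ValueError(f"{var.ID}: only biallelic records are supported")
        ref, alt = var.REF, var.ALT[0]
        if {ref, alt} != {snp.major_allele, snp.minor_allele}:
            raise ValueError(
                f"{var.ID}: VCF alleles {ref}/{alt} do not match panel "
                f"{snp.major_allele}/{snp.minor_allele}"
            )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt_map = np.array([0.0, 1.0, np.nan, 2.0])
        alt_dosage = gt_map[var.gt_types]
        dosage = alt_dosage if alt == snp.minor_allele else 2.0 - alt_dosage
        data[snp.snp_id] = dosage
    absent = set(by_id) - set(data)
    if absent:
        raise ValueError(f"panel SNP(s) not found in VCF: {sorted(absent)}")
    return pd.DataFrame(data, index=samples)


def qc_summary(dataset: StudyDataset, snp: SnpDef) -> tuple[float, float]:
    """Per-SNP QC: (call rate over all subjects, control minor allele frequency)."""
    if snp.snp_id not in dataset.snp_ids:
        raise KeyError(snp.snp_id)
    dosages = dataset.subjects[snp.snp_id]
    call_rate = float(1.0 - pd.isna(dosages).mean())
    controls = dataset.genotype_counts(snp.snp_id, status="control")
    if controls.total == 0:
        raise ValueError(f"{snp.snp_id}: no genotyped controls")
    return call_rate, controls.maf


def _jsonable(obj: object) -> object:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def write_results(results: Iterable[object] | object, path: str | Path) -> None:
    """Write result dataclasses (or lists of them) as JSON or TSV by extension."""
    path = Path(path)
    payload = _jsonable(results)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        rows = payload if isinstance(payload, list) else [payload]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
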