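"""Core data model for case-control SNP risk studies.

Subject-level data live in a :class:`pandas.DataFrame` (one row per subject,
one dosage column per SNP); the small typed containers here carry the marker
panel, grouped genotype counts and the hazard schedule used by the absolute
risk projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SnpDef",
    "GenotypeCounts",
    "HazardBand",
    "HazardSchedule",
    "StudyDataset",
    "MENARCHE_LEVELS",
    "FIRST_BIRTH_LEVELS",
    "categorize_menarche",
    "categorize_first_birth",
]

#: Ordered category labels for age at menarche: <15, [15, 17), >=17 years.
MENARCHE_LEVELS = ("early", "normal", "late")
#: Ordered category labels for age at first live birth: <25, >=25 years.
FIRST_BIRTH_LEVELS = ("early", "late")

#: Columns every subject table carries besides the per-SNP dosage columns.
SUBJECT_COLUMNS = (
    "subject_id",
    "status",
    "stage",
    "age",
    "menarche",
    "first_birth",
    "menopause",
)


def categorize_menarche(age_at_menarche: float) -> str:
    """Map age at menarche (years) onto the early/normal/late partition.

    Half-open intervals [<15), [15,17), [17,inf) so the three groups tile
    the axis without overlap.
    """
    if np.isnan(age_at_menarche):
        return ""
    if age_at_menarche < 15:
        return "early"
    if age_at_menarche < 17:
        return "normal"
    return "late"


def categorize_first_birth(age_at_first_birth: float) -> str:
    """Map age at first live birth (years) onto early (<25) / late (>=25)."""
    if np.isnan(age_at_first_birth):
        return ""
    return "early" if age_at_first_birth < 25 else "late"


@dataclass(frozen=True)
class SnpDef:
    """A biallelic marker: identity, alleles and designated risk allele.

    ``minor_allele`` is fixed at panel definition time (it is not re-derived
    from each dataset) so dosage orientation is identical in the testing and
    validation stages. ``risk_allele`` must be one of the two alleles.
    """

    snp_id: str
    chrom_band: str
    position: int
    major_allele: str
    minor_allele: str
    risk_allele: str
    associated_genes: str = ""
    #: External reference-population minor allele frequency; annotation only.
    reference_maf: float | None = None

    def __post_init__(self) -> None:
        if self.major_allele == self.minor_allele:
            raise ValueError(f"{self.snp_id}: major and minor allele are identical")
        if self.risk_allele not in (self.major_allele, self.minor_allele):
            raise ValueError(
                f"{self.snp_id}: risk allele {self.risk_allele!r} is neither "
                f"{self.major_allele!r} nor {self.minor_allele!r}"
            )

    @property
    def risk_is_minor(self) -> bool:
        return self.risk_allele == self.minor_allele

    def dosage_from_alleles(self, cell: str) -> float:
        """Minor-allele dosage of an unordered allele-pair cell like ``"GA"``."""
        alleles = set(cell)
        valid = {self.major_allele, self.minor_allele}
        if not alleles <= valid:
            bad = alleles - valid
            raise ValueError(
                f"{self.snp_id}: allele(s) {sorted(bad)} not in {sorted(valid)}"
            )
        return float(sum(a == self.minor_allele for a in cell))


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one SNP in one group, ordered by minor-allele dosage."""

    n_hom_major: int
    n_het: int
    n_hom_minor: int

    def __post_init__(self) -> None:
        if min(self.n_hom_major, self.n_het, self.n_hom_minor) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_hom_major + self.n_het + self.n_hom_minor

    @property
    def minor_allele_count(self) -> int:
        return 2 * self.n_hom_minor + self.n_het

    @property
    def maf(self) -> float:
        """Sample minor allele frequency."""
        if self.total == 0:
            raise ValueError("cannot compute MAF from zero genotyped subjects")
        return self.minor_allele_count / (2 * self.total)

    def as_array(self) -> np.ndarray:
        return np.array([self.n_hom_major, self.n_het, self.n_hom_minor])

    @classmethod
    def from_dosages(cls, dosages: np.ndarray | pd.Series) -> "GenotypeCounts":
        d = np.asarray(dosages, dtype=float)
        d = d[~np.isnan(d)]
        return cls(int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))


@dataclass(frozen=True)
class HazardBand:
    age_start: float
    age_end: float
    incidence: float  # disease events per person-year
    mortality: float  # competing (non-disease) deaths per person-year

    def __post_init__(self) -> None:
        if self.age_start >= self.age_end:
            raise ValueError(f"band [{self.age_start}, {self.age_end}) is empty")
        if self.incidence < 0 or self.mortality < 0:
            raise ValueError("hazard rates must be non-negative")


@dataclass(frozen=True)
class HazardSchedule:
    """Age-banded disease incidence and competing mortality (per person-year).

    Bands must be contiguous and non-overlapping; the projection operations
    require the schedule to cover the requested age span.
    """

    bands: tuple[HazardBand, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("hazard schedule has no bands")
        for prev, cur in zip(self.bands, self.bands[1:]):
            if cur.age_start != prev.age_end:
                raise ValueError(
                    f"bands not contiguous: [{prev.age_start}, {prev.age_end}) "
                    f"followed by [{cur.age_start}, {cur.age_end})"
                )

    @property
    def age_start(self) -> float:
        return self.bands[0].age_start

    @property
    def age_end(self) -> float:
        return self.bands[-1].age_end

    def covers(self, age_start: float, age_end: float) -> bool:
        return self.age_start <= age_start and age_end <= self.age_end

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_start": [b.age_start for b in self.bands],
                "age_end": [b.age_end for b in self.bands],
                "incidence": [b.incidence for b in self.bands],
                "mortality": [b.mortality for b in self.bands],
            }
        )


@dataclass
class StudyDataset:
    """A marker panel plus a subject table.

    ``subjects`` columns: ``subject_id``, ``status`` ("case"/"control"),
    ``stage`` ("testing"/"validation"), ``age`` (years), ``menarche``
    (early/normal/late), ``first_birth`` (early/late), ``menopause``
    ("pre"/"post" or missing) and one float dosage column per panel SNP
    (0/1/2 minor-allele copies, NaN = missing).
    """

    panel: list[SnpDef]
    subjects: pd.DataFrame

    def __post_init__(self) -> None:
        ids = [s.snp_id for s in self.panel]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_id in panel")
        missing = [c for c in SUBJECT_COLUMNS if c not in self.subjects.columns]
        if missing:
            raise ValueError(f"subject table lacks columns {missing}")
        for sid in ids:
            if sid not in self.subjects.columns:
                raise ValueError(f"subject table lacks dosage column {sid!r}")

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.panel]

    def snp(self, snp_id: str) -> SnpDef:
        for s in self.panel:
            if s.snp_id == snp_id:
                return s
        raise KeyError(snp_id)

    @property
    def case_mask(self) -> pd.Series:
        return self.subjects["status"] == "case"

    def stratum(self, stage: str) -> "StudyDataset":
        """Subset to one stage ('testing'/'validation') or 'combined'."""
        if stage == "combined":
            return self
        sub = self.subjects[self.subjects["stage"] == stage]
        if sub.empty:
            raise ValueError(f"no subjects in stage {stage!r}")
        return StudyDataset(self.panel, sub.reset_index(drop=True))

    def genotype_counts(self, snp_id: str, status: str | None = None) -> GenotypeCounts:
        """Tabulate non-missing dosages for one SNP, optionally by status."""
        sub = self.subjects
        if status is not None:
            sub = sub[sub["status"] == status]
        return GenotypeCounts.from_dosages(sub[snp_id])

    def n_cases(self) -> int:
        return int(self.case_mask.sum())

    def n_controls(self) -> int:
        return int((~self.case_mask).sum())
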