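"""Bundled summary data for the default five-marker breast-cancer panel.

These are published group-level summary statistics from a two-stage
case-control study of breast cancer in Han Chinese women (878 cases / 900
controls in the testing stage, 914 / 967 in validation): genotype counts by
stage and status for the five validated GWAS markers, the screening
p-values of the full 15-SNP candidate panel, combined-stage per-allele odds
ratios, and the combined distribution of the two clinical risk factors (age
at menarche, age at first live birth). Individual-level data were never
released; everything here is reconstructable arithmetic input, used as
defaults for the simulator and as worked-example material.

The bundled hazard schedule is SYNTHETIC: the study calibrated absolute
risks against registry incidence/mortality rates that were not printed, so
:func:`synthetic_hazard_schedule` provides a plausible stand-in with the
right shape (incidence peaking in late middle age, competing mortality
rising steeply), clearly labeled as such.
"""

from __future__ import annotations

import numpy as np

from .datatypes import GenotypeCounts, HazardBand, HazardSchedule, SnpDef

__all__ = [
    "FIVE_SNP_PANEL",
    "GENOTYPE_COUNTS",
    "SCREENING_PVALUES",
    "VALIDATED_SNP_IDS",
    "COMBINED_ADDITIVE_OR",
    "CONTROL_MAF",
    "CLINICAL_COUNTS",
    "ALLELE_COUNT_BINS",
    "clinical_control_freqs",
    "clinical_crude_ors",
    "synthetic_hazard_schedule",
]

#: The five validated markers, risk allele = designated minor allele.
FIVE_SNP_PANEL: list[SnpDef] = [
    SnpDef("rs13387042", "2q35", 217614077, "G", "A", "A",
           "TNP1, IGFBP5, IGFBP2", reference_maf=0.11),
    SnpDef("rs2307032", "3p24.1", 27407999, "C", "T", "T",
           "SLC4A7", reference_maf=0.41),
    SnpDef("rs2180341", "6q22.33", 127642323, "A", "G", "G",
           "ECHDC1, RNF146", reference_maf=0.22),
    SnpDef("rs2046210", "6q25.1", 151990059, "G", "A", "A",
           "ESR1, C6orf97", reference_maf=0.35),
    SnpDef("rs2981582", "10q26.13", 123342307, "C", "T", "T",
           "FGFR2", reference_maf=0.33),
]

#: Genotype counts (hom-major, het, hom-minor) by stage and status.
GENOTYPE_COUNTS: dict[str, dict[str, dict[str, GenotypeCounts]]] = {
    "rs13387042": {
        "testing": {"case": GenotypeCounts(627, 223, 12),
                    "control": GenotypeCounts(695, 188, 9)},
        "validation": {"case": GenotypeCounts(712, 181, 16),
                       "control": GenotypeCounts(773, 178, 8)},
    },
    "rs2307032": {
        "testing": {"case": GenotypeCounts(265, 436, 160),
                    "control": GenotypeCounts(327, 398, 155)},
        "validation": {"case": GenotypeCounts(288, 429, 195),
                       "control": GenotypeCounts(326, 464, 157)},
    },
    "rs2180341": {
        "testing": {"case": GenotypeCounts(423, 373, 54),
                    "control": GenotypeCounts(480, 334, 66)},
        "validation": {"case": GenotypeCounts(479, 380, 51),
                       "control": GenotypeCounts(541, 350, 66)},
    },
    "rs2046210": {
        "testing": {"case": GenotypeCounts(290, 413, 158),
                    "control": GenotypeCounts(387, 393, 110)},
        "validation": {"case": GenotypeCounts(292, 460, 155),
                       "control": GenotypeCounts(380, 443, 137)},
    },
    "rs2981582": {
        "testing": {"case": GenotypeCounts(362, 400, 110),
                    "control": GenotypeCounts(420, 388, 88)},
        "validation": {"case": GenotypeCounts(370, 420, 106),
                       "control": GenotypeCounts(464, 408, 76)},
    },
}

#: Published testing-stage screening p-values for all 15 candidate SNPs
#: (exact test on the 2x3 genotype-by-status table).
SCREENING_PVALUES: dict[str, float] = {
    "rs13387042": 0.039,
    "rs4973768": 0.265,
    "rs2307032": 0.017,
    "rs16886165": 0.781,
    "rs889312": 0.595,
    "rs4415084": 0.798,
    "rs10941679": 0.768,
    "rs2180341": 0.040,
    "rs2046210": 1.26e-5,
    "rs13281615": 0.353,
    "rs1562430": 0.191,
    "rs2981582": 0.037,
    "rs3817198": 0.213,
    "rs12443621": 0.227,
    "rs6504950": 0.264,
}

VALIDATED_SNP_IDS = ["rs13387042", "rs2307032", "rs2180341", "rs2046210", "rs2981582"]

#: Combined-stage covariate-adjusted per-allele (additive) odds ratios.
COMBINED_ADDITIVE_OR: dict[str, float] = {
    "rs13387042": 1.25,
    "rs2307032": 1.14,
    "rs2180341": 1.08,
    "rs2046210": 1.33,
    "rs2981582": 1.27,
}

#: Published testing-stage control minor allele frequencies.
CONTROL_MAF: dict[str, float] = {
    "rs13387042": 0.12,
    "rs2307032": 0.40,
    "rs2180341": 0.26,
    "rs2046210": 0.34,
    "rs2981582": 0.31,
}

#: Combined-stage counts of the two clinical factors, {factor: {level: (cases, controls)}}.
CLINICAL_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "menarche": {
        "early": (688, 396),   # < 15 years
        "normal": (658, 728),  # 15 to < 17
        "late": (409, 734),    # >= 17 (reference)
    },
    "first_birth": {
        "early": (617, 925),   # < 25 years (reference)
        "late": (1169, 938),   # >= 25
    },
}

#: Combined-stage risk-allele-count bins: {bin label: (cases, controls)}.
ALLELE_COUNT_BINS: dict[str, tuple[int, int]] = {
    "0-1": (187, 295),
    "2": (327, 408),
    "3": (472, 503),
    "4": (404, 351),
    "5": (201, 152),
    ">=6": (97, 57),
}


def clinical_control_freqs() -> dict[str, dict[str, float]]:
    """Control-sample category frequencies of the two clinical factors."""
    out: dict[str, dict[str, float]] = {}
    for factor, levels in CLINICAL_COUNTS.items():
        total = sum(ctrl for _, ctrl in levels.values())
        out[factor] = {lvl: ctrl / total for lvl, (_, ctrl) in levels.items()}
    return out


def clinical_crude_ors() -> dict[str, dict[str, float]]:
    """Crude (cross-product) odds ratios per non-reference clinical category.

    Reference categories: late menarche (>= 17 y), early first birth (< 25 y).
    """
    men = CLINICAL_COUNTS["menarche"]
    fb = CLINICAL_COUNTS["first_birth"]

    def xor(exposed: tuple[int, int], ref: tuple[int, int]) -> float:
        return (exposed[0] * ref[1]) / (ref[0] * exposed[1])

    return {
        "menarche": {
            "early": xor(men["early"], men["late"]),
            "normal": xor(men["normal"], men["late"]),
            "late": 1.0,
        },
        "first_birth": {
            "early": 1.0,
            "late": xor(fb["late"], fb["early"]),
        },
    }


def synthetic_hazard_schedule() -> HazardSchedule:
    """A SYNTHETIC age-banded hazard schedule for women aged 20-85.

    Breast-cancer incidence (per 100,000 person-years) rises from the
    twenties, peaks around ages 55-70 at ~110-120, and eases slightly
    thereafter — the shape reported for urban East-Asian registries.
    Competing (non-breast-cancer) mortality rises roughly exponentially
    with age. The implied average 65-year cumulative breast-cancer risk is
    a few percent. These numbers are fabricated for demonstration and
    testing; real analyses should supply registry rates via
    :func:`bcrisk.io.read_hazard_schedule`.
    """
    ages = np.arange(20, 85, 5)
    incidence = [3, 8, 18, 35, 60, 85, 105, 115, 120, 115, 105, 95, 90]
    mortality = [40, 45, 55, 70, 95, 135, 190, 280, 430, 700, 1150, 1950, 3400]
    bands = tuple(
        HazardBand(float(a), float(a + 5), inc / 1e5, mor / 1e5)
        for a, inc, mor in zip(ages, incidence, mortality)
    )
    return HazardSchedule(bands)
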