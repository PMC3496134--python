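import numpy as np
import pandas as pd
import pytest

from bcrisk.datatypes import GenotypeCounts, SnpDef, StudyDataset
from bcrisk.simulate import default_config, simulate_population, simulate_two_stage_study
from bcrisk.studydata import FIVE_SNP_PANEL


def dataset_from_counts(
    snp: SnpDef,
    case_counts: GenotypeCounts,
    control_counts: GenotypeCounts,
    stage: str = "testing",
) -> StudyDataset:
    """Expand per-group genotype counts into a single-SNP subject table."""
    rows = []
    for status, counts in (("case", case_counts), ("control", control_counts)):
        for dosage, n in zip((0, 1, 2), counts.as_array()):
            rows += [{"status": status, snp.snp_id: float(dosage)}] * int(n)
    df = pd.DataFrame(rows)
    df["subject_id"] = [f"X{i}" for i in range(len(df))]
    df["stage"] = stage
    df["age"] = 50.0
    df["menarche"] = "normal"
    df["first_birth"] = "early"
    df["menopause"] = "pre"
    return StudyDataset([snp], df)


@pytest.fixture(scope="session")
def panel():
    return list(FIVE_SNP_PANEL)


@pytest.fixture(scope="session")
def study():
    """One simulated two-stage study at the default (published) conditions."""
    return simulate_two_stage_study(default_config(seed=7))


@pytest.fixture(scope="session")
def cohort():
    """A large cross-sectional population for ordering/monotonicity checks."""
    return simulate_population(default_config(), n=60_000, seed=11)
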