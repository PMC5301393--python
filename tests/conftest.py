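from __future__ import annotations

import numpy as np
import pytest

from p335 import adhesion_typer as at
from p335 import synthetic_data as syn
from p335.pipeline import RunConfig, run_classify

COHORT_SEEDS = {"I": [11, 12], "II": [21, 22], "III": [31, 32], "IV": [41, 42]}
COHORT_DIVERGENCE = 0.05
COHORT_BACKGROUND_ORFS = 10  # scaled down from genome-realistic 40 for speed


@pytest.fixture(scope="session")
def panel() -> at.ReferencePanel:
    return at.default_panel()


@pytest.fixture(scope="session")
def cohort():
    """Eight phages (two per sub-group template) plus one II/I chimera."""
    phages, truth = syn.make_cohort(
        COHORT_SEEDS,
        COHORT_DIVERGENCE,
        n_background_orfs=COHORT_BACKGROUND_ORFS,
        chimeras={"chimera_II_I": ("II", "I", 99)},
    )
    return phages, truth


@pytest.fixture(scope="session")
def cohort_report(cohort):
    """Full pipeline run over the 9-phage cohort (computed once)."""
    phages, _truth = cohort
    return run_classify(phages, RunConfig())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240335)
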