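"""Shared fixtures: a tiny two-chromosome genome and session-scoped runs of
the default synthetic experiment (simulation is the expensive part, so the
HU, null-HU and timepoint results are computed once per session)."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from repliscape.config import AnalysisConfig
from repliscape.core import GenomeLayout
from repliscape.pipeline import (
    ExperimentDesign,
    run_hu_experiment,
    run_timepoint_experiment,
)

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture()
def tiny_layout() -> GenomeLayout:
    return GenomeLayout(
        [("chrI", 230_000), ("chrII", 410_000)],
        {"chrI": (150_000, 150_120), "chrII": (200_000, 200_120)},
    )


@pytest.fixture(scope="session")
def hu_result():
    """Default HU WT-vs-rif1Δ experiment run end to end."""
    return run_hu_experiment(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def hu_null_result():
    """Same design with no Rif1 effect (delta = 0): both strains share one law."""
    design = dataclasses.replace(
        ExperimentDesign(), delta=0.0, regulated_late_fraction=0.0
    )
    return run_hu_experiment(seed=FIXTURE_SEED, design=design)


@pytest.fixture(scope="session")
def timepoint_result():
    """25/35-min unperturbed S-phase arms with quartile metaprofiles."""
    return run_timepoint_experiment(seed=FIXTURE_SEED)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
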