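"""Shared fixtures: small clinical cohorts and default configs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pexvote import AnalysisConfig, ClinicalTable, SimulationSpec
from pexvote.io import CT_SUFFIX


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig(rng_seed=0)


@pytest.fixture
def sim_spec() -> SimulationSpec:
    return SimulationSpec(seed=0)


def make_clinical_frame(
    n: int = 12,
    genes: tuple[str, ...] = ("HLA-E", "RABL2B"),
    seed: int = 0,
    reference_gene: str = "GAPDH",
) -> pd.DataFrame:
    """Small hand-checkable clinical frame with plausible columns."""
    rng = np.random.default_rng(seed)
    bor = np.resize(["CR", "PR", "SD", "PD", "NE", "PD"], n)
    frame = pd.DataFrame({
        "patient_id": [f"P{i:03d}" for i in range(n)],
        "bor": bor,
        "nlr": np.round(rng.lognormal(1.2, 0.4, n), 2),
        "os_months": np.round(rng.uniform(1, 36, n), 1),
        "os_event": rng.integers(0, 2, n),
        reference_gene + CT_SUFFIX: np.round(rng.normal(25, 0.5, n), 2),
    })
    for g in genes:
        frame[g + CT_SUFFIX] = np.round(frame[reference_gene + CT_SUFFIX]
                                        + rng.normal(5, 1.5, n), 2)
    return frame


@pytest.fixture
def small_table() -> ClinicalTable:
    frame = make_clinical_frame()
    genes = ("GAPDH", "HLA-E", "RABL2B")
    return ClinicalTable(frame=frame, genes=genes)
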