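"""Shared fixtures: small designs and datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from oabdr.synthetic_trial import (
    CovariateSpec, DesignSpec, StudyDesign, default_truth, simulate_trial,
)
from oabdr.trial_data import CSV_COLUMNS, PooledDataset


def scaled_design(factor: float = 0.1) -> DesignSpec:
    """Default pooled design with every arm scaled down (zeros stay zero)."""
    from oabdr.synthetic_trial import default_design

    design = default_design()
    for study in design.studies.values():
        study.arms = {d: int(round(n * factor)) for d, n in study.arms.items()}
    return design


@pytest.fixture(scope="session")
def small_design() -> DesignSpec:
    return scaled_design(0.1)


@pytest.fixture(scope="session")
def mict_small(small_design) -> PooledDataset:
    return simulate_trial(small_design, {"MICT": default_truth("MICT")}, 11)


@pytest.fixture(scope="session")
def tiny_design() -> DesignSpec:
    return DesignSpec(
        studies={"P3A": StudyDesign({0: 8, 4: 8, 8: 8}, (0, 14, 28, 56, 84))},
        covariates=CovariateSpec(),
    )


@pytest.fixture
def handmade_dataset() -> PooledDataset:
    """Two subjects, hand-written rows covering all endpoint kinds."""
    rows = [
        # SUBJ STUDY DOSE TIME EP DV DIARY AGE SEX BMI  BM BU BMV BPVR
        ("P3A-0001", "P3A", 0, 0.0, "MICT", 33.0, 3, 64.0, "F", 26.0, 11.0, 2.0, 150.0, 20.0),
        ("P3A-0001", "P3A", 0, 84.0, "MICT", 30.0, 3, 64.0, "F", 26.0, 11.0, 2.0, 150.0, 20.0),
        ("P3A-0001", "P3A", 0, 0.0, "MVV", 150.0, None, 64.0, "F", 26.0, 11.0, 2.0, 150.0, 20.0),
        ("P3A-0001", "P3A", 0, 84.0, "PVR", 45.0, None, 64.0, "F", 26.0, 11.0, 2.0, 150.0, 20.0),
        ("P3A-0002", "P3A", 8, 0.0, "MICT", 36.0, 3, 72.0, "M", 29.0, 12.0, 3.0, 160.0, 35.0),
        ("P3A-0002", "P3A", 8, 84.0, "MICT", 27.0, 3, 72.0, "M", 29.0, 12.0, 3.0, 160.0, 35.0),
    ]
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df["DIARY_D"] = pd.array(df["DIARY_D"], dtype="Int64")
    return PooledDataset(df=df, provenance="handmade").validate()


def poisson_subject(rng: np.random.Generator, n_visits=4,
                    rate_lo=2.0, rate_hi=40.0, omega2_hi=0.5):
    """One fuzzed Poisson subject: trial-like visit means and heterogeneity."""
    c = rng.uniform(rate_lo, rate_hi, size=n_visits)
    omega2 = rng.uniform(0.01, omega2_hi)
    eta = rng.normal(0, np.sqrt(omega2))
    y = rng.poisson(c * np.exp(eta)).astype(float)
    return y, c, omega2
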