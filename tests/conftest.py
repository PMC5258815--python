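from __future__ import annotations

import pytest

from camrspot.records import (
    AntigenClass,
    ElispotSample,
    TimePoint,
)
from camrspot.simulate import SyntheticCohortConfig, generate_cohort


def make_sample(
    counts,
    background: int = 2,
    patient_id: str = "P001",
    time_point: TimePoint = TimePoint.T1,
    antigen_class: AntigenClass = AntigenClass.DONOR,
    viable: bool = True,
) -> ElispotSample:
    if not viable:
        return ElispotSample(
            patient_id=patient_id,
            time_point=time_point,
            antigen_class=antigen_class,
            viable=False,
        )
    return ElispotSample(
        patient_id=patient_id,
        time_point=time_point,
        antigen_class=antigen_class,
        c_cd8dep=counts[0],
        c_cd8cd19dep=counts[1],
        c_cd8cd25dep=counts[2],
        c_cd8cd25cd19dep=counts[3],
        background=background,
        viable=viable,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default-scenario cohort with its ground truth."""
    return generate_cohort(seed=11)


@pytest.fixture(scope="session")
def clean_cohort():
    """Low-noise, fully viable cohort for recovery tests."""
    config = SyntheticCohortConfig(
        dispersion=float("inf"), nonviable_prob=0.0, residual_sd=0.0
    )
    return generate_cohort(config, seed=5)
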