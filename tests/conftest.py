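import numpy as np
import pandas as pd
import pytest

from cagerest.datamodel import AnalysisConfig, CageMetadata, CapacitanceRecord, LightSchedule
from cagerest.synthetic import SimulationParams, simulate_cohort


@pytest.fixture(scope="session")
def schedule() -> LightSchedule:
    return LightSchedule()


@pytest.fixture(scope="session")
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def tiny_cohort():
    """One-week, 2-cages-per-group cohort shared by pipeline-level tests."""
    params = SimulationParams(
        weeks=1,
        n_cages={("M", "WT"): 2, ("M", "MUT"): 2, ("F", "WT"): 2, ("F", "MUT"): 2},
        seed=7,
    )
    return simulate_cohort(params)


def make_record(values: np.ndarray, fs: float = 4.0, cage_id: str = "C01",
                start: str = "2021-03-01 07:00:00", mask=None) -> CapacitanceRecord:
    return CapacitanceRecord(
        cage_id=cage_id,
        start_time=pd.Timestamp(start),
        fs=fs,
        values=np.asarray(values, dtype=float),
        mask=mask,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def meta_factory():
    def _make(cage_id="C01", genotype="WT", sex="M", changes=()):
        return CageMetadata(
            cage_id=cage_id, genotype=genotype, sex=sex,
            cage_change_dates=frozenset(changes),
        )
    return _make
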