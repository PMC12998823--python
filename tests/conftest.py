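import numpy as np
import pandas as pd
import pytest

from labri.prep import COHORT_COLUMNS
from labri.synthetic import LOW_TAIL_SHARE, ComponentSpec, CellSpec, SyntheticCohortConfig


def make_record(**kwargs) -> dict:
    """One cohort row with sane defaults, overridable per test."""
    base = {
        "subject_id": "S0",
        "age": 30.0,
        "sex": "F",
        "analyzer": "Abbott",
        "tsh": 1.5,
        "ft4": 15.0,
        "ft3": 4.5,
        "tg_ab": 1.0,
        "tpo_ab": 1.0,
        "pregnant": False,
        "inpatient": False,
        "thyroid_dx_or_med": False,
    }
    base.update(kwargs)
    return base


def make_frame(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return df


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def frame_factory():
    return make_frame


def single_cell_config(
    n: int,
    seed: int,
    lam: float = 0.0,
    mu: float = 0.2,
    sigma: float = 0.45,
    healthy_weight: float = 1.0,
    lo=(-2.3, 0.5),
    hi=(2.6, 0.5),
    **kwargs,
) -> SyntheticCohortConfig:
    """Config with the same mixture in every (Abbott, sex, analyte) cell."""
    contamination = 1.0 - healthy_weight
    lo_w = LOW_TAIL_SHARE * contamination
    cell = CellSpec(
        healthy=ComponentSpec(lam, mu, sigma, healthy_weight),
        path_low=ComponentSpec(lam, lo[0], lo[1], lo_w),
        path_high=ComponentSpec(lam, hi[0], hi[1], contamination - lo_w),
    )
    cells = {("Abbott", sex, analyte): cell
             for sex in ("M", "F") for analyte in ("TSH", "fT4", "fT3")}
    defaults = dict(
        antibody_prevalence=0.0,
        antibody_shift={"TSH": 0.0, "fT4": 0.0, "fT3": 0.0},
        antibody_scale={"TSH": 1.0, "fT4": 1.0, "fT3": 1.0},
        exclusion_rates={"pregnant": 0.0, "inpatient": 0.0, "thyroid_dx_or_med": 0.0,
                         "missing": 0.0, "age_out_of_range": 0.0},
        analyzer_weights={"Abbott": 1.0},
    )
    defaults.update(kwargs)
    return SyntheticCohortConfig(n=n, seed=seed, cells=cells, **defaults)


@pytest.fixture
def cell_config_factory():
    return single_cell_config
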