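from datetime import date

import pandas as pd
import pytest

from spigfd.ehr_model import TABLE_COLUMNS, Cohort
from spigfd.synthetic_emr import (
    CohortSpec,
    generate_cohort,
    toy_reference_bundle,
)


@pytest.fixture(scope="session")
def refs():
    return toy_reference_bundle()


@pytest.fixture(scope="session")
def small_cohort():
    """50-patient generated cohort shared by the oracle-equivalence tests."""
    return generate_cohort(CohortSpec(n_patients=50, seed=7))


def empty_frame(table: str) -> pd.DataFrame:
    return pd.DataFrame(columns=TABLE_COLUMNS[table])


def make_cohort(patients=None, observations=None, labs=None, diagnoses=None,
                medications=None, staging=None) -> Cohort:
    """Assemble a typed cohort from row tuples (dates as datetime.date)."""
    def frame(rows, table):
        if not rows:
            return empty_frame(table)
        return pd.DataFrame(rows, columns=TABLE_COLUMNS[table])

    return Cohort(
        patients=frame(patients, "patients"),
        observations=frame(observations, "observations"),
        labs=frame(labs, "labs"),
        diagnoses=frame(diagnoses, "diagnoses"),
        medications=frame(medications, "medications"),
        staging=frame(staging, "staging"),
    )


def patient(pid, sex="male", birth=date(2008, 1, 1), bw_z=None, bl_z=None):
    return (pid, sex, birth, bw_z, bl_z)
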