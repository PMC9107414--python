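import numpy as np
import pytest

from mosaicct import (
    BankSpec,
    ControlBank,
    MosaicParcellation,
    SubjectRecord,
    generate_control_bank,
    generate_toy_parcellation,
)


def make_bank(matrix, ages=None, sexes=None, parcel_ids=None):
    """Assemble a ControlBank from a raw matrix with default demographics."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    n, p = matrix.shape
    ages = ages if ages is not None else [60.0] * n
    sexes = sexes if sexes is not None else ["female"] * n
    records = [
        SubjectRecord(subject_id=f"hc{i}", age=float(ages[i]), sex=sexes[i], group="HC")
        for i in range(n)
    ]
    pids = parcel_ids or [f"p{j}" for j in range(p)]
    return ControlBank(records=records, matrix=matrix, parcel_ids=pids)


@pytest.fixture(scope="session")
def toy_parcellation():
    """Miniature 50-parcel parcellation with proportionally scaled ROI blocks."""
    return generate_toy_parcellation(50)


@pytest.fixture(scope="session")
def small_bank(toy_parcellation):
    """60 controls in one demographic stratum over 50 parcels."""
    spec = BankSpec(n_controls=60, age_range=(59.0, 61.0), sex_ratio=1.0, seed=7)
    return generate_control_bank(spec, toy_parcellation)


@pytest.fixture()
def patient_record():
    return SubjectRecord(subject_id="pt0", age=60.0, sex="female", group="bvFTD")
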