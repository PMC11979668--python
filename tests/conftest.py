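import numpy as np
import pytest

from stagedseg.caseio import CaseRecord, LabelMap, Volume3D
from stagedseg.phantom import PhantomParams, make_case, make_cohort


@pytest.fixture(scope="session")
def default_params() -> PhantomParams:
    return PhantomParams()


@pytest.fixture(scope="session")
def case_pair(default_params):
    """One deterministic (pre, mid) phantom pair at the default study conditions."""
    return make_case(PhantomParams(seed=11), "fix")


@pytest.fixture(scope="session")
def mid_case(case_pair):
    return case_pair[1]


@pytest.fixture(scope="session")
def small_cohort():
    """Six small mid-treatment cases for fast training smokes."""
    params = PhantomParams(shape=(32, 32, 16), gtvp_radius_range=(5.0, 7.0), seed=2)
    return [mid for _, mid in make_cohort(params, 6, seed=2)]


def make_labelmap(labels, spacing=(1.0, 1.0, 1.0)) -> LabelMap:
    return LabelMap(np.asarray(labels, dtype=np.int16), spacing)


def make_volume(data, spacing=(1.0, 1.0, 1.0)) -> Volume3D:
    return Volume3D(np.asarray(data, dtype=np.float32), spacing)


def make_case_record(image, labels, spacing=(1.0, 1.0, 1.0), case_id="t", **kw) -> CaseRecord:
    return CaseRecord(
        case_id,
        make_volume(image, spacing),
        make_labelmap(labels, spacing),
        **kw,
    )
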