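import numpy as np
import pytest

from slseg.core import Exam, ImageVolume, SegmentationMask
from slseg.phantom import PhantomConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort_small():
    """12 exams under the default heterogeneous study conditions."""
    return generate_cohort(PhantomConfig(n_exams=12, seed=101))


@pytest.fixture(scope="session")
def easy_cohort():
    """Homogeneous noise-free cohort: tumors segmentable by thresholding."""
    from slseg.phantom import easy_config

    return generate_cohort(easy_config(n_exams=16, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_exam(voxels, mask, spacing=(1.0, 1.0, 1.0), exam_id="t", **kw):
    """Small helper to assemble an Exam from plain arrays."""
    return Exam(
        ImageVolume(np.asarray(voxels, dtype=np.float32), spacing, exam_id),
        SegmentationMask(np.asarray(mask, dtype=np.uint8), spacing, exam_id),
        **kw,
    )
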