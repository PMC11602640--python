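import numpy as np
import pytest

from steamdti import protocol
from steamdti.encoding import calibrate_background_b
from steamdti.signal_model import SequenceTiming, TissueRelaxation
from steamdti.synthetic_data import (
    GroundTruthLaw,
    PhantomSpec,
    StudyDesign,
    build_phantom,
    simulate_study,
)

RELAX = TissueRelaxation(t1=1420.0, t2=32.0)
SE_TIMING = SequenceTiming("SE", repetition_time=6700, echo_time=42,
                           encoding_time=19)
STEAM100_TIMING = SequenceTiming("STEAM", repetition_time=6700, echo_time=36,
                                 encoding_time=100)

#: effective b of the nominally unweighted STEAM volumes vs mixing time
BACKGROUND_SAMPLES = [(100.0, 12.0), (200.0, 22.0), (400.0, 46.0), (600.0, 69.0)]

#: compact phantom for unit tests (full-size grid reserved for acceptance)
SMALL_SPEC = PhantomSpec(
    shape=(32, 32, 7),
    bundle_halfwidth_frac=0.14,
    bundle_halfheight_frac=0.30,
    bundle_offset_frac=0.20,
)


@pytest.fixture(scope="session")
def relax():
    return RELAX


@pytest.fixture(scope="session")
def background_law():
    return calibrate_background_b(BACKGROUND_SAMPLES)


@pytest.fixture(scope="session")
def small_phantom():
    return build_phantom(SMALL_SPEC)


@pytest.fixture(scope="session")
def law():
    return GroundTruthLaw()


@pytest.fixture(scope="session")
def tiny_study(tmp_path_factory):
    """A 2-subject, 2-session, 3-sequence study on disk (shared, read-only)."""
    out = tmp_path_factory.mktemp("study")
    design = StudyDesign(n_subjects=2, n_sessions=2, master_seed=11)
    simulate_study(design, GroundTruthLaw(), SMALL_SPEC, out,
                   sequences=("SE", "STEAM100", "STEAM600"))
    return out
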