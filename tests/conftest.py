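import numpy as np
import pytest

import ecgpsr as e


@pytest.fixture(scope="session")
def subject():
    return e.make_subject(0)


@pytest.fixture(scope="session")
def clean_record(subject):
    """130-beat record with default noise/baseline, fixed seed."""
    return e.synthesize_record(subject, 130, fs=1000.0, seed=1)


@pytest.fixture(scope="session")
def filtered_record(clean_record):
    return e.bandlimit(clean_record)


@pytest.fixture(scope="session")
def verified_fiducials(filtered_record):
    fid = e.detect_qrs(filtered_record)
    return e.verify_beats(filtered_record, fid)


@pytest.fixture(scope="session")
def segments(filtered_record, verified_fiducials):
    return e.segment_beats(filtered_record, verified_fiducials)


@pytest.fixture(scope="session")
def one_beat(segments):
    return segments[5]
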