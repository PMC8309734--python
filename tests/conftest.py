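import numpy as np
import pytest

import painfeat as pf


@pytest.fixture(scope="session")
def clean_pmdb():
    """12-subject PMDB-scheme dataset with the strong clean-effect preset,
    segmented and with hand-crafted features — shared across the slower
    recovery-style tests."""
    recordings = pf.generate_dataset(12, scheme=pf.PMDB, master_seed=1,
                                     preset="clean")
    segments = pf.segment_dataset(recordings)
    features = pf.feature_matrix(segments, "hcf")
    return recordings, segments, features


@pytest.fixture(scope="session")
def tiny_pmdb():
    """3 subjects, 2 repetitions per level: fast structural checks."""
    recordings = pf.generate_dataset(3, scheme=pf.PMDB, repetitions=2,
                                     master_seed=3, preset="clean")
    segments = pf.segment_dataset(recordings)
    return recordings, segments


@pytest.fixture
def profile():
    return pf.SubjectProfile(subject_id="S1", TP=42.0, TT=46.0, rng_seed=11)
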