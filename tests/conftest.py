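import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from tcrkit import SyntheticSpec, find_downstream_inframe_stop, make_transcript


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(seed=11)


@pytest.fixture(scope="session")
def synthetic_transcript(default_spec):
    """One deterministic transcript + annotation shared across tests."""
    return make_transcript(default_spec)


def brute_force_stop_scan(seq: str, cds_end: int):
    """Oracle: check every in-frame triplet 3' of the CDS, take the first stop."""
    stops = {"TAA", "TAG", "TGA"}
    candidates = [
        pos
        for pos in range(cds_end, len(seq) - 2, 3)
        if seq[pos : pos + 3] in stops
    ]
    return min(candidates) if candidates else None
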