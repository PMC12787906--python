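import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import qrsbench as qb

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

FS = 360.0


@pytest.fixture(scope="session")
def clean_ecg():
    """60 s synthetic ECG with its exact R-peak ground truth."""
    return qb.generate_ecg(qb.SyntheticEcgSpec(fs=FS, duration_s=60.0, seed=1))


@pytest.fixture(scope="session")
def ma_noise():
    """60 s synthetic muscle-artifact noise, RMS 0.3 mV."""
    return qb.generate_ma_noise(
        qb.SyntheticNoiseSpec(fs=FS, duration_s=60.0, rms_mV=0.3, seed=2))


@pytest.fixture(scope="session")
def clean_detection(clean_ecg):
    rec, _ = clean_ecg
    return qb.detect_record(rec)


def brute_force_max_matching(refs, dets, dtt) -> int:
    """Independent oracle: maximum-cardinality tolerance matching by recursion.

    Exhaustively assigns each reference to an unused detection within the
    tolerance (or to nothing) and returns the best achievable pair count.
    Exponential; only for tiny instances.
    """
    refs, dets = list(refs), list(dets)

    def best(i: int, used: frozenset) -> int:
        if i == len(refs):
            return 0
        top = best(i + 1, used)  # leave refs[i] unmatched
        for j, d in enumerate(dets):
            if j not in used and abs(d - refs[i]) <= dtt:
                top = max(top, 1 + best(i + 1, used | {j}))
        return top

    return best(0, frozenset())
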