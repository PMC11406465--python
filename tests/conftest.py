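import numpy as np
import pytest

from interofat.intero import HDTTrial, HTTTrial


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_htt(real_reported_conf):
    """Build HTT trials from (nbeats_real, nbeats_reported, confidence) triples."""
    return [HTTTrial(duration_s=30.0, nbeats_real=r, nbeats_reported=p, confidence=c)
            for r, p, c in real_reported_conf]


def make_hdt(correct_conf):
    """Build HDT trials from (correct, confidence) pairs."""
    trials = []
    for ok, conf in correct_conf:
        trials.append(HDTTrial(tone_type="synchronous",
                               judgement="synchronous" if ok else "asynchronous",
                               confidence=conf))
    return trials
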