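import numpy as np
import pytest

import pigletcalls as pc


@pytest.fixture(scope="session")
def params():
    return pc.SpectrogramParams()


@pytest.fixture(scope="session")
def separated_calls():
    """Full-design dataset with sharply separated call types (seeded)."""
    design = pc.recovery_design()
    return pc.generate_feature_dataset(design, pc.default_prototypes(sd_scale=0.15), seed=42)


@pytest.fixture(scope="session")
def realistic_calls():
    """Full-design dataset at the default (blurred) within-type spread."""
    return pc.generate_feature_dataset(pc.default_design(), pc.default_prototypes(), seed=7)


@pytest.fixture(scope="session")
def standardized_separated(separated_calls):
    Z, scaler = pc.standardize(separated_calls[pc.FEATURE_NAMES])
    return Z.to_numpy(), separated_calls


def make_segment(start=0.0, end=1.0, call_id="c1", situation="IS"):
    return pc.CallSegment(
        call_id=call_id,
        file="f.wav",
        start_s=start,
        end_s=end,
        situation=situation,
        piglet="p1",
        litter="l1",
    )


@pytest.fixture
def tone_call(params):
    """1 kHz pure tone embedded in silence, with its true segment."""
    proto = pc.CallTypePrototype(
        "tone", np.ones(8), np.zeros(8), f_start=1000, f_end=1000, tonal_fraction=1.0, dur_mean=0.5
    )
    waveform, (start, end) = pc.generate_waveform(proto, seed=3)
    return waveform, make_segment(start, end, call_id="tone")
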