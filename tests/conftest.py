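import numpy as np
import pytest

import squidtag as st


def balanced_script(seed: int, rotations: int = 2) -> st.BehaviourScript:
    """66 % finning / 18 % glide / 4 % jet / 12 % other, 5 s-aligned bouts.

    One rotation is 250 s; fractions match the scripted field time budget.
    """
    p = st.GaitParams()
    entries = []
    for _ in range(rotations):
        entries += [
            st.ScriptEntry("finning", 85.0, p),
            st.ScriptEntry("glide", 45.0, p),
            st.ScriptEntry("other", 30.0, p),
            st.ScriptEntry("finning", 80.0, p),
            st.ScriptEntry("jet", 10.0, p),
        ]
    return st.BehaviourScript(tuple(entries), seed=seed)


@pytest.fixture(scope="session")
def mixed_recording():
    """A 500 s deployment exercising all four gaits, with its ground truth."""
    script = balanced_script(seed=42)
    return st.simulate_recording(script, mass=1.14)


@pytest.fixture(scope="session")
def finning_only():
    """60 s of noise-free finning at exactly 1.0 Hz."""
    script = st.BehaviourScript(
        (st.ScriptEntry("finning", 60.0,
                        st.GaitParams(fin_freq=1.0, noise_sd=0.0,
                                      orientation_drift_scale=0.0)),),
        seed=3,
    )
    return st.simulate_recording(script)


def rising_zero_crossings(x: np.ndarray) -> int:
    """Independent fin-count oracle: crossings of the detrended signal."""
    d = x - x.mean()
    return int(np.sum((d[:-1] < 0) & (d[1:] >= 0)))
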