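import numpy as np
import pytest

from itdsmear import (
    CONDITIONS,
    design_band_edges,
    make_synthetic_vcv,
    process_token,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def bank_spec():
    return design_band_edges()


@pytest.fixture(scope="session")
def am_signal():
    """1 s sinusoidally amplitude-modulated tone (4 kHz carrier, 40 Hz
    modulator, modulation index 0.8) at 44.1 kHz."""
    fs = 44100.0
    t = np.arange(int(fs)) / fs
    x = (1.0 + 0.8 * np.sin(2 * np.pi * 40.0 * t)) * np.sin(2 * np.pi * 4000.0 * t)
    return x, fs


@pytest.fixture(scope="session")
def vcv_token():
    return make_synthetic_vcv(rng=np.random.default_rng(7))


@pytest.fixture(scope="session")
def small_token():
    """Short low-rate token for per-trial audio tests."""
    return make_synthetic_vcv(duration=0.5, rate=16000.0,
                              rng=np.random.default_rng(11))


@pytest.fixture(scope="session")
def processed_pairs(small_token, bank_spec):
    """Per-condition (reference-ear, smeared-ear) processed sample pairs."""
    ref = process_token(small_token, 0.0, bank_spec).samples
    return {
        cond.label: (ref, process_token(small_token, cond.s, bank_spec).samples)
        for cond in CONDITIONS
    }
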