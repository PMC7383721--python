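import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sig

from itdsmear import (
    CONDITIONS,
    EnvelopeSignal,
    SmearCondition,
    Waveform,
    apply_itd,
    assemble_trial,
    decompose,
    extract_envelope,
    measure_modulation_depth,
    process_token,
    resynthesize,
    smear_envelope,
)
from itdsmear.stimulus import TFS_DISCARD_HZ, dichotic_with_itd, fractional_delay


# ---------------------------------------------------------------- filterbank

def test_processed_mask_follows_discard_rule(bank_spec, rng):
    w = Waveform(rng.standard_normal(8192), 44100.0)
    dec = decompose(w, bank_spec)
    expected = bank_spec.edges[:-1] >= TFS_DISCARD_HZ
    assert np.array_equal(dec.processed_mask, expected)
    # with the study's 30-band design the boundary band straddling 2 kHz is out
    assert bank_spec.edges[dec.processed_indices()[0]] >= 2000.0
    assert bank_spec.edges[dec.processed_indices()[0] - 1] < 2000.0


def test_tone_lands_in_its_band(bank_spec):
    fs = 44100.0
    t = np.arange(int(0.3 * fs)) / fs
    w = Waveform(np.sin(2 * np.pi * 3000.0 * t), fs)
    dec = decompose(w, bank_spec)
    powers = [np.mean(b**2) for b in dec.bands]
    best = int(np.argmax(powers))
    lo, hi = bank_spec.band_edges(best)
    assert lo <= 3000.0 <= hi


def test_band_rejects_out_of_band_noise(bank_spec, rng):
    fs = 44100.0
    w = Waveform(rng.standard_normal(int(fs)), fs)
    dec = decompose(w, bank_spec)
    i = 25  # a processed band
    lo, hi = bank_spec.band_edges(i)
    f, P = sig.welch(dec.bands[i], fs=fs, nperseg=4096)
    inband = P[(f >= lo) & (f <= hi)].mean()
    # an octave outside the corners; zero-phase doubles the design attenuation
    faroff = P[(f < lo / 2) | (f > hi * 2)].mean()
    atten_db = 10 * np.log10(inband / faroff)
    assert atten_db >= bank_spec.stopband_atten_db - 6


def test_decompose_rejects_low_rate(bank_spec):
    w = Waveform(np.zeros(1024) + 1e-6, 8000.0)
    with pytest.raises(ValueError):
        decompose(w, bank_spec)


# ------------------------------------------------------------------ envelope

def test_envelope_of_pure_tone_is_flat():
    fs = 44100.0
    t = np.arange(int(0.5 * fs)) / fs
    env = extract_envelope(0.3 * np.sin(2 * np.pi * 3000.0 * t), fs).values
    core = env[int(0.1 * fs):-int(0.1 * fs)]
    assert np.allclose(core, 0.3, rtol=0.02)


def test_envelope_tracks_am_modulator():
    fs = 44100.0
    t = np.arange(int(fs)) / fs
    mod = 1.0 + 0.8 * np.sin(2 * np.pi * 40.0 * t)
    env = extract_envelope(mod * np.sin(2 * np.pi * 4000.0 * t), fs).values
    sl = slice(int(0.1 * fs), -int(0.1 * fs))
    assert np.max(np.abs(env[sl] - mod[sl]) / mod[sl]) < 0.05


def test_lowpass_attenuates_fast_modulation():
    fs = 44100.0
    t = np.arange(int(fs)) / fs
    carrier = np.sin(2 * np.pi * 4000.0 * t)
    slow = extract_envelope((1 + 0.8 * np.sin(2 * np.pi * 40.0 * t)) * carrier, fs)
    fast = extract_envelope((1 + 0.8 * np.sin(2 * np.pi * 300.0 * t)) * carrier, fs)
    assert measure_modulation_depth(fast) < 0.5 * measure_modulation_depth(slow)


def test_envelope_errors():
    with pytest.raises(ValueError):
        extract_envelope(np.array([]), 44100.0)
    with pytest.raises(ValueError):
        extract_envelope(np.ones(100), 200.0, cutoff=128.0)  # above Nyquist


# ----------------------------------------------------------- smearing + depth

def test_smear_identity_and_constant(rng):
    env = EnvelopeSignal(1.0 + rng.random(1000), 44100.0)
    assert np.array_equal(smear_envelope(env, 0.0).values, env.values)
    const = EnvelopeSignal(np.full(512, 2.5), 44100.0)
    assert np.allclose(smear_envelope(const, 0.7).values, 2.5)


def test_smear_mean_preserved_and_sinusoid_halved():
    fs = 44100.0
    t = np.arange(int(fs)) / fs
    env = EnvelopeSignal(1.0 + 0.8 * np.sin(2 * np.pi * 40.0 * t), fs)
    out = smear_envelope(env, 0.5)
    assert out.values.mean() == pytest.approx(env.values.mean(), rel=1e-12)
    assert np.allclose(out.values, 1.0 + 0.4 * np.sin(2 * np.pi * 40.0 * t), atol=1e-9)
    assert measure_modulation_depth(out) / measure_modulation_depth(env) == (
        pytest.approx(0.5, abs=1e-9)
    )


@settings(derandomize=True, max_examples=40)
@given(
    st.floats(min_value=0.0, max_value=0.95),
    st.floats(min_value=0.0, max_value=0.95),
    st.integers(min_value=0, max_value=2**31 - 1),
)
def test_smear_composes_multiplicatively(s1, s2, seed):
    env = EnvelopeSignal(1.0 + np.random.default_rng(seed).random(256), 1000.0)
    twice = smear_envelope(smear_envelope(env, s1), s2)
    once = smear_envelope(env, 1.0 - (1.0 - s1) * (1.0 - s2))
    assert np.allclose(twice.values, once.values, atol=1e-9)


@settings(derandomize=True, max_examples=40)
@given(
    st.floats(min_value=0.0, max_value=0.95),
    st.integers(min_value=0, max_value=2**31 - 1),
)
def test_depth_ratio_equals_retained_fraction(s, seed):
    env = EnvelopeSignal(1.0 + np.random.default_rng(seed).random(256), 1000.0)
    ratio = measure_modulation_depth(smear_envelope(env, s)) / (
        measure_modulation_depth(env)
    )
    assert ratio == pytest.approx(1.0 - s, abs=1e-6)


def test_depth_metric_closed_forms():
    fs = 44100.0
    t = np.arange(int(fs)) / fs
    assert measure_modulation_depth(EnvelopeSignal(np.full(100, 3.0), fs)) == 0.0
    env = EnvelopeSignal(2.0 * (1.0 + 0.6 * np.sin(2 * np.pi * 10.0 * t)), fs)
    assert measure_modulation_depth(env) == pytest.approx(0.6 / np.sqrt(2), rel=1e-3)
    with pytest.raises(ValueError):
        measure_modulation_depth(EnvelopeSignal(np.zeros(10), fs))
    with pytest.raises(ValueError):
        smear_envelope(EnvelopeSignal(np.ones(10), fs), 1.0)


# -------------------------------------------------------------- resynthesis

def test_resynthesis_near_identity_for_slow_envelopes(bank_spec):
    # carriers in three processed bands, all modulated below the 128 Hz cutoff,
    # so the envelope chain loses (almost) nothing
    fs = 44100.0
    t = np.arange(int(0.6 * fs)) / fs
    mod = 1.0 + 0.6 * np.sin(2 * np.pi * 30.0 * t)
    x = sum(mod * np.sin(2 * np.pi * f * t) for f in (2500.0, 4000.0, 6000.0))
    w = Waveform(x / np.max(np.abs(x)), fs)
    dec = decompose(w, bank_spec)
    out = process_token(w, 0.0, bank_spec)
    ref = sum(dec.bands[i] for i in dec.processed_indices())
    r = np.corrcoef(out.mono(), ref)[0, 1]
    assert r > 0.95


def test_resynthesis_removes_low_bands(vcv_token, bank_spec):
    out = process_token(vcv_token, 0.0, bank_spec)
    f, P = sig.welch(out.mono(), fs=out.rate, nperseg=4096)
    low = P[f < 2000.0].sum()
    high = P[f >= 2000.0].sum()
    assert 10 * np.log10(high / low) >= 20.0


def test_resynthesis_depth_ratio_survives_summation(vcv_token, bank_spec):
    depths = {}
    for s in (0.0, 0.5):
        out = process_token(vcv_token, s, bank_spec)
        depths[s] = measure_modulation_depth(
            extract_envelope(out.mono(), out.rate)
        )
    assert depths[0.5] / depths[0.0] == pytest.approx(0.5, abs=0.05)


def test_resynthesis_envelope_count_checked(vcv_token, bank_spec):
    dec = decompose(vcv_token, bank_spec)
    envs = [extract_envelope(dec.bands[i], dec.rate)
            for i in dec.processed_indices()[:-1]]
    with pytest.raises(ValueError):
        resynthesize(dec, envs)


# ---------------------------------------------------------------------- ITD

def test_zero_itd_is_diotic(small_token):
    st_wav = apply_itd(small_token, 0.0)
    assert np.array_equal(st_wav.samples[:, 0], st_wav.samples[:, 1])


def test_itd_recovered_by_crosscorrelation(rng):
    # noise carrier: aperiodic, so the global cross-correlation peak is the lag
    fs = 44100.0
    w = Waveform(rng.standard_normal(int(0.4 * fs)), fs)
    out = apply_itd(w, 400.0, lead_ear="left")
    L, R = out.samples[:, 0], out.samples[:, 1]
    c = sig.correlate(L, R, mode="full", method="fft")
    k = int(np.argmax(c))
    denom = c[k - 1] - 2 * c[k] + c[k + 1]
    kf = k + 0.5 * (c[k - 1] - c[k + 1]) / denom
    lag_us = (kf - (R.size - 1)) / fs * 1e6
    assert abs(lag_us) == pytest.approx(400.0, abs=5.0)


def test_itd_introduces_no_level_difference(small_token):
    out = apply_itd(small_token, 400.0, lead_ear="right")
    rms = np.sqrt(np.mean(out.samples**2, axis=0))
    assert abs(20 * np.log10(rms[0] / rms[1])) < 0.1


def test_delay_then_advance_recovers_signal(rng):
    fs = 44100.0
    x = rng.standard_normal(4410)
    y = fractional_delay(x, fs, 400e-6)
    z = fractional_delay(y, fs, -400e-6)
    assert np.sqrt(np.mean((z[: x.size] - x) ** 2)) < 1e-6


def test_delay_longer_than_signal_rejected():
    with pytest.raises(ValueError):
        fractional_delay(np.ones(10), 44100.0, 1.0)


# ------------------------------------------------------------ trial assembly

def test_degenerate_trial_refused(small_token, rng):
    with pytest.raises(ValueError):
        assemble_trial(small_token, CONDITIONS[0], 0.0, rng)


def test_target_position_uniform(small_token, processed_pairs):
    rng = np.random.default_rng(2024)
    pair = processed_pairs["100-100"]
    counts = np.zeros(3)
    n = 3000
    for _ in range(n):
        tr = assemble_trial(small_token, CONDITIONS[0], 400.0, rng, processed=pair)
        counts[tr.target_index] += 1
    # 3-sigma binomial band around p = 1/3
    assert np.all(counts / n >= 0.30)
    assert np.all(counts / n <= 0.37)


def test_trial_structure_and_ear_depths(small_token, processed_pairs):
    rng = np.random.default_rng(5)
    cond = SmearCondition.from_label("100-50")
    tr = assemble_trial(small_token, cond, 400.0, rng,
                        processed=processed_pairs["100-50"])
    assert len(tr.intervals) == 3
    non_targets = [iv for i, iv in enumerate(tr.intervals) if i != tr.target_index]
    for iv in non_targets:
        # diotic up to the per-ear smearing: channels differ only by depth
        assert iv.samples.shape[1] == 2
    # reference ear keeps twice the broadband envelope depth of the smeared ear
    iv = non_targets[0]
    d_left = measure_modulation_depth(extract_envelope(iv.samples[:, 0], iv.rate))
    d_right = measure_modulation_depth(extract_envelope(iv.samples[:, 1], iv.rate))
    assert d_left / d_right == pytest.approx(2.0, rel=0.10)


def test_condition_label_parsing():
    assert SmearCondition.from_label("100-71").s == pytest.approx(0.29)
    assert SmearCondition.from_label("100-100").s == 0.0
    with pytest.raises(ValueError):
        SmearCondition.from_label("50-100")
    with pytest.raises(ValueError):
        SmearCondition(s=1.0)
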