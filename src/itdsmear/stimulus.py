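"""Signal-processing chain for envelope-depth-smeared dichotic stimuli.

Pipeline per token and ear:

1. bandpass the mono token into Greenwood-spaced bands (3rd-order elliptic,
   zero-phase);
2. discard bands whose lower corner lies below 2 kHz, so residual
   temporal-fine-structure ITD cues cannot contribute;
3. in each kept band, extract the Hilbert envelope, low-pass it at 128 Hz,
   and compress its fluctuations about the mean by the smear factor ``s``
   (depth becomes ``1 - s`` of the original);
4. re-impose each smeared envelope on that band's fine-structure carrier
   (cosine of the analytic phase) and sum the bands.

Dichotic trials then delay one ear's processed signal by the trial ITD with
a sub-sample fractional delay, leaving interaural level untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .greenwood import FilterBankSpec, design_band_edges

__all__ = [
    "Waveform",
    "SmearCondition",
    "CONDITIONS",
    "BandDecomposition",
    "EnvelopeSignal",
    "DichoticTrial",
    "decompose",
    "extract_envelope",
    "smear_envelope",
    "measure_modulation_depth",
    "resynthesize",
    "process_token",
    "fractional_delay",
    "apply_itd",
    "dichotic_with_itd",
    "assemble_trial",
    "TFS_DISCARD_HZ",
    "ENV_CUTOFF_HZ",
]

#: Bands with a lower corner below this frequency are discarded to remove
#: temporal-fine-structure ITD cues.
TFS_DISCARD_HZ = 2000.0

#: Envelope low-pass cutoff in Hz.
ENV_CUTOFF_HZ = 128.0


@dataclass
class Waveform:
    """Sampled audio: ``samples`` of shape (n,) mono or (n, 2) stereo."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim not in (1, 2):
            raise ValueError("samples must be (n,) or (n, channels)")
        if self.samples.ndim == 2 and self.samples.shape[1] not in (1, 2):
            raise ValueError("only mono or stereo supported")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def mono(self) -> np.ndarray:
        if self.channels != 1:
            raise ValueError("expected a mono waveform")
        return self.samples if self.samples.ndim == 1 else self.samples[:, 0]


@dataclass(frozen=True)
class SmearCondition:
    """Inter-aural modulation-depth condition.

    One ear always keeps the full envelope depth (``s = 0``); the other ear
    (``smeared_ear``, fixed to the right) receives envelopes whose depth is
    reduced to ``1 - s`` of the original. The three study conditions are
    100-100 (s=0), 100-71 (s=0.29) and 100-50 (s=0.50).
    """

    s: float
    label: str = ""
    smeared_ear: str = "right"

    def __post_init__(self) -> None:
        if not 0 <= self.s < 1:
            raise ValueError("smear factor must lie in [0, 1)")
        if self.smeared_ear not in ("left", "right"):
            raise ValueError("smeared_ear must be 'left' or 'right'")
        if not self.label:
            object.__setattr__(
                self, "label", f"100-{round(100 * self.retained_depth)}"
            )

    @property
    def retained_depth(self) -> float:
        return 1.0 - self.s

    @classmethod
    def from_label(cls, label: str) -> "SmearCondition":
        """Parse labels like ``100-71`` (reference ear %, smeared ear %)."""
        try:
            ref, kept = label.replace("%", "").split("-")
            if int(ref) != 100:
                raise ValueError
            s = 1.0 - int(kept) / 100.0
        except ValueError as exc:
            raise ValueError(f"unrecognized condition label: {label!r}") from exc
        return cls(s=s, label=f"100-{int(kept)}")


#: The three inter-aural depth conditions of the study design.
CONDITIONS = (
    SmearCondition(0.0, "100-100"),
    SmearCondition(0.29, "100-71"),
    SmearCondition(0.50, "100-50"),
)


@dataclass
class BandDecomposition:
    """Output of the filterbank: one band-limited signal per band."""

    bands: list[np.ndarray]
    spec: FilterBankSpec
    rate: float
    processed_mask: np.ndarray  # True for bands kept (lower edge >= 2 kHz)

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def processed_indices(self) -> np.ndarray:
        return np.flatnonzero(self.processed_mask)


@dataclass
class EnvelopeSignal:
    """Low-passed Hilbert envelope of one band."""

    values: np.ndarray
    rate: float
    cutoff: float = ENV_CUTOFF_HZ

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _band_sos(low: float, high: float, rate: float, spec: FilterBankSpec):
    return signal.ellip(
        spec.filter_order,
        spec.passband_ripple_db,
        spec.stopband_atten_db,
        [low, high],
        btype="bandpass",
        fs=rate,
        output="sos",
    )


def decompose(w: Waveform, spec: FilterBankSpec | None = None) -> BandDecomposition:
    """Split a mono waveform into Greenwood-spaced bands (zero-phase elliptic).

    Zero-phase (forward-backward) filtering keeps the bands time-aligned so
    the later envelope/carrier recombination does not smear across bands.
    """
    if spec is None:
        spec = design_band_edges()
    x = w.mono()
    if w.rate <= 2 * spec.f_high:
        raise ValueError(
            f"rate {w.rate} Hz too low for an upper corner of {spec.f_high} Hz"
        )
    bands = []
    for i in range(spec.n_bands):
        lo, hi = spec.band_edges(i)
        sos = _band_sos(lo, hi, w.rate, spec)
        bands.append(signal.sosfiltfilt(sos, x))
    mask = spec.edges[:-1] >= TFS_DISCARD_HZ
    return BandDecomposition(bands=bands, spec=spec, rate=w.rate,
                             processed_mask=np.asarray(mask))


def extract_envelope(
    band: np.ndarray, rate: float, cutoff: float = ENV_CUTOFF_HZ
) -> EnvelopeSignal:
    """Hilbert-envelope magnitude, low-pass filtered at ``cutoff`` Hz.

    The low-pass is a 4th-order Butterworth applied forward-backward
    (zero phase), so the envelope stays aligned with its carrier.
    """
    band = np.asarray(band, dtype=float)
    if band.size == 0:
        raise ValueError("empty signal")
    if cutoff >= rate / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    env = np.abs(signal.hilbert(band))
    sos = signal.butter(4, cutoff, btype="low", fs=rate, output="sos")
    smoothed = signal.sosfiltfilt(sos, env)
    return EnvelopeSignal(values=smoothed, rate=rate, cutoff=cutoff)


def smear_envelope(env: EnvelopeSignal, s: float) -> EnvelopeSignal:
    """Compress envelope fluctuations about the mean by the smear factor.

    ``env' = mean + (1 - s) * (env - mean)``: the mean is preserved exactly
    and any ratio-scale modulation-depth metric is scaled by ``1 - s``.
    """
    if not 0 <= s < 1:
        raise ValueError("smear factor must lie in [0, 1)")
    mu = env.values.mean()
    return replace(env, values=mu + (1.0 - s) * (env.values - mu))


def measure_modulation_depth(env: EnvelopeSignal | np.ndarray) -> float:
    """Modulation depth as RMS fluctuation about the mean, over the mean.

    Coefficient of variation of the envelope: 0 for a constant envelope;
    ``m / sqrt(2)`` for a sinusoidal modulator with modulation index ``m``.
    Ratio-faithful under linear fluctuation compression, which is what makes
    the smear factors verifiable as depth percentages.
    """
    v = env.values if isinstance(env, EnvelopeSignal) else np.asarray(env, float)
    if v.size == 0:
        raise ValueError("empty envelope")
    mu = v.mean()
    if mu <= 0:
        raise ValueError("modulation depth undefined for non-positive mean")
    return float(np.sqrt(np.mean((v - mu) ** 2)) / mu)


def resynthesize(
    dec: BandDecomposition,
    envelopes: dict[int, EnvelopeSignal] | list[EnvelopeSignal],
    keep_low_bands: bool = False,
    match_peak: float | None = None,
) -> Waveform:
    """Recombine processed bands: smeared envelope times fine-structure carrier.

    Each processed band contributes ``env_i(t) * cos(phi_i(t))`` where
    ``phi_i`` is the band's analytic-signal phase. Bands below the 2 kHz
    discard boundary are excluded from the sum unless ``keep_low_bands``
    re-adds them unprocessed. The output is peak-normalized to
    ``match_peak`` when given.
    """
    idx = dec.processed_indices()
    if not isinstance(envelopes, dict):
        if len(envelopes) != len(idx):
            raise ValueError("need one envelope per processed band")
        envelopes = dict(zip(idx, envelopes))
    if set(envelopes) != set(idx.tolist()):
        raise ValueError("envelope keys must match the processed band indices")
    out = np.zeros(dec.bands[0].shape[0])
    for i in idx:
        carrier = np.cos(np.angle(signal.hilbert(dec.bands[i])))
        out += envelopes[i].values * carrier
    if keep_low_bands:
        for i in np.flatnonzero(~dec.processed_mask):
            out += dec.bands[i]
    if match_peak is not None:
        peak = np.max(np.abs(out))
        if peak > 0:
            out *= match_peak / peak
    return Waveform(out, dec.rate)


def process_token(
    token: Waveform,
    s: float,
    spec: FilterBankSpec | None = None,
    cutoff: float = ENV_CUTOFF_HZ,
    keep_low_bands: bool = False,
) -> Waveform:
    """Full monaural chain: filterbank -> envelope -> smear -> resynthesis."""
    dec = decompose(token, spec)
    envs = {
        int(i): smear_envelope(extract_envelope(dec.bands[i], dec.rate, cutoff), s)
        for i in dec.processed_indices()
    }
    peak = float(np.max(np.abs(token.mono())))
    return resynthesize(dec, envs, keep_low_bands=keep_low_bands, match_peak=peak)


def fractional_delay(x: np.ndarray, rate: float, delay_s: float) -> np.ndarray:
    """Delay ``x`` by ``delay_s`` seconds (sub-sample, FFT phase ramp).

    The signal is zero-padded beyond the delay before the circular shift, so
    no energy wraps around; output length equals input length plus the pad.
    A negative ``delay_s`` advances the signal on the *same* grid (no pad),
    which exactly inverts a prior positive delay of the same magnitude; the
    first ``|delay_s|`` of the signal must be (near-)silent headroom or it
    wraps circularly.
    """
    x = np.asarray(x, dtype=float)
    if abs(delay_s) >= x.shape[0] / rate:
        raise ValueError("delay exceeds the signal duration")
    if delay_s >= 0:
        pad = int(np.ceil(delay_s * rate)) + 1
        xp = np.concatenate([x, np.zeros(pad)])
    else:
        xp = x
    n = xp.shape[0]
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    return np.fft.irfft(np.fft.rfft(xp) * np.exp(-2j * np.pi * freqs * delay_s), n=n)


def apply_itd(w: Waveform, itd_us: float, lead_ear: str = "left") -> Waveform:
    """Make a stereo signal whose lagging ear is delayed by ``itd_us``.

    The leading channel is the input; the lagging channel is the identical
    signal fractionally delayed, so no interaural level difference is
    introduced. ``itd_us = 0`` yields a diotic pair.
    """
    x = w.mono()
    return dichotic_with_itd(x, x, w.rate, itd_us, lead_ear)


def dichotic_with_itd(
    left: np.ndarray,
    right: np.ndarray,
    rate: float,
    itd_us: float,
    lead_ear: str = "left",
) -> Waveform:
    """Stack per-ear signals into stereo, delaying the lagging ear by the ITD."""
    if lead_ear not in ("left", "right"):
        raise ValueError("lead_ear must be 'left' or 'right'")
    if itd_us < 0:
        raise ValueError("ITD must be non-negative; use lead_ear for the sign")
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("per-ear signals must have equal length")
    delay_s = itd_us * 1e-6
    if itd_us == 0:
        return Waveform(np.column_stack([left, right]), rate)
    if lead_ear == "left":
        lag = fractional_delay(right, rate, delay_s)
        lead = np.concatenate([left, np.zeros(lag.shape[0] - left.shape[0])])
        stereo = np.column_stack([lead, lag])
    else:
        lag = fractional_delay(left, rate, delay_s)
        lead = np.concatenate([right, np.zeros(lag.shape[0] - right.shape[0])])
        stereo = np.column_stack([lag, lead])
    return Waveform(stereo, rate)


@dataclass
class DichoticTrial:
    """One 3-AFC trial: three stereo intervals, one carrying the ITD."""

    intervals: list[Waveform]
    target_index: int
    itd_us: float
    lead_ear: str
    token_id: int
    condition: SmearCondition


def _equate_rms(intervals: list[Waveform]) -> list[Waveform]:
    rms = [np.sqrt(np.mean(iv.samples**2)) for iv in intervals]
    ref = float(np.mean(rms))
    return [
        Waveform(iv.samples * (ref / r if r > 0 else 1.0), iv.rate)
        for iv, r in zip(intervals, rms)
    ]


def assemble_trial(
    token: Waveform,
    condition: SmearCondition,
    itd_us: float,
    rng: np.random.Generator,
    token_id: int = 0,
    spec: FilterBankSpec | None = None,
    processed: tuple[np.ndarray, np.ndarray] | None = None,
) -> DichoticTrial:
    """Build a 3-AFC dichotic trial for one condition and ITD.

    Both ears receive the envelope-processed token (reference ear ``s = 0``,
    smeared ear ``s`` per the condition) in all three intervals; one
    uniformly random interval carries the ITD with a random leading ear.
    ``processed`` lets callers reuse the per-ear processed pair across
    trials, since the filterbank chain is the expensive step.

    All intervals are equated in RMS so no loudness cue marks the target.
    """
    if itd_us <= 0:
        raise ValueError("the target interval must be lateralizable: itd_us > 0")
    if processed is None:
        ref = process_token(token, 0.0, spec).samples
        smeared = process_token(token, condition.s, spec).samples
    else:
        ref, smeared = processed
    if condition.smeared_ear == "right":
        ear_l, ear_r = ref, smeared
    else:
        ear_l, ear_r = smeared, ref

    target = int(rng.integers(3))
    lead_ear = "left" if rng.integers(2) == 0 else "right"
    intervals = []
    for i in range(3):
        if i == target:
            intervals.append(
                dichotic_with_itd(ear_l, ear_r, token.rate, itd_us, lead_ear)
            )
        else:
            intervals.append(dichotic_with_itd(ear_l, ear_r, token.rate, 0.0))
    return DichoticTrial(
        intervals=_equate_rms(intervals),
        target_index=target,
        itd_us=itd_us,
        lead_ear=lead_ear,
        token_id=token_id,
        condition=condition,
    )
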