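"""Synthetic vowel-consonant-vowel (VCV) probe tokens.

Stand-ins for recorded VCV utterances (/aka/, /aga/, /apa/, /aba/, /ata/,
/ada/): a harmonic complex at a female-like F0 (~220 Hz) with harmonics up
to the filterbank's upper corner, shaped by a vowel-consonant-vowel
amplitude contour — two high-energy vowel segments flanking a low-energy
consonant gap, with a brief plosive-like noise burst at the gap's release.
The contour gives the token a deep broadband temporal envelope, which is
the property the smearing chain manipulates; the tokens carry no phonetic
content and are labelled synthetic throughout.
"""

from __future__ import annotations

import numpy as np

from .stimulus import Waveform

__all__ = ["make_synthetic_vcv", "make_token_set", "TOKEN_LABELS"]

#: Labels for the six synthetic stand-in tokens (mirroring the VCV set size).
TOKEN_LABELS = ("aka", "aga", "apa", "aba", "ata", "ada")


def _raised_cosine_contour(
    t: np.ndarray, duration: float, gap_level: float, ramp: float
) -> np.ndarray:
    """V-C-V amplitude contour: vowel-gap-vowel with raised-cosine edges."""
    v = duration * 0.38          # each vowel segment
    gap = duration - 2 * v       # consonant closure
    contour = np.full_like(t, gap_level)
    in_v1 = t < v
    in_v2 = t >= v + gap
    contour[in_v1] = 1.0
    contour[in_v2] = 1.0
    # smooth the four segment boundaries
    for edge, sign in ((v, -1.0), (v + gap, +1.0)):
        m = np.abs(t - edge) < ramp / 2
        phase = (t[m] - edge) / ramp * np.pi
        mid = 0.5 * (1.0 + gap_level)
        half = 0.5 * (1.0 - gap_level)
        contour[m] = mid + sign * half * np.sin(phase)
    # onset/offset ramps
    on = t < ramp
    contour[on] *= 0.5 * (1.0 - np.cos(np.pi * t[on] / ramp))
    off = t > duration - ramp
    contour[off] *= 0.5 * (1.0 - np.cos(np.pi * (duration - t[off]) / ramp))
    return contour


def make_synthetic_vcv(
    duration: float = 0.8,
    rate: float = 44100.0,
    rng: np.random.Generator | None = None,
    f0: float = 220.0,
    f_max: float = 7562.0,
    gap_level: float = 0.08,
) -> Waveform:
    """Generate one synthetic VCV-like token (mono, peak-normalized).

    Deterministic per ``rng`` state: harmonic phases, a small F0 offset and
    the burst noise are the only random ingredients.
    """
    if duration <= 0.3:
        raise ValueError("token must be longer than 0.3 s")
    if rate < 16000:
        raise ValueError("rate below 16 kHz cannot carry the band content")
    rng = np.random.default_rng(0) if rng is None else rng

    n = int(round(duration * rate))
    t = np.arange(n) / rate
    f0 = f0 * (1.0 + rng.uniform(-0.03, 0.03))
    n_harm = int(f_max // f0)
    phases = rng.uniform(0, 2 * np.pi, n_harm)
    # gentle spectral roll-off so vowel energy is low-frequency dominated
    amps = 1.0 / np.arange(1, n_harm + 1) ** 0.7
    x = np.zeros(n)
    for h in range(n_harm):
        x += amps[h] * np.sin(2 * np.pi * f0 * (h + 1) * t + phases[h])

    ramp = 0.03  # s, raised-cosine transition
    contour = _raised_cosine_contour(t, duration, gap_level, ramp)
    x *= contour

    # plosive-like broadband burst at the release of the consonant gap
    v = duration * 0.38
    burst_t0 = v + (duration - 2 * v) * 0.7
    burst = np.abs(t - burst_t0) < 0.01
    x[burst] += 0.25 * np.max(np.abs(x)) * rng.standard_normal(int(burst.sum()))

    x /= np.max(np.abs(x))
    return Waveform(x, rate)


def make_token_set(
    rate: float = 44100.0,
    duration: float = 0.8,
    seed: int | np.random.SeedSequence = 0,
) -> dict[str, Waveform]:
    """Six synthetic tokens, one per label, each from its own child stream."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(len(TOKEN_LABELS))
    return {
        label: make_synthetic_vcv(duration, rate, np.random.default_rng(s))
        for label, s in zip(TOKEN_LABELS, streams)
    }
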