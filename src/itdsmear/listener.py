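"""Simulated 3-AFC listeners and synthetic experiment generation.

Two responder families stand in for the human participants:

* a *psychometric* listener — probability correct follows
  ``gamma + (1 - gamma - lambda) * F((ln itd - ln alpha) / beta)`` with a
  sigmoid ``F`` on a log-ITD abscissa (chance ``gamma = 1/3`` for 3-AFC);
  cheap, used for staircase validation and panel simulation;
* a *mechanistic* observer — cross-correlates the two ears' broadband
  envelopes in each interval, estimates an interaural lag, and picks the
  most lateralized interval. A constant envelope-domain internal-noise
  floor makes its accuracy degrade as the smeared ear's modulation depth
  shrinks, which is the mechanism hypothesized to drive the headline
  effect (reduced interaural envelope coherence hurting binaural
  processing).

A listener *panel* draws per-listener thresholds from a log-normal and
inflates them multiplicatively per condition, giving a synthetic
within-subject experiment with the structure the statistics stage assumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import erf, sqrt

import numpy as np
import pandas as pd

from .staircase import TrackConfig, TrackResult, run_track
from .stimulus import CONDITIONS, DichoticTrial, SmearCondition, extract_envelope

__all__ = [
    "PsychometricSpec",
    "p_correct",
    "respond",
    "make_responder",
    "envelope_xcorr_observer",
    "PanelSpec",
    "ExperimentResult",
    "simulate_experiment",
]


@dataclass(frozen=True)
class PsychometricSpec:
    """3-AFC psychometric function in log-ITD.

    ``alpha`` (µs) is the ITD at the sigmoid midpoint, ``beta`` the log-ITD
    spread (larger = shallower), ``gamma`` the 3-AFC guess rate, ``lam``
    the lapse rate bounding the ceiling at ``1 - lam``.
    """

    alpha: float = 150.0
    beta: float = 0.5
    gamma: float = 1.0 / 3.0
    lam: float = 0.02
    family: str = "gaussian"  # 'gaussian' | 'logistic' | 'weibull'

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not 0 <= self.lam <= 0.05:
            raise ValueError("lapse rate must lie in [0, 0.05]")
        if self.family not in ("gaussian", "logistic", "weibull"):
            raise ValueError(f"unknown sigmoid family: {self.family!r}")


def _sigmoid(z: float, family: str) -> float:
    if family == "gaussian":
        return 0.5 * (1.0 + erf(z / sqrt(2.0)))
    if family == "logistic":
        return 1.0 / (1.0 + np.exp(-z))
    # Weibull in log coordinates == Gumbel CDF
    return 1.0 - np.exp(-np.exp(z))


def p_correct(itd_us: float, spec: PsychometricSpec) -> float:
    """Probability of a correct 3-AFC response at ``itd_us`` microseconds."""
    if itd_us <= 0:
        raise ValueError("ITD must be positive")
    z = (np.log(itd_us) - np.log(spec.alpha)) / spec.beta
    return spec.gamma + (1.0 - spec.gamma - spec.lam) * _sigmoid(z, spec.family)


def respond(itd_us: float, spec: PsychometricSpec, rng: np.random.Generator) -> bool:
    """One Bernoulli 3-AFC response at the given ITD."""
    return bool(rng.random() < p_correct(itd_us, spec))


def make_responder(spec: PsychometricSpec):
    """Adapter giving the ``responder(itd_us, rng)`` seam of ``run_track``."""
    return lambda itd_us, rng: respond(itd_us, spec, rng)


#: Modulation-rate passband (Hz) of the observer's envelope comparison. The
#: slow utterance contour (< ~10 Hz) carries almost no timing information —
#: its autocorrelation is flat over many milliseconds, so its lag estimate is
#: ill-conditioned — whereas syllabic-to-periodicity-rate fluctuations give a
#: sharp interaural cross-correlation peak.
OBSERVER_MOD_BAND = (10.0, 128.0)

#: Physiological search window for the interaural lag (µs).
OBSERVER_MAX_LAG_US = 1500.0


def _envelope_lag_us(iv, rng: np.random.Generator, env_noise: float) -> float:
    """Interaural lag (µs) of the peak envelope cross-correlation.

    Envelopes are band-passed to modulation rates ``OBSERVER_MOD_BAND``
    before cross-correlation, and the peak is searched within
    ``±OBSERVER_MAX_LAG_US`` with parabolic sub-sample interpolation.
    ``env_noise`` is the SD of additive envelope noise relative to the
    envelope mean (a depth-independent internal noise floor).
    """
    from scipy.signal import butter, correlate, sosfiltfilt

    samples = iv.samples
    if np.max(np.abs(samples)) == 0:
        raise ValueError("silent interval: lateralization undecidable")
    sos = butter(2, OBSERVER_MOD_BAND, btype="bandpass", fs=iv.rate, output="sos")
    envs = []
    for ch in range(2):
        env = extract_envelope(samples[:, ch], iv.rate).values
        mu = env.mean()
        flux = sosfiltfilt(sos, env)
        if env_noise > 0:
            flux = flux + rng.normal(0.0, env_noise * mu, flux.shape)
        envs.append(flux)
    c = correlate(envs[0], envs[1], mode="full", method="fft")
    center = envs[1].size - 1
    half = int(round(OBSERVER_MAX_LAG_US * 1e-6 * iv.rate))
    window = slice(max(0, center - half), min(c.size, center + half + 1))
    k = int(np.argmax(c[window])) + window.start
    kf = float(k)
    if 0 < k < c.size - 1:
        denom = c[k - 1] - 2 * c[k] + c[k + 1]
        if denom != 0:
            kf = k + 0.5 * float(c[k - 1] - c[k + 1]) / float(denom)
    return float((kf - center) / iv.rate * 1e6)


def envelope_xcorr_observer(
    trial: DichoticTrial,
    internal_noise_us: float,
    rng: np.random.Generator,
    env_noise: float = 0.0,
) -> int:
    """Choose the interval with the largest estimated interaural envelope lag.

    ``internal_noise_us`` is Gaussian jitter added to each interval's lag
    estimate (late, decision-stage noise). ``env_noise`` adds a constant
    noise floor to the envelopes themselves (relative to the envelope mean)
    *before* cross-correlation; because smearing shrinks envelope
    fluctuations while this floor stays fixed, the lag estimate degrades as
    the interaural depth difference grows — the mechanistic account of the
    effect under study.
    """
    lags = []
    for iv in trial.intervals:
        lag = _envelope_lag_us(iv, rng, env_noise)
        lags.append(lag + rng.normal(0.0, internal_noise_us))
    return int(np.argmax(np.abs(lags)))


@dataclass(frozen=True)
class PanelSpec:
    """Synthetic listener panel for a within-subject depth-smearing study.

    Listener base thresholds (the 100-100 condition) are log-normal with
    median ``alpha_median`` µs and log-SD ``alpha_log_sd``; each condition
    multiplies a listener's threshold by its entry in
    ``condition_effects`` (non-decreasing across 100-100, 100-71, 100-50:
    thresholds worsen as the interaural depth difference grows). Values are
    synthetic study conditions, not estimates of the human panel.
    """

    n_listeners: int = 6
    alpha_median: float = 150.0
    alpha_log_sd: float = 0.35
    beta: float = 0.5
    lapse: float = 0.02
    family: str = "gaussian"
    condition_effects: tuple[float, ...] = (1.0, 1.3, 1.8)
    conditions: tuple[SmearCondition, ...] = CONDITIONS

    def __post_init__(self) -> None:
        if self.n_listeners < 1:
            raise ValueError("need at least one listener")
        if len(self.condition_effects) != len(self.conditions):
            raise ValueError("one effect per condition")
        if any(
            b < a
            for a, b in zip(self.condition_effects, self.condition_effects[1:])
        ):
            raise ValueError("condition effects must be non-decreasing")


@dataclass
class ExperimentResult:
    """Thresholds (listeners x conditions, µs) plus the raw track results."""

    table: pd.DataFrame
    tracks: dict[tuple[int, str], TrackResult]

    @property
    def all_converged(self) -> bool:
        return all(t.converged for t in self.tracks.values())


def simulate_experiment(
    panel: PanelSpec,
    track_cfg: TrackConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> ExperimentResult:
    """Run every listener through an adaptive track in every condition.

    Each (listener, condition) track gets an independent child stream of the
    seed, so the whole experiment is reproducible bit-for-bit and tracks do
    not share randomness.
    """
    if track_cfg is None:
        track_cfg = TrackConfig()
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    alpha_stream, *track_streams = ss.spawn(1 + panel.n_listeners * len(panel.conditions))
    alpha_rng = np.random.default_rng(alpha_stream)
    base_alpha = panel.alpha_median * np.exp(
        alpha_rng.normal(0.0, panel.alpha_log_sd, panel.n_listeners)
    )

    rows = {}
    tracks: dict[tuple[int, str], TrackResult] = {}
    stream = iter(track_streams)
    for li in range(panel.n_listeners):
        row = {}
        for cond, effect in zip(panel.conditions, panel.condition_effects):
            spec = PsychometricSpec(
                alpha=float(base_alpha[li] * effect),
                beta=panel.beta,
                lam=panel.lapse,
                family=panel.family,
            )
            rng = np.random.default_rng(next(stream))
            result = run_track(track_cfg, make_responder(spec), rng)
            tracks[(li, cond.label)] = result
            row[cond.label] = result.threshold
        rows[li] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "listener"
    return ExperimentResult(table=table, tracks=tracks)
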