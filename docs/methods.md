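# Methods

This note documents the models, numerical choices and limitations behind
`itdsmear`. The package simulates an ITD-threshold experiment in which the
two ears receive speech-like tokens differing only in temporal-envelope
modulation depth, and analyzes the resulting thresholds the way a
within-subject psychoacoustic study would.

## Signal chain

**Filterbank.** Tokens are decomposed into `n_bands = 30` bands between
80 and 7562 Hz. Corner frequencies are equally spaced in normalized
cochlear position under the Greenwood map f(x) = A(10^(ax) − k) with the
standard human constants A = 165.4 Hz, a = 2.1, k = 0.88 (configurable via
`GreenwoodParams`). Filters are 3rd-order elliptic bandpasses; passband
ripple 1 dB and stopband attenuation 50 dB are conventional defaults, and
filtering is zero-phase (forward–backward, `sosfiltfilt`), which (a)
avoids per-band group-delay misalignment that would smear the
recombination and (b) doubles the effective attenuation.

**Fine-structure discard.** Bands whose *lower* corner lies below 2 kHz
are excluded from further processing and from the output sum, so that
low-frequency temporal fine structure cannot contribute ITD information;
with the default 30-band design this keeps the 10 bands spanning
≈2.23–7.56 kHz (the band straddling 2 kHz is discarded). A
`keep_low_bands` flag re-adds the low bands unprocessed for the
alternative reading in which all bands are summed.

**Envelope extraction.** Per band, the envelope is |analytic signal|
(Hilbert transform) low-passed at 128 Hz. The low-pass is a 4th-order
Butterworth applied zero-phase (the filter family is a design choice; only
the cutoff is part of the study conditions).

**Smearing.** `smear_envelope` maps env → mean + (1 − s)(env − mean).
This linear fluctuation compression is chosen because it makes the
stated depth outcomes (71% and 50% of original depth for s = 0.29 and
0.50) hold *exactly* under any ratio-scale depth metric, preserves the
envelope mean (hence band level), and composes multiplicatively:
smearing by s₁ then s₂ equals one smear with 1 − (1 − s₁)(1 − s₂).

**Depth metric.** `measure_modulation_depth` is the coefficient of
variation, RMS(env − mean)/mean: 0 for constant envelopes, m/√2 for a
sinusoidal modulator with index m. It is ratio-faithful under the smear
operation; a peak-based metric such as (max − min)/(max + min) would be
dominated by single extrema on speech envelopes.

**Resynthesis.** Each kept band is rebuilt as env(t)·cos φ(t) with φ the
band's analytic phase (envelope/fine-structure factorization), then bands
are summed and the result peak-normalized to the input. This preserves the
fine structure while giving exact control of each band envelope. The
envelope low-pass bounds what resynthesis can preserve: signals whose
band-envelope fluctuations lie below 128 Hz reconstruct nearly identically
(correlation > 0.95 with the band-sum), whereas a harmonic token with
220 Hz inter-harmonic beating loses that beating (correlation ≈ 0.93).
After full resynthesis the broadband depth ratio tracks 1 − s within a few
percent (band-interaction terms account for the residual).

**ITD imposition.** The trial ITD is a frequency-domain fractional delay
(phase ramp on the rFFT of the zero-padded signal). At the default
44.1 kHz one sample is ≈22.7 µs — coarser than the thresholds being
tracked — hence sub-sample delay. The delayed channel is an exact copy of
the leading channel, so no interaural level difference is introduced
(channel RMS ratio ≪ 0.1 dB). A negative delay applied on the same FFT
grid exactly inverts a prior positive delay. The delay is applied to the
whole waveform (not gated segments), and all three 3-AFC intervals are
RMS-equated so loudness cannot mark the target.

**Conditions.** One ear (fixed: right) receives the smeared token, the
other the s = 0 token, in *all* intervals; only the target interval
carries the ITD, with leading ear randomized per trial. Conditions are
labelled 100–100, 100–71, 100–50 by the percentage of depth per ear.

## Adaptive procedure

Transformed 2-down/1-up staircase: start 400 µs; × 1.25 after every
incorrect response; × 0.75 after two consecutive correct responses
(counter reset on every step and every error); 12 reversals; threshold =
geometric mean of the ITDs presented on the last 8 reversal trials. A
reversal is a trial at which the prescribed step direction differs from
the previous step's; the first step never counts. Safety bounds, not part
of the procedure proper: ITD clipped to [10, 4000] µs (clipped steps still
drive direction bookkeeping) and a 200-trial cap, after which a track is
flagged non-converged.

**Convergence point.** With equal up/down steps in log units a
2-down/1-up rule converges where p² = ½, i.e. 70.7% correct. The
25%-up/25%-down rule implemented here (exactly as specified, not
symmetrized) is asymmetric in log: |ln 0.75| > ln 1.25. Its size-weighted
equilibrium solves p²·ln(4/3) = (1 − p²)·ln(5/4), giving p* ≈ 0.661.
Monte-Carlo runs with the default simulated listeners measure a mean
probability-correct at the estimated thresholds of ≈ 0.67–0.68 (the
reversal-based estimator sits slightly above the raw equilibrium). Users
comparing against the textbook 70.7% figure should be aware the printed
step rule targets a slightly lower point; `TrackConfig.down_factor = 0.8`
would restore the symmetric rule.

An alternative threshold estimator pairing consecutive reversals into
midpoints (`threshold_from_midpoints`) is provided; on log-ITD it is
algebraically identical to the geometric mean of the same reversals, which
is the default.

## Simulated listeners

**Psychometric responder.** p(correct) = γ + (1 − γ − λ)·F((ln ITD −
ln α)/β), γ = ⅓ (3-AFC), lapse λ ∈ [0, 0.05]. F is a cumulative Gaussian
by default (logistic and Weibull/Gumbel available); the log-ITD abscissa
matches the multiplicative staircase. Defaults α = 150 µs, β = 0.5,
λ = 0.02 describe a plausible envelope-ITD listener: performance rises
from near-chance to near-ceiling over roughly a factor of e^(2·0.5) ≈ 2.7
in ITD. These are synthetic panel parameters, not estimates of any human
group.

**Mechanistic observer.** For each interval, the observer extracts both
ears' broadband envelopes, band-passes them to modulation rates of
10–128 Hz, cross-correlates them, and takes the interpolated peak lag
within a ±1500 µs physiological window; it chooses the interval with the
largest |lag|. The lower edge of the modulation passband removes the slow
utterance contour, whose cross-correlation peak is numerically
ill-conditioned for sub-millisecond lags (its autocorrelation is flat over
tens of milliseconds). Two noise sources: `internal_noise_us`, Gaussian
jitter on each lag estimate (decision-stage noise, condition-independent),
and `env_noise`, an additive envelope-domain noise floor scaled to the
envelope mean. Because smearing shrinks envelope fluctuations while the
floor stays fixed, `env_noise` makes accuracy degrade as the interaural
depth difference grows — the mechanistic counterpart of the effect under
study; pure lag jitter cannot produce that dependence. Even noise-free,
cross-correlating a full-depth against a smeared envelope of the
resynthesized signal biases the lag estimate, so accuracy falls across
100–100 → 100–71 → 100–50.

**Panel.** `PanelSpec` draws per-listener base thresholds from a
log-normal (median 150 µs, log-SD 0.35 ≈ a ×1.4 between-listener spread)
and multiplies them by non-decreasing per-condition effects, default
(1.0, 1.3, 1.8). Each (listener, condition) track consumes an independent
child stream of the experiment seed (`numpy` `SeedSequence.spawn`), so
results are reproducible bit-for-bit and insensitive to execution order.

## Statistics

One-way repeated-measures ANOVA by direct sums-of-squares decomposition
(condition, subject, residual); F = MS_cond/MS_err on (k − 1,
(k − 1)(n − 1)) df — (2, 10) for the 6 × 3 design. No sphericity
correction is applied by default (matching the uncorrected df convention);
thresholds are analyzed in µs without log transform. Degenerate inputs: a
table with no condition effect *and* no residual returns F = 0, p = 1; a
perfectly additive table with a nonzero condition effect raises, since
F is genuinely undefined. Post-hoc comparisons are standard two-sided
paired t-tests (identical samples return t = 0, p = 1; constant nonzero
differences raise); the three p-values are corrected with Holm's
step-down procedure, reported both as reject/fail decisions at α = 0.05
and as adjusted p-values (running maxima of (m − i)·p₍ᵢ₎ clipped at 1).
The implementation is cross-checked in the test suite against independent
oracles (a from-definitions SS computation, `pingouin.rm_anova`,
`scipy.stats.ttest_rel`, `statsmodels` Holm).

## Synthetic tokens

`make_synthetic_vcv` builds a harmonic complex (F0 ≈ 220 Hz with ±3%
per-token jitter, 1/n^0.7 spectral roll-off up to 7562 Hz, random
harmonic phases) under a vowel–consonant–vowel amplitude contour
(raised-cosine transitions, consonant gap at 8% of vowel amplitude, a
10 ms noise burst at the gap release). This reproduces the features the
pipeline manipulates — broadband spectrum covering the filterbank,
strong low-rate envelope modulation (broadband depth ≈ 0.5), a
consonant landmark — but none of the phonetic structure of real VCV
recordings: no formant transitions, no voicing distinctions, no
between-token phonetic variability. Passing tests therefore demonstrate
the correctness of the processing, tracking and analysis machinery and
the *direction* of the depth effect under the stated listener model; they
do not certify effect sizes for human listeners or real speech. A loader
(`itdsmear.io.read_wav`) accepts recorded tokens wherever synthetic ones
are used.

## Problem sizes and tolerances

Default simulations are sized for interactive use: 0.8 s tokens at
44.1 kHz (0.5 s at 16 kHz where per-trial audio is assembled in bulk),
6 × 3 × 1 tracks per experiment, 200–500 track/experiment replicates in
Monte-Carlo calibrations. Numerical tolerances used in validation: 1e-9
relative for the Greenwood round-trip, band-edge spacing and ANOVA-vs-
oracle agreement; 1e-6 for envelope depth ratios and the delay-inverse
identity; ±5% for depth ratios after full band resynthesis; binomial
3σ bands for Monte-Carlo frequencies.

## Known limitations

- The smearing operation can drive instantaneous envelope values negative
  for deep envelopes with s near 0 (mean-crossing fluctuations are
  scaled, not floored); with the study's s ≤ 0.5 this does not occur in
  practice.
- The mechanistic observer is a minimal lag-based decision model; it is
  not a calibrated binaural model (no interaural coherence weighting, no
  multiple-channel combination).
- Presentation level, inter-stimulus interval and headphone/transducer
  effects are out of scope (config placeholders only); the responder
  interface is the seam where real playback and a human would sit.
- The repeated-measures ANOVA assumes sphericity; a Greenhouse–Geisser
  option is not applied by default to match the uncorrected-df reporting
  convention.
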