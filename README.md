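# itdsmear

Simulation pipeline for a binaural-hearing question: how does the
interaural time difference (ITD) threshold change when the two ears
receive speech whose **temporal envelope modulation depth** differs?

High-frequency hearing conveys ITDs mainly through the slow amplitude
envelope of each cochlear channel, not the fine structure. If one ear's
envelope is "smeared" — its modulation depth compressed — the interaural
envelope correlation that binaural neurons rely on degrades, and
lateralization should require larger ITDs. This package implements the
full experimental computation around that question with simulated
listeners in place of human participants, so every stage runs on a desk:

- **Stimulus processing** — vowel-consonant-vowel (VCV)-like probe tokens
  are filtered into 30 bands between 80 and 7562 Hz with corner
  frequencies equally spaced along the Greenwood cochlear map
  (f = A(10^(ax) − k), human constants A = 165.4 Hz, a = 2.1, k = 0.88),
  using 3rd-order elliptic filters. Bands below 2 kHz are discarded to
  remove fine-structure ITD cues. In each remaining band the Hilbert
  envelope is low-pass filtered at 128 Hz and its fluctuations about the
  mean are compressed by a smear factor *s* ∈ {0, 0.29, 0.50}, leaving
  100%, 71%, or 50% of the original modulation depth; bands are then
  recombined envelope × fine-structure-carrier and summed.
- **Dichotic trials** — one ear keeps full depth, the other ear the
  smeared version (conditions 100–100, 100–71, 100–50); a sub-sample
  fractional delay imposes the trial ITD on one randomly chosen interval
  of a 3-alternative forced-choice (3-AFC) trial.
- **Adaptive tracking** — a transformed 2-down/1-up staircase starting at
  400 µs, ITD × 1.25 after each error and × 0.75 after two consecutive
  correct responses; 12 reversals, threshold = geometric mean of the ITDs
  at the last 8 reversals.
- **Simulated listeners** — psychometric responders
  p(correct) = ⅓ + (⅔ − λ)·F((ln ITD − ln α)/β) with configurable sigmoid
  F, plus a mechanistic observer that cross-correlates the two ears'
  envelopes; a seeded 6-listener panel with per-condition threshold
  inflation generates complete synthetic experiments.
- **Statistics** — one-way repeated-measures ANOVA (df (2, 10) for
  6 listeners × 3 conditions), post-hoc paired t-tests, Holm's sequential
  Bonferroni correction, and per-condition mean ± SEM.

## Worked example

```bash
itdsmear run-all --seed 42 --out demo/
```

runs the complete synthetic experiment — 6 listeners × 3 conditions, one
adaptive track each — and prints/writes:

```
ITD thresholds under interaural modulation-depth smearing
==========================================================
tracks: 18   all converged: True

Per-condition threshold (µs), mean ± SEM:
   100-100:    173.6 ± 18.1
    100-71:    246.4 ± 32.3
    100-50:    306.1 ± 43.3

Repeated-measures ANOVA: F(2,10) = 10.55, p = 0.003433

Pairwise paired t-tests (Holm-corrected):
     100-100 vs 100-71: t(5) =  -3.12, p = 0.02629, Holm p = 0.05258 [n.s.]
     100-100 vs 100-50: t(5) =  -4.13, p = 0.009106, Holm p = 0.02732 [reject]
      100-71 vs 100-50: t(5) =  -1.96, p = 0.1075, Holm p = 0.1075 [n.s.]
```

Mean thresholds rise as the interaural depth difference grows (the
simulated panel is built with monotone condition effects), the ANOVA
detects the main effect on (2, 10) degrees of freedom, and Holm's
step-down correction adjusts the three pairwise comparisons. The bundle
also contains `thresholds.csv` (the listener × condition matrix),
`trials.csv` (every staircase trial), `token_depths.csv` — a verification
that processing a synthetic token with s = 0.29 and 0.50 leaves 71% and
50% of its broadband envelope depth (measured 0.712 and 0.503) — and a
`manifest.json` from which the run is bit-identically reproducible.

Other subcommands: `synth-token`, `process`, `verify-depth`, `make-trial`,
`track`, `simulate`, `analyze` (see `itdsmear --help`). Everything is also
available as a library, e.g.:

```python
import numpy as np
from itdsmear import (make_synthetic_vcv, process_token,
                      extract_envelope, measure_modulation_depth)

tok = make_synthetic_vcv(rng=np.random.default_rng(0))
out = process_token(tok, s=0.5)
depth = measure_modulation_depth(extract_envelope(out.mono(), out.rate))
```

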