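# sfgamma

A tested, reusable implementation of the analysis pipeline for an EEG
study of **objecthood × spatial frequency** in visual object recognition:
stimulus synthesis, ERP component measures, evoked/total gamma-band
power, and within-subject statistics — together with a synthetic-data
generator so that every stage can be verified by parameter recovery
without any data download.

It is aimed at EEG/ERP researchers who want the individual operations
(spatial-frequency filtering in cycles/degree, phase scrambling,
ERPLAB-style local-peak detection, multitaper gamma extraction,
repeated-measures ANOVA with Greenhouse–Geisser correction) as an
importable, unit-tested Python library.

## The design and the methods

The study is a 2 × 3 within-subject design: **objecthood** (intact
object vs phase-scrambled non-object texture with identical amplitude
spectrum) × **spatial frequency** (high-pass-filtered HSF, unfiltered
broadband BB, low-pass-filtered LSF), 80 trials per cell, 480 per
participant, 15 participants, 64 channels at 512 Hz.

* **Stimuli** — broadband grayscale images are filtered in the 2-D
  frequency plane with a radially symmetric Gaussian gain
  `g(f) = 2^{-(f/f_c)^2}` (half-amplitude cutoff `g(f_c) = ½`; HSF cutoff
  ≈ 4.7 cpd, LSF ≈ 0.9 cpd, with cpd computed from monitor geometry by
  the exact arctangent relation).  Non-objects are made by randomising
  Fourier phases under Hermitian symmetry, preserving the amplitude
  spectrum exactly; all images are matched to the BB set's mean luminance
  and RMS contrast.
* **ERPs** — 40 Hz zero-phase Butterworth low-pass, −200..0 ms baseline;
  P1 (85–130 ms, positive) and N1 (145–220 ms, negative) at clusters
  P7/PO7 and P8/PO8: mean amplitude, local peak latency (the extremum
  not surpassed within ±5 samples = ±9.8 ms, falling back to the
  absolute peak), and P1−N1 peak-to-peak amplitude.
* **Gamma** — multitaper power, 30–110 Hz in 4 Hz steps, 250 ms sliding
  windows with K = 5 Slepian tapers (NW = (K+1)/2 = 3, i.e. ±12 Hz
  smoothing), expressed as % change from a −400..−100 ms baseline.
  *Evoked* power transforms the trial average (phase-locked activity
  only); *total* power transforms each trial then averages.  eGBA:
  occipital cluster, 30–60 Hz, 50–150 ms.  tGBA: bilateral posterior
  clusters, 200–500 ms, at each participant's individual peak frequency
  ±1 bin (a 62 Hz peak → 58–66 Hz), the peak chosen from grand-mean
  total power in 40–90 Hz.
* **Statistics** — fully within-subject factorial rm-ANOVA (each effect
  tested against its subject × effect interaction), Greenhouse–Geisser ε
  with Mauchly's test, generalized η², Holm-corrected paired post-hocs,
  and percentile bootstrap CIs over participants.
* **Synthetic data** — every trial is 1/f noise + 50 Hz line and 85 Hz
  monitor components + Gaussian-windowed P1/N1 deflections + a
  phase-locked 35 Hz burst (50–150 ms) + a random-phase induced-gamma
  burst (200–500 ms, participant-specific frequency), plus lognormal RTs
  and Bernoulli errors, all with known injected condition effects.

## Worked example

`examples/` contains one narrative script per capability.  The full
pipeline at reduced scale (6 participants, 20 trials/cell, strong
injected effects):

```bash
python examples/06_full_pipeline.py     # or: sfgamma run --seed 7 --out demo
```

prints, among other output:

```
ANOVA on N1_mean_amp
  objecthood: F(1, 5) = 277.74, p < .001, ges = 0.327
  frequency: F(2, 10) = 293.46, p < .001, ges = 0.566
  objecthood:frequency: F(2, 10) = 28.62, p = 0.002, ges = 0.135, GG eps = 0.555
ANOVA on tgba
  objecthood: F(1, 5) = 132.20, p < .001, ges = 0.603
  objecthood:frequency: F(2, 10) = 0.56, p = 0.587, ges = 0.000
```

i.e. the injected structure is recovered: the N1 shows an objecthood ×
spatial-frequency interaction (driven by the near-absent N1 to broadband
non-objects), while total gamma shows a pure objecthood effect,
untouched by spatial frequency.  The run directory contains the trial
schedule, behaviour table, long-format measure table, one ANOVA table
per measure, and a plain-text report; rerunning with the same seed
reproduces every file byte-for-byte.

The evoked/total dissociation in isolation
(`examples/04_gamma_power.py`):

```
62 Hz random-phase burst, 160 trials, power at O1, 200-500 ms:
  evoked power (average first):     0.40 uV^2
  total power (transform first):   74.88 uV^2
```

the induced burst cancels in the trial average and is visible only in
total power.

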