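# Methods

This note documents the models, conventions and numerical choices behind
`sfgamma`, in the spirit of a package methods appendix.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Viewing geometry and spatial-frequency units

Spatial frequency is handled in cycles per degree (cpd).  Pixels per
degree is computed from the monitor diagonal, aspect ratio, resolution
and viewing distance via the exact per-pixel arctangent
`θ = 2·atan(p/2d)` rather than the small-angle approximation; for the
default 17″ 4:3 monitor at 1024 × 768 and 80 cm this gives 41.39 px/deg,
so a 400 px stimulus subtends 9.64° (≈ 10°).  The 2-D frequency plane of
an H × W image is built from `fftfreq` in cycles/pixel and scaled by
px/deg; the radial frequency of each bin feeds the filter gain.

## Stimulus synthesis

**Filter convention.**  "Gaussian filter with a cut-off at f_c" is
ambiguous; we adopt the half-amplitude convention common in
spatial-frequency psychophysics: `g(f) = 2^{-(f/f_c)²}` so `g(f_c) = ½`
exactly.  A high-pass is `1 − g`; its DC gain is forced back to 1 by
default (`preserve_mean=True`) so that filtering does not change mean
luminance — the zero-DC variant is available for the classical
definition.  HSF images use the high-pass at ~4.7 cpd and LSF the
low-pass at ~0.9 cpd, which is the reading consistent with the
definitions of HSF/LSF; the opposite assignment is available
via `swap_filter_assignment=True`.

**Phase scrambling.**  New phases are taken as the phases of the FFT of
white noise — i.i.d. uniform and automatically Hermitian-symmetric, so
the inverse transform is real without any explicit symmetrisation.  The
DC bin keeps its original value, preserving the global mean exactly; the
amplitude spectrum is preserved to floating-point precision (the
acceptance script reports the worst per-bin relative deviation, ~1e-12).

**Luminance/contrast matching** is the affine map to the target mean and
pixel standard deviation (RMS contrast), with targets taken from the
grand statistics of the broadband source set.  It is applied after
filtering/scrambling.  Because scrambling preserves both mean (DC fixed)
and variance (Parseval), an object image and its scrambled texture
receive the identical affine map, so their spectra remain equal after
matching.  Matching can push intensities outside the display range;
clipping is off by default and saving to PNG warns if it had to clip.

**Source images.**  No photographs ship with the package.
`make_toy_objects` draws simple angular ("man-made") or rounded
("natural") shape collages on a grey field as synthetic stand-ins; any
grayscale PNG/TIFF can be loaded instead.

## The synthetic study generator

The generator is the package's ground-truth instrument: its defaults are
the study conditions (15 participants, 80 trials/cell, 6 blocks, 64
channels at 512 Hz — a 14-channel posterior montage is provided for
cheap simulations), and its injected cell means reproduce the study's
printed condition structure:

* P1 peak amplitudes built additively from the object (3.67/3.05 µV),
  spatial-frequency (3.91/3.26/2.93 µV) and hemisphere (right > left)
  marginal means; no interaction.
* N1 parameterised as a signed negative-going peak with the published
  cell-to-cell differences, including the signature interaction (the BB
  non-object N1 nearly absent); N1 peak latencies 173 ms (objects) vs
  165 ms (non-objects), HSF slowest.
* Phase-locked 35 Hz burst (evoked gamma) with a spatial-frequency
  effect and no object effect; induced gamma burst (random phase per
  trial, participant-specific centre frequency drawn from 52–76 Hz) with
  an object effect only.
* Lognormal RTs and Bernoulli errors whose cell means solve the printed
  marginals (objects 648 ms/7% vs non-objects 541 ms/1%; BB fastest,
  LSF slowest and most error-prone), with the RT object effect
  concentrated in HSF/LSF cells.  Error responses are typed (wrong
  category / object-as-non-object / miss / non-object-as-object); misses
  carry NaN RTs.

**Component shapes** are Gaussian windows (P1 σ = 12 ms at 105 ms, N1
σ = 18 ms; gamma envelopes σ = 25 ms at 100 ms and σ = 75 ms at 350 ms).
This is a synthetic convention chosen so that expected measurement
windows are analytic: a unit-peak component's expected window mean is
computable on the sample grid (`gaussian_window_mean`), which is how
recovery tests convert measured mean amplitudes back to injected peak
units.

**Noise model.**  1/f background (spectrally shaped white noise,
exponent 1, single-trial SD 10 µV), 50 Hz line and 85 Hz monitor
sinusoids with random phase.  Noise is independent across channels and
trials: no spatial covariance, no non-stationarities, no ocular/muscle
artifacts.  Passing tests therefore demonstrate correctness of the
analysis chain and statistical calibration under the stated model, not
robustness to real-data artifact structure (artifact rejection beyond a
simple amplitude threshold is explicitly out of scope).

**Gamma calibration.**  Burst amplitudes map to percent change through
the noise baseline.  Measured through the actual TFR chain, total-power
change is 3.64 %/µV² at the peak ± 1 bin, giving induced amplitudes of
2.23/1.45 µV for the ~18.1 %/7.6 % object/non-object targets.  Evoked
percent change depends on trial count (its baseline is the noise floor
divided by n trials) and its estimator carries a ratio bias of ≈ +13 %
because the evoked baseline has only ~15 effective degrees of freedom
per channel × frequency; at 80 trials/cell the calibrated amplitudes
3.57/3.13/3.17 µV land the evoked response on the ~805/619/634 % scale.
A corollary worth knowing: for a phase-locked signal, *raw* evoked and
total band power agree (trial-averaging leaves a deterministic signal
unchanged) while *normalized* evoked exceeds normalized total by roughly
the trial count — comparisons of evoked vs total must be made on raw
power or within one mode.

**Between-subject variability** is one additive offset per parameter
family per participant (amplitudes 0.5 µV, latencies 5 ms, RT 30 ms,
error rate 0.005, gamma 0.25/0.5 µV).  Shared offsets leave
within-subject effects exact in expectation.  These SDs are calibration
choices, not estimates of real inter-individual variability.

Randomness is organised per participant (`default_rng([seed, stream,
participant])`), so a participant's data are identical whether simulated
alone or within the full study.

## Preprocessing

All filters are Butterworth, applied forward-backward (zero phase).
This doubles the effective order and removes group delay (verified: a
band-limited pulse's peak moves < 1 sample); the design order is what is
quoted.  ERP chain: 40 Hz low-pass (order 4 — unspecified originally;
configurable) then −200..0 ms baseline subtraction.  TFR chain: order-2
band-stops at 49–51 Hz and 84–86 Hz, then per-trial linear detrending;
no time-domain baseline.  Data are analysed as recorded (no
re-referencing; a common-average option exists, default off).  Cluster
averages are unweighted channel means.

## ERP measurement

Mean amplitude averages samples in the closed window.  Local peaks
follow the ±5-sample (±9.8 ms at 512 Hz) neighbourhood rule with the
neighbourhood allowed to extend past the window edge into the epoch, the
absolute in-window extremum as fallback (flagged `is_local=False`), and
value ties broken toward the earliest latency.  The detector is verified
against an exhaustive brute-force oracle on 1000 random waveforms, half
of them smoothed-and-rounded to force plateaus and ties.  Manual visual
inspection of detected peaks is replaced by the `is_local` flag in the
measure table.  Measures use all trials, regardless of behavioural
performance.  Peak-to-peak is P1 peak amplitude minus N1 peak amplitude,
both from the same local-peak algorithm.

## Time-frequency analysis

Tapers are the exact length-N Slepian sequences (`scipy`'s symmetric
DPSS), unit-energy and exactly orthonormal, ordered by decreasing
concentration.  Power at a frequency is the mean over tapers of the
squared modulus of the tapered transform; requested frequencies are read
off the DFT grid when they align with it (the 4 Hz default grid on a
128-sample window at 512 Hz aligns exactly) and computed by direct DFT
otherwise.  Sliding windows step 10 ms by default; a centre whose 250 ms
window would leave the epoch yields NaN (flagged) rather than a
shortened window — hence epochs span −0.6..0.9 s so that the −400 ms
baseline centre is computable.  The averaged DPSS spectral window is
nearly flat over the inner ±8 Hz of the ±12 Hz concentration band and
falls below 5 % of peak beyond ±16 Hz; the half-power point lies just
inside ±12 Hz, not at it.

Percent change is `100·(P − B)/B` with B the per-channel × frequency
mean over −400..−100 ms.  eGBA defaults to the 30–60 Hz band (the
figure-level definition; the narrower 30–40 Hz band is a config option).
The tGBA peak search uses 40–90 Hz; ties go to the lowest frequency, an
edge peak warns; extraction averages the peak ± 1 bin (edge peaks use
the available bins, with a warning).  Analysis clusters are plain label
lists (occipital O1/Oz/O2/POz for eGBA; P7/PO7/O1 and P8/PO8/O2 for
tGBA) and are configurable.  The ERP-subtraction "induced" estimator is
deliberately not implemented.

## Statistics

The rm-ANOVA is the classical fully-within decomposition for 1–3
factors, computed by inclusion–exclusion of marginal means; every effect
is tested against its own subject × effect interaction.  GG ε̂ comes
from the covariance of orthonormally contrasted subject-level effect
scores, `ε = tr(S)²/(d·tr(S²))`, clipped to [1/d, 1]; Mauchly's test
uses the standard χ² approximation, and an undefined test (n − 1 ≤ d or
singular covariance) is treated as a violation.  The `gg_policy` option
selects when the correction is applied (`mauchly` at α = .05 by default,
`always`, or `never`); both corrected and uncorrected p are always
reported.  Note the correction is only guaranteed conservative where it
matters (it can lower p slightly when F < 1).  Effects whose SS fall
below 1e−12 of the total SS are reported as F = 0, p = 1 (round-off from
degenerate inputs).  Generalized η² uses the fully-within form
`SS_effect/(SS_effect + SS_subjects + ΣSS_error)`.  The implementation
is cross-checked in the tests against pingouin (two-way) and a
hand-written sums-of-squares oracle (2 × 2 fixture), and its type-I
error at the study size (2 × 3, n = 15) is calibrated at 10 000 null
simulations.

Post-hocs are paired t-tests over all pairwise cells of the declared
family with Holm step-down adjustment (cross-checked against
statsmodels).  Bootstrap CIs are percentile intervals of the mean over
B = 10 000 resamples of participants, seeded.

## Problem sizes

Reduced scales are used where full scale adds nothing: unit tests run 3
participants × 20 trials/cell on the 14-channel posterior montage;
parameter-recovery runs use the full 15 × 80 design on that montage,
with gamma power computed on the cluster channels and the
baseline/analysis window centres only.  The latency-recovery check holds
N1 amplitudes fixed across cells while shifting latency, because the
peak latency of a near-absent component (the BB non-object cell under
full defaults) is noise-driven — a property of peak measurement itself,
not of the implementation.  The end-to-end demo (6 × 20, low noise)
completes in well under a minute.

## I/O

Epochs live in a single HDF5 container (`/data`, `/times`, `/srate`,
`/channels`, the condition table embedded as TSV text, the processing
history, and a `schema_version` attribute).  An older minor schema reads
with a warning; a different major version is refused.  Tables are
TSV/CSV; the pipeline writes a manifest with a config hash and per-stage
wall-clock, and is byte-for-byte reproducible under a fixed seed.

## Known limitations

Channel labels carry no geometry (no topographic maps or interpolation);
the noise model omits spatial correlation and artifacts; statistical
options are limited to the GG/Holm/bootstrap family (no mixed models);
evoked-percent-change values are only comparable at a fixed trial count;
and the generator's between-subject SDs are conventions, so absolute
power calibration should not be read as a biophysical claim.
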