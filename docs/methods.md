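# Methods

This note records the models the package implements, the assumptions they
make, the defaults and why they were chosen, and what the synthetic-data
tests do and do not demonstrate about real recordings.

## Spectrograms and the template-correlation detector

Spectrograms are Hann-windowed STFTs with no padding: frames start at
multiples of the hop, the frame count is `floor((N − window)/hop) + 1`,
and power is converted to dB with a guarded floor so an all-zero clip
produces a finite uniform value. Default windowing follows the analysis
settings for each call class — 3000 samples for song review, 2048 for
D calls, both 50% overlap, with a 3072-point FFT available by
configuration. At the 2 kHz sampling rate these give 0.65–0.98 Hz
frequency steps, enough to isolate the 23–24 Hz song band from the 11 and
39 Hz background bins.

The detector slides a time–frequency template along the spectrogram and
scores, at each offset, the inner product of the zero-meaned template with
the zero-meaned co-located window, normalized by both norms and restricted
to the template's frequency band. Scores therefore lie in [−1, 1], equal
1 only for an exact (affinely scaled) copy, and are invariant to adding a
constant in dB — i.e., to waveform gain. Zero-variance windows score 0 by
definition. Per frame, the maximum over the template bank wins
(arbitration by highest score); strict local maxima at or above the
call-type threshold (0.75 song, 0.80 D calls) become detections, and
detections closer than half the shortest template duration merge, keeping
the higher score with ties broken by earlier time.

Two implementation choices matter for operating the published thresholds
at low SNR:

* **Pixel-texture control.** A single Hann periodogram pixel carries
  ≈ 5.6 dB of exponential texture, which bounds the correlation any
  template can reach against a 10 dB signal. The detector's spectrogram
  therefore averages linear power over 3 consecutive frames (the
  long-term-spectral-average device) before the dB conversion; this
  lowers the texture without moving band levels. Averaging over 5 or more
  frames starts to make background noise itself template-like and raises
  the false-alarm rate, so 3 is the default.
* **Template banks.** Templates are cut from annotated clips (the band is
  padded by 0.7 Hz each side so the patch carries the call's contrast
  against neighboring bins). The default banks are cut from clean
  synthetic exemplars planted at offsets staggered across one hop — 5
  song and 13 D-call templates — so the bank spans the alignment of an
  arbitrary call against the frame grid.

Band SNR of a planted call is defined as the ratio of the event's
in-band power to the background's in-band power over the event duration;
the generators place calls at a requested SNR by scaling against the
measured in-band noise power, and `measure_band_snr` verifies the planted
level by comparing the event window with flanking noise-only windows.

## Detector evaluation

A detection matches an annotation when the intersection covers at least
half of the annotation's extent independently in time and in frequency
(annotation-referenced fractions, not IoU — the published rule reads as
"overlapped the annotated call by ≥ 50%"). Matching is greedy and
one-to-one in descending detection score; among eligible annotations the
largest combined overlap wins. Greedy matching can in principle fall
short of the optimal assignment; the test suite bounds this against an
exact maximum-bipartite-matching oracle (which is itself checked against
brute-force enumeration on tiny instances) and requires agreement on at
least 95% of random small instances. Precision is flagged undefined when
there are no detections, recall when there are no annotations; the
false-alarm rate is false positives per recording hour.

## Call classifier

The published feature list for D-call classification lives in an appendix
that is not reproduced here, so the package defines a ten-measurement
stand-in spanning the standard robust spectrogram measurements: duration,
90%-energy bandwidth, low/high/peak/center frequency (center = energy-
weighted median), aggregate entropy of the spectral energy distribution,
band energy, the least-squares slope of the per-frame peak-frequency
ridge (negative for downsweeps), and time-of-peak fraction. The
classifier is a random forest with 100 trees and 7 candidate variables
per split, trained on random stratified 75% splits and evaluated on the
withheld 25%; the bootstrap protocol repeats this with fresh splits
(default 100 iterations) and reports mean ± SD of misclassification,
TPR, FNR, TNR and FPR. The identities TPR + FNR = 1 and TNR + FPR = 1
hold per run by construction. Splits that lose a class are logged and
redrawn. Classification uses the majority-vote threshold (0.5), as no
operating point is published.

## Song intensity index and daily summaries

The SII is computed in linear power: the mean PSD over the 23–24 Hz call
band for the whole day, divided by the arithmetic mean of the PSD at the
bins nearest 11 and 39 Hz. The ratio of daily means (rather than the
daily mean of per-frame ratios) is the default because it is stabler on
sparse-call days; both the aggregation and the background statistic are
configuration. On spectrally flat noise the index sits at 1 by
construction, and any waveform gain cancels exactly.

Daily summaries count D calls per day and the number of hours with at
least one overlapping detection (a call spanning an hour boundary flags
both hours). Annual cycles group by day of year with Feb 29 pooled into
day 59, so leap years do not shift the second half of the cycle.

## Detection areas

Hourly ambient noise is the 1st percentile of per-frame in-band levels
(power summed across the band's bins, in dB); the low percentile makes
the estimate robust to calls and transients within the hour. A grid cell
is detectable when `SL − TL(r, f_c) − NL ≥ DT` with the whale at 25 m
depth; cells shallower than the calling depth, or dry, are excluded. The
band collapses to its geometric-center frequency for TL evaluation.
Areas integrate cell areas (meridian arc × cos-latitude parallel arc) at
1-arc-minute resolution by default; distances are haversine.

The transmission-loss family is deliberately simple and pluggable:
spherical `20 log₁₀ r`, practical `15 log₁₀ r + α(f)·r` with Thorp
absorption, a hybrid that transitions from spherical to cylindrical
spreading at the water depth, and `pe_simple`, a narrow-angle split-step
Fourier parabolic-equation marcher on the range–depth slice (pressure-
release surface, attenuating sponge below the seafloor). The marcher
covers range dependence qualitatively; the pipeline's contract is the
sonar-equation area integration, which is exact to test: under spherical
spreading the limiting range has the closed form
`r = 10^((SL − NL − DT)/20)` and the gridded area must match the circle
πr² within grid quantization (≤ 5% at 1-arc-minute cells for a 10 km
range).

The required signal excess DT is not published; the default is 10 dB and
it is the most prominent knob in `PropagationParams`. Detection areas are
reported per hour and averaged arithmetically into daily means.

## Boosted regression trees

The BRT follows the ecology-standard recipe: stochastic stagewise
boosting of shallow trees with learning rate 0.005, bag fraction 0.75,
and tree complexity 2 (at most two splits per tree). The ensemble itself
is fit with LightGBM (`num_leaves = 3`, `max_depth = 2`,
`subsample = 0.75` per iteration); tree count is selected by 10-fold
cross-validation evaluated every 50 trees up to 3000 (2000 in the
recovery tests), keeping the count that minimizes held-out deviance —
the stagewise-CV idea of the classic `gbm.step` workflow. `cv_dev` is
one minus the ratio of CV deviance to the intercept-only deviance (unit
Poisson deviance for counts, squared error for the Gaussian index);
`cv_cor` is the Pearson correlation of response and CV predictions.
Relative influence is the per-predictor share of total split gain,
normalized to 100%. Partial dependence defaults to the fixed-at-mean
convention — predictions over a predictor grid with all other predictors
held at training means — with the marginalizing average available
separately. Month enters as a numeric 1–12 predictor; its cyclicity is a
known limitation. A constant response short-circuits to a flagged
degenerate fit with uniform influences.

Beyond the full-year models, within-peak seasonal splits restrict the
rows to the calling peaks before fitting: the D-call spring peak
(October–January), the D-call fall peak (April–May), and the song fall
peak (April–June). The windows are configuration — the peaks are named
by season, not by exact dates, in the source analysis.

## Mixed models

Year contrasts fit `response ~ C(year)` with a random intercept per
hydrophone site; the reported χ² is the likelihood-ratio statistic
against the intercept-only model, both fit by maximum likelihood (REML
likelihoods are not comparable across fixed-effect structures). Pairwise
year contrasts are Wald contrasts of the fitted fixed effects with a
Tukey-family correction via the studentized-range distribution
(`p = P(Q_{k,ν} > |Δ|/SE·√2)` with ν the residual degrees of freedom).
The summer window is Jan 1 – Feb 28 (Feb 29 excluded by the window's
definition); the fall song window is Apr 1 – Jun 30, reading the
published "31 June" as June's last day. The foraging→reproduction model
regresses site-year fall SII means on summer D-call means with a site
random intercept; the LRT uses the ML pair while the slope and its
interval come from a REML refit with a t critical value (n − 2 df), since
ML variance estimates are biased low on panels of ten site-years. A
single site triggers a flagged ordinary-least-squares fallback; constant
responses are flagged degenerate.

## Whaling phenology

Subspecies assignment applies, in order: the 24.2 m length rule
(Antarctic); exclusion of the Chilean population off western South
America (operationalized as the box 120–60°W, 0–60°S — the source rule
names the coast without coordinates); Atlantic west of 20°E → Antarctic;
south of the equator and north of the sector boundaries (46°S at
20–30°E, 52°S at 30–70°E, 53°S at 70–80°E, 52°S at 80°E–180°) → pygmy;
otherwise Antarctic unless the record is explicitly tagged "pygmy".
Assignment is total (every record maps to exactly one of antarctic,
pygmy, excluded, unassignable), idempotent, and each record carries the
rule that fired for audit.

Birth timing is read from the seasonal fetal-length curve. The curve is
an **upper-envelope** smooth, not a mean smooth, for a structural reason:
in a steady-state population the mean fetal length at a given date mixes
two cohorts — late-term fetuses about to be born and newly conceived
fetuses of the next cycle — and whales leave the pregnant pool the moment
they give birth. The mean curve consequently peaks tens of days before
the modal birth date. What identifies birth timing in the data is where
the *measurements reach their maximum*, i.e. the envelope of the cloud.
The implementation: (1) fit a preliminary robust local-linear trend
(lowess, ~90-day window, 2 robustness iterations); (2) keep records whose
residuals from that trend are in the top 15% of their 61-day circular
window — residual ranking is essential because on a monotone growth ramp
no point is in the top quantile of raw lengths within its own window;
(3) smooth the kept points with a local-linear lowess (span 0.2 of the
year). The year is treated circularly along the conception→birth arc:
when the records leave a seasonal gap longer than 14 days the circle is
cut there and the smooth runs along the arc (this also makes the
noiseless linear-growth case exact); otherwise the data are replicated
one year each side. Birth day is the circular midpoint of the band where
the curve is within 1% of its maximum — late-term lengths plateau, so the
band midpoint is stabler than a single argmax; a curve flat everywhere
(within 0.1%) is flagged and returns the widest consistent window. The
birth window extends ±15 days; conception subtracts 11 calendar months
(calendar arithmetic in a non-leap reference year, matching the
month-level statements the rule comes from; Feb 29 clamps to Feb 28), so
a 12-month gestation shifts conception exactly one month earlier. Exact
duplicate records collapse before smoothing (the smoother is unweighted,
so duplicates would only perturb count-based windows).

## The synthetic generators

The generators reproduce the *statistical structure* the analysis
assumes, not the acoustics or oceanography of the study system:

* **Audio** is Gaussian noise shaped to a −5 dB/octave power law (generic
  low-frequency ambient), with song units as fixed 23.5 Hz tonals
  (8 s, configurable harmonics — the real song's multi-unit structure and
  unit timing are not public and are not reproduced) and D calls as
  linear 90 → 25 Hz downsweeps over 3 s. Band SNR is exact by
  construction within taper effects (±1.5 dB verified for SNR ≥ 6 dB).
* **Environment** is a seasonal SST sinusoid (peak in early February,
  +0.3 °C per degree toward the equator) plus boxcar heatwave anomalies;
  log NPP decreases linearly in SST anomaly (default −0.15 per °C around
  500 mg C m⁻² day⁻¹) and is aggregated to 8-day composites, forward
  filled, mirroring the satellite cadence.
* **Call series** draw daily D-call counts Poisson with a log link on a
  planted linear predictor (log NPP, SST, SST anomaly, harmonic month
  terms) and build SII as a seasonal bump (peak mid-May, ~1 month wide)
  whose height scales with the prior summer's standardized mean D-call
  count (the foraging→song coupling) plus Gaussian noise.
* **Catches** draw a conception day-of-year Normal(June 1, 15 d) — births
  concentrated over roughly two months, read as ±2 SD — and catch each
  pregnant whale at a uniform time during its 334-day pregnancy,
  year-round by default; fetal length grows linearly to 700 cm at term
  (a lagged growth law in the style of conceptus cube-root-of-mass
  models is available but off by default). Positions are uniform in the
  New Zealand box.

Passing the recovery tests therefore shows that the pipeline's inference
machinery is correct under its own assumptions; it does not show that the
detector handles real multi-unit song, propagation-distorted sweeps,
shipping noise, or that real fetal-length records are as well behaved as
the generator's.

## Problem sizes and tolerances

The test and acceptance runs use desk-scale sizes chosen to make the
statistical checks sharp while staying single-CPU friendly: 1-hour clips
with 20–50 planted calls for detector recovery; 500 random instances for
the matching oracle; n = 700 site-days and 20 seeds for BRT recovery;
50 simulations for the heatwave contrast pattern and the foraging
coupling, with 500 null replicates for the type-I error bound; n = 300
catch records and 20 seeds for phenology; 100 bootstrap iterations for
the classifier; and a two-site, 30-day demo pipeline (plus a three-year,
five-site daily call series for the statistical stages) run twice for
the determinism check. Seeds fix every random draw; identical seeds give
bit-identical generator output and hash-identical pipeline runs.

## Known limitations

* Detector performance on real recordings will differ: real song units
  are longer, multi-part, and vary in frequency; the synthetic exemplars
  are deliberately minimal.
* The transmission-loss family is not a full-physics propagation model;
  absolute detection areas should not be compared against
  range-dependent-model results, only the integration machinery.
* Month as a numeric predictor cannot wrap December into January.
* The envelope-curve device assumes catches sample pregnancy uniformly
  enough that the late-term plateau is populated; strongly seasonal
  catch windows shrink the usable arc and are flagged when the support
  falls under 60 days.
* The sensitivity offset (−145.5 dB) is carried as metadata; synthetic
  waveforms are dimensionless and no absolute calibration is applied.
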