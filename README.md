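# bluecall

Passive-acoustic analysis of blue whale calling, built as a tested,
reusable pipeline. The package is aimed at bioacousticians and
quantitative ecologists who work with long-term, low-frequency hydrophone
recordings (2 kHz archival moorings) and want the full chain from raw
audio to ecological inference:

1. **Call detection** — spectrogram template correlation for the two call
   classes: stereotyped song (tonal units in the 23–24 Hz band, detection
   threshold 0.75) and downswept D calls (90 → 25 Hz sweeps in the
   20–100 Hz band, threshold 0.80). Templates slide along a Hann-windowed
   STFT (3000-sample windows for song, 2048 for D calls, 50% overlap) and
   score the zero-mean, unit-norm correlation in the template's band, so
   scores live in [−1, 1] and are invariant to gain.
2. **Detector evaluation** — detections match ground-truth annotations
   one-to-one when they overlap by ≥ 50% in both time and frequency;
   precision = TP/(TP+FP), recall = TP/(TP+FN), and the false-alarm rate
   is false positives per recording hour.
3. **Call classification** — a random forest (ntree = 100, mtry = 7)
   separates true D calls from detector false positives using ten spectral
   measurements per detection, evaluated over 100 bootstrap iterations of
   75/25 train/test splits.
4. **Calling indices** — the song intensity index (SII) is the ratio of
   band energy at 23–24 Hz to the mean energy at the 11 and 39 Hz
   background bins; daily summaries count D calls and call-present hours,
   and annual cycles average by day of year.
5. **Detection areas** — the passive sonar equation SL − TL(r) − NL ≥ DT
   integrated over a 1-arc-minute grid, with hourly ambient noise taken as
   the 1st percentile of in-band frame levels, source levels of 179 dB
   (song) and 174 dB re 1 μPa @ 1 m (D calls), a 25 m calling depth, and a
   pluggable transmission-loss family (spherical 20 log₁₀ r, practical
   spreading with Thorp absorption, a spherical-to-cylindrical hybrid, and
   a simple narrow-angle parabolic-equation marcher).
6. **Environmental models** — boosted regression trees (learning rate
   0.005, bag fraction 0.75, tree complexity 2, 10-fold stagewise CV) of
   daily D-call counts (Poisson) and SII (Gaussian) against SST, SST
   anomaly, log NPP, month, and detection area, reporting cv.dev, cv.cor,
   relative influence, and fixed-at-mean partial dependence.
7. **Heatwave contrasts** — linear mixed models with a site random
   intercept test year effects on summer (Jan 1 – Feb 28) conditions and
   calling, with likelihood-ratio χ² and Tukey-corrected pairwise year
   contrasts; a companion mixed model links summer D-call activity to the
   subsequent fall (Apr–Jun) song intensity.
8. **Breeding phenology** — whaling catch records are split into pygmy and
   Antarctic blue whales (24.2 m length rule plus longitude-sector
   latitude boundaries), filtered to the New Zealand region
   (145°E–180°, 32–50°S), and the seasonal fetal-length curve's maximum
   gives birth timing; conception follows 11 calendar months earlier.

Every stage is testable without any restricted data: the `synth` module
generates hydrophone audio with planted calls at controlled band SNR,
gridded SST/NPP fields with heatwave episodes, environment-driven daily
call series with known coefficients, and catch records with a planted
conception-date distribution.

## Worked example

Detect planted D calls in ten minutes of synthetic hydrophone audio and
score the detector against the planted truth:

```python
from bluecall.synth import synth_clip
from bluecall.templates import make_template_bank, detector_spectrogram
from bluecall.spectro import detect_calls, DCALL_THRESHOLD
from bluecall.evaluate import match_detections, detector_metrics

clip, truth = synth_clip(
    600.0, "dcall", event_times=[60.0, 180.0, 420.0], snr_db=12.0, seed=0
)
bank = make_template_bank("dcall", seed=1)
spec = detector_spectrogram(clip, "dcall")
detections = detect_calls(spec, bank, threshold=DCALL_THRESHOLD)
metrics = detector_metrics(match_detections(detections, truth),
                           recording_hours=600 / 3600)
for d in detections:
    print(f"D call at {d.start_s:6.1f} s  score {d.score:.3f}  ({d.template_id})")
print(f"precision {metrics.precision:.2f}  recall {metrics.recall:.2f}  "
      f"false alarms {metrics.false_alarm_rate:.1f}/h")
```

```
D call at   60.4 s  score 0.934  (dcall_t0)
D call at  180.2 s  score 0.936  (dcall_t5)
D call at  420.4 s  score 0.932  (dcall_t1)
precision 1.00  recall 1.00  false alarms 0.0/h
```

All three planted sweeps are found within half a second of truth with
correlation scores well above the 0.80 threshold, and no false alarms —
at 12 dB band SNR the detector operates with a comfortable margin.

The `bluecall` CLI wraps the same stages (`bluecall detect`,
`bluecall evaluate`, `bluecall classify`, `bluecall range`,
`bluecall whaling`, `bluecall run`); `bluecall run` executes the whole
demo pipeline — synthetic audio for two sites, detection, evaluation,
classification, daily metrics, detection areas, BRT fits, mixed models,
and phenology — writing every stage's outputs and a SHA-256 manifest.

## Layout

```
src/bluecall/
  synth.py        synthetic audio, environment, call series, catches
  spectro.py      STFT spectrograms, templates, correlation detector
  templates.py    default template banks and detector settings
  evaluate.py     matching and precision/recall/false-alarm metrics
  classify.py     spectral features, random forest, bootstrap protocol
  call_metrics.py song intensity index, daily summaries, annual cycles
  propagation.py  noise percentiles, transmission loss, detection areas
  brt.py          environment extraction and boosted regression trees
  mixed.py        year LMMs, Tukey contrasts, foraging→song model
  whaling.py      subspecies rules, fetal curve, conception timing
  pipeline.py     nine-stage orchestrated run with manifest
  cli.py          command-line entry points
docs/methods.md   models, assumptions, parameter choices, limitations
```
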