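# plmad

Automatic detection of periodic leg movements (PLM) from leg-EMG
polysomnography, with a synthetic-recording generator so every stage is
testable without real patient data.

The pipeline takes an EDF recording (one or two leg-EMG channels, optional
ECG), a 30-s-epoch hypnogram CSV and a respiratory-event CSV, and produces
scored leg movements (LM), periodic runs (PLM) and subject-level metrics:

1. the two leg channels are merged (per-sample mean by default);
2. cardiac interference is removed with a recursive-least-squares adaptive
   canceller, driven by the ECG channel when present or by a time-advanced
   copy of the leg channel itself otherwise;
3. a 20-s moving average of the rectified signal tracks the noise floor;
   dynamic upper/lower/falloff thresholds (8 µV / 2 µV / midpoint at a
   quiet baseline, log growth with noise, shutoff above 50 µV) ride on it;
4. an optional SNR+ two-tap summing filter boosts sub-33 Hz signal where
   the floor is below 2 µV, catching visible sub-8 µV movements;
5. a 0.15-s RMS envelope is run through a three-threshold state machine
   (onset above the upper threshold, release after 0.05 s below the lower
   threshold, offset at the falloff threshold);
6. candidates are bridged (≤ 0.1 s), duration-filtered (0.75–10 s), merged
   (≤ 2.0 s) and screened by time-normalized trapezoidal AUC against half
   the upper threshold to drop fragmentary-myoclonus spikes;
7. two full passes are run: first-pass detections are substituted with half
   the lower threshold before the noise floor is recomputed;
8. LMs overlapping respiratory-event boundary windows (−5.0/+0.5 s around
   onset, −0.5/+5.0 s around offset) are excluded, while LMs strictly
   inside an event are kept (the narrower AASM-2007 whole-event ± 0.5 s
   rule is available for comparison);
9. runs of ≥ 4 LMs with onset-to-onset intervals of 5–90 s become PLMs;
   PLMS/h, PLMW/h, periodicity index, night ratios and PLM-locked
   heart-rate delta/slope (from Pan-Tompkins-style R-peak detection) are
   reported.

## CLI

```bash
# generate a synthetic recording with exact ground-truth labels
plmad simulate --spec spec.yaml --out-dir sim/ --seed 7

# run the detector
plmad detect --edf sim/recording.edf --hypnogram sim/hypnogram.csv \
    --resp-events sim/resp_events.csv --leg-channels LAT,RAT \
    --ecg-channel ECG --out-dir results/

# respiratory-event time-locked EMG profile (120 half-second bins)
plmad resp-profile --edf sim/recording.edf --hypnogram sim/hypnogram.csv \
    --resp-events sim/resp_events.csv --leg-channels LAT,RAT \
    --anchor offset --out profile.csv
```

`detect` writes `lm_events.csv` (onset_s, offset_s, duration_s, state,
flags, run_id — rejected events are kept with audit flags), `metrics.json`,
the effective configuration and a per-stage count log. All scoring
constants can be overridden via `--config config.yaml`; see
`plmad.config.PipelineConfig` for the schema.

## Library use

```python
from plmad import SynthSpec, Train, generate, run_detection
from plmad.model import Recording

spec = SynthSpec(duration_h=2.0, fs_hz=200.0, seed=7,
                 trains=[Train(start_s=120, count=10, imi_s=30, amplitude_uv=25)],
                 ecg_leak=0.1)
res = generate(spec)
rec = Recording(traces={"leg_left": res.recording["LAT"],
                        "leg_right": res.recording["RAT"],
                        "ecg": res.recording["ECG"]})
out = run_detection(rec, res.hypnogram, res.resp_events)
print(out.metrics.to_dict())
```

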