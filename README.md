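# farrowwatch

Early warning and supervision of sow farrowing from object-detection
streams.

On commercial pig farms, catching the onset of farrowing early enough to
assist lets breeders prevent stillbirths, crushing and chilling of newborn
piglets.  Sows announce farrowing themselves: in the last ~24 h they show
nest-building behavior — markedly more posture changes — which collapses in
the final hours before the first piglet.  A ceiling camera plus an object
detector can turn this into data: per-frame detections of four sow postures
(lateral lying, sternal lying, standing, sitting) and of newborn piglets.

`farrowwatch` is the decision layer on top of any such detector.  It is
detector-agnostic: its input is a time-stamped stream of
`(t, class, bbox, confidence)` records (JSON Lines), not pixels.  From that
stream it computes:

* **Pre-farrowing warning.**  The posture-transition frequency
  `f = n / T` (transitions per hour) on a sliding window; a warning fires
  when `f` stays above the upper threshold (17.5/h) sustained for more than
  5 h, and a second signal fires when `f` subsequently stays below the
  lower threshold (10/h) for the same persistence — the nest-building surge
  and the pre-farrowing collapse.
* **Farrowing alarm.**  Debounced on "three consecutive detections": only
  after piglets appear in three consecutive frames is farrowing declared
  (`Alarm = 1`, `T_start` set, message `"Delivery Begin! Start time: …"`
  dispatched to pluggable alert sinks).
* **Piglet count and duration.**  Per-frame count `Cur_num`, running
  maximum `Detected_num` as the litter estimate, `T_end` at the last new
  maximum, duration `D = T_end − T_start`.
* **Metrics.**  Current/Detected Number Accuracy
  `CA = Σ Cur_num / Σ True_num`, `DA = Σ Detected_num / Σ True_num`,
  precision/recall, and reference GIoU / binary-cross-entropy losses.

Because real farrowing video is not shippable, the package includes a
first-class simulator: an inhomogeneous-Poisson posture process following
the three-stage perinatal pattern, a litter/birth-time model, and a
detector-noise channel with presets taken from a 410-image field test of a
reference detector (missed/wrong posture rates, spurious piglet boxes).
Every test and the acceptance script run end to end on simulated sows.

## Worked example

Simulate one sow over −30…+4 h around farrowing (5 s frames, mild-noise
scenario), then run the warning engine and the evaluator:

```bash
cat > run.yaml <<EOF
frame_interval: 5.0
posture_sample_interval: 20.0
horizon: [-30.0, 4.0]
noise:
  scenario: heat_lamp_color
EOF

farrowwatch --config run.yaml --seed 7 simulate \
    --stream-out sow7.jsonl --truth-out sow7_truth.json
farrowwatch --config run.yaml warn sow7.jsonl \
    --report-out warn7.json --series-out series7.csv
farrowwatch --config run.yaml evaluate sow7.jsonl sow7_truth.json \
    --metrics-out eval7.json
```

`warn7.json` reports one upper warning:

```json
{"kind": "upper", "condition_onset_s": 28800.0, "emitted_at_s": 46800.0}
```

— the sustained-frequency condition began 8 h into the stream (22 h before
farrowing, at the start of the nest-building surge) and the warning was
sent after the 5 h persistence.  `eval7.json` scores the run against the
ground truth:

```json
{
  "litter_size": 3,
  "farrow_onset_s": 108000.0,
  "warning": {"emitted_at_s": 46800.0, "lead_hours": 17.0,
              "error_hours": 12.0, "late": false},
  "alarm": {"alarm": 1, "t_start_s": 108000.0, "duration_s": 1840.0,
            "detected_num": 4},
  "false_alarms_k": 0,
  "false_alarms_single": 53,
  "ca": 0.9999,
  "da": 1.2970
}
```

Reading it: the warning preceded farrowing by 17 h (12 h more than the
intended 5 h lead — the synthetic surge starts early and the rule fires
near its beginning); the debounced alarm tripped exactly at the true first
birth (`t_start_s` equals `farrow_onset_s`), while single-frame detection
would have raised 53 false alarms against 0 for the three-consecutive
rule; frame-level counting was essentially perfect (CA ≈ 1) but spurious
boxes pushed the running-maximum litter estimate to 4 against a true
litter of 3 (DA > 1).

The `monitor` subcommand runs the alarm/count logic alone, and `report`
simulates a whole cohort and writes summary statistics.

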