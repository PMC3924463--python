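# ctgdiag

Rule-based interpretation of cardiotocograms (CTG): automated key-point
extraction from paired fetal-heart-rate / uterine-contraction traces and
classification of six clinically recognised abnormality patterns, with
per-patient thresholds that an obstetrician can customise in a small XML
profile. A seeded synthetic CTG generator with exact ground-truth
annotations makes the whole engine testable without clinical recordings.

## Who this is for

Electronic fetal monitoring produces a continuous pair of signals — the
fetal heart rate (FHR, beats per minute, conventionally plotted twice per
second) and uterine-contraction intensity (UC, relative units). Reading
these strips is skilled, qualitative work; remote-monitoring systems need
a quantitative engine that can watch a telemetered trace and raise an
alert when a worrying pattern appears. `ctgdiag` is such an engine as a
library plus a thin `ctg` command-line tool: researchers and engineers
building monitoring pipelines can run it on delimited-text traces, swap
in per-patient criteria, and validate it end to end on synthetic data.

## The model

The diagnostic vocabulary is a set of named key points. On the UC
channel: contraction cycle start **UCs**, peak **UCp** and end **UCe**
(the peak is a sample higher than both neighbours; start and end are the
intersections with the resting tone). On the FHR channel, anchored to a
contraction: fall onset **HRs**, nadir **HRp**, recovery **HRe**, and —
after some variable decelerations — a brief overshoot above baseline
called the *shoulder region* (**HSp**, **HSe**). **B** is the local FHR
baseline, estimated as a trimmed median per 10-minute window.

Six patterns are recognised, each as a conjunction of inclusive
inequalities over these points (all thresholds configurable per patient;
defaults shown):

| Pattern | Rules (defaults) |
|---|---|
| Tachycardia | FHR ≥ 160 bpm sustained ≥ 3 min |
| Bradycardia | FHR ≤ 110 bpm sustained ≥ 3 min |
| Early deceleration | HRp.t < UCe.t; HRp.t − HRs.t ≥ 30 s; HRs.t ≥ UCs.t + 5 s; B − HRp.v ≥ 15 bpm |
| Late deceleration | HRp.t ≥ UCe.t; HRp.t − HRs.t ≥ 30 s; B − HRp.v ≥ 15 bpm |
| Variable deceleration A | HRp.t − HRs.t ≤ 30 s; HRs.t ≥ UCs.t + 5 s; B − HRp.v ≥ 15 bpm |
| Variable deceleration B | HRs.t ≥ UCs.t + 5 s; B − HRp.v ≥ 15 bpm; HSp.v − B ≥ 10 bpm; HSe.t − HRe.t ≥ 10 s |

Clinical shorthand overloads the symbols as both times and values
("HRp − HRs ≥ 30" is a lag in seconds, "B − HRp ≥ 15" a depth in bpm);
every key point here carries both `.t` and `.v` and each rule states
which field it uses. All satisfied rule sets are reported — an episode
on the 30-second fall-time boundary legitimately satisfies both the
gradual and the abrupt pattern, and the report flags it ambiguous rather
than imposing a precedence.

## Worked example

Simulate the canonical early-deceleration geometry — one contraction
(onset 300 s, 80 s long), a deceleration of depth 45 bpm starting 14 s
after contraction onset with a 45-second fall to the nadir — then
diagnose it:

```sh
ctg simulate --spec spec.json --out trace.csv --truth truth.json
# wrote 1800 samples (900 s) to trace.csv
ctg diagnose --trace trace.csv --out report.json
# synth-seed7: 1 deceleration episode(s), 0 sustained episode(s), 1 alert(s)
```

The report (`report.json`, schema in `docs/report.schema.json`) contains
one episode:

```
hrs  t=314.0  v=139.92     # fall onset: 14 s after contraction onset
hrp  t=359.0  v=95.12      # nadir: 45-s fall, 44.9 bpm below baseline
hre  t=394.5  v=135.11     # recovery to within 5 bpm of baseline
b    140.0                 # local baseline (trimmed median)
cycle ucs=297.5 ucp=340.0 uce=382.5
labels: EarlyDeceleration  (rules early.nadir_before_uce,
        early.gradual_fall, early.lags_contraction, early.depth)
alerts: [EarlyDeceleration at t=314.0 -> decels[0]]
```

Read it as a clinician would: the nadir (359 s) comes before the
contraction ends (382.5 s), the fall took 45 s (≥ 30 s, so it is gradual,
not a variable deceleration), it began 16.5 s after the measured
contraction onset (≥ 5 s), and the excursion is 44.9 bpm deep (≥ 15 bpm)
— an early deceleration, and nothing else fires. The library equivalent
is three calls: `generate_trace(spec)`, `run_diagnosis(trace, criteria)`,
`emit_alerts(report, sink)`.

Per-patient thresholds load from XML
(`ctg validate-criteria --criteria criteria.xml`):

```xml
<criteria patient="gravida-7">
  <symptom name="LateDeceleration">
    <threshold key="fall_time_s" value="30"/>
    <threshold key="depth_bpm" value="15"/>
  </symptom>
</criteria>
```

Any threshold absent from the file keeps its default (with a logged
warning), so a profile only needs to spell out what differs.

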