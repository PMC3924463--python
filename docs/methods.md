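# Methods

This note documents the algorithms behind `ctgdiag`, the choices made
where the design was genuinely open, the synthetic study conditions, and
what the validation suite does and does not demonstrate.

## Signal model and conventions

A CTG trace is a pair of uniformly sampled series — fetal heart rate
(FHR, bpm) and uterine-contraction intensity (UC, relative units 0–100)
— at a default 2 samples/second. Times are seconds from trace start,
sample indices 0-based, intervals closed, and every rule comparison
inclusive (≥/≤). UC units are normalised to a relative 0–100 scale; the
engine only ever uses UC levels relative to the resting tone, so the
absolute calibration (e.g. mmHg from a tocodynamometer) does not matter.

Missing samples are NaN. A value of 0 bpm is treated as an invalid
transducer reading, not as missing, and is handled by cleaning.

## Cleaning

Telemetered CTG data carry dropouts, held readings and impossible
values. `preprocess.clean`:

1. marks FHR samples outside a plausible band (default 50–240 bpm)
   invalid;
2. marks exact consecutive-duplicate FHR runs longer than
   `dup_run_samples` (default 10 samples = 5 s at 2 Hz) invalid — a real
   heart rate always carries beat-to-beat variability, so a long
   bit-identical run is a stuck transducer, while short plateaus of
   genuinely flat rate survive. The heuristic applies to the FHR channel
   only: a uterine channel resting at constant tone between contractions
   is normal;
3. linearly interpolates invalid/missing runs up to `max_gap_s`
   (default 15 s); longer runs stay missing and split the trace into
   analysis segments (minimum 2 valid samples).

Valid in-range samples are never altered.

## Smoothing

Both channels are smoothed before any detection with a centered moving
average over `round(window_s · rate)` samples (forced odd; default 5 s).
Missing samples are excluded from each window's mean, windows truncate
at the edges, and output positions that were missing stay missing — the
smoother must not invent data across gaps. A moving average was chosen
over spline fitting because it is deterministic, cheap, and every output
value is independently checkable by a brute-force windowed mean.
Consequences: a smoothed extremum is slightly shallower than the raw one
and edges spread by half a window (~2.5 s) — the onset estimator below
accounts for this.

## Baseline and resting tone

The FHR baseline **B** is what a clinician reads "between" excursions.
Per consecutive 600-second window, B is the median of the smoothed
samples lying between the window's 10th and 90th percentiles, rounded
to the nearest 1 bpm. The percentile trim discards deceleration nadirs
and acceleration peaks, so a single deceleration occupying ≲ 10–15 % of
the window leaves B untouched (asserted as a property test). The
600-second horizon is the conventional baseline window in CTG practice;
both it and the trim are configurable. Windows shorter than 60 s, or
without valid samples, reuse the nearest window's estimate. The UC
resting tone is the per-window 10th percentile of the smoothed UC
channel. Limitation: a sustained rate shift occupying more than half a
window (e.g. a long tachycardia) drags the trimmed median toward the
shifted level; sustained-rate detection does not use B, so this only
matters if decelerations coincide with such an episode in one window.

## Key-point extraction

**Contraction cycles.** A UC peak is a sample strictly higher than both
neighbours — equal-height plateaus collapse to their earliest sample —
rising at least `min_prominence` (10 units) above tone. From the peak,
the nearest earlier and later crossings of `tone + crossing_tol`
(2 units) are found and then refined down the flank to the actual
intersection with the resting tone, which becomes UCs / UCe; the
tolerance level is a robust search level, not the cycle boundary itself.
Without the refinement the measured UCs sits several seconds inside the
contraction (a 40-unit bell crosses tone + 2 about 6 s after its true
onset), which systematically shrinks the measured onset lag. Adjacent
bells that never return to the crossing level between their peaks are
split at the valley minimum; bells truncated by the trace edge or a data
gap are dropped.

**Decelerations.** Per cycle, the search window runs from UCs to
UCe + 60 s; if that horizon extends past the end of the data the cycle
is skipped. The nadir HRp is the deepest smoothed sample in the window
(the deepest — rather than first — excursion is used: with one
deceleration per contraction the two coincide, and the deepest is robust
to small noise dips that would preempt a first-fall scan). Episodes
shallower than 2 bpm, or whose minimum sits at the window start (a dip
that began before the contraction), are discarded. The fall onset HRs
is recovered by a two-stage backward walk from the nadir: first to the
last sample within 2 bpm of baseline, then onward while the forward
slope over a 3-s window stays below −0.15 bpm/s, stopping after 3
consecutive failures of the slope condition (the patience absorbs
isolated noisy slope estimates). On noiseless raised-cosine geometry
this lands within ~1 s of the injected onset despite the smoothing
spread; under 5-bpm noise the jitter is a few seconds. HRe is the first
return to within `return_tol` (5 bpm) of baseline after the nadir, or
the last valid sample if recovery is truncated.

**Shoulders.** After HRe, the highest smoothed sample in a 60-s window
strictly above baseline becomes HSp, and HSe is the first subsequent
return to within `return_tol` of baseline. Small noise overshoots
routinely produce "shoulders" of 1–3 bpm; they are harmless because the
type-B rule demands ≥ 10 bpm of height.

**Sustained rates.** Maximal runs of consecutive smoothed samples at or
beyond the tachycardia/bradycardia thresholds, duration `n / rate`;
missing samples break runs and runs never merge across a gap. This is
deliberately a literal sample-wise run-length criterion (not a windowed
mean), matching the "condition must last" reading, and is validated
against an independent brute-force scan.

Detection constants (`min_prominence` 10, `crossing_tol` 2,
`return_tol` 5, horizon 60 s, onset estimator 2 bpm / 3 s / 0.15 bpm/s /
patience 3) live in `DetectionConfig` and are pinned by tests. The
engine always detects on smoothed samples; the raw trace is preserved
for the report.

## Classification

Each rule set is a conjunction of inclusive inequalities (see README
table). Every satisfied label is reported with the identifiers of its
fired rules; multi-label episodes are flagged ambiguous. Early and late
deceleration are mutually exclusive by construction (nadir strictly
before vs at/after contraction end); the variable-deceleration rules can
co-fire with each other and, exactly on the 30-s boundary, with the
early rule — properties the test suite asserts. Criteria are per patient,
loaded from the XML profile; absent thresholds fall back to defaults
with a warning so a profile only states what differs.

## Synthetic generator and study conditions

The generator renders analytically known shapes so every extracted key
point has an exact ground truth: contractions are raised cosines over
the resting tone; decelerations are inverted raised cosines
(fall = recovery = `fall_s`, so the nadir is at onset + `fall_s`) —
abrupt V-shapes are simply short falls; shoulders are positive raised
cosines appended at recovery; tachycardia/bradycardia are plateaus with
15-s cosine ramps. FHR noise is additive Gaussian; dropout makes each
sample independently missing on each channel. Identical seeds give
bit-identical traces.

The FHR additionally always carries a deterministic micro-variability
term (0.05 bpm sinusoid, 7.31-s period, seeded phase). A real FHR is
never sample-for-sample constant — absent variability is itself a
pathological sign — and without this term a noiseless synthetic baseline
would be bit-identical for minutes on end and trip the stuck-transducer
heuristic. The amplitude is two orders of magnitude below every clinical
threshold.

Recovery-suite conditions (fixed once; `synthgen.RECOVERY_RANGES`): one
900-s trace at 2 Hz per event, integer baselines drawn from 130–145 bpm,
resting tone 5, one contraction (amplitude 40–70, onset 300 s) for
deceleration events. Twenty events per class; parameters drawn uniformly
from ranges inside the rule-satisfying regions with margin for the known
estimation jitter: early falls 42–58 s against the 30-s rule, abrupt
falls 12–24 s, onset lags 12–20 s against the 5-s rule, depths 25–45 bpm
against the 15-bpm rule, shoulder heights 14–20 bpm against the 10-bpm
rule, sustained levels 168–178 / 88–102 bpm for 240–330 s against the
3-minute rule. Scoring: an event is recovered when its intended label
appears in the report, and a reported label is spurious when the exact
injected geometry, evaluated directly against the rules, does not
satisfy it (an abrupt deceleration with a shoulder genuinely satisfies
both variable-deceleration rule sets, so reporting both is correct, not
spurious).

What passing does and does not show: the suite demonstrates that
extraction and classification are faithful to the rule semantics on
morphologically clean, single-event traces under moderate noise. Real
intrapartum traces have baseline wander, accelerations, overlapping and
irregular contractions, maternal-heart-rate confusion and
autocorrelated artefacts, none of which the generator models; recovery
rates here are not clinical performance claims.

## Numerical choices and degenerate inputs

Times derive from sample indices (`i / rate`); a run of `n` samples
lasts `n / rate` s. Peak plateau ties break to the earliest sample.
Baselines round to 1 bpm. Traces with fewer than 2 valid FHR samples,
empty series, or no valid baseline window raise a degenerate-input
error (CLI exit code 2). Reports serialize with sorted keys and
repr-exact floats, so equal analyses are byte-identical and round-trip
exactly.

## Known limitations

- One deceleration per contraction cycle: multiple dips within one
  cycle yield only the deepest.
- Decelerations not linked to any detected contraction are not reported
  (the type A/B rules themselves reference the contraction onset, so an
  unlinked episode could not be classified anyway).
- No FHR variability indices, acceleration scoring, or sinusoidal
  pattern detection; no composite category grading.
- The onset estimator's jitter under heavy noise (> ~8 bpm sd) can move
  a fall time across the 30-s gradual/abrupt boundary for events near
  it.
- Alert delivery is an in-process callback contract; transport (SMS,
  e-mail) is out of scope.
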