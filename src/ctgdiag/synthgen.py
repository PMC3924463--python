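"""Seeded synthetic CTG generator with ground-truth annotations.

Generates paired FHR/UC traces reproducing the six canonical abnormality
morphologies so the whole diagnostic engine is testable without clinical
recordings.  Contractions are raised-cosine bells over a resting tone;
decelerations are inverted raised cosines of stated depth and fall time
anchored to a contraction cycle; a variable deceleration may append a
positive raised-cosine "shoulder" overshoot after recovery; tachycardia
and bradycardia are cosine-ramped plateaus.  All key points of every
injected event are known analytically and recorded as ground truth.

The FHR always carries a tiny deterministic micro-variability term
(default 0.05 bpm): a real heart rate is never sample-for-sample
constant, and the cleaning stage treats exactly repeated readings as a
stuck transducer.  Optional Gaussian noise and independent per-sample
dropout exercise the cleaning and smoothing stages.  Identical seeds
give bit-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .errors import SpecValidationError
from .keypoints import DecelEpisode, KeyPoint, Shoulder, UCCycle
from .rules import Symptom
from .trace_io import CTGTrace

FHR_PHYS_RANGE = (30.0, 240.0)


# ---------------------------------------------------------------------------
# Spec
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UCBell:
    """One contraction: raised cosine of ``amplitude`` over the resting
    tone, spanning ``[onset_s, onset_s + duration_s]``."""

    onset_s: float
    duration_s: float
    amplitude: float


@dataclass(frozen=True)
class EarlyDecelEvent:
    kind = "early_decel"
    cycle: int
    depth_bpm: float
    fall_s: float
    lag_s: float


@dataclass(frozen=True)
class LateDecelEvent:
    kind = "late_decel"
    cycle: int
    depth_bpm: float
    fall_s: float
    nadir_after_uce_s: float


@dataclass(frozen=True)
class ShoulderSpec:
    height_bpm: float
    duration_s: float


@dataclass(frozen=True)
class VarDecelEvent:
    kind = "var_decel"
    cycle: int
    depth_bpm: float
    fall_s: float  # <= 30: abrupt V/U shape
    lag_s: float
    shoulder: Optional[ShoulderSpec] = None


@dataclass(frozen=True)
class TachyEvent:
    kind = "tachy"
    start_s: float
    duration_s: float
    level_bpm: float


@dataclass(frozen=True)
class BradyEvent:
    kind = "brady"
    start_s: float
    duration_s: float
    level_bpm: float


Event = Union[EarlyDecelEvent, LateDecelEvent, VarDecelEvent, TachyEvent, BradyEvent]

_EVENT_TYPES = {
    "early_decel": EarlyDecelEvent,
    "late_decel": LateDecelEvent,
    "var_decel": VarDecelEvent,
    "tachy": TachyEvent,
    "brady": BradyEvent,
}

#: plateau edge ramp for sustained-rate events, seconds
RAMP_S = 15.0


@dataclass
class SynthSpec:
    """Full description of one synthetic trace."""

    duration_s: float
    rate: float = 2.0
    baseline_bpm: float = 140.0
    resting_tone: float = 5.0
    uc: list[UCBell] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)
    noise_sd_bpm: float = 0.0
    dropout_prob: float = 0.0
    variability_bpm: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.duration_s <= 0 or self.rate <= 0:
            problems.append("duration_s and rate must be positive")
        lo, hi = FHR_PHYS_RANGE
        if not lo <= self.baseline_bpm <= hi:
            problems.append(f"baseline {self.baseline_bpm} outside physical range {lo}-{hi}")
        for i, bell in enumerate(self.uc):
            if bell.duration_s <= 0 or bell.amplitude <= 0 or bell.onset_s < 0:
                problems.append(f"uc[{i}]: non-positive geometry")
            if bell.onset_s + bell.duration_s > self.duration_s:
                problems.append(f"uc[{i}]: extends past trace end")
        for i, ev in enumerate(self.events):
            tag = f"events[{i}] ({ev.kind})"
            if isinstance(ev, (EarlyDecelEvent, LateDecelEvent, VarDecelEvent)):
                if not 0 <= ev.cycle < len(self.uc):
                    problems.append(f"{tag}: references missing cycle {ev.cycle}")
                if ev.depth_bpm <= 0 or ev.fall_s <= 0:
                    problems.append(f"{tag}: non-positive depth/fall")
                if self.baseline_bpm - ev.depth_bpm < lo:
                    problems.append(f"{tag}: nadir below physical range")
                if isinstance(ev, VarDecelEvent) and ev.fall_s > 30:
                    problems.append(f"{tag}: variable deceleration fall must be <= 30 s")
            else:
                if not lo <= ev.level_bpm <= hi:
                    problems.append(f"{tag}: level outside physical range {lo}-{hi}")
                if ev.duration_s <= 0 or ev.start_s < 0:
                    problems.append(f"{tag}: non-positive geometry")
                if ev.start_s + ev.duration_s > self.duration_s:
                    problems.append(f"{tag}: extends past trace end")
        if problems:
            raise SpecValidationError(problems)

    # -- JSON ----------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["events"] = [dict(asdict(ev), kind=ev.kind) for ev in self.events]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthSpec":
        d = dict(d)
        d["uc"] = [UCBell(**b) for b in d.get("uc", [])]
        events = []
        for ev in d.get("events", []):
            ev = dict(ev)
            kind = ev.pop("kind")
            typ = _EVENT_TYPES[kind]
            if kind == "var_decel" and ev.get("shoulder") is not None:
                ev["shoulder"] = ShoulderSpec(**ev["shoulder"])
            events.append(typ(**ev))
        d["events"] = events
        return cls(**d)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthEvent:
    """Exact injected geometry and intended label for one event."""

    kind: str
    label: str
    keypoints: dict[str, tuple[float, float]]  # name -> (t, v)
    cycle_index: Optional[int] = None
    b: Optional[float] = None

    def as_episode(self) -> DecelEpisode:
        """Reconstruct the ideal deceleration episode from the injected
        key points (for truth-side rule evaluation)."""
        if self.kind not in ("early_decel", "late_decel", "var_decel"):
            raise ValueError(f"{self.kind} is not a deceleration event")
        kp = {k: KeyPoint(*v) for k, v in self.keypoints.items()}
        shoulder = None
        if "hsp" in kp:
            shoulder = Shoulder(hsp=kp["hsp"], hse=kp["hse"])
        cycle = UCCycle(ucs=kp["ucs"], ucp=kp["ucp"], uce=kp["uce"])
        return DecelEpisode(
            hrs=kp["hrs"], hrp=kp["hrp"], hre=kp["hre"], b=self.b, cycle=cycle,
            shoulder=shoulder,
        )


@dataclass
class GroundTruth:
    events: list[TruthEvent] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"events": [asdict(ev) for ev in self.events]}

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        events = []
        for ev in d.get("events", []):
            ev = dict(ev)
            ev["keypoints"] = {k: tuple(v) for k, v in ev["keypoints"].items()}
            events.append(TruthEvent(**ev))
        return cls(events=events)


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path: str | Path) -> GroundTruth:
    with open(path, "r", encoding="utf-8") as fh:
        return GroundTruth.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _raised_cosine(t: np.ndarray, onset: float, duration: float, amplitude: float) -> np.ndarray:
    """0 outside [onset, onset+duration]; half-sine-squared bump inside,
    peaking at amplitude in the middle."""
    tau = t - onset
    inside = (tau >= 0) & (tau <= duration)
    out = np.zeros_like(t)
    out[inside] = amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * tau[inside] / duration))
    return out


def _ramped_plateau(t: np.ndarray, start: float, duration: float, delta: float) -> np.ndarray:
    """Cosine-ramped plateau: ramps of RAMP_S seconds flank a flat hold of
    ``duration`` seconds at offset ``delta``."""
    out = np.zeros_like(t)
    up = (t >= start - RAMP_S) & (t < start)
    out[up] = delta * 0.5 * (1.0 - np.cos(np.pi * (t[up] - (start - RAMP_S)) / RAMP_S))
    hold = (t >= start) & (t <= start + duration)
    out[hold] = delta
    down = (t > start + duration) & (t <= start + duration + RAMP_S)
    out[down] = delta * 0.5 * (1.0 + np.cos(np.pi * (t[down] - (start + duration)) / RAMP_S))
    return out


def generate_trace(spec: SynthSpec) -> tuple[CTGTrace, GroundTruth]:
    """Render a spec into a trace plus exact ground-truth annotations."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.rate))
    t = np.arange(n) / spec.rate

    uc = np.full(n, spec.resting_tone, dtype=float)
    for bell in spec.uc:
        uc += _raised_cosine(t, bell.onset_s, bell.duration_s, bell.amplitude)

    # micro-variability: small seeded-phase sinusoid, period deliberately
    # incommensurate with the sampling grid so no two samples repeat exactly
    phase = rng.uniform(0.0, 2.0 * np.pi)
    fhr = spec.baseline_bpm + spec.variability_bpm * np.sin(
        2.0 * np.pi * t / 7.31 + phase
    )

    truth = GroundTruth()
    b = spec.baseline_bpm
    for ev in spec.events:
        if isinstance(ev, (EarlyDecelEvent, VarDecelEvent)):
            bell = spec.uc[ev.cycle]
            hrs_t = bell.onset_s + ev.lag_s
            _add_decel(fhr, t, truth, spec, ev, hrs_t)
        elif isinstance(ev, LateDecelEvent):
            bell = spec.uc[ev.cycle]
            uce_t = bell.onset_s + bell.duration_s
            hrs_t = uce_t + ev.nadir_after_uce_s - ev.fall_s
            _add_decel(fhr, t, truth, spec, ev, hrs_t)
        elif isinstance(ev, TachyEvent):
            fhr += _ramped_plateau(t, ev.start_s, ev.duration_s, ev.level_bpm - b)
            truth.events.append(
                TruthEvent(
                    kind=ev.kind,
                    label=Symptom.TACHYCARDIA.value,
                    keypoints={
                        "start": (ev.start_s, ev.level_bpm),
                        "end": (ev.start_s + ev.duration_s, ev.level_bpm),
                    },
                    b=b,
                )
            )
        elif isinstance(ev, BradyEvent):
            fhr += _ramped_plateau(t, ev.start_s, ev.duration_s, ev.level_bpm - b)
            truth.events.append(
                TruthEvent(
                    kind=ev.kind,
                    label=Symptom.BRADYCARDIA.value,
                    keypoints={
                        "start": (ev.start_s, ev.level_bpm),
                        "end": (ev.start_s + ev.duration_s, ev.level_bpm),
                    },
                    b=b,
                )
            )

    if spec.noise_sd_bpm > 0:
        fhr = fhr + rng.normal(0.0, spec.noise_sd_bpm, n)
    if spec.dropout_prob > 0:
        fhr[rng.random(n) < spec.dropout_prob] = np.nan
        uc[rng.random(n) < spec.dropout_prob] = np.nan

    trace = CTGTrace(fhr, uc, rate=spec.rate, label=f"synth-seed{spec.seed}")
    return trace, truth


def _add_decel(fhr, t, truth, spec, ev, hrs_t: float) -> None:
    """Inject a symmetric inverted raised cosine (fall = recovery = fall_s),
    plus an optional shoulder, and record the exact key points."""
    b = spec.baseline_bpm
    total = 2.0 * ev.fall_s
    fhr -= _raised_cosine(t, hrs_t, total, ev.depth_bpm)
    hrp_t = hrs_t + ev.fall_s
    hre_t = hrs_t + total

    bell = spec.uc[ev.cycle]
    keypoints = {
        "hrs": (hrs_t, b),
        "hrp": (hrp_t, b - ev.depth_bpm),
        "hre": (hre_t, b),
        "ucs": (bell.onset_s, spec.resting_tone),
        "ucp": (bell.onset_s + bell.duration_s / 2.0, spec.resting_tone + bell.amplitude),
        "uce": (bell.onset_s + bell.duration_s, spec.resting_tone),
    }
    label = {
        "early_decel": Symptom.EARLY_DECELERATION,
        "late_decel": Symptom.LATE_DECELERATION,
        "var_decel": Symptom.VARIABLE_DECELERATION_A,
    }[ev.kind]
    if isinstance(ev, VarDecelEvent) and ev.shoulder is not None:
        sh = ev.shoulder
        fhr += _raised_cosine(t, hre_t, sh.duration_s, sh.height_bpm)
        keypoints["hsp"] = (hre_t + sh.duration_s / 2.0, b + sh.height_bpm)
        keypoints["hse"] = (hre_t + sh.duration_s, b)
        label = Symptom.VARIABLE_DECELERATION_B
    truth.events.append(
        TruthEvent(
            kind=ev.kind,
            label=label.value,
            keypoints=keypoints,
            cycle_index=ev.cycle,
            b=b,
        )
    )


# ---------------------------------------------------------------------------
# Recovery-suite study conditions
# ---------------------------------------------------------------------------

#: Randomized-parameter ranges for the recovery suite, chosen once to sit
#: inside the rule-satisfying regions with margin for the known onset- and
#: crossing-estimation biases (documented in docs/methods.md).
RECOVERY_RANGES = {
    "early": dict(fall=(42.0, 58.0), lag=(12.0, 18.0), depth=(25.0, 45.0)),
    "late": dict(fall=(35.0, 50.0), after=(8.0, 25.0), depth=(25.0, 45.0)),
    "var_a": dict(fall=(12.0, 24.0), lag=(12.0, 20.0), depth=(25.0, 45.0)),
    "var_b": dict(
        fall=(12.0, 24.0), lag=(12.0, 20.0), depth=(25.0, 45.0),
        sh_height=(14.0, 20.0), sh_dur=(25.0, 35.0),
    ),
    "tachy": dict(level=(168.0, 178.0), duration=(240.0, 330.0)),
    "brady": dict(level=(88.0, 102.0), duration=(240.0, 330.0)),
}

CLASSES = ("early", "late", "var_a", "var_b", "tachy", "brady")


def make_recovery_suite(
    seed: int,
    n_per_class: int = 20,
    noise_sd_bpm: float = 0.0,
    dropout_prob: float = 0.0,
) -> list[SynthSpec]:
    """One single-event 900-second trace per injected event, ``n_per_class``
    per symptom class, parameters drawn uniformly from RECOVERY_RANGES."""
    rng = np.random.default_rng(seed)
    specs = []
    for cls in CLASSES:
        r = RECOVERY_RANGES[cls]
        for _ in range(n_per_class):
            baseline = float(rng.integers(130, 146))
            trace_seed = int(rng.integers(0, 2**31 - 1))
            common = dict(
                duration_s=900.0,
                baseline_bpm=baseline,
                noise_sd_bpm=noise_sd_bpm,
                dropout_prob=dropout_prob,
                seed=trace_seed,
            )
            if cls in ("tachy", "brady"):
                level = float(rng.uniform(*r["level"]))
                dur = float(rng.uniform(*r["duration"]))
                ev = (TachyEvent if cls == "tachy" else BradyEvent)(
                    start_s=200.0, duration_s=dur, level_bpm=level
                )
                specs.append(SynthSpec(uc=[], events=[ev], **common))
                continue
            fall = float(rng.uniform(*r["fall"]))
            depth = float(rng.uniform(*r["depth"]))
            if cls == "late":
                after = float(rng.uniform(*r["after"]))
                bell_dur = float(rng.uniform(70.0, 90.0))
                ev = LateDecelEvent(
                    cycle=0, depth_bpm=depth, fall_s=fall, nadir_after_uce_s=after
                )
            else:
                lag = float(rng.uniform(*r["lag"]))
                if cls == "early":
                    # nadir comfortably before the contraction ends
                    bell_dur = lag + fall + float(rng.uniform(10.0, 18.0))
                    ev = EarlyDecelEvent(cycle=0, depth_bpm=depth, fall_s=fall, lag_s=lag)
                else:
                    bell_dur = float(rng.uniform(70.0, 90.0))
                    shoulder = None
                    if cls == "var_b":
                        shoulder = ShoulderSpec(
                            height_bpm=float(rng.uniform(*r["sh_height"])),
                            duration_s=float(rng.uniform(*r["sh_dur"])),
                        )
                    ev = VarDecelEvent(
                        cycle=0, depth_bpm=depth, fall_s=fall, lag_s=lag,
                        shoulder=shoulder,
                    )
            bell = UCBell(onset_s=300.0, duration_s=bell_dur, amplitude=float(rng.uniform(40.0, 70.0)))
            specs.append(SynthSpec(uc=[bell], events=[ev], **common))
    return specs
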