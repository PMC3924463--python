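"""Symptom classification rules.

Six abnormality patterns are recognised: sustained tachycardia and
bradycardia, and four contraction-linked deceleration patterns — early,
late, and variable types A and B.  Each is a conjunction of inclusive
inequalities over the extracted key points; clinical shorthand overloads
the point symbols as both times and values, so each rule below states
explicitly which field it compares:

==========================  ==============================================
Early deceleration          hrp.t < uce.t (nadir before contraction ends);
                            hrp.t - hrs.t >= fall_time_s (gradual fall);
                            hrs.t >= ucs.t + uc_lag_s (fall lags onset);
                            b - hrp.v >= depth_bpm
Late deceleration           hrp.t >= uce.t (nadir after contraction ends);
                            hrp.t - hrs.t >= fall_time_s;
                            b - hrp.v >= depth_bpm
Variable deceleration A     hrp.t - hrs.t <= fall_time_s (abrupt fall);
                            hrs.t >= ucs.t + uc_lag_s;
                            b - hrp.v >= depth_bpm
Variable deceleration B     hrs.t >= ucs.t + uc_lag_s;
                            b - hrp.v >= depth_bpm;
                            shoulder present with
                            hsp.v - b >= shoulder_height_bpm and
                            hse.t - hre.t >= shoulder_lag_s
Tachycardia / Bradycardia   samples >= tachy_bpm / <= brady_bpm for at
                            least sustained_min_s (enforced upstream by
                            sustained-run detection)
==========================  ==============================================

All satisfied rule sets are reported: an episode whose fall time equals
the boundary exactly can legitimately satisfy both an "early" and a
"type A" pattern, and the report marks such episodes ambiguous rather
than imposing a precedence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .keypoints import DecelEpisode, SustainedRateEpisode
from .trace_io import CriteriaSet


class Symptom(str, enum.Enum):
    TACHYCARDIA = "Tachycardia"
    BRADYCARDIA = "Bradycardia"
    EARLY_DECELERATION = "EarlyDeceleration"
    LATE_DECELERATION = "LateDeceleration"
    VARIABLE_DECELERATION_A = "VariableDecelerationA"
    VARIABLE_DECELERATION_B = "VariableDecelerationB"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class SymptomLabel:
    """An assigned symptom together with the rule ids that fired."""

    symptom: Symptom
    satisfied_rules: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.satisfied_rules:
            raise ValueError("an assigned label must satisfy at least one rule")


def samples_to_seconds(n: int | float, rate: float) -> float:
    """Convert a sample count to seconds at ``rate`` samples/second.

    At the conventional 2 samples/second, 90 points span 45 s and 10
    points span 5 s.
    """
    if rate <= 0:
        raise ValueError(f"rate must be > 0, got {rate}")
    if n < 0:
        raise ValueError(f"sample count must be >= 0, got {n}")
    return n / rate


def classify_decel(e: DecelEpisode, c: CriteriaSet) -> list[SymptomLabel]:
    """Evaluate the four deceleration rule sets against one episode.

    Returns every satisfied label (possibly none, possibly several),
    each with the identifiers of its satisfied rules.  The episode must
    carry a linked contraction cycle.
    """
    if e.cycle is None:
        raise ValueError("classify_decel requires an episode with a linked UC cycle")
    ucs, uce = e.cycle.ucs, e.cycle.uce
    fall = e.hrp.t - e.hrs.t
    lag_ok = e.hrs.t >= ucs.t + c.uc_lag_s
    depth_ok = e.b - e.hrp.v >= c.depth_bpm

    out: list[SymptomLabel] = []

    rules = []
    if e.hrp.t < uce.t:
        rules.append("early.nadir_before_uce")
    if fall >= c.fall_time_s:
        rules.append("early.gradual_fall")
    if lag_ok:
        rules.append("early.lags_contraction")
    if depth_ok:
        rules.append("early.depth")
    if len(rules) == 4:
        out.append(SymptomLabel(Symptom.EARLY_DECELERATION, tuple(rules)))

    rules = []
    if e.hrp.t >= uce.t:
        rules.append("late.nadir_after_uce")
    if fall >= c.fall_time_s:
        rules.append("late.gradual_fall")
    if depth_ok:
        rules.append("late.depth")
    if len(rules) == 3:
        out.append(SymptomLabel(Symptom.LATE_DECELERATION, tuple(rules)))

    rules = []
    if fall <= c.fall_time_s:
        rules.append("var_a.abrupt_fall")
    if lag_ok:
        rules.append("var_a.lags_contraction")
    if depth_ok:
        rules.append("var_a.depth")
    if len(rules) == 3:
        out.append(SymptomLabel(Symptom.VARIABLE_DECELERATION_A, tuple(rules)))

    rules = []
    if lag_ok:
        rules.append("var_b.lags_contraction")
    if depth_ok:
        rules.append("var_b.depth")
    if e.shoulder is not None:
        if e.shoulder.hsp.v - e.b >= c.shoulder_height_bpm:
            rules.append("var_b.shoulder_height")
        if e.shoulder.hse.t - e.hre.t >= c.shoulder_lag_s:
            rules.append("var_b.shoulder_lag")
    if len(rules) == 4:
        out.append(SymptomLabel(Symptom.VARIABLE_DECELERATION_B, tuple(rules)))

    return out


def classify_sustained(e: SustainedRateEpisode, c: CriteriaSet) -> SymptomLabel:
    """Label a sustained-rate episode as tachycardia or bradycardia."""
    if e.kind == "high":
        return SymptomLabel(
            Symptom.TACHYCARDIA, ("tachy.level", "tachy.duration")
        )
    return SymptomLabel(Symptom.BRADYCARDIA, ("brady.level", "brady.duration"))
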