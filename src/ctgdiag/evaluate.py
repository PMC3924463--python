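"""Scoring diagnosis reports against synthetic ground truth.

Used by the recovery suite: an injected event is *recovered* when some
reported episode carries the event's intended label; a reported label is
*spurious* when the exact injected geometry, evaluated directly against
the rules, could not have produced it.  Deceleration truth is evaluated
by running the classifier on the ideal episode reconstructed from the
injected key points, so an abrupt deceleration with a shoulder that
genuinely satisfies both variable-deceleration rule sets is not penalised
for being reported with both labels.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pipeline import DiagnosisReport
from .rules import Symptom, classify_decel
from .synthgen import GroundTruth
from .trace_io import CriteriaSet


@dataclass
class RecoveryScore:
    recovered: int = 0
    total: int = 0
    spurious: int = 0

    @property
    def rate(self) -> float:
        return self.recovered / self.total if self.total else float("nan")

    def __iadd__(self, other: "RecoveryScore") -> "RecoveryScore":
        self.recovered += other.recovered
        self.total += other.total
        self.spurious += other.spurious
        return self


def admissible_labels(truth: GroundTruth, criteria: CriteriaSet) -> set[Symptom]:
    """All labels the injected geometry genuinely satisfies."""
    out: set[Symptom] = set()
    for ev in truth.events:
        if ev.kind in ("tachy", "brady"):
            out.add(Symptom(ev.label))
        else:
            out |= {lab.symptom for lab in classify_decel(ev.as_episode(), criteria)}
    return out


def score_report(
    truth: GroundTruth, report: DiagnosisReport, criteria: CriteriaSet
) -> RecoveryScore:
    """Score one trace: intended labels recovered, inadmissible labels spurious."""
    assigned = report.label_set()
    admissible = admissible_labels(truth, criteria)
    score = RecoveryScore(total=len(truth.events))
    score.recovered = sum(1 for ev in truth.events if Symptom(ev.label) in assigned)
    score.spurious = len(assigned - admissible)
    return score
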