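"""End-to-end diagnosis: clean -> smooth -> baselines -> key points ->
rule labels -> alert events, plus the report container and alert dispatch.

The pipeline is fully deterministic: identical (trace, criteria, config)
produce byte-identical serialized reports.  Alerts are in-process events
handed to a caller-supplied sink (delivery infrastructure such as SMS or
e-mail is deliberately out of scope); every labelled episode produces
exactly one alert per assigned label.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Callable, Optional

from . import preprocess
from .errors import DegenerateInputError
from .keypoints import (
    DecelEpisode,
    DetectionConfig,
    KeyPoint,
    Shoulder,
    SustainedRateEpisode,
    UCCycle,
    detect_shoulder,
    detect_sustained,
    detect_uc_cycles,
    extract_decel,
)
from .preprocess import CleanConfig, baseline_at, clean, estimate_baseline, smooth
from .rules import Symptom, SymptomLabel, classify_decel, classify_sustained
from .trace_io import CriteriaSet, CTGTrace

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    clean: CleanConfig = field(default_factory=CleanConfig)
    detect: DetectionConfig = field(default_factory=DetectionConfig)
    baseline_window_s: float = 600.0
    recipient_hint: str = ""


@dataclass(frozen=True)
class AlertEvent:
    """One notification-worthy finding: a labelled episode occurrence."""

    timestamp: float
    label: str
    episode_ref: str
    recipient_hint: str = ""


@dataclass
class LabelledDecel:
    episode: DecelEpisode
    labels: list[SymptomLabel]

    @property
    def ambiguous(self) -> bool:
        return len(self.labels) > 1


@dataclass
class LabelledSustained:
    episode: SustainedRateEpisode
    label: SymptomLabel


@dataclass
class DiagnosisReport:
    trace_label: str
    criteria: CriteriaSet
    decels: list[LabelledDecel] = field(default_factory=list)
    sustained: list[LabelledSustained] = field(default_factory=list)
    alerts: list[AlertEvent] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    baselines: list[preprocess.BaselineEstimate] = field(default_factory=list)

    def label_set(self) -> set[Symptom]:
        out = {lab.symptom for d in self.decels for lab in d.labels}
        out |= {s.label.symptom for s in self.sustained}
        return out

    # -- serialization (deterministic; schema in docs/report.schema.json) --

    def to_dict(self) -> dict:
        return {
            "trace_label": self.trace_label,
            "criteria": dict(self.criteria.to_dict(), patient=self.criteria.patient),
            "config": self.config,
            "baselines": [asdict(b) for b in self.baselines],
            "decels": [
                {
                    "episode": _episode_to_dict(d.episode),
                    "labels": [_label_to_dict(lab) for lab in d.labels],
                    "ambiguous": d.ambiguous,
                }
                for d in self.decels
            ],
            "sustained": [
                {"episode": asdict(s.episode), "label": _label_to_dict(s.label)}
                for s in self.sustained
            ],
            "alerts": [asdict(a) for a in self.alerts],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2) + "\n"

    @classmethod
    def from_dict(cls, d: dict) -> "DiagnosisReport":
        crit = dict(d["criteria"])
        patient = crit.pop("patient", "")
        return cls(
            trace_label=d["trace_label"],
            criteria=CriteriaSet(patient=patient, **crit),
            config=d.get("config", {}),
            baselines=[
                preprocess.BaselineEstimate(
                    b=b["b"], uc_tone=b["uc_tone"], window=tuple(b["window"])
                )
                for b in d.get("baselines", [])
            ],
            decels=[
                LabelledDecel(
                    episode=_episode_from_dict(x["episode"]),
                    labels=[_label_from_dict(lab) for lab in x["labels"]],
                )
                for x in d.get("decels", [])
            ],
            sustained=[
                LabelledSustained(
                    episode=SustainedRateEpisode(**x["episode"]),
                    label=_label_from_dict(x["label"]),
                )
                for x in d.get("sustained", [])
            ],
            alerts=[AlertEvent(**a) for a in d.get("alerts", [])],
        )

    @classmethod
    def from_json(cls, text: str) -> "DiagnosisReport":
        return cls.from_dict(json.loads(text))


def _label_to_dict(lab: SymptomLabel) -> dict:
    return {"symptom": lab.symptom.value, "satisfied_rules": list(lab.satisfied_rules)}


def _label_from_dict(d: dict) -> SymptomLabel:
    return SymptomLabel(Symptom(d["symptom"]), tuple(d["satisfied_rules"]))


def _episode_to_dict(e: DecelEpisode) -> dict:
    d = {
        "hrs": asdict(e.hrs),
        "hrp": asdict(e.hrp),
        "hre": asdict(e.hre),
        "b": e.b,
        "cycle": None
        if e.cycle is None
        else {"ucs": asdict(e.cycle.ucs), "ucp": asdict(e.cycle.ucp), "uce": asdict(e.cycle.uce)},
        "shoulder": None
        if e.shoulder is None
        else {"hsp": asdict(e.shoulder.hsp), "hse": asdict(e.shoulder.hse)},
    }
    return d


def _episode_from_dict(d: dict) -> DecelEpisode:
    kp = lambda x: KeyPoint(**x)  # noqa: E731
    return DecelEpisode(
        hrs=kp(d["hrs"]),
        hrp=kp(d["hrp"]),
        hre=kp(d["hre"]),
        b=d["b"],
        cycle=None
        if d["cycle"] is None
        else UCCycle(kp(d["cycle"]["ucs"]), kp(d["cycle"]["ucp"]), kp(d["cycle"]["uce"])),
        shoulder=None
        if d["shoulder"] is None
        else Shoulder(kp(d["shoulder"]["hsp"]), kp(d["shoulder"]["hse"])),
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def run_diagnosis(
    trace: CTGTrace,
    criteria: CriteriaSet = CriteriaSet(),
    config: PipelineConfig = PipelineConfig(),
) -> DiagnosisReport:
    """Full diagnostic pass over one trace.

    Cleans and smooths both channels, estimates per-window FHR baseline
    and UC resting tone, extracts contraction cycles and their linked
    decelerations (with shoulder regions) plus sustained-rate runs,
    applies the per-patient criteria, and emits one alert event per
    (episode, label).  Raises :class:`DegenerateInputError` for traces
    too empty to analyse.
    """
    cleaned = clean(trace, config.clean)
    estimates = estimate_baseline(cleaned, config.baseline_window_s, config.clean)
    fhr_s = smooth(cleaned.fhr, cleaned.rate, config.clean.smooth_window_s)
    uc_s = smooth(cleaned.uc, cleaned.rate, config.clean.smooth_window_s)

    report = DiagnosisReport(
        trace_label=trace.label,
        criteria=criteria,
        config=_config_snapshot(config),
        baselines=estimates,
    )

    tone_at = lambda t: baseline_at(estimates, t).uc_tone  # noqa: E731
    cycles = detect_uc_cycles(uc_s, tone_at, cleaned.rate, config.detect)
    for cycle in cycles:
        b = baseline_at(estimates, cycle.ucp.t).b
        ep = extract_decel(fhr_s, cycle, b, cleaned.rate, criteria, config.detect)
        if ep is None:
            continue
        ep = detect_shoulder(fhr_s, ep, b, cleaned.rate, config.detect)
        labels = classify_decel(ep, criteria)
        report.decels.append(LabelledDecel(episode=ep, labels=labels))

    for ep in detect_sustained(fhr_s, cleaned.rate, criteria):
        report.sustained.append(
            LabelledSustained(episode=ep, label=classify_sustained(ep, criteria))
        )

    alerts = []
    for i, d in enumerate(report.decels):
        for lab in d.labels:
            alerts.append(
                AlertEvent(
                    timestamp=d.episode.hrs.t,
                    label=lab.symptom.value,
                    episode_ref=f"decels[{i}]",
                    recipient_hint=config.recipient_hint,
                )
            )
    for i, s in enumerate(report.sustained):
        alerts.append(
            AlertEvent(
                timestamp=s.episode.start,
                label=s.label.symptom.value,
                episode_ref=f"sustained[{i}]",
                recipient_hint=config.recipient_hint,
            )
        )
    alerts.sort(key=lambda a: (a.timestamp, a.label))
    report.alerts = alerts
    return report


def _config_snapshot(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["clean"]["fhr_valid_range"] = list(config.clean.fhr_valid_range)
    return d


def emit_alerts(report: DiagnosisReport, sink: Callable[[AlertEvent], None]) -> int:
    """Hand every alert to ``sink`` exactly once, in time order.

    A sink failure on an alert is retried once; a second failure is
    logged and the alert skipped.  Returns the number delivered.
    """
    delivered = 0
    for alert in sorted(report.alerts, key=lambda a: (a.timestamp, a.label)):
        try:
            sink(alert)
        except Exception:
            log.warning("alert sink failed for %s at %.1fs, retrying", alert.label, alert.timestamp)
            try:
                sink(alert)
            except Exception:
                log.error(
                    "alert sink failed twice for %s at %.1fs; skipped",
                    alert.label,
                    alert.timestamp,
                )
                continue
        delivered += 1
    return delivered
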