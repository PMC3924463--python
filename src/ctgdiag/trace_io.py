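"""Reading and writing CTG traces, abnormality criteria and diagnosis reports.

A cardiotocogram (CTG) is a paired recording of fetal heart rate (FHR, in
beats per minute) and uterine-contraction intensity (UC, relative units
0-100), conventionally sampled twice per second.  Traces travel as UTF-8
CSV with header ``t,fhr,uc`` (``t`` optional, seconds from trace start);
missing samples are empty cells and become NaN in memory.

Per-patient diagnostic thresholds are prescribed by the responsible
obstetrician and stored as a small XML document, one file per patient
profile::

    <criteria patient="...">
      <symptom name="Tachycardia">
        <threshold key="tachy_bpm" value="160"/>
        <threshold key="sustained_min_s" value="180"/>
      </symptom>
      ...
    </criteria>

Any threshold absent from the file falls back to its conventional default
(and a warning is logged), so an empty ``<criteria/>`` is a valid,
fully-default profile.
"""

from __future__ import annotations

import csv
import io
import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import CriteriaError, FormatError

log = logging.getLogger(__name__)

DEFAULT_RATE = 2.0  # samples per second


@dataclass
class CTGTrace:
    """Paired FHR / UC sample series with a common sampling rate.

    ``fhr`` and ``uc`` are float arrays of equal length; NaN marks a
    missing sample.  ``rate`` is in samples per second; sample ``i`` is at
    time ``i / rate`` seconds from trace start.
    """

    fhr: np.ndarray
    uc: np.ndarray
    rate: float = DEFAULT_RATE
    label: str = ""

    def __post_init__(self) -> None:
        self.fhr = np.asarray(self.fhr, dtype=float)
        self.uc = np.asarray(self.uc, dtype=float)
        if self.fhr.shape != self.uc.shape or self.fhr.ndim != 1:
            raise FormatError(
                f"fhr and uc must be 1-D and equally long, got {self.fhr.shape} vs {self.uc.shape}"
            )
        if not self.rate > 0:
            raise FormatError(f"sampling rate must be > 0, got {self.rate}")
        for name, arr in (("fhr", self.fhr), ("uc", self.uc)):
            if np.isinf(arr).any():
                raise FormatError(f"non-finite (infinite) sample in {name}")

    def __len__(self) -> int:
        return len(self.fhr)

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def duration_s(self) -> float:
        return len(self) / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.rate

    def copy(self) -> "CTGTrace":
        return replace(self, fhr=self.fhr.copy(), uc=self.uc.copy())


# ---------------------------------------------------------------------------
# Criteria
# ---------------------------------------------------------------------------

#: Canonical grouping of threshold keys under the six symptom rule sets.
SYMPTOM_KEYS: dict[str, tuple[str, ...]] = {
    "Tachycardia": ("tachy_bpm", "sustained_min_s"),
    "Bradycardia": ("brady_bpm", "sustained_min_s"),
    "EarlyDeceleration": ("fall_time_s", "uc_lag_s", "depth_bpm"),
    "LateDeceleration": ("fall_time_s", "depth_bpm"),
    "VariableDecelerationA": ("fall_time_s", "uc_lag_s", "depth_bpm"),
    "VariableDecelerationB": (
        "uc_lag_s",
        "depth_bpm",
        "shoulder_height_bpm",
        "shoulder_lag_s",
    ),
}


@dataclass(frozen=True)
class CriteriaSet:
    """All numeric abnormality thresholds for one patient profile.

    Defaults are the conventional obstetric values: tachycardia at or above
    160 bpm and bradycardia at or below 110 bpm, each sustained for at least
    three minutes; a deceleration is "gradual" when the fall from onset to
    nadir takes at least 30 s, must start at least 5 s after contraction
    onset to count as contraction-linked, and must reach at least 15 bpm
    below baseline; a post-deceleration shoulder must overshoot the baseline
    by at least 10 bpm and persist at least 10 s beyond recovery.
    """

    tachy_bpm: float = 160.0
    brady_bpm: float = 110.0
    sustained_min_s: float = 180.0
    fall_time_s: float = 30.0
    uc_lag_s: float = 5.0
    depth_bpm: float = 15.0
    shoulder_height_bpm: float = 10.0
    shoulder_lag_s: float = 10.0
    patient: str = ""

    _KEYS = (
        "tachy_bpm",
        "brady_bpm",
        "sustained_min_s",
        "fall_time_s",
        "uc_lag_s",
        "depth_bpm",
        "shoulder_height_bpm",
        "shoulder_lag_s",
    )

    def __post_init__(self) -> None:
        for k in self._KEYS:
            v = getattr(self, k)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise CriteriaError(f"threshold {k!r} must be a finite positive number, got {v!r}")
        if not self.tachy_bpm > self.brady_bpm:
            raise CriteriaError(
                f"tachy_bpm ({self.tachy_bpm}) must exceed brady_bpm ({self.brady_bpm})"
            )

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in self._KEYS}


def read_criteria(path: str | Path) -> CriteriaSet:
    """Load a :class:`CriteriaSet` from a per-patient XML profile.

    Thresholds missing from the document take their defaults (one warning
    per missing key).  A non-positive value, an unknown symptom or
    threshold key, or two occurrences of the same key with conflicting
    values raise :class:`CriteriaError` naming the offending element.
    """
    try:
        tree = ET.parse(str(path))
    except OSError:
        raise
    except ET.ParseError as exc:
        raise CriteriaError(f"malformed criteria XML in {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "criteria":
        raise CriteriaError(f"root element must be <criteria>, got <{root.tag}>")

    values: dict[str, float] = {}
    for sym in root:
        if sym.tag != "symptom":
            raise CriteriaError(f"unexpected element <{sym.tag}> under <criteria>")
        name = sym.get("name", "")
        if name not in SYMPTOM_KEYS:
            raise CriteriaError(f"unknown symptom name {name!r}")
        for th in sym:
            if th.tag != "threshold":
                raise CriteriaError(f"unexpected element <{th.tag}> under <symptom name={name!r}>")
            key = th.get("key", "")
            if key not in CriteriaSet._KEYS:
                raise CriteriaError(f"unknown threshold key {key!r} under symptom {name!r}")
            raw = th.get("value", "")
            try:
                val = float(raw)
            except ValueError:
                raise CriteriaError(
                    f"threshold {key!r} under {name!r} has non-numeric value {raw!r}"
                ) from None
            if not (math.isfinite(val) and val > 0):
                raise CriteriaError(
                    f"threshold {key!r} under {name!r} must be positive, got {val}"
                )
            if key in values and values[key] != val:
                raise CriteriaError(
                    f"threshold {key!r} appears twice with conflicting values "
                    f"({values[key]} vs {val})"
                )
            values[key] = val

    for key in CriteriaSet._KEYS:
        if key not in values:
            log.warning(
                "criteria %s: threshold %r missing, using default %s",
                path,
                key,
                getattr(CriteriaSet, key),
            )
    return CriteriaSet(patient=root.get("patient", ""), **values)


def write_criteria(criteria: CriteriaSet, path: str | Path) -> None:
    """Write a criteria XML document with every threshold spelled out."""
    root = ET.Element("criteria", patient=criteria.patient)
    for name, keys in SYMPTOM_KEYS.items():
        sym = ET.SubElement(root, "symptom", name=name)
        for key in keys:
            v = getattr(criteria, key)
            ET.SubElement(sym, "threshold", key=key, value=_fmt_num(v))
    ET.indent(root)
    ET.ElementTree(root).write(str(path), encoding="unicode", xml_declaration=True)


def _fmt_num(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------


def read_trace(path: str | Path, rate_override: Optional[float] = None) -> CTGTrace:
    """Read a CTG trace from delimited text.

    The file is CSV with a header naming at least ``fhr`` and ``uc``
    columns (case-insensitive; ``t`` is accepted and ignored for indexing
    since samples are uniform).  Comment lines of the form ``# key = value``
    before the header may carry ``rate`` and ``label`` metadata.  Cells that
    fail to parse as numbers, and empty cells, become missing (NaN) samples.

    The sampling rate is ``rate_override`` if given, else the ``rate``
    header value, else 2 samples/second.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        lines = []
        for line in fh:
            if line.lstrip().startswith("#"):
                body = line.lstrip()[1:].strip()
                if "=" in body:
                    k, _, v = body.partition("=")
                    meta[k.strip().lower()] = v.strip()
                continue
            if line.strip():
                lines.append(line)
    if not lines:
        raise FormatError(f"{path}: empty trace file")

    reader = csv.reader(io.StringIO("".join(lines)))
    header = [h.strip().lower() for h in next(reader)]
    if "fhr" not in header or "uc" not in header:
        raise FormatError(f"{path}: header must name 'fhr' and 'uc' columns, got {header}")
    i_fhr, i_uc = header.index("fhr"), header.index("uc")

    fhr, uc = [], []
    for row in reader:
        if not any(cell.strip() for cell in row):
            continue
        fhr.append(_parse_cell(row[i_fhr] if i_fhr < len(row) else ""))
        uc.append(_parse_cell(row[i_uc] if i_uc < len(row) else ""))

    if rate_override is not None:
        rate = float(rate_override)
    elif "rate" in meta:
        try:
            rate = float(meta["rate"])
        except ValueError:
            raise FormatError(f"{path}: unparsable rate header {meta['rate']!r}") from None
    else:
        rate = DEFAULT_RATE
    return CTGTrace(np.array(fhr), np.array(uc), rate=rate, label=meta.get("label", path.stem))


def _parse_cell(cell: str) -> float:
    cell = cell.strip()
    if not cell:
        return math.nan
    try:
        v = float(cell)
    except ValueError:
        return math.nan
    return v if math.isfinite(v) else math.nan


def write_trace(trace: CTGTrace, path: str | Path) -> None:
    """Write a trace as ``t,fhr,uc`` CSV with rate/label metadata comments.

    Sample values are written with :func:`repr`, so a read-back reproduces
    every non-missing value to machine precision.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# rate = {trace.rate!r}\n")
        if trace.label:
            fh.write(f"# label = {trace.label}\n")
        w = csv.writer(fh)
        w.writerow(["t", "fhr", "uc"])
        for i in range(len(trace)):
            w.writerow(
                [
                    repr(i / trace.rate),
                    "" if math.isnan(trace.fhr[i]) else repr(float(trace.fhr[i])),
                    "" if math.isnan(trace.uc[i]) else repr(float(trace.uc[i])),
                ]
            )


# ---------------------------------------------------------------------------
# Reports (JSON; schema in docs/report.schema.json)
# ---------------------------------------------------------------------------


def write_report(report, path: str | Path) -> None:
    """Serialize a :class:`~ctgdiag.pipeline.DiagnosisReport` to JSON text.

    The encoding is deterministic (sorted keys, repr-exact floats) so that
    identical reports produce byte-identical files and a read-back
    round-trips every key point and label exactly.
    """
    text = report.to_json()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)


def read_report(path: str | Path):
    from .pipeline import DiagnosisReport

    with open(path, "r", encoding="utf-8") as fh:
        return DiagnosisReport.from_json(fh.read())
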