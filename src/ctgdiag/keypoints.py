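"""Key-point extraction from smoothed CTG channels.

The diagnostic vocabulary is a small set of named points.  On the uterine
channel: contraction cycle start ``UCs``, peak ``UCp`` and end ``UCe``.
On the heart-rate channel, anchored to a contraction cycle: the time the
rate starts to fall ``HRs``, the nadir ``HRp``, the recovery point
``HRe``, and — after some variable decelerations — a brief overshoot
above baseline called the shoulder region, with peak ``HSp`` and end
``HSe``.  ``B`` is the local FHR baseline.

Extraction walks each contraction cycle: the UC peak is a sample higher
than both neighbours (plateaus collapse to their earliest sample), the
cycle start/end are the nearest crossings of the resting-tone level;
within a forward search window from the cycle start the deepest FHR
excursion below baseline yields the nadir, the fall onset is found by
walking back up the descent, and the recovery point is the first return
to near-baseline after the nadir.

Every symbol is a :class:`KeyPoint` carrying both its time ``t`` (seconds
from trace start) and channel value ``v``; the classification rules state
explicitly which field each inequality uses, since clinical shorthand
like "HRp - HRs >= 30" (a time lag) and "B - HRp >= 15" (a depth in bpm)
overloads the same symbols.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .trace_io import CriteriaSet


@dataclass(frozen=True)
class KeyPoint:
    """A named instant on one channel: time (s from trace start) and value."""

    t: float
    v: float

    def __post_init__(self) -> None:
        if self.t < 0 or not np.isfinite(self.v):
            raise ValueError(f"invalid key point (t={self.t}, v={self.v})")


@dataclass(frozen=True)
class UCCycle:
    """One uterine contraction cycle: start, peak and end key points."""

    ucs: KeyPoint
    ucp: KeyPoint
    uce: KeyPoint

    def __post_init__(self) -> None:
        if not (self.ucs.t < self.ucp.t < self.uce.t):
            raise ValueError("UC cycle must be ordered ucs.t < ucp.t < uce.t")
        if self.ucp.v < self.ucs.v or self.ucp.v < self.uce.v:
            raise ValueError("UC peak must not lie below the cycle endpoints")


@dataclass(frozen=True)
class Shoulder:
    hsp: KeyPoint
    hse: KeyPoint


@dataclass(frozen=True)
class DecelEpisode:
    """One candidate deceleration with its linked contraction cycle.

    ``b`` is the local FHR baseline the excursion is measured against.
    """

    hrs: KeyPoint
    hrp: KeyPoint
    hre: KeyPoint
    b: float
    cycle: Optional[UCCycle] = None
    shoulder: Optional[Shoulder] = None

    def __post_init__(self) -> None:
        if not (self.hrs.t <= self.hrp.t <= self.hre.t):
            raise ValueError("deceleration must be ordered hrs.t <= hrp.t <= hre.t")
        if self.shoulder is not None:
            if self.shoulder.hsp.t < self.hre.t or self.shoulder.hse.t < self.shoulder.hsp.t:
                raise ValueError("shoulder must follow recovery: hre.t <= hsp.t <= hse.t")

    @property
    def depth_bpm(self) -> float:
        return self.b - self.hrp.v

    @property
    def fall_s(self) -> float:
        return self.hrp.t - self.hrs.t


@dataclass(frozen=True)
class SustainedRateEpisode:
    """A maximal run of samples beyond the tachy/brady threshold.

    ``start``/``end`` are in seconds; ``end - start`` is the run duration
    (end is exclusive, i.e. one sample period past the last sample).
    ``extreme_v`` is the most extreme sample in the run.
    """

    start: float
    end: float
    kind: str  # "high" | "low"
    extreme_v: float

    def __post_init__(self) -> None:
        if self.kind not in ("high", "low"):
            raise ValueError(f"kind must be 'high' or 'low', got {self.kind!r}")
        if not self.end - self.start > 0:
            raise ValueError("episode must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable extraction parameters (none are clinical thresholds).

    min_prominence
        Minimum UC rise above resting tone for a peak to count as a
        contraction, relative units.
    crossing_tol
        Level above resting tone whose crossings mark UCs / UCe.
    return_tol
        FHR band around baseline (bpm) that counts as "returned to
        baseline" when locating HRe and HSe.
    min_depth_bpm
        Excursions shallower than this are not reported as episodes.
    horizon_s
        The deceleration search window runs from UCs to UCe + horizon_s.
    shoulder_window_s
        Shoulder search window after HRe.
    onset_delta_bpm, trend_window_s, trend_slope_bpm_s, trend_patience
        Fall-onset (HRs) estimator: from the nadir, walk back to the
        first sample within ``onset_delta_bpm`` of baseline, then keep
        walking while the forward slope over ``trend_window_s`` stays
        below ``-trend_slope_bpm_s``; the walk ends once the slope
        condition has failed for ``trend_patience`` consecutive samples
        (the patience absorbs isolated noisy slope estimates).
    """

    min_prominence: float = 10.0
    crossing_tol: float = 2.0
    return_tol: float = 5.0
    min_depth_bpm: float = 2.0
    horizon_s: float = 60.0
    shoulder_window_s: float = 60.0
    onset_delta_bpm: float = 2.0
    trend_window_s: float = 3.0
    trend_slope_bpm_s: float = 0.15
    trend_patience: int = 3


# ---------------------------------------------------------------------------
# UC cycles
# ---------------------------------------------------------------------------


def _plateau_peaks(x: np.ndarray) -> list[int]:
    """Indices of local maxima; equal-height plateaus collapse to their
    earliest sample ("higher than both neighbours" after plateau collapse)."""
    peaks = []
    n = len(x)
    i = 1
    while i < n - 1:
        if not np.isfinite(x[i]):
            i += 1
            continue
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j + 1 < n and np.isfinite(x[j + 1]) and x[j + 1] < x[i]:
                peaks.append(i)
            i = j + 1
        else:
            i += 1
    return peaks


def detect_uc_cycles(
    uc: Sequence[float],
    tone: float | Callable[[float], float],
    rate: float,
    cfg: DetectionConfig = DetectionConfig(),
    t0: float = 0.0,
) -> list[UCCycle]:
    """Detect contraction cycles on a smoothed UC channel.

    ``tone`` is the resting-tone level, either a constant or a callable of
    time (seconds).  A contraction peak is a sample strictly higher than
    its neighbours (plateaus collapse to their earliest sample) rising at
    least ``cfg.min_prominence`` above tone; UCs (UCe) is the nearest
    earlier (later) crossing of ``tone + cfg.crossing_tol``.  Adjacent
    candidate cycles that never dip back to the crossing level are split
    at the valley minimum between their peaks.  Cycles lacking a crossing
    on either side (trace-edge bells) are dropped.  ``t0`` offsets the
    reported times, for per-segment analysis.
    """
    x = np.asarray(uc, dtype=float)
    dt = 1.0 / rate
    tone_at = tone if callable(tone) else (lambda t, _v=float(tone): _v)

    cand = [
        i
        for i in _plateau_peaks(x)
        if x[i] >= tone_at(t0 + i * dt) + cfg.min_prominence
    ]
    if not cand:
        return []

    n = len(x)
    raw: list[list[int]] = []  # [ucs_idx, peak_idx, uce_idx]
    for p in cand:
        level = tone_at(t0 + p * dt) + cfg.crossing_tol
        s = p
        while s > 0 and np.isfinite(x[s - 1]) and x[s - 1] > level:
            s -= 1
        if s == 0 or not np.isfinite(x[s - 1]):
            continue  # trace-edge or gap-truncated bell: no earlier crossing
        e = p
        while e < n - 1 and np.isfinite(x[e + 1]) and x[e + 1] > level:
            e += 1
        if e == n - 1 or not np.isfinite(x[e + 1]):
            continue  # no later crossing
        s_idx, e_idx = s - 1, e + 1
        # refine from the crossing level down to the actual intersection
        # with the resting tone (the cycle start/end proper)
        while s_idx > 0 and np.isfinite(x[s_idx - 1]) and x[s_idx - 1] < x[s_idx]:
            s_idx -= 1
        while e_idx < n - 1 and np.isfinite(x[e_idx + 1]) and x[e_idx + 1] < x[e_idx]:
            e_idx += 1

        # neighbours that never dip to the crossing level between their
        # peaks share crossings; split the pair at the valley minimum
        if raw and s_idx <= raw[-1][2]:
            prev = raw[-1]
            valley = prev[1] + int(np.nanargmin(x[prev[1] : p + 1]))
            prev[2] = valley
            s_idx = valley
        if s_idx < p < e_idx:
            raw.append([s_idx, p, e_idx])

    cycles = []
    for s_idx, p, e_idx in raw:
        if not (s_idx < p < e_idx):
            continue
        cycles.append(
            UCCycle(
                ucs=KeyPoint(t0 + s_idx * dt, float(x[s_idx])),
                ucp=KeyPoint(t0 + p * dt, float(x[p])),
                uce=KeyPoint(t0 + e_idx * dt, float(x[e_idx])),
            )
        )
    return cycles


# ---------------------------------------------------------------------------
# Decelerations
# ---------------------------------------------------------------------------


def extract_decel(
    fhr: Sequence[float],
    cycle: UCCycle,
    b: float,
    rate: float,
    criteria: CriteriaSet = CriteriaSet(),
    cfg: DetectionConfig = DetectionConfig(),
    t0: float = 0.0,
) -> Optional[DecelEpisode]:
    """Extract the deceleration (if any) linked to one contraction cycle.

    Scanning forward from the cycle start within the search horizon
    (``uce.t + cfg.horizon_s``), the nadir HRp is the deepest smoothed
    FHR sample below baseline ``b``; HRs is found by walking back up the
    descent from the nadir (level-crossing at ``b - onset_delta_bpm``
    then a windowed-trend walk); HRe is the first return to within
    ``cfg.return_tol`` of ``b`` after the nadir (the last valid sample if
    recovery is truncated).  Returns ``None`` when the excursion depth is
    below ``cfg.min_depth_bpm``, when the deepest sample sits at the
    window start (a dip that began before the cycle), or when the search
    horizon extends past the end of the data.
    """
    x = np.asarray(fhr, dtype=float)
    dt = 1.0 / rate
    i0 = int(round((cycle.ucs.t - t0) * rate))
    i_end = int(round((cycle.uce.t + cfg.horizon_s - t0) * rate))
    if i0 < 0 or i_end >= len(x):
        return None  # search horizon exceeds the available data
    win = x[i0 : i_end + 1]
    if not np.isfinite(win).any():
        return None
    p = i0 + int(np.nanargmin(win))
    depth = b - x[p]
    if not depth >= cfg.min_depth_bpm:
        return None
    if p == i0:
        return None  # still recovering from a dip that started before UCs

    # --- HRs: two-stage backward walk from the nadir --------------------
    j = p
    onset_level = b - cfg.onset_delta_bpm
    while j > i0 and np.isfinite(x[j - 1]) and x[j - 1] < onset_level:
        j -= 1
    k = max(int(round(cfg.trend_window_s * rate)), 1)
    hrs_idx = j
    misses = 0
    while j > i0 and np.isfinite(x[j - 1]):
        ahead = min(j - 1 + k, p)
        if ahead <= j - 1:
            break
        slope = (x[ahead] - x[j - 1]) / ((ahead - (j - 1)) * dt)
        j -= 1
        if slope <= -cfg.trend_slope_bpm_s:
            hrs_idx = j
            misses = 0
        else:
            misses += 1
            if misses >= cfg.trend_patience:
                break

    # --- HRe: first return to within return_tol of baseline -------------
    e = p
    while e < len(x) - 1 and np.isfinite(x[e + 1]) and x[e + 1] < b - cfg.return_tol:
        e += 1
    if e < len(x) - 1 and np.isfinite(x[e + 1]):
        e += 1

    return DecelEpisode(
        hrs=KeyPoint(t0 + hrs_idx * dt, float(x[hrs_idx])),
        hrp=KeyPoint(t0 + p * dt, float(x[p])),
        hre=KeyPoint(t0 + e * dt, float(x[e])),
        b=float(b),
        cycle=cycle,
    )


def detect_shoulder(
    fhr: Sequence[float],
    episode: DecelEpisode,
    b: float,
    rate: float,
    cfg: DetectionConfig = DetectionConfig(),
    t0: float = 0.0,
) -> DecelEpisode:
    """Fill the episode's shoulder region if an overshoot follows recovery.

    Searches ``[hre.t, hre.t + cfg.shoulder_window_s]`` for the highest
    smoothed sample strictly above baseline; if found, HSp is that peak
    and HSe the first subsequent return to within ``cfg.return_tol`` of
    baseline.  Otherwise the episode is returned with no shoulder.
    """
    x = np.asarray(fhr, dtype=float)
    dt = 1.0 / rate
    s = int(round((episode.hre.t - t0) * rate))
    e = min(int(round((episode.hre.t + cfg.shoulder_window_s - t0) * rate)), len(x) - 1)
    if s < 0 or s > e:
        return episode
    win = x[s : e + 1]
    if not np.isfinite(win).any():
        return episode
    p = s + int(np.nanargmax(win))
    if not x[p] > b:
        return episode
    j = p
    while j < len(x) - 1 and np.isfinite(x[j + 1]) and x[j + 1] > b + cfg.return_tol:
        j += 1
    if j < len(x) - 1 and np.isfinite(x[j + 1]):
        j += 1
    return replace(
        episode,
        shoulder=Shoulder(
            hsp=KeyPoint(t0 + p * dt, float(x[p])),
            hse=KeyPoint(t0 + j * dt, float(x[j])),
        ),
    )


# ---------------------------------------------------------------------------
# Sustained high/low rate
# ---------------------------------------------------------------------------


def detect_sustained(
    fhr: Sequence[float],
    rate: float,
    criteria: CriteriaSet = CriteriaSet(),
    t0: float = 0.0,
) -> list[SustainedRateEpisode]:
    """Maximal sample runs at/beyond the tachycardia or bradycardia level.

    A run of ``n`` consecutive samples >= ``criteria.tachy_bpm`` (kind
    "high") or <= ``criteria.brady_bpm`` (kind "low") becomes an episode
    when its duration ``n / rate`` reaches ``criteria.sustained_min_s``.
    Missing samples break runs; runs across a gap never merge.
    """
    x = np.asarray(fhr, dtype=float)
    dt = 1.0 / rate
    out: list[SustainedRateEpisode] = []
    with np.errstate(invalid="ignore"):
        masks = (
            ("high", np.isfinite(x) & (x >= criteria.tachy_bpm)),
            ("low", np.isfinite(x) & (x <= criteria.brady_bpm)),
        )
    from .preprocess import _runs

    for kind, mask in masks:
        for s, e in _runs(mask):
            n = e - s
            if n * dt >= criteria.sustained_min_s:
                seg = x[s:e]
                extreme = float(seg.max() if kind == "high" else seg.min())
                out.append(
                    SustainedRateEpisode(
                        start=t0 + s * dt, end=t0 + e * dt, kind=kind, extreme_v=extreme
                    )
                )
    out.sort(key=lambda ep: ep.start)
    return out
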