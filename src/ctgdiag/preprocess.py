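"""Cleaning, smoothing and baseline estimation for CTG traces.

Raw telemetered CTG data carry transducer dropouts (runs of held or zero
readings), physiologically impossible values and gaps.  The cleaning stage
marks those invalid, bridges short gaps by linear interpolation and leaves
long gaps missing so that downstream detection runs per contiguous
analysis segment.

Both channels are smoothed with a centered, NaN-aware moving average
before any key-point detection; the fetal heart rate baseline ``B`` — the
level an obstetrician reads "between" accelerations and decelerations —
is a trimmed median per 10-minute window, and the uterine resting tone is
the per-window 10th percentile of the contraction channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError
from .trace_io import CTGTrace


@dataclass(frozen=True)
class CleanConfig:
    """Cleaning and smoothing parameters.

    fhr_valid_range
        Physiologically plausible FHR band in bpm; samples outside it
        (including 0-bpm dropout sentinels) are invalid.
    max_gap_s
        Longest run of missing/invalid samples bridged by linear
        interpolation; longer runs stay missing and split the trace into
        analysis segments.
    smooth_window_s
        Length of the centered moving-average window, seconds.
    dup_run_samples
        An exact consecutive-duplicate FHR run longer than this many
        samples is treated as a stuck transducer and marked invalid
        (real FHR always carries beat-to-beat variability); ``None``
        disables the heuristic.
    """

    fhr_valid_range: tuple[float, float] = (50.0, 240.0)
    max_gap_s: float = 15.0
    smooth_window_s: float = 5.0
    dup_run_samples: int | None = 10

    def __post_init__(self) -> None:
        lo, hi = self.fhr_valid_range
        if not lo < hi:
            raise ValueError(f"fhr_valid_range low must be < high, got {self.fhr_valid_range}")
        if self.max_gap_s < 0:
            raise ValueError("max_gap_s must be >= 0")
        if not self.smooth_window_s > 0:
            raise ValueError("smooth_window_s must be > 0")


@dataclass(frozen=True)
class BaselineEstimate:
    """Baseline levels over one analysis window.

    ``b`` is the FHR baseline in bpm (rounded to the nearest 1 bpm, as
    read clinically); ``uc_tone`` the uterine resting tone in relative
    units; ``window`` the ``(start_s, end_s)`` interval covered.
    """

    b: float
    uc_tone: float
    window: tuple[float, float]


def _runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of maximal True runs (stop exclusive)."""
    if not mask.any():
        return
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for s, e in zip(edges[::2], edges[1::2]):
        yield int(s), int(e)


def clean(trace: CTGTrace, cfg: CleanConfig = CleanConfig()) -> CTGTrace:
    """Mark invalid samples, bridge short gaps, leave long gaps missing.

    Out-of-range FHR samples and exact consecutive-duplicate FHR runs
    longer than ``cfg.dup_run_samples`` become invalid (NaN); invalid or
    missing runs no longer than ``cfg.max_gap_s`` on either channel are
    then linearly interpolated from their valid neighbours.  Longer runs
    remain missing; :func:`analysis_segments` enumerates the contiguous
    valid stretches they delimit.
    """
    if len(trace) == 0:
        raise DegenerateInputError("empty trace")
    fhr = trace.fhr.copy()
    uc = trace.uc.copy()

    lo, hi = cfg.fhr_valid_range
    with np.errstate(invalid="ignore"):
        fhr[(fhr < lo) | (fhr > hi)] = np.nan

    if cfg.dup_run_samples is not None and len(fhr) > 1:
        same = np.concatenate(([False], fhr[1:] == fhr[:-1]))  # NaN != NaN, so gaps break runs
        for s, e in _runs(same):
            if (e - s) + 1 > cfg.dup_run_samples:  # run length includes the anchor sample
                fhr[s - 1 : e] = np.nan

    if np.isfinite(fhr).sum() < 2:
        raise DegenerateInputError("fewer than 2 valid FHR samples after cleaning")

    max_gap = int(round(cfg.max_gap_s * trace.rate))
    fhr = _bridge(fhr, max_gap)
    uc = _bridge(uc, max_gap)
    return CTGTrace(fhr, uc, rate=trace.rate, label=trace.label)


def _bridge(x: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate interior NaN runs of length <= max_gap."""
    x = x.copy()
    bad = ~np.isfinite(x)
    for s, e in _runs(bad):
        n = e - s
        if n > max_gap or s == 0 or e == len(x):
            continue  # too long, or no neighbour on one side
        x[s:e] = np.interp(np.arange(s, e), [s - 1, e], [x[s - 1], x[e]])
    return x


def analysis_segments(x: np.ndarray, min_len: int = 2) -> list[tuple[int, int]]:
    """Contiguous runs of finite samples, as (start, stop) index pairs."""
    return [(s, e) for s, e in _runs(np.isfinite(np.asarray(x, float))) if e - s >= min_len]


def smooth(series: Sequence[float], rate: float, window_s: float) -> np.ndarray:
    """Centered moving average, NaN-aware, length-preserving.

    The window spans ``round(window_s * rate)`` samples, forced odd by
    adding one if even.  Missing samples are excluded from each window's
    mean; positions that are missing in the input stay missing in the
    output (smoothing must not invent data across gaps).  Windows are
    truncated at the series edges.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise DegenerateInputError("cannot smooth an empty series")
    if not window_s > 0:
        raise ValueError("window_s must be > 0")
    w = int(round(window_s * rate))
    w = max(w, 1)
    if w % 2 == 0:
        w += 1
    half = w // 2
    valid = np.isfinite(x)
    vals = np.where(valid, x, 0.0)
    idx = np.arange(x.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, x.size)
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    ccnt = np.concatenate(([0], np.cumsum(valid)))
    sums = csum[hi] - csum[lo]
    counts = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    out[~valid] = np.nan
    return out


def _windows(n: int, rate: float, window_s: float) -> list[tuple[int, int]]:
    """Tile [0, n) into consecutive windows of window_s seconds (last partial)."""
    w = max(int(round(window_s * rate)), 1)
    return [(s, min(s + w, n)) for s in range(0, n, w)]


def estimate_baseline(
    trace: CTGTrace,
    window_s: float = 600.0,
    cfg: CleanConfig = CleanConfig(),
    min_window_s: float = 60.0,
) -> list[BaselineEstimate]:
    """Per-window FHR baseline B and UC resting tone for a cleaned trace.

    The trace is tiled into consecutive ``window_s`` windows.  Within each,
    the FHR channel is smoothed and B is the median of the samples lying
    between the window's 10th and 90th percentiles — the trim discards
    deceleration nadirs and acceleration peaks, mimicking a clinician
    reading the level between excursions — rounded to the nearest 1 bpm.
    The uterine resting tone is the 10th percentile of the smoothed UC
    channel.  Windows shorter than ``min_window_s`` or without valid
    samples reuse the nearest window's estimate.
    """
    fhr_s = smooth(trace.fhr, trace.rate, cfg.smooth_window_s)
    uc_s = smooth(trace.uc, trace.rate, cfg.smooth_window_s)
    spans = _windows(len(trace), trace.rate, window_s)
    min_n = min_window_s * trace.rate

    b_vals: list[float | None] = []
    tone_vals: list[float | None] = []
    for s, e in spans:
        if e - s < min_n:
            b_vals.append(None)
            tone_vals.append(None)
            continue
        b_vals.append(_trimmed_median(fhr_s[s:e]))
        tone_vals.append(_low_percentile(uc_s[s:e]))

    if all(v is None for v in b_vals):
        # single short trace: estimate over everything we have
        b_all = _trimmed_median(fhr_s)
        tone_all = _low_percentile(uc_s)
        if b_all is None:
            raise DegenerateInputError("no valid FHR samples in any baseline window")
        b_vals = [b_all] * len(spans)
        tone_vals = [tone_all if tone_all is not None else 0.0] * len(spans)

    b_filled = _fill_nearest(b_vals)
    tone_filled = _fill_nearest(tone_vals)
    if any(v is None for v in b_filled):
        raise DegenerateInputError("no valid FHR samples in any baseline window")

    out = []
    for (s, e), b, tone in zip(spans, b_filled, tone_filled):
        out.append(
            BaselineEstimate(
                b=float(round(b)),
                uc_tone=float(tone) if tone is not None else 0.0,
                window=(s / trace.rate, e / trace.rate),
            )
        )
    return out


def _trimmed_median(x: np.ndarray) -> float | None:
    v = x[np.isfinite(x)]
    if v.size == 0:
        return None
    q10, q90 = np.percentile(v, [10, 90])
    core = v[(v >= q10) & (v <= q90)]
    if core.size == 0:
        core = v
    return float(np.median(core))


def _low_percentile(x: np.ndarray) -> float | None:
    v = x[np.isfinite(x)]
    if v.size == 0:
        return None
    return float(np.percentile(v, 10))


def _fill_nearest(vals: list) -> list:
    """Replace None entries by the value of the nearest non-None window."""
    idx = [i for i, v in enumerate(vals) if v is not None]
    if not idx:
        return vals
    out = list(vals)
    for i, v in enumerate(vals):
        if v is None:
            j = min(idx, key=lambda k: (abs(k - i), k))
            out[i] = vals[j]
    return out


def estimate_fhr_baseline(
    trace: CTGTrace, window_s: float = 600.0, cfg: CleanConfig = CleanConfig()
) -> list[BaselineEstimate]:
    """FHR baseline per window; see :func:`estimate_baseline`."""
    return estimate_baseline(trace, window_s=window_s, cfg=cfg)


def estimate_uc_tone(
    trace: CTGTrace, window_s: float = 600.0, cfg: CleanConfig = CleanConfig()
) -> list[tuple[tuple[float, float], float]]:
    """UC resting tone per window, as (window, tone) pairs."""
    return [(est.window, est.uc_tone) for est in estimate_baseline(trace, window_s, cfg)]


def baseline_at(estimates: list[BaselineEstimate], t: float) -> BaselineEstimate:
    """The estimate whose window contains time ``t`` (nearest if outside)."""
    if not estimates:
        raise DegenerateInputError("no baseline estimates")
    for est in estimates:
        if est.window[0] <= t < est.window[1]:
            return est
    return min(estimates, key=lambda e: min(abs(t - e.window[0]), abs(t - e.window[1])))
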