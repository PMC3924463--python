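import numpy as np
import pytest

from ctgdiag import (
    CriteriaSet,
    DetectionConfig,
    EarlyDecelEvent,
    SynthSpec,
    UCBell,
    detect_shoulder,
    detect_sustained,
    detect_uc_cycles,
    extract_decel,
    generate_trace,
    run_diagnosis,
)
from ctgdiag.keypoints import UCCycle, KeyPoint


def bell(t, onset, dur, amp, tone=5.0):
    out = np.full_like(t, tone)
    inside = (t >= onset) & (t <= onset + dur)
    out[inside] += amp * 0.5 * (1 - np.cos(2 * np.pi * (t[inside] - onset) / dur))
    return out


class TestUCCycles:
    def test_single_bell_keypoints(self):
        t = np.arange(1200) / 2.0
        uc = bell(t, 200, 80, 60)
        (cycle,) = detect_uc_cycles(uc, tone=5.0, rate=2.0)
        assert cycle.ucs.t == pytest.approx(200, abs=0.5)
        assert cycle.ucp.t == pytest.approx(240, abs=0.5)
        assert cycle.ucp.v == pytest.approx(65, abs=0.5)
        assert cycle.uce.t == pytest.approx(280, abs=0.5)

    def test_constant_uc_no_cycles(self):
        assert detect_uc_cycles(np.full(600, 5.0), tone=5.0, rate=2.0) == []

    def test_low_prominence_bump_ignored(self):
        t = np.arange(1200) / 2.0
        uc = bell(t, 200, 80, 8)  # below min_prominence 10
        assert detect_uc_cycles(uc, tone=5.0, rate=2.0) == []

    def test_two_separated_bells(self):
        t = np.arange(2400) / 2.0
        uc = bell(t, 200, 80, 60) + bell(t, 500, 70, 50) - 5.0
        c1, c2 = detect_uc_cycles(uc, tone=5.0, rate=2.0)
        assert c1.uce.t <= c2.ucs.t
        assert c1.ucp.t == pytest.approx(240, abs=0.5)
        assert c2.ucp.t == pytest.approx(535, abs=0.5)

    def test_merged_bells_split_at_valley(self):
        # two bells overlapping so the trough never returns to tone
        t = np.arange(1600) / 2.0
        uc = bell(t, 200, 100, 60) + bell(t, 270, 100, 55) - 5.0
        cycles = detect_uc_cycles(uc, tone=5.0, rate=2.0)
        assert len(cycles) == 2
        c1, c2 = cycles
        assert c1.uce.t == c2.ucs.t  # shared valley split
        assert c1.ucs.t < c1.ucp.t < c1.uce.t < c2.ucp.t < c2.uce.t

    def test_edge_bell_without_crossing_dropped(self):
        t = np.arange(400) / 2.0
        uc = bell(t, -20, 80, 60)  # rises before the trace starts
        assert detect_uc_cycles(uc, tone=5.0, rate=2.0) == []

    def test_translation_equivariance(self):
        t = np.arange(2000) / 2.0
        uc = bell(t, 300, 80, 60)
        shift = 101  # samples
        (c0,) = detect_uc_cycles(uc, tone=5.0, rate=2.0)
        (c1,) = detect_uc_cycles(np.concatenate([np.full(shift, 5.0), uc[:-shift]]), 5.0, 2.0)
        for name in ("ucs", "ucp", "uce"):
            assert getattr(c1, name).t == pytest.approx(getattr(c0, name).t + shift / 2.0)


def early_spec(**kw):
    params = dict(duration_s=900.0, baseline_bpm=140.0, seed=11)
    params.update(kw)
    return SynthSpec(
        uc=[UCBell(onset_s=300.0, duration_s=80.0, amplitude=55.0)],
        events=[EarlyDecelEvent(cycle=0, depth_bpm=45.0, fall_s=45.0, lag_s=14.0)],
        **params,
    )


class TestExtractDecel:
    def test_early_pattern_matches_injected_truth(self):
        trace, truth = generate_trace(early_spec())
        report = run_diagnosis(trace)
        (d,) = report.decels
        kp = truth.events[0].keypoints
        assert d.episode.hrs.t == pytest.approx(kp["hrs"][0], abs=1.0)
        assert d.episode.hrp.t == pytest.approx(kp["hrp"][0], abs=1.0)
        assert d.episode.hrp.v == pytest.approx(kp["hrp"][1], abs=2.0)

    def test_nadir_is_window_minimum(self):
        trace, _ = generate_trace(early_spec())
        report = run_diagnosis(trace)
        (d,) = report.decels
        e = d.episode
        # scan check: no smoothed sample between hrs and hre is lower
        from ctgdiag import clean, smooth

        cleaned = clean(trace)
        fhr_s = smooth(cleaned.fhr, 2.0, 5.0)
        i0, i1 = int(e.hrs.t * 2), int(e.hre.t * 2) + 1
        assert e.hrp.v <= np.nanmin(fhr_s[i0:i1]) + 1e-9

    def test_flat_fhr_yields_nothing(self):
        t = np.arange(1800) / 2.0
        fhr = np.full_like(t, 140.0)
        cycle = UCCycle(KeyPoint(300.0, 5.0), KeyPoint(340.0, 60.0), KeyPoint(380.0, 5.0))
        assert extract_decel(fhr, cycle, b=140.0, rate=2.0) is None

    def test_dip_before_cycle_start_yields_nothing(self):
        t = np.arange(1800) / 2.0
        fhr = np.full_like(t, 140.0)
        dip = (t >= 200) & (t <= 290)  # entirely before ucs at 300
        fhr[dip] -= 40 * 0.5 * (1 - np.cos(2 * np.pi * (t[dip] - 200) / 90))
        cycle = UCCycle(KeyPoint(300.0, 5.0), KeyPoint(340.0, 60.0), KeyPoint(380.0, 5.0))
        assert extract_decel(fhr, cycle, b=140.0, rate=2.0) is None

    def test_horizon_past_trace_end_yields_nothing(self):
        t = np.arange(800) / 2.0  # 400 s; horizon 380 + 60 > 400
        fhr = np.full_like(t, 140.0)
        cycle = UCCycle(KeyPoint(300.0, 5.0), KeyPoint(340.0, 60.0), KeyPoint(380.0, 5.0))
        assert extract_decel(fhr, cycle, b=140.0, rate=2.0) is None


class TestShoulder:
    @staticmethod
    def episode_with_recovery():
        t = np.arange(1800) / 2.0
        fhr = np.full_like(t, 140.0)
        dip = (t >= 310) & (t <= 350)
        fhr[dip] -= 40 * 0.5 * (1 - np.cos(2 * np.pi * (t[dip] - 310) / 40))
        cycle = UCCycle(KeyPoint(300.0, 5.0), KeyPoint(340.0, 60.0), KeyPoint(380.0, 5.0))
        return t, fhr, cycle

    def test_overshoot_detected(self):
        t, fhr, cycle = self.episode_with_recovery()
        bump = (t >= 350) & (t <= 365)
        fhr[bump] += 12 * 0.5 * (1 - np.cos(2 * np.pi * (t[bump] - 350) / 15))
        ep = extract_decel(fhr, cycle, b=140.0, rate=2.0)
        ep = detect_shoulder(fhr, ep, b=140.0, rate=2.0)
        assert ep.shoulder is not None
        assert ep.shoulder.hsp.v - 140.0 == pytest.approx(12, abs=1.0)
        assert ep.shoulder.hsp.t >= ep.hre.t

    def test_no_overshoot_no_shoulder(self):
        t, fhr, cycle = self.episode_with_recovery()
        ep = extract_decel(fhr, cycle, b=140.0, rate=2.0)
        ep = detect_shoulder(fhr, ep, b=140.0, rate=2.0)
        assert ep.shoulder is None

    def test_overshoot_outside_window_ignored(self):
        t, fhr, cycle = self.episode_with_recovery()
        bump = (t >= 460) & (t <= 475)  # ~110 s after recovery > 60-s window
        fhr[bump] += 12 * 0.5 * (1 - np.cos(2 * np.pi * (t[bump] - 460) / 15))
        ep = extract_decel(fhr, cycle, b=140.0, rate=2.0)
        ep = detect_shoulder(fhr, ep, b=140.0, rate=2.0)
        assert ep.shoulder is None


def brute_force_sustained(fhr, rate, criteria):
    """Independent run-length oracle: walk every sample, accumulate maximal
    runs beyond each threshold, keep those lasting >= sustained_min_s."""
    out = []
    for kind, ok in (
        ("high", lambda v: np.isfinite(v) and v >= criteria.tachy_bpm),
        ("low", lambda v: np.isfinite(v) and v <= criteria.brady_bpm),
    ):
        run = []
        for i, v in enumerate(list(fhr) + [np.nan]):
            if ok(v):
                run.append(i)
            else:
                if run and len(run) / rate >= criteria.sustained_min_s:
                    out.append((kind, run[0], run[-1] + 1))
                run = []
    return sorted(out, key=lambda r: r[1])


class TestSustained:
    def test_long_high_run_detected(self, criteria):
        fhr = np.full(1000, 140.0)
        fhr[200:600] = 165.0  # 200 s >= 180 s
        (ep,) = detect_sustained(fhr, 2.0, criteria)
        assert ep.kind == "high"
        assert ep.duration_s == pytest.approx(200.0)
        assert ep.extreme_v == 165.0

    def test_short_run_ignored(self, criteria):
        fhr = np.full(1000, 140.0)
        fhr[200:400] = 165.0  # 100 s < 180 s
        assert detect_sustained(fhr, 2.0, criteria) == []

    def test_gap_does_not_merge_runs(self, criteria):
        fhr = np.full(1200, 165.0)
        fhr[500:510] = np.nan
        eps = detect_sustained(fhr, 2.0, criteria)
        assert [e.kind for e in eps] == ["high", "high"]

    def test_matches_brute_force_on_random_traces(self, criteria):
        rng = np.random.default_rng(99)
        for _ in range(60):
            fhr = rng.choice(
                [100.0, 112.0, 140.0, 158.0, 170.0, np.nan],
                size=1200,
                p=[0.25, 0.1, 0.25, 0.1, 0.25, 0.05],
            )
            # stretch into runs so episodes actually occur
            fhr = np.repeat(fhr[: 1200 // 4], 4)
            got = [
                (e.kind, int(e.start * 2), int(e.end * 2))
                for e in detect_sustained(fhr, 2.0, criteria)
            ]
            assert got == brute_force_sustained(fhr, 2.0, criteria)
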