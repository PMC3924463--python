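import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctgdiag import CriteriaSet, Symptom, classify_decel, classify_sustained, samples_to_seconds
from ctgdiag.keypoints import SustainedRateEpisode

from conftest import make_episode


def labels_of(episode, criteria):
    return {lab.symptom for lab in classify_decel(episode, criteria)}


class TestSamplesToSeconds:
    @pytest.mark.parametrize("n,rate,expected", [(90, 2, 45.0), (0, 2, 0.0), (10, 2, 5.0)])
    def test_conversion(self, n, rate, expected):
        assert samples_to_seconds(n, rate) == expected

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            samples_to_seconds(10, 0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            samples_to_seconds(-1, 2)


class TestClassifyDecel:
    def test_worked_early_example(self, criteria):
        # nadir before contraction end, 45-s gradual fall, 5-s lag after
        # contraction onset, 45-bpm depth, no shoulder
        e = make_episode(ucs_t=100, uce_t=200, hrs_t=105, fall_s=45, depth=45)
        labels = classify_decel(e, criteria)
        assert {lab.symptom for lab in labels} == {Symptom.EARLY_DECELERATION}
        # and each alternative fails for its stated reason:
        assert e.hrp.t < e.cycle.uce.t          # so Late's first rule fails
        assert e.hrp.t - e.hrs.t > 30           # so Variable A's first rule fails
        assert e.shoulder is None               # so Variable B fails

    def test_late_pattern(self, criteria):
        e = make_episode(ucs_t=100, uce_t=140, hrs_t=106, fall_s=45, depth=20)
        # nadir at 151 >= uce 140
        assert Symptom.LATE_DECELERATION in labels_of(e, criteria)

    def test_variable_a_pattern(self, criteria):
        e = make_episode(ucs_t=100, uce_t=200, hrs_t=106, fall_s=20, depth=20)
        assert labels_of(e, criteria) == {Symptom.VARIABLE_DECELERATION_A}

    def test_variable_b_pattern(self, criteria):
        e = make_episode(
            ucs_t=100, uce_t=200, hrs_t=106, fall_s=20, depth=20,
            shoulder_height=12, shoulder_lag=15,
        )
        assert Symptom.VARIABLE_DECELERATION_B in labels_of(e, criteria)

    def test_boundary_fall_time_fires_both_early_and_variable_a(self, criteria):
        # inclusive comparisons: fall exactly 30 s satisfies >= 30 and <= 30
        e = make_episode(ucs_t=100, uce_t=200, hrs_t=106, fall_s=30, depth=20)
        assert labels_of(e, criteria) == {
            Symptom.EARLY_DECELERATION,
            Symptom.VARIABLE_DECELERATION_A,
        }

    def test_missing_cycle_rejected(self, criteria):
        e = make_episode()
        e = type(e)(hrs=e.hrs, hrp=e.hrp, hre=e.hre, b=e.b, cycle=None)
        with pytest.raises(ValueError):
            classify_decel(e, criteria)

    def test_satisfied_rules_nonempty_and_named(self, criteria):
        e = make_episode(ucs_t=100, uce_t=200, hrs_t=105, fall_s=45, depth=45)
        (label,) = classify_decel(e, criteria)
        assert len(label.satisfied_rules) == 4
        assert all(r.startswith("early.") for r in label.satisfied_rules)


def truth_table_episodes():
    """Exhaustive grid over the sign combinations of the six inequalities.

    Factors: nadir before/after contraction end; fall time >= / < 30 s;
    onset lag >= / < 5 s; depth >= / < 15 bpm; shoulder height >= / < 10;
    shoulder persistence >= / < 10 s; plus the shoulder-absent half-grid.
    """
    cases = []
    for before, gradual, lagged, deep, sh in itertools.product(
        [True, False], [True, False], [True, False], [True, False],
        [None, (True, True), (True, False), (False, True), (False, False)],
    ):
        fall = 45.0 if gradual else 20.0
        hrs_t = 106.0 if lagged else 102.0
        # place uce around the nadir according to the before/after factor
        nadir_t = hrs_t + fall
        uce_t = nadir_t + 10 if before else nadir_t - 5
        kw = dict(
            ucs_t=100.0,
            uce_t=uce_t,
            hrs_t=hrs_t,
            fall_s=fall,
            depth=20.0 if deep else 8.0,
        )
        if sh is not None:
            kw["shoulder_height"] = 12.0 if sh[0] else 4.0
            kw["shoulder_lag"] = 15.0 if sh[1] else 3.0
        cases.append((before, gradual, lagged, deep, sh, make_episode(**kw)))
    return cases


class TestTruthTable:
    def test_agrees_with_direct_inequality_evaluation(self, criteria):
        n = 0
        for before, gradual, lagged, deep, sh, e in truth_table_episodes():
            expected = set()
            if before and gradual and lagged and deep:
                expected.add(Symptom.EARLY_DECELERATION)
            if (not before) and gradual and deep:
                expected.add(Symptom.LATE_DECELERATION)
            if (not gradual) and lagged and deep:
                expected.add(Symptom.VARIABLE_DECELERATION_A)
            if sh is not None and lagged and deep and sh[0] and sh[1]:
                expected.add(Symptom.VARIABLE_DECELERATION_B)
            assert labels_of(e, criteria) == expected, (before, gradual, lagged, deep, sh)
            n += 1
        assert n == 80


episode_strategy = st.builds(
    make_episode,
    ucs_t=st.just(100.0),
    uce_t=st.floats(min_value=130, max_value=260),
    hrs_t=st.floats(min_value=100, max_value=125),
    fall_s=st.floats(min_value=5, max_value=60),
    depth=st.floats(min_value=2, max_value=60),
    shoulder_height=st.one_of(st.none(), st.floats(min_value=1, max_value=25)),
    shoulder_lag=st.floats(min_value=1, max_value=30),
)


class TestRuleProperties:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(episode_strategy)
    def test_early_late_mutually_exclusive(self, e):
        got = labels_of(e, CriteriaSet())
        assert not (
            Symptom.EARLY_DECELERATION in got and Symptom.LATE_DECELERATION in got
        )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(episode_strategy, st.floats(min_value=1, max_value=14))
    def test_lower_depth_threshold_never_removes_labels(self, e, smaller_depth):
        base = labels_of(e, CriteriaSet())
        relaxed = labels_of(e, CriteriaSet(depth_bpm=smaller_depth))
        assert base <= relaxed

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(episode_strategy, st.floats(min_value=31, max_value=90))
    def test_longer_fall_threshold_never_adds_early_or_late(self, e, longer_fall):
        base = labels_of(e, CriteriaSet())
        stricter = labels_of(e, CriteriaSet(fall_time_s=longer_fall))
        for sym in (Symptom.EARLY_DECELERATION, Symptom.LATE_DECELERATION):
            assert sym not in stricter - base

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(episode_strategy)
    def test_deterministic(self, e):
        c = CriteriaSet()
        assert classify_decel(e, c) == classify_decel(e, c)


class TestClassifySustained:
    def test_high_is_tachycardia(self, criteria):
        ep = SustainedRateEpisode(start=0.0, end=200.0, kind="high", extreme_v=170.0)
        assert classify_sustained(ep, criteria).symptom == Symptom.TACHYCARDIA

    def test_low_is_bradycardia(self, criteria):
        ep = SustainedRateEpisode(start=0.0, end=185.0, kind="low", extreme_v=100.0)
        assert classify_sustained(ep, criteria).symptom == Symptom.BRADYCARDIA
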