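"""Funnel-test classification, consensus rules and sample reduction."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emlenkit import (
    FunnelTest,
    ObserverCall,
    angular_difference,
    classify_test,
    correct_alignment,
    group_sample,
    individual_mean,
    normalize_angle,
    read_tests_tsv,
)
from emlenkit.orientation import IndividualSummary, reduce_tests
from emlenkit.orientation import TestOutcome as Outcome

finite_angles = st.floats(
    min_value=-720, max_value=720, allow_nan=False, allow_infinity=False
)


def make_test(mark_count=50, c1=None, c2=None, alignment=0.0, **kw):
    def call(c):
        if c is None:
            return ObserverCall(random=True)
        return ObserverCall(random=False, direction=c)

    return FunnelTest(
        bird_id=kw.get("bird_id", "b1"),
        treatment=kw.get("treatment", "control"),
        night=kw.get("night", "2019-09-12"),
        mark_count=mark_count,
        call_1=call(c1),
        call_2=call(c2),
        funnel_alignment=alignment,
    )


@pytest.mark.parametrize(
    "raw, expected",
    [(370, 10), (-90, 270), (360, 0), (0, 0), (719.5, 359.5)],
)
def test_normalize_angle(raw, expected):
    assert normalize_angle(raw) == pytest.approx(expected)


def test_normalize_rejects_nonfinite():
    with pytest.raises(ValueError):
        normalize_angle(float("nan"))


@pytest.mark.parametrize(
    "a, b, expected", [(10, 50, 40), (350, 10, 20), (0, 180, 180), (90, 90, 0)]
)
def test_angular_difference(a, b, expected):
    assert angular_difference(a, b) == pytest.approx(expected)
    assert angular_difference(b, a) == pytest.approx(expected)


@pytest.mark.parametrize(
    "assessed, alignment, expected",
    [(100, 0, 100), (100, 180, 280), (350, 180, 170)],
)
def test_correct_alignment(assessed, alignment, expected):
    assert correct_alignment(assessed, alignment) == pytest.approx(expected)


@settings(max_examples=200, deadline=None)
@given(a=finite_angles, d=finite_angles)
def test_alignment_correction_is_invertible(a, d):
    back = correct_alignment(correct_alignment(a, d), -d)
    assert angular_difference(back, a) < 1e-9


class TestClassification:
    def test_below_activity_threshold_is_inactive(self):
        out = classify_test(make_test(mark_count=34, c1=10, c2=20))
        assert out.status == "inactive"
        assert out.reason == "below_activity_threshold"

    def test_disagreement_over_30_degrees_discards(self):
        out = classify_test(make_test(c1=10, c2=50))
        assert out.status == "not_oriented"
        assert out.reason == "observer_disagreement"

    def test_exactly_30_degrees_is_kept(self):
        out = classify_test(make_test(c1=10, c2=40))
        assert out.status == "oriented"
        assert out.direction == pytest.approx(25.0)

    def test_consensus_wraps_across_north(self):
        out = classify_test(make_test(c1=350, c2=10))
        assert out.status == "oriented"
        assert out.direction == pytest.approx(0.0, abs=1e-9)

    def test_both_random_discards(self):
        out = classify_test(make_test())
        assert out.status == "not_oriented"
        assert out.reason == "both_random"

    def test_one_random_discards_conservatively(self):
        out = classify_test(make_test(c1=100))
        assert out.status == "not_oriented"
        assert out.reason == "one_random"

    def test_alignment_is_applied_to_consensus(self):
        # raw calls near 100° in a South-aligned funnel -> true ~280°
        out = classify_test(make_test(c1=90, c2=110, alignment=180))
        assert out.status == "oriented"
        assert out.direction == pytest.approx(280.0)

    @settings(max_examples=100, deadline=None)
    @given(
        delta=finite_angles,
        c1=st.floats(min_value=0, max_value=359.9),
        gap=st.floats(min_value=-29, max_value=29),
    )
    def test_rotation_equivariance(self, delta, c1, gap):
        base = classify_test(make_test(c1=c1, c2=c1 + gap))
        rot = classify_test(
            make_test(c1=normalize_angle(c1 + delta), c2=normalize_angle(c1 + gap + delta))
        )
        assert base.status == rot.status == "oriented"
        assert angular_difference(
            normalize_angle(base.direction + delta), rot.direction
        ) < 1e-6


def test_status_partition_is_exhaustive():
    import numpy as np

    rng = np.random.default_rng(7)
    tests = []
    for i in range(200):
        c1 = None if rng.uniform() < 0.2 else float(rng.uniform(0, 360))
        c2 = None if rng.uniform() < 0.2 else float(rng.uniform(0, 360))
        tests.append(
            make_test(mark_count=int(rng.integers(0, 200)), c1=c1, c2=c2,
                      bird_id=f"b{i % 10}")
        )
    outcomes, _, _ = reduce_tests(tests)
    statuses = {o.status for o in outcomes}
    assert statuses <= {"oriented", "not_oriented", "inactive"}
    assert len(outcomes) == len(tests)


class TestIndividualAndGroup:
    def outcomes(self, directions):
        return [
            Outcome(bird_id="b1", treatment="control", night=f"n{i}",
                        status="oriented", direction=d)
            for i, d in enumerate(directions)
        ]

    def test_single_oriented_test_excludes_bird(self):
        s = individual_mean("b1", "control", self.outcomes([150]))
        assert s.n_oriented == 1 and not s.included

    def test_symmetric_pair_mean(self):
        s = individual_mean("b1", "control", self.outcomes([140, 160]))
        assert s.included
        assert s.mean_direction == pytest.approx(150.0)

    def test_vector_sum_oracle(self):
        # independent hand computation of the resultant of 10,20,30,40
        angs = [10, 20, 30, 40]
        C = sum(math.cos(math.radians(a)) for a in angs)
        S = sum(math.sin(math.radians(a)) for a in angs)
        expected = math.degrees(math.atan2(S, C)) % 360
        s = individual_mean("b1", "control", self.outcomes(angs))
        assert s.mean_direction == pytest.approx(expected)
        assert s.mean_direction == pytest.approx(25.0, abs=1e-6)

    def test_no_oriented_tests(self):
        s = individual_mean("b1", "control", [])
        assert not s.included and s.mean_direction is None

    def test_group_sample_filters_excluded(self):
        summaries = [
            IndividualSummary("b1", "control", 2, 150.0, 0.9, True),
            IndividualSummary("b2", "control", 3, 160.0, 0.8, True),
            IndividualSummary("b3", "control", 2, 140.0, 0.9, True),
            IndividualSummary("b4", "control", 1, 10.0, 1.0, False),
            IndividualSummary("b5", "control", 0, None, None, False),
        ]
        g = group_sample(summaries, "control")
        assert g.n == 3
        assert sorted(g.directions) == [140.0, 150.0, 160.0]

    def test_all_excluded_raises(self):
        summaries = [IndividualSummary("b1", "control", 1, 10.0, 1.0, False)]
        with pytest.raises(ValueError, match="no analyzable birds"):
            group_sample(summaries, "control")


def test_read_tests_tsv_missing_column(tmp_path):
    p = tmp_path / "tests.tsv"
    p.write_text("bird_id\ttreatment\nb1\tcontrol\n")
    with pytest.raises(ValueError, match="housing_group"):
        read_tests_tsv(p)


def test_read_tests_tsv_roundtrip(tmp_path):
    from emlenkit import SimConfig, simulate_experiment

    ds = simulate_experiment(SimConfig(seed=3))
    ds.write(tmp_path)
    tests = read_tests_tsv(tmp_path / "tests.tsv")
    assert len(tests) == len(ds.tests)
    outcomes, _, groups = reduce_tests(tests)
    assert set(groups) <= {"control", "magnet", "sham"}
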