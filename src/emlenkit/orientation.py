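"""Reduction of raw Emlen-funnel test records to circular samples.

A funnel test yields a scratch-mark count and two independent observer
assessments of the bird's mean direction (each either a direction or a
"randomly distributed" call, made assuming the funnel overlap faced
North). Reduction applies, in order:

1. activity filter — fewer than ``activity_threshold`` (default 35)
   scratch marks means no migratory restlessness: *inactive*;
2. consensus filter — both observers calling the marks random, or one
   observer random, or directional calls more than
   ``disagreement_threshold`` (default 30°) apart: *not oriented*;
3. otherwise *oriented*, with direction the equal-weight circular mean
   of the two alignment-corrected calls.

Per bird and treatment, oriented test directions are averaged into an
individual mean direction; birds directional in at least
``min_oriented`` (default 2) tests enter the treatment's group sample,
the unit of all downstream inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .angles import angular_difference, correct_alignment, normalize_angle
from .circstats import circ_mean_r

__all__ = [
    "ObserverCall",
    "FunnelTest",
    "TestOutcome",
    "IndividualSummary",
    "GroupSample",
    "classify_test",
    "individual_mean",
    "group_sample",
    "reduce_tests",
    "read_tests_tsv",
    "outcomes_frame",
]

TESTS_COLUMNS = [
    "bird_id",
    "housing_group",
    "treatment",
    "night",
    "session",
    "funnel_alignment_deg",
    "mark_count",
    "obs1_random",
    "obs1_dir_deg",
    "obs2_random",
    "obs2_dir_deg",
]


@dataclass(frozen=True)
class ObserverCall:
    """One observer's assessment: a direction, or 'randomly distributed'."""

    random: bool
    direction: float | None = None

    def __post_init__(self):
        if self.random and self.direction is not None:
            raise ValueError("random call carries no direction")
        if not self.random:
            if self.direction is None:
                raise ValueError("directional call requires a direction")
            object.__setattr__(self, "direction", normalize_angle(self.direction))


@dataclass(frozen=True)
class FunnelTest:
    bird_id: str
    treatment: str
    night: str
    mark_count: int
    call_1: ObserverCall
    call_2: ObserverCall
    funnel_alignment: float = 0.0
    housing_group: str = "A"
    session: int = 1

    def __post_init__(self):
        if self.mark_count < 0:
            raise ValueError("mark_count must be nonnegative")
        if self.session not in (1, 2):
            raise ValueError("session must be 1 or 2")
        object.__setattr__(
            self, "funnel_alignment", normalize_angle(self.funnel_alignment)
        )


@dataclass(frozen=True)
class TestOutcome:
    """Classified funnel test: oriented / not_oriented / inactive.

    ``reason`` records the triggering rule for audit: 'ok',
    'below_activity_threshold', 'both_random', 'one_random',
    'observer_disagreement'.
    """

    bird_id: str
    treatment: str
    night: str
    status: str
    direction: float | None = None
    reason: str = "ok"


@dataclass(frozen=True)
class IndividualSummary:
    bird_id: str
    treatment: str
    n_oriented: int
    mean_direction: float | None
    r_individual: float | None
    included: bool


@dataclass(frozen=True)
class GroupSample:
    """Per-bird mean directions for one treatment; unit of inference."""

    treatment: str
    directions: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.directions)


def classify_test(
    test: FunnelTest,
    activity_threshold: int = 35,
    disagreement_threshold: float = 30.0,
) -> TestOutcome:
    """Classify one funnel test and derive its consensus direction.

    Directional observer calls are alignment-corrected before the
    consensus circular mean is taken (observers assess assuming a North
    alignment). A test with at least ``activity_threshold`` marks whose
    two directional calls agree to within ``disagreement_threshold``
    (strictly: discarded only when the difference exceeds it) is
    oriented. One random call is treated conservatively as not oriented
    (reason 'one_random'), since consensus requires two directional
    assessments.
    """
    if activity_threshold <= 0 or disagreement_threshold <= 0:
        raise ValueError("thresholds must be positive")
    base = dict(bird_id=test.bird_id, treatment=test.treatment, night=test.night)
    if test.mark_count < activity_threshold:
        return TestOutcome(status="inactive", reason="below_activity_threshold", **base)
    c1, c2 = test.call_1, test.call_2
    if c1.random and c2.random:
        return TestOutcome(status="not_oriented", reason="both_random", **base)
    if c1.random or c2.random:
        return TestOutcome(status="not_oriented", reason="one_random", **base)
    d1 = correct_alignment(c1.direction, test.funnel_alignment)
    d2 = correct_alignment(c2.direction, test.funnel_alignment)
    if angular_difference(d1, d2) > disagreement_threshold:
        return TestOutcome(
            status="not_oriented", reason="observer_disagreement", **base
        )
    consensus = circ_mean_r([d1, d2]).mean_direction
    return TestOutcome(status="oriented", direction=consensus, **base)


def individual_mean(
    bird_id: str,
    treatment: str,
    outcomes: Iterable[TestOutcome],
    min_oriented: int = 2,
) -> IndividualSummary:
    """Individual mean direction over a bird's oriented tests.

    A bird directional in fewer than ``min_oriented`` tests of a
    treatment is flagged excluded and contributes no direction to the
    group sample.
    """
    dirs = [
        o.direction
        for o in outcomes
        if o.status == "oriented" and o.bird_id == bird_id and o.treatment == treatment
    ]
    if not dirs:
        return IndividualSummary(bird_id, treatment, 0, None, None, False)
    s = circ_mean_r(dirs)
    return IndividualSummary(
        bird_id=bird_id,
        treatment=treatment,
        n_oriented=len(dirs),
        mean_direction=s.mean_direction,
        r_individual=s.r,
        included=len(dirs) >= min_oriented,
    )


def group_sample(summaries: Sequence[IndividualSummary], treatment: str) -> GroupSample:
    """Group sample of included birds' mean directions for a treatment."""
    dirs = [
        s.mean_direction
        for s in summaries
        if s.treatment == treatment and s.included
    ]
    if not dirs:
        raise ValueError(f"no analyzable birds for treatment {treatment!r}")
    return GroupSample(treatment=treatment, directions=[float(d) for d in dirs])


def _row_to_test(row: pd.Series) -> FunnelTest:
    def call(prefix: str) -> ObserverCall:
        is_random = bool(int(row[f"{prefix}_random"]))
        if is_random:
            return ObserverCall(random=True)
        return ObserverCall(random=False, direction=float(row[f"{prefix}_dir_deg"]))

    return FunnelTest(
        bird_id=str(row["bird_id"]),
        housing_group=str(row["housing_group"]),
        treatment=str(row["treatment"]),
        night=str(row["night"]),
        session=int(row["session"]),
        funnel_alignment=float(row["funnel_alignment_deg"]),
        mark_count=int(row["mark_count"]),
        call_1=call("obs1"),
        call_2=call("obs2"),
    )


def read_tests_tsv(path) -> list[FunnelTest]:
    """Read funnel-test records from a tests.tsv file (raw observer
    assessments, before alignment correction)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TESTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tests table missing required column(s): {missing}")
    return [_row_to_test(row) for _, row in df.iterrows()]


def reduce_tests(
    tests: Sequence[FunnelTest],
    activity_threshold: int = 35,
    disagreement_threshold: float = 30.0,
    min_oriented: int = 2,
) -> tuple[list[TestOutcome], list[IndividualSummary], dict[str, GroupSample]]:
    """Full reduction: classify every test, summarize birds, build
    group samples per treatment.

    Returns outcomes, individual summaries and a dict mapping treatment
    to its GroupSample (treatments with no analyzable bird are absent).
    """
    outcomes = [
        classify_test(t, activity_threshold, disagreement_threshold) for t in tests
    ]
    pairs = sorted({(t.bird_id, t.treatment) for t in tests})
    summaries = [
        individual_mean(b, tr, outcomes, min_oriented=min_oriented) for b, tr in pairs
    ]
    groups: dict[str, GroupSample] = {}
    for tr in sorted({t.treatment for t in tests}):
        try:
            groups[tr] = group_sample(summaries, tr)
        except ValueError:
            continue
    return outcomes, summaries, groups


def outcomes_frame(outcomes: Sequence[TestOutcome]) -> pd.DataFrame:
    """Tabulate classified outcomes (outcomes.tsv schema)."""
    return pd.DataFrame(
        {
            "bird_id": [o.bird_id for o in outcomes],
            "treatment": [o.treatment for o in outcomes],
            "night": [o.night for o in outcomes],
            "status": [o.status for o in outcomes],
            "direction_deg": [
                round(o.direction, 4) if o.direction is not None else ""
                for o in outcomes
            ],
            "reason": [o.reason for o in outcomes],
        }
    )
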