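"""Seeded generator of synthetic Emlen-funnel experiments.

Emulates the study design end to end so every pipeline stage is
testable without field data: two housing groups of birds, four tests
per bird per treatment in a crossover schedule, von Mises heading
hierarchy (bird-level preference around a group direction near 152°,
test-level scatter around the bird's preference), disoriented
treatments with uniform (optionally axial) test headings, negative
binomial scratch-mark counts, and a two-observer assessment model with
von Mises reading noise and a "randomly distributed" call probability
that falls logistically with how concentrated the test's marks are.

Observer calls are emitted raw, i.e. as read assuming a North funnel
alignment; the reduction pipeline applies the alignment correction,
exactly as with real records. Alongside the records, truth tables give
the generating bird and test headings and the generative reason any
record will be discarded.

Defaults reproduce the study conditions: 9+8 birds (or 9+9 for the
two-treatment design), group direction 152°, and discard rates of
roughly a quarter "not oriented" and under a tenth inactive.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .angles import angular_difference, normalize_angle
from .circstats import circ_mean_r
from .orientation import TESTS_COLUMNS, FunnelTest, _row_to_test

__all__ = ["SimConfig", "SyntheticDataset", "sample_von_mises",
           "simulate_observer", "simulate_experiment"]


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults are the three-treatment
    crossover design (17 birds: 9 in housing group A, 8 in B).

    Heading hierarchy: bird preference ~ vM(mu_group, kappa_between);
    per-test heading ~ vM(bird preference, kappa_within), except in
    ``disoriented_treatments`` where test headings are uniform (or
    axial around mu_group for treatments in ``axial_treatments``, the
    reverse mode chosen with probability ``p_axial``). Scratch-mark
    counts are negative binomial (mean ``mark_mean``, dispersion
    ``mark_dispersion``); mark angles around the test heading with
    concentration ``kappa_marks`` determine the per-test mark resultant
    the observers respond to. Each observer independently calls the
    marks random with probability
    1 / (1 + exp(slope * (marks_r - midpoint))) and otherwise reads a
    direction with vM noise ``kappa_obs`` around the test heading.
    """

    n_group_a: int = 9
    n_group_b: int = 8
    treatments: tuple[str, ...] = ("control", "magnet", "sham")
    tests_per_treatment: int = 4
    disoriented_treatments: frozenset = frozenset({"magnet"})
    axial_treatments: frozenset = frozenset()
    p_axial: float = 0.5
    mu_group: float = 152.0
    kappa_between: float = 2.0
    kappa_within: float = 3.0
    mark_mean: float = 120.0
    mark_dispersion: float = 5.0
    kappa_marks: float = 2.0
    kappa_obs: float = 50.0
    p_random_midpoint: float = 0.45
    p_random_slope: float = 8.0
    p_magnet_loss: float = 0.30
    start_date: str = "2019-09-12"
    emit_marks: bool = False
    seed: int | None = None

    def __post_init__(self):
        for p in (self.p_axial, self.p_magnet_loss):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0,1]")
        for k in (self.kappa_between, self.kappa_within, self.kappa_marks,
                  self.kappa_obs):
            if k < 0:
                raise ValueError("concentrations must be >= 0")
        if self.n_group_a < 1 or self.n_group_b < 0:
            raise ValueError("need at least one bird")

    @classmethod
    def experiment_magnet_celestial(cls, **kw) -> "SimConfig":
        """Two-treatment design: 18 birds (9+9), magnet vs
        magnet with celestial cues available."""
        base = dict(
            n_group_a=9, n_group_b=9,
            treatments=("magnet", "magnet_celestial"),
            disoriented_treatments=frozenset({"magnet"}),
            start_date="2020-09-10",
        )
        base.update(kw)
        return cls(**base)

    @property
    def n_birds(self) -> int:
        return self.n_group_a + self.n_group_b


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated experiment: the record table plus aligned truth.

    ``tests`` follows the tests.tsv schema (raw observer calls).
    ``birds`` holds each bird's true heading; ``truth`` one row per
    record with the true test heading, mark resultant and the
    generative discard reason ('' when the record should classify as
    oriented).
    """

    tests: pd.DataFrame
    birds: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig
    marks: pd.DataFrame | None = None

    def funnel_tests(self) -> list[FunnelTest]:
        return [_row_to_test(row) for _, row in self.tests.iterrows()]

    def provenance(self) -> dict:
        cfg = dataclasses.asdict(self.config)
        cfg["disoriented_treatments"] = sorted(self.config.disoriented_treatments)
        cfg["axial_treatments"] = sorted(self.config.axial_treatments)
        return {"generator": "emlenkit.simulate", "config": cfg}

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.tests.to_csv(out / "tests.tsv", sep="\t", index=False)
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        if self.marks is not None:
            self.marks.to_csv(out / "marks.tsv", sep="\t", index=False)
        (out / "provenance.json").write_text(
            json.dumps(self.provenance(), indent=2) + "\n"
        )


def sample_von_mises(n: int, mu: float, kappa: float, rng: np.random.Generator):
    """n seeded von Mises draws in degrees; kappa = 0 is uniform."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa == 0.0:
        return np.mod(rng.uniform(0.0, 360.0, size=n), 360.0)
    draws = rng.vonmises(np.deg2rad(mu), kappa, size=n)
    return np.mod(np.rad2deg(draws), 360.0)


def p_random_call(marks_r: float, cfg: SimConfig) -> float:
    """Probability an observer calls the marks randomly distributed,
    as a decreasing logistic in the test's mark resultant length."""
    z = cfg.p_random_slope * (marks_r - cfg.p_random_midpoint)
    return float(1.0 / (1.0 + np.exp(z)))


def simulate_observer(
    test_heading: float, marks_r: float, cfg: SimConfig, rng: np.random.Generator
):
    """One observer's call for a test: (is_random, direction_or_None).

    Directional calls are von Mises reads (kappa_obs) around the true
    test heading, in the true (alignment-corrected) frame.
    """
    if rng.uniform() < p_random_call(marks_r, cfg):
        return True, None
    d = float(sample_von_mises(1, test_heading, cfg.kappa_obs, rng)[0])
    return False, d


def _schedule(cfg: SimConfig) -> dict[str, list[str]]:
    """Per-housing-group treatment sequence over test nights.

    Three treatments: everyone starts with the first treatment's block,
    then the two groups take the remaining blocks in opposite order (a
    time-balanced crossover). Two treatments: blocks alternate night by
    night. Otherwise: plain blocks in listed order.
    """
    t = cfg.treatments
    k = cfg.tests_per_treatment
    if len(t) == 3:
        a = [t[0]] * k + [t[1]] * k + [t[2]] * k
        b = [t[0]] * k + [t[2]] * k + [t[1]] * k
    elif len(t) == 2:
        a = [t[i % 2] for i in range(2 * k)]
        b = list(a)
    else:
        a = [tr for tr in t for _ in range(k)]
        b = list(a)
    return {"A": a, "B": b}


def _test_heading(treatment: str, bird_heading: float, cfg: SimConfig,
                  rng: np.random.Generator) -> float:
    if treatment in cfg.disoriented_treatments:
        if treatment in cfg.axial_treatments:
            mode = cfg.mu_group + (180.0 if rng.uniform() < cfg.p_axial else 0.0)
            return float(sample_von_mises(1, mode, cfg.kappa_within, rng)[0])
        return float(rng.uniform(0.0, 360.0))
    return float(sample_von_mises(1, bird_heading, cfg.kappa_within, rng)[0])


def simulate_experiment(cfg: SimConfig | None = None) -> SyntheticDataset:
    """Generate a complete synthetic experiment, reproducible by seed."""
    if cfg is None:
        cfg = SimConfig()
    rng = np.random.default_rng(cfg.seed)
    start = _dt.date.fromisoformat(cfg.start_date)
    sched = _schedule(cfg)
    n_nights = len(sched["A"])

    bird_rows, test_rows, truth_rows, mark_rows = [], [], [], []
    bird_ids, groups, headings = [], [], []
    for i in range(cfg.n_birds):
        grp = "A" if i < cfg.n_group_a else "B"
        bid = f"{grp}{i + 1:02d}"
        heading = float(sample_von_mises(1, cfg.mu_group, cfg.kappa_between, rng)[0])
        bird_ids.append(bid)
        groups.append(grp)
        headings.append(heading)
        bird_rows.append(dict(bird_id=bid, housing_group=grp,
                              true_heading_deg=round(heading, 4)))

    nb_n = cfg.mark_dispersion
    nb_p = cfg.mark_dispersion / (cfg.mark_dispersion + cfg.mark_mean)

    for night_idx in range(n_nights):
        night = (start + _dt.timedelta(days=night_idx)).isoformat()
        for i, bid in enumerate(bird_ids):
            grp = groups[i]
            treatment = sched[grp][night_idx]
            session = 1 if grp == "A" else 2
            alignment = 0.0 if (night_idx + i) % 2 == 0 else 180.0
            heading = _test_heading(treatment, headings[i], cfg, rng)
            n_marks = int(rng.negative_binomial(nb_n, nb_p))
            if n_marks > 0:
                angles = sample_von_mises(n_marks, heading, cfg.kappa_marks, rng)
                marks_r = circ_mean_r(angles).r
                if cfg.emit_marks:
                    for a in angles:
                        mark_rows.append(dict(test_id=f"{bid}_{night}",
                                              mark_angle_deg=round(float(a), 2)))
            else:
                marks_r = 0.0

            r1, d1 = simulate_observer(heading, marks_r, cfg, rng)
            r2, d2 = simulate_observer(heading, marks_r, cfg, rng)
            lost_magnet = (
                "magnet" in treatment and rng.uniform() < cfg.p_magnet_loss
            )

            # generative discard provenance, mirroring the reduction rules
            if n_marks < 35:
                reason = "below_activity_threshold"
            elif r1 and r2:
                reason = "both_random"
            elif r1 or r2:
                reason = "one_random"
            elif angular_difference(d1, d2) > 30.0:
                reason = "observer_disagreement"
            else:
                reason = ""

            def raw(d):
                return (
                    "" if d is None
                    else round(normalize_angle(d - alignment), 2)
                )

            test_rows.append(dict(
                bird_id=bid, housing_group=grp, treatment=treatment,
                night=night, session=session,
                funnel_alignment_deg=alignment, mark_count=n_marks,
                obs1_random=int(r1), obs1_dir_deg=raw(d1),
                obs2_random=int(r2), obs2_dir_deg=raw(d2),
            ))
            truth_rows.append(dict(
                bird_id=bid, treatment=treatment, night=night,
                true_bird_heading_deg=round(headings[i], 4),
                true_test_heading_deg=round(heading, 4),
                marks_r=round(marks_r, 4), mark_count=n_marks,
                lost_magnet=int(lost_magnet),
                discard_reason=reason,
            ))

    return SyntheticDataset(
        tests=pd.DataFrame(test_rows, columns=TESTS_COLUMNS),
        birds=pd.DataFrame(bird_rows),
        truth=pd.DataFrame(truth_rows),
        config=cfg,
        marks=pd.DataFrame(mark_rows) if cfg.emit_marks else None,
    )
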