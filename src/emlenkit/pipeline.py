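"""Orchestration of full analysis runs.

Ties together simulation (or reading) of funnel-test records, the
discard/consensus reduction, Rayleigh tests and mean-direction CIs per
treatment, ten-model AICc selection, pairwise comparisons (MWW between
significantly oriented treatments, rank-based bootstrap against
non-oriented ones), and the ring-recovery bearing analysis. Every
stochastic stage is seeded from one master seed; a run with the same
configuration and seed writes byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import BootstrapConfig, compare_directedness
from .circstats import mean_direction_ci, mww_test, rayleigh_test
from .models import select_models
from .orientation import outcomes_frame, read_tests_tsv, reduce_tests
from .recoveries import (bearings_frame, filter_recoveries, natural_direction,
                         read_recoveries_csv)
from .simulate import SimConfig, simulate_experiment

log = logging.getLogger("emlenkit")

__all__ = ["RunConfig", "run_pipeline"]

SIG_ALPHA = 0.05


@dataclass
class RunConfig:
    """Configuration of one pipeline run; defaults are the study's
    stated analysis choices (35-mark activity threshold, 30° observer
    disagreement rule, two oriented tests to include a bird, 100,000
    bootstrap replicates)."""

    out_dir: str = "run_out"
    seed: int = 0
    tests_path: str | None = None       # None -> simulate
    recoveries_path: str | None = None
    activity_threshold: int = 35
    disagreement_deg: float = 30.0
    min_oriented: int = 2
    bootstrap_B: int = 100_000
    ci_method: str = "bootstrap"
    ci_B: int = 10_000
    declination_deg: float = 0.0
    sim: SimConfig | None = None
    fit_models: bool = True


def _stage_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence([master, zlib.crc32(stage.encode()) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the tables as DataFrames and
    writes them (TSV) plus a manifest JSON under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result: dict = {}
    manifest: dict = {
        "package": "emlenkit",
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "sim"
        },
        "outputs": [],
    }

    # --- records: read or simulate -------------------------------------
    if config.tests_path is not None:
        tests = read_tests_tsv(config.tests_path)
        log.info("read %d funnel-test records from %s",
                 len(tests), config.tests_path)
    else:
        sim = config.sim or SimConfig(seed=_stage_seed(config.seed, "simulate"))
        if sim.seed is None:
            sim = dataclasses.replace(sim, seed=_stage_seed(config.seed, "simulate"))
        ds = simulate_experiment(sim)
        ds.write(out)
        result["dataset"] = ds
        tests = ds.funnel_tests()
        manifest["outputs"] += ["tests.tsv", "truth.tsv", "provenance.json"]
        log.info("simulated %d funnel-test records (seed %s)", len(tests), sim.seed)

    # --- reduction ------------------------------------------------------
    outcomes, summaries, groups = reduce_tests(
        tests,
        activity_threshold=config.activity_threshold,
        disagreement_threshold=config.disagreement_deg,
        min_oriented=config.min_oriented,
    )
    oc = outcomes_frame(outcomes)
    oc.to_csv(out / "outcomes.tsv", sep="\t", index=False)
    manifest["outputs"].append("outcomes.tsv")
    for o in outcomes:
        if o.status != "oriented":
            log.info("discarded %s %s %s: %s", o.bird_id, o.treatment,
                     o.night, o.reason)
    counts = oc["status"].value_counts().to_dict()
    manifest["discards"] = {k: int(v) for k, v in counts.items()}
    result["outcomes"] = oc
    result["groups"] = groups

    # --- per-treatment stats -------------------------------------------
    stats_rows = []
    rayleigh = {}
    for tr, grp in groups.items():
        from .circstats import circ_mean_r

        summ = circ_mean_r(grp.directions)
        rt = rayleigh_test(summ.n, summ.r)
        rayleigh[tr] = rt
        row = dict(treatment=tr, n=summ.n,
                   mean_deg=round(summ.mean_direction, 2)
                   if np.isfinite(summ.mean_direction) else "",
                   r=round(summ.r, 4),
                   rayleigh_Z=round(rt.Z, 4), rayleigh_p=rt.p,
                   ci_low_deg="", ci_high_deg="")
        if rt.p < SIG_ALPHA and summ.r > 0:
            ci = mean_direction_ci(
                grp.directions, level=0.95, method=config.ci_method,
                B=config.ci_B, seed=_stage_seed(config.seed, f"ci:{tr}"),
            )
            row["ci_low_deg"] = round(ci.lower, 2)
            row["ci_high_deg"] = round(ci.upper, 2)
        stats_rows.append(row)
    stats = pd.DataFrame(stats_rows)
    stats.to_csv(out / "stats_report.tsv", sep="\t", index=False)
    manifest["outputs"].append("stats_report.tsv")
    result["stats_report"] = stats

    # --- model selection -------------------------------------------------
    if config.fit_models:
        tables = {}
        for tr, grp in groups.items():
            sel = select_models(grp.directions,
                                seed=_stage_seed(config.seed, f"models:{tr}"))
            tbl = sel.table()
            fname = f"model_table_{tr}.tsv"
            tbl.to_csv(out / fname, sep="\t", index=False)
            manifest["outputs"].append(fname)
            tables[tr] = sel
        result["model_selection"] = tables

    # --- pairwise comparisons --------------------------------------------
    pair_rows, boot_rows = [], []
    for tr_a, tr_b in itertools.combinations(sorted(groups), 2):
        sig_a = rayleigh[tr_a].p < SIG_ALPHA
        sig_b = rayleigh[tr_b].p < SIG_ALPHA
        if sig_a and sig_b:
            res = mww_test(groups[tr_a].directions, groups[tr_b].directions)
            pair_rows.append(dict(treatment_a=tr_a, treatment_b=tr_b,
                                  test="MWW", statistic=round(res.W, 4),
                                  p_or_confidence=res.p))
        elif sig_a or sig_b:
            oriented, other = (tr_a, tr_b) if sig_a else (tr_b, tr_a)
            r_other = rayleigh[other].r
            bres = compare_directedness(
                groups[oriented].directions, r_other,
                BootstrapConfig(B=config.bootstrap_B,
                                seed=_stage_seed(config.seed,
                                                 f"boot:{oriented}:{other}")),
            )
            pair_rows.append(dict(treatment_a=oriented, treatment_b=other,
                                  test="bootstrap", statistic=round(bres.r_other, 4),
                                  p_or_confidence=bres.verdict))
            row = dict(oriented_treatment=oriented, other_treatment=other,
                       r_oriented=round(bres.r_observed_oriented, 4),
                       r_other=round(bres.r_other, 4))
            for lv, key in [(0.95, "95"), (0.99, "99"), (0.999, "999")]:
                lo, hi = bres.bounds[lv]
                row[f"low{key}"] = round(lo, 4)
                row[f"high{key}"] = round(hi, 4)
            row.update(verdict=bres.verdict, B=bres.B, seed=bres.seed)
            boot_rows.append(row)
        else:
            pair_rows.append(dict(treatment_a=tr_a, treatment_b=tr_b,
                                  test="none",
                                  statistic="",
                                  p_or_confidence="neither_oriented"))
    pairwise = pd.DataFrame(pair_rows)
    pairwise.to_csv(out / "pairwise.tsv", sep="\t", index=False)
    manifest["outputs"].append("pairwise.tsv")
    result["pairwise"] = pairwise
    boot = pd.DataFrame(boot_rows)
    boot.to_csv(out / "bootstrap_report.tsv", sep="\t", index=False)
    manifest["outputs"].append("bootstrap_report.tsv")
    result["bootstrap_report"] = boot

    # --- ring recoveries --------------------------------------------------
    if config.recoveries_path is not None:
        records = read_recoveries_csv(config.recoveries_path)
        kept = filter_recoveries(records)
        bf = bearings_frame(records, kept)
        bf.to_csv(out / "bearings.tsv", sep="\t", index=False)
        manifest["outputs"].append("bearings.tsv")
        summ, rt = natural_direction(
            kept, declination_deg=config.declination_deg, prefiltered=True
        )
        result["recoveries"] = dict(
            n=summ.n, mean_deg=summ.mean_direction, r=summ.r,
            rayleigh_Z=rt.Z, rayleigh_p=rt.p,
        )
        manifest["recoveries"] = {
            k: (round(v, 4) if isinstance(v, float) else v)
            for k, v in result["recoveries"].items()
        }
        result["bearings"] = bf

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return result
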