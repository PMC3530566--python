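"""End-to-end orchestration: simulate/ingest -> stats -> cluster ->
entropy -> predict -> workday, with a consolidated JSON report."""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import entropy as ent
from . import ingest, locstats, patterns, predict, synthetic, workday
from .core import DayMatrix

log = logging.getLogger("daytrace")


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration (YAML-friendly)."""

    trace_file: str | None = None  # CSV events; exclusive with generator
    generator: dict | None = None  # GeneratorConfig fields
    slot_minutes: int = 60
    max_gap_slots: int = 6
    max_missing_fraction: float = 0.30
    location_threshold: float = 0.01
    min_days: int = 30
    clustering: str = "both"  # eo | kmeans | both
    delta: float | None = None
    tau: float = 1.4
    eo_restarts: int = 4
    kmeans_k: int | None = None  # default: EO-emergent count
    kmeans_runs: int = 200
    rules: tuple[str, ...] = ("matching", "mode")
    max_lag: int = 12
    workday_window: tuple[int, int] = (9, 17)
    min_workdays: int = 20
    seed: int = 0
    out_dir: str = "daytrace_out"

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "rules" in d:
            d["rules"] = tuple(d["rules"])
        if "workday_window" in d:
            d["workday_window"] = tuple(d["workday_window"])
        cfg = cls(**d)
        if cfg.clustering not in ("eo", "kmeans", "both"):
            raise ValueError("clustering must be eo, kmeans, or both")
        if cfg.trace_file is None and cfg.generator is None:
            raise ValueError("either trace_file or generator must be given")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _cluster_user(dm: DayMatrix, cfg: RunConfig) -> dict[str, patterns.ClusterAssignment]:
    out: dict[str, patterns.ClusterAssignment] = {}
    eo_assign = None
    if cfg.clustering in ("eo", "both") and dm.n_days >= 2:
        graph = patterns.build_day_graph(dm, delta=cfg.delta)
        eo_assign = patterns.eo_modularity(
            graph, tau=cfg.tau, rng=np.random.default_rng((cfg.seed, 1)),
            restarts=cfg.eo_restarts,
        )
        out["eo"] = eo_assign
    if cfg.clustering in ("kmeans", "both"):
        k = cfg.kmeans_k or (eo_assign.n_clusters if eo_assign else 1)
        k = min(max(k, 1), dm.n_days)
        out["kmeans"] = patterns.kmeans_days(
            dm, k, n_runs=cfg.kmeans_runs, random_state=cfg.seed
        )
    return out


def _predict_user(dm: DayMatrix, assign, cfg: RunConfig) -> dict:
    labels = None if assign is None else assign.labels
    out: dict[str, Any] = {}
    for rule in cfg.rules:
        static_no = predict.static_quality(dm, None, rule)
        trans_no = predict.transition_quality(
            predict.fit_transition_model(dm, 1, None), dm, rule
        )
        block = {
            "static": static_no.day_average,
            "transition": trans_no.overall,
        }
        if labels is not None:
            block["static_patterns"] = predict.static_quality(dm, labels, rule).day_average
            block["transition_patterns"] = predict.transition_quality(
                predict.fit_transition_model(dm, 1, labels), dm, rule
            ).overall
        curve = predict.long_range_curve(dm, cfg.max_lag, rule)
        block["q_curve"] = {
            "lags": curve.lags.tolist(),
            "quality": curve.quality.tolist(),
            "log_fit": {"intercept": curve.fit_intercept, "slope": curve.fit_slope},
            "stays_above_static": curve.stays_above_static,
        }
        out[rule] = block
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage; write per-module outputs and return the report."""
    t_start = time.time()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        log.info("stage %s", name)
        timings[name] = time.time()

    def stage_done(name):
        timings[name] = round(time.time() - timings[name], 3)

    stage("input")
    if cfg.trace_file is not None:
        events = ingest.read_events_csv(cfg.trace_file)
    else:
        gen_cfg = synthetic.GeneratorConfig.from_dict(
            {"seed": cfg.seed, **(cfg.generator or {})}
        )
        events, truth = synthetic.generate_panel(gen_cfg)
        synthetic.write_events_csv(events, out_dir / "events.csv")
        synthetic.write_ground_truth(truth, out_dir / "ground_truth.json")
    stage_done("input")

    stage("ingest")
    result = ingest.ingest_events(
        events,
        slot_minutes=cfg.slot_minutes,
        max_gap_slots=cfg.max_gap_slots,
        max_missing_fraction=cfg.max_missing_fraction,
        min_days=cfg.min_days,
    )
    ingest.write_day_matrices(result.matrices, out_dir / "day_matrix.csv")
    (out_dir / "exclusions.json").write_text(
        json.dumps(result.exclusion_log(), indent=1, sort_keys=True)
    )
    stage_done("ingest")

    users: dict[str, dict] = {}
    reports: list[ent.EntropyReport] = []
    pooled_z: list[float] = []
    per_user_q: dict[str, dict] = {}

    stage("per_user")
    for user, raw_dm in sorted(result.matrices.items()):
        alphabet = locstats.location_frequencies(raw_dm, cfg.location_threshold)
        dm, reduced = locstats.threshold_locations(raw_dm, alphabet)
        assigns = _cluster_user(dm, cfg)
        rep = ent.entropy_report(
            dm,
            {m: a.labels for m, a in assigns.items()},
            alphabet.n_significant,
        )
        reports.append(rep)
        best = assigns.get("eo") or assigns.get("kmeans")
        qualities = _predict_user(dm, best, cfg)
        per_user_q[user] = qualities

        wd: dict[str, Any] = {"work_location": None}
        work = workday.find_work_location(
            dm, day_window=cfg.workday_window, min_workdays=cfg.min_workdays
        )
        if work is not None:
            try:
                table = workday.day_lengths(dm, work, cfg.min_workdays)
                pooled_z.extend(table["z_length"].tolist())
                wd = {
                    "work_location": work,
                    "n_workdays": int(len(table)),
                    "mean_length": float(table["length"].mean()),
                }
            except ValueError:
                pass

        users[user] = {
            "n_days": dm.n_days,
            "n_significant_locations": alphabet.n_significant,
            "entropy": rep.to_record(),
            "prediction": qualities,
            "workday": wd,
            "clustering": {
                m: {"n_clusters": a.n_clusters, "score": a.score}
                for m, a in assigns.items()
            },
        }
    stage_done("per_user")

    stage("panel")
    panel: dict[str, Any] = {
        "n_users_accepted": len(result.matrices),
        "n_users_rejected": len(result.rejected_users),
        "missing_fraction_before_padding": result.missing_before,
        "missing_fraction_after_padding": result.missing_after,
    }
    if len(result.matrices) >= 1:
        curve = locstats.pooled_rank_curve(result.matrices)
        curve.to_csv(out_dir / "rank_frequency.csv", index=False)
        samples = locstats.panel_rank_samples(result.matrices)
        try:
            fit = locstats.fit_power_law(samples)
            panel["power_law"] = {
                "alpha": fit.alpha,
                "ci95": list(fit.ci95),
                "xmin": fit.xmin,
                "n_tail": fit.n_tail,
            }
        except ValueError as exc:
            panel["power_law"] = {"error": str(exc)}
    if len(reports) >= 2:
        panel["entropy_distributions"] = ent.entropy_distributions(reports)
        for rule in cfg.rules:
            try:
                rho, p = predict.entropy_predictability_correlation(
                    [r.s_bare for r in reports],
                    [per_user_q[r.user_id][rule]["static"] for r in reports],
                )
                panel[f"entropy_quality_correlation_{rule}"] = {"rho": rho, "p": p}
            except ValueError as exc:
                panel[f"entropy_quality_correlation_{rule}"] = {"error": str(exc)}
    if len(pooled_z) >= 100:
        z = np.asarray(pooled_z)
        grid = np.arange(np.floor(z.min() * 4) / 4, np.ceil(z.max() * 4) / 4 + 0.25, 0.25)
        try:
            fit = workday.fit_departure_model(z, grid=grid)
            panel["departure_fit"] = {
                "t0": fit.model.t0,
                "a_early": fit.model.a_early,
                "a_late": fit.model.a_late,
                "h0": fit.model.h0,
                "se": fit.se,
                "ks": fit.ks,
                "n": fit.n,
            }
        except (ValueError, RuntimeError) as exc:
            panel["departure_fit"] = {"error": str(exc)}
    else:
        panel["departure_fit"] = {"error": f"only {len(pooled_z)} pooled lengths"}
    stage_done("panel")

    report = {
        "config": {
            "seed": cfg.seed,
            "slot_minutes": cfg.slot_minutes,
            "clustering": cfg.clustering,
            "rules": list(cfg.rules),
        },
        "panel": panel,
        "users": users,
        "timings_s": {},  # filled below; keys stable for determinism
    }
    report_no_time = json.dumps(
        {k: v for k, v in report.items() if k != "timings_s"}, indent=1, sort_keys=True
    )
    (out_dir / "report.json").write_text(report_no_time)
    report["timings_s"] = {k: v for k, v in timings.items()}
    log.info("pipeline done in %.1fs", time.time() - t_start)
    return report


def render_fig_tables(report: dict, out_dir) -> list[str]:
    """Tabular analogues of the headline figures; returns files written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    users = report.get("users", {})
    if users:
        rows = []
        for u, blob in users.items():
            rec = dict(blob["entropy"])
            rec["n_days"] = blob["n_days"]
            rows.append(rec)
        path = out_dir / "user_entropies.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        written.append(str(path))

        q_rows = []
        for u, blob in users.items():
            for rule, vals in blob["prediction"].items():
                q_rows.append(
                    {
                        "user_id": u,
                        "rule": rule,
                        **{
                            k: v
                            for k, v in vals.items()
                            if isinstance(v, (int, float))
                        },
                    }
                )
        path = out_dir / "prediction_quality.csv"
        pd.DataFrame(q_rows).to_csv(path, index=False)
        written.append(str(path))
    else:
        log.warning("report has no users; figure tables skipped")

    dist = report.get("panel", {}).get("entropy_distributions")
    if dist:
        frames = []
        for key, blob in dist.items():
            frames.append(
                pd.DataFrame(
                    {"measure": key, "value": blob["values"], "cdf": blob["cdf"]}
                )
            )
        path = out_dir / "entropy_cdfs.csv"
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        written.append(str(path))

    dep = report.get("panel", {}).get("departure_fit")
    if dep and "error" not in dep:
        path = out_dir / "departure_fit.json"
        Path(path).write_text(json.dumps(dep, indent=1, sort_keys=True))
        written.append(str(path))
    return written
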