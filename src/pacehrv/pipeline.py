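"""End-to-end study orchestration: simulate -> extract -> measure -> analyze.

A run is fully determined by its configuration and master seed: it writes
the simulated cohort (one beat-series file per patient plus a ground-truth
table), a per-patient metrics table, all statistics tables, Bland-Altman and
SODP plots, an audit log of every discarded window, and a machine-readable
JSON summary.  Externally supplied beat-series files can enter at the
analyze stage unchanged.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as bsio
from . import stats as chs
from .metrics import hrv_from_window, snrt_csnrt, wenckebach_point
from .simulate import GroundTruth, SimParams, parse_av_ramp, simulate_cohort
from .windows import AuditEntry, measure_patient

HRV_METRICS = ("rmssd", "delta_pp", "median_cl")
EP_METRICS = ("snrt", "csnrt", "wp_rate")
BA_PAIRS = (("A", "B"), ("A", "C"), ("C", "D"), ("B", "D"))


@dataclass
class RunConfig:
    """Configuration of one reproducible study run."""

    sim: SimParams = field(default_factory=SimParams)
    include_recovery_beat: bool = False
    alpha: float = 0.05
    bonferroni_m: int = 2
    csnrt_aggregator: str = "mean"  # baseline CL aggregator for cSNRT
    make_plots: bool = True

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.bonferroni_m

    def validate(self) -> "RunConfig":
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.bonferroni_m < 1:
            raise ValueError("bonferroni_m must be >= 1")
        self.sim.validate()
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimParams.from_dict(d["sim"])
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def analyze_patient(
    series: bsio.BeatSeries, config: RunConfig
) -> tuple[dict, list[AuditEntry]]:
    """Measure one patient's series into a flat {(metric, period): value} row."""
    measurements, audit = measure_patient(series, config.include_recovery_beat)
    row: dict = {}
    for key, post_period in (("AB", "B"), ("CD", "D")):
        meas = measurements.get(key)
        if meas is None:
            continue
        ramp_key = "av_ramp_1" if key == "AB" else "av_ramp_2"
        if meas.pre.valid:
            hrv = hrv_from_window(meas.pre)
            for m in HRV_METRICS:
                row[(m, meas.pre.period)] = getattr(hrv, m)
        if meas.post.valid:
            hrv = hrv_from_window(meas.post)
            for m in HRV_METRICS:
                row[(m, meas.post.period)] = getattr(hrv, m)
        if meas.pre.valid and meas.recovery_interval is not None:
            snrt, csnrt = snrt_csnrt(
                meas.recovery_interval, meas.pre, config.csnrt_aggregator
            )
            row[("snrt", post_period)] = snrt
            row[("csnrt", post_period)] = csnrt
        if ramp_key in series.metadata:
            try:
                wp_rate, wp_cl = wenckebach_point(
                    parse_av_ramp(series.metadata[ramp_key])
                )
                row[("wp_rate", post_period)] = wp_rate
                row[("wp_cl", post_period)] = wp_cl
            except ValueError:
                pass  # WP not reached: left missing
    return row, audit


def build_cohort_frame(
    series_list: Sequence[bsio.BeatSeries], config: RunConfig
) -> tuple[pd.DataFrame, list[AuditEntry]]:
    """Per-patient measurement of a whole cohort into a wide frame."""
    rows = {}
    audit: list[AuditEntry] = []
    for series in series_list:
        row, entries = analyze_patient(series, config)
        rows[series.patient_id] = row
        audit.extend(entries)
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = pd.MultiIndex.from_tuples(frame.columns)
    frame = frame.sort_index().sort_index(axis=1)
    frame.index.name = "patient_id"
    return frame, audit


def _median_iqr(values: np.ndarray) -> dict:
    v = values[~np.isnan(values)]
    if v.size == 0:
        return {"median": float("nan"), "q1": float("nan"),
                "q3": float("nan"), "n": 0}
    return {
        "median": float(np.median(v)),
        "q1": float(np.percentile(v, 25)),
        "q3": float(np.percentile(v, 75)),
        "n": int(v.size),
    }


def summarize_cohort(frame: pd.DataFrame, config: RunConfig) -> dict:
    """All cohort statistics in one JSON-serializable summary."""
    summary: dict = {
        "config": config.to_dict(),
        "n_patients": int(len(frame)),
        "bonferroni_threshold": config.bonferroni_threshold,
        "metrics": {},
        "ep_params": {},
    }
    for metric in HRV_METRICS:
        block: dict = {"periods": {}}
        for period in chs.PERIODS:
            col = frame[(metric, period)].to_numpy(float)
            block["periods"][period] = _median_iqr(col)
        block["tests"] = chs.contrast_tests(
            frame, metric, config.alpha, config.bonferroni_m
        )
        block["positive_delta"] = {}
        for pair in chs.PRESPECIFIED:
            count, pct = chs.positive_delta_freq(frame, metric, pair)
            block["positive_delta"]["%s-%s" % pair] = {
                "count": count, "percent": pct,
            }
        block["bland_altman"] = {}
        for pair in BA_PAIRS:
            res = chs.bland_altman(frame, metric, pair)
            block["bland_altman"]["%s-%s" % pair] = {
                "bias": res.bias, "sd_diff": res.sd_diff,
                "pct_bias": res.pct_bias, "n": res.n,
            }
        block["repeatability"] = {}
        for pair in chs.DESCRIPTIVE:
            try:
                block["repeatability"]["%s-%s" % pair] = chs.repeatability(
                    frame, metric, pair
                )
            except ValueError as exc:  # e.g. < 5 complete pairs
                block["repeatability"]["%s-%s" % pair] = {"unavailable": str(exc)}
        _, sodp_summary, skipped = chs.sodp(frame, metric)
        block["sodp"] = {"quadrant_fractions": sodp_summary,
                         "skipped_patients": skipped}
        summary["metrics"][metric] = block
    for metric in EP_METRICS:
        if (metric, "B") not in frame.columns or (metric, "D") not in frame.columns:
            continue
        b, d = chs._pair_vectors(frame, metric, ("B", "D"))
        block = {
            "B": _median_iqr(frame[(metric, "B")].to_numpy(float)),
            "D": _median_iqr(frame[(metric, "D")].to_numpy(float)),
            "wilcoxon_B_D": chs.wilcoxon_signed_rank(b, d),
        }
        summary["ep_params"][metric] = block
    return summary


@dataclass
class StudyBundle:
    """Everything a completed run produced."""

    out_dir: str
    frame: pd.DataFrame
    summary: dict
    audit: list[AuditEntry]
    ground_truth: list[GroundTruth]


def write_ground_truth(truths: Sequence[GroundTruth], path: str) -> None:
    rows = []
    for t in truths:
        rows.append({
            "patient_id": t.patient_id,
            "baseline_cl": t.baseline_cl,
            "sd_succ_diff": t.sd_succ_diff,
            "surge_multiplier": t.surge_multiplier,
            "snrt_1": t.snrt[0], "snrt_2": t.snrt[1],
            "wp_threshold_1": t.wp_threshold[0],
            "wp_threshold_2": t.wp_threshold[1],
            "wp_cycle_length_1": t.wp_cycle_length[0],
            "wp_cycle_length_2": t.wp_cycle_length[1],
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_audit_log(audit: Sequence[AuditEntry], path: str) -> None:
    rows = [{
        "patient_id": e.patient_id, "period": e.period, "reason": e.reason,
        "replacement_time": "" if e.replacement_time is None else e.replacement_time,
    } for e in audit]
    pd.DataFrame(rows, columns=["patient_id", "period", "reason",
                                "replacement_time"]).to_csv(path, index=False)


def run_study(
    config: RunConfig,
    out_dir: str,
    seed: int | None = None,
    series_list: Sequence[bsio.BeatSeries] | None = None,
) -> StudyBundle:
    """Run the full study and write the report bundle to ``out_dir``.

    With ``series_list`` given (externally supplied beat tables), the
    simulation stage is skipped.  Otherwise a cohort is simulated from
    ``config.sim`` (with ``seed`` overriding the configured master seed).
    Identical config + seed produce byte-identical summaries.
    """
    config.validate()
    os.makedirs(out_dir, exist_ok=True)
    truths: list[GroundTruth] = []
    if series_list is None:
        sim = config.sim if seed is None else dataclasses.replace(config.sim, seed=seed)
        config = dataclasses.replace(config, sim=sim)
        pairs = simulate_cohort(sim)
        series_list = [s for s, _ in pairs]
        truths = [t for _, t in pairs]
        cohort_dir = os.path.join(out_dir, "cohort")
        bsio.write_cohort(series_list, cohort_dir)
        write_ground_truth(truths, os.path.join(out_dir, "ground_truth.csv"))

    frame, audit = build_cohort_frame(series_list, config)
    if frame.empty:
        raise ValueError("empty cohort: nothing to analyze")

    flat = frame.copy()
    flat.columns = ["%s_%s" % c for c in flat.columns]
    flat.to_csv(os.path.join(out_dir, "patient_metrics.csv"))
    write_audit_log(audit, os.path.join(out_dir, "audit_log.csv"))

    summary = summarize_cohort(frame, config)
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    from .report import render_tables, save_plots

    with open(os.path.join(out_dir, "tables.txt"), "w") as fh:
        fh.write(render_tables(summary))
    if config.make_plots:
        save_plots(frame, os.path.join(out_dir, "plots"))

    return StudyBundle(out_dir=out_dir, frame=frame, summary=summary,
                       audit=audit, ground_truth=truths)
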