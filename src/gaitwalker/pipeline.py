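"""End-to-end orchestration: simulate -> process -> model -> report.

``run_pipeline`` executes the full study flow on a synthetic cohort —
force-stream generation, daily FSI trajectories and the cohort symmetry
table, haptic-event simulation, fall-detection validation, the EMG Day-1 vs
Day-15 comparison, Gaussian-process trajectory fits, and the stride-
variability group comparison — writing every stage artifact plus one
consolidated JSON report. Identical seeds yield byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import emg as emg_mod
from . import feedback, falls, gpr, io, stride, synth, symmetry
from .symmetry import round_half_up

__all__ = ["GPRSettings", "RunConfig", "RunReport", "PipelineStageError",
           "default_run_config", "run_pipeline", "render_table4_report", "table4_csv",
           "validate_stream_file"]

log = logging.getLogger("gaitwalker.pipeline")

validate_stream_file = io.validate_stream_file  # re-export at the pipeline surface


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and offending context."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"pipeline stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass(frozen=True)
class GPRSettings:
    """Trajectory-model settings: pooled-series size, split and optimizer."""

    series_points: int = 1200
    series_noise_sd: float = 0.01
    split_fraction: float = 0.8
    n_restarts: int = 4
    maxiter: int = 120


@dataclass(frozen=True)
class RunConfig:
    cohort: synth.CohortConfig
    haptic: feedback.HapticConfig = feedback.HapticConfig()
    filter_spec: emg_mod.FilterSpec = emg_mod.FilterSpec()
    fall_thresholds: falls.FallThresholds = falls.FallThresholds()
    gpr_settings: GPRSettings = GPRSettings()
    output_dir: str = "results/run"
    master_seed: int = 0
    emg_duration_s: float = 10.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the analytic configuration (where the artifacts are
        written does not change what they contain)."""
        payload = self.to_dict()
        payload.pop("output_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    cohort_summary: symmetry.CohortSummary
    emg_result: emg_mod.PairedTestResult
    gpr_reports: dict  # channel -> FitReport
    event_totals: dict  # day -> haptic events across the cohort
    fall_validation: dict
    stride_comparison: stride.VarianceComparison
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "cohort_summary": dataclasses.asdict(self.cohort_summary),
            "emg_result": dataclasses.asdict(self.emg_result),
            "gpr_reports": {
                ch: {"r_squared": r.r_squared, "rmse": r.rmse,
                     "split_fraction": r.split_fraction,
                     "hyperparams": dataclasses.asdict(r.hyperparams)}
                for ch, r in self.gpr_reports.items()},
            "event_totals": {str(k): v for k, v in self.event_totals.items()},
            "fall_validation": self.fall_validation,
            "stride_comparison": dataclasses.asdict(self.stride_comparison),
            "provenance": self.provenance,
        }


def default_run_config(output_dir, master_seed: int = 0, smoke: bool = False,
                       noise_sd_force: float = 1.0) -> RunConfig:
    """Study-scale configuration (or a fast ``smoke`` variant with shorter
    sessions and a smaller pooled series; the analytics are identical)."""
    if smoke:
        cohort = synth.default_cohort(seed=master_seed, session_length_s=5.0,
                                      noise_sd_force=noise_sd_force)
        gset = GPRSettings(series_points=240, n_restarts=2, maxiter=60)
        emg_s = 2.0
    else:
        cohort = synth.default_cohort(seed=master_seed,
                                      noise_sd_force=noise_sd_force)
        gset = GPRSettings()
        emg_s = 10.0
    return RunConfig(cohort=cohort, gpr_settings=gset, output_dir=str(output_dir),
                     master_seed=master_seed, emg_duration_s=emg_s)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineStageError:
                raise
            except Exception as e:  # noqa: BLE001 - reported with stage name
                raise PipelineStageError(name, str(e)) from e
        return wrapped
    return deco


@_stage("symmetry_analysis")
def _run_symmetry(cfg: RunConfig, out: Path):
    cohort = cfg.cohort
    trajectories = {}
    streams_by_day = {p.subject_id: {} for p in cohort.subjects}
    force_dir = out / "force"
    for p in cohort.subjects:
        fsis = []
        for day in range(1, cohort.n_days + 1):
            df = synth.generate_force_pair(p, day, cohort)
            io.write_stream(df, force_dir / f"{p.subject_id.replace(' ', '_')}_day{day:02d}.csv",
                            "force")
            streams_by_day[p.subject_id][day] = df
            fsis.append(symmetry.session_fsi(df))
        trajectories[p.subject_id] = symmetry.FSITrajectory(
            subject_id=p.subject_id, days=tuple(range(1, cohort.n_days + 1)),
            fsi_values=tuple(fsis))
    rows = [(sid, tr.fsi_values[0], tr.fsi_values[-1])
            for sid, tr in trajectories.items()]
    summary = symmetry.cohort_summary(rows)
    (out / "table4_report.csv").write_text(table4_csv(summary))
    (out / "cohort_summary.json").write_text(json.dumps({
        "mean_fsi_day1": summary.mean_fsi_day1,
        "mean_fsi_day15": summary.mean_fsi_day15,
        "mean_improvement_pct": summary.mean_improvement_pct,
    }, indent=2, sort_keys=True))
    log.info("symmetry stage: %d subjects x %d days", len(cohort.subjects),
             cohort.n_days)
    return summary, trajectories, streams_by_day


@_stage("feedback_loop")
def _run_feedback(cfg: RunConfig, streams_by_day: dict, out: Path):
    thr = feedback.default_threshold(seed=cfg.master_seed)
    totals = {day: 0 for day in range(1, cfg.cohort.n_days + 1)}
    rows = []
    for sid, days in streams_by_day.items():
        for day, df in days.items():
            events = feedback.run_feedback(df, thr, cfg.haptic)
            totals[day] += len(events)
            rows += [{"subject_id": sid, "day": day, "onset_s": e.onset_s,
                      "side": e.side, "duration_ms": e.duration_ms,
                      "triggering_asymmetry": e.triggering_asymmetry}
                     for e in events]
    pd.DataFrame(rows, columns=["subject_id", "day", "onset_s", "side",
                                "duration_ms", "triggering_asymmetry"]
                 ).to_csv(out / "haptic_events.csv", index=False)
    log.info("feedback stage: threshold %.4f, %d events", thr, len(rows))
    return thr, totals


@_stage("fall_detection")
def _run_falls(cfg: RunConfig, out: Path):
    seq = [("upright", 3.0), ("inclined", 2.0), ("falling", 1.5),
           ("inclined", 2.0), ("falling", 1.5)]
    stream, truth = synth.generate_accel_sequence(
        seq, config=cfg.cohort, seed=cfg.master_seed)
    io.write_stream(stream, out / "accel_fivestate.csv", "accel")
    states, alerts = falls.detect_events(stream, cfg.fall_thresholds)
    truth_falls = [t for t, name in truth if name == "falling"]
    pd.DataFrame({"timestamp_s": stream["timestamp_s"], "state": states}
                 ).to_csv(out / "accel_states.csv", index=False)
    result = {"n_programmed_falls": len(truth_falls),
              "n_alerts": len(alerts),
              "alert_onsets_s": [a.onset_s for a in alerts]}
    log.info("fall stage: %d/%d episodes detected", len(alerts), len(truth_falls))
    return result


@_stage("emg_pipeline")
def _run_emg(cfg: RunConfig, out: Path):
    cohort = cfg.cohort
    day1, day15 = [], []
    rows = []
    for p in cohort.subjects:
        for day, sink in ((1, day1), (cohort.n_days, day15)):
            rec = synth.generate_emg(p, day, cohort, duration_s=cfg.emg_duration_s)
            den = emg_mod.wavelet_denoise(emg_mod.bandpass_filter(rec, cfg.filter_spec))
            amp = emg_mod.mean_amplitude(den)
            sink.append(amp)
            rows.append({"subject_id": p.subject_id, "day": day,
                         "mean_amplitude_mv": amp,
                         "rms_mv": emg_mod.rms_amplitude(den)})
    pd.DataFrame(rows).to_csv(out / "emg_amplitudes.csv", index=False)
    result = emg_mod.paired_ttest(day1, day15)
    log.info("emg stage: delta %.3f mV, t(%d) = %.2f", result.delta_mv,
             result.df, result.t_statistic)
    return result


@_stage("gpr_model")
def _run_gpr(cfg: RunConfig, out: Path):
    g = cfg.gpr_settings
    series = synth.generate_fsr_resistance_series(
        cfg.cohort, n_points=g.series_points, noise_sd=g.series_noise_sd)
    series.to_csv(out / "fsr_series.csv", index=False)
    settings = gpr.OptimizerSettings(n_restarts=g.n_restarts,
                                     seed=cfg.master_seed, maxiter=g.maxiter)
    reports, pred_rows = {}, []
    for ch, col in (("fsr1", "r_right"), ("fsr2", "r_left")):
        tx, ty, ex, ey = gpr.chronological_split(series["x"], series[col],
                                                 g.split_fraction)
        model = gpr.fit(tx, ty, settings)
        reports[ch] = gpr.evaluate(model, ex, ey, split_fraction=g.split_fraction)
        pred = gpr.predict(model, series["x"])
        pred_rows.append(pd.DataFrame({
            "channel": ch, "x": series["x"], "mean": pred.mean,
            "ci_low": pred.ci95_low, "ci_high": pred.ci95_high}))
        log.info("gpr stage %s: R^2 = %.4f, RMSE = %.4f", ch,
                 reports[ch].r_squared, reports[ch].rmse)
    pd.concat(pred_rows).to_csv(out / "gpr_predictions.csv", index=False)
    (out / "gpr_metrics.json").write_text(json.dumps(
        {ch: {"r_squared": r.r_squared, "rmse": r.rmse}
         for ch, r in reports.items()}, indent=2, sort_keys=True))
    return reports


@_stage("stride_variability")
def _run_stride(cfg: RunConfig, out: Path, n_per_group: int = 5):
    groups = {}
    for grp in ("control", "als_like"):
        groups[grp] = [
            synth.generate_stride_series(
                synth.default_stride_config(grp, seed=cfg.master_seed * 1000 + i),
                subject_id=f"{grp}_{i}")
            for i in range(n_per_group)]
    rows = [{"subject_id": s.subject_id, "group": s.group, "interval_s": iv}
            for grp in groups.values() for s in grp for iv in s.intervals_s]
    io.write_stream(pd.DataFrame(rows), out / "stride_intervals.csv", "intervals")
    comp = stride.compare_groups(groups["als_like"], groups["control"])
    log.info("stride stage: variance ratio %.2f, p = %.3g", comp.ratio, comp.p_value)
    return comp


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage and write the consolidated report.

    Raises :class:`PipelineStageError` naming the failing stage on any error.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary, trajectories, streams = _run_symmetry(config, out)
    thr, totals = _run_feedback(config, streams, out)
    fall_result = _run_falls(config, out)
    emg_result = _run_emg(config, out)
    gpr_reports = _run_gpr(config, out)
    stride_comp = _run_stride(config, out)
    report = RunReport(
        cohort_summary=summary, emg_result=emg_result, gpr_reports=gpr_reports,
        event_totals=totals, fall_validation=fall_result,
        stride_comparison=stride_comp,
        provenance={"config_hash": config.config_hash(),
                    "master_seed": config.master_seed,
                    "haptic_threshold": thr,
                    "package": "gaitwalker 0.1.0"})
    (out / "run_report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True))
    return report


# ----------------------------------------------------------------- reporting

def table4_csv(summary: symmetry.CohortSummary) -> str:
    lines = ["subject_id,day1_fsi,day15_fsi,improvement_pct"]
    for sid, d1, d15, imp in summary.per_subject_rows:
        lines.append(f"{sid},{round_half_up(d1, 4):.4f},"
                     f"{round_half_up(d15, 4):.4f},{round_half_up(imp, 2):.2f}")
    lines.append(f"Mean,{round_half_up(summary.mean_fsi_day1, 4):.4f},"
                 f"{round_half_up(summary.mean_fsi_day15, 4):.4f},"
                 f"{round_half_up(summary.mean_improvement_pct, 2):.2f}")
    return "\n".join(lines) + "\n"


def render_table4_report(summary: symmetry.CohortSummary) -> str:
    """Human-readable per-subject symmetry table with cohort-mean footer.

    FSI values are printed to 4 decimals and improvements to 2 (half-up),
    matching the study's reporting convention. Row order does not affect the
    footer.
    """
    if not summary.per_subject_rows:
        raise ValueError("empty cohort summary")
    header = f"{'Subject':<12}{'Day 1 FSI':>11}{'Day 15 FSI':>12}{'Improvement %':>15}"
    lines = [header, "-" * len(header)]
    for sid, d1, d15, imp in summary.per_subject_rows:
        lines.append(f"{sid:<12}{round_half_up(d1, 4):>11.4f}"
                     f"{round_half_up(d15, 4):>12.4f}{round_half_up(imp, 2):>15.2f}")
    lines.append("-" * len(header))
    lines.append(f"{'Mean':<12}{round_half_up(summary.mean_fsi_day1, 4):>11.4f}"
                 f"{round_half_up(summary.mean_fsi_day15, 4):>12.4f}"
                 f"{round_half_up(summary.mean_improvement_pct, 2):>15.2f}")
    return "\n".join(lines)
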