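"""Closed-loop vibrotactile feedback simulation.

The device compares left and right handle forces in real time and, when the
asymmetry exceeds a calibrated threshold, drives a short vibration pulse on
the *heavier* side to cue the user to unload it. This module reproduces the
trigger logic off-line: threshold calibration as the mean of observed
asymmetry instances, and an event scanner with per-side refractory windows
and a latency budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .symmetry import FORCE_FLOOR_N

__all__ = [
    "HapticConfig",
    "ThresholdCalibration",
    "FeedbackEvent",
    "calibrate_threshold",
    "default_threshold",
    "run_feedback",
    "session_summary",
]


@dataclass(frozen=True)
class HapticConfig:
    """Vibrotactile stimulus parameters and the feedback-loop latency budget.

    The stimulus parameters (100 Hz, 1.5 g, 300 ms) are carried as metadata;
    only the pulse duration and latency budget affect the simulated event
    train. ``trigger_mode`` selects the trigger statistic: ``"fsi"`` uses the
    normalized per-sample asymmetry |F_R-F_L|/(F_R+F_L) (load-insensitive,
    default); ``"raw_difference"`` uses |F_R-F_L| in newtons.
    """

    vibration_frequency_hz: float = 100.0
    amplitude_g: float = 1.5
    duration_ms: float = 300.0
    max_latency_ms: float = 120.0
    trigger_mode: str = "fsi"

    def __post_init__(self):
        for name in ("vibration_frequency_hz", "amplitude_g", "duration_ms",
                     "max_latency_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.trigger_mode not in ("fsi", "raw_difference"):
            raise ValueError("trigger_mode must be 'fsi' or 'raw_difference'")


@dataclass(frozen=True)
class ThresholdCalibration:
    samples: tuple
    threshold: float


@dataclass(frozen=True)
class FeedbackEvent:
    """One vibration pulse: onset at the threshold-crossing sample."""

    onset_s: float
    side: str  # "left" or "right": the heavier side, cued to unload
    duration_ms: float
    triggering_asymmetry: float
    latency_ms: float  # simulated sense-to-actuation delay, within budget


def calibrate_threshold(asymmetry_samples) -> ThresholdCalibration:
    """Threshold = arithmetic mean of observed asymmetry instances.

    Mirrors the pilot calibration procedure: asymmetry recorded across many
    instances under varying load, threshold set to the average.
    """
    samples = np.asarray(list(asymmetry_samples), dtype=float)
    if samples.size == 0:
        raise ValueError("calibration requires at least one asymmetry sample")
    if np.any(samples < 0) or np.any(samples > 1):
        raise ValueError("asymmetry samples must lie in [0, 1]")
    return ThresholdCalibration(samples=tuple(samples.tolist()),
                                threshold=float(samples.mean()))


def default_threshold(seed: int = 0, n_subjects: int = 5, n_instances: int = 100) -> float:
    """Ship-default threshold from a seeded synthetic calibration set.

    Emulates the bench calibration (5 testers x 100 instances under varying
    load): independent uniform left/right loads give a broad spread of
    instantaneous asymmetry whose mean defines the universal threshold.
    """
    rng = np.random.default_rng([int(seed), 71])
    loads = rng.uniform(1.0, 80.0, size=(n_subjects * n_instances, 2))
    fsi = np.abs(loads[:, 0] - loads[:, 1]) / loads.sum(axis=1)
    return calibrate_threshold(fsi).threshold


def run_feedback(
    stream: pd.DataFrame,
    threshold: float,
    config: HapticConfig = HapticConfig(),
    force_floor_n: float = FORCE_FLOOR_N,
) -> list:
    """Scan a force stream and emit haptic events.

    An event opens at the first sample whose trigger statistic exceeds
    ``threshold`` and is assigned to the heavier side; that side cannot
    retrigger until the pulse window (``duration_ms``) has elapsed. The
    simulated actuation lags the crossing by one sample period plus a fixed
    25 ms processing delay, kept within the latency budget.
    """
    t = np.asarray(stream["timestamp_s"], float)
    if len(t) and np.any(np.diff(t) < 0):
        raise ValueError("force stream timestamps must be sorted")
    if config.trigger_mode == "fsi" and not (0 < threshold < 1):
        raise ValueError("normalized threshold must lie in (0, 1)")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    fr = np.asarray(stream["f_right_n"], float)
    fl = np.asarray(stream["f_left_n"], float)
    total = fr + fl
    if config.trigger_mode == "fsi":
        stat = np.zeros_like(total)
        contact = ~((fr < force_floor_n) & (fl < force_floor_n)) & (total > 0)
        stat[contact] = np.abs(fr[contact] - fl[contact]) / total[contact]
    else:
        stat = np.abs(fr - fl)

    period = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    latency_ms = min(period * 1000.0 + 25.0, config.max_latency_ms)
    window_s = config.duration_ms / 1000.0
    busy_until = {"left": -np.inf, "right": -np.inf}
    events = []
    for i in np.flatnonzero(stat > threshold):
        side = "right" if fr[i] >= fl[i] else "left"
        if t[i] < busy_until[side]:
            continue
        events.append(FeedbackEvent(onset_s=float(t[i]), side=side,
                                    duration_ms=config.duration_ms,
                                    triggering_asymmetry=float(stat[i]),
                                    latency_ms=latency_ms))
        busy_until[side] = t[i] + window_s
    return events


def session_summary(events) -> dict:
    """Per-session event statistics for the JSON log."""
    events = list(events)
    return {
        "n_events": len(events),
        "n_left": sum(e.side == "left" for e in events),
        "n_right": sum(e.side == "right" for e in events),
        "mean_latency_ms": float(np.mean([e.latency_ms for e in events])) if events else None,
        "mean_triggering_asymmetry": float(
            np.mean([e.triggering_asymmetry for e in events])) if events else None,
    }
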