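"""Force-symmetry analytics for bilateral handlebar load streams.

The central quantity is the Robinson-style Force Symmetry Index

    FSI = |F_R - F_L| / (F_R + F_L)

computed from the right- and left-hand vertical forces applied to the walker
handles. FSI is 0 for perfectly symmetric loading and 1 when one hand carries
the entire load. A rehabilitation program is summarized by one FSI value per
day (the FSI of the session-mean forces), the per-subject percentage
improvement between the first and last day, and cohort-level means.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "UndefinedSymmetryError",
    "CalibrationCurve",
    "FSITrajectory",
    "CohortSummary",
    "compute_fsi",
    "session_fsi",
    "improvement_percent",
    "cohort_summary",
    "interlimb_difference",
    "adc_to_force",
    "round_half_up",
]

#: Forces (N) below which a sample is treated as "no hand contact" when both
#: channels are simultaneously under the floor; FSI is undefined at zero load.
FORCE_FLOOR_N = 0.5

ADC_MAX = 1023


class UndefinedSymmetryError(ValueError):
    """Raised when FSI is requested for a zero-total-force input."""


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, matching printed report conventions."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def compute_fsi(f_right: float, f_left: float) -> float:
    """Force Symmetry Index |F_R - F_L| / (F_R + F_L) of a force pair.

    Parameters
    ----------
    f_right, f_left : float
        Non-negative right/left hand forces (any common unit).

    Returns
    -------
    float in [0, 1]; 0 = perfect symmetry, 1 = total asymmetry.
    """
    fr = float(f_right)
    fl = float(f_left)
    if fr < 0 or fl < 0:
        raise ValueError(f"forces must be non-negative, got ({fr}, {fl})")
    total = fr + fl
    if total <= 0:
        raise UndefinedSymmetryError("FSI undefined: both forces are zero")
    return abs(fr - fl) / total


def session_fsi(stream: pd.DataFrame, force_floor_n: float = FORCE_FLOOR_N) -> float:
    """Daily FSI of a force stream: FSI of the session-mean forces.

    Samples where *both* channels are below ``force_floor_n`` are treated as
    non-contact and excluded from the means. Aggregating as FSI-of-means (not
    mean-of-FSI) yields one robust value per session even when individual
    samples carry near-zero load.

    Parameters
    ----------
    stream : DataFrame with columns ``f_right_n`` and ``f_left_n``.
    """
    if len(stream) == 0:
        raise UndefinedSymmetryError("empty force stream")
    fr = np.asarray(stream["f_right_n"], dtype=float)
    fl = np.asarray(stream["f_left_n"], dtype=float)
    contact = ~((fr < force_floor_n) & (fl < force_floor_n))
    if not contact.any():
        raise UndefinedSymmetryError("no sample with positive total force")
    return compute_fsi(fr[contact].mean(), fl[contact].mean())


def improvement_percent(fsi_day1: float, fsi_day15: float) -> float:
    """Percentage reduction in FSI between program start and end.

    Defined as ``100 * (day1 - day15) / day1``; this reproduces every
    per-subject improvement value in the pilot-study report table.
    Returned unrounded; reports round half-up to 2 decimals.
    """
    if fsi_day1 <= 0:
        raise ValueError("improvement undefined for non-positive baseline FSI")
    return 100.0 * (fsi_day1 - fsi_day15) / fsi_day1


@dataclass(frozen=True)
class CalibrationCurve:
    """Piecewise-linear mapping from known reference loads to ADC readings."""

    reference_loads_n: tuple
    adc_readings: tuple

    def __post_init__(self):
        loads = np.asarray(self.reference_loads_n, dtype=float)
        adc = np.asarray(self.adc_readings, dtype=float)
        if loads.size != adc.size or loads.size < 2:
            raise ValueError("calibration needs >= 2 matched (load, adc) points")
        if not (np.diff(loads) > 0).all():
            raise ValueError("reference loads must be strictly increasing")
        if not (np.diff(adc) > 0).all():
            raise ValueError("adc readings must be strictly increasing")


#: Mildly saturating default curve typical of a thin-film force sensor read
#: through a voltage divider into a 10-bit ADC.
DEFAULT_CALIBRATION = CalibrationCurve(
    reference_loads_n=(0.0, 10.0, 25.0, 50.0, 100.0),
    adc_readings=(0.0, 180.0, 400.0, 700.0, 1023.0),
)


def adc_to_force(adc, curve: CalibrationCurve = DEFAULT_CALIBRATION):
    """Map ADC counts to newtons by interpolating the calibration curve.

    Queries outside the calibrated ADC range of the curve are clamped to the
    end loads; values outside the converter's physical range [0, 1023] are
    rejected.
    """
    a = np.asarray(adc, dtype=float)
    if np.any(a < 0) or np.any(a > ADC_MAX):
        raise ValueError(f"ADC counts must lie in [0, {ADC_MAX}]")
    out = np.interp(a, np.asarray(curve.adc_readings, float),
                    np.asarray(curve.reference_loads_n, float))
    return float(out) if np.isscalar(adc) else out


@dataclass(frozen=True)
class FSITrajectory:
    """Per-day FSI series for one subject."""

    subject_id: str
    days: tuple
    fsi_values: tuple

    def __post_init__(self):
        days = np.asarray(self.days)
        vals = np.asarray(self.fsi_values, dtype=float)
        if days.size != vals.size:
            raise ValueError("days and fsi_values must have equal length")
        if days.size and not (np.diff(days) > 0).all():
            raise ValueError("days must be strictly increasing")
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("FSI values must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSummary:
    mean_fsi_day1: float
    mean_fsi_day15: float
    mean_improvement_pct: float
    per_subject_rows: tuple = field(default_factory=tuple)
    # rows: (subject_id, day1, day15, improvement_pct)


def cohort_summary(rows) -> CohortSummary:
    """Cohort means of baseline FSI, final FSI and per-subject improvement.

    Parameters
    ----------
    rows : iterable of (subject_id, fsi_day1, fsi_day15) or (fsi_day1, fsi_day15)
    """
    rows = list(rows)
    if not rows:
        raise ValueError("cohort_summary requires at least one subject row")
    out = []
    for i, row in enumerate(rows):
        if len(row) == 3:
            sid, d1, d15 = row
        else:
            d1, d15 = row
            sid = f"Subject {i + 1}"
        out.append((str(sid), float(d1), float(d15), improvement_percent(d1, d15)))
    d1s = np.array([r[1] for r in out])
    d15s = np.array([r[2] for r in out])
    imps = np.array([r[3] for r in out])
    return CohortSummary(
        mean_fsi_day1=float(d1s.mean()),
        mean_fsi_day15=float(d15s.mean()),
        mean_improvement_pct=float(imps.mean()),
        per_subject_rows=tuple(out),
    )


def interlimb_difference(daily_streams: dict) -> pd.Series:
    """Mean signed right-minus-left channel difference per day.

    Parameters
    ----------
    daily_streams : mapping day -> force stream DataFrame. The difference is
        taken on the ``f_right_n``/``f_left_n`` columns (mirrors the plotted
        average inter-sensor voltage differential when fed ADC columns via a
        renamed frame).

    Returns
    -------
    pandas.Series indexed by day, preserving sign.
    """
    if not daily_streams:
        raise ValueError("no daily streams provided")
    vals = {}
    for day, df in sorted(daily_streams.items()):
        if len(df) == 0:
            raise ValueError(f"empty stream for day {day}")
        vals[day] = float((np.asarray(df["f_right_n"], float)
                           - np.asarray(df["f_left_n"], float)).mean())
    return pd.Series(vals, name="interlimb_diff")
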