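"""Walker-instability detection from tri-axial acceleration.

Orientation is estimated from the gravity direction: with the device z-axis
vertical (right-handed frame, z up), the tilt angle of a sample
a = (ax, ay, az) is arccos(az / |a|). Samples are classified as upright /
inclined / falling by tilt thresholds, with a free-fall override when the
acceleration magnitude collapses. The module flags *walker* instability; it
does not claim to detect user falls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "FallThresholds",
    "AlertEvent",
    "tilt_angle",
    "classify_state",
    "detect_events",
]

STATES = ("upright", "inclined", "falling")


@dataclass(frozen=True)
class FallThresholds:
    """Classification thresholds.

    incline_deg / fall_deg : tilt boundaries (upright < incline_deg <=
        inclined < fall_deg <= falling).
    freefall_floor_g : magnitude below which a sample is falling regardless
        of tilt (free-fall signature).
    """

    incline_deg: float = 15.0
    fall_deg: float = 60.0
    freefall_floor_g: float = 0.5

    def __post_init__(self):
        if not (0 < self.incline_deg < self.fall_deg <= 180):
            raise ValueError(
                f"inconsistent thresholds: incline {self.incline_deg} must be "
                f"< fall {self.fall_deg}"
            )
        if self.freefall_floor_g < 0:
            raise ValueError("free-fall floor must be non-negative")


@dataclass(frozen=True)
class AlertEvent:
    """One audible-alert event for a debounced falling episode."""

    onset_s: float
    state: str
    tilt_deg: float


def tilt_angle(ax, ay, az):
    """Tilt of the acceleration vector from the vertical (z) axis, degrees.

    Vectorized; invariant to positive scaling of the vector. Zero-magnitude
    vectors are rejected (free fall is handled by the magnitude rule, not by
    tilt).
    """
    ax = np.asarray(ax, float)
    ay = np.asarray(ay, float)
    az = np.asarray(az, float)
    mag = np.sqrt(ax**2 + ay**2 + az**2)
    if np.any(mag == 0):
        raise ValueError("tilt undefined for zero-magnitude acceleration")
    c = np.clip(az / mag, -1.0, 1.0)
    out = np.degrees(np.arccos(c))
    return float(out) if out.ndim == 0 else out


def classify_state(tilt_deg, magnitude_g, thresholds: FallThresholds = FallThresholds()):
    """Classify samples as upright / inclined / falling.

    falling if tilt >= fall_deg OR magnitude < freefall_floor_g;
    inclined if incline_deg <= tilt < fall_deg; upright otherwise.
    """
    tilt = np.asarray(tilt_deg, float)
    mag = np.asarray(magnitude_g, float)
    if np.any(tilt < 0) or np.any(tilt > 180):
        raise ValueError("tilt must lie in [0, 180] degrees")
    if np.any(mag < 0):
        raise ValueError("magnitude must be non-negative")
    falling = (tilt >= thresholds.fall_deg) | (mag < thresholds.freefall_floor_g)
    inclined = ~falling & (tilt >= thresholds.incline_deg)
    out = np.where(falling, "falling", np.where(inclined, "inclined", "upright"))
    return str(out) if out.ndim == 0 else out


def _gravity_lowpass(x: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    # Zero-phase 2nd-order low-pass isolates the gravity component from gait
    # impact spikes; short streams are passed through untouched.
    sos = sps.butter(2, cutoff_hz, btype="low", fs=fs, output="sos")
    padlen = 3 * 2 * 2  # conservative for a 2nd-order sos section pair
    if len(x) <= 3 * padlen:
        return x
    return sps.sosfiltfilt(sos, x)


def detect_events(
    stream: pd.DataFrame,
    thresholds: FallThresholds = FallThresholds(),
    debounce_ms: float = 200.0,
    gravity_cutoff_hz: float = 2.0,
):
    """Scan an accelerometer stream and emit one alert per falling episode.

    Parameters
    ----------
    stream : DataFrame with columns timestamp_s, ax_g, ay_g, az_g, ordered in
        time.
    debounce_ms : a falling episode must persist at least this long before an
        alert is raised (suppresses single-sample transients).

    Returns
    -------
    (states, alerts) : per-sample state array (after gravity low-pass) and a
        list of :class:`AlertEvent`, one per debounced contiguous falling run.
    """
    t = np.asarray(stream["timestamp_s"], float)
    if len(t) == 0:
        raise ValueError("empty accelerometer stream")
    if np.any(np.diff(t) < 0):
        raise ValueError("accelerometer stream timestamps must be sorted")
    fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    ax = _gravity_lowpass(np.asarray(stream["ax_g"], float), fs, gravity_cutoff_hz)
    ay = _gravity_lowpass(np.asarray(stream["ay_g"], float), fs, gravity_cutoff_hz)
    az = _gravity_lowpass(np.asarray(stream["az_g"], float), fs, gravity_cutoff_hz)
    mag = np.sqrt(ax**2 + ay**2 + az**2)
    # guard against exactly-zero filtered magnitude (classified falling anyway)
    safe = mag > 0
    tilt = np.zeros_like(mag)
    tilt[safe] = np.degrees(np.arccos(np.clip(az[safe] / mag[safe], -1, 1)))
    states = classify_state(tilt, mag, thresholds)

    alerts = []
    min_dur = debounce_ms / 1000.0
    falling = states == "falling"
    i = 0
    n = len(falling)
    while i < n:
        if falling[i]:
            j = i
            while j + 1 < n and falling[j + 1]:
                j += 1
            if t[j] - t[i] >= min_dur:
                alerts.append(AlertEvent(onset_s=float(t[i]), state="falling",
                                         tilt_deg=float(tilt[i])))
            i = j + 1
        else:
            i += 1
    return states, alerts
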