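"""CSV stream schemas, readers/writers and structural validation.

All sensor streams travel as plain CSV with fixed column names:

====================  =================================================
modality              columns
====================  =================================================
force                 timestamp_s, adc_right, adc_left, f_right_n, f_left_n
accel                 timestamp_s, ax_g, ay_g, az_g
emg                   timestamp_s, emg_mv
intervals             subject_id, group, interval_s
====================  =================================================

Writers may drop a JSON sidecar (``<name>.meta.json``) echoing the seed and
configuration that produced the stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SCHEMAS", "ValidationReport", "write_stream", "read_stream",
           "validate_stream_file"]

SCHEMAS = {
    "force": ("timestamp_s", "adc_right", "adc_left", "f_right_n", "f_left_n"),
    "accel": ("timestamp_s", "ax_g", "ay_g", "az_g"),
    "emg": ("timestamp_s", "emg_mv"),
    "intervals": ("subject_id", "group", "interval_s"),
}

ADC_MAX = 1023


@dataclass
class ValidationReport:
    path: str
    modality: str
    n_rows: int = 0
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def write_stream(df: pd.DataFrame, path, modality: str, metadata: dict = None) -> Path:
    if modality not in SCHEMAS:
        raise ValueError(f"unknown modality {modality!r}")
    cols = list(SCHEMAS[modality])
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"stream is missing columns {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df[cols].to_csv(path, index=False)
    if metadata is not None:
        path.with_suffix(".meta.json").write_text(
            json.dumps(metadata, indent=2, sort_keys=True))
    return path


def read_stream(path, modality: str) -> pd.DataFrame:
    if modality not in SCHEMAS:
        raise ValueError(f"unknown modality {modality!r}")
    df = pd.read_csv(path)
    missing = [c for c in SCHEMAS[modality] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def validate_stream_file(path, modality: str) -> ValidationReport:
    """Schema / range / monotonicity check of a stream CSV.

    Errors name the offending rows (0-based, excluding the header).
    """
    if modality not in SCHEMAS:
        raise ValueError(f"unknown modality {modality!r}")
    path = Path(path)
    rep = ValidationReport(path=str(path), modality=modality)
    if not path.exists():
        rep.errors.append("file does not exist")
        return rep
    df = pd.read_csv(path)
    rep.n_rows = len(df)
    missing = [c for c in SCHEMAS[modality] if c not in df.columns]
    if missing:
        rep.errors.append(f"missing columns: {missing}")
        return rep
    if rep.n_rows == 0:
        rep.warnings.append("empty stream")
        return rep

    if "timestamp_s" in df.columns:
        t = df["timestamp_s"].to_numpy(float)
        bad = np.flatnonzero(np.diff(t) < 0)
        if bad.size:
            rep.errors.append(
                f"non-monotone timestamps at rows {bad[:10].tolist()}")
    if modality == "force":
        for col in ("adc_right", "adc_left"):
            v = df[col].to_numpy(float)
            bad = np.flatnonzero((v < 0) | (v > ADC_MAX) | (v != np.rint(v)))
            if bad.size:
                rep.errors.append(
                    f"{col}: values outside integer ADC range [0, {ADC_MAX}] "
                    f"at rows {bad[:10].tolist()}")
        for col in ("f_right_n", "f_left_n"):
            v = df[col].to_numpy(float)
            bad = np.flatnonzero(v < 0)
            if bad.size:
                rep.errors.append(f"{col}: negative forces at rows {bad[:10].tolist()}")
    elif modality == "accel":
        for col in ("ax_g", "ay_g", "az_g"):
            v = df[col].to_numpy(float)
            bad = np.flatnonzero(~np.isfinite(v))
            if bad.size:
                rep.errors.append(f"{col}: non-finite values at rows {bad[:10].tolist()}")
    elif modality == "intervals":
        v = df["interval_s"].to_numpy(float)
        bad = np.flatnonzero(v <= 0)
        if bad.size:
            rep.errors.append(f"interval_s: non-positive at rows {bad[:10].tolist()}")
        bad_g = df.loc[~df["group"].isin(["control", "als_like"])].index
        if len(bad_g):
            rep.errors.append(f"group: unknown labels at rows {list(bad_g[:10])}")
    return rep
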