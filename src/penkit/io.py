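"""Reading and writing pen recordings, indicator tables and clinical scores.

A pen recording lives on disk as a pair of files: a CSV holding the sampled
channels (``time_s, acc_x, acc_y, acc_z, gyr_x, gyr_y, gyr_z, force, label``)
and a JSON sidecar with the session metadata (subject, group, task, allograph,
session, sampling rate, device). Time is stored in seconds; the sampling rate
is both written to the sidecar and re-inferred from the time column, and a
mismatch beyond 0.1% is rejected so silently resampled files cannot slip
through. The label column stores human-readable strings and is mapped to small
integer codes in memory.

Indicator tables are wide CSVs, one row per (subject, session, task,
allograph) execution, with a deterministic column order (alphabetical within
domain, domains in a fixed order), so identical inputs yield byte-identical
files. Clinical scores are one row per subject with empty cells for missing
values; missingness is propagated, never imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, SamplingError, SchemaError, ValidationError

__all__ = [
    "LABELS",
    "LABEL_CODES",
    "DOMAIN_ORDER",
    "RecordingMeta",
    "PenRecording",
    "IndicatorVector",
    "read_recording",
    "write_recording",
    "write_indicator_table",
    "read_indicator_table",
    "indicator_frame",
    "read_clinical",
    "write_clinical",
    "validate_clinical",
    "write_report",
    "read_report",
]

#: word-type label strings in code order (code = index)
LABELS = ("none", "regular", "irregular", "made_up")
LABEL_CODES = {name: i for i, name in enumerate(LABELS)}

GROUPS = ("MCI", "HC")
TASKS = ("list", "text", "pnp")
ALLOGRAPHS = ("cursive", "block", "na")
SESSIONS = ("test", "retest")

#: fixed indicator-domain ordering used for table column layout
DOMAIN_ORDER = ("temporal", "fluency", "force", "tilt", "hf_time", "hf_freq")

RECORDING_COLUMNS = (
    "time_s",
    "acc_x",
    "acc_y",
    "acc_z",
    "gyr_x",
    "gyr_y",
    "gyr_z",
    "force",
    "label",
)

#: relative tolerance between sidecar fs and the fs inferred from time_s
FS_MISMATCH_RTOL = 1e-3
#: absolute tolerance (seconds) on per-step deviation from 1/fs
STEP_ATOL = 1e-6


@dataclass
class RecordingMeta:
    """Session metadata carried in the JSON sidecar."""

    subject: str
    group: str = "HC"
    task: str = "list"
    allograph: str = "na"
    session: str = "test"
    fs_hz: float = 50.0
    device: str = "synthetic-pen"

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}, expected one of {GROUPS}")
        if self.task not in TASKS:
            raise ValidationError(f"unknown task {self.task!r}, expected one of {TASKS}")
        if self.allograph not in ALLOGRAPHS:
            raise ValidationError(
                f"unknown allograph {self.allograph!r}, expected one of {ALLOGRAPHS}"
            )
        if self.session not in SESSIONS:
            raise ValidationError(f"unknown session {self.session!r}, expected one of {SESSIONS}")
        if not self.fs_hz > 0:
            raise ValidationError("fs_hz must be positive")


@dataclass
class PenRecording:
    """A uniformly sampled multichannel pen signal with a word-label track.

    Channels: tri-axial linear acceleration (m/s^2), tri-axial angular
    velocity (deg/s), tip force (arbitrary units, >= 0) and a per-sample
    word-type code, all sharing one 50 Hz (by default) time base.
    """

    time: np.ndarray  # (N,) seconds, uniform step 1/fs
    accel: np.ndarray  # (3, N) m/s^2
    gyro: np.ndarray  # (3, N) deg/s
    force: np.ndarray  # (N,) a.u., >= 0
    label: np.ndarray  # (N,) int codes into LABELS
    meta: RecordingMeta = field(default_factory=lambda: RecordingMeta(subject="anon"))

    @property
    def fs(self) -> float:
        return float(self.meta.fs_hz)

    @property
    def n(self) -> int:
        return int(self.time.shape[0])

    @property
    def duration(self) -> float:
        """Total duration in seconds (last minus first sample time)."""
        return float(self.time[-1] - self.time[0])

    def validate(self) -> "PenRecording":
        self.meta.validate()
        n = self.n
        if n < 2:
            raise ValidationError("a recording needs at least 2 samples")
        for name, arr, shape in (
            ("accel", self.accel, (3, n)),
            ("gyro", self.gyro, (3, n)),
            ("force", self.force, (n,)),
            ("label", self.label, (n,)),
        ):
            if tuple(arr.shape) != shape:
                raise ValidationError(f"{name} has shape {arr.shape}, expected {shape}")
        step = 1.0 / self.fs
        dt = np.diff(self.time)
        if np.any(np.abs(dt - step) > STEP_ATOL):
            worst = float(np.max(np.abs(dt - step)))
            raise SamplingError(
                f"time step deviates from 1/fs={step:.6g}s by up to {worst:.3g}s"
            )
        if np.any(self.force < 0):
            raise ValidationError("force must be non-negative everywhere")
        if self.label.min() < 0 or self.label.max() >= len(LABELS):
            raise ValidationError("label codes outside the known set")
        if self.meta.task != "pnp" and np.any(self.label != 0):
            raise ValidationError("word labels are only allowed for the pnp task")
        return self


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: PenRecording, path: str | Path) -> Path:
    """Write a recording as CSV + JSON sidecar; returns the CSV path."""
    rec.validate()
    path = Path(path)
    label_str = np.asarray(LABELS, dtype=object)[rec.label]
    df = pd.DataFrame(
        {
            "time_s": rec.time,
            "acc_x": rec.accel[0],
            "acc_y": rec.accel[1],
            "acc_z": rec.accel[2],
            "gyr_x": rec.gyro[0],
            "gyr_y": rec.gyro[1],
            "gyr_z": rec.gyro[2],
            "force": rec.force,
            "label": label_str,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")
    _sidecar_path(path).write_text(json.dumps(asdict(rec.meta), indent=2) + "\n")
    return path


def read_recording(path: str | Path) -> PenRecording:
    """Read a CSV + JSON-sidecar recording and validate every invariant."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar}")
    meta = RecordingMeta(**json.loads(sidecar.read_text()))
    df = pd.read_csv(path)
    for col in RECORDING_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"recording CSV is missing required column {col!r}")
    time = df["time_s"].to_numpy(float)
    if len(time) >= 2:
        inferred_fs = 1.0 / float(np.median(np.diff(time)))
        if abs(inferred_fs - meta.fs_hz) > FS_MISMATCH_RTOL * meta.fs_hz:
            raise SamplingError(
                f"sidecar fs={meta.fs_hz:g} Hz but time column implies "
                f"{inferred_fs:g} Hz (mismatch > 0.1%)"
            )
    try:
        label = np.array([LABEL_CODES[str(s)] for s in df["label"]], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - defensive
        raise FormatError(f"unknown label string {exc.args[0]!r}") from exc
    rec = PenRecording(
        time=time,
        accel=df[["acc_x", "acc_y", "acc_z"]].to_numpy(float).T,
        gyro=df[["gyr_x", "gyr_y", "gyr_z"]].to_numpy(float).T,
        force=df["force"].to_numpy(float),
        label=label,
        meta=meta,
    )
    return rec.validate()


# ---------------------------------------------------------------------------
# Indicator tables
# ---------------------------------------------------------------------------

ID_COLUMNS = ("subject", "session", "task", "allograph")


@dataclass
class IndicatorVector:
    """Named indicator values for one (subject, session, task, allograph).

    ``values`` maps indicator name -> float (NaN encodes a missing value);
    ``domains`` maps indicator name -> one of :data:`DOMAIN_ORDER`.
    """

    subject: str
    session: str
    task: str
    allograph: str
    values: dict[str, float]
    domains: dict[str, str]

    def column_order(self) -> list[str]:
        """Deterministic column order: alphabetical within each domain."""
        out: list[str] = []
        for dom in DOMAIN_ORDER:
            out.extend(sorted(k for k, d in self.domains.items() if d == dom))
        leftover = sorted(set(self.values) - set(out))
        return out + leftover

    @property
    def ids(self) -> tuple[str, str, str, str]:
        return (self.subject, self.session, self.task, self.allograph)


def indicator_frame(rows: list[IndicatorVector]) -> pd.DataFrame:
    """Stack indicator vectors into a wide DataFrame with stable columns."""
    if not rows:
        return pd.DataFrame(columns=list(ID_COLUMNS))
    ref = set(rows[0].values)
    for row in rows[1:]:
        if set(row.values) != ref:
            extra = sorted(set(row.values) - ref)
            missing = sorted(ref - set(row.values))
            raise SchemaError(
                f"inconsistent indicator sets: extra={extra}, missing={missing}"
            )
    cols = rows[0].column_order()
    data = {
        "subject": [r.subject for r in rows],
        "session": [r.session for r in rows],
        "task": [r.task for r in rows],
        "allograph": [r.allograph for r in rows],
    }
    for c in cols:
        data[c] = [r.values[c] for r in rows]
    return pd.DataFrame(data)


def write_indicator_table(rows: list[IndicatorVector], path: str | Path) -> Path:
    """Write indicator vectors as a wide CSV with deterministic column order."""
    path = Path(path)
    indicator_frame(rows).to_csv(path, index=False, float_format="%.12g")
    return path


def read_indicator_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Clinical scores
# ---------------------------------------------------------------------------

CLINICAL_SCORES = (
    "MMSE",
    "CDR",
    "CDT",
    "B-ADL",
    "I-ADL",
    "TMT-A",
    "PnP-errors",
    "PnP-errors-R",
    "PnP-errors-I",
    "PnP-errors-MU",
)


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical-score table (one row per subject, NaN = missing)."""
    if "subject" not in df.columns:
        raise SchemaError("clinical table needs a 'subject' column")
    if df["subject"].duplicated().any():
        dup = df.loc[df["subject"].duplicated(), "subject"].tolist()
        raise ValidationError(f"duplicate subject rows: {dup}")
    err_cols = ["PnP-errors-R", "PnP-errors-I", "PnP-errors-MU"]
    present = [c for c in err_cols + ["PnP-errors"] if c in df.columns]
    for c in present:
        if (df[c].dropna() < 0).any():
            raise ValidationError(f"negative error counts in {c}")
    if set(err_cols + ["PnP-errors"]).issubset(df.columns):
        complete = df[err_cols + ["PnP-errors"]].notna().all(axis=1)
        total = df.loc[complete, err_cols].sum(axis=1)
        if not np.allclose(total, df.loc[complete, "PnP-errors"]):
            raise ValidationError("PnP-errors must equal the sum of per-type errors")
    return df


def read_clinical(path: str | Path) -> pd.DataFrame:
    return validate_clinical(pd.read_csv(path))


def write_clinical(df: pd.DataFrame, path: str | Path) -> Path:
    validate_clinical(df)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# JSON reports
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def write_report(report: dict, path: str | Path) -> Path:
    """Serialize an analysis report (plain dict) as indented JSON."""
    path = Path(path)
    path.write_text(json.dumps(_jsonable(report), indent=2) + "\n")
    return path


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
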