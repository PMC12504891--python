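"""Shared fixtures and scripted-recording builders."""

from __future__ import annotations

import numpy as np
import pytest

from penkit.io import PenRecording, RecordingMeta

GRAVITY = 9.81


def make_recording(
    force: np.ndarray,
    fs: float = 50.0,
    accel: np.ndarray | None = None,
    gyro: np.ndarray | None = None,
    label: np.ndarray | None = None,
    task: str = "list",
    **meta_kw,
) -> PenRecording:
    """Build a recording from explicit channel arrays (defaults: static pen)."""
    force = np.asarray(force, dtype=float)
    n = len(force)
    if accel is None:
        accel = np.tile(np.array([[0.0], [0.0], [GRAVITY]]), (1, n))
    if gyro is None:
        gyro = np.zeros((3, n))
    if label is None:
        label = np.zeros(n, dtype=np.int8)
    meta = RecordingMeta(subject="scripted", task=task, fs_hz=fs, **meta_kw)
    return PenRecording(
        time=np.arange(n) / fs, accel=accel, gyro=gyro,
        force=force, label=np.asarray(label, dtype=np.int8), meta=meta,
    ).validate()


def square_wave_force(
    bursts: list[tuple[float, float]], fs: float = 50.0, level: float = 5.0
) -> np.ndarray:
    """Force trace from (on_duration, following_gap_duration) pairs in seconds."""
    parts = []
    for on, gap in bursts:
        parts.append(np.full(int(round(on * fs)), level))
        if gap > 0:
            parts.append(np.zeros(int(round(gap * fs))))
    return np.concatenate(parts)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20261001)
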