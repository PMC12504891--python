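"""Stroke / in-air / pause segmentation of a pen recording.

The pen has no touch sensor: contact with the paper is inferred from the tip
force. A sample is on-sheet when the force crosses a hysteresis band — on
above ``theta_on``, off below ``theta_off = 0.5 * theta_on`` — and runs
shorter than a de-bounce duration are merged into their neighbour. Because the
force channel is in arbitrary units, the default threshold is relative: 5% of
the recording's force range.

Intervals are 0-based, half-open, in samples; durations are reported in
seconds. In-air intervals strictly longer than 2 s count as pauses. Strokes
and in-air intervals jointly partition ``[0, N)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import LabelError, ValidationError
from .io import PenRecording

__all__ = [
    "SegmentationResult",
    "segment_strokes",
    "detect_pauses",
    "split_by_labels",
    "DEFAULT_PAUSE_THRESHOLD_S",
    "DEFAULT_MIN_SEGMENT_S",
]

DEFAULT_PAUSE_THRESHOLD_S = 2.0
DEFAULT_MIN_SEGMENT_S = 0.04  # 2 samples at 50 Hz
DEFAULT_CONTACT_FRACTION = 0.05  # of the force range, when no absolute threshold given

Interval = tuple[int, int]


@dataclass
class SegmentationResult:
    """Partition of a recording into on-sheet strokes and in-air intervals."""

    strokes: list[Interval]
    airs: list[Interval]
    fs: float
    n: int
    pause_threshold_s: float = DEFAULT_PAUSE_THRESHOLD_S
    contact_threshold: float = 0.0
    pauses: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pauses = detect_pauses(self)

    def durations(self, intervals: list[Interval]) -> np.ndarray:
        """Interval durations in seconds."""
        return np.array([(e - s) / self.fs for s, e in intervals], dtype=float)

    @property
    def total_duration(self) -> float:
        return self.n / self.fs

    def check_partition(self) -> None:
        """Raise unless strokes + airs exactly partition [0, n)."""
        merged = sorted(self.strokes + self.airs)
        pos = 0
        for s, e in merged:
            if s != pos or e <= s:
                raise ValidationError("strokes and airs do not partition the recording")
            pos = e
        if pos != self.n:
            raise ValidationError("segmentation does not cover the full recording")


def _hysteresis_contact(force: np.ndarray, theta_on: float, theta_off: float) -> np.ndarray:
    """Per-sample contact state from a force trace with hysteresis.

    State switches on when force > theta_on and off when force < theta_off;
    between the two thresholds the previous state persists. The initial state
    is on iff the first sample exceeds theta_on.
    """
    on = force > theta_on
    off = force < theta_off
    state = np.zeros(len(force), dtype=bool)
    cur = bool(on[0])
    for i in range(len(force)):
        if on[i]:
            cur = True
        elif off[i]:
            cur = False
        state[i] = cur
    return state


def _runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal runs of equal value: list of (start, end, value), half-open."""
    out = []
    start = 0
    for i in range(1, len(mask) + 1):
        if i == len(mask) or mask[i] != mask[start]:
            out.append((start, i, bool(mask[start])))
            start = i
    return out


def _merge_short_runs(mask: np.ndarray, min_samples: int) -> np.ndarray:
    """Flip runs shorter than min_samples into their neighbour, shortest first."""
    mask = mask.copy()
    while True:
        runs = _runs(mask)
        if len(runs) <= 1:
            return mask
        short = [(e - s, idx) for idx, (s, e, _) in enumerate(runs) if e - s < min_samples]
        if not short:
            return mask
        _, idx = min(short)
        s, e, v = runs[idx]
        mask[s:e] = not v
    return mask


def segment_strokes(
    rec: PenRecording,
    contact_threshold: float | None = None,
    min_segment_s: float = DEFAULT_MIN_SEGMENT_S,
    pause_threshold_s: float = DEFAULT_PAUSE_THRESHOLD_S,
) -> SegmentationResult:
    """Segment a recording into strokes and in-air intervals.

    Parameters
    ----------
    rec
        Validated pen recording.
    contact_threshold
        Absolute force level for pen-down (``theta_on``); the release level is
        half of it. ``None`` selects 5% of the recording's force range.
    min_segment_s
        De-bounce: runs shorter than this are merged into their neighbour.
    pause_threshold_s
        In-air intervals strictly longer than this are pauses.
    """
    force = np.asarray(rec.force, dtype=float)
    if contact_threshold is None:
        rng = float(force.max() - force.min())
        contact_threshold = force.min() + DEFAULT_CONTACT_FRACTION * rng if rng > 0 else np.inf
    if not contact_threshold > 0:
        raise ValidationError("contact_threshold must be positive")
    theta_on = float(contact_threshold)
    theta_off = 0.5 * theta_on

    if np.all(force <= theta_off) or not np.isfinite(theta_on):
        # all-air recording: zero strokes, one spanning air interval
        return SegmentationResult(
            strokes=[], airs=[(0, rec.n)], fs=rec.fs, n=rec.n,
            pause_threshold_s=pause_threshold_s, contact_threshold=theta_on,
        )

    contact = _hysteresis_contact(force, theta_on, theta_off)
    min_samples = max(1, int(round(min_segment_s * rec.fs)))
    contact = _merge_short_runs(contact, min_samples)

    strokes, airs = [], []
    for s, e, v in _runs(contact):
        (strokes if v else airs).append((s, e))
    return SegmentationResult(
        strokes=strokes, airs=airs, fs=rec.fs, n=rec.n,
        pause_threshold_s=pause_threshold_s, contact_threshold=theta_on,
    )


def detect_pauses(seg: SegmentationResult) -> list[Interval]:
    """In-air intervals strictly longer than the pause threshold."""
    thr = seg.pause_threshold_s
    return [(s, e) for s, e in seg.airs if (e - s) / seg.fs > thr]


def split_by_labels(rec: PenRecording) -> list[tuple[int, str, PenRecording]]:
    """Split a PnP recording into per-word sub-recordings.

    Returns one ``(word_index, word_type, sub_recording)`` per maximal run of
    identically labelled samples, in temporal order. Unlabelled inter-word
    samples belong to no word.
    """
    from .io import LABELS, RecordingMeta

    if rec.meta.task != "pnp":
        raise LabelError("split_by_labels requires a pnp-task recording")
    if np.all(rec.label == 0):
        raise LabelError("recording has no labelled samples")

    words = []
    idx = 0
    for s, e, _ in _runs(rec.label != 0):
        if rec.label[s] == 0:
            continue
        # a labelled run may switch type without an unlabelled gap
        sub_start = s
        for j in range(s + 1, e + 1):
            if j == e or rec.label[j] != rec.label[sub_start]:
                code = int(rec.label[sub_start])
                meta = RecordingMeta(
                    subject=rec.meta.subject, group=rec.meta.group, task="pnp",
                    allograph=rec.meta.allograph, session=rec.meta.session,
                    fs_hz=rec.meta.fs_hz, device=rec.meta.device,
                )
                sub = PenRecording(
                    time=rec.time[sub_start:j] - rec.time[sub_start],
                    accel=rec.accel[:, sub_start:j],
                    gyro=rec.gyro[:, sub_start:j],
                    force=rec.force[sub_start:j],
                    label=rec.label[sub_start:j],
                    meta=meta,
                )
                words.append((idx, LABELS[code], sub))
                idx += 1
                sub_start = j
    return words
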