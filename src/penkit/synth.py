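"""Synthetic sensorized-pen recordings with the study's statistical structure.

The generator does not attempt letterform realism: the downstream indicators
never look at the written trace, only at force, kinematic and tilt signals.
A recording is rendered from a *schedule* of alternating on-sheet strokes and
in-air gaps:

* **force** — on-sheet bursts at a subject-specific level with occasional
  overshoot spikes, near-zero in the air;
* **angular velocity** — band-limited oscillations (base frequency =
  ``stroke_rate``) during strokes, plus a tremor component at ``tremor_freq``
  whose relative power is ``1 - smoothness``;
* **acceleration** — gravity seen by a pen whose axis makes a slowly varying
  angle ``tilt_mean`` (CV ``tilt_cv``) with the vertical, plus movement
  transients and the same tremor structure.

Gap durations come from two well-separated regimes so the 2-second pause rule
has clean sides: pauses are uniform on 2.2–6 s, ordinary gaps are a scaled
uniform with mean ``gap_dur_mean`` kept below 1.9 s.

Cohorts are drawn hierarchically: per-subject parameters with between-subject
SD ``sigma_between`` (plus a standardized MCI-vs-HC effect), then per-session
parameters with within-subject SD ``sigma_within``, so the true test-retest
ICC of any parameter is ``sb^2 / (sb^2 + sw^2)`` by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GenerationError, ParameterError
from .io import LABEL_CODES, PenRecording, RecordingMeta

__all__ = [
    "SubjectParams",
    "CohortSpec",
    "PnPScript",
    "DEFAULT_PNP_WORDS",
    "Segment",
    "simulate_recording",
    "simulate_pnp_session",
    "simulate_cohort",
    "draw_cohort_params",
    "mci_default_effects",
]

GRAVITY = 9.81  # m/s^2; pen axis = device z-axis
DEFAULT_FS = 50.0

PAUSE_RANGE = (2.2, 6.0)  # seconds, uniform
GAP_UNIFORM = (0.1, 1.5)  # seconds; rescaled so the mean equals gap_dur_mean
GAP_UNIFORM_MEAN = 0.5 * (GAP_UNIFORM[0] + GAP_UNIFORM[1])
MAX_NONPAUSE_GAP_S = 1.9


@dataclass
class SubjectParams:
    """Generator-side counterparts of the handwriting indicators.

    All fields are positive; ``pause_prob`` is a probability and
    ``smoothness`` lies in (0, 1] (fraction of stroke-time kinematic power in
    the base band — lowering it injects tremor-band power and degrades the
    smoothness indicators).
    """

    stroke_rate: float = 3.0  # Hz, base within-stroke oscillation frequency
    stroke_dur_mean: float = 0.5  # s
    gap_dur_mean: float = 0.4  # s
    pause_prob: float = 0.05  # probability a gap comes from the pause regime
    force_level: float = 5.0  # a.u.
    force_overshoot_scale: float = 1.5  # a.u., spike amplitude scale
    tremor_freq: float = 8.0  # Hz
    tremor_amp: float = 0.5  # deg/s, always-on tremor floor
    tilt_mean: float = 35.0  # deg
    tilt_cv: float = 0.08  # dimensionless
    smoothness: float = 0.9  # (0, 1]

    def validate(self, fs: float = DEFAULT_FS) -> "SubjectParams":
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "pause_prob":
                if not 0.0 <= v <= 1.0:
                    raise ParameterError("pause_prob must lie in [0, 1]")
            elif not v > 0:
                raise ParameterError(f"{f.name} must be positive, got {v!r}")
        if not 0.0 < self.smoothness <= 1.0:
            raise ParameterError("smoothness must lie in (0, 1]")
        if self.tremor_freq >= fs / 2:
            raise ParameterError(
                f"tremor_freq={self.tremor_freq} Hz is at or above Nyquist ({fs / 2} Hz)"
            )
        return self


PARAM_FIELDS = tuple(f.name for f in dataclasses.fields(SubjectParams))


def mci_default_effects() -> dict[str, float]:
    """Default standardized MCI-minus-HC shifts (between-subject SD units).

    Directions follow the clinical picture the indicators are built to catch:
    slower tempo with more and longer hesitations, less smooth kinematics, and
    larger pen-inclination variability.
    """
    return {
        "stroke_dur_mean": 0.5,
        "gap_dur_mean": 1.0,
        "pause_prob": 0.8,
        "smoothness": -0.8,
        "tilt_cv": 1.0,
        "stroke_rate": -0.5,
    }


# the 15 dictated PnP items: 7 regular, 3 irregular, 5 made-up, fixed order
DEFAULT_PNP_WORDS: tuple[tuple[str, str], ...] = (
    ("tavolo", "regular"),
    ("cartone", "regular"),
    ("attore", "regular"),
    ("sorella", "regular"),
    ("postini", "regular"),
    ("cuoceva", "regular"),
    ("democratiche", "regular"),
    ("cieco", "irregular"),
    ("nacquero", "irregular"),
    ("conoscenza", "irregular"),
    ("sabomi", "made_up"),
    ("fule", "made_up"),
    ("descia", "made_up"),
    ("sterpanzi", "made_up"),
    ("getrunna", "made_up"),
)


@dataclass
class PnPScript:
    """Ordered dictation items with per-word-type tempo multipliers.

    ``tempo_air`` multiplies intra-word in-air durations (default: irregular
    words are slower in the air); ``tempo_stroke`` multiplies stroke durations.
    """

    items: tuple[tuple[str, str], ...] = DEFAULT_PNP_WORDS
    tempo_air: dict[str, float] = field(default_factory=lambda: {"irregular": 1.5})
    tempo_stroke: dict[str, float] = field(default_factory=dict)

    def type_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, t in self.items:
            out[t] = out.get(t, 0) + 1
        return out


@dataclass
class Segment:
    """One schedule element: an on-sheet stroke or an in-air gap."""

    kind: str  # "stroke" | "air"
    dur: float  # seconds
    label: str = "none"  # word-type label carried by the samples


# ---------------------------------------------------------------------------
# schedule construction
# ---------------------------------------------------------------------------


def _draw_gap(p: SubjectParams, rng: np.random.Generator, tempo: float = 1.0) -> float:
    if rng.random() < p.pause_prob:
        dur = rng.uniform(*PAUSE_RANGE)
    else:
        scale = p.gap_dur_mean / GAP_UNIFORM_MEAN
        dur = min(rng.uniform(*GAP_UNIFORM) * scale, MAX_NONPAUSE_GAP_S)
    return dur * tempo


def _draw_stroke(p: SubjectParams, rng: np.random.Generator, tempo: float = 1.0) -> float:
    return max(0.1, rng.normal(p.stroke_dur_mean, 0.2 * p.stroke_dur_mean)) * tempo


def _free_schedule(p: SubjectParams, duration: float, rng: np.random.Generator) -> list[Segment]:
    """Alternating stroke/gap schedule filling roughly ``duration`` seconds."""
    if duration < 2.0:
        raise GenerationError("duration must be at least 2 s for list/text tasks")
    segs: list[Segment] = []
    t = 0.0
    while t < duration:
        d = _draw_stroke(p, rng)
        segs.append(Segment("stroke", d))
        t += d
        if t >= duration:
            break
        g = _draw_gap(p, rng)
        segs.append(Segment("air", g))
        t += g
    if segs and segs[-1].kind == "air":
        segs.pop()
    if not any(s.kind == "stroke" for s in segs):
        raise GenerationError("duration too short to fit a single stroke")
    return segs


def _word_schedule(
    p: SubjectParams, script: PnPScript, rng: np.random.Generator
) -> list[Segment]:
    """Dictation schedule: labelled word blocks separated by unlabelled gaps."""
    if not script.items:
        raise GenerationError("empty PnP script")
    segs: list[Segment] = []
    for w_idx, (word, wtype) in enumerate(script.items):
        air_tempo = script.tempo_air.get(wtype, 1.0)
        stroke_tempo = script.tempo_stroke.get(wtype, 1.0)
        n_strokes = max(2, round(len(word) / 2))
        for k in range(n_strokes):
            segs.append(Segment("stroke", _draw_stroke(p, rng, stroke_tempo), wtype))
            if k < n_strokes - 1:
                segs.append(Segment("air", _draw_gap(p, rng, air_tempo), wtype))
        if w_idx < len(script.items) - 1:
            # inter-word gap: dictation pacing, unlabelled
            segs.append(Segment("air", rng.uniform(1.0, 1.8), "none"))
    return segs


# ---------------------------------------------------------------------------
# signal rendering
# ---------------------------------------------------------------------------


def _slow_unit_oscillation(n: int, fs: float, rng: np.random.Generator, n_comp: int = 3,
                           fband: tuple[float, float] = (0.1, 0.8)) -> np.ndarray:
    """Sum of low-frequency sinusoids with random phase, normalized to RMS 1."""
    t = np.arange(n) / fs
    x = np.zeros(n)
    for _ in range(n_comp):
        f = rng.uniform(*fband)
        x += rng.uniform(0.5, 1.0) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _render(
    schedule: list[Segment],
    p: SubjectParams,
    meta: RecordingMeta,
    rng: np.random.Generator,
    fs: float = DEFAULT_FS,
    noise: float = 1.0,
    accel_transient_amp: float = 1.5,
    gyro_amp: float = 30.0,
) -> PenRecording:
    """Render a schedule into channel signals.

    ``noise`` scales every stochastic texture (force jitter, spikes,
    measurement noise); 0 gives fully deterministic channel shapes given the
    oscillation phases. ``accel_transient_amp`` (m/s^2) and ``gyro_amp``
    (deg/s) set movement-transient amplitudes; 0 disables movement content.
    """
    lens = [max(1, int(round(s.dur * fs))) for s in schedule]
    n = int(np.sum(lens))
    if n < 2:
        raise GenerationError("schedule renders to fewer than 2 samples")
    t = np.arange(n) / fs

    stroke_mask = np.zeros(n, dtype=bool)
    label = np.zeros(n, dtype=np.int8)
    pos = 0
    for seg, ln in zip(schedule, lens):
        if seg.kind == "stroke":
            stroke_mask[pos : pos + ln] = True
        label[pos : pos + ln] = LABEL_CODES[seg.label]
        pos += ln
    if meta.task != "pnp":
        label[:] = 0

    # ---- force ----------------------------------------------------------
    force = np.zeros(n)
    jitter = rng.standard_normal(n)
    # 5-sample moving average keeps jitter below the hysteresis band
    kernel = np.ones(5) / 5.0
    jitter = np.convolve(jitter, kernel, mode="same")
    force[stroke_mask] = p.force_level * (1.0 + 0.04 * noise * jitter[stroke_mask])
    force[~stroke_mask] = np.abs(0.01 * noise * p.force_level * jitter[~stroke_mask])
    # overshoot spikes: occasional Gaussian bumps inside strokes
    pos = 0
    for seg, ln in zip(schedule, lens):
        if seg.kind == "stroke" and ln >= 5 and rng.random() < 0.4 * min(noise, 1.0):
            center = pos + rng.integers(2, ln - 2)
            width = max(1.0, 0.05 * fs)
            amp = p.force_overshoot_scale * rng.uniform(0.5, 1.5)
            idx = np.arange(max(0, center - 4 * int(width)), min(n, center + 4 * int(width)))
            force[idx] += amp * np.exp(-0.5 * ((idx - center) / width) ** 2)
        pos += ln
    np.clip(force, 0.0, None, out=force)

    # ---- angular velocity ------------------------------------------------
    env = np.where(stroke_mask, 1.0, 0.1)
    tremor_rel = max(0.0, 1.0 - p.smoothness)
    # amplitude ratio giving tremor relative power (1 - smoothness)
    tremor_ratio = np.sqrt(tremor_rel / max(p.smoothness, 1e-9))
    phases = rng.uniform(0, 2 * np.pi, size=6)
    f0 = p.stroke_rate
    gx = gyro_amp * env * np.sin(2 * np.pi * f0 * t + phases[0])
    gy = 0.8 * gyro_amp * env * np.sin(2 * np.pi * 1.3 * f0 * t + phases[1])
    gz = 0.2 * gyro_amp * env * np.sin(2 * np.pi * 0.7 * f0 * t + phases[2])
    tremor = np.sin(2 * np.pi * p.tremor_freq * t + phases[3])
    gx = gx + gyro_amp * tremor_ratio * env * tremor / np.sqrt(2)
    gy = gy + 0.8 * gyro_amp * tremor_ratio * env * np.sin(
        2 * np.pi * p.tremor_freq * t + phases[4]
    ) / np.sqrt(2)
    gx = gx + p.tremor_amp * tremor  # always-on tremor floor
    gyro = np.vstack([gx, gy, gz])
    gyro = gyro + 0.2 * noise * rng.standard_normal((3, n))

    # ---- acceleration ----------------------------------------------------
    if p.tilt_cv > 0:
        theta = p.tilt_mean * (1.0 + p.tilt_cv * _slow_unit_oscillation(n, fs, rng))
    else:
        theta = np.full(n, p.tilt_mean)
    theta = np.clip(theta, 0.0, 179.0)
    phi = rng.uniform(0, 2 * np.pi) + 0.4 * _slow_unit_oscillation(n, fs, rng, 2, (0.05, 0.3))
    th, ph = np.deg2rad(theta), phi
    accel = GRAVITY * np.vstack(
        [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
    )
    if accel_transient_amp > 0:
        senv = np.where(stroke_mask, 1.0, 0.0)
        for axis in range(3):
            fm = rng.uniform(2.5, 5.0)
            accel[axis] += accel_transient_amp * senv * np.sin(
                2 * np.pi * fm * t + rng.uniform(0, 2 * np.pi)
            )
            accel[axis] += (
                accel_transient_amp
                * tremor_ratio
                * senv
                * np.sin(2 * np.pi * p.tremor_freq * t + rng.uniform(0, 2 * np.pi))
                / np.sqrt(3)
            )
        accel += 0.05 * noise * rng.standard_normal((3, n))

    return PenRecording(
        time=t, accel=accel, gyro=gyro, force=force, label=label, meta=meta
    ).validate()


# ---------------------------------------------------------------------------
# public simulation ops
# ---------------------------------------------------------------------------


def simulate_recording(
    p: SubjectParams,
    task: str = "list",
    duration: float | None = 20.0,
    script: PnPScript | None = None,
    seed: int | np.random.Generator = 0,
    schedule: list[Segment] | None = None,
    meta: RecordingMeta | None = None,
    fs: float = DEFAULT_FS,
    noise: float = 1.0,
    accel_transient_amp: float = 1.5,
    gyro_amp: float = 30.0,
) -> PenRecording:
    """Simulate one task execution.

    For ``list``/``text`` a stroke/gap schedule is drawn to fill ``duration``
    seconds; for ``pnp`` a :class:`PnPScript` drives labelled word blocks.
    An explicit ``schedule`` overrides both, which is how tests script exact
    stroke/gap layouts (the schedule is then the segmentation oracle).
    """
    p.validate(fs)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if meta is None:
        meta = RecordingMeta(subject="sim", task=task, fs_hz=fs)
    if schedule is None:
        if task == "pnp":
            schedule = _word_schedule(p, script or PnPScript(), rng)
        else:
            if duration is None:
                raise GenerationError("duration required for list/text tasks")
            schedule = _free_schedule(p, duration, rng)
    return _render(
        schedule, p, meta, rng, fs=fs, noise=noise,
        accel_transient_amp=accel_transient_amp, gyro_amp=gyro_amp,
    )


def simulate_pnp_session(
    p: SubjectParams,
    script: PnPScript | None = None,
    seed: int | np.random.Generator = 0,
    meta: RecordingMeta | None = None,
    fs: float = DEFAULT_FS,
    noise: float = 1.0,
) -> PenRecording:
    """Simulate a full dictation session: one labelled block per word."""
    script = script or PnPScript()
    if meta is None:
        meta = RecordingMeta(subject="sim", task="pnp", fs_hz=fs)
    meta.task = "pnp"
    return simulate_recording(
        p, task="pnp", script=script, seed=seed, meta=meta, fs=fs, noise=noise
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Study-structure description for a two-group, two-session cohort.

    ``effect`` maps a :class:`SubjectParams` field to the standardized
    MCI-minus-HC shift in between-subject SD units. ``sigma_between`` and
    ``sigma_within`` are relative (coefficient-of-variation) SDs — scalars
    apply to every field, dicts per field. Within-subject SD drives
    test-retest reliability: the true ICC of a parameter is
    ``sb^2 / (sb^2 + sw^2)``.
    """

    n_mci: int = 45
    n_hc: int = 45
    effect: dict[str, float] = field(default_factory=dict)
    sigma_between: float | dict[str, float] = 0.15
    sigma_within: float | dict[str, float] = 0.05
    allograph_probs: tuple[float, float, float] = (0.62, 0.33, 0.05)  # cursive/block/na
    allograph_switch_prob: float = 0.0
    tasks: tuple[str, ...] = ("list", "text", "pnp")
    task_durations: dict[str, float] = field(
        default_factory=lambda: {"list": 30.0, "text": 45.0}
    )
    base: SubjectParams = field(default_factory=SubjectParams)
    seed: int = 0

    def validate(self) -> "CohortSpec":
        if self.n_mci < 0 or self.n_hc < 0:
            raise ParameterError("cohort sizes must be non-negative")
        for s in (self.sigma_between, self.sigma_within):
            vals = s.values() if isinstance(s, dict) else [s]
            if any(v < 0 for v in vals):
                raise ParameterError("sigma_between/sigma_within must be >= 0")
        if not np.isclose(sum(self.allograph_probs), 1.0):
            raise ParameterError("allograph_probs must sum to 1")
        for k in self.effect:
            if k not in PARAM_FIELDS:
                raise ParameterError(f"unknown effect field {k!r}")
        return self


def _sigma(spec_sigma: float | dict[str, float], fld: str) -> float:
    if isinstance(spec_sigma, dict):
        return float(spec_sigma.get(fld, 0.0))
    return float(spec_sigma)


def _clip_param(fld: str, value: float, base: float, fs: float) -> float:
    if fld == "pause_prob":
        return float(np.clip(value, 0.0, 1.0))
    if fld == "smoothness":
        return float(np.clip(value, 0.05, 1.0))
    if fld == "tremor_freq":
        return float(np.clip(value, 0.5, 0.9 * fs / 2))
    return float(max(value, 0.05 * base))


def draw_cohort_params(spec: CohortSpec, fs: float = DEFAULT_FS) -> pd.DataFrame:
    """Draw the hierarchical parameter table without rendering any signal.

    One row per (subject, session) with the realized :class:`SubjectParams`
    fields, group, and allograph — the ground truth for recovery tests.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    base = spec.base
    allos = ("cursive", "block", "na")
    rows = []
    groups = ["MCI"] * spec.n_mci + ["HC"] * spec.n_hc
    for i, group in enumerate(groups):
        sid = f"{group}{i:04d}"
        allo = allos[rng.choice(3, p=spec.allograph_probs)]
        subj_level: dict[str, float] = {}
        for fld in PARAM_FIELDS:
            b = float(getattr(base, fld))
            sb = _sigma(spec.sigma_between, fld) * b
            shift = spec.effect.get(fld, 0.0) * sb if group == "MCI" else 0.0
            subj_level[fld] = b + shift + sb * rng.standard_normal()
        for session in ("test", "retest"):
            sess_allo = allo
            if session == "retest" and rng.random() < spec.allograph_switch_prob:
                sess_allo = {"cursive": "block", "block": "cursive", "na": "na"}[allo]
            row = {"subject": sid, "group": group, "session": session,
                   "allograph": sess_allo}
            for fld in PARAM_FIELDS:
                b = float(getattr(base, fld))
                sw = _sigma(spec.sigma_within, fld) * b
                v = subj_level[fld] + sw * rng.standard_normal()
                if sess_allo == "block":
                    # block letters: shorter strokes, more in-air transitions
                    if fld == "stroke_dur_mean":
                        v *= 0.8
                    elif fld == "gap_dur_mean":
                        v *= 1.2
                row[fld] = _clip_param(fld, v, b, fs)
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_cohort(
    spec: CohortSpec, fs: float = DEFAULT_FS
) -> tuple[list[PenRecording], pd.DataFrame]:
    """Simulate recordings for a full cohort.

    Returns the recordings (one per subject x session x task) and the
    ground-truth parameter table from :func:`draw_cohort_params`.
    """
    truth = draw_cohort_params(spec, fs=fs)
    if truth.empty:
        return [], truth
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    recordings: list[PenRecording] = []
    for _, row in truth.iterrows():
        p = SubjectParams(**{f: row[f] for f in PARAM_FIELDS})
        for task in spec.tasks:
            meta = RecordingMeta(
                subject=row["subject"], group=row["group"], task=task,
                allograph=row["allograph"], session=row["session"], fs_hz=fs,
            )
            if task == "pnp":
                rec = simulate_pnp_session(p, seed=rng, meta=meta, fs=fs)
            else:
                rec = simulate_recording(
                    p, task=task, duration=spec.task_durations.get(task, 30.0),
                    seed=rng, meta=meta, fs=fs,
                )
            recordings.append(rec)
    return recordings, truth
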