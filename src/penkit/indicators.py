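"""Handwriting indicators computed from a segmented pen recording.

The indicator set spans six domains:

* **temporal** — execution time, stroke counts and the on-sheet / in-air /
  pause timing structure;
* **fluency** — movement-smoothness metrics (log dimensionless jerk on
  acceleration and angular velocity, spectral arc length on angular
  velocity) and oscillation-shape counts;
* **force** — level, overshoot (max minus median) and oscillation of the tip
  force while on paper;
* **tilt** — the angle between the pen axis (device z) and gravity, its
  variability and its spectral spread;
* **high-frequency, time domain** — approximate entropy of the acceleration
  norm;
* **high-frequency, frequency domain** — Welch-PSD band powers around 8 and
  11 Hz, spectral peaks and bandwidths.

Conventions that matter numerically: tri-axial channels enter as their
Euclidean norm except for the explicitly "dominant-axis" spectral indicators;
smoothness metrics are computed per stroke and averaged (in-air gaps would
corrupt the spectrum of a concatenated signal); signal derivatives use
central differences and integrals the trapezoidal rule; the spectral floor of
0.5 Hz keeps DC/drift out of every total-power normalization. Missing values
are NaN and propagate; degenerate content never raises.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import DOMAIN_ORDER, IndicatorVector, PenRecording
from .segment import SegmentationResult, segment_strokes, split_by_labels

__all__ = [
    "SpectralConfig",
    "EntropyConfig",
    "IndicatorConfig",
    "INDICATOR_DOMAINS",
    "INDICATOR_NAMES",
    "VARIABILITY_INDICATORS",
    "temporal_indicators",
    "ldlj",
    "sparc",
    "oscillation_shape",
    "force_indicators",
    "tilt_series",
    "tilt_indicators",
    "approximate_entropy",
    "spectral_indicators",
    "extract_all",
    "ExtractionResult",
]

#: indicator name -> domain; fixes the full indicator catalogue
INDICATOR_DOMAINS: dict[str, str] = {
    # temporal
    "execution_time": "temporal",
    "rel_stroke_num": "temporal",
    "mean_on_sheet": "temporal",
    "on_sheet_cv": "temporal",
    "on_sheet_ratio": "temporal",
    "mean_in_air": "temporal",
    "in_air_cv": "temporal",
    "mean_pause": "temporal",
    "pause_num": "temporal",
    "air_sheet_ratio": "temporal",
    # fluency
    "ldlj_a": "fluency",
    "ldlj_g": "fluency",
    "sparc": "fluency",
    "g_nc": "fluency",
    "a_nc": "fluency",
    "cons_peak_diff_g": "fluency",
    # force
    "mean_force": "force",
    "force_overshoot": "force",
    "force_nc": "force",
    "cons_peak_diff_f": "force",
    # tilt
    "mean_tilt": "tilt",
    "tilt_cv": "tilt",
    "tilt_median_bandwidth": "tilt",
    # high-frequency oscillations, time domain
    "a_apen": "hf_time",
    # high-frequency oscillations, frequency domain
    "g_peak_power": "hf_freq",
    "g_rpw_8": "hf_freq",
    "g_rpw_11": "hf_freq",
    "g_dom_rpw_11": "hf_freq",
    "a_peak_frequency": "hf_freq",
    "a_peak_power": "hf_freq",
    "a_median_bandwidth": "hf_freq",
    "a_dom_68_peak_bandwidth": "hf_freq",
}

INDICATOR_NAMES = tuple(INDICATOR_DOMAINS)

#: variance / coefficient-of-variation indicators (excluded from reliability)
VARIABILITY_INDICATORS = ("on_sheet_cv", "in_air_cv", "tilt_cv")


@dataclass
class SpectralConfig:
    """Welch / sliding-window spectral analysis settings."""

    segment_s: float = 2.56  # 128 samples at 50 Hz
    overlap: float = 0.5
    band_8: tuple[float, float] = (6.5, 9.5)
    band_11: tuple[float, float] = (9.5, 12.5)
    total_band: tuple[float, float] = (0.5, 25.0)


@dataclass
class EntropyConfig:
    """Approximate-entropy parameters (field-standard m=2, r=0.2*SD)."""

    m: int = 2
    r_factor: float = 0.2


@dataclass
class IndicatorConfig:
    contact_threshold: float | None = None  # None -> 5% of force range
    min_segment_s: float = 0.04
    pause_threshold_s: float = 2.0
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    entropy: EntropyConfig = field(default_factory=EntropyConfig)


# ---------------------------------------------------------------------------
# temporal domain
# ---------------------------------------------------------------------------


def temporal_indicators(seg: SegmentationResult) -> dict[str, float]:
    """Timing-structure indicators from a segmentation.

    Conventions: no in-air intervals -> ``mean_in_air = 0`` and
    ``air_sheet_ratio = 0``; no pauses -> ``mean_pause = 0``; a single stroke
    -> ``on_sheet_cv = 0``; zero strokes -> stroke-dependent means are NaN
    while ``execution_time`` (and the zero counts) are still returned.
    """
    out: dict[str, float] = {k: np.nan for k, d in INDICATOR_DOMAINS.items() if d == "temporal"}
    total = seg.total_duration
    out["execution_time"] = total
    out["pause_num"] = float(len(seg.pauses))
    pause_d = seg.durations(seg.pauses)
    out["mean_pause"] = float(pause_d.mean()) if len(pause_d) else 0.0
    air_d = seg.durations(seg.airs)
    out["mean_in_air"] = float(air_d.mean()) if len(air_d) else 0.0
    out["in_air_cv"] = _cv(air_d)
    stroke_d = seg.durations(seg.strokes)
    if len(stroke_d) == 0:
        out["rel_stroke_num"] = 0.0
        out["on_sheet_ratio"] = 0.0
        out["air_sheet_ratio"] = 0.0 if len(air_d) == 0 else np.nan
        return out
    out["rel_stroke_num"] = len(stroke_d) / total
    out["mean_on_sheet"] = float(stroke_d.mean())
    out["on_sheet_cv"] = _cv(stroke_d)
    out["on_sheet_ratio"] = float(stroke_d.sum() / total)
    out["air_sheet_ratio"] = 0.0 if len(air_d) == 0 else out["mean_in_air"] / out["mean_on_sheet"]
    return out


def _cv(x: np.ndarray) -> float:
    if len(x) == 0:
        return np.nan
    if len(x) == 1:
        return 0.0
    m = float(x.mean())
    return float(x.std(ddof=1) / m) if m != 0 else np.nan


# ---------------------------------------------------------------------------
# fluency domain
# ---------------------------------------------------------------------------


def _norm(channel: np.ndarray) -> np.ndarray:
    channel = np.asarray(channel, dtype=float)
    return np.linalg.norm(channel, axis=0) if channel.ndim == 2 else channel


def ldlj(channel: np.ndarray, seg: SegmentationResult, fs: float) -> float:
    """Log dimensionless jerk of a sensor channel, per stroke, averaged.

    Per stroke, on the Euclidean norm s(t):
    ``LDLJ = -ln( (T^3 / s_peak^2) * (1/T) * integral (ds/dt)^2 dt )`` with T
    the stroke duration and ``s_peak`` the within-stroke peak of the norm.
    Derivatives are central differences, the integral is trapezoidal. Strokes
    shorter than 4 samples are skipped; NaN when none remain. Amplitude
    scaling cancels through ``s_peak``; more negative means less smooth.
    """
    s_full = _norm(channel)
    vals = []
    for a, b in seg.strokes:
        s = s_full[a:b]
        if len(s) < 4:
            continue
        T = len(s) / fs
        peak = float(np.max(np.abs(s)))
        if peak == 0:
            continue
        ds = np.gradient(s, 1.0 / fs)
        integ = float(np.trapezoid(ds**2, dx=1.0 / fs))
        d = (T**3 / peak**2) * (integ / T)
        if d > 0:
            vals.append(-np.log(d))
    return float(np.mean(vals)) if vals else np.nan


SPARC_MAX_CUTOFF_HZ = 20.0
SPARC_AMP_THRESHOLD = 0.05
SPARC_PAD_FACTOR = 4


def sparc(channel: np.ndarray, seg: SegmentationResult, fs: float) -> float:
    """Spectral arc length of a channel norm, per stroke, averaged.

    Per stroke: zero-padded magnitude spectrum of the norm, normalized to its
    maximum; adaptive cutoff = largest frequency <= 20 Hz where the normalized
    magnitude is >= 0.05; the value is minus the arc length of the normalized
    spectrum over [0, cutoff] with frequency normalized by the cutoff.
    Strokes shorter than 8 samples are skipped.
    """
    s_full = _norm(channel)
    vals = []
    for a, b in seg.strokes:
        s = s_full[a:b]
        if len(s) < 8:
            continue
        nfft = int(2 ** np.ceil(np.log2(SPARC_PAD_FACTOR * len(s))))
        freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
        mag = np.abs(np.fft.rfft(s, nfft))
        if mag.max() == 0:
            continue
        mag = mag / mag.max()
        sel = np.flatnonzero((freqs <= SPARC_MAX_CUTOFF_HZ) & (mag >= SPARC_AMP_THRESHOLD))
        if len(sel) == 0:
            continue
        cutoff_idx = sel[-1]
        cutoff = freqs[cutoff_idx]
        if cutoff == 0:
            vals.append(0.0)
            continue
        f = freqs[: cutoff_idx + 1] / cutoff
        v = mag[: cutoff_idx + 1]
        arc = float(np.sum(np.sqrt(np.diff(f) ** 2 + np.diff(v) ** 2)))
        vals.append(-arc)
    return float(np.mean(vals)) if vals else np.nan


PROMINENCE_FRACTION = 0.01


def _stroke_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alternating extrema (indices, values) of one stroke's signal.

    Local maxima/minima with prominence >= 1% of the stroke's signal range;
    consecutive same-type extrema are collapsed to the more extreme one so the
    sequence alternates.
    """
    rng = float(x.max() - x.min())
    if rng == 0:
        return np.array([], int), np.array([])
    prom = PROMINENCE_FRACTION * rng
    peaks, _ = sps.find_peaks(x, prominence=prom)
    troughs, _ = sps.find_peaks(-x, prominence=prom)
    kinds = np.r_[np.ones(len(peaks), int), -np.ones(len(troughs), int)]
    idx = np.r_[peaks, troughs]
    order = np.argsort(idx)
    idx, kinds = idx[order], kinds[order]
    keep_idx: list[int] = []
    keep_kind: list[int] = []
    for i, k in zip(idx, kinds):
        if keep_kind and keep_kind[-1] == k:
            # same type twice: keep the more extreme
            if (k == 1 and x[i] > x[keep_idx[-1]]) or (k == -1 and x[i] < x[keep_idx[-1]]):
                keep_idx[-1] = int(i)
        else:
            keep_idx.append(int(i))
            keep_kind.append(int(k))
    keep = np.array(keep_idx, int)
    return keep, x[keep]


def oscillation_shape(
    channel: np.ndarray, seg: SegmentationResult, fs: float
) -> dict[str, float]:
    """Oscillation count per second and mean consecutive-extremum difference.

    Extrema are detected within strokes only; ``nc_per_s`` is the total count
    divided by total on-sheet time, ``cons_peak_diff`` the mean absolute value
    difference over consecutive extremum pairs (NaN with < 2 extrema).
    """
    x_full = _norm(channel)
    n_extrema = 0
    diffs: list[float] = []
    on_sheet = float(seg.durations(seg.strokes).sum()) if seg.strokes else 0.0
    for a, b in seg.strokes:
        _, vals = _stroke_extrema(x_full[a:b])
        n_extrema += len(vals)
        if len(vals) >= 2:
            diffs.extend(np.abs(np.diff(vals)).tolist())
    if on_sheet == 0:
        return {"nc_per_s": np.nan, "cons_peak_diff": np.nan}
    return {
        "nc_per_s": n_extrema / on_sheet,
        "cons_peak_diff": float(np.mean(diffs)) if diffs else np.nan,
    }


# ---------------------------------------------------------------------------
# force domain
# ---------------------------------------------------------------------------


def force_indicators(force: np.ndarray, seg: SegmentationResult, fs: float) -> dict[str, float]:
    """Force level, overshoot and oscillation, on on-sheet samples only."""
    if not seg.strokes:
        return {k: np.nan for k in ("mean_force", "force_overshoot", "force_nc", "cons_peak_diff_f")}
    on = np.concatenate([force[a:b] for a, b in seg.strokes])
    osc = oscillation_shape(force, seg, fs)
    return {
        "mean_force": float(on.mean()),
        "force_overshoot": float(on.max() - np.median(on)),
        "force_nc": osc["nc_per_s"],
        "cons_peak_diff_f": osc["cons_peak_diff"],
    }


# ---------------------------------------------------------------------------
# tilt domain
# ---------------------------------------------------------------------------

TILT_LP_CUTOFF_HZ = 2.0
TILT_MIN_MEAN_DEG = 1.0


def tilt_series(accel: np.ndarray, fs: float) -> np.ndarray:
    """Per-sample pen tilt (degrees) from tri-axial acceleration.

    The gravity direction is estimated by zero-phase 2nd-order low-pass
    filtering (2 Hz); the tilt is the angle between the filtered vector and
    the pen's longitudinal axis (device z), folded so that a pen aligned with
    gravity in either direction reads 0 degrees.
    """
    b, a = sps.butter(2, TILT_LP_CUTOFF_HZ / (fs / 2), btype="low")
    g = sps.filtfilt(b, a, accel, axis=1)
    norm = np.linalg.norm(g, axis=0)
    norm[norm == 0] = np.nan
    cos = np.clip(np.abs(g[2]) / norm, 0.0, 1.0)
    return np.degrees(np.arccos(cos))


def tilt_indicators(
    accel: np.ndarray, fs: float, spectral: SpectralConfig | None = None
) -> dict[str, float]:
    spectral = spectral or SpectralConfig()
    tilt = tilt_series(accel, fs)
    tilt = tilt[np.isfinite(tilt)]
    if len(tilt) < 2:
        return {"mean_tilt": np.nan, "tilt_cv": np.nan, "tilt_median_bandwidth": np.nan}
    mean_tilt = float(tilt.mean())
    cv = float(tilt.std(ddof=1) / mean_tilt) if mean_tilt >= TILT_MIN_MEAN_DEG else np.nan
    freqs, psd = _welch(tilt, fs, spectral)
    bw = _iqr_bandwidth(freqs, psd, spectral.total_band) if psd is not None else np.nan
    return {"mean_tilt": mean_tilt, "tilt_cv": cv, "tilt_median_bandwidth": bw}


# ---------------------------------------------------------------------------
# approximate entropy
# ---------------------------------------------------------------------------


def approximate_entropy(x: np.ndarray, cfg: EntropyConfig | None = None) -> float:
    """Classical approximate entropy ApEn(m, r) with self-matches included.

    ``r = r_factor * SD(x)``; a constant series returns 0 by convention.
    """
    cfg = cfg or EntropyConfig()
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < cfg.m + 2:
        return np.nan
    sd = float(x.std(ddof=0))
    if sd == 0:
        return 0.0
    r = cfg.r_factor * sd

    # Chebyshev distances between m-windows via the pairwise scalar-distance
    # matrix: C_m[i, j] = max_{t<m} |x[i+t] - x[j+t]|, i.e. a running max
    # along shifted diagonals of D0 = |x_i - x_j|. Row blocks keep the
    # footprint bounded for long recordings.
    block_rows = max(1, int(2e7 // max(n, 1)))

    def phi(m: int) -> float:
        nm = n - m + 1
        log_sum = 0.0
        for i0 in range(0, nm, block_rows):
            i1 = min(i0 + block_rows, nm)
            dm = np.abs(x[i0:i1, None] - x[None, :nm])
            for t in range(1, m):
                np.maximum(dm, np.abs(x[i0 + t : i1 + t, None] - x[None, t : t + nm]), out=dm)
            c = np.count_nonzero(dm <= r, axis=1) / nm
            log_sum += float(np.sum(np.log(c)))
        return log_sum / nm

    return phi(cfg.m) - phi(cfg.m + 1)


# ---------------------------------------------------------------------------
# spectral indicators
# ---------------------------------------------------------------------------


def _welch(x: np.ndarray, fs: float, cfg: SpectralConfig):
    nperseg = int(round(cfg.segment_s * fs))
    if len(x) < nperseg:
        return None, None
    noverlap = int(round(cfg.overlap * nperseg))
    freqs, psd = sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap, detrend="constant"
    )
    return freqs, psd


def _band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    return (freqs >= band[0]) & (freqs <= band[1])


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    return float(np.sum(psd[_band_mask(freqs, band)]))


def _relative_power(freqs, psd, band, total_band) -> float:
    tot = _band_power(freqs, psd, total_band)
    return _band_power(freqs, psd, band) / tot if tot > 0 else np.nan


def _iqr_bandwidth(freqs: np.ndarray, psd: np.ndarray, total_band) -> float:
    """Width between the 25% and 75% points of cumulative power in the band."""
    m = _band_mask(freqs, total_band)
    f, p = freqs[m], psd[m]
    tot = p.sum()
    if tot <= 0 or len(f) < 2:
        return np.nan
    cum = np.cumsum(p) / tot
    f25 = float(np.interp(0.25, cum, f))
    f75 = float(np.interp(0.75, cum, f))
    return f75 - f25


def _peak_68_bandwidth(freqs: np.ndarray, psd: np.ndarray, total_band) -> float:
    """Smallest symmetric interval around the PSD peak holding 68% of power."""
    m = _band_mask(freqs, total_band)
    f, p = freqs[m], psd[m]
    tot = p.sum()
    if tot <= 0 or len(f) < 2:
        return np.nan
    k = int(np.argmax(p))
    target = 0.68 * tot
    lo = hi = k
    acc = p[k]
    while acc < target and (lo > 0 or hi < len(p) - 1):
        lo2 = max(lo - 1, 0)
        hi2 = min(hi + 1, len(p) - 1)
        grew = False
        if lo2 < lo:
            acc += p[lo2]
            lo = lo2
            grew = True
        if hi2 > hi:
            acc += p[hi2]
            hi = hi2
            grew = True
        if not grew:  # pragma: no cover - loop guard
            break
    return float(f[hi] - f[lo])


def _windowed_relative_power(x, fs, band, cfg: SpectralConfig) -> float:
    """Median across sliding windows of band power / total-band power."""
    nperseg = int(round(cfg.segment_s * fs))
    if len(x) < nperseg:
        return np.nan
    noverlap = int(round(cfg.overlap * nperseg))
    freqs, _, spec = sps.spectrogram(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
        detrend="constant", mode="psd",
    )
    bm, tm = _band_mask(freqs, band), _band_mask(freqs, cfg.total_band)
    tot = spec[tm].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = spec[bm].sum(axis=0) / tot
    rel = rel[np.isfinite(rel)]
    return float(np.median(rel)) if len(rel) else np.nan


def spectral_indicators(
    accel: np.ndarray, gyro: np.ndarray, fs: float, cfg: SpectralConfig | None = None
) -> dict[str, float]:
    """Whole-task spectral indicators on the acceleration / gyro channels.

    Median relative powers use per-window normalization (2.56 s Hann windows,
    50% overlap); peaks and bandwidths use the whole-task Welch PSD. The
    "dominant" axis is the single axis with the greatest total-band power.
    """
    cfg = cfg or SpectralConfig()
    a_norm, g_norm = _norm(accel), _norm(gyro)
    out = {k: np.nan for k, d in INDICATOR_DOMAINS.items() if d == "hf_freq"}

    out["g_rpw_8"] = _windowed_relative_power(g_norm, fs, cfg.band_8, cfg)
    out["g_rpw_11"] = _windowed_relative_power(g_norm, fs, cfg.band_11, cfg)

    fg, pg = _welch(g_norm, fs, cfg)
    if pg is not None:
        m = _band_mask(fg, cfg.total_band)
        if m.any():
            out["g_peak_power"] = float(pg[m].max())
    fa, pa = _welch(a_norm, fs, cfg)
    if pa is not None:
        m = _band_mask(fa, cfg.total_band)
        if m.any():
            k = int(np.argmax(pa[m]))
            out["a_peak_frequency"] = float(fa[m][k])
            out["a_peak_power"] = float(pa[m][k])
        out["a_median_bandwidth"] = _iqr_bandwidth(fa, pa, cfg.total_band)

    # dominant axes
    def dominant_axis(channel: np.ndarray):
        best, best_pow = None, -np.inf
        for ax in range(channel.shape[0]):
            f, p = _welch(channel[ax], fs, cfg)
            if p is None:
                return None, None
            pw = _band_power(f, p, cfg.total_band)
            if pw > best_pow:
                best, best_pow = (f, p), pw
        return best

    dom_g = dominant_axis(gyro)
    if dom_g is not None and dom_g[0] is not None:
        out["g_dom_rpw_11"] = _relative_power(*dom_g, cfg.band_11, cfg.total_band)
    dom_a = dominant_axis(accel)
    if dom_a is not None and dom_a[0] is not None:
        out["a_dom_68_peak_bandwidth"] = _peak_68_bandwidth(*dom_a, cfg.total_band)
    return out


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------


@dataclass
class ExtractionResult:
    """Output of :func:`extract_all`.

    ``vector`` holds the whole-task indicators; for PnP recordings
    ``word_vectors`` carries one vector per dictated word and ``type_means``
    the per-word-type averages used by the word-type contrast stage.
    """

    vector: IndicatorVector
    segmentation: SegmentationResult
    word_vectors: list[tuple[int, str, IndicatorVector]] | None = None
    type_means: dict[str, IndicatorVector] | None = None


def _compute_vector(rec: PenRecording, cfg: IndicatorConfig) -> tuple[IndicatorVector, SegmentationResult]:
    seg = segment_strokes(
        rec,
        contact_threshold=cfg.contact_threshold,
        min_segment_s=cfg.min_segment_s,
        pause_threshold_s=cfg.pause_threshold_s,
    )
    values: dict[str, float] = {k: np.nan for k in INDICATOR_NAMES}
    values.update(temporal_indicators(seg))
    values["ldlj_a"] = ldlj(rec.accel, seg, rec.fs)
    values["ldlj_g"] = ldlj(rec.gyro, seg, rec.fs)
    values["sparc"] = sparc(rec.gyro, seg, rec.fs)
    osc_g = oscillation_shape(rec.gyro, seg, rec.fs)
    values["g_nc"] = osc_g["nc_per_s"]
    values["cons_peak_diff_g"] = osc_g["cons_peak_diff"]
    values["a_nc"] = oscillation_shape(rec.accel, seg, rec.fs)["nc_per_s"]
    values.update(force_indicators(rec.force, seg, rec.fs))
    values.update(tilt_indicators(rec.accel, rec.fs, cfg.spectral))
    a_norm = np.linalg.norm(rec.accel, axis=0)
    values["a_apen"] = (
        approximate_entropy(a_norm, cfg.entropy) if rec.n >= 50 else np.nan
    )
    values.update(spectral_indicators(rec.accel, rec.gyro, rec.fs, cfg.spectral))
    vec = IndicatorVector(
        subject=rec.meta.subject,
        session=rec.meta.session,
        task=rec.meta.task,
        allograph=rec.meta.allograph,
        values=values,
        domains=dict(INDICATOR_DOMAINS),
    )
    return vec, seg


def extract_all(rec: PenRecording, cfg: IndicatorConfig | None = None) -> ExtractionResult:
    """Segment a recording and compute the full indicator set.

    For PnP recordings the per-word sub-recordings are additionally extracted
    and averaged across words of the same type, which is what the word-type
    contrast analysis consumes downstream.
    """
    cfg = cfg or IndicatorConfig()
    vec, seg = _compute_vector(rec, cfg)
    result = ExtractionResult(vector=vec, segmentation=seg)
    if rec.meta.task == "pnp" and np.any(rec.label != 0):
        words = split_by_labels(rec)
        word_vecs = []
        by_type: dict[str, list[dict[str, float]]] = {}
        for idx, wtype, sub in words:
            wvec, _ = _compute_vector(sub, cfg)
            word_vecs.append((idx, wtype, wvec))
            by_type.setdefault(wtype, []).append(wvec.values)
        type_means: dict[str, IndicatorVector] = {}
        for wtype, dicts in by_type.items():
            arr = {
                k: float(np.nanmean([d[k] for d in dicts]))
                if not np.all(np.isnan([d[k] for d in dicts]))
                else np.nan
                for k in INDICATOR_NAMES
            }
            type_means[wtype] = IndicatorVector(
                subject=rec.meta.subject, session=rec.meta.session, task=rec.meta.task,
                allograph=rec.meta.allograph, values=arr, domains=dict(INDICATOR_DOMAINS),
            )
        result.word_vectors = word_vecs
        result.type_means = type_means
    return result
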