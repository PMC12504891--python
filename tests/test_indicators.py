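"""Indicator definitions against independent brute-force oracles."""

import numpy as np
import pytest

from penkit import (
    INDICATOR_DOMAINS,
    INDICATOR_NAMES,
    SubjectParams,
    approximate_entropy,
    extract_all,
    ldlj,
    simulate_pnp_session,
    simulate_recording,
    sparc,
)
from penkit.indicators import (
    EntropyConfig,
    force_indicators,
    oscillation_shape,
    spectral_indicators,
    temporal_indicators,
    tilt_indicators,
)
from penkit.segment import SegmentationResult

from conftest import make_recording

FS = 50.0


def seg_of(strokes, airs, n, fs=FS):
    return SegmentationResult(strokes=strokes, airs=airs, fs=fs, n=n)


def single_stroke_seg(n, fs=FS):
    return seg_of([(0, n)], [], n, fs)


# ---------------------------------------------------------------------------
# temporal
# ---------------------------------------------------------------------------


def test_temporal_scripted_arithmetic():
    # 3 strokes x 0.5 s, gaps 0.3 s and 2.5 s; total 4.3 s = 215 samples
    seg = seg_of([(0, 25), (40, 65), (190, 215)], [(25, 40), (65, 190)], 215)
    t = temporal_indicators(seg)
    assert t["execution_time"] == pytest.approx(4.3)
    assert t["rel_stroke_num"] == pytest.approx(3 / 4.3)
    assert t["mean_on_sheet"] == pytest.approx(0.5)
    assert t["on_sheet_ratio"] == pytest.approx(1.5 / 4.3)
    assert t["mean_in_air"] == pytest.approx(1.4)
    assert t["pause_num"] == 1
    assert t["mean_pause"] == pytest.approx(2.5)
    assert t["air_sheet_ratio"] == pytest.approx(2.8)


def test_temporal_saturated_recording():
    seg = seg_of([(0, 500)], [], 500)
    t = temporal_indicators(seg)
    assert t["on_sheet_ratio"] == 1.0
    assert t["pause_num"] == 0
    assert t["air_sheet_ratio"] == 0.0
    assert t["on_sheet_cv"] == 0.0  # single stroke


def test_exact_two_second_gap_counts_as_air_not_pause():
    seg = seg_of([(0, 50), (150, 200)], [(50, 150)], 200)
    t = temporal_indicators(seg)
    assert t["mean_in_air"] == pytest.approx(2.0)
    assert t["pause_num"] == 0


def test_zero_strokes_conventions():
    seg = seg_of([], [(0, 100)], 100)
    t = temporal_indicators(seg)
    assert t["execution_time"] == pytest.approx(2.0)
    assert t["rel_stroke_num"] == 0.0
    assert np.isnan(t["mean_on_sheet"])


# ---------------------------------------------------------------------------
# LDLJ
# ---------------------------------------------------------------------------


def ldlj_oracle(s, fs):
    """Loop-based evaluation of the defining integral (central differences,
    trapezoidal rule) for a single full-length stroke."""
    n = len(s)
    dt = 1.0 / fs
    ds = [0.0] * n
    ds[0] = (s[1] - s[0]) / dt
    ds[-1] = (s[-1] - s[-2]) / dt
    for i in range(1, n - 1):
        ds[i] = (s[i + 1] - s[i - 1]) / (2 * dt)
    integ = 0.0
    for i in range(n - 1):
        integ += 0.5 * (ds[i] ** 2 + ds[i + 1] ** 2) * dt
    T = n / fs
    peak = max(abs(v) for v in s)
    return -np.log((T**3 / peak**2) * (integ / T))


def test_ldlj_matches_quadrature_oracle():
    t = np.arange(50) / FS  # 1 s stroke
    s = 1.0 + 0.5 * np.sin(2 * np.pi * 2 * t)
    got = ldlj(s, single_stroke_seg(50), FS)
    assert got == pytest.approx(ldlj_oracle(s, FS), abs=1e-6)


def test_ldlj_amplitude_scale_invariant(rng):
    t = np.arange(100) / FS
    s = 1.0 + 0.4 * np.sin(2 * np.pi * 3 * t) + 0.1 * np.sin(2 * np.pi * 7 * t)
    base = ldlj(s, single_stroke_seg(100), FS)
    for c in rng.uniform(0.01, 100, size=5):
        assert ldlj(c * s, single_stroke_seg(100), FS) == pytest.approx(base, rel=1e-9)


def test_ldlj_penalizes_high_frequency_content():
    t = np.arange(100) / FS
    pure = 1.0 + 0.5 * np.sin(2 * np.pi * 2 * t)
    mixed = pure + 0.5 * np.sin(2 * np.pi * 9 * t)
    seg = single_stroke_seg(100)
    assert ldlj(pure, seg, FS) > ldlj(mixed, seg, FS)
    # independent check of the ordering via the quadrature oracle
    assert ldlj_oracle(pure, FS) > ldlj_oracle(mixed, FS)


def test_ldlj_short_strokes_missing():
    seg = seg_of([(0, 3)], [(3, 10)], 10)
    assert np.isnan(ldlj(np.ones(10), seg, FS))


# ---------------------------------------------------------------------------
# SPARC
# ---------------------------------------------------------------------------


def sparc_oracle(s, fs):
    """Direct-DFT arc-length evaluation on a zero-padded spectrum."""
    n = len(s)
    nfft = int(2 ** np.ceil(np.log2(4 * n)))
    ks = np.arange(nfft // 2 + 1)
    freqs = ks * fs / nfft
    mags = []
    for k in ks:
        re = sum(s[m] * np.cos(2 * np.pi * k * m / nfft) for m in range(n))
        im = sum(-s[m] * np.sin(2 * np.pi * k * m / nfft) for m in range(n))
        mags.append(np.hypot(re, im))
    mags = np.array(mags) / max(mags)
    sel = [i for i, (f, v) in enumerate(zip(freqs, mags)) if f <= 20.0 and v >= 0.05]
    ci = sel[-1]
    fc = freqs[ci]
    arc = 0.0
    for i in range(ci):
        df = (freqs[i + 1] - freqs[i]) / fc
        dv = mags[i + 1] - mags[i]
        arc += np.hypot(df, dv)
    return -arc


def test_sparc_matches_direct_dft_oracle():
    t = np.arange(40) / FS
    s = np.abs(np.sin(2 * np.pi * 2 * t)) + 0.2
    got = sparc(s, single_stroke_seg(40), FS)
    assert got == pytest.approx(sparc_oracle(s, FS), abs=1e-9)


def test_sparc_amplitude_scale_invariant(rng):
    t = np.arange(80) / FS
    s = 1.0 + 0.5 * np.sin(2 * np.pi * 3 * t)
    seg = single_stroke_seg(80)
    base = sparc(s, seg, FS)
    for c in rng.uniform(0.01, 100, size=5):
        assert sparc(c * s, seg, FS) == pytest.approx(base, rel=1e-12)


def test_sparc_penalizes_high_frequency_content():
    t = np.arange(100) / FS
    pure = 1.0 + 0.5 * np.sin(2 * np.pi * 2 * t)
    mixed = pure + 0.5 * np.sin(2 * np.pi * 9 * t)
    seg = single_stroke_seg(100)
    assert sparc(pure, seg, FS) > sparc(mixed, seg, FS)
    assert sparc_oracle(pure, FS) > sparc_oracle(mixed, FS)


def test_sparc_constant_stroke_deterministic():
    s = np.full(64, 3.0)
    seg = single_stroke_seg(64)
    v1 = sparc(s, seg, FS)
    v2 = sparc(np.full(64, 3.0), seg, FS)
    assert v1 == v2
    assert np.isfinite(v1)


# ---------------------------------------------------------------------------
# oscillation shape / NC
# ---------------------------------------------------------------------------


def test_nc_of_two_hz_sine():
    t = np.arange(100) / FS  # 2 s stroke
    s = np.sin(2 * np.pi * 2 * t)
    out = oscillation_shape(s, single_stroke_seg(100), FS)
    assert out["nc_per_s"] == pytest.approx(4.0)  # 8 extrema / 2 s


def test_cons_peak_diff_of_scaled_sine():
    t = np.arange(100) / FS
    s = 30.0 * np.sin(2 * np.pi * 2 * t)
    out = oscillation_shape(s, single_stroke_seg(100), FS)
    # closed form is 60 (peak-to-trough); 50 Hz sampling shaves the extrema
    assert out["cons_peak_diff"] == pytest.approx(60.0, abs=0.2)


def test_constant_signal_has_no_oscillation():
    out = oscillation_shape(np.ones(100), single_stroke_seg(100), FS)
    assert out["nc_per_s"] == 0.0
    assert np.isnan(out["cons_peak_diff"])


# ---------------------------------------------------------------------------
# force
# ---------------------------------------------------------------------------


def test_constant_force():
    seg = single_stroke_seg(100)
    out = force_indicators(np.full(100, 5.0), seg, FS)
    assert out["mean_force"] == 5.0
    assert out["force_overshoot"] == 0.0
    assert out["force_nc"] == 0.0


def test_overshoot_is_max_minus_median():
    force = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
    seg = single_stroke_seg(5)
    out = force_indicators(force, seg, FS)
    assert out["force_overshoot"] == pytest.approx(7.0)


def test_overshoot_permutation_invariant(rng):
    force = rng.uniform(0, 10, 50)
    seg = single_stroke_seg(50)
    base = force_indicators(force, seg, FS)["force_overshoot"]
    shuffled = force_indicators(rng.permutation(force), seg, FS)["force_overshoot"]
    assert shuffled == pytest.approx(base)


# ---------------------------------------------------------------------------
# tilt
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "vec,expected",
    [((0.0, 0.0, -9.81), 0.0), ((9.81, 0.0, 0.0), 90.0),
     ((6.937, 0.0, 6.937), 45.0)],
)
def test_static_tilt(vec, expected):
    n = 200
    accel = np.tile(np.asarray(vec)[:, None], (1, n))
    out = tilt_indicators(accel, FS)
    assert out["mean_tilt"] == pytest.approx(expected, abs=0.1)


# ---------------------------------------------------------------------------
# approximate entropy
# ---------------------------------------------------------------------------


def apen_oracle(x, m=2, rf=0.2):
    n = len(x)
    r = rf * np.std(x)

    def phi(m):
        nm = n - m + 1
        logs = []
        for i in range(nm):
            cnt = 0
            for j in range(nm):
                if max(abs(x[i + t] - x[j + t]) for t in range(m)) <= r:
                    cnt += 1
            logs.append(np.log(cnt / nm))
        return float(np.mean(logs))

    return phi(m) - phi(m + 1)


def test_apen_constant_series_is_zero():
    assert approximate_entropy(np.full(100, 2.5)) == 0.0


def test_apen_matches_brute_force(rng):
    x = rng.normal(0, 1, 60)
    got = approximate_entropy(x, EntropyConfig(m=2, r_factor=0.2))
    assert got == pytest.approx(apen_oracle(x), abs=1e-12)


def test_apen_noise_exceeds_sine():
    wins = 0
    t = np.arange(500) / FS
    for seed in range(100):
        r = np.random.default_rng(seed)
        noise = r.normal(0, 1, 500)
        sine = np.sin(2 * np.pi * 1.3 * t)
        sine = sine / sine.std()
        if approximate_entropy(noise) > approximate_entropy(sine):
            wins += 1
    assert wins >= 95


# ---------------------------------------------------------------------------
# spectral
# ---------------------------------------------------------------------------


def test_pure_8hz_gyro_tone_band_powers():
    # tone rides on an offset so the channel *norm* keeps the 8 Hz line
    t = np.arange(1000) / FS
    gyro = np.vstack([5.0 + np.sin(2 * np.pi * 8 * t), np.zeros(1000), np.zeros(1000)])
    accel = np.vstack([5.0 + np.sin(2 * np.pi * 3 * t), np.zeros(1000), np.zeros(1000)])
    out = spectral_indicators(accel, gyro, FS)
    assert out["g_rpw_8"] >= 0.95
    assert out["g_rpw_11"] <= 0.05


def test_accel_peak_frequency_recovered():
    t = np.arange(1000) / FS
    accel = np.vstack([np.zeros(1000), np.zeros(1000),
                       5.0 + np.sin(2 * np.pi * 7 * t)])
    gyro = np.vstack([np.sin(2 * np.pi * 4 * t), np.zeros(1000), np.zeros(1000)])
    out = spectral_indicators(accel, gyro, FS)
    df = FS / 128  # Welch frequency resolution
    assert out["a_peak_frequency"] == pytest.approx(7.0, abs=df)


def test_relative_powers_partition_the_band():
    from penkit.indicators import SpectralConfig, _relative_power, _welch

    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 2000)
    cfg = SpectralConfig()
    freqs, psd = _welch(x, FS, cfg)
    edges = np.linspace(*cfg.total_band, 6)
    # partition with band edges placed between PSD bins to avoid double counting
    tot = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        hi_adj = hi - 1e-9 if hi != edges[-1] else hi
        tot += _relative_power(freqs, psd, (lo, hi_adj), cfg.total_band)
    assert 0.95 <= tot <= 1.05  # bin-edge effects only
    assert 0.0 <= _relative_power(freqs, psd, cfg.band_8, cfg.total_band) <= 1.0


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def test_extract_all_emits_full_catalogue():
    rec = simulate_recording(SubjectParams(), task="list", duration=12, seed=2)
    res = extract_all(rec)
    assert set(res.vector.values) == set(INDICATOR_NAMES)
    domains = set(INDICATOR_DOMAINS.values())
    assert domains == {"temporal", "fluency", "force", "tilt", "hf_time", "hf_freq"}


def test_extract_all_pnp_returns_three_type_means():
    rec = simulate_pnp_session(SubjectParams(), seed=3)
    res = extract_all(rec)
    assert set(res.type_means) == {"regular", "irregular", "made_up"}
    assert len(res.word_vectors) == 15


def test_dimensionless_indicators_amplitude_invariant():
    rec = simulate_recording(SubjectParams(), task="list", duration=12, seed=7)
    res = extract_all(rec)
    scaled = rec
    scaled.accel = rec.accel * 3.7
    scaled.gyro = rec.gyro * 0.21
    res2 = extract_all(scaled)
    for name in ("ldlj_a", "ldlj_g", "sparc", "a_apen", "g_rpw_8", "g_rpw_11",
                 "g_dom_rpw_11", "tilt_cv", "mean_tilt"):
        assert res2.vector.values[name] == pytest.approx(
            res.vector.values[name], rel=1e-6, abs=1e-9), name
    # temporal indicators only depend on the force segmentation
    scaled.force = rec.force * 11.0
    res3 = extract_all(scaled)
    for name in ("execution_time", "rel_stroke_num", "on_sheet_ratio",
                 "mean_in_air", "pause_num"):
        assert res3.vector.values[name] == pytest.approx(res.vector.values[name])


def _reversed_recording(rec):
    from penkit.io import PenRecording

    return PenRecording(
        time=rec.time, accel=rec.accel[:, ::-1].copy(),
        gyro=rec.gyro[:, ::-1].copy(), force=rec.force[::-1].copy(),
        label=rec.label[::-1].copy(), meta=rec.meta,
    )


def test_time_reversal_preserves_counting_indicators():
    # clean force edges: reversal preserves segmentation-driven indicators
    rec = simulate_recording(SubjectParams(), task="list", duration=12, seed=9,
                             noise=0.0)
    res = extract_all(rec)
    res2 = extract_all(_reversed_recording(rec))
    for name in ("execution_time", "rel_stroke_num", "on_sheet_ratio",
                 "mean_force", "force_overshoot"):
        assert res2.vector.values[name] == pytest.approx(
            res.vector.values[name], rel=1e-9), name


def test_time_reversal_with_noisy_edges_is_stable():
    # with force jitter, hysteresis is only approximately time-symmetric
    rec = simulate_recording(SubjectParams(), task="list", duration=12, seed=9)
    res = extract_all(rec)
    res2 = extract_all(_reversed_recording(rec))
    assert res2.vector.values["execution_time"] == pytest.approx(
        res.vector.values["execution_time"])
    for name in ("on_sheet_ratio", "mean_force", "force_overshoot"):
        assert res2.vector.values[name] == pytest.approx(
            res.vector.values[name], rel=0.01), name


def test_pause_prob_monotonically_raises_pause_num():
    means = []
    for pp in (0.05, 0.4):
        vals = []
        for seed in range(15):
            rec = simulate_recording(SubjectParams(pause_prob=pp), task="list",
                                     duration=15, seed=seed)
            vals.append(extract_all(rec).vector.values["pause_num"])
        means.append(np.mean(vals))
    assert means[1] > means[0]


def test_lower_smoothness_degrades_smoothness_metrics():
    stats = {}
    for sm in (0.95, 0.55):
        sparc_v, ldlj_v = [], []
        for seed in range(10):
            rec = simulate_recording(SubjectParams(smoothness=sm), task="list",
                                     duration=12, seed=seed)
            v = extract_all(rec).vector.values
            sparc_v.append(v["sparc"])
            ldlj_v.append(v["ldlj_g"])
        stats[sm] = (np.mean(sparc_v), np.mean(ldlj_v))
    assert stats[0.55][0] < stats[0.95][0]  # SPARC more negative
    assert stats[0.55][1] < stats[0.95][1]  # LDLJ more negative
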