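"""Feature definitions against independent brute-force oracles."""

import numpy as np
import pytest

from tremormark.features import (
    FEATURE_NAMES,
    FeatureConfig,
    Spectrum,
    extract_feature_vector,
    mmav,
    sample_entropy,
    segment_rms,
    slope_sign_changes,
    spectral_summaries,
    tremor_peak,
    waveform_length,
    welch_spectrum,
    zero_crossings,
)
from tremormark.io import Recording
from tremormark.synthetic import SimParams, synth_emg, synth_patient

from .conftest import FS, sine


# ---------------------------------------------------------------------------
# independent oracles (explicit loops, no numpy vectorisation tricks)
# ---------------------------------------------------------------------------

def mmav_oracle(seg, variant):
    n = len(seg)
    total = 0.0
    for i in range(1, n + 1):  # 1-based sample index
        if 0.25 * n <= i <= 0.75 * n:
            w = 1.0
        elif variant == 1:
            w = 0.5
        elif i < 0.25 * n:
            w = 4.0 * i / n
        else:
            w = 4.0 * (n - i) / n
        total += w * abs(seg[i - 1])
    return total / n


def zc_oracle(seg, eps):
    signs = []
    last = 0.0
    for v in seg:
        s = int(v > 0) - int(v < 0)
        if s != 0:
            last = s
        signs.append(last)
    count = 0
    for i in range(len(seg) - 1):
        if signs[i] * signs[i + 1] < 0 and abs(seg[i] - seg[i + 1]) >= eps:
            count += 1
    return count


def ssc_oracle(seg, eps):
    count = 0
    for i in range(1, len(seg) - 1):
        if (seg[i] - seg[i - 1]) * (seg[i] - seg[i + 1]) >= eps:
            count += 1
    return count


def sampen_oracle(x, m=2, r=0.2, r_is_fraction=True):
    x = list(map(float, x))
    n = len(x)
    if r_is_fraction:
        mean = sum(x) / n
        sd = (sum((v - mean) ** 2 for v in x) / n) ** 0.5
        r = r * sd
    nt = n - m
    a = b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            dm = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if dm <= r:
                b += 1
                if max(dm, abs(x[i + m] - x[j + m])) <= r:
                    a += 1
    if a == 0 or b == 0:
        return None
    import math

    return -math.log(a / b)


# ---------------------------------------------------------------------------
# time-domain features
# ---------------------------------------------------------------------------

class TestTimeDomain:
    @pytest.mark.parametrize(
        "seg, expected",
        [
            (np.full(100, 2.0), 2.0),
            (np.array([3.0, 4.0]), np.sqrt(12.5)),
        ],
    )
    def test_segment_rms_closed_form(self, seg, expected):
        assert segment_rms(seg) == pytest.approx(expected)

    def test_segment_rms_of_sine_is_amplitude_over_sqrt2(self):
        assert segment_rms(sine(10.0, duration_s=1.0)) == pytest.approx(
            1 / np.sqrt(2), abs=1e-3
        )

    @pytest.mark.parametrize("variant", [1, 2])
    def test_mmav_matches_explicit_weight_loop(self, rng, variant):
        for seg in (np.ones(512), rng.normal(size=512), rng.normal(size=37)):
            assert mmav(seg, variant) == pytest.approx(
                mmav_oracle(seg, variant), rel=1e-12
            )

    @pytest.mark.parametrize("variant", [1, 2])
    def test_mmav_constant_is_three_quarters(self, variant):
        # central half weighted 1, outer quarters average 0.5
        assert mmav(np.ones(512), variant) == pytest.approx(0.75, abs=0.01)
        assert mmav(np.zeros(512), variant) == 0.0

    @pytest.mark.parametrize(
        "seg, expected",
        [
            ([1.0, 3.0, 2.0], 3.0),
            (np.full(50, 7.0), 0.0),
            (np.arange(10.0), 9.0),
        ],
    )
    def test_waveform_length(self, seg, expected):
        assert waveform_length(np.asarray(seg)) == pytest.approx(expected)

    def test_zero_crossings_examples(self):
        assert zero_crossings(np.array([1.0, -1.0, 1.0, -1.0]), eps=0.0) == 3
        assert zero_crossings(np.full(100, 3.0), eps=0.0) == 0
        # cosine at 5 Hz crosses zero 10 times per second
        t = np.arange(int(FS)) / FS
        assert zero_crossings(np.cos(2 * np.pi * 5 * t), eps=1e-6) == 10

    def test_slope_sign_changes_examples(self):
        assert slope_sign_changes(np.array([1.0, 3.0, 2.0]), eps=0.0) == 1
        assert slope_sign_changes(np.arange(20.0), eps=1e-9) == 0

    @pytest.mark.parametrize("eps", [0.0, 0.3])
    def test_counting_features_match_loop_oracles_hypothesis(self, eps):
        from hypothesis import given, settings
        from hypothesis import strategies as hst

        @settings(max_examples=60, derandomize=True, deadline=None)
        @given(
            hst.lists(
                hst.floats(-5, 5, allow_nan=False, width=32),
                min_size=4,
                max_size=40,
            )
        )
        def check(values):
            seg = np.asarray(values, dtype=float)
            assert zero_crossings(seg, eps) == zc_oracle(seg, eps)
            assert slope_sign_changes(seg, eps) == ssc_oracle(seg, eps)

        check()

    def test_counting_features_match_loop_oracles(self, rng):
        """100 random draws: vectorised counts equal the explicit loops."""
        for _ in range(100):
            n = int(rng.integers(5, 80))
            seg = rng.normal(size=n) * rng.choice([0.1, 1.0, 10.0])
            if rng.random() < 0.2:
                seg[rng.random(n) < 0.2] = 0.0  # exercise the zero-sign rule
            eps_z = float(rng.choice([0.0, 0.05, 0.5]))
            eps_s = float(rng.choice([0.0, 0.01, 0.2]))
            assert zero_crossings(seg, eps_z) == zc_oracle(seg, eps_z)
            assert slope_sign_changes(seg, eps_s) == ssc_oracle(seg, eps_s)


class TestSampleEntropy:
    def test_constant_signal_is_perfectly_regular(self):
        value, capped = sample_entropy(np.full(50, 3.3))
        assert value == 0.0 and not capped

    def test_periodic_example_matches_double_loop(self):
        x = np.array([1, 2, 3, 1, 2, 3, 1, 2, 3, 1], dtype=float)
        got, capped = sample_entropy(x, m=2, r=0.5, r_is_fraction=False)
        assert not capped
        assert got == pytest.approx(sampen_oracle(x, m=2, r=0.5, r_is_fraction=False))

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(25):
            n = int(rng.integers(20, 200))
            x = rng.normal(size=n)
            expected = sampen_oracle(x)
            got, capped = sample_entropy(x)
            if expected is None:
                assert capped
            else:
                assert got == pytest.approx(expected, rel=1e-12)

    def test_no_match_capped_and_flagged(self):
        # strictly exponential growth: no two templates are ever close
        x = 10.0 ** np.arange(8)
        value, capped = sample_entropy(x, r=1e-6, r_is_fraction=False)
        assert capped and value == 10.0

    def test_periodic_bursts_more_regular_than_shuffled(self, rng):
        """Rhythmic bursts score lower entropy than the same samples shuffled."""
        t = np.arange(256) / 256
        wins = 0
        for i in range(100):
            r = np.random.default_rng(i)
            burst = np.maximum(np.sin(2 * np.pi * 8 * t), 0.0) * r.normal(
                1.0, 0.1, size=t.size
            )
            shuffled = r.permutation(burst)
            if sample_entropy(burst)[0] < sample_entropy(shuffled)[0]:
                wins += 1
        assert wins >= 95


# ---------------------------------------------------------------------------
# spectral features
# ---------------------------------------------------------------------------

class TestSpectral:
    def test_welch_peak_at_tone_frequency(self):
        spec = welch_spectrum(sine(10.0, duration_s=60.0), FS)
        peak = spec.frequencies[np.argmax(spec.psd)]
        assert peak == pytest.approx(10.0, abs=spec.resolution_hz)
        assert spec.resolution_hz <= 0.125

    def test_welch_total_power_matches_variance(self, rng):
        x = rng.normal(size=int(60 * FS))
        spec = welch_spectrum(x, FS)
        total = np.sum(spec.psd) * spec.resolution_hz
        assert total == pytest.approx(np.var(x), rel=0.10)

    def test_welch_power_ordering_of_two_tones(self):
        x = sine(5.0, amplitude=2.0) + sine(9.0, amplitude=1.0)
        spec = welch_spectrum(x, FS)
        p5 = spec.psd[np.argmin(np.abs(spec.frequencies - 5.0))]
        p9 = spec.psd[np.argmin(np.abs(spec.frequencies - 9.0))]
        assert p5 > p9

    def test_tremor_peak_single_nonzero_bin(self):
        freqs = np.arange(0, 20.0, 0.125)
        psd = np.zeros_like(freqs)
        psd[np.argmin(np.abs(freqs - 4.5))] = 2.0
        peak = tremor_peak(Spectrum(freqs, psd, 0.125))
        assert peak.detected
        assert peak.frequency_hz == pytest.approx(4.5)
        assert peak.power_db == pytest.approx(10 * np.log10(2.0))

    def test_tremor_peak_zero_power_flags_missing(self):
        freqs = np.arange(0, 20.0, 0.125)
        peak = tremor_peak(Spectrum(freqs, np.zeros_like(freqs), 0.125))
        assert not peak.detected
        assert np.isnan(peak.frequency_hz) and np.isnan(peak.power_db)

    def test_tremor_peak_tie_breaks_to_lower_frequency(self):
        freqs = np.arange(0, 20.0, 0.125)
        psd = np.zeros_like(freqs)
        psd[[24, 40]] = 5.0  # 3.0 Hz and 5.0 Hz, equal power
        peak = tremor_peak(Spectrum(freqs, psd, 0.125))
        assert peak.frequency_hz == pytest.approx(3.0)

    def test_spectral_summaries_flat_spectrum(self):
        freqs = np.arange(0.0, 256.0, 0.5)
        psd = np.where((freqs >= 20) & (freqs <= 200), 1.0, 0.0)
        mdp, mnp, fr = spectral_summaries(Spectrum(freqs, psd, 0.5))
        assert mdp == pytest.approx(mnp)
        # split at 110 Hz = band midpoint -> equal halves
        _, _, fr_mid = spectral_summaries(
            Spectrum(freqs, psd, 0.5), fr_split_hz=110.0
        )
        assert fr_mid == pytest.approx(1.0, rel=0.02)

    def test_frequency_ratio_tracks_low_band_share(self):
        freqs = np.arange(0.0, 256.0, 0.5)

        def two_tone(low_amp, high_amp):
            psd = np.zeros_like(freqs)
            psd[np.argmin(np.abs(freqs - 30.0))] = low_amp
            psd[np.argmin(np.abs(freqs - 150.0))] = high_amp
            return Spectrum(freqs, psd, 0.5)

        frs = [
            spectral_summaries(two_tone(a, 2.0 - a))[2] for a in (0.2, 1.0, 1.8)
        ]
        assert frs[0] < frs[1] < frs[2]
        assert frs[1] == pytest.approx(1.0)
        # degenerate high band -> missing
        psd = np.zeros_like(freqs)
        psd[np.argmin(np.abs(freqs - 30.0))] = 1.0
        assert np.isnan(spectral_summaries(Spectrum(freqs, psd, 0.5))[2])


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

class TestExtraction:
    def test_deterministic(self, tremor_recording):
        a = extract_feature_vector(tremor_recording)
        b = extract_feature_vector(tremor_recording)
        for name in FEATURE_NAMES:
            assert getattr(a, name) == getattr(b, name)

    def test_all_features_finite_on_default_recording(self, tremor_recording):
        fv = extract_feature_vector(tremor_recording)
        for name in FEATURE_NAMES:
            assert np.isfinite(getattr(fv, name)), name
        assert fv.n_segments_used > 0
        assert fv.tremor_detected

    def test_suppressed_pair_moves_features_in_study_directions(self, short_params):
        """DBS-on (suppression 0.8) lowers amplitude features; SampEn rises
        in the clear majority of pairs (the entropy shift is a cohort-level
        effect with per-patient variability)."""
        floor_off = 40.0 * (1 - 0.9) / 0.9
        sampen_up = 0
        n_pairs = 10
        for i in range(n_pairs):
            rng = np.random.default_rng(210 + i)
            off = synth_emg(5.0, 40.0, 0.9, short_params, rng, floor=floor_off)
            on = synth_emg(
                5.0, 40.0 * 0.2, 0.9, short_params, rng,
                floor=floor_off * (1 - 0.8 * 0.8),
            )
            fv_off = extract_feature_vector(off)
            fv_on = extract_feature_vector(on)
            for name in ("wRMS", "MMAV1", "MMAV2", "WL", "MDP", "MNP", "PeakFPSD"):
                assert getattr(fv_on, name) < getattr(fv_off, name), name
            sampen_up += fv_on.SampEn > fv_off.SampEn
        assert sampen_up >= 7

    def test_scale_equivariance(self, tremor_recording):
        cfg = FeatureConfig(eps_zc=0.0, eps_ssc=0.0)
        base = extract_feature_vector(tremor_recording, cfg)
        scaled_rec = tremor_recording.with_samples(tremor_recording.samples * 3.0)
        scaled = extract_feature_vector(scaled_rec, cfg)
        for name in ("wRMS", "MMAV1", "MMAV2", "WL"):
            assert getattr(scaled, name) == pytest.approx(
                3.0 * getattr(base, name), rel=1e-9
            )
        for name in ("ZC", "SSC", "PeakF"):
            assert getattr(scaled, name) == pytest.approx(getattr(base, name))
        assert scaled.FR == pytest.approx(base.FR, rel=1e-9)
        # r is SD-relative, so entropy ignores amplitude scale
        assert scaled.SampEn == pytest.approx(base.SampEn, rel=1e-9)

    def test_peak_recovery_within_quarter_hz(self, short_params):
        """50 seeded bursts at known frequency; >=95% recovered to 0.25 Hz."""
        hits = 0
        for i in range(50):
            r = np.random.default_rng(3000 + i)
            f_true = float(r.uniform(3.5, 7.5))
            rec = synth_emg(f_true, 40.0, 0.7, short_params, r)
            fv = extract_feature_vector(rec)
            if fv.tremor_detected and abs(fv.PeakF - f_true) <= 0.25:
                hits += 1
        assert hits >= 48

    def test_no_tremor_flag_on_flat_recording(self, short_params):
        rec = synth_emg(
            5.0, 0.0, 0.9, short_params, np.random.default_rng(0), floor=10.0
        )
        fv = extract_feature_vector(rec)
        assert not fv.tremor_detected
        assert np.isnan(fv.PeakF) and np.isnan(fv.PeakFPSD)
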