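"""The 12 tremor-sEMG features and their spectral machinery.

Three feature categories are computed per recording:

* frequency / motor-unit firing rate — peak tremor frequency ``PeakF``,
  frequency ratio ``FR``, zero crossings ``ZC``, slope sign changes ``SSC``;
* amplitude / power — weighted RMS ``wRMS``, modified mean absolute values
  ``MMAV1``/``MMAV2``, waveform length ``WL``, peak-frequency power
  ``PeakFPSD``, median and mean band power ``MDP``/``MNP``;
* regularity — sample entropy ``SampEn``.

Time-domain features are computed per 1-s segment on the band-pass-filtered
signal and averaged over artifact-free segments. The tremor peak (PeakF,
PeakFPSD) is read off the Welch spectrum of the rectified RMS envelope,
because the ~5 Hz burst rhythm lies below the 20 Hz filter edge and is only
observable as amplitude modulation. Band-power summaries (MDP, MNP, FR) use
the Welch spectrum of the filtered signal itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.spatial import cKDTree

from .io import Condition, PatientRecord, Recording
from .preprocess import (
    EnvelopeConfig,
    FilterConfig,
    SignalLengthError,
    artifact_mask,
    bandpass_filter,
    full_wave_rectify,
    rms_envelope,
    segment_signal,
)

__all__ = [
    "FEATURE_NAMES",
    "AMPLITUDE_FEATURES",
    "FeatureConfig",
    "FeatureVector",
    "Spectrum",
    "TremorPeak",
    "QualityError",
    "segment_rms",
    "mmav",
    "waveform_length",
    "zero_crossings",
    "slope_sign_changes",
    "sample_entropy",
    "welch_spectrum",
    "tremor_peak",
    "spectral_summaries",
    "extract_feature_vector",
    "cohort_feature_table",
]

#: Canonical feature order (frequency domain first, as in the source layout).
FEATURE_NAMES = [
    "PeakF",
    "PeakFPSD",
    "MDP",
    "MNP",
    "FR",
    "wRMS",
    "MMAV1",
    "MMAV2",
    "WL",
    "ZC",
    "SSC",
    "SampEn",
]

#: Features expected to scale linearly with signal amplitude.
AMPLITUDE_FEATURES = ["wRMS", "MMAV1", "MMAV2", "WL"]


class QualityError(RuntimeError):
    """All segments of a recording were rejected as artifacts."""


@dataclass(frozen=True)
class FeatureConfig:
    """Every tunable of the feature-extraction chain, with defaults.

    ``eps_zc`` (µV) and ``eps_ssc`` (µV²) are fixed amplitude thresholds in
    the Hudgins convention: a zero crossing / slope reversal only counts when
    the excursion around it is large enough, which makes both counts respond
    to burst suppression rather than to the noise floor. ``sampen_max_points``
    bounds the O(N²) sample-entropy cost by uniform decimation of the
    retained signal.
    """

    filter: FilterConfig = field(default_factory=FilterConfig)
    envelope: EnvelopeConfig = field(default_factory=EnvelopeConfig)
    seg_s: float = 1.0
    artifact_k: float = 5.0
    eps_zc: float = 50.0
    eps_ssc: float = 1250.0
    sampen_m: int = 2
    sampen_r: float = 0.2
    sampen_max_points: int = 8192
    sampen_cap: float = 10.0
    welch_window_s: float = 2.0
    welch_overlap: float = 0.5
    welch_taper: str = "hann"
    welch_resolution_hz: float = 0.125
    tremor_band: tuple[float, float] = (2.0, 12.0)
    analysis_band: tuple[float, float] = (20.0, 200.0)
    fr_split_hz: float = 60.0
    peak_prominence_ratio: float = 2.5
    channel_reduction: str = "best_off_tremor_power"


@dataclass(frozen=True)
class Spectrum:
    """A one-sided power spectral density on a uniform frequency grid."""

    frequencies: np.ndarray
    psd: np.ndarray
    resolution_hz: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        p = np.asarray(self.psd, dtype=float)
        if f.shape != p.shape:
            raise ValueError("frequencies and psd must have the same shape")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("power density must be non-negative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "psd", p)

    def band_mask(self, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        if lo < self.frequencies[0] - 1e-9 or hi > self.frequencies[-1] + 1e-9:
            raise ValueError(
                f"band {band} outside spectrum range "
                f"[{self.frequencies[0]}, {self.frequencies[-1]}]"
            )
        return (self.frequencies >= lo) & (self.frequencies <= hi)

    def band_power(self, band: tuple[float, float]) -> float:
        mask = self.band_mask(band)
        return float(np.sum(self.psd[mask]) * self.resolution_hz)


@dataclass(frozen=True)
class TremorPeak:
    """Peak of the tremor band in an envelope spectrum (power in dB)."""

    frequency_hz: float
    power_db: float
    detected: bool


@dataclass(frozen=True)
class FeatureVector:
    """The 12 features of one recording, plus extraction metadata."""

    PeakF: float
    PeakFPSD: float
    MDP: float
    MNP: float
    FR: float
    wRMS: float
    MMAV1: float
    MMAV2: float
    WL: float
    ZC: float
    SSC: float
    SampEn: float
    patient_id: str = ""
    condition: Condition = Condition.DBS_OFF
    channel: str = "emg"
    n_segments_used: int = 0
    sampen_capped: bool = False
    tremor_detected: bool = True
    tremor_band_power: float = np.nan

    def to_series(self) -> pd.Series:
        data = {name: getattr(self, name) for name in FEATURE_NAMES}
        data.update(
            patient_id=self.patient_id,
            condition=Condition.parse(self.condition).value,
            channel=self.channel,
            n_segments_used=self.n_segments_used,
            sampen_capped=self.sampen_capped,
            tremor_detected=self.tremor_detected,
            tremor_band_power=self.tremor_band_power,
        )
        return pd.Series(data)


# ---------------------------------------------------------------------------
# time-domain features (per 1-s segment)
# ---------------------------------------------------------------------------

def segment_rms(seg: np.ndarray) -> float:
    """Root mean square of one segment."""
    seg = _as_segment(seg, min_len=1)
    return float(np.sqrt(np.mean(seg * seg)))


def mmav(seg: np.ndarray, variant: int = 1) -> float:
    """Modified mean absolute value.

    Weighted mean of |x| with weight 1 on the central half of (1-based)
    sample indices. Variant 1 uses weight 0.5 on the outer quarters; variant
    2 ramps linearly, 4i/N on the first quarter and 4(N−i)/N on the last.
    """
    seg = _as_segment(seg, min_len=1)
    n = seg.size
    i = np.arange(1, n + 1, dtype=float)
    central = (i >= 0.25 * n) & (i <= 0.75 * n)
    if variant == 1:
        w = np.where(central, 1.0, 0.5)
    elif variant == 2:
        w = np.where(central, 1.0, np.where(i < 0.25 * n, 4 * i / n, 4 * (n - i) / n))
    else:
        raise ValueError("variant must be 1 or 2")
    return float(np.mean(w * np.abs(seg)))


def waveform_length(seg: np.ndarray) -> float:
    """Cumulative waveform length Σ|x_{i+1} − x_i| over the segment."""
    seg = _as_segment(seg, min_len=2)
    return float(np.sum(np.abs(np.diff(seg))))


def zero_crossings(seg: np.ndarray, eps: float = 0.0) -> int:
    """Count sign changes whose amplitude step is at least ``eps`` (µV).

    A zero sample adopts the sign of the previous nonzero sample; crossings
    are counted only between samples of strictly opposite (adopted) sign.
    """
    seg = _as_segment(seg, min_len=2)
    if eps < 0:
        raise ValueError("eps must be >= 0")
    s = np.sign(seg)
    filled = _forward_fill_sign(s)
    step = np.abs(np.diff(seg))
    return int(np.sum((filled[:-1] * filled[1:] < 0) & (step >= eps)))


def slope_sign_changes(seg: np.ndarray, eps: float = 0.0) -> int:
    """Count interior samples where the slope reverses sign.

    Sample i counts when ``(x_i − x_{i−1})(x_i − x_{i+1}) ≥ eps`` (eps in
    µV²), i.e. a local extremum with excursion product above threshold.
    """
    seg = _as_segment(seg, min_len=3)
    if eps < 0:
        raise ValueError("eps must be >= 0")
    left = seg[1:-1] - seg[:-2]
    right = seg[1:-1] - seg[2:]
    return int(np.sum(left * right >= eps))


def sample_entropy(
    x: np.ndarray,
    m: int = 2,
    r: float = 0.2,
    r_is_fraction: bool = True,
    cap: float = 10.0,
) -> tuple[float, bool]:
    """Sample entropy −ln(A/B) with Chebyshev distance, no self-matches.

    ``B`` counts template pairs of length ``m`` within tolerance ``r``;
    ``A`` counts the same pairs still matching at length ``m+1``. With
    ``r_is_fraction`` the tolerance is ``r`` times the SD of ``x``. When no
    m+1 match exists (A = 0) or no m match exists (B = 0) the value is
    capped at ``cap`` and the second return value flags the cap.

    Returns ``(value, capped)``.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < m + 2:
        raise SignalLengthError(f"sample entropy needs >= m+2={m + 2} samples")
    if r_is_fraction:
        sd = float(np.std(x))
        if sd == 0:
            # A constant signal is perfectly regular: every template matches.
            return 0.0, False
        r = r * sd
    if r <= 0:
        raise ValueError("tolerance r must be > 0")

    n_t = n - m  # templates that admit an (m+1)-length extension
    win = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:n_t]
    # KD-tree pair counting under the Chebyshev metric; count_neighbors on a
    # tree against itself counts ordered pairs plus self-matches.
    tree_m = cKDTree(win[:, :m])
    tree_m1 = cKDTree(win)
    b_pairs = (int(tree_m.count_neighbors(tree_m, r, p=np.inf)) - n_t) // 2
    a_pairs = (int(tree_m1.count_neighbors(tree_m1, r, p=np.inf)) - n_t) // 2
    if a_pairs == 0 or b_pairs == 0:
        return float(cap), True
    return float(-np.log(a_pairs / b_pairs)), False


# ---------------------------------------------------------------------------
# frequency-domain features
# ---------------------------------------------------------------------------

def welch_spectrum(
    x: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    overlap: float = 0.5,
    taper: str = "hann",
    resolution_hz: float = 0.125,
) -> Spectrum:
    """Averaged-periodogram PSD with zero-padding to the requested grid.

    The FFT length is padded (next power of two) so the frequency grid is at
    least as fine as ``resolution_hz``.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_s * fs))
    if x.size < nperseg:
        raise SignalLengthError(
            f"signal of {x.size} samples shorter than one Welch window "
            f"({nperseg} samples)"
        )
    nfft = nperseg
    while fs / nfft > resolution_hz:
        nfft *= 2
    freqs, psd = sps.welch(
        x,
        fs=fs,
        window=taper,
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        nfft=nfft,
        detrend="constant",
        scaling="density",
    )
    return Spectrum(
        frequencies=freqs,
        psd=np.maximum(psd, 0.0),
        resolution_hz=fs / nfft,
        params={
            "window_s": window_s,
            "overlap": overlap,
            "taper": taper,
            "nfft": nfft,
        },
    )


def tremor_peak(
    spec: Spectrum,
    band: tuple[float, float] = (2.0, 12.0),
    min_prominence_ratio: float = 2.5,
) -> TremorPeak:
    """Locate the tremor-burst peak in an envelope spectrum.

    Returns the in-band argmax frequency and its power in dB
    (``10·log10(PSD)`` relative to one power unit). Ties break toward the
    lower frequency. When the in-band spectrum carries no power, or the peak
    does not stand above the in-band median by ``min_prominence_ratio``, no
    tremor is declared and both values are NaN (missing, not zero).
    """
    mask = spec.band_mask(band)
    psd = spec.psd[mask]
    freqs = spec.frequencies[mask]
    if psd.size == 0 or np.all(psd <= 0):
        return TremorPeak(np.nan, np.nan, False)
    idx = int(np.argmax(psd))  # argmax returns the first (lowest-f) maximum
    floor = float(np.median(psd))
    if floor > 0 and psd[idx] / floor < min_prominence_ratio:
        return TremorPeak(np.nan, np.nan, False)
    return TremorPeak(
        float(freqs[idx]), float(10.0 * np.log10(psd[idx])), True
    )


def spectral_summaries(
    spec: Spectrum,
    analysis_band: tuple[float, float] = (20.0, 200.0),
    fr_split_hz: float = 60.0,
) -> tuple[float, float, float]:
    """(MDP, MNP, FR) over the analysis band.

    MDP/MNP are the median/mean PSD value across band bins; FR is the ratio
    of summed power below ``fr_split_hz`` to summed power above it (the
    low/high frequency-ratio feature). FR is NaN when the high band carries
    no power.
    """
    lo, hi = analysis_band
    if not (lo < fr_split_hz < hi):
        raise ValueError("fr_split_hz must lie strictly inside analysis_band")
    psd = spec.psd[spec.band_mask(analysis_band)]
    mdp = float(np.median(psd))
    mnp = float(np.mean(psd))
    low = float(np.sum(spec.psd[spec.band_mask((lo, fr_split_hz))]))
    high = float(np.sum(spec.psd[spec.band_mask((fr_split_hz, hi))]))
    fr = low / high if high > 0 else float("nan")
    return mdp, mnp, fr


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

def extract_feature_vector(
    rec: Recording, cfg: FeatureConfig | None = None
) -> FeatureVector:
    """Run the full conditioning + feature chain on one recording.

    Band-pass filter → 1-s segmentation → amplitude-clip artifact rejection →
    per-segment time-domain features averaged over retained segments; sample
    entropy on the (decimated) retained signal; tremor peak from the Welch
    spectrum of the rectified RMS envelope; MDP/MNP/FR from the Welch
    spectrum of the filtered signal.
    """
    cfg = cfg or FeatureConfig()
    y = bandpass_filter(rec.samples, rec.fs, cfg.filter)
    segments = segment_signal(y, rec.fs, cfg.seg_s)
    keep = artifact_mask(segments, cfg.artifact_k)
    if not keep.any():
        raise QualityError(
            f"all {keep.size} segments of {rec.patient_id}/{rec.channel} rejected"
        )
    kept = segments[keep]

    wrms = float(np.mean([segment_rms(s) for s in kept]))
    mmav1 = float(np.mean([mmav(s, 1) for s in kept]))
    mmav2 = float(np.mean([mmav(s, 2) for s in kept]))
    wl = float(np.mean([waveform_length(s) for s in kept]))
    zc = float(np.mean([zero_crossings(s, cfg.eps_zc) for s in kept]))
    ssc = float(np.mean([slope_sign_changes(s, cfg.eps_ssc) for s in kept]))

    retained = kept.ravel()
    stride = max(1, int(np.ceil(retained.size / cfg.sampen_max_points)))
    sampen, capped = sample_entropy(
        retained[::stride], m=cfg.sampen_m, r=cfg.sampen_r, cap=cfg.sampen_cap
    )

    envelope = rms_envelope(full_wave_rectify(retained), rec.fs, cfg.envelope)
    env_spec = welch_spectrum(
        envelope,
        rec.fs,
        window_s=cfg.welch_window_s,
        overlap=cfg.welch_overlap,
        taper=cfg.welch_taper,
        resolution_hz=cfg.welch_resolution_hz,
    )
    peak = tremor_peak(env_spec, cfg.tremor_band, cfg.peak_prominence_ratio)
    band_power = env_spec.band_power(cfg.tremor_band)

    emg_spec = welch_spectrum(
        y,
        rec.fs,
        window_s=cfg.welch_window_s,
        overlap=cfg.welch_overlap,
        taper=cfg.welch_taper,
        resolution_hz=cfg.welch_resolution_hz,
    )
    mdp, mnp, fr = spectral_summaries(emg_spec, cfg.analysis_band, cfg.fr_split_hz)

    return FeatureVector(
        PeakF=peak.frequency_hz,
        PeakFPSD=peak.power_db,
        MDP=mdp,
        MNP=mnp,
        FR=fr,
        wRMS=wrms,
        MMAV1=mmav1,
        MMAV2=mmav2,
        WL=wl,
        ZC=zc,
        SSC=ssc,
        SampEn=sampen,
        patient_id=rec.patient_id,
        condition=rec.condition,
        channel=rec.channel,
        n_segments_used=int(keep.sum()),
        sampen_capped=capped,
        tremor_detected=peak.detected,
        tremor_band_power=band_power,
    )


def cohort_feature_table(
    patients: Sequence[PatientRecord], cfg: FeatureConfig | None = None
) -> pd.DataFrame:
    """Feature table with one row per (patient, condition).

    Multi-channel patients are reduced to one channel per patient by the
    configured rule: ``"best_off_tremor_power"`` keeps, for both conditions,
    the channel with the highest DBS-off tremor-band envelope power;
    ``"mean"`` averages features across channels.
    """
    cfg = cfg or FeatureConfig()
    rows: list[pd.Series] = []
    for patient in patients:
        per_channel: dict[str, dict[Condition, FeatureVector]] = {}
        for cond in (Condition.DBS_OFF, Condition.DBS_ON):
            for rec in patient.recordings_for(cond):
                fv = extract_feature_vector(rec, cfg)
                per_channel.setdefault(rec.channel, {})[cond] = fv
        rows.extend(_reduce_channels(patient.patient_id, per_channel, cfg))
    df = pd.DataFrame(rows).reset_index(drop=True)
    return df


def _reduce_channels(
    patient_id: str,
    per_channel: dict[str, dict[Condition, "FeatureVector"]],
    cfg: FeatureConfig,
) -> list[pd.Series]:
    complete = {
        ch: fvs
        for ch, fvs in per_channel.items()
        if Condition.DBS_OFF in fvs and Condition.DBS_ON in fvs
    }
    if not complete:
        raise QualityError(
            f"patient {patient_id!r}: no channel has both conditions"
        )
    if cfg.channel_reduction == "best_off_tremor_power":
        best = max(
            complete, key=lambda ch: _nan_to_neginf(
                complete[ch][Condition.DBS_OFF].tremor_band_power
            )
        )
        return [complete[best][c].to_series() for c in (Condition.DBS_OFF, Condition.DBS_ON)]
    if cfg.channel_reduction == "mean":
        out = []
        for cond in (Condition.DBS_OFF, Condition.DBS_ON):
            series = [complete[ch][cond].to_series() for ch in sorted(complete)]
            num = pd.DataFrame(series)[FEATURE_NAMES + ["tremor_band_power"]].mean()
            meta = series[0][
                ["patient_id", "condition", "n_segments_used",
                 "sampen_capped", "tremor_detected"]
            ]
            row = pd.concat([num, meta])
            row["channel"] = "mean(%d)" % len(series)
            out.append(row)
        return out
    raise ValueError(f"unknown channel_reduction {cfg.channel_reduction!r}")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _as_segment(seg: np.ndarray, min_len: int) -> np.ndarray:
    seg = np.asarray(seg, dtype=float).ravel()
    if seg.size < min_len:
        raise SignalLengthError(f"segment needs >= {min_len} samples, got {seg.size}")
    return seg


def _forward_fill_sign(s: np.ndarray) -> np.ndarray:
    """Replace zero signs with the previous nonzero sign (0 before any)."""
    out = s.copy()
    nz = out != 0
    idx = np.where(nz, np.arange(out.size), -1)
    idx = np.maximum.accumulate(idx)
    out = np.where(idx >= 0, out[np.maximum(idx, 0)], 0.0)
    return out


def _nan_to_neginf(v: float) -> float:
    return -np.inf if np.isnan(v) else v
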