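"""Signal conditioning for tremor sEMG.

The chain mirrors standard practice for surface-EMG burst analysis:

1. band-pass filtering to the EMG band (default 20–200 Hz) with a Butterworth
   filter whose order is selected automatically as the minimum meeting
   explicit stop-band/ripple specifications, applied forward–backward so the
   output is zero-phase;
2. segmentation into non-overlapping 1-s epochs with automatic amplitude-clip
   artifact rejection;
3. full-wave rectification;
4. a centred sliding-window RMS envelope (default 50 ms) that exposes the
   ~3–8 Hz tremor burst rhythm, which lies below the EMG pass band and is
   therefore only visible in the envelope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "FilterConfig",
    "EnvelopeConfig",
    "FilterDesignError",
    "SignalLengthError",
    "design_bandpass",
    "bandpass_filter",
    "full_wave_rectify",
    "rms_envelope",
    "segment_signal",
    "artifact_mask",
]

logger = logging.getLogger(__name__)


class FilterDesignError(ValueError):
    """The filter specification cannot be met at the given sampling rate."""


class SignalLengthError(ValueError):
    """The signal is too short for the requested operation."""


@dataclass(frozen=True)
class FilterConfig:
    """Band-pass design specification.

    The pass band defaults to 20–200 Hz with stop-band edges at 10 and
    230 Hz, ≤3 dB pass-band ripple and ≥40 dB stop-band attenuation. The
    Butterworth order is chosen automatically as the minimum satisfying these
    specs ("self-adapting order"); with ``zero_phase`` the filter runs
    forward and backward so features that depend on timing (zero crossings,
    slope sign changes, envelope onsets) see no group delay.
    """

    pass_band: tuple[float, float] = (20.0, 200.0)
    stop_band: tuple[float, float] = (10.0, 230.0)
    max_passband_ripple_db: float = 3.0
    min_stopband_atten_db: float = 40.0
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        s_lo, s_hi = self.stop_band
        p_lo, p_hi = self.pass_band
        if not (0 < s_lo < p_lo < p_hi < s_hi < fs / 2):
            raise FilterDesignError(
                f"need 0 < {s_lo} < {p_lo} < {p_hi} < {s_hi} < fs/2={fs / 2}"
            )


@dataclass(frozen=True)
class EnvelopeConfig:
    """Sliding-window RMS envelope parameters (window length in ms)."""

    window_ms: float = 50.0

    def window_samples(self, fs: float) -> int:
        n = int(round(self.window_ms * 1e-3 * fs))
        if n < 2:
            raise ValueError(
                f"window_ms={self.window_ms} gives {n} sample(s) at fs={fs}; need >=2"
            )
        return n


def design_bandpass(fs: float, cfg: FilterConfig | None = None) -> np.ndarray:
    """Design the minimum-order Butterworth band-pass meeting ``cfg``.

    Returns second-order sections. The selected order is logged at DEBUG.
    """
    cfg = cfg or FilterConfig()
    cfg.validate(fs)
    order, wn = signal.buttord(
        wp=list(cfg.pass_band),
        ws=list(cfg.stop_band),
        gpass=cfg.max_passband_ripple_db,
        gstop=cfg.min_stopband_atten_db,
        fs=fs,
    )
    sos = signal.butter(order, wn, btype="bandpass", output="sos", fs=fs)
    logger.debug("band-pass design: order=%d natural=%s fs=%g", order, wn, fs)
    return sos


def bandpass_filter(
    x: np.ndarray, fs: float, cfg: FilterConfig | None = None
) -> np.ndarray:
    """Zero-phase band-pass filter; same length as the input."""
    cfg = cfg or FilterConfig()
    x = np.asarray(x, dtype=float)
    sos = design_bandpass(fs, cfg)
    if cfg.zero_phase:
        padlen = 3 * (2 * sos.shape[0] + 1)
        if x.size <= padlen:
            raise SignalLengthError(
                f"signal of {x.size} samples too short for zero-phase "
                f"filtering (needs > {padlen})"
            )
        return signal.sosfiltfilt(sos, x)
    if x.size <= 3 * (2 * sos.shape[0]):
        raise SignalLengthError("signal too short for stable filtering")
    return signal.sosfilt(sos, x)


def full_wave_rectify(x: np.ndarray) -> np.ndarray:
    """Elementwise absolute value."""
    return np.abs(np.asarray(x, dtype=float))


def rms_envelope(
    x: np.ndarray, fs: float, cfg: EnvelopeConfig | None = None
) -> np.ndarray:
    """Centred sliding-window RMS of ``x``.

    Element ``i`` is the RMS over a window of ``cfg.window_ms`` centred on
    ``i``; at the edges the window shrinks to the available samples (no
    padding, so burst onsets are not diluted with fabricated zeros).
    """
    cfg = cfg or EnvelopeConfig()
    x = np.asarray(x, dtype=float)
    # A 1-sample window degenerates to |x|; normal use needs >=2 samples.
    win = max(int(round(cfg.window_ms * 1e-3 * fs)), 1)
    return _sliding_rms(x, win)


def _sliding_rms(x: np.ndarray, win: int) -> np.ndarray:
    if win > x.size:
        raise SignalLengthError(
            f"envelope window of {win} samples exceeds signal length {x.size}"
        )
    if win == 1:
        return np.abs(x)
    half_lo = (win - 1) // 2
    half_hi = win - 1 - half_lo
    csum = np.concatenate(([0.0], np.cumsum(x * x)))
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi, n - 1)
    sums = csum[hi + 1] - csum[lo]
    counts = hi - lo + 1
    return np.sqrt(sums / counts)


def segment_signal(x: np.ndarray, fs: float, seg_s: float = 1.0) -> np.ndarray:
    """Split into non-overlapping contiguous ``seg_s`` segments.

    Returns an array of shape ``(n_segments, seg_s*fs)``; the trailing
    remainder shorter than one segment is dropped.
    """
    x = np.asarray(x, dtype=float)
    seg_len = int(round(seg_s * fs))
    if seg_len < 1:
        raise ValueError("seg_s*fs must be >= 1 sample")
    n_seg = x.size // seg_len
    if n_seg < 1:
        raise SignalLengthError(
            f"signal of {x.size / fs:.3f}s shorter than one {seg_s}s segment"
        )
    return x[: n_seg * seg_len].reshape(n_seg, seg_len)


def artifact_mask(segments: np.ndarray, k: float = 5.0) -> np.ndarray:
    """Automatic amplitude-clip rejection.

    A segment is rejected when its peak absolute amplitude exceeds ``k``
    times the median per-segment peak — a reproducible stand-in for manual
    artifact screening. Returns a boolean keep-mask; the rejected count is
    logged.
    """
    segments = np.asarray(segments, dtype=float)
    peaks = np.max(np.abs(segments), axis=1)
    med = np.median(peaks)
    if med == 0:
        keep = np.ones(segments.shape[0], dtype=bool)
    else:
        keep = peaks <= k * med
    n_rej = int((~keep).sum())
    if n_rej:
        logger.info("artifact rejection: dropped %d/%d segments", n_rej, keep.size)
    return keep
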