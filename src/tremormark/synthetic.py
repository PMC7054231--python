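"""Synthetic tremor-sEMG cohort generator.

Emulates the statistical structure the analysis pipeline assumes, so every
stage can be exercised without patient data:

* resting-tremor bursts at ``f_tremor ~ N(4.93, 0.98²)`` Hz (truncated to
  3–8 Hz) riding on band-limited EMG noise at 512 Hz;
* DBS-on suppression of the burst gain by a factor ``1 − u_emg``, where the
  EMG-level improvement ``u_emg`` is a noisy copy (coupling ``rho``) of the
  latent clinical improvement ``u ~ Beta`` with mean 0.76 and SD 0.15;
* UPDRS-like scores: tremor subscale pre ``~ N(15.60, 5.13²)`` truncated to
  4–28 and rounded, post derived from the latent improvement; total motor
  score analogous with pre ``~ N(63.42, 17.85²)`` and mean improvement 0.52.

The burst carrier noise is band-limited to 20–100 Hz while the tonic
background spans the full 20–200 Hz EMG band: grouped motor-unit discharges
during tremor bursts concentrate spectral power at lower EMG frequencies, so
suppressing the bursts lowers the low/high frequency ratio and the
large-excursion crossing counts as well as the amplitude features.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io import Condition, PatientRecord, Recording, write_recording
from .preprocess import FilterConfig, bandpass_filter

__all__ = [
    "SimParams",
    "SyntheticPatient",
    "beta_from_moments",
    "synth_emg",
    "synth_patient",
    "synth_cohort",
    "write_cohort",
]


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments Beta(α, β) parameters for a given mean and SD."""
    if not 0 < mean < 1:
        raise ValueError("mean must be in (0, 1)")
    var = sd * sd
    if var >= mean * (1 - mean):
        raise ValueError("variance too large for a Beta distribution")
    nu = mean * (1 - mean) / var - 1.0
    return mean * nu, (1 - mean) * nu


@dataclass(frozen=True)
class SimParams:
    """Cohort-level generator settings (defaults are the study conditions)."""

    n_patients: int = 39
    fs: float = 512.0
    duration_s: float = 60.0
    f_tremor_mean: float = 4.93
    f_tremor_sd: float = 0.98
    f_tremor_bounds: tuple[float, float] = (3.0, 8.0)
    #: off-state burst modulation depth, drawn uniformly from this range
    depth_range: tuple[float, float] = (0.6, 0.95)
    #: fix the modulation depth (overrides depth_range) when not None
    depth: float | None = None
    #: typical off-state burst gain in µV (log-normal median) and log-SD
    gain_median_uv: float = 40.0
    gain_log_sd: float = 0.4
    burst_sharpness: float = 2.0
    #: band of the burst-locked carrier noise vs. the tonic background
    burst_band: tuple[float, float] = (20.0, 100.0)
    noise_band: tuple[float, float] = (20.0, 200.0)
    #: latent clinical improvement distribution (tremor subscale)
    u_mean: float = 0.76
    u_sd: float = 0.15
    #: EMG–clinical coupling: corr(u_emg, u)
    rho: float = 0.7
    #: fraction of the tonic floor that stimulation suppresses at u_emg = 1
    #: (DBS lowers tonic pathological activation as well as the bursts)
    floor_suppression: float = 0.8
    updrs_t_pre_mean: float = 15.60
    updrs_t_pre_sd: float = 5.13
    updrs_t_pre_bounds: tuple[float, float] = (4.0, 28.0)
    updrs_iii_pre_mean: float = 63.42
    updrs_iii_pre_sd: float = 17.85
    updrs_iii_pre_bounds: tuple[float, float] = (20.0, 108.0)
    u_iii_mean: float = 0.52
    u_iii_sd: float = 0.15
    score_noise_sd: float = 0.8
    n_channels: int = 1
    seed: int = 42

    def beta_params(self) -> tuple[float, float]:
        return beta_from_moments(self.u_mean, self.u_sd)


@dataclass
class SyntheticPatient:
    """A PatientRecord plus the latent truth used to generate it."""

    record: PatientRecord
    u: float
    u_emg: float
    u_iii: float
    f_tremor: float
    depth: float
    gain_off: float

    @property
    def patient_id(self) -> str:
        return self.record.patient_id

    def truth_row(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "u": self.u,
            "u_emg": self.u_emg,
            "u_iii": self.u_iii,
            "f_tremor": self.f_tremor,
            "depth": self.depth,
            "gain_off": self.gain_off,
        }


def _bandlimited_noise(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-SD Gaussian noise band-passed to ``band``."""
    lo, hi = band
    stop = (max(lo / 2.0, 1.0), min(hi * 1.15, fs / 2 * 0.98))
    cfg = FilterConfig(pass_band=(lo, hi), stop_band=stop)
    x = bandpass_filter(rng.standard_normal(n), fs, cfg)
    sd = float(np.std(x))
    return x / sd if sd > 0 else x


def synth_emg(
    f_tremor: float,
    gain: float,
    depth: float,
    params: SimParams,
    rng: "np.random.Generator | int",
    *,
    floor: float | None = None,
    patient_id: str = "",
    channel: str = "extensor_digitorum_R",
    condition: "Condition | str" = Condition.DBS_OFF,
) -> Recording:
    """One synthetic sEMG recording.

    ``x(t) = floor·n_bg(t) + gain·m(t)·n_burst(t)`` with ``n_bg`` unit-SD
    noise in the 20–200 Hz EMG band, ``n_burst`` unit-SD noise in the burst
    band, and ``m(t)`` a half-wave-rectified sinusoid at ``f_tremor`` raised
    to a sharpening exponent and normalised to peak 1. The tonic floor
    defaults to ``gain·(1−depth)/depth`` so ``depth`` is the burst
    modulation depth ``gain/(gain+floor)``.
    """
    if not (0 < f_tremor < params.fs / 2):
        raise ValueError(f"f_tremor={f_tremor} must lie in (0, fs/2)")
    if not (0 < depth <= 1):
        raise ValueError("depth must be in (0, 1]")
    if gain < 0:
        raise ValueError("gain must be >= 0")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    n = int(round(params.duration_s * params.fs))
    t = np.arange(n) / params.fs
    phase = rng.uniform(0, 2 * np.pi)
    m = np.maximum(np.sin(2 * np.pi * f_tremor * t + phase), 0.0) ** params.burst_sharpness
    if floor is None:
        floor = gain * (1.0 - depth) / depth
    x = floor * _bandlimited_noise(n, params.fs, params.noise_band, rng)
    if gain > 0:
        x = x + gain * m * _bandlimited_noise(n, params.fs, params.burst_band, rng)
    return Recording(
        samples=x,
        fs=params.fs,
        patient_id=patient_id,
        channel=channel,
        condition=condition,
    )


def _truncnorm(
    mean: float,
    sd: float,
    bounds: tuple[float, float],
    rng: np.random.Generator,
) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if bounds[0] <= v <= bounds[1]:
            return float(v)
    return float(np.clip(mean, *bounds))  # pragma: no cover


def synth_patient(
    params: SimParams,
    rng: "np.random.Generator | int",
    patient_id: str = "P001",
    *,
    u: "float | None" = None,
    u_emg: "float | None" = None,
) -> SyntheticPatient:
    """Draw one patient: latent improvement, scores, off/on recordings.

    ``u`` / ``u_emg`` force the latent clinical and EMG improvements
    (useful for probing the null-patient and full-responder regimes).
    """
    from scipy import stats as _st

    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    alpha, beta = params.beta_params()
    # Gaussian copula: both improvements share the Beta(α, β) marginal and
    # correlate at rho without boundary clipping (which would pile mass at 1
    # and destroy the intended rank coupling).
    rho = params.rho
    if u is None:
        z_u = rng.standard_normal()
        u = float(_st.beta.ppf(_st.norm.cdf(z_u), alpha, beta))
    else:
        # forced u: place it on the copula's latent scale so u_emg stays
        # coherently coupled
        z_u = float(
            _st.norm.ppf(np.clip(_st.beta.cdf(u, alpha, beta), 1e-12, 1 - 1e-12))
        )
    if u_emg is None:
        z_e = rho * z_u + np.sqrt(max(1.0 - rho * rho, 0.0)) * rng.standard_normal()
        u_emg = float(_st.beta.ppf(_st.norm.cdf(z_e), alpha, beta))
    u_iii = float(
        np.clip(
            params.u_iii_mean
            + 0.6 * (u - params.u_mean)
            + 0.8 * rng.normal(0.0, params.u_iii_sd),
            0.0,
            1.0,
        )
    )
    f_tremor = _truncnorm(
        params.f_tremor_mean, params.f_tremor_sd, params.f_tremor_bounds, rng
    )
    depth = (
        params.depth
        if params.depth is not None
        else float(rng.uniform(*params.depth_range))
    )
    gain_off = float(
        params.gain_median_uv * np.exp(rng.normal(0.0, params.gain_log_sd))
    )
    floor = gain_off * (1.0 - depth) / depth

    updrs_t_pre = round(
        _truncnorm(
            params.updrs_t_pre_mean,
            params.updrs_t_pre_sd,
            params.updrs_t_pre_bounds,
            rng,
        )
    )
    updrs_t_post = max(
        0, round(updrs_t_pre * (1.0 - u) + rng.normal(0.0, params.score_noise_sd))
    )
    updrs_iii_pre = round(
        _truncnorm(
            params.updrs_iii_pre_mean,
            params.updrs_iii_pre_sd,
            params.updrs_iii_pre_bounds,
            rng,
        )
    )
    updrs_iii_post = max(
        0,
        round(updrs_iii_pre * (1.0 - u_iii) + rng.normal(0.0, params.score_noise_sd)),
    )

    channels = _channel_labels(params.n_channels)
    recordings: dict[Condition, list[Recording]] = {
        Condition.DBS_OFF: [],
        Condition.DBS_ON: [],
    }
    gain_on = gain_off * (1.0 - u_emg)
    floor_on = floor * (1.0 - params.floor_suppression * u_emg)
    for i, channel in enumerate(channels):
        # secondary channels carry a weaker copy of the tremor
        scale = 1.0 if i == 0 else float(rng.uniform(0.2, 0.6))
        recordings[Condition.DBS_OFF].append(
            synth_emg(
                f_tremor,
                gain_off * scale,
                depth,
                params,
                rng,
                floor=floor * scale,
                patient_id=patient_id,
                channel=channel,
                condition=Condition.DBS_OFF,
            )
        )
        recordings[Condition.DBS_ON].append(
            synth_emg(
                f_tremor,
                gain_on * scale,
                depth,
                params,
                rng,
                floor=floor_on * scale,
                patient_id=patient_id,
                channel=channel,
                condition=Condition.DBS_ON,
            )
        )
    record = PatientRecord(
        patient_id=patient_id,
        recordings=recordings,
        updrs_iii_pre=float(updrs_iii_pre),
        updrs_iii_post=float(updrs_iii_post),
        updrs_t_pre=float(updrs_t_pre),
        updrs_t_post=float(updrs_t_post),
        truth={"u": u, "u_emg": u_emg, "f_tremor": f_tremor},
    )
    return SyntheticPatient(
        record=record,
        u=u,
        u_emg=u_emg,
        u_iii=u_iii,
        f_tremor=f_tremor,
        depth=depth,
        gain_off=gain_off,
    )


def synth_cohort(params: SimParams | None = None) -> list[SyntheticPatient]:
    """Generate ``params.n_patients`` patients, deterministic under seed."""
    params = params or SimParams()
    seeds = np.random.SeedSequence(params.seed).spawn(params.n_patients)
    return [
        synth_patient(params, np.random.default_rng(s), patient_id=f"P{i + 1:03d}")
        for i, s in enumerate(seeds)
    ]


def write_cohort(
    patients: Sequence[SyntheticPatient],
    out_dir: "str | Path",
    params: SimParams | None = None,
) -> Path:
    """Write a self-contained cohort directory.

    Layout: ``manifest.csv``, ``recordings/*.csv``, ``truth.csv`` and
    ``params.yaml``. Returns the manifest path.
    """
    out_dir = Path(out_dir)
    rec_dir = out_dir / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for patient in patients:
        rec_map = patient.record.recordings
        for cond, recs in rec_map.items():
            for rec in recs:
                fname = f"{patient.patient_id}_{cond.value}_{rec.channel}.csv"
                write_recording(rec, rec_dir / fname)
                rows.append(
                    {
                        "patient_id": patient.patient_id,
                        "condition": cond.value,
                        "channel": rec.channel,
                        "file": f"recordings/{fname}",
                        "UPDRS_III_pre": patient.record.updrs_iii_pre,
                        "UPDRS_III_post": patient.record.updrs_iii_post,
                        "UPDRS_t_pre": patient.record.updrs_t_pre,
                        "UPDRS_t_post": patient.record.updrs_t_post,
                    }
                )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    pd.DataFrame([p.truth_row() for p in patients]).to_csv(
        out_dir / "truth.csv", index=False
    )
    if params is not None:
        with open(out_dir / "params.yaml", "w") as fh:
            yaml.safe_dump(_params_to_dict(params), fh, sort_keys=False)
    return manifest


def _params_to_dict(params: SimParams) -> dict:
    from dataclasses import asdict

    out = asdict(params)
    for key, value in out.items():
        if isinstance(value, tuple):
            out[key] = list(value)
    return out


def _channel_labels(n: int) -> list[str]:
    base = [
        "extensor_digitorum_R",
        "flexor_digitorum_superficialis_R",
        "tibialis_anterior_R",
        "gastrocnemius_R",
    ]
    if n < 1:
        raise ValueError("n_channels must be >= 1")
    return base[:n] if n <= len(base) else base + [f"emg_{i}" for i in range(len(base), n)]
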