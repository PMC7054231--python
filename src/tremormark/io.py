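"""Recording and cohort I/O.

Defines the shared data model (:class:`Recording`, :class:`PatientRecord`) and
readers/writers for the on-disk formats: one CSV per recording (header
``time_s,amplitude_uV`` or ``amplitude_uV`` alone) and a cohort manifest CSV
binding recordings to patients, conditions, channels and UPDRS scores.

Amplitudes are microvolts (µV) throughout the package; manifests carry no unit
column. EDF files are accepted as an optional read-only input path when
:mod:`mne` is importable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "Recording",
    "PatientRecord",
    "RecordingFormatError",
    "ManifestError",
    "read_recording",
    "read_recording_edf",
    "write_recording",
    "read_manifest",
    "load_cohort",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = [
    "patient_id",
    "condition",
    "channel",
    "file",
    "UPDRS_III_pre",
    "UPDRS_III_post",
    "UPDRS_t_pre",
    "UPDRS_t_post",
]

#: Relative tolerance for agreement between a time column and a stated rate.
_FS_RTOL = 1e-3


class RecordingFormatError(ValueError):
    """A recording file violates the on-disk format contract."""


class ManifestError(ValueError):
    """A cohort manifest is inconsistent (missing condition, dangling file...)."""


class Condition(str, enum.Enum):
    """Stimulation state during the recording."""

    DBS_OFF = "DBS_OFF"
    DBS_ON = "DBS_ON"

    @classmethod
    def parse(cls, value: "str | Condition") -> "Condition":
        if isinstance(value, Condition):
            return value
        key = str(value).strip().upper().replace("-", "_").replace(" ", "_")
        if key in ("OFF", "DBS_OFF", "BASELINE"):
            return cls.DBS_OFF
        if key in ("ON", "DBS_ON", "STIM_ON"):
            return cls.DBS_ON
        raise ValueError(f"unknown condition {value!r}")


@dataclass(frozen=True)
class Recording:
    """A uniformly sampled single-channel sEMG trace.

    Parameters
    ----------
    samples : ndarray
        Amplitude values in µV. Must be finite and non-empty.
    fs : float
        Sampling rate in Hz (the acquisition system in the source cohort ran
        at 512 Hz).
    patient_id, channel : str
        Metadata; ``channel`` is a muscle label such as
        ``"extensor_digitorum_L"``.
    condition : Condition
        DBS_OFF (baseline after lead implantation) or DBS_ON.
    """

    samples: np.ndarray
    fs: float
    patient_id: str = ""
    channel: str = "emg"
    condition: Condition = Condition.DBS_OFF

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D vector")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if not (self.fs > 0):
            raise ValueError("fs must be positive")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "condition", Condition.parse(self.condition))

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray) -> "Recording":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass
class PatientRecord:
    """One patient: paired DBS-off/on recordings plus clinical scores.

    ``recordings`` maps condition -> list of channel recordings. ``truth``
    optionally carries latent simulation ground truth for synthetic cohorts.
    """

    patient_id: str
    recordings: dict[Condition, list[Recording]]
    updrs_iii_pre: float
    updrs_iii_post: float
    updrs_t_pre: float
    updrs_t_post: float
    truth: dict = field(default_factory=dict)

    def recordings_for(self, condition: "Condition | str") -> list[Recording]:
        return self.recordings.get(Condition.parse(condition), [])

    def validate(self) -> None:
        for cond in (Condition.DBS_OFF, Condition.DBS_ON):
            if not self.recordings.get(cond):
                raise ManifestError(
                    f"patient {self.patient_id!r} has no {cond.value} recording"
                )
        for name in ("updrs_iii_pre", "updrs_iii_post", "updrs_t_pre", "updrs_t_post"):
            value = getattr(self, name)
            if value is None or not np.isfinite(value):
                raise ManifestError(
                    f"patient {self.patient_id!r} is missing {name}"
                )
            if value < 0:
                raise ManifestError(
                    f"patient {self.patient_id!r} has negative {name}={value}"
                )


def read_recording(
    path: "str | Path",
    meta: Mapping[str, object] | None = None,
) -> Recording:
    """Read one recording CSV.

    The file holds either a single ``amplitude_uV`` column or
    ``time_s,amplitude_uV``. When a time column is present, the sampling rate
    is inferred from the median spacing; it must be uniform to within 0.1 %
    and agree with ``meta['fs']`` (within 0.1 %) when both are given.
    """
    path = Path(path)
    meta = dict(meta or {})
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise RecordingFormatError(f"{path}: {exc}") from exc

    if "amplitude_uV" not in df.columns:
        raise RecordingFormatError(
            f"{path}: expected an 'amplitude_uV' column, got {list(df.columns)}"
        )
    amp = pd.to_numeric(df["amplitude_uV"], errors="coerce").to_numpy()
    bad = np.flatnonzero(~np.isfinite(amp))
    if bad.size:
        # +2: one for the header line, one for 1-based numbering
        raise RecordingFormatError(
            f"{path}: non-numeric or non-finite amplitude at data row {bad[0] + 2}"
        )

    fs = meta.get("fs")
    if "time_s" in df.columns:
        t = pd.to_numeric(df["time_s"], errors="coerce").to_numpy()
        if not np.all(np.isfinite(t)):
            row = int(np.flatnonzero(~np.isfinite(t))[0]) + 2
            raise RecordingFormatError(f"{path}: non-numeric time at data row {row}")
        dt = np.diff(t)
        if dt.size == 0:
            raise RecordingFormatError(f"{path}: a time column needs >= 2 rows")
        med = float(np.median(dt))
        if med <= 0 or np.any(np.abs(dt - med) > _FS_RTOL * med):
            raise RecordingFormatError(
                f"{path}: time column is not uniformly spaced (>0.1% jitter)"
            )
        fs_inferred = 1.0 / med
        if fs is not None and abs(fs_inferred - float(fs)) > _FS_RTOL * float(fs):
            raise RecordingFormatError(
                f"{path}: time column implies fs={fs_inferred:.4f} Hz, "
                f"metadata says {fs}"
            )
        fs = float(fs) if fs is not None else fs_inferred
    elif fs is None:
        raise RecordingFormatError(
            f"{path}: no time column and no sampling rate in metadata"
        )

    return Recording(
        samples=amp,
        fs=float(fs),
        patient_id=str(meta.get("patient_id", "")),
        channel=str(meta.get("channel", "emg")),
        condition=Condition.parse(meta.get("condition", Condition.DBS_OFF)),
    )


def read_recording_edf(
    path: "str | Path",
    meta: Mapping[str, object] | None = None,
    channel_index: int = 0,
) -> Recording:
    """Read one channel from an EDF file (optional input path, needs ``mne``)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF reading requires the optional 'mne' dependency"
        ) from exc
    meta = dict(meta or {})
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()[channel_index] * 1e6  # volts -> µV
    return Recording(
        samples=data,
        fs=float(raw.info["sfreq"]),
        patient_id=str(meta.get("patient_id", "")),
        channel=str(meta.get("channel", raw.ch_names[channel_index])),
        condition=Condition.parse(meta.get("condition", Condition.DBS_OFF)),
    )


def write_recording(
    rec: Recording, path: "str | Path", include_time: bool = False
) -> Path:
    """Write a recording CSV; round-trips samples to >= 6 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if include_time:
        df = pd.DataFrame({"time_s": rec.time(), "amplitude_uV": rec.samples})
    else:
        df = pd.DataFrame({"amplitude_uV": rec.samples})
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def read_manifest(manifest_path: "str | Path") -> pd.DataFrame:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, dtype={"patient_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{manifest_path}: missing manifest columns {missing}")
    dup = df.duplicated(subset=["patient_id", "condition", "channel"], keep=False)
    if dup.any():
        rows = df.loc[dup, ["patient_id", "condition", "channel"]]
        raise ManifestError(
            "duplicate (patient_id, condition, channel) rows:\n"
            + rows.to_string(index=False)
        )
    return df


def load_cohort(manifest_path: "str | Path") -> list[PatientRecord]:
    """Load a cohort manifest and its recordings.

    Returns one :class:`PatientRecord` per patient, sorted by ``patient_id``
    (so the result is invariant to manifest row order). Raises
    :class:`ManifestError` naming the offending patient/row on any
    inconsistency.
    """
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    base = manifest_path.parent
    patients: list[PatientRecord] = []
    for pid, group in sorted(df.groupby("patient_id", sort=True)):
        scores = {}
        for col in ("UPDRS_III_pre", "UPDRS_III_post", "UPDRS_t_pre", "UPDRS_t_post"):
            vals = pd.unique(group[col])
            if len(vals) != 1:
                raise ManifestError(
                    f"patient {pid!r}: inconsistent {col} values {list(vals)}"
                )
            scores[col] = float(vals[0])
        recs: dict[Condition, list[Recording]] = {}
        for row in group.itertuples():
            fpath = Path(row.file)
            if not fpath.is_absolute():
                fpath = base / fpath
            if not fpath.exists():
                raise ManifestError(
                    f"patient {pid!r}: recording file not found: {row.file}"
                )
            cond = Condition.parse(row.condition)
            rec = read_recording(
                fpath,
                meta={
                    "fs": None,
                    "patient_id": pid,
                    "channel": row.channel,
                    "condition": cond,
                },
            ) if _has_time_column(fpath) else read_recording(
                fpath,
                meta={
                    "fs": _default_fs(group),
                    "patient_id": pid,
                    "channel": row.channel,
                    "condition": cond,
                },
            )
            recs.setdefault(cond, []).append(rec)
        record = PatientRecord(
            patient_id=str(pid),
            recordings=recs,
            updrs_iii_pre=scores["UPDRS_III_pre"],
            updrs_iii_post=scores["UPDRS_III_post"],
            updrs_t_pre=scores["UPDRS_t_pre"],
            updrs_t_post=scores["UPDRS_t_post"],
        )
        record.validate()
        patients.append(record)
    return patients


def _has_time_column(path: Path) -> bool:
    with open(path) as fh:
        header = fh.readline()
    return "time_s" in header


def _default_fs(group: pd.DataFrame) -> float:
    # Manifests may carry an optional fs column; 512 Hz is the package default.
    if "fs" in group.columns:
        return float(group["fs"].iloc[0])
    return 512.0
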