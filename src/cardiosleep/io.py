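"""Reading and writing the formats the pipeline touches.

Signals come in as EDF (one ECG channel, one thoracic respiratory-effort
channel), per-epoch sleep stages and apnea-event intervals as delimited text.
Stages are scored on the standard 30 s grid; epoch ``i`` covers the half-open
window ``[30*i, 30*(i+1))`` seconds from recording start and a trailing
partial window is dropped.

EDF reading is delegated to :mod:`mne`. Writing uses a minimal EDF writer
(16-bit samples, 1 s data records) sufficient for the synthetic recordings
this package generates.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import EPOCH_LEN_S
from .errors import (
    ChannelNotFoundError,
    FormatError,
    GridError,
    ParameterError,
    VocabularyError,
)

STAGES = ("W", "N1", "N2", "N3", "REM")
_STAGE_SYNONYMS = {
    "W": "W", "WAKE": "W",
    "N1": "N1", "N2": "N2", "N3": "N3",
    "R": "REM", "REM": "REM",
}
#: Sleep/wake label convention: class 0 is Sleep, class 1 is Wake.
SLEEP, WAKE = 0, 1


def canonical_stage(code: str) -> str:
    """Map a stage code (case-insensitive, 'R' synonym allowed) to the
    canonical vocabulary, raising :class:`VocabularyError` otherwise."""
    key = str(code).strip().upper()
    if key not in _STAGE_SYNONYMS:
        raise VocabularyError(f"unknown sleep stage code: {code!r}")
    return _STAGE_SYNONYMS[key]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """A two-channel cardiorespiratory recording.

    Both channels are assumed to start at the same instant. ``ahi_reference``
    is the clinical apnea-hypopnea index (events per hour of sleep), carried
    only for evaluation and cohort splitting, never used by the classifier.
    """

    patient_id: str
    ecg: np.ndarray
    ecg_fs: float
    rip: np.ndarray
    rip_fs: float
    ahi_reference: float | None = None

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.rip = np.asarray(self.rip, dtype=float)
        if self.ecg_fs <= 0 or self.rip_fs <= 0:
            raise ParameterError("sampling rates must be positive")
        if self.ecg.ndim != 1 or self.rip.ndim != 1:
            raise ParameterError("channels must be 1-D sample arrays")

    @property
    def duration_s(self) -> float:
        """Common duration covered by both channels, in seconds."""
        return min(len(self.ecg) / self.ecg_fs, len(self.rip) / self.rip_fs)

    @property
    def n_epochs(self) -> int:
        return int(self.duration_s // EPOCH_LEN_S)


@dataclass
class Hypnogram:
    """Per-epoch sleep stages plus apnea-event intervals.

    ``stages`` holds one canonical stage code per 30 s epoch;
    ``apnea_events`` is a list of ``[start_s, end_s)`` intervals.
    """

    stages: list[str]
    apnea_events: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    epoch_len_s: float = EPOCH_LEN_S

    def __post_init__(self) -> None:
        self.stages = [canonical_stage(s) for s in self.stages]
        ev = np.asarray(self.apnea_events, dtype=float).reshape(-1, 2)
        if len(ev) and np.any(ev[:, 1] <= ev[:, 0]):
            raise GridError("apnea event intervals must have positive length")
        if len(ev) and np.any(ev[:, 0] < 0):
            raise GridError("apnea event intervals must start at t >= 0")
        span = len(self.stages) * self.epoch_len_s
        if len(ev) and np.any(ev[:, 1] > span):
            raise GridError("apnea event extends beyond the scored recording span")
        self.apnea_events = ev

    @property
    def n_epochs(self) -> int:
        return len(self.stages)


@dataclass(frozen=True)
class EpochGrid:
    """The 0-based, half-open 30 s epoch grid of one recording."""

    n_epochs: int
    epoch_len_s: float = EPOCH_LEN_S

    @classmethod
    def from_duration(cls, duration_s: float) -> "EpochGrid":
        return cls(int(duration_s // EPOCH_LEN_S))

    def start_s(self, i: int) -> float:
        return i * self.epoch_len_s

    def sample_slice(self, i: int, fs: float) -> slice:
        """Index slice of epoch ``i`` in a channel sampled at ``fs`` Hz."""
        n = int(round(self.epoch_len_s * fs))
        return slice(i * n, (i + 1) * n)

    def overlaps(self, intervals: np.ndarray) -> np.ndarray:
        """Boolean per-epoch mask: does any ``[start, end)`` interval intersect
        the epoch window?"""
        out = np.zeros(self.n_epochs, dtype=bool)
        iv = np.asarray(intervals, dtype=float).reshape(-1, 2)
        starts = np.arange(self.n_epochs) * self.epoch_len_s
        for s, e in iv:
            out |= (s < starts + self.epoch_len_s) & (e > starts)
        return out


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    b = str(value).encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(path: str | Path, channels: Sequence[tuple[str, np.ndarray, float]],
              patient_id: str = "X", physical_dims: Sequence[str] | None = None) -> None:
    """Write ``(label, samples, fs)`` channels to a minimal EDF file.

    Uses 1 s data records, so every sampling rate must be a positive integer;
    samples beyond the last whole second are dropped. Amplitudes are scaled
    channel-wise to the full 16-bit digital range.
    """
    if not channels:
        raise ParameterError("at least one channel required")
    rates = []
    for _, _, fs in channels:
        if fs <= 0 or abs(fs - round(fs)) > 1e-9:
            raise ParameterError("EDF writer requires integer sampling rates")
        rates.append(int(round(fs)))
    n_records = min(len(x) // r for (_, x, _), r in zip(channels, rates))
    if n_records == 0:
        raise ParameterError("channels are shorter than one 1 s data record")
    ns = len(channels)
    if physical_dims is None:
        physical_dims = [""] * ns

    dig_min, dig_max = -32768, 32767
    phys = []
    digital = []
    for (label, x, _), r in zip(channels, rates):
        x = np.asarray(x, dtype=float)[: n_records * r]
        pmin, pmax = float(np.min(x)), float(np.max(x))
        if pmax <= pmin:  # constant channel: avoid zero scale
            pmax = pmin + 1.0
        scale = (dig_max - dig_min) / (pmax - pmin)
        d = np.rint((x - pmin) * scale + dig_min).astype(np.int16)
        phys.append((pmin, pmax))
        digital.append(d.reshape(n_records, r))

    header = b""
    header += _edf_field("0", 8)
    header += _edf_field(patient_id, 80)
    header += _edf_field("cardiosleep synthetic", 80)
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(str(256 * (1 + ns)), 8)
    header += _edf_field("", 44)
    header += _edf_field(str(n_records), 8)
    header += _edf_field("1", 8)
    header += _edf_field(str(ns), 4)
    # signal headers are field-major: all labels, then all transducers, ...
    header += b"".join(_edf_field(lbl, 16) for lbl, _, _ in channels)
    header += b"".join(_edf_field("", 80) for _ in channels)
    header += b"".join(_edf_field(dim, 8) for dim in physical_dims)
    header += b"".join(_edf_field(f"{pmin:.6g}", 8) for pmin, _ in phys)
    header += b"".join(_edf_field(f"{pmax:.6g}", 8) for _, pmax in phys)
    header += b"".join(_edf_field(str(dig_min), 8) for _ in channels)
    header += b"".join(_edf_field(str(dig_max), 8) for _ in channels)
    header += b"".join(_edf_field("", 80) for _ in channels)
    header += b"".join(_edf_field(str(r), 8) for r in rates)
    header += b"".join(_edf_field("", 32) for _ in channels)

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            for d in digital:
                fh.write(struct.pack(f"<{d.shape[1]}h", *d[rec]))


def _read_edf_channel(path: Path, label: str):
    """Read one channel at its native rate via mne."""
    import mne

    try:
        raw = mne.io.read_raw_edf(path, include=[label], preload=True, verbose="error")
    except Exception as exc:  # unreadable header or truncated file
        raise FormatError(f"could not read EDF file {path}: {exc}") from exc
    if label not in raw.ch_names:
        raise ChannelNotFoundError(f"channel {label!r} not found in {path}")
    data = raw.get_data(picks=[label])[0]
    fs = float(raw.info["sfreq"])
    # undo mne's conversion of dimensioned channels to SI base units
    orig_units = getattr(raw, "_orig_units", {}) or {}
    unit = str(orig_units.get(label, "")).strip().lower()
    factor = {"mv": 1e3, "uv": 1e6, "µv": 1e6, "v": 1.0}.get(unit)
    if factor is not None:
        data = data * factor
    return data, fs


def read_edf(path: str | Path, ecg_label: str = "ECG", rip_label: str = "Thorax",
             patient_id: str | None = None, ahi_reference: float | None = None) -> Recording:
    """Read the ECG and respiratory-effort channels of an EDF file.

    Channels may have different sampling rates; each is read at its native
    rate. Raises :class:`ChannelNotFoundError` if a named channel is absent
    and :class:`FormatError` for an unreadable file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ecg, ecg_fs = _read_edf_channel(path, ecg_label)
    rip, rip_fs = _read_edf_channel(path, rip_label)
    return Recording(
        patient_id=patient_id or path.stem,
        ecg=ecg, ecg_fs=ecg_fs, rip=rip, rip_fs=rip_fs,
        ahi_reference=ahi_reference,
    )


# ---------------------------------------------------------------------------
# hypnogram / event tables
# ---------------------------------------------------------------------------

def write_hypnogram(path: str | Path, stages: Sequence[str]) -> None:
    pd.DataFrame({"epoch_index": np.arange(len(stages)), "stage": list(stages)}
                 ).to_csv(path, index=False)


def write_events(path: str | Path, events: np.ndarray) -> None:
    ev = np.asarray(events, dtype=float).reshape(-1, 2)
    pd.DataFrame({"start_s": ev[:, 0], "end_s": ev[:, 1]}).to_csv(path, index=False)


def read_hypnogram(path: str | Path, n_epochs: int,
                   events_path: str | Path | None = None) -> Hypnogram:
    """Read a per-epoch stage table (columns ``epoch_index,stage``) and an
    optional event table (columns ``start_s,end_s``).

    The table must cover exactly ``n_epochs`` rows with consecutive indices
    from 0; a mismatch raises :class:`GridError`, an unknown stage code
    :class:`VocabularyError`.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"could not parse hypnogram file {path}: {exc}") from exc
    if not {"epoch_index", "stage"}.issubset(df.columns):
        raise FormatError(f"{path} must have columns epoch_index,stage")
    df = df.sort_values("epoch_index")
    if len(df) != n_epochs:
        raise GridError(
            f"hypnogram has {len(df)} epochs but the recording grid has {n_epochs}")
    if not np.array_equal(df["epoch_index"].to_numpy(), np.arange(n_epochs)):
        raise GridError("epoch_index must be consecutive integers from 0")
    events = np.empty((0, 2))
    if events_path is not None:
        try:
            ev = pd.read_csv(events_path)
        except Exception as exc:
            raise FormatError(f"could not parse events file {events_path}: {exc}") from exc
        if not {"start_s", "end_s"}.issubset(ev.columns):
            raise FormatError(f"{events_path} must have columns start_s,end_s")
        events = ev[["start_s", "end_s"]].to_numpy(dtype=float)
    return Hypnogram(stages=list(df["stage"]), apnea_events=events)


def collapse_to_sleep_wake(h: Hypnogram) -> np.ndarray:
    """Collapse five stages to the binary convention Sleep=0, Wake=1."""
    return np.array([WAKE if s == "W" else SLEEP for s in h.stages], dtype=int)


# ---------------------------------------------------------------------------
# cohort manifest
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV.

    Required columns: ``patient_id, edf_path, hypnogram_path, ahi``;
    ``events_path`` is optional (empty = no scored events). Relative paths are
    resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"patient_id", "edf_path", "hypnogram_path", "ahi"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    if "events_path" not in df.columns:
        df["events_path"] = ""
    for col in ("edf_path", "hypnogram_path", "events_path"):
        df[col] = [
            str((path.parent / p).resolve()) if p and not Path(str(p)).is_absolute() else str(p or "")
            for p in df[col].fillna("")
        ]
    return df
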