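"""Respiratory-effort (RIP) preprocessing.

Each 30 s thoracic-effort segment is band-pass filtered at [0.04, 2] Hz with
a zero-phase 4th-order Butterworth filter (the segment is extended by 60 s of
autoregressive extrapolation per border, since the 0.04 Hz edge settles over
tens of seconds and naive reflection injects border kinks with in-band
energy), resampled to 4 Hz by cubic-spline
evaluation, and normalized per recording: subtract the median of the
per-epoch medians and divide by the median of the per-epoch SDs, then
re-center every epoch to median zero. Epochs whose paired tachogram epoch
was discarded are discarded here too, so the network always consumes
matching pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .config import EPOCH_LEN_S, EPOCH_SAMPLES, TARGET_FS, RipConfig
from .ecg import IhrEpoch
from .errors import DegenerateRecordingError, GridError, ParameterError


@dataclass
class RipEpoch:
    """One 120-sample normalized respiratory-effort epoch."""

    values: np.ndarray = field(default_factory=lambda: np.full(EPOCH_SAMPLES, np.nan))
    valid: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (EPOCH_SAMPLES,):
            raise ParameterError(f"RIP epoch must have {EPOCH_SAMPLES} samples")


def _ar_extend(x: np.ndarray, npad: int, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Autoregressive edge extension (Yule-Walker fit, lfilter extrapolation).

    Returns (backward, forward) continuations of length ``npad``. Falls back
    to constant extension for degenerate or unstable fits.
    """
    m = float(np.mean(x))
    xc = x - m
    n = len(xc)
    order = min(order, n - 1)
    const = (np.full(npad, x[0]), np.full(npad, x[-1]))
    r = np.correlate(xc, xc, "full")[n - 1:n + order] / n
    if r[0] <= 0 or order < 1:
        return const
    R = np.empty((order, order))
    for i in range(order):
        for j in range(order):
            R[i, j] = r[abs(i - j)]
    try:
        a = np.linalg.solve(R + 1e-9 * r[0] * np.eye(order), r[1:order + 1])
    except np.linalg.LinAlgError:
        return const
    den = np.r_[1.0, -a]

    def extrapolate(history: np.ndarray) -> np.ndarray:
        zi = signal.lfiltic([1.0], den, y=history[::-1][:order])
        out, _ = signal.lfilter([1.0], den, np.zeros(npad), zi=zi)
        return out

    fwd = extrapolate(xc) + m
    bwd = extrapolate(xc[::-1])[::-1] + m
    bound = 10.0 * max(np.max(np.abs(x)), 1e-12)
    if np.max(np.abs(fwd)) > bound or np.max(np.abs(bwd)) > bound:
        return const
    return bwd, fwd


def filter_resample(segment: np.ndarray, fs: float, cfg: RipConfig | None = None) -> np.ndarray:
    """Band-pass one 30 s segment at [0.04, 2] Hz and resample to 4 Hz.

    The filter is applied forward-backward (zero phase) on the segment
    extended per border by ``edge_pad_s`` seconds of autoregressive
    extrapolation — a smooth continuation that keeps the long-settling
    0.04 Hz edge and the border discontinuity of any naive padding out of
    the segment. The extension is cropped before cubic-spline evaluation on
    the 120-point grid.
    """
    cfg = cfg or RipConfig()
    if fs <= TARGET_FS:
        raise ParameterError(f"RIP sampling rate must exceed {TARGET_FS} Hz")
    x = np.asarray(segment, dtype=float)
    pad = int(round(cfg.edge_pad_s * fs))
    bwd, fwd = _ar_extend(x, pad, cfg.ar_order)
    ext = np.concatenate([bwd, x, fwd])
    sos = signal.butter(cfg.filter_order, list(cfg.band_hz), btype="band", fs=fs,
                        output="sos")
    filt = signal.sosfiltfilt(sos, ext)[pad:pad + len(x)]
    t = np.arange(len(x)) / fs
    grid = np.arange(EPOCH_SAMPLES) / TARGET_FS
    return CubicSpline(t, filt)(np.minimum(grid, t[-1]))


def normalize_recording(epochs: list[RipEpoch], cfg: RipConfig | None = None) -> list[RipEpoch]:
    """Normalize all epochs of one recording.

    With M the 50th percentile of the per-epoch medians and S the 50th
    percentile of the per-epoch SDs (population formula), every sample maps
    to (x - M) / S, after which each epoch's own median is subtracted, so
    every output epoch has median exactly zero. Statistics pool *all*
    candidate epochs, before any discard propagation. Raises
    :class:`DegenerateRecordingError` when S is zero.
    """
    if not epochs:
        raise ParameterError("no epochs to normalize")
    meds = np.array([np.median(e.values) for e in epochs])
    sds = np.array([np.std(e.values) for e in epochs])
    m50 = np.percentile(meds, 50)
    s50 = np.percentile(sds, 50)
    if s50 == 0:
        raise DegenerateRecordingError("all RIP epochs are constant; cannot normalize")
    out = []
    for e in epochs:
        v = (e.values - m50) / s50
        v = v - np.median(v)
        out.append(RipEpoch(values=v, valid=e.valid))
    return out


def propagate_discards(rip: list[RipEpoch], ihr: list[IhrEpoch]) -> list[RipEpoch]:
    """Discard every RIP epoch whose paired tachogram epoch was discarded."""
    if len(rip) != len(ihr):
        raise GridError(f"modalities disagree on the grid: {len(rip)} vs {len(ihr)} epochs")
    return [RipEpoch(values=r.values, valid=r.valid and e.valid)
            for r, e in zip(rip, ihr)]


def preprocess_rip(rip: np.ndarray, fs: float, n_epochs: int,
                   cfg: RipConfig | None = None) -> list[RipEpoch]:
    """Full per-recording RIP pipeline (before discard propagation)."""
    cfg = cfg or RipConfig()
    seg_len = int(round(EPOCH_LEN_S * fs))
    epochs = [
        RipEpoch(values=filter_resample(rip[i * seg_len:(i + 1) * seg_len], fs, cfg),
                 valid=True)
        for i in range(n_epochs)
    ]
    return normalize_recording(epochs, cfg)
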