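"""ECG tachogram preprocessing.

Each 30 s ECG segment is converted into a 120-sample instantaneous-heart-rate
(IHR) epoch: R-peaks are detected per segment, the IHR (60 / inter-beat
interval, beats per minute) is interpolated onto a 4 Hz grid with a
shape-preserving piecewise-cubic (PCHIP) interpolant, outliers are flagged
and short gaps repaired by mirroring, and finally the subject's overall
median is subtracted from every retained epoch so that between-subject level
differences vanish while between-stage differences survive.

An epoch is *invalid* (and excluded from training/inference) when fewer than
15 beats were found or an outlier gap could not be repaired.

The R-peak detector is a Pan-Tompkins-style filter/derivative/energy detector
with a 250 ms refractory period, exposed behind :func:`detect_r_peaks` so an
alternative detector can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import PchipInterpolator

from .config import EPOCH_LEN_S, EPOCH_SAMPLES, TARGET_FS, EcgConfig
from .errors import EmptyRecordingError, ParameterError

#: 4 Hz sample times of one epoch, seconds from epoch start.
EPOCH_GRID_S = np.arange(EPOCH_SAMPLES) / TARGET_FS


@dataclass
class BeatSeries:
    """Ascending R-peak times (s) within one 30 s segment."""

    beat_times_s: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.beat_times_s, dtype=float)
        if len(t) and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] >= EPOCH_LEN_S):
            raise ParameterError("beat times must be strictly increasing within [0, 30)")
        self.beat_times_s = t

    def __len__(self) -> int:
        return len(self.beat_times_s)


@dataclass
class IhrEpoch:
    """One 120-sample IHR epoch.

    ``nan_mask`` marks samples flagged as outliers; a *valid* epoch has had
    every flagged sample repaired (no NaN reaches the network).
    """

    values: np.ndarray = field(default_factory=lambda: np.full(EPOCH_SAMPLES, np.nan))
    valid: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (EPOCH_SAMPLES,):
            raise ParameterError(f"IHR epoch must have {EPOCH_SAMPLES} samples")

    @property
    def nan_mask(self) -> np.ndarray:
        return np.isnan(self.values)


def detect_r_peaks(segment: np.ndarray, fs: float, cfg: EcgConfig | None = None) -> BeatSeries:
    """Detect R-peaks in one 30 s ECG segment.

    Pipeline: 5-15 Hz zero-phase band-pass, differentiation, squaring,
    150 ms moving-window integration, then peak picking with a 250 ms
    refractory period and an adaptive amplitude floor. Peak times are refined
    to the nearest extremum of the band-passed signal within +/-100 ms.
    """
    cfg = cfg or EcgConfig()
    if fs <= 0:
        raise ParameterError("sampling rate must be positive")
    x = np.asarray(segment, dtype=float)
    if np.ptp(x) == 0:
        return BeatSeries(np.empty(0))
    sos = signal.butter(2, [5.0, 15.0], btype="band", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, x)
    energy = np.diff(bp, prepend=bp[0]) ** 2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(energy, np.ones(win) / win, mode="same")
    floor = 0.2 * np.quantile(mwi, 0.98)
    if floor <= 0:
        return BeatSeries(np.empty(0))
    dist = max(1, int(round(cfg.refractory_s * fs)))
    peaks, _ = signal.find_peaks(mwi, height=floor, distance=dist)
    if len(peaks) == 0:
        return BeatSeries(np.empty(0))
    # refine each detection onto the band-passed waveform's local extremum
    half = int(round(0.100 * fs))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(bp), p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    refined = np.unique(refined)
    # re-impose the refractory period after refinement
    kept: list[int] = []
    for p in refined:
        if kept and p - kept[-1] < dist:
            if mwi[p] > mwi[kept[-1]]:
                kept[-1] = p
        else:
            kept.append(p)
    times = np.asarray(kept, dtype=float) / fs
    return BeatSeries(times[times < EPOCH_LEN_S])


def make_ihr_epoch(beats: BeatSeries, cfg: EcgConfig | None = None) -> IhrEpoch:
    """Interpolate one segment's beats onto the 4 Hz grid (120 samples).

    Segments with fewer than ``cfg.min_beats`` (default 15) beats are
    discarded. The IHR value at beat *i* (i >= 1) is 60 over the preceding
    inter-beat interval; the first beat repeats the second beat's value. To
    avoid border artifacts the first beat time is moved to (second beat time
    minus the mean of the 2nd and 3rd inter-beat intervals) and the last beat
    time symmetrically, before PCHIP interpolation; outside the shifted
    outermost beats the boundary value is held constant.
    """
    cfg = cfg or EcgConfig()
    t = np.asarray(beats.beat_times_s, dtype=float)
    if len(t) < max(cfg.min_beats, 4):  # border shift needs 3 inter-beat intervals
        return IhrEpoch(valid=False)
    ibi = np.diff(t)
    vals = np.empty_like(t)
    vals[1:] = 60.0 / ibi
    vals[0] = vals[1]
    t = t.copy()
    t[0] = t[1] - 0.5 * (ibi[1] + ibi[2])
    t[-1] = t[-2] + 0.5 * (ibi[-2] + ibi[-3])
    if np.any(np.diff(t) <= 0):  # pathological rhythm: border shift broke ordering
        return IhrEpoch(valid=False)
    interp = PchipInterpolator(t, vals)
    # constant extension outside the (shifted) outermost beats: cubic
    # extrapolation could leave the observed rate range at the borders
    grid = np.clip(EPOCH_GRID_S, t[0], t[-1])
    return IhrEpoch(values=interp(grid), valid=True)


def flag_outliers(e: IhrEpoch, cfg: EcgConfig | None = None) -> IhrEpoch:
    """Mark implausible IHR samples as missing (NaN).

    A sample is an outlier iff it lies outside 40-180 bpm, or more than
    20 bpm from the epoch median, or more than 3 epoch-SDs from the epoch
    median. Median and SD (population formula) are computed over the 120
    samples *before* any flagging, and the three rules are applied jointly in
    a single pass.
    """
    cfg = cfg or EcgConfig()
    if not e.valid:
        return e
    v = e.values
    med = np.median(v)
    sd = np.std(v)  # population formula (n divisor)
    mask = (
        (v < cfg.ihr_low_bpm)
        | (v > cfg.ihr_high_bpm)
        | (np.abs(v - med) > cfg.median_band_bpm)
        | (np.abs(v - med) > cfg.sd_multiplier * sd)
    )
    out = v.copy()
    out[mask] = np.nan
    return IhrEpoch(values=out, valid=True)


def fill_nan_gaps(e: IhrEpoch, cfg: EcgConfig | None = None) -> IhrEpoch:
    """Repair flagged samples by mirroring, or invalidate the epoch.

    Each maximal NaN run of length L <= 10 is replaced by the L samples
    immediately preceding it, in reverse order. A run longer than 10 samples
    (2.5 s at 4 Hz), or one without L non-missing samples before it (e.g. at
    the epoch start), invalidates the epoch.
    """
    cfg = cfg or EcgConfig()
    if not e.valid:
        return e
    v = e.values.copy()
    isnan = np.isnan(v)
    if not isnan.any():
        return IhrEpoch(values=v, valid=True)
    i = 0
    n = len(v)
    while i < n:
        if not np.isnan(v[i]):
            i += 1
            continue
        j = i
        while j < n and np.isnan(v[j]):
            j += 1
        run = j - i
        if run > cfg.max_gap_samples or i - run < 0 or np.isnan(v[i - run:i]).any():
            return IhrEpoch(values=e.values, valid=False)
        v[i:j] = v[i - run:i][::-1]
        i = j
    return IhrEpoch(values=v, valid=True)


def center_subject(epochs: list[IhrEpoch]) -> list[IhrEpoch]:
    """Subtract the subject's overall median (over all samples of all valid
    epochs) from every valid epoch; invalid epochs pass through untouched."""
    valid_vals = [e.values for e in epochs if e.valid]
    if not valid_vals:
        raise EmptyRecordingError("recording retained no valid IHR epochs")
    overall = np.median(np.concatenate(valid_vals))
    return [
        IhrEpoch(values=e.values - overall, valid=True) if e.valid else e
        for e in epochs
    ]


def preprocess_ecg(ecg: np.ndarray, fs: float, n_epochs: int,
                   cfg: EcgConfig | None = None) -> list[IhrEpoch]:
    """Full per-recording ECG pipeline: segment, detect, interpolate, flag,
    repair, and median-center. Returns one :class:`IhrEpoch` per grid epoch."""
    cfg = cfg or EcgConfig()
    seg_len = int(round(EPOCH_LEN_S * fs))
    epochs = []
    for i in range(n_epochs):
        seg = ecg[i * seg_len:(i + 1) * seg_len]
        beats = detect_r_peaks(seg, fs, cfg)
        e = make_ihr_epoch(beats, cfg)
        e = flag_outliers(e, cfg)
        e = fill_nan_gaps(e, cfg)
        epochs.append(e)
    return center_subject(epochs)
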