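"""Synthetic stage-labelled cardiorespiratory cohort generator.

Generates surrogate overnight recordings with the statistical structure the
pipeline assumes, so that every stage — preprocessing, training, uncertainty
metrics, screening — is testable without clinical data:

* a first-order Markov hypnogram over {W, N1, N2, N3, REM}, calibrated by
  default to realistic overnight stage proportions;
* beat times from an integrate-and-fire process on a stage-dependent
  instantaneous heart rate with respiratory sinus arrhythmia (RSA) coupling,
  rendered as QRS-like pulses at the ECG rate;
* a thoracic-effort oscillation whose rate, amplitude and irregularity
  depend on the stage (wake and REM breathe faster and more irregularly);
* apnea events placed only during sleep: effort collapses to a configured
  fraction during the event and is followed by recovery breaths and a
  transient heart-rate surge toward wake-like values — the mechanism by
  which apneic sleep resembles wakefulness to the classifier;
* optional movement artifacts (noise bursts or flat spans on both channels).

Stage-dependent parameters are package defaults chosen for physiological
plausibility and class separability; they are not clinical facts. Everything
is deterministic under the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import EPOCH_LEN_S
from .errors import ParameterError
from .io import (
    Hypnogram, Recording, STAGES, write_edf, write_events, write_hypnogram,
)

#: stage order used by all per-stage parameter dicts
_IDX = {s: i for i, s in enumerate(STAGES)}

#: overnight stage proportions used to calibrate the default Markov chain
#: (order W, N1, N2, N3, REM)
DEFAULT_STATIONARY = (0.17, 0.04, 0.40, 0.22, 0.17)


def default_transition_matrix(persistence: float = 0.8,
                              stationary=DEFAULT_STATIONARY) -> np.ndarray:
    """Row-stochastic 5x5 matrix ``P = a*I + (1-a)*1 pi^T``.

    Its stationary distribution is exactly ``pi`` and the mean dwell time is
    ``1/(1-a)`` epochs (2.5 min at the default persistence 0.8).
    """
    pi = np.asarray(stationary, dtype=float)
    if pi.shape != (5,) or abs(pi.sum() - 1) > 1e-9 or np.any(pi < 0):
        raise ParameterError("stationary distribution must be a length-5 simplex point")
    if not 0.0 <= persistence < 1.0:
        raise ParameterError("persistence must lie in [0, 1)")
    return persistence * np.eye(5) + (1.0 - persistence) * np.outer(np.ones(5), pi)


@dataclass
class SimConfig:
    """All knobs of the generator; per-stage dicts are keyed by stage code."""

    epochs_per_night: int = 960
    ecg_fs: float = 256.0
    rip_fs: float = 32.0
    transition: np.ndarray = field(default_factory=default_transition_matrix)
    # heart rate (bpm): stage level, between-epoch wander, per-beat jitter, RSA depth.
    # Stage levels overlap substantially (wander comparable to the level gaps),
    # as in real tachograms where sleep-wake separation is far from clean.
    ihr_mean: dict = field(default_factory=lambda: {
        "W": 76.0, "N1": 70.0, "N2": 66.0, "N3": 63.0, "REM": 71.0})
    ihr_sd: dict = field(default_factory=lambda: {
        "W": 8.0, "N1": 5.0, "N2": 4.0, "N3": 3.0, "REM": 6.0})
    hr_jitter_bpm: dict = field(default_factory=lambda: {
        "W": 4.0, "N1": 3.0, "N2": 2.5, "N3": 2.0, "REM": 3.5})
    rsa_gain_bpm: dict = field(default_factory=lambda: {
        "W": 1.5, "N1": 2.5, "N2": 3.5, "N3": 4.0, "REM": 2.0})
    # respiration: rate (breaths/min), amplitude (a.u.), amplitude-modulation
    # depth; the per-epoch rate wander is comparable to the stage gaps, so
    # breathing rate alone does not separate the stages
    resp_rate_bpm: dict = field(default_factory=lambda: {
        "W": 15.0, "N1": 14.3, "N2": 13.8, "N3": 13.3, "REM": 14.8})
    resp_rate_jitter_bpm: float = 1.0
    resp_amp: dict = field(default_factory=lambda: {
        "W": 1.0, "N1": 1.0, "N2": 1.0, "N3": 1.1, "REM": 0.9})
    resp_irregularity: dict = field(default_factory=lambda: {
        "W": 0.50, "N1": 0.35, "N2": 0.20, "N3": 0.12, "REM": 0.40})
    rip_noise_sd: float = 0.15
    ecg_noise_sd_mv: float = 0.02
    # apnea events (scored events must last at least 10 s); the post-event
    # sympathetic response pushes heart rate and breathing toward wake-like
    # behaviour, which is what makes apneic sleep confusable with wake
    apnea_rate_per_hour: float = 0.0
    apnea_duration_s: tuple = (15.0, 40.0)
    effort_reduction: float = 0.7      # mean effort amplitude fraction during an event
    event_irregularity: float = 0.45   # extra amplitude modulation during event+recovery
    recovery_overshoot: float = 1.5    # amplitude factor of the recovery breaths
    recovery_duration_s: float = 10.0
    hr_surge_bpm: float = 14.0         # post-event surge toward wake-like rates
    hr_surge_duration_s: float = 20.0
    hr_event_drop_bpm: float = 3.0     # mild bradycardia during the event
    # movement artifacts
    artifact_rate_per_hour: float = 0.0
    artifact_duration_s: tuple = (5.0, 40.0)
    seed: int = 0

    def __post_init__(self) -> None:
        P = np.asarray(self.transition, dtype=float)
        if P.shape != (5, 5) or np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1) > 1e-9):
            raise ParameterError("transition matrix must be 5x5 row-stochastic")
        self.transition = P
        lo, hi = self.apnea_duration_s
        if not (10.0 <= lo <= hi <= 120.0):
            raise ParameterError("apnea durations must lie within [10, 120] s")
        if self.apnea_rate_per_hour < 0 or self.artifact_rate_per_hour < 0:
            raise ParameterError("event rates must be non-negative")


@dataclass
class SyntheticPatient:
    """One generated patient with its ground truth."""

    recording: Recording
    hypnogram: Hypnogram
    beat_times_s: np.ndarray
    true_ahi: float
    artifact_intervals: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))


# ---------------------------------------------------------------------------
# hypnogram and events
# ---------------------------------------------------------------------------

def simulate_hypnogram(cfg: SimConfig, seed: int | None = None,
                       rng: np.random.Generator | None = None,
                       initial: str | None = None) -> list[str]:
    """Draw a stage sequence from the first-order Markov chain.

    The first epoch is drawn from the chain's stationary distribution unless
    ``initial`` names a starting stage.
    """
    rng = rng or np.random.default_rng(cfg.seed if seed is None else seed)
    P = cfg.transition
    states = np.empty(cfg.epochs_per_night, dtype=int)
    if initial is not None:
        states[0] = _IDX[initial]
    else:
        # stationary distribution of P (left eigenvector for eigenvalue 1)
        w, vl = np.linalg.eig(P.T)
        pi = np.real(vl[:, np.argmin(np.abs(w - 1))])
        pi = np.abs(pi) / np.abs(pi).sum()
        states[0] = rng.choice(5, p=pi)
    for i in range(1, cfg.epochs_per_night):
        states[i] = rng.choice(5, p=P[states[i - 1]])
    return [STAGES[s] for s in states]


def place_apnea_events(stages: list[str], cfg: SimConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Place non-overlapping apnea events uniformly within sleep epochs.

    The event count is Poisson with mean ``rate * true sleep hours``.
    """
    sleep_epochs = np.flatnonzero([s != "W" for s in stages])
    if cfg.apnea_rate_per_hour == 0 or len(sleep_epochs) == 0:
        return np.empty((0, 2))
    sleep_hours = len(sleep_epochs) * EPOCH_LEN_S / 3600.0
    n_events = rng.poisson(cfg.apnea_rate_per_hour * sleep_hours)
    span = len(stages) * EPOCH_LEN_S
    events: list[tuple[float, float]] = []
    attempts = 0
    while len(events) < n_events and attempts < 50 * max(n_events, 1):
        attempts += 1
        ep = sleep_epochs[rng.integers(len(sleep_epochs))]
        start = ep * EPOCH_LEN_S + rng.uniform(0, EPOCH_LEN_S)
        dur = rng.uniform(*cfg.apnea_duration_s)
        end = min(start + dur, span)
        if end - start < cfg.apnea_duration_s[0]:
            continue
        if any(start < e and end > s for s, e in events):
            continue
        events.append((start, end))
    return np.array(sorted(events)).reshape(-1, 2)


# ---------------------------------------------------------------------------
# signal rendering
# ---------------------------------------------------------------------------

def _smooth_noise(n: int, fs: float, knot_spacing_s: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Standard-normal noise low-passed by linear interpolation of knots."""
    n_knots = max(2, int(n / fs / knot_spacing_s) + 2)
    knots = rng.normal(size=n_knots)
    t_knots = np.linspace(0, n - 1, n_knots)
    return np.interp(np.arange(n), t_knots, knots)


def _per_stage(stages_idx: np.ndarray, table: dict) -> np.ndarray:
    vals = np.array([table[s] for s in STAGES])
    return vals[stages_idx]


def render_signals(stages: list[str], events: np.ndarray, cfg: SimConfig,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render (ecg, rip, beat_times) for one night.

    All slow modulations are built at the effort-channel rate and the beat
    process reads from them by sample index.
    """
    n_ep = len(stages)
    stages_idx = np.array([_IDX[s] for s in stages])
    fs = cfg.rip_fs
    n = int(round(n_ep * EPOCH_LEN_S * fs))
    t = np.arange(n) / fs
    ep_of_sample = np.minimum((t / EPOCH_LEN_S).astype(int), n_ep - 1)

    # --- respiration -------------------------------------------------------
    resp_rate_ep = _per_stage(stages_idx, cfg.resp_rate_bpm) / 60.0 \
        + rng.normal(0, cfg.resp_rate_jitter_bpm / 60.0, size=n_ep)
    resp_rate = np.clip(resp_rate_ep[ep_of_sample], 6.0 / 60.0, None)
    amp = _per_stage(stages_idx, cfg.resp_amp)[ep_of_sample]
    depth = _per_stage(stages_idx, cfg.resp_irregularity)[ep_of_sample]

    # --- apnea modulation ---------------------------------------------------
    # obstructive events: irregular (paradoxical) thoracic effort at reduced
    # mean amplitude and slowed rhythm, large fast recovery breaths, and a
    # sustained post-event heart-rate surge — the wake-resembling
    # sympathetic response
    effort_gate = np.ones(n)
    rate_gate = np.ones(n)
    event_irreg = np.zeros(n)
    hr_mod = np.zeros(n)  # additive bpm
    for s, e in np.asarray(events).reshape(-1, 2):
        i0, i1 = int(s * fs), min(int(e * fs), n)
        effort_gate[i0:i1] = cfg.effort_reduction
        rate_gate[i0:i1] = 0.85
        hr_mod[i0:i1] -= cfg.hr_event_drop_bpm
        i2 = min(int((e + cfg.recovery_duration_s) * fs), n)
        effort_gate[i1:i2] = cfg.recovery_overshoot
        rate_gate[i1:i2] = 1.2
        i3 = min(int((e + cfg.hr_surge_duration_s) * fs), n)
        event_irreg[i0:i3] = cfg.event_irregularity
        if i3 > i1:
            decay = np.exp(-(t[i1:i3] - e) / (cfg.hr_surge_duration_s / 3.0))
            hr_mod[i1:i3] += cfg.hr_surge_bpm * decay

    phase = 2 * np.pi * np.cumsum(resp_rate * rate_gate) / fs
    depth = np.maximum(depth, event_irreg)
    amp = amp * (1.0 + depth * _smooth_noise(n, fs, 3.0, rng))
    rip = amp * effort_gate * np.abs(np.sin(phase)) ** 0.8 * np.sign(np.sin(phase))
    rip = rip + cfg.rip_noise_sd * rng.normal(size=n)

    # --- heart rate and beats ----------------------------------------------
    hr_offset_ep = rng.normal(0, 1, size=n_ep) * _per_stage(stages_idx, cfg.ihr_sd)
    base_hr = _per_stage(stages_idx, cfg.ihr_mean)[ep_of_sample] \
        + hr_offset_ep[ep_of_sample] + hr_mod
    # RSA tracks actual respiratory excursion: suppressed while effort is
    # reduced, slightly exaggerated by the recovery breaths
    rsa = _per_stage(stages_idx, cfg.rsa_gain_bpm)[ep_of_sample] \
        * np.minimum(effort_gate, 1.2) * np.sin(phase)
    inst_hr = np.clip(base_hr + rsa, 35.0, 170.0)

    duration = n_ep * EPOCH_LEN_S
    jitter_ep = _per_stage(stages_idx, cfg.hr_jitter_bpm)
    beats = []
    tb = rng.uniform(0, 0.8)
    while tb < duration:
        i = min(int(tb * fs), n - 1)
        r = inst_hr[i] + jitter_ep[ep_of_sample[i]] * rng.normal()
        r = np.clip(r, 35.0, 170.0)
        beats.append(tb)
        tb += 60.0 / r
    beat_times = np.asarray(beats)

    # --- ECG waveform -------------------------------------------------------
    n_ecg = int(round(duration * cfg.ecg_fs))
    ecg = cfg.ecg_noise_sd_mv * rng.normal(size=n_ecg)
    # QRS-like pulse: sharp R wave with small lateral troughs, plus a T wave
    tt = np.arange(-0.05, 0.05, 1.0 / cfg.ecg_fs)
    qrs = 1.0 * np.exp(-0.5 * (tt / 0.012) ** 2) - 0.15 * np.exp(
        -0.5 * ((tt - 0.025) / 0.01) ** 2) - 0.1 * np.exp(-0.5 * ((tt + 0.025) / 0.01) ** 2)
    t_wave = 0.2 * np.exp(-0.5 * (np.arange(-0.08, 0.08, 1.0 / cfg.ecg_fs) / 0.04) ** 2)
    for tb in beat_times:
        i = int(round(tb * cfg.ecg_fs))
        lo, hi = i - len(qrs) // 2, i - len(qrs) // 2 + len(qrs)
        if 0 <= lo and hi <= n_ecg:
            ecg[lo:hi] += qrs
        j = int(round((tb + 0.22) * cfg.ecg_fs))
        lo, hi = j - len(t_wave) // 2, j - len(t_wave) // 2 + len(t_wave)
        if 0 <= lo and hi <= n_ecg:
            ecg[lo:hi] += t_wave
    return ecg, rip, beat_times


def inject_artifacts(rec: Recording, cfg: SimConfig,
                     rng: np.random.Generator) -> tuple[Recording, np.ndarray]:
    """Overlay movement artifacts (high-amplitude noise bursts or flat spans)
    on both channels; returns the modified recording and the true artifact
    intervals."""
    if cfg.artifact_rate_per_hour == 0:
        return rec, np.empty((0, 2))
    duration = rec.duration_s
    n_art = rng.poisson(cfg.artifact_rate_per_hour * duration / 3600.0)
    ecg = rec.ecg.copy()
    rip = rec.rip.copy()
    intervals = []
    for _ in range(n_art):
        dur = rng.uniform(*cfg.artifact_duration_s)
        start = rng.uniform(0, max(duration - dur, 0))
        end = start + dur
        intervals.append((start, end))
        flat = rng.random() < 0.5
        for x, fs in ((ecg, rec.ecg_fs), (rip, rec.rip_fs)):
            i0, i1 = int(start * fs), int(end * fs)
            if flat:
                x[i0:i1] = x[i0] if i0 < len(x) else 0.0
            else:
                x[i0:i1] += 8.0 * np.std(x) * rng.normal(size=max(i1 - i0, 0))
    out = Recording(patient_id=rec.patient_id, ecg=ecg, ecg_fs=rec.ecg_fs,
                    rip=rip, rip_fs=rec.rip_fs, ahi_reference=rec.ahi_reference)
    return out, np.array(sorted(intervals)).reshape(-1, 2)


# ---------------------------------------------------------------------------
# patients and cohorts
# ---------------------------------------------------------------------------

def simulate_patient(cfg: SimConfig, patient_id: str = "sim",
                     seed: int | None = None) -> SyntheticPatient:
    """Generate one full patient (hypnogram, events, signals, artifacts)."""
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    rng_h, rng_e, rng_s, rng_a = (np.random.default_rng(c) for c in root.spawn(4))
    stages = simulate_hypnogram(cfg, rng=rng_h)
    events = place_apnea_events(stages, cfg, rng_e)
    ecg, rip, beat_times = render_signals(stages, events, cfg, rng_s)
    sleep_hours = sum(s != "W" for s in stages) * EPOCH_LEN_S / 3600.0
    true_ahi = len(events) / sleep_hours if sleep_hours > 0 else 0.0
    rec = Recording(patient_id=patient_id, ecg=ecg, ecg_fs=cfg.ecg_fs,
                    rip=rip, rip_fs=cfg.rip_fs, ahi_reference=true_ahi)
    rec, artifacts = inject_artifacts(rec, cfg, rng_a)
    hyp = Hypnogram(stages=stages, apnea_events=events)
    return SyntheticPatient(recording=rec, hypnogram=hyp, beat_times_s=beat_times,
                            true_ahi=true_ahi, artifact_intervals=artifacts)


#: severity-class mean event rates (events/h): none, mild, moderate, severe
SEVERITY_RATES = {"none": 2.0, "mild": 10.0, "moderate": 20.0, "severe": 60.0}


def simulate_cohort(n_per_class: int, cfg: SimConfig | None = None,
                    class_rates: dict | None = None, seed: int = 0) -> list[SyntheticPatient]:
    """Generate a severity-stratified cohort with known per-patient AHI.

    ``class_rates`` maps severity-class names to apnea rates (events/h);
    each class contributes ``n_per_class`` patients.
    """
    import dataclasses

    base = cfg or SimConfig()
    rates = class_rates or SEVERITY_RATES
    root = np.random.SeedSequence(seed)
    patients = []
    for cls, rate in rates.items():
        for k in range(n_per_class):
            child = root.spawn(1)[0]
            pcfg = dataclasses.replace(base, apnea_rate_per_hour=float(rate))
            patients.append(simulate_patient(
                pcfg, patient_id=f"{cls}-{k:02d}",
                seed=int(child.generate_state(1)[0] % (2**31))))
    return patients


def write_patient(patient: SyntheticPatient, out_dir: str | Path) -> dict:
    """Write one patient as EDF + hypnogram CSV + events CSV + truth JSON;
    returns the manifest row."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pid = patient.recording.patient_id
    edf = out_dir / f"{pid}.edf"
    write_edf(edf, [("ECG", patient.recording.ecg, patient.recording.ecg_fs),
                    ("Thorax", patient.recording.rip, patient.recording.rip_fs)],
              patient_id=pid, physical_dims=["mV", ""])
    hyp = out_dir / f"{pid}_hypnogram.csv"
    write_hypnogram(hyp, patient.hypnogram.stages)
    ev = out_dir / f"{pid}_events.csv"
    write_events(ev, patient.hypnogram.apnea_events)
    truth = out_dir / f"{pid}_truth.json"
    truth.write_text(json.dumps({
        "patient_id": pid, "true_ahi": patient.true_ahi,
        "n_beats": int(len(patient.beat_times_s)),
        "artifact_intervals": patient.artifact_intervals.tolist(),
    }, indent=1))
    return {"patient_id": pid, "edf_path": str(edf), "hypnogram_path": str(hyp),
            "events_path": str(ev), "ahi": patient.true_ahi}
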