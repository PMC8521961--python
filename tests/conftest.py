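"""Shared fixtures.

The heavy session fixtures (`trained`, `severity_cohort`) generate synthetic
cohorts and train the fused network once per session; only the end-to-end
tests request them.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import cardiosleep as cs
from cardiosleep.config import PipelineConfig, TrainConfig
from cardiosleep.simulate import SimConfig, simulate_patient

# problem sizes of the end-to-end checks: ~20k epochs of training material
# (28 patients x 6 h), 6 held-out patients for selection/recovery, and a
# 40-patient severity-stratified cohort (10 per class, 4 h nights)
TRAIN_PATIENTS = 28
TRAIN_EPOCHS_PER_NIGHT = 720
TEST_PATIENTS = 6
SEVERITY_PER_CLASS = 10
SEVERITY_EPOCHS_PER_NIGHT = 480
SESSION_SEED = 20260920


def make_patient_dataset(cfg: SimConfig, patient_id: str, seed: int):
    """Generate one synthetic patient and run the full preprocessing."""
    p = simulate_patient(cfg, patient_id=patient_id, seed=seed)
    ds = cs.EpochDataset.from_patient(p.recording, p.hypnogram)
    return p, ds


@pytest.fixture(scope="session")
def trained():
    """Cohort generation + training of the fused network, shared per session.

    Returns a dict with the fit results, the held-out test dataset, its
    posteriors and the fitted confidence thresholds.
    """
    base = SimConfig(epochs_per_night=TRAIN_EPOCHS_PER_NIGHT,
                     apnea_rate_per_hour=2.0)
    datasets, ahi = {}, {}
    for i in range(TRAIN_PATIENTS):
        p, ds = make_patient_dataset(base, f"train-{i:02d}", SESSION_SEED + i)
        datasets[p.recording.patient_id] = ds
        ahi[p.recording.patient_id] = p.true_ahi
    test_parts = []
    for i in range(TEST_PATIENTS):
        _, ds = make_patient_dataset(base, f"test-{i:02d}", SESSION_SEED + 1000 + i)
        test_parts.append(ds)
    test_ds = cs.EpochDataset.concatenate(test_parts)

    config = PipelineConfig()
    config.train = TrainConfig(max_epochs=12, patience=5)
    clf = cs.SleepWakeClassifier(datasets, ahi, config)
    results = clf.fit(seeds=[0], test=test_ds)
    posteriors = results.predict(test_ds)
    thresholds = cs.fit_confidence_thresholds(posteriors)
    return {
        "results": results,
        "test_ds": test_ds,
        "posteriors": posteriors,
        "thresholds": thresholds,
        "n_train_epochs": sum(len(d) for d in datasets.values()),
    }


@pytest.fixture(scope="session")
def severity_cohort(trained):
    """40 synthetic patients over the four severity classes, scored with the
    session's trained network."""
    cfg = SimConfig(epochs_per_night=SEVERITY_EPOCHS_PER_NIGHT)
    patients = cs.simulate_cohort(SEVERITY_PER_CLASS, cfg, seed=SESSION_SEED + 7)
    rows = []
    for p in patients:
        ds = cs.EpochDataset.from_patient(p.recording, p.hypnogram)
        post = trained["results"].predict(ds)
        summary = cs.summarize_patient(post, trained["thresholds"],
                                       patient_id=p.recording.patient_id)
        rows.append({"patient": p, "dataset": ds, "posteriors": post,
                     "summary": summary, "ahi": p.true_ahi})
    return rows


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_epoch_dataset(n: int, wake_fraction: float, seed: int = 0,
                       separation: float = 0.0) -> cs.EpochDataset:
    """Small in-memory dataset with random epochs (no signal pipeline).

    ``separation`` shifts the wake-epoch feature mean, making the two classes
    linearly separable when large.
    """
    r = np.random.default_rng(seed)
    label = (r.random(n) < wake_fraction).astype(int)
    ihr = r.normal(0, 1, (n, 120)) + separation * label[:, None]
    rip = r.normal(0, 1, (n, 120)) + separation * label[:, None]
    return cs.EpochDataset(
        ihr=ihr, rip=rip, label=label, valid=np.ones(n, dtype=bool),
        patient_id=np.array(["p0"] * n, dtype=object),
        stage=np.array(["W" if l else "N2" for l in label], dtype=object),
        apnea_overlap=np.zeros(n, dtype=bool),
    )
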