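"""Epoch datasets, cohort splits and balanced batch sampling.

An :class:`EpochDataset` holds the paired 120-sample tachogram / effort
epochs with their sleep-wake labels, per-epoch validity, five-stage
annotation, patient identity and apnea overlap. Training cohorts are split
by patient (70/30) among low-AHI patients only, and the network consumes
class-balanced, shuffled batches of 16 non-sequential epochs (minority class
over-sampled with replacement).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .config import EPOCH_SAMPLES, EcgConfig, PipelineConfig
from .ecg import preprocess_ecg
from .errors import BalanceError, CohortError, GridError
from .io import SLEEP, WAKE, EpochGrid, Hypnogram, Recording, collapse_to_sleep_wake
from .rip import preprocess_rip, propagate_discards


@dataclass
class EpochDataset:
    """Column-wise container of paired, labelled epochs."""

    ihr: np.ndarray          # (n, 120) centered IHR
    rip: np.ndarray          # (n, 120) normalized effort
    label: np.ndarray        # (n,) 0=Sleep, 1=Wake
    valid: np.ndarray        # (n,) bool: both modalities usable
    patient_id: np.ndarray   # (n,) str
    stage: np.ndarray        # (n,) five-stage code, for analysis only
    apnea_overlap: np.ndarray  # (n,) bool: any scored event intersects the epoch

    def __post_init__(self) -> None:
        n = len(self.label)
        for name in ("ihr", "rip", "valid", "patient_id", "stage", "apnea_overlap"):
            if len(getattr(self, name)) != n:
                raise GridError(f"dataset column {name!r} has inconsistent length")
        if self.ihr.shape[1] != EPOCH_SAMPLES or self.rip.shape[1] != EPOCH_SAMPLES:
            raise GridError(f"epochs must have {EPOCH_SAMPLES} samples")

    def __len__(self) -> int:
        return len(self.label)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def subset(self, mask: np.ndarray) -> "EpochDataset":
        return EpochDataset(*(getattr(self, f)[mask] for f in (
            "ihr", "rip", "label", "valid", "patient_id", "stage", "apnea_overlap")))

    def valid_only(self) -> "EpochDataset":
        return self.subset(self.valid)

    def for_patients(self, ids: Iterable[str]) -> "EpochDataset":
        ids = set(ids)
        return self.subset(np.array([p in ids for p in self.patient_id]))

    @classmethod
    def from_patient(cls, rec: Recording, hyp: Hypnogram,
                     config: PipelineConfig | None = None) -> "EpochDataset":
        """Run both preprocessing pipelines on one recording and pair the
        result with its hypnogram on the common epoch grid."""
        config = config or PipelineConfig()
        n = min(rec.n_epochs, hyp.n_epochs)
        if n == 0:
            raise GridError("recording shorter than one epoch")
        ihr_epochs = preprocess_ecg(rec.ecg, rec.ecg_fs, n, config.ecg)
        rip_epochs = preprocess_rip(rec.rip, rec.rip_fs, n, config.rip)
        rip_epochs = propagate_discards(rip_epochs, ihr_epochs)
        grid = EpochGrid(n)
        labels = collapse_to_sleep_wake(Hypnogram(hyp.stages[:n], hyp.apnea_events))
        valid = np.array([r.valid for r in rip_epochs])
        ihr = np.stack([e.values if e.valid else np.zeros(EPOCH_SAMPLES)
                        for e in ihr_epochs])
        ripv = np.stack([r.values if r.valid else np.zeros(EPOCH_SAMPLES)
                         for r in rip_epochs])
        return cls(
            ihr=ihr, rip=ripv, label=labels, valid=valid,
            patient_id=np.array([rec.patient_id] * n, dtype=object),
            stage=np.array(hyp.stages[:n], dtype=object),
            apnea_overlap=grid.overlaps(hyp.apnea_events),
        )

    @classmethod
    def concatenate(cls, parts: Sequence["EpochDataset"]) -> "EpochDataset":
        if not parts:
            raise CohortError("cannot concatenate an empty list of datasets")
        return cls(*(np.concatenate([getattr(p, f) for p in parts]) for f in (
            "ihr", "rip", "label", "valid", "patient_id", "stage", "apnea_overlap")))


@dataclass(frozen=True)
class SplitPlan:
    """Patient-disjoint train/validation/test split."""

    train_ids: tuple
    val_ids: tuple
    test_ids: tuple
    seed: int

    def __post_init__(self) -> None:
        groups = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        for i in range(3):
            for j in range(i + 1, 3):
                if groups[i] & groups[j]:
                    raise CohortError("split groups must be patient-disjoint")


def make_split(cohort: dict[str, float], seed: int,
               train_fraction: float = 0.7, ahi_cutoff: float = 10.0) -> SplitPlan:
    """Randomly split the low-AHI patients 70/30 by patient.

    ``cohort`` maps patient id to reference AHI. Only patients with
    AHI < ``ahi_cutoff`` enter train/validation; the rest form the fixed test
    pool. Deterministic given ``seed``.
    """
    eligible = sorted(p for p, ahi in cohort.items() if ahi < ahi_cutoff)
    rest = sorted(p for p in cohort if p not in set(eligible))
    if len(eligible) < 2:
        raise CohortError(f"need at least 2 patients with AHI < {ahi_cutoff}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(eligible))
    n_train = int(np.floor(train_fraction * len(eligible)))
    train = tuple(eligible[i] for i in order[:n_train])
    val = tuple(eligible[i] for i in order[n_train:])
    return SplitPlan(train_ids=train, val_ids=val, test_ids=tuple(rest), seed=seed)


def balanced_batches(ds: EpochDataset, batch_size: int = 16, *, seed: int,
                     n_batches: int | None = None) -> Iterator[np.ndarray]:
    """Yield index arrays of class-balanced, shuffled batches.

    Every draw picks Sleep or Wake with probability 1/2 and then an epoch
    uniformly within that class (with replacement), so the minority class is
    over-sampled and each batch holds 8/8 on average. Only valid epochs are
    sampled; epochs are drawn independently of temporal order. Yields
    ``n_batches`` batches (default: enough full batches to cover the valid
    epochs once).
    """
    valid_idx = np.flatnonzero(ds.valid)
    by_class = [valid_idx[ds.label[valid_idx] == c] for c in (SLEEP, WAKE)]
    if any(len(c) == 0 for c in by_class):
        raise BalanceError("both classes must be present to balance batches")
    if n_batches is None:
        n_batches = len(valid_idx) // batch_size
    rng = np.random.default_rng(seed)
    for _ in range(n_batches):
        cls = rng.integers(0, 2, size=batch_size)
        idx = np.array([by_class[c][rng.integers(len(by_class[c]))] for c in cls])
        yield rng.permutation(idx)
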