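"""Sleep-wake network construction, training, fusion and selection.

Two unimodal branches (tachogram and respiratory effort) are trained first;
their convolutional stacks are then copied — weights frozen — into a
multimodal network whose fresh dense head is trained on the concatenated
convolutional features. Ten such multimodal networks, one per train/val
split seed, are candidates; the one with the highest Cohen's kappa on a
fixed test set is selected.

The statsmodels-style entry point is :class:`SleepWakeClassifier` whose
``fit`` returns a :class:`SleepWakeResults` carrying the selected network,
per-seed agreement scores, training history and prediction helpers.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .config import ArchConfig, EPOCH_SAMPLES, PipelineConfig, TrainConfig
from .dataset import EpochDataset, balanced_batches, make_split
from .errors import ArchitectureError, CohortError, ParameterError
from .nn import (
    Adam, Conv1D, Dense, Dropout, Flatten, ReLU, Sequential, cross_entropy, softmax,
)

logger = logging.getLogger(__name__)

_PREDICT_CHUNK = 2048


@dataclass
class PosteriorSeries:
    """Per-epoch wake probability with a validity mask.

    ``p_wake`` is NaN at invalid epochs; ``p_sleep`` is its complement.
    """

    p_wake: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.p_wake = np.asarray(self.p_wake, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.p_wake.shape != self.valid.shape:
            raise ParameterError("p_wake and valid must have the same shape")
        ok = self.p_wake[self.valid]
        if len(ok) and (np.any(ok < 0) or np.any(ok > 1)):
            raise ParameterError("posteriors must lie in [0, 1]")

    @property
    def p_sleep(self) -> np.ndarray:
        return 1.0 - self.p_wake

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def _conv_stack(arch: ArchConfig, rng: np.random.Generator) -> tuple[Sequential, int]:
    """Build the per-branch convolutional stack and return its flat feature
    length for a 120-sample input."""
    layers: list = []
    in_ch, length = 1, EPOCH_SAMPLES
    for f, k, s in arch.conv:
        conv = Conv1D(in_ch, f, k, s, rng)
        length = conv.out_len(length)
        layers += [conv, ReLU()]
        in_ch = f
    layers.append(Flatten())
    return Sequential(layers), in_ch * length


def _dense_head(n_in: int, arch: ArchConfig, rng_w: np.random.Generator,
                rng_drop: np.random.Generator) -> Sequential:
    return Sequential([
        Dense(n_in, arch.dense, rng_w),
        ReLU(),
        Dropout(arch.dropout, rng_drop),
        Dense(arch.dense, arch.n_classes, rng_w),
    ])


class UnimodalNet:
    """Single-modality network: conv stack -> dense head -> 2-class softmax."""

    kind = "unimodal"

    def __init__(self, modality: str, arch: ArchConfig, seed: int):
        if modality not in ("ecg", "rip"):
            raise ParameterError("modality must be 'ecg' or 'rip'")
        self.modality = modality
        self.arch = arch
        self.seed = seed
        ss = np.random.SeedSequence([seed, 0 if modality == "ecg" else 1])
        rng_w, rng_drop = (np.random.default_rng(c) for c in ss.spawn(2))
        self.conv, self.n_features = _conv_stack(arch, rng_w)
        self.head = _dense_head(self.n_features, arch, rng_w, rng_drop)

    def inputs(self, ds: EpochDataset, idx=None):
        x = ds.ihr if self.modality == "ecg" else ds.rip
        return x if idx is None else x[idx]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        feats = self.conv.forward(np.asarray(x)[:, None, :], train=train)
        return self.head.forward(feats, train=train)

    def backward(self, grad: np.ndarray) -> None:
        self.conv.backward(self.head.backward(grad))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def trainable_params(self):
        return self.conv.params() + self.head.params()

    def trainable_grads(self):
        return self.conv.grads() + self.head.grads()

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.conv.params() + self.head.params()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for p, w in zip(self.conv.params() + self.head.params(), weights, strict=True):
            p[...] = w


class MultimodalNet:
    """Fused network: two frozen convolutional branches, fresh dense head."""

    kind = "multimodal"

    def __init__(self, conv_ecg: Sequential, conv_rip: Sequential,
                 n_features: int, arch: ArchConfig, seed: int):
        self.arch = arch
        self.seed = seed
        self.conv_ecg = conv_ecg
        self.conv_rip = conv_rip
        self.n_features = n_features
        ss = np.random.SeedSequence([seed, 2])
        rng_w, rng_drop = (np.random.default_rng(c) for c in ss.spawn(2))
        self.head = _dense_head(n_features, arch, rng_w, rng_drop)

    def inputs(self, ds: EpochDataset, idx=None):
        if idx is None:
            return ds.ihr, ds.rip
        return ds.ihr[idx], ds.rip[idx]

    def branch_features(self, x) -> np.ndarray:
        xe, xr = x
        fe = self.conv_ecg.forward(np.asarray(xe)[:, None, :], train=False)
        fr = self.conv_rip.forward(np.asarray(xr)[:, None, :], train=False)
        return np.concatenate([fe, fr], axis=1)

    def forward(self, x, train: bool = False) -> np.ndarray:
        return self.head.forward(self.branch_features(x), train=train)

    def backward(self, grad: np.ndarray) -> None:
        self.head.backward(grad)  # branches are frozen: gradient stops here

    def predict_proba(self, x) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def trainable_params(self):
        return self.head.params()

    def trainable_grads(self):
        return self.head.grads()

    def conv_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.conv_ecg.params() + self.conv_rip.params()]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in
                self.conv_ecg.params() + self.conv_rip.params() + self.head.params()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        params = self.conv_ecg.params() + self.conv_rip.params() + self.head.params()
        for p, w in zip(params, weights, strict=True):
            p[...] = w


def param_count(model) -> int:
    if isinstance(model, MultimodalNet):
        return sum(p.size for p in model.conv_weights()) + sum(
            p.size for p in model.head.params())
    return sum(p.size for p in model.trainable_params())


def build_unimodal(modality: str, arch: ArchConfig | None = None,
                   seed: int = 0) -> UnimodalNet:
    """Build an untrained unimodal network for 120-sample epochs."""
    return UnimodalNet(modality, arch or ArchConfig(), seed)


def fuse_multimodal(ecg_model: UnimodalNet, rip_model: UnimodalNet,
                    seed: int | None = None) -> MultimodalNet:
    """Combine two trained unimodal networks into a multimodal one.

    The convolutional stacks are copied with their trained weights and marked
    non-trainable; the concatenated feature vector feeds a fresh dense head.
    """
    if ecg_model.modality != "ecg" or rip_model.modality != "rip":
        raise ArchitectureError("fusion expects an ECG model and a RIP model")
    conv_e = copy.deepcopy(ecg_model.conv)
    conv_r = copy.deepcopy(rip_model.conv)
    for seq in (conv_e, conv_r):
        for layer in seq.layers:
            layer.trainable = False
    n_features = ecg_model.n_features + rip_model.n_features
    return MultimodalNet(conv_e, conv_r, n_features, ecg_model.arch,
                         seed=ecg_model.seed if seed is None else seed)


def _mean_loss(model, ds: EpochDataset, idx: np.ndarray) -> float:
    total, n = 0.0, 0
    for lo in range(0, len(idx), _PREDICT_CHUNK):
        chunk = idx[lo:lo + _PREDICT_CHUNK]
        logits = model.forward(model.inputs(ds, chunk), train=False)
        loss, _ = cross_entropy(logits, ds.label[chunk])
        total += loss * len(chunk)
        n += len(chunk)
    return total / n


def train(model, train_ds: EpochDataset, val_ds: EpochDataset,
          cfg: TrainConfig | None = None) -> dict:
    """Train a network on balanced batches with early stopping.

    One pass covers the valid training epochs once in expectation. After each
    pass the plain (unbalanced) cross-entropy on the validation set is
    evaluated; the weights achieving the lowest validation loss are restored
    at the end. Returns a history dict with per-pass train/val losses.
    """
    cfg = cfg or TrainConfig()
    if train_ds.n_valid == 0 or val_ds.n_valid == 0:
        raise CohortError("training and validation sets must contain valid epochs")
    val_idx = np.flatnonzero(val_ds.valid)
    steps = max(1, train_ds.n_valid // cfg.batch_size)
    opt = Adam(model.trainable_params(), lr=cfg.learning_rate,
               beta1=cfg.beta1, beta2=cfg.beta2)
    batch_seed = int(np.random.SeedSequence([cfg.seed, 3]).generate_state(1)[0] % (2**31))
    batches = balanced_batches(train_ds, cfg.batch_size, seed=batch_seed,
                               n_batches=cfg.max_epochs * steps)
    history = {"train_loss": [], "val_loss": []}
    best_loss, best_weights, since_best = np.inf, model.get_weights(), 0
    for _ in range(cfg.max_epochs):
        running = 0.0
        for _ in range(steps):
            idx = next(batches)
            logits = model.forward(model.inputs(train_ds, idx), train=True)
            loss, dlogits = cross_entropy(logits, train_ds.label[idx])
            model.backward(dlogits)
            opt.step(model.trainable_grads())
            running += loss
        val_loss = _mean_loss(model, val_ds, val_idx)
        history["train_loss"].append(running / steps)
        history["val_loss"].append(val_loss)
        if val_loss < best_loss:
            best_loss, best_weights, since_best = val_loss, model.get_weights(), 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
        history["best_val_loss"] = best_loss
    model.set_weights(best_weights)
    history["best_val_loss"] = best_loss
    return history


def predict(model, ds: EpochDataset) -> PosteriorSeries:
    """Per-epoch wake posteriors; invalid epochs carry NaN."""
    p_wake = np.full(len(ds), np.nan)
    idx = np.flatnonzero(ds.valid)
    for lo in range(0, len(idx), _PREDICT_CHUNK):
        chunk = idx[lo:lo + _PREDICT_CHUNK]
        p_wake[chunk] = model.predict_proba(model.inputs(ds, chunk))[:, 1]
    return PosteriorSeries(p_wake=p_wake, valid=ds.valid.copy())


def select_model(candidates: Sequence, test_ds: EpochDataset):
    """Return the candidate with the highest Cohen's kappa on the fixed test
    set (ties to the lowest seed), plus the per-candidate kappas.

    ``candidates`` are networks carrying a ``seed`` attribute.
    """
    from .metrics import classify_epochs, cohen_kappa

    if not len(candidates):
        raise ParameterError("no candidate models")
    scores = []
    for m in candidates:
        post = predict(m, test_ds)
        labels = classify_epochs(post)
        k = cohen_kappa(test_ds.label[post.valid], labels[post.valid])
        scores.append(k)
    order = sorted(range(len(candidates)),
                   key=lambda i: (-scores[i], candidates[i].seed))
    return candidates[order[0]], np.asarray(scores)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_model(model, path: str | Path) -> None:
    """Save a network (weights + architecture) as a .npz checkpoint."""
    meta = {
        "kind": model.kind,
        "seed": int(model.seed),
        "arch": {"conv": [list(c) for c in model.arch.conv],
                 "dense": model.arch.dense, "dropout": model.arch.dropout,
                 "n_classes": model.arch.n_classes},
    }
    if model.kind == "unimodal":
        meta["modality"] = model.modality
    weights = model.get_weights()
    np.savez(path, meta=json.dumps(meta),
             **{f"w{i}": w for i, w in enumerate(weights)})


def load_model(path: str | Path):
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
    arch = ArchConfig(conv=tuple(tuple(c) for c in meta["arch"]["conv"]),
                      dense=meta["arch"]["dense"], dropout=meta["arch"]["dropout"],
                      n_classes=meta["arch"]["n_classes"])
    if meta["kind"] == "unimodal":
        model = build_unimodal(meta["modality"], arch, seed=meta["seed"])
    else:
        ecg = build_unimodal("ecg", arch, seed=meta["seed"])
        rip = build_unimodal("rip", arch, seed=meta["seed"])
        model = fuse_multimodal(ecg, rip, seed=meta["seed"])
    model.set_weights(weights)
    return model


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

@dataclass
class SleepWakeResults:
    """Fit results: the selected multimodal network and its provenance."""

    model: MultimodalNet
    unimodal: dict
    seed_kappas: dict
    selected_seed: int
    history: dict
    config: PipelineConfig

    def predict(self, ds: EpochDataset) -> PosteriorSeries:
        return predict(self.model, ds)

    def predict_labels(self, ds: EpochDataset) -> np.ndarray:
        from .metrics import classify_epochs

        return classify_epochs(self.predict(ds))

    def kappa(self, ds: EpochDataset) -> float:
        from .metrics import classify_epochs, cohen_kappa

        post = self.predict(ds)
        labels = classify_epochs(post)
        return cohen_kappa(ds.label[post.valid], labels[post.valid])

    def save(self, path: str | Path) -> None:
        save_model(self.model, path)

    def summary(self) -> str:
        n_head = sum(p.size for p in self.model.head.params())
        lines = [
            "Sleep-wake classifier (multimodal CNN, frozen conv branches)",
            "=" * 62,
            f"selected seed        : {self.selected_seed}",
            f"parameters           : {param_count(self.model):,} total, "
            f"{n_head:,} trainable (fused head)",
            f"candidates trained   : {len(self.seed_kappas)}",
            "",
            "  seed   test kappa",
        ]
        for seed, k in sorted(self.seed_kappas.items()):
            mark = " <- selected" if seed == self.selected_seed else ""
            shown = f"{k:10.3f}" if np.isfinite(k) else "       n/a"
            lines.append(f"  {seed:>4}   {shown}{mark}")
        return "\n".join(lines)


class SleepWakeClassifier:
    """Single-epoch sleep-wake classifier over a cohort of patients.

    Built from per-patient :class:`EpochDataset` objects plus their reference
    AHI. ``fit`` trains, per split seed: the two unimodal networks on a 70/30
    patient split of the low-AHI pool, then the fused multimodal head; with
    several seeds the candidate with the highest kappa on the fixed test set
    is selected.
    """

    def __init__(self, patient_datasets: Mapping[str, EpochDataset],
                 ahi: Mapping[str, float],
                 config: PipelineConfig | None = None):
        if set(patient_datasets) - set(ahi):
            raise CohortError("every patient dataset needs a reference AHI")
        self.patient_datasets = dict(patient_datasets)
        self.ahi = {p: float(ahi[p]) for p in patient_datasets}
        self.config = config or PipelineConfig()

    def _concat(self, ids: Sequence[str]) -> EpochDataset:
        return EpochDataset.concatenate([self.patient_datasets[p] for p in ids])

    def fit(self, seeds: Sequence[int] = (0,),
            test: EpochDataset | None = None) -> SleepWakeResults:
        """Train one fused network per seed and select on ``test``.

        ``test`` is the fixed (non-randomized) selection set; required when
        more than one seed is given. Note the selected model's reported test
        kappa reuses the same set, so it is a model-selection score, not an
        unbiased generalization estimate.
        """
        seeds = list(seeds)
        if len(seeds) > 1 and test is None:
            raise CohortError("a fixed test set is required to select among seeds")
        if len(seeds) > 1:
            logger.warning(
                "model selection reuses the fixed test set for both selection "
                "and reporting; treat the selected kappa as optimistic")
        cfg = self.config
        candidates, unimodals, histories = [], {}, {}
        for seed in seeds:
            plan = make_split(self.ahi, seed,
                              train_fraction=1.0 - cfg.train.val_fraction,
                              ahi_cutoff=cfg.detect.train_ahi_cutoff)
            tr, va = self._concat(plan.train_ids), self._concat(plan.val_ids)
            tcfg = dataclasses.replace(cfg.train, seed=seed)
            nets = {}
            hist = {}
            for modality in ("ecg", "rip"):
                net = build_unimodal(modality, cfg.arch, seed=seed)
                hist[modality] = train(net, tr, va, tcfg)
                nets[modality] = net
            fused = fuse_multimodal(nets["ecg"], nets["rip"], seed=seed)
            hist["fused"] = train(fused, tr, va, tcfg)
            candidates.append(fused)
            unimodals[seed] = nets
            histories[seed] = hist
        if test is not None:
            best, scores = select_model(candidates, test)
        else:
            best, scores = candidates[0], np.array([np.nan])
        seed_kappas = {s: float(k) for s, k in zip(seeds, scores)}
        return SleepWakeResults(
            model=best, unimodal=unimodals[best.seed], seed_kappas=seed_kappas,
            selected_seed=best.seed, history=histories[best.seed], config=cfg)
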