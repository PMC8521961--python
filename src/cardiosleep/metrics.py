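"""Posterior-derived outcome metrics and OSA screening.

From the per-epoch wake posteriors this module derives:

* the predicted sleep-wake labels (Wake iff p(Wake) >= 0.5);
* total sleep time (TST): 0.5 min per valid epoch predicted Sleep;
* confidence thresholds T_s / T_w — the median confidence of the
  sleep-/wake-predicted pool minus its SD, fitted once on a reference
  cohort — and the per-patient uncertainty metrics %USE and %UWE (fraction
  of valid epochs predicted with sub-threshold confidence);
* %SWT, the fraction of valid epochs at which the predicted label flips;
* the screening decision: a patient is flagged as likely OSA when %USE or
  %SWT strictly exceeds its threshold (defaults 64% and 24%), thresholds
  selectable by ROC analysis at a specificity floor.

Cohen's kappa and the trapezoid AUROC are implemented here (they are part of
the selection/decision machinery) and cross-checked against scikit-learn in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ParameterError, ThresholdError
from .io import SLEEP, WAKE


# ---------------------------------------------------------------------------
# labels and TST
# ---------------------------------------------------------------------------

def classify_epochs(p) -> np.ndarray:
    """Threshold posteriors at 0.5: Wake iff p(Wake) >= 0.5.

    Returns an int array over the full grid with -1 at invalid epochs.
    """
    labels = np.full(len(p.p_wake), -1, dtype=int)
    labels[p.valid] = np.where(p.p_wake[p.valid] >= 0.5, WAKE, SLEEP)
    return labels


def estimate_tst(labels: np.ndarray, valid: np.ndarray,
                 extrapolate: bool = False) -> float:
    """Total sleep time in minutes: 0.5 min per valid epoch predicted Sleep.

    With ``extrapolate=True`` the count is scaled by total/valid epochs,
    attributing discarded epochs proportionally (clearly a model choice; the
    plain estimate is the default).
    """
    valid = np.asarray(valid, dtype=bool)
    if valid.sum() == 0:
        raise ParameterError("TST needs at least one valid epoch")
    tst = 0.5 * float(np.sum(np.asarray(labels)[valid] == SLEEP))
    if extrapolate:
        tst *= len(valid) / valid.sum()
    return tst


# ---------------------------------------------------------------------------
# confidence thresholds and uncertainty metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfidenceThresholds:
    """Sleep / wake confidence thresholds (both must exceed 0.5)."""

    t_s: float
    t_w: float

    def __post_init__(self) -> None:
        if not (0.5 < self.t_s <= 1.0 and 0.5 < self.t_w <= 1.0):
            raise ThresholdError(
                f"confidence thresholds must lie in (0.5, 1], got "
                f"t_s={self.t_s:.3f}, t_w={self.t_w:.3f}")


def fit_confidence_thresholds(p) -> ConfidenceThresholds:
    """Fit T_s and T_w on a pooled reference cohort.

    T_w is the median p(Wake) of wake-predicted epochs minus its SD; T_s the
    median p(Sleep) of sleep-predicted epochs minus its SD, pooling epochs
    across subjects. Raises :class:`ThresholdError` if a predicted class is
    empty.
    """
    pw = p.p_wake[p.valid]
    wake_pool = pw[pw >= 0.5]
    sleep_pool = 1.0 - pw[pw < 0.5]
    if len(wake_pool) == 0 or len(sleep_pool) == 0:
        raise ThresholdError("both predicted classes must be non-empty")
    return ConfidenceThresholds(
        t_s=float(np.median(sleep_pool) - np.std(sleep_pool)),
        t_w=float(np.median(wake_pool) - np.std(wake_pool)),
    )


def uncertainty_metrics(p, t: ConfidenceThresholds) -> tuple[float, float]:
    """%USE and %UWE: share of valid epochs predicted with sub-threshold
    confidence, as percentages of all valid predicted epochs."""
    pw = p.p_wake[p.valid]
    if len(pw) == 0:
        raise ParameterError("no valid epochs")
    pred_wake = pw >= 0.5
    use = np.sum(~pred_wake & (1.0 - pw < t.t_s))
    uwe = np.sum(pred_wake & (pw < t.t_w))
    return 100.0 * use / len(pw), 100.0 * uwe / len(pw)


def apnea_uncertainty_split(p, t: ConfidenceThresholds,
                            apnea_overlap: np.ndarray) -> tuple[float, float]:
    """%USE split into epochs with / without an overlapping scored apnea,
    both with the same denominator as %USE (all valid predicted epochs)."""
    pw = p.p_wake[p.valid]
    ov = np.asarray(apnea_overlap, dtype=bool)[p.valid]
    if len(pw) == 0:
        raise ParameterError("no valid epochs")
    uncertain_sleep = (pw < 0.5) & (1.0 - pw < t.t_s)
    with_ap = 100.0 * np.sum(uncertain_sleep & ov) / len(pw)
    without = 100.0 * np.sum(uncertain_sleep & ~ov) / len(pw)
    return with_ap, without


def transition_metric(labels: np.ndarray, valid: np.ndarray) -> float:
    """%SWT: label changes between consecutive valid epochs, as a percentage
    of the valid epochs (invalid epochs are removed before pairing)."""
    valid = np.asarray(valid, dtype=bool)
    seq = np.asarray(labels)[valid]
    if len(seq) < 2:
        raise ParameterError("transition metric needs at least two valid epochs")
    return 100.0 * float(np.sum(seq[1:] != seq[:-1])) / len(seq)


# ---------------------------------------------------------------------------
# patient summary and detection
# ---------------------------------------------------------------------------

@dataclass
class PatientSummary:
    """Night-level outcome for one patient."""

    patient_id: str
    tst_min: float
    tst_min_extrapolated: float
    pct_use: float
    pct_uwe: float
    pct_swt: float
    n_valid_epochs: int
    n_epochs: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_patient(p, t: ConfidenceThresholds,
                      patient_id: str = "") -> PatientSummary:
    labels = classify_epochs(p)
    use, uwe = uncertainty_metrics(p, t)
    return PatientSummary(
        patient_id=patient_id,
        tst_min=estimate_tst(labels, p.valid),
        tst_min_extrapolated=estimate_tst(labels, p.valid, extrapolate=True),
        pct_use=use,
        pct_uwe=uwe,
        pct_swt=transition_metric(labels, p.valid),
        n_valid_epochs=p.n_valid,
        n_epochs=len(p.valid),
    )


def detect_osa(s: PatientSummary, thr_use: float = 64.0,
               thr_swt: float = 24.0) -> bool:
    """Screening rule: positive iff %USE or %SWT *strictly* exceeds its
    threshold (boundary equality is negative)."""
    return bool(s.pct_use > thr_use or s.pct_swt > thr_swt)


# ---------------------------------------------------------------------------
# ROC threshold selection
# ---------------------------------------------------------------------------

@dataclass
class RocSelection:
    threshold: float
    sensitivity: float
    specificity: float
    auroc: float
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    specificity_floor_met: bool


def auroc(values: np.ndarray, labels: np.ndarray) -> float:
    """Area under the empirical ROC curve by the trapezoid rule."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ParameterError("AUROC needs both label groups")
    # thresholds descending: (fpr, tpr) then trace the ROC staircase from
    # (0, 0) to (1, 1) monotonically
    thr = np.concatenate([[np.inf], np.unique(values)[::-1], [-np.inf]])
    tpr = np.array([np.mean(values[labels] > t) for t in thr])
    fpr = np.array([np.mean(values[~labels] > t) for t in thr])
    return float(np.trapezoid(tpr, fpr))


def select_threshold_roc(metric_values: np.ndarray, osa_labels: np.ndarray,
                         min_specificity: float = 0.95) -> RocSelection:
    """Choose a detection threshold from per-patient metric values.

    Candidate thresholds are the midpoints between consecutive sorted unique
    values (plus outer sentinels); a patient is called positive when the
    metric strictly exceeds the threshold. Among candidates reaching the
    specificity floor, the one maximizing sensitivity is returned (ties to
    the most specific). If no candidate reaches the floor, the most specific
    candidate is returned with ``specificity_floor_met=False``.
    """
    v = np.asarray(metric_values, dtype=float)
    y = np.asarray(osa_labels, dtype=bool)
    if y.all() or not y.any():
        raise ParameterError("both label groups must be non-empty")
    u = np.unique(v)
    candidates = np.concatenate([[u[0] - 1.0], (u[:-1] + u[1:]) / 2.0, [u[-1]]])
    sens = np.array([np.mean(v[y] > t) for t in candidates])
    spec = np.array([np.mean(~(v[~y] > t)) for t in candidates])
    feasible = spec >= min_specificity
    if feasible.any():
        pool = np.flatnonzero(feasible)
        best = pool[np.lexsort((-spec[pool], -sens[pool]))][0]
        floor_met = True
    else:
        best = int(np.argmax(spec))
        floor_met = False
    return RocSelection(
        threshold=float(candidates[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        auroc=auroc(v, y),
        thresholds=candidates, tpr=sens, fpr=1.0 - spec,
        specificity_floor_met=floor_met,
    )


# ---------------------------------------------------------------------------
# agreement and evaluation
# ---------------------------------------------------------------------------

def cohen_kappa(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Chance-corrected agreement from the confusion matrix:
    (observed - chance) / (1 - chance)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ParameterError("label vectors must be non-empty and aligned")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    k = len(classes)
    lut = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((k, k))
    for t, pr in zip(y_true, y_pred):
        cm[lut[t], lut[pr]] += 1
    n = cm.sum()
    po = np.trace(cm) / n
    pe = float(cm.sum(axis=1) @ cm.sum(axis=0)) / n**2
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return float((po - pe) / (1.0 - pe))


@dataclass
class EvaluationReport:
    """Cohort-level evaluation of epochs, TST and detection decisions."""

    kappa: float | None = None
    pearson_rho: float | None = None
    tst_bias_mean_min: float | None = None
    tst_bias_sd_min: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None
    auroc: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def evaluate(epoch_true: np.ndarray | None = None,
             epoch_pred: np.ndarray | None = None,
             tst_est: np.ndarray | None = None,
             tst_ref: np.ndarray | None = None,
             detect_pred: np.ndarray | None = None,
             detect_true: np.ndarray | None = None,
             detect_scores: np.ndarray | None = None) -> EvaluationReport:
    """Aggregate evaluation; every block is optional.

    Epoch block: Cohen's kappa of predicted vs reference sleep-wake labels.
    TST block: bias (estimated minus reference, mean and SD over patients)
    and Pearson's rho (an error is raised for constant vectors, where rho is
    undefined). Detection block: sensitivity/specificity/accuracy of the
    screening decisions, plus AUROC when continuous scores are given.
    """
    rep = EvaluationReport()
    if epoch_true is not None:
        rep.kappa = cohen_kappa(epoch_true, epoch_pred)
    if tst_est is not None:
        est = np.asarray(tst_est, dtype=float)
        ref = np.asarray(tst_ref, dtype=float)
        if est.shape != ref.shape or est.size < 2:
            raise ParameterError("TST comparison needs >= 2 aligned pairs")
        if np.ptp(est) == 0 or np.ptp(ref) == 0:
            raise ParameterError("Pearson's rho is undefined for constant TST vectors")
        diff = est - ref
        rep.tst_bias_mean_min = float(np.mean(diff))
        rep.tst_bias_sd_min = float(np.std(diff, ddof=1))
        rep.pearson_rho = float(stats.pearsonr(est, ref).statistic)
    if detect_pred is not None:
        pred = np.asarray(detect_pred, dtype=bool)
        true = np.asarray(detect_true, dtype=bool)
        if not true.any() or true.all():
            raise ParameterError("detection evaluation needs both classes")
        rep.sensitivity = float(np.mean(pred[true]))
        rep.specificity = float(np.mean(~pred[~true]))
        rep.accuracy = float(np.mean(pred == true))
        if detect_scores is not None:
            rep.auroc = auroc(detect_scores, true)
    return rep
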