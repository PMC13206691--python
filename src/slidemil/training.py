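"""Training protocol: patient-level splits, 5-fold CV, Adam, early stopping.

Splitting and cross-validation always operate on patients, never slides:
every slide of a patient travels with the patient across train/validation/
test and across folds, which is what prevents leakage of patient-specific
morphology between partitions.

Optimization is plain Adam over bag cross-entropy, one bag per step (bags
have variable instance counts, so there is no natural fixed batch).  The
slide-level model uses a constant learning rate of 1e-5; the hierarchical
patient-level model uses 1e-4 under cosine annealing with warm restarts
(first cycle 20 epochs, each cycle twice as long).  Early stopping watches
macro one-vs-rest validation AUC with patience 15 and minimum improvement
delta = 0.001, capped at 600 epochs; the best-validation checkpoint is
returned.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import mil_core
from .mil_core import PatientModel, SlideModel

logger = logging.getLogger(__name__)

SPLITS = ("train", "val", "test")


# ---------------------------------------------------------------------------
# cohort container


@dataclass
class PatientEntry:
    patient_id: str
    label: int
    slide_ids: List[str]


@dataclass
class Cohort:
    """Patients -> slides -> instance bags, with split/fold assignments.

    ``bags`` maps slide_id to its (N, D) embedding matrix.  ``witnesses``
    (optional, synthetic cohorts only) maps slide_id to the row indices of
    planted class-defining instances.
    """

    patients: Dict[str, PatientEntry]
    bags: Dict[str, np.ndarray]
    slide_labels: Dict[str, int]
    n_classes: int
    dim: int
    class_names: Optional[List[str]] = None
    witnesses: Dict[str, np.ndarray] = field(default_factory=dict)
    informative_slides: Dict[str, str] = field(default_factory=dict)
    split: Dict[str, str] = field(default_factory=dict)
    folds: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        owners: Dict[str, str] = {}
        for pid, entry in self.patients.items():
            for sid in entry.slide_ids:
                if sid in owners:
                    raise ValueError(f"slide {sid} belongs to two patients")
                owners[sid] = pid
        missing = set(owners) - set(self.bags)
        if missing:
            raise ValueError(f"missing bags for slides: {sorted(missing)[:5]}")

    @property
    def patient_ids(self) -> List[str]:
        return sorted(self.patients)

    def patient_labels(self) -> Dict[str, int]:
        return {pid: e.label for pid, e in self.patients.items()}

    def patients_in(self, split: str) -> List[str]:
        return [pid for pid in self.patient_ids if self.split.get(pid) == split]

    def slide_items(self, split: str) -> List[Tuple[str, np.ndarray, int]]:
        """(slide_id, bag, label) triples of the split, patient-sorted."""
        out = []
        for pid in self.patients_in(split):
            for sid in self.patients[pid].slide_ids:
                out.append((sid, self.bags[sid], self.slide_labels[sid]))
        return out

    def patient_items(self, split: str) -> List[Tuple[str, List[np.ndarray], int]]:
        out = []
        for pid in self.patients_in(split):
            entry = self.patients[pid]
            out.append((pid, [self.bags[s] for s in entry.slide_ids], entry.label))
        return out

    def assert_no_leakage(self) -> None:
        """Splits partition patients; folds partition patients; slides co-travel."""
        if self.split:
            assigned = [p for p in self.patient_ids if p in self.split]
            by_split = {s: {p for p in assigned if self.split[p] == s}
                        for s in SPLITS}
            for a in SPLITS:
                for b in SPLITS:
                    if a < b and by_split[a] & by_split[b]:
                        raise AssertionError(f"patient leakage between {a} and {b}")
            if set().union(*by_split.values()) != set(assigned):
                raise AssertionError("split does not cover all assigned patients")
        if self.folds:
            if set(self.folds) != set(self.patient_ids):
                raise AssertionError("folds do not cover the cohort")
        # slides co-assigned trivially: split/folds are keyed by patient only


# ---------------------------------------------------------------------------
# configuration / history


@dataclass
class TrainConfig:
    level: str = "slide"                 # {"slide", "patient"}
    lr0: float = 1e-5
    schedule: str = "none"               # {"none", "cosine_warm_restarts"}
    T0: int = 20
    Tmult: int = 2
    max_epochs: int = 600
    patience: int = 15
    min_delta: float = 0.001
    seed: int = 0
    hidden_dim: int = mil_core.DEFAULT_HIDDEN_DIM
    augmentation_hook: Optional[str] = None

    def __post_init__(self) -> None:
        if self.lr0 <= 0 or self.T0 < 1 or self.Tmult < 1 or self.patience < 1:
            raise ValueError("invalid training configuration")
        if self.level not in ("slide", "patient"):
            raise ValueError("level must be 'slide' or 'patient'")

    @classmethod
    def for_level(cls, level: str, **kw) -> "TrainConfig":
        """Protocol defaults: slide = constant 1e-5; patient = 1e-4 + cosine."""
        if level == "slide":
            base = dict(level="slide", lr0=1e-5, schedule="none")
        else:
            base = dict(level="patient", lr0=1e-4, schedule="cosine_warm_restarts")
        base.update(kw)
        return cls(**base)


@dataclass
class TrainHistory:
    epochs: List[dict] = field(default_factory=list)  # epoch, lr, loss, val_auc
    stopped_epoch: int = 0
    best_epoch: int = 0
    best_val_auc: float = float("-inf")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)


# ---------------------------------------------------------------------------
# split / fold operations


def split_patients(patient_ids: Sequence[str],
                   ratios: Tuple[float, float, float] = (0.8, 0.1, 0.1),
                   seed: int = 0) -> Dict[str, str]:
    """Random patient-level train/val/test split with largest-remainder sizes."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    ids = list(patient_ids)
    n = len(ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)

    exact = [n * r for r in ratios]
    sizes = [int(math.floor(e)) for e in exact]
    rema = [e - s for e, s in zip(exact, sizes)]
    for _ in range(n - sum(sizes)):
        i = int(np.argmax(rema))
        sizes[i] += 1
        rema[i] = -1.0
    assignment: Dict[str, str] = {}
    cursor = 0
    for split, size in zip(SPLITS, sizes):
        for j in order[cursor:cursor + size]:
            assignment[ids[j]] = split
        cursor += size
    return assignment


def make_cv_folds(patient_labels: Dict[str, int], k: int = 5,
                  seed: int = 0) -> Dict[str, int]:
    """Patient-level stratified k-fold assignment (folds numbered 1..k).

    Within each class, patients are shuffled and dealt cyclically; the deal
    pointer continues across classes so global fold sizes differ by at most
    one.  Classes with fewer than k patients cannot be stratified and fall
    through the same cyclic deal with a warning.
    """
    if len(patient_labels) < k:
        raise ValueError("need at least k patients")
    rng = np.random.default_rng(seed)
    by_class: Dict[int, List[str]] = {}
    for pid in sorted(patient_labels):
        by_class.setdefault(patient_labels[pid], []).append(pid)
    folds: Dict[str, int] = {}
    cursor = 0
    for label in sorted(by_class):
        pids = by_class[label]
        if len(pids) < k:
            warnings.warn(
                f"class {label} has {len(pids)} patients (< {k}): "
                "stratification degrades to a plain cyclic assignment")
        order = rng.permutation(len(pids))
        for j in order:
            folds[pids[j]] = cursor % k + 1
            cursor += 1
    return folds


# ---------------------------------------------------------------------------
# schedule / stopping


def cosine_lr(epoch: int, config: TrainConfig) -> float:
    """Learning rate at a 0-based epoch under the configured schedule.

    Cosine warm restarts: within a cycle of length T the rate decays as
    lr0 * (1 + cos(pi * t / T)) / 2; cycles last T0, T0*Tmult, T0*Tmult^2...
    so restarts occur at cumulative epochs 20, 60, 140, ... by default.
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if config.schedule == "none":
        return config.lr0
    if config.schedule != "cosine_warm_restarts":
        raise ValueError(f"unknown schedule {config.schedule!r}")
    start, T = 0, config.T0
    while epoch >= start + T:
        start += T
        T *= config.Tmult
    t = epoch - start
    return config.lr0 * (1.0 + math.cos(math.pi * t / T)) / 2.0


def early_stopping_step(val_aucs: Sequence[float], config: TrainConfig) -> str:
    """'stop' when no epoch within the last ``patience`` beat the best by > delta.

    Epochs are 1-based positions in ``val_aucs``; an improvement only counts
    when it exceeds ``min_delta``.  The ``max_epochs`` cap always stops.
    """
    if len(val_aucs) == 0:
        raise ValueError("need at least one recorded epoch")
    best = float("-inf")
    best_epoch = 0
    for i, auc in enumerate(val_aucs, start=1):
        if auc > best + config.min_delta:
            best = auc
            best_epoch = i
    if len(val_aucs) >= config.max_epochs:
        return "stop"
    if len(val_aucs) - best_epoch >= config.patience:
        return "stop"
    return "continue"


# ---------------------------------------------------------------------------
# augmentation hooks (train-time only; evaluation is never augmented)

_HOOKS: Dict[str, Callable] = {"identity": lambda patch: patch}


def register_hook(name: str, fn: Callable) -> None:
    _HOOKS[name] = fn


def get_hook(name: Optional[str]) -> Callable:
    if name is None:
        name = "identity"
    try:
        return _HOOKS[name]
    except KeyError:
        raise ValueError(f"unknown augmentation hook {name!r}; "
                         f"registered: {sorted(_HOOKS)}")


# ---------------------------------------------------------------------------
# optimization


class Adam:
    """Per-tensor Adam with bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: Dict[str, np.ndarray],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray],
             grads: Dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * (g * g)
            p -= lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)


def _macro_ovr_auc(probs: np.ndarray, truth: np.ndarray, n_classes: int) -> float:
    """Macro one-vs-rest AUC, skipping classes without both outcomes."""
    from .evaluation import roc_auc
    aucs = []
    for c in range(n_classes):
        auc = roc_auc(probs, truth, c)
        if auc is not None:
            aucs.append(auc)
    return float(np.mean(aucs)) if aucs else float("nan")


def _eval_bags(bags, labels, model, level: str):
    probs = np.zeros((len(bags), model.classifier.n_classes))
    for i, bag in enumerate(bags):
        if level == "slide":
            probs[i] = mil_core.slide_forward(bag, model).probabilities
        else:
            probs[i] = mil_core.patient_forward(bag, model).probabilities
    return probs


def train_model(cohort: Cohort, level: str,
                config: Optional[TrainConfig] = None):
    """Train a slide- or patient-level model on the cohort's train split.

    Returns ``(model, TrainHistory)`` where the model carries the parameters
    of the epoch with the best validation macro AUC.  Fully deterministic
    for a fixed config seed.  The patch encoder is untouched: training sees
    only precomputed embeddings.
    """
    config = config or TrainConfig.for_level(level)
    if config.level != level:
        raise ValueError("config level does not match requested level")
    cohort.assert_no_leakage()

    if level == "slide":
        train_items = cohort.slide_items("train")
        val_items = cohort.slide_items("val")
    else:
        train_items = cohort.patient_items("train")
        val_items = cohort.patient_items("val")
    if not train_items or not val_items:
        raise ValueError("cohort needs non-empty train and val splits")

    rng = np.random.default_rng(config.seed)
    if level == "slide":
        model = SlideModel.init(cohort.dim, config.hidden_dim,
                                cohort.n_classes, seed=config.seed,
                                class_names=cohort.class_names)
        loss_and_grads = mil_core.slide_loss_and_grads
    else:
        model = PatientModel.init(cohort.dim, config.hidden_dim,
                                  cohort.n_classes, seed=config.seed,
                                  class_names=cohort.class_names)
        loss_and_grads = mil_core.patient_loss_and_grads

    params = model.parameters()
    opt = Adam(params)
    history = TrainHistory()
    val_bags = [b for _, b, _ in val_items]
    val_truth = np.array([y for _, _, y in val_items])
    val_aucs: List[float] = []
    best_params = {k: v.copy() for k, v in params.items()}

    for epoch in range(1, config.max_epochs + 1):
        lr = cosine_lr(epoch - 1, config)
        order = rng.permutation(len(train_items))
        total = 0.0
        for j in order:
            _, bag, label = train_items[j]
            loss, grads, _ = loss_and_grads(bag, label, model)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} on bag "
                    f"{train_items[j][0]!r}: aborting")
            opt.step(params, grads, lr)
            total += loss
        train_loss = total / len(train_items)

        val_probs = _eval_bags(val_bags, val_truth, model, level)
        val_auc = _macro_ovr_auc(val_probs, val_truth, cohort.n_classes)
        val_aucs.append(val_auc)
        history.epochs.append({"epoch": epoch, "lr": lr,
                               "train_loss": train_loss, "val_auc": val_auc})
        if val_auc > history.best_val_auc + config.min_delta:
            history.best_val_auc = val_auc
            history.best_epoch = epoch
            best_params = {k: v.copy() for k, v in params.items()}
        if early_stopping_step(val_aucs, config) == "stop":
            history.stopped_epoch = epoch
            break
    else:
        history.stopped_epoch = config.max_epochs

    for k, v in params.items():
        v[...] = best_params[k]
    logger.info("training stopped at epoch %d (best %d, val AUC %.4f)",
                history.stopped_epoch, history.best_epoch, history.best_val_auc)
    return model, history
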