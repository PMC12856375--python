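"""Leave-one-out training/validation and the classification metric suite.

One fold trains a freshly initialized model on every participant except one,
with augmentation applied to training images only, then evaluates the
final-epoch model once on the held-out participant (no augmentation, no
gradient) and measures per-feature perturbation errors there. All RNG
streams (weight init, dropout, shuffling, augmentation, perturbation) derive
from one seed via named substreams, so a run is bit-reproducible on one CPU.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from dmnfuse import cnn_model, perturbation_ranking
from dmnfuse.cohort_io import (
    Cohort,
    NormalizationParams,
    assemble_bundle,
    augment,
    fit_normalization,
    resize,
)
from dmnfuse.cnn_model import ModelConfig, build_model
from dmnfuse.errors import EmptyCohortError, InvalidSpecError
from dmnfuse.nn import Adam, binary_cross_entropy, sigmoid

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; defaults follow the reference configuration."""

    epochs: int = 80
    batch_size: int = 64
    learning_rate: float = 1e-4
    p_flip: float = 0.5
    p_rotate: float = 0.5
    seed: int = 0
    mode: str = cnn_model.MULTIMODAL
    resize_to: tuple[int, int, int] | None = None
    per_fold_normalization: bool = False
    perturb_repeats: int = 20
    perturb_error: str = "bce"  # or "misclassification"

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise InvalidSpecError("epochs, batch_size and learning_rate must be positive")
        if not (0.0 <= self.p_flip <= 1.0 and 0.0 <= self.p_rotate <= 1.0):
            raise InvalidSpecError("augmentation probabilities must be in [0, 1]")


@dataclass
class FoldOutcome:
    """Held-out prediction and perturbation errors for one LOOCV fold."""

    held_out_id: str
    group: str  # diagnosis of the held-out participant
    true_label: int
    predicted_prob: float
    predicted_label: int
    baseline_error: float
    perturbation_errors: dict[str, float]
    n_train: int
    epoch_losses: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class MetricsReport:
    """Confusion-matrix counts and the derived classification metrics."""

    tp: int
    fn: int
    tn: int
    fp: int
    accuracy_pct: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("tp", "fn", "tn", "fp", "accuracy_pct", "sensitivity",
                 "specificity", "precision", "f1", "mcc")}


#: Classification threshold on the sigmoid output.
THRESHOLD = 0.5


def _fold_streams(seed: int | np.random.SeedSequence):
    """Named RNG substreams for one fold: init, dropout, shuffle, augment, perturb."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(5)
    return (children[0],) + tuple(np.random.default_rng(c) for c in children[1:])


def train_fold(cohort: Cohort, held_out_id: str, model_config: ModelConfig,
               train_config: TrainConfig,
               norm_params: NormalizationParams | None = None,
               seed: int | np.random.SeedSequence | None = None,
               compute_perturbations: bool = True) -> FoldOutcome:
    """Train on all participants except ``held_out_id``; validate on it once.

    Augmentation touches training images only. The effective batch size is
    ``min(batch_size, n_train)``. The final-epoch model produces the held-out
    prediction and, optionally, per-feature perturbation errors.
    """
    ids = cohort.ids
    if held_out_id not in ids:
        raise KeyError(f"held_out_id {held_out_id!r} not in cohort")
    held = cohort[held_out_id]
    train_records = [r for r in cohort.records if r.id != held_out_id]
    n_train = len(train_records)
    if n_train == 0:
        raise EmptyCohortError("cannot train on an empty fold")

    if norm_params is None:
        fit_on = cohort.subset(r.id for r in train_records) \
            if train_config.per_fold_normalization else cohort
        norm_params = fit_normalization(fit_on)

    init_ss, dropout_rng, shuffle_rng, aug_rng, perturb_rng = _fold_streams(
        train_config.seed if seed is None else seed)

    config = model_config.as_mode(train_config.mode)
    model = build_model(config, seed=init_ss)
    model.set_dropout_rng(dropout_rng)

    def prepare(stack: np.ndarray) -> np.ndarray:
        if train_config.resize_to is not None:
            return resize(stack, train_config.resize_to)
        return stack

    bundles = [assemble_bundle(r, norm_params) for r in train_records]
    images = np.stack([prepare(b.image_stack) for b in bundles])
    clinical = np.stack([b.clinical for b in bundles]).astype(np.float32)
    labels = np.array([b.label for b in bundles], dtype=np.float32)

    # anti-leakage audit: the held-out participant never enters a training batch
    train_ids = {b.participant_id for b in bundles}
    assert held_out_id not in train_ids
    logger.info("fold %s: training on %d participants (held-out excluded)",
                held_out_id, n_train)

    batch_size = min(train_config.batch_size, n_train)
    if train_config.batch_size > n_train:
        logger.info("fold %s: batch size %d exceeds training-set size %d; "
                    "training full-batch", held_out_id, train_config.batch_size, n_train)

    optimizer = Adam(model.parameters(), lr=train_config.learning_rate)
    epoch_losses: list[float] = []
    for _ in range(train_config.epochs):
        order = (shuffle_rng.permutation(n_train) if batch_size < n_train
                 else np.arange(n_train))
        total = 0.0
        for start in range(0, n_train, batch_size):
            idx = order[start:start + batch_size]
            batch_images = np.stack([
                augment(images[i], train_config.p_flip, train_config.p_rotate, aug_rng)
                for i in idx])
            logit = model.forward_logit(batch_images, clinical[idx], train=True)
            prob = sigmoid(logit)
            total += float(binary_cross_entropy(prob, labels[idx]).sum())
            optimizer.zero_grad()
            model.backward(((prob - labels[idx]) / len(idx)).astype(np.float32))
            optimizer.step()
        epoch_losses.append(total / n_train)

    held_bundle = assemble_bundle(held, norm_params)
    held_bundle.image_stack = prepare(held_bundle.image_stack)
    prob = model.predict_proba_bundle(held_bundle)
    baseline = cnn_model.bce_loss(prob, held.label)

    perturbation_errors: dict[str, float] = {}
    if compute_perturbations:
        features = perturbation_ranking.feature_ids(cohort.roi_names,
                                                    cohort.clinical_names)
        if train_config.mode == cnn_model.UNIMODAL:
            features = [f for f in features if f.kind == "roi"]
        perturbation_errors = perturbation_ranking.fold_perturbation_errors(
            model, held_bundle, features, n_repeats=train_config.perturb_repeats,
            rng=perturb_rng, error=train_config.perturb_error)

    return FoldOutcome(
        held_out_id=held_out_id,
        group=held.diagnosis,
        true_label=held.label,
        predicted_prob=prob,
        predicted_label=int(prob >= THRESHOLD),
        baseline_error=baseline,
        perturbation_errors=perturbation_errors,
        n_train=n_train,
        epoch_losses=epoch_losses,
    )


def run_loocv(cohort: Cohort, model_config: ModelConfig,
              train_config: TrainConfig,
              compute_perturbations: bool = True,
              progress: bool = False) -> list[FoldOutcome]:
    """Run every LOOCV fold; per-fold seeds derive from the master seed."""
    if len(cohort) < 2:
        raise EmptyCohortError("LOOCV needs at least 2 participants")
    labels = {r.diagnosis for r in cohort.records}
    if len(labels) < 2:
        raise InvalidSpecError("LOOCV needs both diagnosis groups present")
    norm_params = None
    if not train_config.per_fold_normalization:
        norm_params = fit_normalization(cohort)
    outcomes = []
    for i, pid in enumerate(cohort.ids):
        fold_seed = np.random.SeedSequence(entropy=train_config.seed, spawn_key=(i,))
        outcome = train_fold(cohort, pid, model_config, train_config,
                             norm_params=norm_params, seed=fold_seed,
                             compute_perturbations=compute_perturbations)
        outcomes.append(outcome)
        if progress:
            logger.info("fold %d/%d (%s): true=%d prob=%.3f",
                        i + 1, len(cohort), pid, outcome.true_label,
                        outcome.predicted_prob)
    return outcomes


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def confusion_matrix(outcomes: list[FoldOutcome]) -> tuple[int, int, int, int]:
    """Tally (TP, FN, TN, FP) over fold outcomes; AD (label 1) is positive."""
    if not outcomes:
        raise EmptyCohortError("no outcomes to tally")
    tp = sum(1 for o in outcomes if o.true_label == 1 and o.predicted_label == 1)
    fn = sum(1 for o in outcomes if o.true_label == 1 and o.predicted_label == 0)
    tn = sum(1 for o in outcomes if o.true_label == 0 and o.predicted_label == 0)
    fp = sum(1 for o in outcomes if o.true_label == 0 and o.predicted_label == 1)
    return tp, fn, tn, fp


def compute_metrics(tp: int, fn: int, tn: int, fp: int) -> MetricsReport:
    """Accuracy (%), sensitivity, specificity, precision, F1 and MCC.

    Precision and F1 are defined as 0 when TP + FP = 0; MCC is 0 when any
    factor of its denominator is 0.
    """
    n = tp + fn + tn + fp
    if n == 0:
        raise EmptyCohortError("empty confusion matrix")
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("confusion-matrix counts must be non-negative")
    accuracy = 100.0 * (tp + tn) / n
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return MetricsReport(tp, fn, tn, fp, accuracy, sensitivity, specificity,
                         precision, f1, mcc)


def _round_half_away(x: float) -> int:
    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)


def recover_confusion_from_rates(sensitivity: float, specificity: float,
                                 n_pos: int, n_neg: int) -> tuple[int, int, int, int]:
    """Integer confusion matrix implied by printed rates and group sizes.

    TP = round(sensitivity * n_pos), TN = round(specificity * n_neg) with
    half rounded away from zero; FN and FP are the complements.
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("group counts must be >= 1")
    tp = _round_half_away(sensitivity * n_pos)
    tn = _round_half_away(specificity * n_neg)
    return tp, n_pos - tp, tn, n_neg - tn
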