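"""Perturbation-based feature importance: per-fold errors, per-group
aggregation, ranking, normalized importance, and between-group rank changes.

A "feature" is one model input: one ROI image channel or one clinical score
(10 features in the default configuration). Perturbing a feature randomizes
it while leaving every other input bit-identical; the resulting increase in
held-out error measures that feature's importance. Errors are averaged per
diagnosis group across LOOCV folds, ranked descending (rank 1 = most
important), and normalized by the within-group maximum so each group's top
feature scores exactly 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from dmnfuse.cohort_io import InputBundle
from dmnfuse.errors import InvalidSpecError
from dmnfuse.nn import binary_cross_entropy

ROI = "roi"
CLINICAL = "clinical"


@dataclass(frozen=True)
class FeatureId:
    """One perturbable model input."""

    kind: str  # "roi" or "clinical"
    name: str
    index: int  # channel index (roi) or clinical-vector position (clinical)


def feature_ids(roi_names: Sequence[str],
                clinical_names: Sequence[str]) -> list[FeatureId]:
    """The frozen feature list: ROI channels first, then clinical scores."""
    rois = [FeatureId(ROI, n, i) for i, n in enumerate(roi_names)]
    clin = [FeatureId(CLINICAL, n, i) for i, n in enumerate(clinical_names)]
    return rois + clin


def perturb_feature(bundle: InputBundle, feature: FeatureId,
                    rng: np.random.Generator, strategy: str | None = None,
                    reference: np.ndarray | None = None) -> InputBundle:
    """Return a copy of ``bundle`` with exactly one feature randomized.

    Clinical strategies: ``"uniform"`` (default) draws from U[0, 1];
    ``"reference"`` draws from the given reference column (one value per
    cohort participant). ROI strategies: ``"permute"`` (default) shuffles the
    channel's voxels, preserving its multiset; ``"noise"`` replaces it with
    Gaussian noise matched to the channel's mean and SD.
    """
    out = bundle.copy()
    if feature.kind == CLINICAL:
        if feature.index >= out.clinical.shape[0]:
            raise InvalidSpecError(f"unknown clinical feature {feature}")
        strategy = strategy or "uniform"
        if strategy == "uniform":
            out.clinical[feature.index] = rng.uniform(0.0, 1.0)
        elif strategy == "reference":
            if reference is None:
                raise InvalidSpecError("'reference' strategy needs reference values")
            out.clinical[feature.index] = rng.choice(np.asarray(reference))
        else:
            raise InvalidSpecError(f"unknown clinical strategy {strategy!r}")
    elif feature.kind == ROI:
        if feature.index >= out.image_stack.shape[0]:
            raise InvalidSpecError(f"unknown ROI feature {feature}")
        channel = out.image_stack[feature.index]
        strategy = strategy or "permute"
        if strategy == "permute":
            out.image_stack[feature.index] = rng.permutation(
                channel.ravel()).reshape(channel.shape)
        elif strategy == "noise":
            out.image_stack[feature.index] = rng.normal(
                float(channel.mean()), float(channel.std()),
                size=channel.shape).astype(channel.dtype)
        else:
            raise InvalidSpecError(f"unknown ROI strategy {strategy!r}")
    else:
        raise InvalidSpecError(f"unknown feature kind {feature.kind!r}")
    return out


def fold_perturbation_errors(model, bundle: InputBundle,
                             features: Iterable[FeatureId],
                             n_repeats: int = 20,
                             rng: np.random.Generator | None = None,
                             strategy: str | None = None,
                             error: str = "bce") -> dict[str, float]:
    """Mean held-out error per feature over independent perturbation draws.

    ``model`` needs a ``predict_proba_bundle(bundle) -> float`` method and is
    evaluated without gradients or augmentation. ``error`` is ``"bce"``
    (default) or ``"misclassification"`` (0/1 at threshold 0.5).
    """
    if n_repeats < 1:
        raise InvalidSpecError("n_repeats must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    out: dict[str, float] = {}
    for feature in features:
        errs = []
        for _ in range(n_repeats):
            perturbed = perturb_feature(bundle, feature, rng, strategy=strategy)
            prob = model.predict_proba_bundle(perturbed)
            if error == "bce":
                errs.append(float(binary_cross_entropy(prob, bundle.label)))
            elif error == "misclassification":
                errs.append(float(int(prob >= 0.5) != bundle.label))
            else:
                raise InvalidSpecError(f"unknown error metric {error!r}")
        out[feature.name] = float(np.mean(errs))
    return out


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass
class GroupImportance:
    """Per-feature mean error, rank (1 = most important) and importance for
    one diagnosis group."""

    mean_error: dict[str, float]
    rank: dict[str, int]
    importance: dict[str, float]


@dataclass
class ImportanceTable:
    """Per-group rankings over a shared, ordered feature set."""

    feature_order: tuple[str, ...]
    groups: dict[str, GroupImportance]


@dataclass(frozen=True)
class RankChange:
    feature: str
    cn_rank: int
    ad_rank: int
    change: int  # cn_rank - ad_rank


def _rank_group(errors: dict[str, float],
                feature_order: Sequence[str]) -> GroupImportance:
    order_index = {name: i for i, name in enumerate(feature_order)}
    ordered = sorted(errors, key=lambda nm: (-errors[nm], order_index[nm]))
    rank = {name: i + 1 for i, name in enumerate(ordered)}
    max_err = max(errors.values())
    if max_err <= 0:
        importance = {name: 1.0 for name in errors}  # all-zero errors: flat
    else:
        importance = {name: errors[name] / max_err for name in errors}
    return GroupImportance(dict(errors), rank, importance)


def importance_from_errors(group_errors: dict[str, dict[str, float]],
                           feature_order: Sequence[str] | None = None) -> ImportanceTable:
    """Build an :class:`ImportanceTable` from per-group mean-error vectors.

    Ranks are descending in mean error with ties broken by ``feature_order``;
    importance is mean error divided by the within-group maximum, so the
    top-ranked feature of each group has importance exactly 1.0.
    """
    if not group_errors:
        raise InvalidSpecError("no groups given")
    feature_sets = {frozenset(errs) for errs in group_errors.values()}
    if len(feature_sets) != 1:
        raise InvalidSpecError("groups rank different feature sets")
    if feature_order is None:
        feature_order = tuple(next(iter(group_errors.values())))
    groups = {g: _rank_group(errs, feature_order)
              for g, errs in group_errors.items()}
    return ImportanceTable(tuple(feature_order), groups)


def aggregate_importance(fold_outcomes: Sequence,
                         feature_order: Sequence[str] | None = None) -> ImportanceTable:
    """Average each feature's perturbation error within each diagnosis group
    (folds grouped by their held-out participant's diagnosis), then rank and
    normalize."""
    by_group: dict[str, list[dict[str, float]]] = {}
    for outcome in fold_outcomes:
        if not outcome.perturbation_errors:
            raise InvalidSpecError(
                f"fold {outcome.held_out_id} carries no perturbation errors")
        by_group.setdefault(outcome.group, []).append(outcome.perturbation_errors)
    if len(by_group) < 2:
        raise InvalidSpecError(
            f"need folds from both diagnosis groups, got {sorted(by_group)}")
    group_errors = {
        g: {name: float(np.mean([errs[name] for errs in fold_errs]))
            for name in fold_errs[0]}
        for g, fold_errs in by_group.items()}
    return importance_from_errors(group_errors, feature_order)


def rank_change(table: ImportanceTable, cn_group: str = "CN",
                ad_group: str = "AD") -> list[RankChange]:
    """Per-feature CN rank minus AD rank, in feature order."""
    for g in (cn_group, ad_group):
        if g not in table.groups:
            raise InvalidSpecError(f"group {g!r} missing from importance table")
    cn, ad = table.groups[cn_group].rank, table.groups[ad_group].rank
    if set(cn) != set(ad):
        raise InvalidSpecError("groups rank different feature sets")
    return [RankChange(name, cn[name], ad[name], cn[name] - ad[name])
            for name in table.feature_order]
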