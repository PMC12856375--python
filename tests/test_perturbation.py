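"""Perturbation ranking: locality, strategies, aggregation arithmetic."""

import numpy as np
import pytest

import dmnfuse as dm
from dmnfuse.errors import InvalidSpecError
from dmnfuse.loocv_training import FoldOutcome
from dmnfuse.nn import sigmoid
from dmnfuse.perturbation_ranking import CLINICAL, ROI


@pytest.fixture
def bundle(rng):
    return dm.InputBundle("sub-001",
                          rng.normal(size=(4, 8, 8, 8)).astype(np.float32),
                          rng.random(6), 1)


@pytest.fixture
def features():
    return dm.feature_ids(dm.DEFAULT_ROI_NAMES, dm.DEFAULT_CLINICAL_NAMES)


def test_feature_ids_layout(features):
    assert len(features) == 10
    assert [f.kind for f in features] == [ROI] * 4 + [CLINICAL] * 6
    assert len({f.name for f in features}) == 10
    assert [f.index for f in features] == [0, 1, 2, 3, 0, 1, 2, 3, 4, 5]


def test_perturb_clinical_locality(bundle, features, rng):
    feat = features[5]  # a clinical feature
    out = dm.perturb_feature(bundle, feat, rng)
    np.testing.assert_array_equal(out.image_stack, bundle.image_stack)
    mask = np.arange(6) != feat.index
    np.testing.assert_array_equal(out.clinical[mask], bundle.clinical[mask])
    assert 0.0 <= out.clinical[feat.index] <= 1.0
    # the original bundle is untouched
    assert bundle.clinical[feat.index] != out.clinical[feat.index]


def test_perturb_roi_permutation_preserves_multiset(bundle, features, rng):
    feat = features[2]  # an ROI feature
    out = dm.perturb_feature(bundle, feat, rng)
    np.testing.assert_array_equal(out.clinical, bundle.clinical)
    for c in range(4):
        if c == feat.index:
            np.testing.assert_array_equal(
                np.sort(out.image_stack[c].ravel()),
                np.sort(bundle.image_stack[c].ravel()))
        else:
            np.testing.assert_array_equal(out.image_stack[c],
                                          bundle.image_stack[c])


def test_perturb_roi_noise_strategy(bundle, features, rng):
    feat = features[0]
    out = dm.perturb_feature(bundle, feat, rng, strategy="noise")
    chan = out.image_stack[feat.index]
    src = bundle.image_stack[feat.index]
    assert chan.shape == src.shape
    assert not np.array_equal(chan, src)
    assert abs(chan.mean() - src.mean()) < 0.1


def test_perturb_clinical_reference_strategy(bundle, features, rng):
    ref = np.array([0.2, 0.4, 0.6])
    feat = features[4]
    out = dm.perturb_feature(bundle, feat, rng, strategy="reference", reference=ref)
    assert out.clinical[feat.index] in ref


def test_perturb_unknown_feature(bundle, rng):
    bad = dm.FeatureId("clinical", "nope", 17)
    with pytest.raises(InvalidSpecError):
        dm.perturb_feature(bundle, bad, rng)


class _ClinicalProbe:
    """Toy model: sigmoid of a linear score over the clinical vector."""

    def __init__(self, weights, bias=0.0):
        self.w = np.asarray(weights, dtype=float)
        self.b = bias

    def predict_proba_bundle(self, bundle):
        return float(sigmoid(np.array([self.w @ bundle.clinical + self.b]))[0])


def test_informative_feature_has_greatest_error(features, rng):
    """Analytic probe: only feature 0 (first clinical entry) carries weight,
    so only its perturbation can change the output."""
    probe = _ClinicalProbe([8.0, 0, 0, 0, 0, 0], bias=-4.0)
    clinical = np.array([1.0, 0.5, 0.5, 0.5, 0.5, 0.5])
    bundle = dm.InputBundle("sub-x", np.zeros((4, 6, 6, 6), np.float32), clinical, 1)
    clin_feats = [f for f in features if f.kind == CLINICAL]
    errors = dm.fold_perturbation_errors(probe, bundle, clin_feats,
                                         n_repeats=50,
                                         rng=np.random.default_rng(0))
    informative = clin_feats[0].name
    for name, err in errors.items():
        if name != informative:
            assert errors[informative] > err


def test_unimodal_clinical_errors_equal_baseline(tiny_cohort, rng):
    """Severed input path: a unimodal model is invariant to clinical
    perturbation, so every clinical error equals the baseline error."""
    model = dm.build_model(dm.ModelConfig(mode="unimodal"), seed=0)
    params = dm.fit_normalization(tiny_cohort)
    bundle = dm.assemble_bundle(tiny_cohort.records[0], params)
    baseline = dm.bce_loss(model.predict_proba_bundle(bundle), bundle.label)
    clin_feats = [f for f in dm.feature_ids(tiny_cohort.roi_names,
                                            tiny_cohort.clinical_names)
                  if f.kind == CLINICAL]
    errors = dm.fold_perturbation_errors(model, bundle, clin_feats,
                                         n_repeats=3, rng=rng)
    for err in errors.values():
        assert err == pytest.approx(baseline, abs=1e-12)


def test_fold_perturbation_errors_deterministic(bundle, features):
    probe = _ClinicalProbe([1, -1, 2, 0, 0.5, -0.5])
    a = dm.fold_perturbation_errors(probe, bundle, features, n_repeats=2,
                                    rng=np.random.default_rng(5))
    b = dm.fold_perturbation_errors(probe, bundle, features, n_repeats=2,
                                    rng=np.random.default_rng(5))
    assert a == b


def test_misclassification_error_mode(bundle, features):
    probe = _ClinicalProbe([0, 0, 0, 0, 0, 0], bias=3.0)  # always predicts AD
    errors = dm.fold_perturbation_errors(probe, bundle, features, n_repeats=2,
                                         rng=np.random.default_rng(1),
                                         error="misclassification")
    assert all(v == 0.0 for v in errors.values())  # label 1, always correct


# ---------------------------------------------------------------------------
# aggregation arithmetic
# ---------------------------------------------------------------------------

CN_ERRORS = {"MoCA": 0.237, "RAVLT_immediate": 0.179, "FAQ": 0.141,
             "EcogPtTotal": 0.140, "ADAS13": 0.131, "RAVLT_pct_forgetting": 0.122}
AD_ERRORS = {"RAVLT_pct_forgetting": 0.209, "ADAS13": 0.175, "FAQ": 0.164,
             "EcogPtTotal": 0.140, "RAVLT_immediate": 0.116, "MoCA": 0.091}


def test_importance_from_error_vectors():
    table = dm.importance_from_errors({"CN": CN_ERRORS, "AD": AD_ERRORS},
                                      dm.DEFAULT_CLINICAL_NAMES)
    cn, ad = table.groups["CN"], table.groups["AD"]
    assert round(cn.importance["FAQ"], 3) == 0.595
    assert round(ad.importance["EcogPtTotal"], 3) == 0.670
    assert cn.importance["MoCA"] == 1.0
    assert ad.importance["RAVLT_pct_forgetting"] == 1.0
    assert cn.rank["MoCA"] == 1 and cn.rank["RAVLT_pct_forgetting"] == 6
    assert ad.rank["RAVLT_pct_forgetting"] == 1 and ad.rank["MoCA"] == 6


def test_importance_all_equal_is_tie_broken_by_feature_order():
    errs = {n: 0.2 for n in dm.DEFAULT_CLINICAL_NAMES}
    table = dm.importance_from_errors({"CN": errs, "AD": errs},
                                      dm.DEFAULT_CLINICAL_NAMES)
    for group in table.groups.values():
        assert all(v == 1.0 for v in group.importance.values())
        ranks = [group.rank[n] for n in dm.DEFAULT_CLINICAL_NAMES]
        assert ranks == [1, 2, 3, 4, 5, 6]


def test_aggregate_importance_means_over_folds():
    def fo(pid, group, errs):
        return FoldOutcome(pid, group, int(group == "AD"), 0.5, 1, 0.1, errs, 3)

    outcomes = [
        fo("a", "CN", {"f1": 0.1, "f2": 0.3}),
        fo("b", "CN", {"f1": 0.3, "f2": 0.5}),
        fo("c", "AD", {"f1": 0.8, "f2": 0.2}),
    ]
    table = dm.aggregate_importance(outcomes, feature_order=("f1", "f2"))
    assert table.groups["CN"].mean_error == {"f1": pytest.approx(0.2),
                                             "f2": pytest.approx(0.4)}
    assert table.groups["AD"].mean_error == {"f1": 0.8, "f2": 0.2}
    assert table.groups["CN"].rank == {"f2": 1, "f1": 2}
    assert table.groups["AD"].importance["f2"] == pytest.approx(0.25)


def test_aggregate_importance_needs_both_groups():
    def fo(pid, group):
        return FoldOutcome(pid, group, 1, 0.5, 1, 0.1, {"f": 0.2}, 3)

    with pytest.raises(InvalidSpecError):
        dm.aggregate_importance([fo("a", "AD"), fo("b", "AD")])


def test_rank_change_from_reference_ranks():
    table = dm.importance_from_errors({"CN": CN_ERRORS, "AD": AD_ERRORS},
                                      dm.DEFAULT_CLINICAL_NAMES)
    changes = {c.feature: c for c in dm.rank_change(table)}
    assert changes["MoCA"].change == 1 - 6 == -5
    assert changes["FAQ"].change == 0  # rank 3 in both groups
    assert sum(c.change for c in changes.values()) == 0


def test_rank_change_identical_rankings_all_zero():
    errs = {"a": 0.3, "b": 0.2, "c": 0.1}
    table = dm.importance_from_errors({"CN": errs, "AD": errs}, ("a", "b", "c"))
    assert all(c.change == 0 for c in dm.rank_change(table))


def test_rank_change_mismatched_features():
    table = dm.importance_from_errors({"CN": {"a": 1.0}, "AD": {"a": 1.0}}, ("a",))
    table.groups["AD"].rank = {"b": 1}
    with pytest.raises(InvalidSpecError):
        dm.rank_change(table)


def test_importance_from_errors_rejects_mismatched_groups():
    with pytest.raises(InvalidSpecError):
        dm.importance_from_errors({"CN": {"a": 1.0}, "AD": {"b": 1.0}})
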