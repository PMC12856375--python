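"""I/O round-trips, normalization, bundle assembly, augmentation, resizing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import dmnfuse as dm
from dmnfuse.cohort_io import write_records
from dmnfuse.errors import (
    DegenerateMeasureError,
    EmptyCohortError,
    IncompleteParticipantError,
    ShapeError,
    UnsupportedShapeError,
)


# ---------------------------------------------------------------------------
# round trip
# ---------------------------------------------------------------------------

def test_write_load_round_trip(tmp_path, tiny_cohort):
    out = tmp_path / "cohort"
    dm.write_cohort(tiny_cohort, out)
    loaded = dm.load_cohort(out)
    assert loaded.ids == tiny_cohort.ids
    assert set(loaded.roi_names) == set(tiny_cohort.roi_names)
    for src, dst in zip(tiny_cohort.records, loaded.records):
        assert src.diagnosis == dst.diagnosis
        np.testing.assert_allclose(src.clinical_raw, dst.clinical_raw, atol=1e-6)
    # ROI volumes survive float32 storage
    order = {n: i for i, n in enumerate(tiny_cohort.roi_names)}
    for src, dst in zip(tiny_cohort.records, loaded.records):
        for name, vol in zip(loaded.roi_names, dst.volumes):
            np.testing.assert_allclose(vol, src.volumes[order[name]], atol=1e-6)


def test_load_missing_roi(tmp_path, tiny_cohort):
    out = tmp_path / "cohort"
    manifest = dm.write_cohort(tiny_cohort, out)
    victim = next(p for p in manifest if p.name.endswith(".nii.gz")
                  and tiny_cohort.ids[1] in p.name)
    victim.unlink()
    with pytest.raises(IncompleteParticipantError, match=tiny_cohort.ids[1]):
        dm.load_cohort(out)


def test_load_missing_clinical_value(tmp_path, tiny_cohort):
    out = tmp_path / "cohort"
    dm.write_cohort(tiny_cohort, out)
    tsv = out / "participants.tsv"
    lines = tsv.read_text().splitlines()
    cells = lines[1].split("\t")
    cells[2] = ""  # blank out the first clinical value
    lines[1] = "\t".join(cells)
    tsv.write_text("\n".join(lines) + "\n")
    with pytest.raises(IncompleteParticipantError, match=tiny_cohort.ids[0]):
        dm.load_cohort(out)


def test_load_empty_directory(tmp_path):
    with pytest.raises(EmptyCohortError):
        dm.load_cohort(tmp_path)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _cohort_with_clinical(rows, names=dm.DEFAULT_CLINICAL_NAMES):
    vol = np.zeros((2, 2, 2))
    records = [
        dm.ParticipantRecord(f"sub-{i:03d}", "AD" if i % 2 else "CN",
                             (vol,) * 4, np.asarray(row, dtype=float))
        for i, row in enumerate(rows)]
    return dm.Cohort(records, dm.DEFAULT_ROI_NAMES, tuple(names))


def test_fit_normalization_extrema():
    rows = [[0, 1, 0, 10, 0, 0], [1, 2, 1, 30, 1, 1], [0.5, 1.5, 0.2, 20, 0.7, 0.1]]
    params = dm.fit_normalization(_cohort_with_clinical(rows))
    moca = list(params.names).index("MoCA")
    assert params.minima[moca] == 10 and params.maxima[moca] == 30


def test_fit_normalization_degenerate_single_participant():
    with pytest.raises(DegenerateMeasureError):
        dm.fit_normalization(_cohort_with_clinical([[1, 2, 3, 4, 5, 6]]))


def test_fit_normalization_names_constant_measure():
    rows = [[0, 1, 5, 10, 0, 0], [1, 2, 5, 30, 1, 1]]
    with pytest.raises(DegenerateMeasureError, match="FAQ"):
        dm.fit_normalization(_cohort_with_clinical(rows))


def test_normalized_scores_attain_endpoints(default_cohort):
    params = dm.fit_normalization(default_cohort)
    scaled = np.stack([dm.normalize_clinical(r.clinical_raw, params)
                       for r in default_cohort.records])
    assert np.all(scaled >= 0) and np.all(scaled <= 1)
    np.testing.assert_allclose(scaled.min(axis=0), 0, atol=1e-12)
    np.testing.assert_allclose(scaled.max(axis=0), 1, atol=1e-12)


def test_normalize_formula_values():
    params = dm.NormalizationParams(("m",), np.array([10.0]), np.array([30.0]))
    assert dm.normalize_clinical([10.0], params)[0] == 0.0
    assert dm.normalize_clinical([30.0], params)[0] == 1.0
    assert dm.normalize_clinical([15.0], params)[0] == pytest.approx(0.25)
    # out-of-range values clip to the unit interval
    assert dm.normalize_clinical([5.0], params)[0] == 0.0
    assert dm.normalize_clinical([95.0], params)[0] == 1.0


@given(st.lists(st.floats(min_value=10, max_value=30), min_size=2, max_size=20))
def test_normalize_is_order_preserving(values):
    params = dm.NormalizationParams(("m",), np.array([10.0]), np.array([30.0]))
    scaled = [dm.normalize_clinical([v], params)[0] for v in values]
    order = np.argsort(values, kind="stable")
    assert np.all(np.diff(np.asarray(scaled)[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# bundle assembly
# ---------------------------------------------------------------------------

def test_assemble_bundle_shape(default_cohort):
    params = dm.fit_normalization(default_cohort)
    bundle = dm.assemble_bundle(default_cohort.records[0], params)
    assert bundle.image_stack.shape == (4, 16, 16, 16)
    assert bundle.clinical.shape == (6,)
    assert bundle.label in (0, 1)


def test_assemble_bundle_at_minima():
    rows = [[0, 1, 0, 10, 0, 0], [1, 2, 1, 30, 1, 1]]
    cohort = _cohort_with_clinical(rows)
    params = dm.fit_normalization(cohort)
    bundle = dm.assemble_bundle(cohort.records[0], params)
    np.testing.assert_array_equal(bundle.clinical, 0.0)


def test_assemble_bundle_shape_mismatch():
    rec = dm.ParticipantRecord("sub-x", "AD", (np.zeros((2, 2, 2)),) * 2,
                               np.zeros(6))
    rec.volumes = (np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))  # corrupt in place
    params = dm.NormalizationParams(dm.DEFAULT_CLINICAL_NAMES,
                                    np.zeros(6), np.ones(6))
    with pytest.raises(ShapeError):
        dm.assemble_bundle(rec, params)


def test_bundles_do_not_share_memory(default_cohort):
    """Anti-leakage: mutating one participant's bundle leaves another's
    bundle bit-identical."""
    params = dm.fit_normalization(default_cohort)
    bundle_b = dm.assemble_bundle(default_cohort.records[1], params)
    before = (bundle_b.image_stack.copy(), bundle_b.clinical.copy())
    bundle_a = dm.assemble_bundle(default_cohort.records[0], params)
    bundle_a.image_stack[...] = 99.0
    bundle_a.clinical[...] = 99.0
    np.testing.assert_array_equal(bundle_b.image_stack, before[0])
    np.testing.assert_array_equal(bundle_b.clinical, before[1])


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def test_augment_identity_at_zero_probability(rng):
    stack = rng.normal(size=(4, 6, 6, 6))
    out = dm.augment(stack, 0.0, 0.0, rng)
    np.testing.assert_array_equal(out, stack)


def test_augment_flip_is_involution(rng):
    stack = rng.normal(size=(4, 6, 6, 6))
    once = dm.augment(stack, 1.0, 0.0, np.random.default_rng(7))
    twice = dm.augment(once, 1.0, 0.0, np.random.default_rng(7))
    np.testing.assert_array_equal(twice, stack)


def test_augment_preserves_voxel_multiset_per_channel(rng):
    stack = rng.normal(size=(4, 6, 6, 6))
    out = dm.augment(stack, 1.0, 1.0, rng)
    assert out.shape == stack.shape
    for c in range(4):
        np.testing.assert_array_equal(np.sort(out[c].ravel()),
                                      np.sort(stack[c].ravel()))


def test_augment_same_transform_all_channels(rng):
    base = rng.normal(size=(6, 6, 6))
    stack = np.stack([base, base + 1.0])
    out = dm.augment(stack, 1.0, 1.0, rng)
    np.testing.assert_allclose(out[1] - out[0], 1.0)


def test_augment_rejects_noncubic_rotation(rng):
    stack = rng.normal(size=(4, 6, 6, 8))
    with pytest.raises(UnsupportedShapeError):
        dm.augment(stack, 0.0, 1.0, rng)
    # flips alone are fine on non-cubic grids
    dm.augment(stack, 1.0, 0.0, rng)


def test_augment_probability_bounds(rng):
    with pytest.raises(ValueError):
        dm.augment(np.zeros((1, 2, 2, 2)), -0.1, 0.0, rng)


# ---------------------------------------------------------------------------
# resizing
# ---------------------------------------------------------------------------

def test_resize_identity(rng):
    stack = rng.normal(size=(4, 8, 8, 8))
    np.testing.assert_allclose(dm.resize(stack, (8, 8, 8)), stack, atol=1e-6)


def test_resize_constant_volume():
    stack = np.full((2, 6, 6, 6), 3.5)
    out = dm.resize(stack, (9, 9, 9))
    assert out.shape == (2, 9, 9, 9)
    np.testing.assert_allclose(out, 3.5, atol=1e-6)


def test_resize_monotone_ramp():
    ramp = np.tile(np.linspace(0, 1, 8)[:, None, None], (1, 8, 8))
    out = dm.resize(ramp[None], (13, 13, 13))[0]
    profile = out[:, 6, 6]
    assert np.all(np.diff(profile) >= -1e-9)


def test_resize_rejects_bad_target(rng):
    with pytest.raises(ShapeError):
        dm.resize(rng.normal(size=(1, 4, 4, 4)), (0, 4, 4))
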