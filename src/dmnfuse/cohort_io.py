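"""Cohort data model, NIfTI/TSV I/O, clinical normalization, and image transforms.

Core types
----------
:class:`ParticipantRecord` couples one subject's ordered ROI volumes, raw
clinical scores, and diagnosis. :class:`InputBundle` is the atomic model
input: a 4-channel image stack plus the min-max normalized clinical vector
and the binary label. A bundle is assembled from exactly one participant and
never mixes data across participants.

Orderings
---------
Channel order and clinical order follow :data:`dmnfuse.constants.DEFAULT_ROI_NAMES`
and :data:`dmnfuse.constants.DEFAULT_CLINICAL_NAMES` (or the orderings stored
on the :class:`Cohort`). They are frozen so perturbation feature indices stay
stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from dmnfuse.constants import AD, CN, DIAGNOSIS_CODES
from dmnfuse.errors import (
    DegenerateMeasureError,
    EmptyCohortError,
    IncompleteParticipantError,
    ShapeError,
    UnsupportedShapeError,
)

PARTICIPANTS_TSV = "participants.tsv"


@dataclass
class ParticipantRecord:
    """One subject: ordered ROI volumes, raw clinical scores, diagnosis."""

    id: str
    diagnosis: str  # "AD" or "CN"
    volumes: tuple[np.ndarray, ...]
    clinical_raw: np.ndarray

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSIS_CODES:
            raise ValueError(f"diagnosis must be one of {sorted(DIAGNOSIS_CODES)}, "
                             f"got {self.diagnosis!r}")
        self.volumes = tuple(np.asarray(v) for v in self.volumes)
        self.clinical_raw = np.asarray(self.clinical_raw, dtype=float)
        shapes = {v.shape for v in self.volumes}
        if len(shapes) > 1:
            raise ShapeError(f"participant {self.id}: ROI volumes differ in shape {shapes}")

    @property
    def label(self) -> int:
        return DIAGNOSIS_CODES[self.diagnosis]


@dataclass
class Cohort:
    """Ordered collection of participants plus the ROI/clinical orderings."""

    records: list[ParticipantRecord]
    roi_names: tuple[str, ...]
    clinical_names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ParticipantRecord]:
        return iter(self.records)

    def __getitem__(self, participant_id: str) -> ParticipantRecord:
        for rec in self.records:
            if rec.id == participant_id:
                return rec
        raise KeyError(participant_id)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, ids: Iterable[str]) -> "Cohort":
        wanted = set(ids)
        return Cohort([r for r in self.records if r.id in wanted],
                      self.roi_names, self.clinical_names)


@dataclass(frozen=True)
class NormalizationParams:
    """Per-measure raw-scale minima and maxima for min-max scaling."""

    names: tuple[str, ...]
    minima: np.ndarray
    maxima: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "minima", np.asarray(self.minima, dtype=float))
        object.__setattr__(self, "maxima", np.asarray(self.maxima, dtype=float))


@dataclass
class InputBundle:
    """Atomic per-participant model input: image stack + normalized clinical + label."""

    participant_id: str
    image_stack: np.ndarray  # (n_roi, D, H, W)
    clinical: np.ndarray  # (n_clinical,), values in [0, 1]
    label: int

    def copy(self) -> "InputBundle":
        return InputBundle(self.participant_id, self.image_stack.copy(),
                           self.clinical.copy(), self.label)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def fit_normalization(cohort: Cohort) -> NormalizationParams:
    """Fit per-measure min and max over every participant in `cohort`.

    Raises
    ------
    EmptyCohortError
        If the cohort has no participants.
    DegenerateMeasureError
        If any measure is constant across the cohort (max == min), naming it.
    """
    if len(cohort) == 0:
        raise EmptyCohortError("cannot fit normalization on an empty cohort")
    raw = np.stack([r.clinical_raw for r in cohort.records])
    minima = raw.min(axis=0)
    maxima = raw.max(axis=0)
    constant = np.nonzero(maxima <= minima)[0]
    if constant.size:
        names = [cohort.clinical_names[i] for i in constant]
        raise DegenerateMeasureError(
            f"measure(s) {names} are constant across the cohort; "
            "min-max normalization is undefined")
    return NormalizationParams(tuple(cohort.clinical_names), minima, maxima)


def normalize_clinical(raw: Sequence[float] | np.ndarray,
                       params: NormalizationParams) -> np.ndarray:
    """Map raw scores to [0, 1] via (x - min) / (max - min), clipping overflow.

    Values outside the fitted [min, max] (possible at inference under
    per-fold refitting) are clipped so the head always sees bounded inputs.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape[-1] != len(params.names):
        raise ShapeError(f"expected {len(params.names)} scores, got {raw.shape[-1]}")
    scaled = (raw - params.minima) / (params.maxima - params.minima)
    return np.clip(scaled, 0.0, 1.0)


# ---------------------------------------------------------------------------
# disk I/O (BIDS-like layout)
# ---------------------------------------------------------------------------

def _roi_filename(participant_id: str, roi_name: str) -> str:
    return f"{participant_id}_roi-{roi_name}.nii.gz"


def load_cohort(directory: str | Path,
                roi_names: Sequence[str] | None = None,
                clinical_names: Sequence[str] | None = None) -> Cohort:
    """Load a cohort from a BIDS-like directory written by ``write_cohort``.

    Layout: ``participants.tsv`` at the root (columns: participant_id,
    diagnosis, one column per clinical measure) and one sub-directory per
    participant holding one ``.nii.gz`` per ROI.

    Participants missing any ROI file or clinical value are rejected with
    :class:`IncompleteParticipantError` naming them.
    """
    directory = Path(directory)
    tsv = directory / PARTICIPANTS_TSV
    if not tsv.is_file():
        raise EmptyCohortError(f"no {PARTICIPANTS_TSV} found in {directory}")
    table = pd.read_csv(tsv, sep="\t", dtype={"participant_id": str})
    if clinical_names is None:
        clinical_names = tuple(c for c in table.columns
                               if c not in ("participant_id", "diagnosis"))
    else:
        clinical_names = tuple(clinical_names)
    if len(table) == 0:
        raise EmptyCohortError(f"{tsv} lists no participants")

    records: list[ParticipantRecord] = []
    inferred_rois = tuple(roi_names) if roi_names is not None else None
    for row in table.itertuples(index=False):
        pid = row.participant_id
        subj_dir = directory / pid
        if inferred_rois is None:
            # infer ROI order from the first participant's sorted file names
            files = sorted(subj_dir.glob(f"{pid}_roi-*.nii.gz"))
            if not files:
                raise IncompleteParticipantError(f"participant {pid}: no ROI volumes found")
            inferred_rois = tuple(f.name[len(pid) + 5:-len(".nii.gz")] for f in files)
        clin = np.array([getattr(row, c) for c in clinical_names], dtype=float)
        if np.isnan(clin).any():
            bad = [c for c, v in zip(clinical_names, clin) if np.isnan(v)]
            raise IncompleteParticipantError(
                f"participant {pid}: missing clinical value(s) {bad}")
        vols = []
        for roi in inferred_rois:
            path = subj_dir / _roi_filename(pid, roi)
            if not path.is_file():
                raise IncompleteParticipantError(
                    f"participant {pid}: missing ROI volume {path.name}")
            vols.append(np.asanyarray(nib.load(path).dataobj, dtype=np.float64))
        records.append(ParticipantRecord(pid, row.diagnosis, tuple(vols), clin))
    return Cohort(records, inferred_rois, clinical_names)


def write_records(records: Iterable[ParticipantRecord],
                  roi_names: Sequence[str],
                  clinical_names: Sequence[str],
                  directory: str | Path) -> list[Path]:
    """Write records in the BIDS-like layout; returns the manifest of files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []
    rows = []
    affine = np.eye(4)
    for rec in records:
        subj_dir = directory / rec.id
        subj_dir.mkdir(exist_ok=True)
        for roi, vol in zip(roi_names, rec.volumes):
            path = subj_dir / _roi_filename(rec.id, roi)
            nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), path)
            manifest.append(path)
        rows.append({"participant_id": rec.id, "diagnosis": rec.diagnosis,
                     **{c: v for c, v in zip(clinical_names, rec.clinical_raw)}})
    tsv = directory / PARTICIPANTS_TSV
    columns = ["participant_id", "diagnosis", *clinical_names]
    pd.DataFrame(rows, columns=columns).to_csv(tsv, sep="\t", index=False)
    manifest.append(tsv)
    return manifest


# ---------------------------------------------------------------------------
# bundle assembly and image transforms
# ---------------------------------------------------------------------------

def assemble_bundle(record: ParticipantRecord,
                    params: NormalizationParams) -> InputBundle:
    """Stack a participant's ROI volumes into channels and attach the
    normalized clinical vector and label.

    All of one participant's data travels in the returned bundle; nothing is
    shared with any other record (anti-leakage contract).
    """
    if not record.volumes:
        raise ShapeError(f"participant {record.id} has no ROI volumes")
    shapes = {v.shape for v in record.volumes}
    if len(shapes) > 1:
        raise ShapeError(f"participant {record.id}: ROI shape mismatch {shapes}")
    stack = np.stack([np.asarray(v, dtype=np.float32) for v in record.volumes])
    clinical = normalize_clinical(record.clinical_raw, params)
    return InputBundle(record.id, stack, clinical, record.label)


def augment(image_stack: np.ndarray, p_flip: float, p_rotate: float,
            rng: np.random.Generator) -> np.ndarray:
    """Randomly flip and/or rotate an image stack, identically on all channels.

    With probability ``p_flip`` one spatial axis is reversed; with
    probability ``p_rotate`` the stack is rotated by a random multiple of 90
    degrees in a random spatial plane. Rotation requires a cubic grid (shape
    preservation); clinical data are never touched by augmentation.
    """
    if not (0.0 <= p_flip <= 1.0 and 0.0 <= p_rotate <= 1.0):
        raise ValueError("p_flip and p_rotate must be in [0, 1]")
    spatial = image_stack.shape[1:]
    if p_rotate > 0 and len(set(spatial)) != 1:
        raise UnsupportedShapeError(
            f"90-degree rotation requires a cubic grid, got {spatial}")
    out = image_stack
    if rng.random() < p_flip:
        axis = 1 + int(rng.integers(3))
        out = np.flip(out, axis=axis)
    if rng.random() < p_rotate:
        planes = ((1, 2), (1, 3), (2, 3))
        plane = planes[int(rng.integers(3))]
        quarter_turns = 1 + int(rng.integers(3))
        out = np.rot90(out, k=quarter_turns, axes=plane)
    return np.ascontiguousarray(out)


def resize(image_stack: np.ndarray, target: Sequence[int]) -> np.ndarray:
    """Trilinearly interpolate each channel to the target spatial shape."""
    target = tuple(int(t) for t in target)
    if len(target) != 3 or any(t <= 0 for t in target):
        raise ShapeError(f"target shape must be 3 positive dims, got {target}")
    if image_stack.shape[1:] == target:
        return image_stack.copy()
    factors = np.array(target, dtype=float) / np.array(image_stack.shape[1:], dtype=float)
    out = np.empty((image_stack.shape[0], *target), dtype=image_stack.dtype)
    for c in range(image_stack.shape[0]):
        out[c] = ndimage.zoom(image_stack[c], factors, order=1,
                              mode="nearest", grid_mode=True)
    return out
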