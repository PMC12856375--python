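"""Synthetic cohort generator emulating the analysis' expected data shape.

Produces balanced AD/CN cohorts in which each participant carries four
co-registered 3-D "correlation map" volumes (values in [-1, 1]) and six
bounded clinical scores. Group structure is injected two ways:

* clinical scores are drawn from per-group truncated normals on each
  measure's plausible raw range (the true raw distributions of the source
  cohort are not published, so these defaults are placeholders);
* AD volumes receive a configurable scalar shift inside an axis-aligned
  signal subregion, on top of smoothed Gaussian voxel noise shared by both
  groups.

A "null" configuration with zero group differences is constructible for
calibration tests. Same spec + seed => bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, stats

from dmnfuse.constants import (
    AD,
    CN,
    DEFAULT_CLINICAL_NAMES,
    DEFAULT_CLINICAL_RANGES,
    DEFAULT_ROI_NAMES,
)
from dmnfuse.cohort_io import Cohort, ParticipantRecord, write_records
from dmnfuse.errors import InvalidSpecError

#: Placeholder per-group (CN, AD) raw means for the default effect. Chosen to
#: point in the clinically expected direction (AD worse), not calibrated.
_DEFAULT_GROUP_MEANS: dict[str, tuple[float, float]] = {
    "ADAS13": (10.0, 30.0),
    "EcogPtTotal": (1.5, 2.5),
    "FAQ": (2.0, 15.0),
    "MoCA": (26.0, 17.0),
    "RAVLT_immediate": (40.0, 22.0),
    "RAVLT_pct_forgetting": (35.0, 75.0),
}

_DEFAULT_SD: dict[str, float] = {
    "ADAS13": 5.0,
    "EcogPtTotal": 0.5,
    "FAQ": 4.0,
    "MoCA": 3.0,
    "RAVLT_immediate": 8.0,
    "RAVLT_pct_forgetting": 18.0,
}


@dataclass(frozen=True)
class CohortSpec:
    """Shape of a synthetic cohort: group size, grid, orderings, seed."""

    n_per_group: int = 26
    grid_size: tuple[int, int, int] = (16, 16, 16)
    roi_names: tuple[str, ...] = DEFAULT_ROI_NAMES
    clinical_names: tuple[str, ...] = DEFAULT_CLINICAL_NAMES
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise InvalidSpecError(f"n_per_group must be >= 1, got {self.n_per_group}")
        if len(self.grid_size) != 3 or any(g < 1 for g in self.grid_size):
            raise InvalidSpecError(f"grid_size must be 3 positive dims, got {self.grid_size}")
        if len(set(self.roi_names)) != len(self.roi_names):
            raise InvalidSpecError("roi_names must be unique")
        if len(set(self.clinical_names)) != len(self.clinical_names):
            raise InvalidSpecError("clinical_names must be unique")


@dataclass(frozen=True)
class EffectConfig:
    """Group-effect parameters for the generator.

    ``clinical_group_means[name] = (cn_mean, ad_mean)`` on the raw scale;
    ``roi_effect[name]`` is a scalar correlation-unit shift added to AD
    volumes inside ``signal_region`` (voxel coordinates, 0-based, half-open:
    ``((z0, z1), (y0, y1), (x0, x1))``).
    """

    clinical_group_means: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_GROUP_MEANS))
    clinical_sd: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_SD))
    clinical_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_RANGES))
    roi_effect: Mapping[str, float] = field(
        default_factory=lambda: {name: 0.15 for name in DEFAULT_ROI_NAMES})
    roi_noise_sd: float = 0.3
    signal_region: tuple[tuple[int, int], ...] = ((4, 10), (4, 10), (4, 10))
    smoothing_sigma: float = 1.0

    @classmethod
    def null(cls, spec: "CohortSpec | None" = None,
             clinical_mean: float = 0.0) -> "EffectConfig":
        """A configuration with zero group differences everywhere.

        Clinical measures collapse to a single shared truncated normal per
        measure; no ROI shift is applied.
        """
        names = spec.clinical_names if spec is not None else DEFAULT_CLINICAL_NAMES
        rois = spec.roi_names if spec is not None else DEFAULT_ROI_NAMES
        ranges = {n: DEFAULT_CLINICAL_RANGES.get(n, (0.0, 1.0)) for n in names}
        means = {n: ((lo + hi) / 2.0,) * 2 for n, (lo, hi) in ranges.items()}
        sds = {n: (hi - lo) / 6.0 for n, (lo, hi) in ranges.items()}
        return cls(clinical_group_means=means, clinical_sd=sds,
                   clinical_ranges=ranges,
                   roi_effect={r: 0.0 for r in rois},
                   signal_region=((0, 1), (0, 1), (0, 1)))

    @classmethod
    def default_for_grid(cls, grid_size: Sequence[int], **overrides) -> "EffectConfig":
        """Default effect with the signal region scaled to the central half
        of ``grid_size`` (the stock region assumes a 16-voxel grid)."""
        region = tuple((g // 4, g // 4 + max(1, g // 2)) for g in grid_size)
        overrides.setdefault("signal_region", region)
        return cls(**overrides)

    def validate(self, spec: CohortSpec) -> None:
        for name in spec.clinical_names:
            if name not in self.clinical_group_means:
                raise InvalidSpecError(f"no group means configured for measure {name!r}")
            sd = self.clinical_sd.get(name, 0.0)
            if not sd > 0:
                raise InvalidSpecError(f"clinical_sd for {name!r} must be > 0, got {sd}")
            lo, hi = self.clinical_ranges.get(name, (-np.inf, np.inf))
            if not hi > lo:
                raise InvalidSpecError(f"range for {name!r} must satisfy hi > lo")
        if not self.roi_noise_sd > 0:
            raise InvalidSpecError("roi_noise_sd must be > 0")
        if len(self.signal_region) != 3:
            raise InvalidSpecError("signal_region must have 3 (start, stop) pairs")
        for (start, stop), size in zip(self.signal_region, spec.grid_size):
            if not (0 <= start < stop <= size):
                raise InvalidSpecError(
                    f"signal_region {self.signal_region} does not fit inside "
                    f"grid {spec.grid_size}")


def _truncnorm_draw(rng: np.random.Generator, mean: float, sd: float,
                    lo: float, hi: float) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _make_volume(rng: np.random.Generator, grid: tuple[int, int, int],
                 noise_sd: float, sigma: float, shift: float,
                 region: tuple[tuple[int, int], ...]) -> np.ndarray:
    vol = rng.normal(0.0, noise_sd, size=grid)
    if sigma > 0:
        vol = ndimage.gaussian_filter(vol, sigma=sigma)
    if shift != 0.0:
        (z0, z1), (y0, y1), (x0, x1) = region
        vol[z0:z1, y0:y1, x0:x1] += shift
    return np.clip(vol, -1.0, 1.0)


def generate_cohort(spec: CohortSpec, effect: EffectConfig) -> Cohort:
    """Generate a balanced synthetic cohort.

    Returns 2 * n_per_group participants (CN first, then AD). AD records get
    ``effect.roi_effect`` added inside ``effect.signal_region`` and clinical
    scores drawn from the AD means. Deterministic for a given spec + seed.
    """
    spec.validate()
    effect.validate(spec)
    rng = np.random.default_rng(spec.seed)
    width = max(3, len(str(2 * spec.n_per_group)))
    records: list[ParticipantRecord] = []
    counter = 0
    for diagnosis in (CN, AD):
        is_ad = diagnosis == AD
        for _ in range(spec.n_per_group):
            counter += 1
            pid = f"sub-{counter:0{width}d}"
            vols = tuple(
                _make_volume(rng, tuple(spec.grid_size), effect.roi_noise_sd,
                             effect.smoothing_sigma,
                             effect.roi_effect.get(roi, 0.0) if is_ad else 0.0,
                             effect.signal_region)
                for roi in spec.roi_names)
            clin = np.array([
                _truncnorm_draw(
                    rng,
                    effect.clinical_group_means[name][1 if is_ad else 0],
                    effect.clinical_sd[name],
                    *effect.clinical_ranges.get(name, (-np.inf, np.inf)))
                for name in spec.clinical_names])
            records.append(ParticipantRecord(pid, diagnosis, vols, clin))
    return Cohort(records, tuple(spec.roi_names), tuple(spec.clinical_names))


def write_cohort(cohort: Cohort, directory: str | Path) -> list[Path]:
    """Write a cohort to a BIDS-like directory; returns the file manifest."""
    return write_records(cohort.records, cohort.roi_names,
                         cohort.clinical_names, directory)
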