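import numpy as np
import pytest

import dmnfuse as dm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def clinical_signal_effect(separation_sd: float = 4.0,
                           informative=("MoCA", "ADAS13")) -> dm.EffectConfig:
    """Effect with clinical-only group signal on the given measures and a
    null imaging effect. Means sit mid-range so truncation bias is tiny."""
    names = dm.DEFAULT_CLINICAL_NAMES
    sds = {n: 3.0 for n in names}
    means = {n: (15.0, 15.0) for n in names}
    half = separation_sd * 3.0 / 2.0
    for i, n in enumerate(informative):
        sign = -1 if i % 2 else 1
        means[n] = (15.0 + sign * half, 15.0 - sign * half)
    return dm.EffectConfig(
        clinical_group_means=means,
        clinical_sd=sds,
        clinical_ranges={n: (0.0, 40.0) for n in names},
        roi_effect={r: 0.0 for r in dm.DEFAULT_ROI_NAMES},
        signal_region=((0, 1), (0, 1), (0, 1)),
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """2 + 2 participants on an 8^3 grid: the smallest trainable cohort."""
    spec = dm.CohortSpec(n_per_group=2, grid_size=(8, 8, 8), seed=11)
    return dm.generate_cohort(spec, clinical_signal_effect())


@pytest.fixture(scope="session")
def small_cohort():
    """4 + 4 participants on an 8^3 grid with strong clinical signal."""
    spec = dm.CohortSpec(n_per_group=4, grid_size=(8, 8, 8), seed=21)
    return dm.generate_cohort(spec, clinical_signal_effect())


@pytest.fixture(scope="session")
def default_cohort():
    """26 + 26 participants at the default 16^3 grid and default effect."""
    spec = dm.CohortSpec(seed=5)
    return dm.generate_cohort(spec, dm.EffectConfig())
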