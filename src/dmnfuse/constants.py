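"""Frozen orderings and label conventions shared across the pipeline.

The ROI and clinical orderings are constants so that channel indices and
feature indices used by the perturbation ranking are stable across runs.
"""

#: Ordered ROI identifiers: posterior cingulate, left/right lateral parietal,
#: medial prefrontal. Channel i of every image stack is DEFAULT_ROI_NAMES[i].
DEFAULT_ROI_NAMES: tuple[str, ...] = ("PCC", "LatParLeft", "LatParRight", "MPFC")

#: Ordered clinical measure identifiers; position i of every clinical vector
#: is DEFAULT_CLINICAL_NAMES[i].
DEFAULT_CLINICAL_NAMES: tuple[str, ...] = (
    "ADAS13",
    "EcogPtTotal",
    "FAQ",
    "MoCA",
    "RAVLT_immediate",
    "RAVLT_pct_forgetting",
)

AD = "AD"
CN = "CN"

#: AD is the positive class (label 1); CN the negative class (label 0).
DIAGNOSIS_CODES: dict[str, int] = {CN: 0, AD: 1}

#: Plausible raw score ranges used by the synthetic generator's truncated
#: normals and available as clipping bounds. Not calibrated to any cohort.
DEFAULT_CLINICAL_RANGES: dict[str, tuple[float, float]] = {
    "ADAS13": (0.0, 85.0),
    "EcogPtTotal": (1.0, 4.0),
    "FAQ": (0.0, 30.0),
    "MoCA": (0.0, 30.0),
    "RAVLT_immediate": (0.0, 75.0),
    "RAVLT_pct_forgetting": (-10.0, 110.0),
}
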