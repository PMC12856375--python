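# dmnfuse

Explainable multimodal classification of Alzheimer's disease (AD) versus
cognitively normal (CN) participants from default-mode-network (DMN) ROI
connectivity volumes fused with clinical scores.

The pipeline:

1. **Cohort** — each participant carries four co-registered 3-D ROI
   correlation volumes (posterior cingulate, left/right lateral parietal,
   medial prefrontal) and six clinical measures (ADAS13, EcogPtTotal, FAQ,
   MoCA, RAVLT immediate, RAVLT % forgetting). Cohorts are read from a
   BIDS-like directory (NIfTI volumes + `participants.tsv`) or generated by
   the built-in synthetic cohort generator.
2. **Model** — a 3-D CNN feature extractor (six conv layers, max pooling,
   global max pool to a 64-value feature vector) whose output is
   concatenated with the six min-max-normalized clinical scores and passed
   to a linear head (70→32→1, batch norm + dropout, sigmoid). A unimodal
   variant drops the clinical inputs (64→32→1) but shares the extractor
   layout.
3. **Evaluation** — strict leave-one-out cross-validation with per-fold
   seeded RNG substreams, augmentation (random flips / 90° rotations) on
   training images only, Adam + binary cross-entropy, and a full metric
   suite (accuracy, sensitivity, specificity, precision, F1, MCC).
4. **Explanation** — perturbation feature ranking: each of the 10 input
   features (4 ROI channels + 6 clinical scores) is randomized on the
   held-out participant of every fold; errors are averaged per diagnosis
   group, ranked, and normalized so each group's top feature has importance
   exactly 1.0. Rank change = CN rank − AD rank.

The network is implemented in pure NumPy (`dmnfuse.nn`), including
reverse-mode gradients verified against finite differences in the test
suite; no deep-learning framework is required.

## CLI

```sh
dmnfuse simulate --out cohort/ --n-per-group 26 --grid 16 --seed 1
dmnfuse run --cohort-dir cohort/ --out results/ --mode both --seed 1
dmnfuse run --out results/ --scale test --seed 1      # tiny synthetic smoke run
dmnfuse report results/                               # formatted tables
dmnfuse rank results/                                 # importance + rank changes
dmnfuse compare results/                              # multimodal − unimodal accuracy
```

`run` persists per-fold tables (TSV), metrics (JSON), the importance table,
rank changes, and a `summary.json`; every rendered number is re-derivable
from the persisted fold tables. A YAML pipeline config can be supplied via
`--config` (see `dmnfuse.reporting.PipelineConfig`).

## Notes

- Diagnosis coding: AD = 1 (positive class), CN = 0.
- Default synthetic grids are 16³ for speed; the 91×91×91 resize target is
  available via `dmnfuse.resize` / `TrainConfig.resize_to`.
- Min-max normalization is fitted on the full cohort by default (documented
  leakage caveat); `TrainConfig(per_fold_normalization=True)` refits on each
  fold's training set.
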