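"""Result persistence and human-readable report rendering.

Every number in a rendered report is re-derived from the persisted fold and
perturbation tables; this layer does no statistics of its own beyond
rounding (percentages and rates to 2 dp, importances to 3 dp).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from dmnfuse.cnn_model import ModelConfig
from dmnfuse.errors import EmptyCohortError
from dmnfuse.loocv_training import (
    FoldOutcome,
    MetricsReport,
    TrainConfig,
    compute_metrics,
    confusion_matrix,
)
from dmnfuse.perturbation_ranking import (
    ImportanceTable,
    RankChange,
    aggregate_importance,
    importance_from_errors,
    rank_change,
)

FOLD_COLUMNS = ["held_out_id", "group", "true_label", "predicted_prob",
                "predicted_label", "baseline_error", "n_train"]
PERTURB_COLUMNS = ["held_out_id", "group", "feature", "error"]


def format_percent(x: float) -> str:
    return f"{x:.2f}%"


def format_rate(x: float) -> str:
    return f"{x:.2f}"


def format_importance(x: float) -> str:
    return f"{x:.3f}"


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def fold_table_path(results_dir: Path, mode: str) -> Path:
    return Path(results_dir) / f"fold_table_{mode}.tsv"


def perturb_table_path(results_dir: Path, mode: str) -> Path:
    return Path(results_dir) / f"perturbation_{mode}.tsv"


def append_fold(results_dir: Path, mode: str, outcome: FoldOutcome) -> None:
    """Flush one fold's results to disk (supports resumable runs)."""
    results_dir = Path(results_dir)
    results_dir.mkdir(parents=True, exist_ok=True)
    fpath = fold_table_path(results_dir, mode)
    header = not fpath.exists()
    row = pd.DataFrame([[outcome.held_out_id, outcome.group, outcome.true_label,
                         repr(outcome.predicted_prob), outcome.predicted_label,
                         repr(outcome.baseline_error), outcome.n_train]],
                       columns=FOLD_COLUMNS)
    row.to_csv(fpath, sep="\t", index=False, mode="a", header=header)
    if outcome.perturbation_errors:
        ppath = perturb_table_path(results_dir, mode)
        pheader = not ppath.exists()
        rows = pd.DataFrame(
            [[outcome.held_out_id, outcome.group, feat, repr(err)]
             for feat, err in outcome.perturbation_errors.items()],
            columns=PERTURB_COLUMNS)
        rows.to_csv(ppath, sep="\t", index=False, mode="a", header=pheader)


def load_fold_outcomes(results_dir: Path, mode: str) -> list[FoldOutcome]:
    """Rebuild fold outcomes from the persisted tables."""
    results_dir = Path(results_dir)
    fpath = fold_table_path(results_dir, mode)
    if not fpath.is_file():
        raise EmptyCohortError(f"no fold table for mode {mode!r} in {results_dir}")
    table = pd.read_csv(fpath, sep="\t", dtype={"held_out_id": str})
    perturb: dict[str, dict[str, float]] = {}
    ppath = perturb_table_path(results_dir, mode)
    if ppath.is_file():
        ptable = pd.read_csv(ppath, sep="\t", dtype={"held_out_id": str})
        for row in ptable.itertuples(index=False):
            perturb.setdefault(row.held_out_id, {})[row.feature] = float(row.error)
    return [FoldOutcome(held_out_id=row.held_out_id, group=row.group,
                        true_label=int(row.true_label),
                        predicted_prob=float(row.predicted_prob),
                        predicted_label=int(row.predicted_label),
                        baseline_error=float(row.baseline_error),
                        perturbation_errors=perturb.get(row.held_out_id, {}),
                        n_train=int(row.n_train))
            for row in table.itertuples(index=False)]


def write_importance_table(table: ImportanceTable, path: Path) -> None:
    rows = []
    for group, gi in sorted(table.groups.items()):
        for name in sorted(gi.rank, key=gi.rank.get):
            rows.append({"group": group, "rank": gi.rank[name], "feature": name,
                         "mean_error": repr(gi.mean_error[name]),
                         "importance": repr(gi.importance[name])})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_rank_changes(changes: Sequence[RankChange], path: Path) -> None:
    rows = [{"feature": c.feature, "cn_rank": c.cn_rank, "ad_rank": c.ad_rank,
             "change": c.change} for c in changes]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_metrics(report: MetricsReport, path: Path) -> None:
    Path(path).write_text(json.dumps(report.as_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_confusion(report: MetricsReport) -> str:
    return ("            pred AD  pred CN\n"
            f"true AD     {report.tp:7d}  {report.fn:7d}\n"
            f"true CN     {report.fp:7d}  {report.tn:7d}")


def render_metrics(report: MetricsReport) -> str:
    lines = [
        f"accuracy     {format_percent(report.accuracy_pct)}",
        f"sensitivity  {format_rate(report.sensitivity)}",
        f"specificity  {format_rate(report.specificity)}",
        f"precision    {format_rate(report.precision)}",
        f"F1           {format_rate(report.f1)}",
        f"MCC          {format_rate(report.mcc)}",
    ]
    return "\n".join(lines)


def render_importance(table: ImportanceTable) -> str:
    lines = ["group  rank  feature                 mean_error  importance"]
    for group, gi in sorted(table.groups.items()):
        for name in sorted(gi.rank, key=gi.rank.get):
            lines.append(f"{group:<5}  {gi.rank[name]:>4}  {name:<22}  "
                         f"{gi.mean_error[name]:>10.3f}  "
                         f"{format_importance(gi.importance[name]):>10}")
    return "\n".join(lines)


def render_rank_changes(changes: Sequence[RankChange]) -> str:
    lines = ["feature                 cn_rank  ad_rank  change"]
    for c in changes:
        lines.append(f"{c.feature:<22}  {c.cn_rank:>7}  {c.ad_rank:>7}  {c.change:>+6d}")
    return "\n".join(lines)


def summarize_mode(outcomes: list[FoldOutcome]) -> MetricsReport:
    return compute_metrics(*confusion_matrix(outcomes))


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


@dataclass
class SyntheticSpec:
    n_per_group: int = 26
    grid_size: tuple[int, int, int] = (16, 16, 16)
    seed: int = 0
    effect: str = "default"  # "default" or "null"


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; YAML round-trippable."""

    seed: int = 0
    output_dir: str = "results"
    mode: str = "both"  # multimodal | unimodal | both
    cohort_dir: str | None = None
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def to_yaml(self, path: Path) -> None:
        doc = _listify(dataclasses.asdict(self))
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        synthetic = doc.pop("synthetic", {})
        model = doc.pop("model", {})
        train = doc.pop("train", {})
        if "grid_size" in synthetic:
            synthetic["grid_size"] = tuple(synthetic["grid_size"])
        for key in ("conv_channels", "conv_kernels"):
            if key in model:
                model[key] = tuple(model[key])
        if train.get("resize_to") is not None:
            train["resize_to"] = tuple(train["resize_to"])
        return cls(synthetic=SyntheticSpec(**synthetic),
                   model=ModelConfig(**model), train=TrainConfig(**train), **doc)
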