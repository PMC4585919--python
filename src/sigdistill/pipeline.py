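"""Orchestration: panel scoring, panel comparison reports, and the end-to-end run.

The comparison harness scores several gene panels on the same expression
matrix under identical clustering settings (standardization, average
linkage, dendrogram cut at the number of ground-truth subtypes) so that
their F-values and Rand indices are directly comparable — the typical use is
diff-genes vs. the distilled signature vs. external reference panels.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import io
from .clustering import average_linkage, cut, euclidean_distances, standardize
from .metrics import ValidationScore, score_partitions
from .panels import GenePanel, panel_overlap, union_panels
from .partition import Partition
from .select import SelectionResult, select_signature
from .simulate import SimulationConfig, simulate_layer, truth_panels

logger = logging.getLogger("sigdistill")

__all__ = [
    "ComparisonReport",
    "ReportRow",
    "RunConfig",
    "evaluate_panel",
    "compare_panels",
    "run_pipeline",
]


@dataclass(frozen=True)
class ReportRow:
    dataset: str
    panel: str
    dimension: int  # panel genes actually present in the matrix
    f_value: float | None
    rand: float | None
    error: str | None = None


@dataclass(frozen=True)
class ComparisonReport:
    rows: tuple[ReportRow, ...]
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "dataset": r.dataset,
                    "panel": r.panel,
                    "dimension": r.dimension,
                    "f_value": r.f_value,
                    "rand": r.rand,
                    "error": r.error or "",
                }
                for r in self.rows
            ]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")

    def write_json(self, path: str | Path) -> None:
        payload = {
            "metadata": self.metadata,
            "rows": self.to_frame().to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def evaluate_panel(
    expr: pd.DataFrame,
    labels: pd.Series,
    panel: GenePanel,
    *,
    standardize_genes: bool = True,
) -> ValidationScore:
    """Cluster samples on a panel's genes and score against the subtype labels.

    Panel genes absent from the matrix are dropped with a logged warning (a
    fixed panel applied across platforms rarely has full coverage); fewer
    than 2 usable genes or subtypes is an error.
    """
    io.check_labels_cover(expr, labels)
    usable = panel.restrict_to(expr.index)
    n_dropped = len(panel) - len(usable)
    if n_dropped:
        logger.warning(
            "panel %r: dropped %d/%d genes absent from the matrix",
            panel.name, n_dropped, len(panel),
        )
    if len(usable) < 2:
        raise ValueError(
            f"panel {panel.name!r} has {len(usable)} usable genes; need at least 2"
        )
    n_subtypes = labels.nunique()
    if n_subtypes < 2:
        raise ValueError(f"need at least 2 subtype labels, got {n_subtypes}")
    # sorted row order makes the score numerically independent of panel order
    sub = expr.loc[sorted(usable), list(labels.index)]
    if standardize_genes:
        sub = standardize(sub)
    clustered = cut(average_linkage(euclidean_distances(sub, axis="samples")), n_subtypes)
    return score_partitions(Partition.from_labels(labels), clustered)


def compare_panels(
    expr: pd.DataFrame,
    labels: pd.Series,
    panels: Mapping[str, GenePanel],
    *,
    dataset: str = "dataset",
    standardize_genes: bool = True,
    metadata: dict | None = None,
) -> ComparisonReport:
    """Score each named panel under identical clustering settings.

    A panel that cannot be evaluated yields a row flagged with the error
    message instead of aborting the whole report.
    """
    rows = []
    for name, panel in panels.items():
        dimension = len(panel.restrict_to(expr.index))
        try:
            score = evaluate_panel(
                expr, labels, panel, standardize_genes=standardize_genes
            )
            rows.append(ReportRow(dataset, name, dimension, score.f_value, score.rand))
        except (ValueError, KeyError) as exc:
            logger.warning("panel %r failed: %s", name, exc)
            rows.append(ReportRow(dataset, name, dimension, None, None, error=str(exc)))
    return ComparisonReport(tuple(rows), metadata=dict(metadata or {}))


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``simulate`` (a :class:`SimulationConfig`) or the three input
    paths (``expression``, ``labels``, ``panels``) must be given.
    """

    out_dir: str
    seed: int = 0
    simulate: SimulationConfig | None = None
    expression: str | None = None
    labels: str | None = None
    panels: tuple[str, ...] = ()
    k_grid: tuple[float, ...] | None = None  # None -> automatic grid
    standardize: bool = True
    dataset_name: str = "synthetic"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = SimulationConfig(**{**sim, "seed": raw.get("seed", sim.get("seed", 0))})
        k_grid = raw.pop("k_grid", None)
        if isinstance(k_grid, str) and k_grid == "auto":
            k_grid = None
        return cls(
            simulate=sim,
            k_grid=tuple(k_grid) if k_grid else None,
            panels=tuple(raw.pop("panels", ())),
            **raw,
        )

    def digest(self) -> str:
        payload = {
            "out_dir": "",  # output location must not affect results
            "seed": self.seed,
            "simulate": None if self.simulate is None else {
                k: getattr(self.simulate, k)
                for k in (
                    "n_subtypes", "samples_per_subtype", "blocks_per_subtype",
                    "block_size", "effect_size", "within_block_correlation",
                    "n_noise_genes", "noise_sd", "layer_name", "seed", "subtype_names",
                )
            },
            "expression": self.expression,
            "labels": self.labels,
            "panels": self.panels,
            "k_grid": self.k_grid,
            "standardize": self.standardize,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _write_selection(result: SelectionResult, out: Path, tag: str) -> None:
    result.signature.write(out / f"signature_{tag}.txt")
    (out / f"selection_{tag}.json").write_text(
        json.dumps(result.as_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    trace = pd.DataFrame(
        [
            {"class": p.class_label or "", "K": p.K,
             "signature_size": p.signature_size, "f_value": p.f_value}
            for p in result.sweep_trace
        ]
    )
    trace.to_csv(out / f"sweep_trace_{tag}.tsv", sep="\t", index=False, lineterminator="\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all artifacts to ``config.out_dir``.

    Stages: (optionally) simulate a labeled layer; distill the signature in
    both pooled and per-subtype modes; compare the signatures against the
    input candidate panels; report the overlap between the two signatures.
    Reruns with an identical config reproduce identical artifacts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"seed={config.seed}", f"config_digest={config.digest()}"]

    if config.simulate is not None:
        expr, labels, truth = simulate_layer(config.simulate)
        panels = truth_panels(truth)
        io.write_expression(expr, out / "expression.tsv")
        io.write_labels(labels, out / "labels.tsv")
        (out / "truth.json").write_text(
            json.dumps(truth.as_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        log_lines.append("stage=simulate ok")
    else:
        if not (config.expression and config.labels and config.panels):
            raise ValueError(
                "config needs either a 'simulate' block or expression+labels+panels paths"
            )
        expr = io.read_expression(config.expression)
        labels = io.read_labels(config.labels)
        panels = {}
        for p in config.panels:
            panel = GenePanel.read(p)
            panels[panel.name] = panel
        log_lines.append("stage=load ok")
    io.check_labels_cover(expr, labels)

    pooled_input = union_panels(panels.values(), name="diff-genes")
    pooled = select_signature(expr, labels, panels, mode="pooled", K_grid=config.k_grid)
    log_lines.append(
        f"stage=select_pooled ok chosen_K={pooled.chosen_K} "
        f"size={len(pooled.signature)} f={pooled.score.f_value:.4f}"
    )
    _write_selection(pooled, out, "pooled")

    per_subtype: SelectionResult | None = None
    if set(labels.unique()) <= set(panels):
        per_subtype = select_signature(
            expr, labels, panels, mode="per_subtype", K_grid=config.k_grid
        )
        log_lines.append(
            f"stage=select_per_subtype ok size={len(per_subtype.signature)} "
            f"f={per_subtype.score.f_value:.4f}"
        )
        _write_selection(per_subtype, out, "per_subtype")
    else:
        log_lines.append("stage=select_per_subtype skipped (panels do not match subtype labels)")

    compare: dict[str, GenePanel] = {pooled_input.name: pooled_input}
    compare.update({f"diff-genes[{k}]": v for k, v in panels.items()})
    compare["signature(pooled)"] = pooled.signature
    if per_subtype is not None:
        compare["signature(per-subtype)"] = per_subtype.signature
    report = compare_panels(
        expr,
        labels,
        compare,
        dataset=config.dataset_name,
        standardize_genes=config.standardize,
        metadata={"seed": config.seed, "config_digest": config.digest()},
    )
    report.write_tsv(out / "comparison.tsv")
    report.write_json(out / "comparison.json")
    log_lines.append("stage=compare ok")

    overlap_info: dict = {}
    if per_subtype is not None:
        shared = panel_overlap(pooled.signature, per_subtype.signature)
        overlap_info = {
            "pooled_size": len(pooled.signature),
            "per_subtype_size": len(per_subtype.signature),
            "overlap_size": len(shared),
            "overlap_genes": list(shared),
        }
        (out / "overlap.json").write_text(
            json.dumps(overlap_info, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        log_lines.append("stage=overlap ok")

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return {
        "pooled": pooled,
        "per_subtype": per_subtype,
        "report": report,
        "overlap": overlap_info,
        "expression": expr,
        "labels": labels,
        "panels": panels,
    }
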