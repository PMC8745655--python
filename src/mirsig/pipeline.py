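"""Pipeline orchestration: configuration, stage ordering, result bundle.

Stages run in a fixed order (simulate/load -> normalize -> diffexpr ->
select -> integrate); each can be toggled. All outputs land in the
configured output directory and are re-readable by the package's own
readers. A stage failure removes any partial outputs and re-raises with a
stage-tagged message.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diffexpr, io, normalization, selection, synthetic
from .integration import (
    DEFAULT_GO_KEYWORDS,
    aggregate_targets,
    export_network,
    filter_by_go,
    pairs_to_frame,
    select_inverse_pairs,
)
from .selection import Thresholds

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, round-trippable through YAML."""

    out_dir: str = "mirsig-out"
    seed: int = 0

    # stage toggles
    simulate: bool = False
    normalize: bool = False
    diffexpr: bool = True
    select: bool = True
    integrate: bool = False

    # inputs (ignored where a stage is simulated/disabled)
    expression_path: str | None = None
    wide_table_path: str | None = None  # precomputed fold/padj table (skips diffexpr)
    use_table1_fixture: bool = False
    target_paths: dict[str, str] = field(default_factory=dict)  # source -> path
    gene_de_path: str | None = None
    go_path: str | None = None

    # parameters
    fold_cut: float = 5.0
    fold_cut_single: float = 10.0
    alpha: float = 0.05
    go_keywords: tuple[str, ...] = DEFAULT_GO_KEYWORDS
    n_features: int = 200
    n_planted: int = 20
    planted_fold: float = 10.0
    noise_sd: float = 0.25
    n_replicates: int = 4
    decoy_rate: float = 0.0

    @property
    def thresholds(self) -> Thresholds:
        return Thresholds(
            fold_cut=self.fold_cut,
            fold_cut_single=self.fold_cut_single,
            alpha=self.alpha,
        )

    def to_yaml(self, path) -> Path:
        path = Path(path)
        data = dataclasses.asdict(self)
        data["go_keywords"] = list(self.go_keywords)
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "go_keywords" in data:
            data["go_keywords"] = tuple(data["go_keywords"])
        return cls(**data)


@dataclass
class PipelineResult:
    summary: dict
    selection: selection.SelectionResult | None
    pairs: list
    files: list[Path]


def _check_inputs(config: PipelineConfig) -> None:
    paths = [config.expression_path, config.wide_table_path, config.gene_de_path, config.go_path]
    paths += list(config.target_paths.values())
    missing = [p for p in paths if p is not None and not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    _check_inputs(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_path = out_dir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("mirsig")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage = "setup"
    try:
        summary: dict = {"seed": config.seed}
        thresholds = config.thresholds
        logger.info(
            "thresholds: fold_cut=%s fold_cut_single=%s alpha=%s (strict_fold=%s strict_alpha=%s)",
            thresholds.fold_cut,
            thresholds.fold_cut_single,
            thresholds.alpha,
            thresholds.strict_fold,
            thresholds.strict_alpha,
        )

        truth = None
        resources = None
        matrix = None
        wide = None

        stage = "simulate"
        if config.simulate:
            sim_config = synthetic.two_line_signature_config(
                n_features=config.n_features,
                n_planted=config.n_planted,
                fold=config.planted_fold,
                noise_sd=config.noise_sd,
                n_replicates=config.n_replicates,
                seed=config.seed,
            )
            matrix, truth = synthetic.simulate_expression(sim_config)
            resources = synthetic.simulate_target_resources(
                truth, sim_config, decoy_rate=config.decoy_rate, fold_cut=config.fold_cut
            )
            written.append(io.write_expression_matrix(matrix, out_dir / "expression.tsv"))
        elif config.expression_path:
            matrix = io.read_expression_matrix(config.expression_path)

        stage = "normalize"
        if config.normalize and matrix is not None:
            matrix = normalization.quantile_normalize(matrix)
            written.append(io.write_expression_matrix(matrix, out_dir / "normalized.tsv"))

        stage = "diffexpr"
        contrasts = None
        if config.use_table1_fixture:
            wide = io.load_table1_fixture()
        elif config.wide_table_path:
            wide = io.read_wide_fold_table(config.wide_table_path)
        elif config.diffexpr and matrix is not None:
            contrasts = diffexpr.run_all_contrasts(matrix)
            for line, table in contrasts.items():
                written.append(io.write_contrast_table(table, out_dir / f"contrast_{line}.tsv"))
            wide = diffexpr.contrasts_to_wide(contrasts)
            written.append(io.write_wide_fold_table(wide, out_dir / "fold_table.tsv"))

        stage = "select"
        sel = None
        if config.select:
            if wide is None:
                raise ValueError("selection requested but no fold/padj table available")
            fold_cols = [c for c in wide.columns if c.startswith(("fold_", "padj_"))]
            sel = selection.apply_two_tier_selection(wide[fold_cols], thresholds)
            sel_out = sel.table.copy()
            sel_out.to_csv(out_dir / "selection.tsv", sep="\t")
            written.append(out_dir / "selection.tsv")
            sel.calls.to_csv(out_dir / "calls.tsv", sep="\t")
            written.append(out_dir / "calls.tsv")
            summary["selection"] = selection.selection_summary(sel)

        stage = "integrate"
        pairs: list = []
        if config.integrate:
            if resources is not None:
                db = aggregate_targets(
                    (src, grp.drop(columns=["source"]))
                    for src, grp in resources.targets.groupby("source")
                )
                gene_de = resources.mrna_de
                go = resources.go
            else:
                db = aggregate_targets(
                    (src, io.read_target_table(path))
                    for src, path in sorted(config.target_paths.items())
                )
                gene_de = io.read_long_de_table(config.gene_de_path)
                go = io.read_go_annotations(config.go_path) if config.go_path else None
            if contrasts is not None:
                mir_de = diffexpr.contrasts_to_long(contrasts)
            elif wide is not None:
                frames = []
                for col in wide.columns:
                    if col.startswith("fold_"):
                        line = col[len("fold_") :]
                        frames.append(
                            pd.DataFrame(
                                {
                                    "cell_line": line,
                                    "feature": wide.index,
                                    "signed_fold": wide[col].to_numpy(),
                                    "p_adj": wide[f"padj_{line}"].to_numpy(),
                                }
                            )
                        )
                mir_de = pd.concat(frames, ignore_index=True)
            else:
                raise ValueError("integration requested but no miRNA DE results available")
            pairs = select_inverse_pairs(mir_de, gene_de, db, thresholds)
            if go is not None:
                pairs = filter_by_go(pairs, go, config.go_keywords)
            written.append(export_network(pairs, out_dir / "pairs.tsv", fmt="tsv"))
            if pairs:
                written.append(export_network(pairs, out_dir / "network.sif", fmt="sif"))
                written.append(export_network(pairs, out_dir / "network.graphml", fmt="graphml"))
            summary["integration"] = {
                "n_pairs": len(pairs),
                "n_edges_db": len(db),
                "per_line": pairs_to_frame(pairs).groupby("cell_line").size().to_dict()
                if pairs
                else {},
            }

        stage = "recovery"
        if truth is not None and sel is not None:
            metrics = synthetic.evaluate_recovery(sel, pairs, truth)
            summary["recovery"] = {
                "sensitivity": metrics.sensitivity,
                "fdp": metrics.fdp,
                "pair_sensitivity": metrics.pair_sensitivity,
                "pair_fdp": metrics.pair_fdp,
                "tier_counts": metrics.tier_counts,
            }

        stage = "summary"
        summary_path = out_dir / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        written.append(summary_path)
        return PipelineResult(summary=summary, selection=sel, pairs=pairs, files=written)
    except Exception as exc:
        for path in written:
            Path(path).unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
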