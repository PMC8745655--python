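"""Cross-omics integration: target aggregation, inverse-pair retention,
GO-keyword subsetting, and network export.

Target edges from multiple prediction/validation databases are unioned with
per-edge provenance. A miRNA-gene pair is retained, within one cell line,
when the edge exists, both members pass the fold and adjusted-p cut-offs,
and their signed folds have opposite signs. Retained pairs can then be
restricted to genes annotated with a configurable Gene Ontology keyword
list and exported as Cytoscape-importable networks.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import pandas as pd

from .selection import Thresholds

__all__ = [
    "PREDICTED_SOURCES",
    "VALIDATED_SOURCES",
    "KNOWN_SOURCES",
    "DEFAULT_GO_KEYWORDS",
    "TargetDB",
    "PairRecord",
    "aggregate_targets",
    "select_inverse_pairs",
    "filter_by_go",
    "export_network",
    "read_pairs_tsv",
    "pairs_to_frame",
]

logger = logging.getLogger(__name__)

PREDICTED_SOURCES = ("DIANA", "Miranda", "PicTar", "TargetScan")
VALIDATED_SOURCES = ("miRTAR", "miRwalk")
KNOWN_SOURCES = PREDICTED_SOURCES + VALIDATED_SOURCES

# Union of the two keyword lists used for target-gene subsetting.
DEFAULT_GO_KEYWORDS = (
    "collagen-containing extracellular matrix",
    "extracellular matrix",
    "extracellular space",
    "response to drug",
    "drug transport",
    "stem cell",
)


@dataclass
class TargetDB:
    """miRNA -> gene edges with per-edge source provenance."""

    edges: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    validated_sources: frozenset[str] = frozenset(VALIDATED_SOURCES)

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, edge: tuple[str, str]) -> bool:
        return edge in self.edges

    def sources(self, mirna: str, gene: str) -> frozenset[str]:
        return self.edges[(mirna, gene)]

    def is_validated(self, mirna: str, gene: str) -> bool:
        return bool(self.edges[(mirna, gene)] & self.validated_sources)

    def targets_of(self, mirna: str) -> list[str]:
        return sorted(g for (m, g) in self.edges if m == mirna)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "mirna": m,
                "gene": g,
                "sources": "|".join(sorted(src)),
                "validated": bool(src & self.validated_sources),
            }
            for (m, g), src in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["mirna", "gene", "sources", "validated"])


def aggregate_targets(
    source_tables,
    known_sources: tuple[str, ...] = KNOWN_SOURCES,
    validated_sources: tuple[str, ...] = VALIDATED_SOURCES,
) -> TargetDB:
    """Union edge tables from several databases into one :class:`TargetDB`.

    ``source_tables`` is an iterable of ``(source name, DataFrame)`` where
    each frame has ``mirna`` and ``gene`` columns. Provenance is the union
    of contributing sources per edge; malformed rows (missing miRNA or
    gene) are dropped with a logged count.
    """
    edges: dict[tuple[str, str], set[str]] = {}
    n_rejected = 0
    for source, table in source_tables:
        if source not in known_sources:
            raise ValueError(f"unrecognized target source: {source!r}")
        for _, row in table.iterrows():
            mirna, gene = row.get("mirna"), row.get("gene")
            if not isinstance(mirna, str) or not isinstance(gene, str) or not mirna or not gene:
                n_rejected += 1
                continue
            edges.setdefault((mirna, gene), set()).add(source)
    if n_rejected:
        logger.warning("aggregate_targets: rejected %d malformed edge rows", n_rejected)
    return TargetDB(
        edges={e: frozenset(s) for e, s in edges.items()},
        validated_sources=frozenset(validated_sources),
    )


@dataclass(frozen=True)
class PairRecord:
    """One retained miRNA-target pair within a single cell line."""

    mirna: str
    gene: str
    cell_line: str
    mir_fold: float
    mir_p_adj: float
    gene_fold: float
    gene_p_adj: float
    sources: frozenset[str] = frozenset()
    matched_go_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.mir_fold * self.gene_fold >= 0:
            raise ValueError("pair folds must have opposite signs")


def _check_long(table: pd.DataFrame, kind: str) -> None:
    required = {"cell_line", "feature", "signed_fold", "p_adj"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{kind} table missing columns: {sorted(missing)}")


def select_inverse_pairs(
    mir_de: pd.DataFrame,
    gene_de: pd.DataFrame,
    db: TargetDB,
    thresholds: Thresholds = Thresholds(),
) -> list[PairRecord]:
    """Retain inverse, doubly-significant miRNA-target pairs per cell line.

    Both tables are long-format with columns ``cell_line``, ``feature``,
    ``signed_fold``, ``p_adj``. A pair (miRNA, gene, line) is emitted when
    the edge is in ``db``, both folds exceed the cut-off in magnitude with
    adjusted p below alpha in that line, and the fold signs are opposite.
    Gene observations below the cut-off count as not significant and
    suppress the pair.
    """
    _check_long(mir_de, "miRNA DE")
    _check_long(gene_de, "gene DE")
    gene_lookup = {
        (row.cell_line, row.feature): (row.signed_fold, row.p_adj)
        for row in gene_de.itertuples()
    }
    pairs: list[PairRecord] = []
    n_no_edge = 0
    for row in mir_de.itertuples():
        if not (
            thresholds._passes_fold(abs(row.signed_fold), thresholds.fold_cut)
            and thresholds._passes_alpha(row.p_adj)
        ):
            continue
        genes = db.targets_of(row.feature)
        if not genes:
            n_no_edge += 1
            continue
        for gene in genes:
            obs = gene_lookup.get((row.cell_line, gene))
            if obs is None:
                continue
            gene_fold, gene_p = obs
            if not (
                thresholds._passes_fold(abs(gene_fold), thresholds.fold_cut)
                and thresholds._passes_alpha(gene_p)
            ):
                continue
            if row.signed_fold * gene_fold >= 0:
                continue
            pairs.append(
                PairRecord(
                    mirna=row.feature,
                    gene=gene,
                    cell_line=row.cell_line,
                    mir_fold=float(row.signed_fold),
                    mir_p_adj=float(row.p_adj),
                    gene_fold=float(gene_fold),
                    gene_p_adj=float(gene_p),
                    sources=db.sources(row.feature, gene),
                )
            )
    if n_no_edge:
        logger.info(
            "select_inverse_pairs: %d significant miRNA observations had no edges in the target database",
            n_no_edge,
        )
    return pairs


def filter_by_go(
    pairs: list[PairRecord],
    annotations: dict[str, set[str]] | pd.DataFrame,
    keywords=DEFAULT_GO_KEYWORDS,
) -> list[PairRecord]:
    """Keep pairs whose gene carries at least one of the GO keywords.

    Matching is by case-insensitive exact term name. ``annotations`` maps
    gene -> set of term names, or is a (gene, term) DataFrame. Unannotated
    genes are non-matching (logged count).
    """
    if not len(tuple(keywords)):
        raise ValueError("keyword list must be non-empty")
    if isinstance(annotations, pd.DataFrame):
        mapping: dict[str, set[str]] = {}
        for row in annotations.itertuples():
            mapping.setdefault(row.gene, set()).add(row.term)
        annotations = mapping
    norm = {g: {t.strip().lower() for t in terms} for g, terms in annotations.items()}
    kw = {k.strip().lower() for k in keywords}
    kept: list[PairRecord] = []
    n_unannotated = 0
    for pair in pairs:
        terms = norm.get(pair.gene)
        if terms is None:
            n_unannotated += 1
            continue
        matched = terms & kw
        if matched:
            kept.append(replace(pair, matched_go_terms=frozenset(matched)))
    if n_unannotated:
        logger.info("filter_by_go: %d pairs had genes with no GO annotation", n_unannotated)
    return kept


_PAIR_COLUMNS = [
    "mirna",
    "gene",
    "cell_line",
    "mir_fold",
    "mir_p_adj",
    "gene_fold",
    "gene_p_adj",
    "sources",
    "matched_go_terms",
]


def pairs_to_frame(pairs: list[PairRecord]) -> pd.DataFrame:
    rows = [
        {
            "mirna": p.mirna,
            "gene": p.gene,
            "cell_line": p.cell_line,
            "mir_fold": repr(p.mir_fold),
            "mir_p_adj": repr(p.mir_p_adj),
            "gene_fold": repr(p.gene_fold),
            "gene_p_adj": repr(p.gene_p_adj),
            "sources": "|".join(sorted(p.sources)),
            "matched_go_terms": "|".join(sorted(p.matched_go_terms)),
        }
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=_PAIR_COLUMNS)


def read_pairs_tsv(path) -> list[PairRecord]:
    """Read back a pair table written by :func:`export_network` (TSV)."""
    pairs = []
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            pairs.append(
                PairRecord(
                    mirna=row["mirna"],
                    gene=row["gene"],
                    cell_line=row["cell_line"],
                    mir_fold=float(row["mir_fold"]),
                    mir_p_adj=float(row["mir_p_adj"]),
                    gene_fold=float(row["gene_fold"]),
                    gene_p_adj=float(row["gene_p_adj"]),
                    sources=frozenset(s for s in row["sources"].split("|") if s),
                    matched_go_terms=frozenset(
                        t for t in row["matched_go_terms"].split("|") if t
                    ),
                )
            )
    return pairs


def _pairs_graph(pairs: list[PairRecord]) -> nx.DiGraph:
    graph = nx.DiGraph()
    for p in pairs:
        graph.add_node(p.mirna, type="miRNA")
        graph.add_node(p.gene, type="gene")
        graph.add_edge(
            p.mirna,
            p.gene,
            cell_line=p.cell_line,
            mir_fold=p.mir_fold,
            gene_fold=p.gene_fold,
            sources="|".join(sorted(p.sources)),
            matched_go_terms="|".join(sorted(p.matched_go_terms)),
        )
    return graph


def export_network(pairs: list[PairRecord], path, fmt: str = "tsv") -> Path:
    """Write retained pairs as 'sif', 'graphml' or a round-trippable 'tsv'."""
    path = Path(path)
    if fmt not in ("sif", "graphml", "tsv"):
        raise ValueError(f"unknown network format: {fmt!r}")
    if fmt != "tsv" and not pairs:
        raise ValueError(f"cannot export an empty pair list as {fmt}")
    if fmt == "tsv":
        pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)
    elif fmt == "sif":
        with open(path, "w") as handle:
            for p in pairs:
                handle.write(f"{p.mirna}\ttargets\t{p.gene}\n")
    else:
        nx.write_graphml(_pairs_graph(pairs), path)
    return path
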