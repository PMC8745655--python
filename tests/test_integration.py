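import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mirsig.integration import (
    DEFAULT_GO_KEYWORDS,
    PairRecord,
    aggregate_targets,
    export_network,
    filter_by_go,
    pairs_to_frame,
    read_pairs_tsv,
    select_inverse_pairs,
)
from mirsig.selection import Thresholds


def edge_frame(edges):
    return pd.DataFrame(edges, columns=["mirna", "gene"])


def de_frame(rows):
    return pd.DataFrame(rows, columns=["cell_line", "feature", "signed_fold", "p_adj"])


def make_pair(**overrides):
    base = dict(
        mirna="miR-1",
        gene="G1",
        cell_line="A2780CR1",
        mir_fold=-10.0,
        mir_p_adj=1e-6,
        gene_fold=8.0,
        gene_p_adj=1e-4,
        sources=frozenset({"TargetScan"}),
    )
    base.update(overrides)
    return PairRecord(**base)


class TestAggregateTargets:
    def test_union_semantics_and_validated_flag(self):
        db = aggregate_targets(
            [
                ("TargetScan", edge_frame([("miR-1", "G1")])),
                ("miRwalk", edge_frame([("miR-1", "G1")])),
            ]
        )
        assert len(db) == 1
        assert db.sources("miR-1", "G1") == {"TargetScan", "miRwalk"}
        assert db.is_validated("miR-1", "G1")

    def test_predicted_only_edge_not_validated(self):
        db = aggregate_targets([("DIANA", edge_frame([("miR-1", "G1")]))])
        assert not db.is_validated("miR-1", "G1")

    def test_disjoint_tables_sum(self):
        db = aggregate_targets(
            [
                ("DIANA", edge_frame([("miR-1", "G1")])),
                ("PicTar", edge_frame([("miR-2", "G2")])),
                ("miRTAR", edge_frame([("miR-3", "G3")])),
            ]
        )
        assert len(db) == 3

    def test_matches_set_union_oracle(self, rng):
        mirs = [f"miR-{i}" for i in range(4)]
        genes = [f"G{i}" for i in range(5)]
        tables = []
        for source in ("DIANA", "TargetScan", "miRwalk"):
            edges = [
                (m, g) for m in mirs for g in genes if rng.random() < 0.4
            ]
            tables.append((source, edge_frame(edges)))
        db = aggregate_targets(tables)
        oracle = set()
        for _, table in tables:
            oracle |= {tuple(r) for r in table.to_numpy()}
        assert set(db.edges) == oracle
        for (m, g), sources in db.edges.items():
            assert sources == {s for s, t in tables if (m, g) in set(map(tuple, t.to_numpy()))}

    def test_malformed_rows_rejected_with_count(self, caplog):
        table = pd.DataFrame({"mirna": ["miR-1", None, ""], "gene": ["G1", "G2", "G3"]})
        with caplog.at_level("WARNING", logger="mirsig.integration"):
            db = aggregate_targets([("DIANA", table)])
        assert len(db) == 1
        assert "2" in caplog.text

    def test_unknown_source_rejected(self):
        with pytest.raises(ValueError):
            aggregate_targets([("GuessDB", edge_frame([("miR-1", "G1")]))])


class TestSelectInversePairs:
    db = aggregate_targets([("TargetScan", edge_frame([("miR-1", "G1")]))])

    def run(self, mir_fold, mir_p, gene_fold, gene_p):
        mir_de = de_frame([("A2780CR1", "miR-1", mir_fold, mir_p)])
        gene_de = de_frame([("A2780CR1", "G1", gene_fold, gene_p)])
        return select_inverse_pairs(mir_de, gene_de, self.db)

    def test_inverse_significant_pair_retained(self):
        pairs = self.run(-29.12, 3.6e-9, 8.0, 1e-4)
        assert len(pairs) == 1
        assert pairs[0].mirna == "miR-1" and pairs[0].gene == "G1"
        assert pairs[0].sources == {"TargetScan"}

    def test_same_sign_pair_dropped(self):
        assert self.run(6.0, 0.001, 7.0, 0.001) == []

    def test_gene_below_cutoff_dropped(self):
        assert self.run(6.0, 0.001, -4.9, 0.001) == []

    def test_gene_p_above_alpha_dropped(self):
        assert self.run(6.0, 0.001, -8.0, 0.2) == []

    def test_mirna_below_cutoff_forms_no_pair(self):
        assert self.run(-4.0, 0.001, 8.0, 0.001) == []

    def test_pair_only_within_matching_cell_line(self):
        mir_de = de_frame([("A2780CR1", "miR-1", -10.0, 1e-6)])
        gene_de = de_frame([("A2780CR2", "G1", 8.0, 1e-4)])
        assert select_inverse_pairs(mir_de, gene_de, self.db) == []

    def test_output_respects_invariants(self, rng):
        mirs = [f"miR-{i}" for i in range(6)]
        genes = [f"G{i}" for i in range(6)]
        db = aggregate_targets(
            [("DIANA", edge_frame([(m, g) for m in mirs for g in genes if rng.random() < 0.5]))]
        )
        lines = ["A2780CR1", "A2780PR1"]
        mir_de = de_frame(
            [
                (ln, m, float(rng.choice([1, -1]) * rng.uniform(1, 20)), float(rng.uniform(0, 0.1)))
                for ln in lines
                for m in mirs
            ]
        )
        gene_de = de_frame(
            [
                (ln, g, float(rng.choice([1, -1]) * rng.uniform(1, 20)), float(rng.uniform(0, 0.1)))
                for ln in lines
                for g in genes
            ]
        )
        pairs = select_inverse_pairs(mir_de, gene_de, db)
        for p in pairs:
            assert (p.mirna, p.gene) in db
            assert np.sign(p.mir_fold) * np.sign(p.gene_fold) == -1
            assert abs(p.mir_fold) > 5 and abs(p.gene_fold) > 5
            assert p.mir_p_adj < 0.05 and p.gene_p_adj < 0.05

    def test_record_rejects_same_sign_folds(self):
        with pytest.raises(ValueError):
            make_pair(gene_fold=-8.0)


class TestFilterByGo:
    def test_matching_gene_retained_with_terms(self):
        pair = make_pair()
        kept = filter_by_go([pair], {"G1": {"Extracellular Matrix", "nucleus"}})
        assert len(kept) == 1
        assert kept[0].matched_go_terms == {"extracellular matrix"}

    def test_non_matching_gene_dropped(self):
        assert filter_by_go([make_pair()], {"G1": {"nucleus"}}) == []

    def test_unannotated_gene_dropped(self):
        assert filter_by_go([make_pair()], {}) == []

    def test_empty_keywords_rejected(self):
        with pytest.raises(ValueError):
            filter_by_go([make_pair()], {"G1": {"stem cell"}}, keywords=())

    def test_superset_keywords_identity_and_disjoint_empty(self):
        pairs = [make_pair(gene=f"G{i}", mirna=f"miR-{i}") for i in range(4)]
        annotations = {f"G{i}": {"stem cell", f"other-{i}"} for i in range(4)}
        all_terms = set(DEFAULT_GO_KEYWORDS) | {f"other-{i}" for i in range(4)}
        assert [p.gene for p in filter_by_go(pairs, annotations, all_terms)] == [
            p.gene for p in pairs
        ]
        assert filter_by_go(pairs, annotations, {"cytoplasm"}) == []

    def test_matches_brute_force_scan_oracle(self, rng):
        pairs = [make_pair(gene=f"G{i}", mirna=f"miR-{i}") for i in range(10)]
        terms = list(DEFAULT_GO_KEYWORDS) + ["nucleus", "membrane"]
        annotations = {
            f"G{i}": {terms[int(j)] for j in rng.integers(0, len(terms), size=2)}
            for i in rng.integers(0, 10, size=4)
        }
        kept = filter_by_go(pairs, annotations)
        oracle = [
            p.gene
            for p in pairs
            if p.gene in annotations
            and any(t.lower() in {a.lower() for a in annotations[p.gene]} for t in DEFAULT_GO_KEYWORDS)
        ]
        assert [p.gene for p in kept] == oracle

    def test_dataframe_annotations_accepted(self):
        table = pd.DataFrame({"gene": ["G1"], "term": ["stem cell"]})
        assert len(filter_by_go([make_pair()], table)) == 1


class TestExportNetwork:
    pairs = [
        make_pair(),
        make_pair(mirna="miR-2", gene="G2", mir_fold=6.0, gene_fold=-7.0, cell_line="A2780PR1"),
    ]

    def test_sif_two_lines_with_targets_relation(self, tmp_path):
        path = export_network(self.pairs, tmp_path / "net.sif", fmt="sif")
        lines = path.read_text().splitlines()
        assert lines == ["miR-1\ttargets\tG1", "miR-2\ttargets\tG2"]

    def test_tsv_round_trip(self, tmp_path):
        path = export_network(self.pairs, tmp_path / "pairs.tsv", fmt="tsv")
        assert read_pairs_tsv(path) == self.pairs

    def test_empty_tsv_allowed_header_only(self, tmp_path):
        path = export_network([], tmp_path / "pairs.tsv", fmt="tsv")
        assert read_pairs_tsv(path) == []
        assert path.read_text().startswith("mirna\tgene")

    def test_empty_sif_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_network([], tmp_path / "net.sif", fmt="sif")

    def test_graphml_parses_with_expected_node_count(self, tmp_path):
        path = export_network(self.pairs, tmp_path / "net.graphml", fmt="graphml")
        graph = nx.read_graphml(path)
        mirs = {p.mirna for p in self.pairs}
        genes = {p.gene for p in self.pairs}
        assert graph.number_of_nodes() == len(mirs) + len(genes)
        assert graph.nodes["miR-1"]["type"] == "miRNA"
        assert graph.nodes["G1"]["type"] == "gene"
        assert graph.edges["miR-1", "G1"]["sources"] == "TargetScan"

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_network(self.pairs, tmp_path / "x", fmt="gexf")

    def test_frame_columns_stable(self):
        frame = pairs_to_frame(self.pairs)
        assert list(frame.columns[:4]) == ["mirna", "gene", "cell_line", "mir_fold"]
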