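"""QC filters, pathway-report loading, genus aggregation, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import funcphylo as fp
from funcphylo.profile_matrix import (
    FormatError,
    QCConfig,
    hierarchical_cluster,
    load_pathway_reports,
    write_matrix,
)


def record(genome_id="G1", genus="g", contigs=10, genes=2000, **kw):
    return fp.GenomeRecord(
        genome_id=genome_id,
        genus=genus,
        phylum=kw.get("phylum", "P"),
        domain=kw.get("domain", "Bacteria"),
        status=kw.get("status", "finished"),
        n_contigs=contigs,
        n_genes=genes,
    )


class TestQCFilter:
    def test_contig_threshold_is_strict_greater(self):
        kept, rejected = fp.qc_filter_genomes(
            [record("A", contigs=1001, genes=5000), record("B", contigs=1000, genes=5000)]
        )
        assert [r.genome_id for r in kept] == ["B"]
        assert rejected[0][0] == "A" and "contigs" in rejected[0][1]

    def test_gene_threshold_is_strict_less(self):
        kept, rejected = fp.qc_filter_genomes(
            [record("A", contigs=10, genes=399), record("B", contigs=10, genes=400)]
        )
        assert [r.genome_id for r in kept] == ["B"]
        assert "genes" in rejected[0][1]

    def test_empty_result_allowed(self):
        kept, rejected = fp.qc_filter_genomes([record("A", contigs=2000)])
        assert kept == [] and len(rejected) == 1


class TestPathwayLoading:
    def write_report(self, tmp_path, rows, name="r.tsv"):
        path = tmp_path / name
        body = "\n".join(f"{g}\t{p}\t{c}" for g, p, c in rows)
        path.write_text("genome_id\tpathway_id\tconfidence\n" + body + "\n")
        return path

    def test_confidence_threshold_inclusive(self, tmp_path):
        path = self.write_report(
            tmp_path,
            [("G1", "pwy-1", 70), ("G1", "pwy-2", 69.9), ("G2", "pwy-1", 90)],
        )
        m = load_pathway_reports([path])
        assert m.loc["G1", "pwy-1"] == 1
        assert m.loc["G1", "pwy-2"] == 0
        assert m.loc["G2", "pwy-2"] == 0  # absent row means 0

    def test_duplicates_collapse_by_max(self, tmp_path):
        path = self.write_report(
            tmp_path, [("G1", "pwy-1", 40), ("G1", "pwy-1", 80), ("G2", "pwy-1", 10)]
        )
        m = load_pathway_reports([path])
        assert m.loc["G1", "pwy-1"] == 1
        assert m.loc["G2", "pwy-1"] == 0

    def test_union_of_pathways_across_files(self, tmp_path):
        p1 = self.write_report(tmp_path, [("G1", "pwy-1", 90)], "a.tsv")
        p2 = self.write_report(tmp_path, [("G2", "pwy-2", 90)], "b.tsv")
        m = load_pathway_reports([p1, p2])
        assert set(m.columns) == {"pwy-1", "pwy-2"}
        assert m.values.sum() == 2

    def test_missing_column_names_file(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("genome_id\tpathway\n" + "G1\tx\n")
        with pytest.raises(FormatError, match="bad.tsv"):
            load_pathway_reports([path])

    def test_matrix_round_trips_through_tsv(self, tmp_path):
        path = self.write_report(tmp_path, [("G1", "pwy-1", 90), ("G2", "pwy-2", 75)])
        m = load_pathway_reports([path])
        out = tmp_path / "m.tsv"
        write_matrix(m, out)
        back = pd.read_csv(out, sep="\t", index_col=0)
        assert (back.values == m.values).all()


class TestGenusAggregation:
    def make_matrix(self):
        return pd.DataFrame(
            [[1, 0], [0, 0], [0, 1]],
            index=["G1", "G2", "G3"],
            columns=["pwy-1", "pwy-2"],
        )

    def test_any_member_makes_genus_present(self):
        records = [record("G1", "a"), record("G2", "a"), record("G3", "b")]
        agg = fp.aggregate_by_genus(self.make_matrix(), records)
        assert agg.shape == (2, 2)
        assert agg.loc["a", "pwy-1"] == 1  # G1 has it, G2 does not
        assert agg.loc["a", "pwy-2"] == 0
        assert agg.loc["b", "pwy-2"] == 1

    def test_singleton_genera_are_identity(self):
        records = [record(f"G{i}", f"g{i}") for i in (1, 2, 3)]
        agg = fp.aggregate_by_genus(self.make_matrix(), records)
        assert (agg.values == self.make_matrix().values).all()

    def test_column_sums_bounded_by_genome_level(self):
        records = [record("G1", "a"), record("G2", "a"), record("G3", "a")]
        m = self.make_matrix()
        agg = fp.aggregate_by_genus(m, records)
        assert (agg.sum(axis=0) <= m.sum(axis=0)).all()

    def test_missing_metadata_is_an_error(self):
        with pytest.raises(ValueError, match="G3"):
            fp.aggregate_by_genus(self.make_matrix(), [record("G1"), record("G2")])


class TestManhattanDistance:
    def test_counts_differing_entries(self):
        assert fp.manhattan_distance([1, 0, 1], [1, 1, 1]) == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fp.manhattan_distance([1, 0], [1, 0, 1])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 1), min_size=1, max_size=30).flatmap(
            lambda a: st.tuples(
                st.just(a),
                st.lists(st.integers(0, 1), min_size=len(a), max_size=len(a)),
                st.lists(st.integers(0, 1), min_size=len(a), max_size=len(a)),
            )
        )
    )
    def test_is_a_metric(self, vecs):
        a, b, c = vecs
        d = fp.manhattan_distance
        assert d(a, a) == 0
        assert d(a, b) == d(b, a)
        assert d(a, c) <= d(a, b) + d(b, c)
        comp = [1 - x for x in a]
        assert d(a, comp) == len(a)


class TestHierarchicalClustering:
    def test_identical_rows_merge_first_at_zero(self):
        m = pd.DataFrame(
            [[1, 0, 0], [1, 0, 0], [0, 1, 1]], index=["a", "b", "c"],
            columns=["p1", "p2", "p3"],
        )
        res = hierarchical_cluster(m)
        assert res.linkage_matrix[0, 2] == 0.0
        order = res.leaf_order
        assert abs(order.index("a") - order.index("b")) == 1

    def test_complete_linkage_hand_case(self):
        # pairwise distances: d(a,b)=1, d(a,c)=4, d(b,c)=5
        m = pd.DataFrame(
            [
                [0, 0, 0, 0, 0, 0, 0, 0, 0],
                [1, 0, 0, 0, 0, 0, 0, 0, 0],
                [0, 1, 1, 1, 1, 0, 0, 0, 0],
            ],
            index=["a", "b", "c"],
            columns=[f"p{i}" for i in range(9)],
        )
        res = hierarchical_cluster(m)
        heights = res.linkage_matrix[:, 2].tolist()
        assert heights == [1.0, 5.0]

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(
            rng.integers(0, 2, size=(8, 12)),
            index=[f"r{i}" for i in range(8)],
            columns=[f"p{i}" for i in range(12)],
        )
        res1 = hierarchical_cluster(m)
        res2 = hierarchical_cluster(m.sample(frac=1, random_state=4))
        assert np.allclose(res1.linkage_matrix[:, 2], res2.linkage_matrix[:, 2])
        assert res1.leaf_order == res2.leaf_order
        assert res1.newick == res2.newick

    def test_single_row_gives_single_leaf(self):
        m = pd.DataFrame([[1, 0]], index=["a"], columns=["p1", "p2"])
        res = hierarchical_cluster(m)
        assert res.leaf_order == ["a"]
        assert res.newick.startswith("a")

    def test_dendrogram_newick_parses_with_merge_heights(self):
        m = pd.DataFrame(
            [[1, 1, 0], [1, 0, 0], [0, 1, 1]], index=["a", "b", "c"],
            columns=["p1", "p2", "p3"],
        )
        res = hierarchical_cluster(m)
        t = fp.parse_newick(res.newick)
        assert sorted(t.tip_labels()) == ["a", "b", "c"]
        # root-to-leaf path length equals the final merge height for each leaf
        final = res.linkage_matrix[-1, 2]
        for tip in t.tips():
            depth, n = 0.0, tip
            while n.parent is not None:
                depth += n.length
                n = n.parent
            assert depth == pytest.approx(final)

    def test_columns_axis(self):
        m = pd.DataFrame(
            [[1, 1, 0], [1, 1, 0]], index=["a", "b"], columns=["p1", "p2", "p3"]
        )
        res = hierarchical_cluster(m, axis="columns")
        assert set(res.leaf_order) == {"p1", "p2", "p3"}
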