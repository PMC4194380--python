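"""domtblout parsing, coverage arithmetic, hit filtering, cluster rules."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import funcphylo as fp
from funcphylo.annotation_filtering import (
    AnnotationFilterConfig,
    DomtblFormatError,
    coverage,
    parse_domtbl,
)


def domtbl_row(fam, tlen, query, qlen, ev, hf, ht, af, at, desc="-"):
    return (
        f"{fam} - {tlen} {query} - {qlen} {ev} 50.0 0.1 1 1 "
        f"{ev} {ev} 49.0 0.1 {hf} {ht} {af} {at} {af} {at} 0.95 {desc}"
    )


def make_hit(evalue=1e-10, qlen=100, hlen=100, qints=None, hints=None):
    return fp.HmmerHit(
        query_id="q",
        family_id="f",
        evalue=evalue,
        query_len=qlen,
        hmm_len=hlen,
        query_intervals=qints or [(1, qlen)],
        hmm_intervals=hints or [(1, hlen)],
    )


class TestParseDomtbl:
    def test_domain_rows_aggregate_per_query_family(self):
        text = "\n".join(
            [
                "# comment",
                domtbl_row("F1", 200, "q1", 150, "1e-9", 1, 80, 1, 60, "dom 1"),
                domtbl_row("F1", 200, "q1", 150, "1e-9", 90, 180, 70, 140, "dom 2"),
            ]
        )
        hits = parse_domtbl(io.StringIO(text))
        assert len(hits) == 1
        hit = hits[0]
        assert hit.query_id == "q1" and hit.family_id == "F1"
        assert hit.query_intervals == [(1, 60), (70, 140)]
        assert hit.hmm_intervals == [(1, 80), (90, 180)]
        assert hit.evalue == 1e-9

    def test_comment_only_file_is_empty(self):
        assert parse_domtbl(io.StringIO("# a\n#\n# b\n")) == []

    def test_wrong_column_count_names_line(self):
        text = "# ok\nF1 - 200 q1\n"
        with pytest.raises(DomtblFormatError, match="line 2"):
            parse_domtbl(io.StringIO(text))

    def test_non_numeric_evalue_names_line(self):
        text = domtbl_row("F1", 200, "q1", 150, "not-a-number", 1, 80, 1, 60)
        with pytest.raises(DomtblFormatError, match="line 1"):
            parse_domtbl(io.StringIO(text))

    def test_agrees_with_biopython_searchio(self, tmp_path):
        from Bio import SearchIO

        rows = [
            domtbl_row("F1", 200, "q1", 150, "1e-9", 1, 80, 1, 60, "protein one"),
            domtbl_row("F1", 200, "q1", 150, "1e-9", 90, 180, 70, 140, "protein one"),
            domtbl_row("F2", 300, "q2", 250, "2e-4", 10, 200, 5, 190, "protein two"),
        ]
        path = tmp_path / "hits.domtbl"
        path.write_text("\n".join(rows) + "\n")
        ours = {(h.query_id, h.family_id): h for h in parse_domtbl(path)}
        ref = {}
        for qresult in SearchIO.parse(str(path), "hmmscan3-domtab"):
            for hit in qresult.hits:
                intervals = [
                    (hsp.query_start + 1, hsp.query_end) for hsp in hit.hsps
                ]
                ref[(qresult.id, hit.id)] = (hit.evalue, sorted(intervals))
        assert set(ours) == set(ref)
        for key, (evalue, intervals) in ref.items():
            assert ours[key].evalue == pytest.approx(evalue)
            assert sorted(ours[key].query_intervals) == intervals


class TestCoverage:
    def test_disjoint_intervals_sum(self):
        hit = make_hit(qints=[(1, 30), (41, 65)])
        qcov, _ = coverage(hit)
        assert qcov == pytest.approx(0.55)

    def test_overlap_merged_once(self):
        hit = make_hit(qints=[(1, 50), (26, 75)])
        qcov, _ = coverage(hit)
        assert qcov == pytest.approx(0.75)

    def test_full_length_single_interval(self):
        qcov, hcov = coverage(make_hit())
        assert qcov == 1.0 and hcov == 1.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(1, 90), st.integers(1, 10)).map(
                lambda p: (p[0], min(p[0] + p[1], 100))
            ),
            min_size=1,
            max_size=6,
        ),
        st.randoms(use_true_random=False),
    )
    def test_order_and_split_invariance(self, intervals, rnd):
        base = make_hit(qints=list(intervals))
        shuffled = list(intervals)
        rnd.shuffle(shuffled)
        assert coverage(make_hit(qints=shuffled)) == coverage(base)
        # split every interval of length >= 2 into two adjacent pieces
        split = []
        for lo, hi in intervals:
            if hi > lo:
                mid = (lo + hi) // 2
                split += [(lo, mid), (mid + 1, hi)]
            else:
                split.append((lo, hi))
        assert coverage(make_hit(qints=split)) == coverage(base)


class TestFilterHits:
    def test_passing_hit_is_kept(self):
        best, un = fp.filter_hits(
            [make_hit(evalue=1e-4, qints=[(1, 60)], hints=[(1, 55)])]
        )
        assert set(best) == {"q"} and un == []

    def test_evalue_threshold_is_strict(self):
        best, un = fp.filter_hits([make_hit(evalue=1e-3)])
        assert best == {} and un == ["q"]
        best, _ = fp.filter_hits([make_hit(evalue=0.999e-3)])
        assert set(best) == {"q"}

    def test_either_coverage_failure_discards(self):
        low_q = make_hit(qints=[(1, 49)])
        low_h = make_hit(hints=[(1, 49)])
        assert fp.filter_hits([low_q])[0] == {}
        assert fp.filter_hits([low_h])[0] == {}
        at_half = make_hit(qints=[(1, 50)], hints=[(1, 50)])
        assert set(fp.filter_hits([at_half])[0]) == {"q"}  # >= 50% passes

    def test_best_evalue_wins_with_family_tiebreak(self):
        h1 = make_hit(evalue=1e-6)
        h1.family_id = "FB"
        h2 = make_hit(evalue=1e-4)
        h2.family_id = "FA"
        assert fp.filter_hits([h1, h2])[0]["q"].family_id == "FB"
        h2.evalue = 1e-6
        assert fp.filter_hits([h1, h2])[0]["q"].family_id == "FA"

    def test_relaxing_thresholds_is_monotone(self):
        hits = [
            make_hit(evalue=ev, qints=[(1, q)], hints=[(1, h)])
            for ev, q, h in [(1e-5, 60, 60), (5e-3, 80, 80), (1e-8, 40, 90)]
        ]
        strict = set(fp.filter_hits(hits)[0])
        loose = set(
            fp.filter_hits(
                hits, AnnotationFilterConfig(max_evalue=1e-2, min_coverage=0.3)
            )[0]
        )
        assert strict <= loose


class TestFamilyAnnotations:
    def ann(self, fam="F", **kw):
        return fp.FamilyAnnotation(
            family_id=fam,
            product_names=frozenset(kw.get("names", ())),
            ec_numbers=frozenset(kw.get("ec", ())),
            gene_names=frozenset(kw.get("genes", ())),
            go_terms=frozenset(kw.get("go", ())),
        )

    def test_union_is_idempotent_and_keeps_everything(self):
        a = self.ann(ec={"1.1.1.1"}, go={"GO:0008150"})
        b = self.ann(ec={"1.1.1.1"}, go={"GO:0003674"})
        merged = fp.merge_family_annotations([a, b])
        assert merged.ec_numbers == frozenset({"1.1.1.1"})
        assert merged.go_terms == frozenset({"GO:0008150", "GO:0003674"})

    def test_single_member_is_identity(self):
        a = self.ann(names={"kinase"}, genes={"pfkA"})
        assert fp.merge_family_annotations([a]) == a

    def test_associative_and_commutative(self):
        anns = [
            self.ann(names={"x"}),
            self.ann(ec={"2.7.1.1"}),
            self.ann(go={"GO:0008150"}),
        ]
        left = fp.merge_family_annotations(
            [fp.merge_family_annotations(anns[:2]), anns[2]]
        )
        right = fp.merge_family_annotations(
            [anns[0], fp.merge_family_annotations(anns[1:])]
        )
        assert left == right == fp.merge_family_annotations(anns[::-1])

    def test_empty_member_list_rejected(self):
        with pytest.raises(ValueError):
            fp.merge_family_annotations([])

    def test_malformed_go_id_rejected(self):
        with pytest.raises(ValueError):
            self.ann(go={"GO:123"})


class TestClusterRules:
    def test_valid_cluster(self):
        ok, violations = fp.validate_cluster([(1.0, 100), (0.85, 90)])
        assert ok and violations == []

    def test_identity_threshold_is_strict(self):
        ok, violations = fp.validate_cluster([(1.0, 100), (0.79, 95)])
        assert not ok and any("identity" in v for v in violations)
        ok, _ = fp.validate_cluster([(1.0, 100), (0.80, 95)])
        assert not ok  # exactly 80% fails the strict rule

    def test_length_ratio_threshold(self):
        ok, violations = fp.validate_cluster([(1.0, 100), (0.9, 79)])
        assert not ok and any("ratio" in v for v in violations)
        ok, _ = fp.validate_cluster([(1.0, 100), (0.9, 81)])
        assert ok
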