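"""tss_analysis: Paraclu clustering, common TSSs, alt-TSS calls, promoters."""

from math import inf

import numpy as np
import pytest

from beecage.io_core import BeeCageError, GeneModel, GenomeAnnotation
from beecage.tss_analysis import (
    AltTSSCall,
    TagCluster,
    alternative_tss,
    common_tss,
    extract_promoters,
    filter_clusters,
    gc_fraction,
    multi_cluster_genes,
    paraclu,
    paraclu_all_segments,
)


def cluster_key(c: TagCluster):
    return (c.start, c.end, round(c.tag_sum, 9), round(c.min_density, 9),
            c.max_density if c.max_density == inf else round(c.max_density, 9))


class TestParaclu:
    def test_singleton(self):
        (c,) = paraclu([100], [5.0])
        assert (c.start, c.end, c.tag_sum) == (100, 101, 5.0)
        assert c.min_density == 0.0 and c.max_density == inf

    def test_two_adjacent_equal_positions_hand_trace(self):
        clusters = paraclu([100, 101], [5.0, 5.0])
        by_span = {(c.start, c.end): c for c in clusters}
        top = by_span[(100, 102)]
        assert top.density == 5.0 and top.min_density == 0.0 and top.max_density == 5.0
        assert len(top.children) == 2
        for child in ((100, 101), (101, 102)):
            assert by_span[child].min_density == 5.0
            assert by_span[child].max_density == inf

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(60):
            n = int(rng.integers(1, 13))
            pos = np.sort(rng.choice(np.arange(0, 50), size=n, replace=False))
            w = rng.uniform(0.5, 9.5, size=n)
            rec = {cluster_key(c) for c in paraclu(pos, w)}
            ora = {
                (i, j + 1, round(s, 9), round(mn, 9), mx if mx == inf else round(mx, 9))
                for i, j, s, mn, mx in paraclu_all_segments(pos, w)
            }
            assert rec == ora

    def test_weight_conservation_down_the_hierarchy(self):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(np.arange(0, 200), size=20, replace=False))
        w = rng.uniform(0.5, 9.5, size=20)
        for c in paraclu(pos, w):
            if c.children:
                assert np.isclose(c.tag_sum, sum(ch.tag_sum for ch in c.children))

    def test_unsorted_positions_rejected(self):
        with pytest.raises(BeeCageError, match="increasing"):
            paraclu([5, 3], [1.0, 1.0])

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(BeeCageError, match="positive"):
            paraclu([1, 2], [1.0, 0.0])


def mk_cluster(start, end, tag_sum, min_den=1.0, max_den=10.0, sample_id="s1",
               scaffold="scf1", strand="+"):
    return TagCluster(scaffold, strand, start, end, tag_sum, min_den, max_den, sample_id)


class TestFilterClusters:
    def test_span_over_50_removed(self):
        assert filter_clusters([mk_cluster(0, 51, 99.0)]) == []
        assert len(filter_clusters([mk_cluster(0, 50, 99.0)])) == 1

    def test_fewer_than_5_rescaled_tags_removed(self):
        assert filter_clusters([mk_cluster(0, 10, 4.9)]) == []
        assert len(filter_clusters([mk_cluster(0, 10, 5.0)])) == 1

    def test_stability_below_2_removed_and_infinite_passes(self):
        assert filter_clusters([mk_cluster(0, 10, 9.0, min_den=5.0, max_den=9.0)]) == []
        assert len(filter_clusters([mk_cluster(0, 10, 9.0, min_den=5.0, max_den=inf)])) == 1
        assert len(filter_clusters([mk_cluster(0, 10, 9.0, min_den=0.0, max_den=1.0)])) == 1

    def test_nested_kept_cluster_dropped(self):
        outer = mk_cluster(100, 120, 30.0)
        inner = mk_cluster(105, 110, 20.0)
        out = filter_clusters([outer, inner])
        assert out == [outer]


def _one_gene_annotation(strand="+"):
    return GenomeAnnotation([GeneModel("g", "scf1", strand, 100, 5_000)])


class TestCommonTss:
    def test_component_in_all_samples_beats_bigger_partial_component(self):
        ann = _one_gene_annotation()
        clusters = {
            f"s{i}": [mk_cluster(200, 210, 10.0, sample_id=f"s{i}")] for i in (1, 2, 3)
        }
        clusters["s1"].append(mk_cluster(400, 410, 25.0, sample_id="s1"))
        clusters["s2"].append(mk_cluster(400, 410, 25.0, sample_id="s2"))
        res = common_tss(clusters, {"grp": ["s1", "s2", "s3"]}, ann)
        assert res["grp"]["g"].tss_pos == 200
        assert res["grp"]["g"].tag_total == 30.0

    def test_greater_tag_total_wins_when_both_common(self):
        ann = _one_gene_annotation()
        clusters = {
            f"s{i}": [
                mk_cluster(200, 210, 10.0, sample_id=f"s{i}"),
                mk_cluster(400, 410, 17.0, sample_id=f"s{i}"),
            ]
            for i in (1, 2, 3)
        }
        res = common_tss(clusters, {"grp": ["s1", "s2", "s3"]}, ann)
        assert res["grp"]["g"].tss_pos == 400

    def test_single_sample_single_cluster(self):
        ann = _one_gene_annotation()
        res = common_tss({"s1": [mk_cluster(200, 210, 6.0)]}, {"grp": ["s1"]}, ann)
        t = res["grp"]["g"]
        assert t.tss_pos == 200 and t.n_samples_supporting == 1

    def test_minus_strand_tss_is_high_boundary(self):
        ann = GenomeAnnotation([GeneModel("g", "scf1", "-", 100, 5_000)])
        clusters = {"s1": [mk_cluster(200, 210, 6.0, strand="-")]}
        res = common_tss(clusters, {"grp": ["s1"]}, ann)
        assert res["grp"]["g"].tss_pos == 209

    def test_gene_without_common_component_absent(self):
        ann = _one_gene_annotation()
        clusters = {
            "s1": [mk_cluster(200, 210, 10.0, sample_id="s1")],
            "s2": [mk_cluster(400, 410, 10.0, sample_id="s2")],
        }
        res = common_tss(clusters, {"grp": ["s1", "s2"]}, ann)
        assert res["grp"] == {}


class TestAlternativeTss:
    def _common(self, pos, group):
        from beecage.tss_analysis import CommonTSS

        return {"g": CommonTSS("g", group, pos, (pos, pos + 10), 10.0, 2)}

    @pytest.mark.parametrize(
        "a,b,dist,alt",
        [(100, 250, 150, True), (100, 180, 80, False), (100, 100, 0, False),
         (100, 201, 101, True), (100, 200, 100, False)],
    )
    def test_strict_100bp_rule(self, a, b, dist, alt):
        (call,) = alternative_tss(self._common(a, "n"), self._common(b, "f"))
        assert call.distance == dist and call.is_alternative is alt

    def test_inclusive_flag_admits_exactly_100(self):
        (call,) = alternative_tss(self._common(100, "n"), self._common(200, "f"), inclusive=True)
        assert call.is_alternative

    def test_symmetric_in_group_arguments(self):
        a, b = self._common(120, "n"), self._common(400, "f")
        c1 = alternative_tss(a, b)[0]
        c2 = alternative_tss(b, a)[0]
        assert c1.distance == c2.distance and c1.is_alternative == c2.is_alternative

    def test_eligibility_filter_drops_single_cluster_genes(self):
        calls = alternative_tss(self._common(100, "n"), self._common(300, "f"),
                                eligible_genes=set())
        assert calls == []


class TestPromoters:
    def test_full_promoter_when_unobstructed(self):
        ann = GenomeAnnotation([GeneModel("g", "scf1", "+", 10_000, 16_000, cds_end=15_000)])
        out = extract_promoters(ann, {"g": 10_000})
        assert out["g"] == ("scf1", 8_000, 10_200)

    def test_clipped_at_scaffold_start(self):
        ann = GenomeAnnotation([GeneModel("g", "scf1", "+", 500, 4_000)])
        out = extract_promoters(ann, {"g": 500})
        assert out["g"] == ("scf1", 0, 700)

    def test_truncated_at_upstream_gene(self):
        ann = GenomeAnnotation(
            [
                GeneModel("up", "scf1", "+", 7_000, 8_900),
                GeneModel("g", "scf1", "+", 10_000, 16_000, cds_end=15_000),
            ]
        )
        out = extract_promoters(ann, {"g": 10_000})
        assert out["g"] == ("scf1", 8_900, 10_200)

    def test_truncated_at_stop_codon(self):
        ann = GenomeAnnotation([GeneModel("g", "scf1", "+", 10_000, 16_000, cds_end=10_150)])
        out = extract_promoters(ann, {"g": 10_000})
        assert out["g"] == ("scf1", 8_000, 10_150)

    def test_minus_strand_mirrored(self):
        ann = GenomeAnnotation([GeneModel("g", "scf1", "-", 4_000, 10_000, cds_end=4_100)])
        out = extract_promoters(ann, {"g": 9_999})
        # [-2000,+200] in transcription direction: [tss-199, tss+2001)
        assert out["g"] == ("scf1", 9_800, 12_000)

    def test_background_uses_annotated_start(self):
        ann = GenomeAnnotation([GeneModel("g", "scf1", "+", 10_000, 16_000)])
        out = extract_promoters(ann)
        assert out["g"] == ("scf1", 8_000, 10_200)

    def test_empty_after_truncation_omitted(self):
        ann = GenomeAnnotation(
            [
                GeneModel("up", "scf1", "+", 7_000, 10_300),
                GeneModel("g", "scf1", "+", 10_000, 16_000),
            ]
        )
        # overlapping upstream gene swallows the whole window
        out = extract_promoters(ann, {"g": 10_000})
        assert "g" not in out


class TestGcFraction:
    @pytest.mark.parametrize("seq,val", [("ACGT", 0.5), ("GGCC", 1.0), ("GNC", 1.0)])
    def test_values(self, seq, val):
        assert gc_fraction([seq]) == [val]

    def test_all_n_flagged_nan(self):
        assert np.isnan(gc_fraction(["NNN"])[0])

    def test_non_dna_rejected(self):
        with pytest.raises(BeeCageError, match="non-DNA"):
            gc_fraction(["ACGU"])


class TestAltTssIntegration:
    def test_recall_and_specificity_on_study_sim(self, study_sim):
        truth = study_sim["truth"]
        calls = {c.gene_id: c for c in study_sim["tss"]["alt_calls"]}
        called_alt = {g for g, c in calls.items() if c.is_alternative}
        truth_alt = set(truth.genes.index[truth.genes["is_alt_tss"]])
        assert len(truth_alt) >= 10
        recall = len(called_alt & truth_alt) / len(truth_alt)
        assert recall >= 0.9
        false_rate = len(called_alt - truth_alt) / max(1, len(called_alt))
        assert false_rate <= 0.05
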