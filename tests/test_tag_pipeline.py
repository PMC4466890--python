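"""tag_pipeline: filters, association regions, count matrices, TMM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from beecage.io_core import BeeCageError, GeneModel, GenomeAnnotation
from beecage.tag_pipeline import (
    CountMatrix,
    associate_tags,
    association_region,
    build_count_matrix,
    estimate_inner_distance,
    filter_expressed,
    filter_pairs,
    rescale_to_min,
    tmm_factors,
)
from conftest import make_pair


class TestInnerDistance:
    def test_sample_moments(self):
        pairs = [make_pair(qname=f"q{i}", m2=(179 + d, 258 + d)) for i, d in enumerate((100, 200, 300))]
        mean, sd = estimate_inner_distance(pairs)
        assert (mean, sd) == (200.0, 100.0)

    def test_constant_distances(self):
        pairs = [make_pair(qname=f"q{i}") for i in range(3)]
        mean, sd = estimate_inner_distance(pairs)
        assert (mean, sd) == (521.0, 0.0)

    def test_too_few_eligible_pairs(self):
        with pytest.raises(BeeCageError, match=">= 2"):
            estimate_inner_distance([make_pair(), make_pair(qname="u", mate2_unmapped=True)])


class TestFilterPairs:
    def test_mapq_threshold_is_strict(self):
        kept, rep = filter_pairs([make_pair(mapq=19), make_pair(qname="q2", mapq=20)])
        assert rep.low_mapq == 1 and rep.retained == 1
        assert kept[0].mapq == 20

    def test_different_scaffolds_removed(self):
        _, rep = filter_pairs([make_pair(scaffold2="scf2")])
        assert rep.different_scaffold == 1 and rep.retained == 0

    def test_same_orientation_removed_by_default_and_flag_inverts(self):
        same = make_pair(strand2="+")
        opposite = make_pair(qname="q2")
        _, rep = filter_pairs([same, opposite])
        assert rep.same_orientation == 1 and rep.retained == 1
        _, rep_lit = filter_pairs([same, opposite], orientation_literal=True)
        assert rep_lit.same_orientation == 1 and rep_lit.retained == 1

    def test_one_violation_per_rule_fixture(self):
        pairs = [make_pair(qname=f"c{i}") for i in range(5)]  # clean, inner 521
        pairs += [
            make_pair(qname="v1", mapq=5),
            make_pair(qname="v2", mate2_unmapped=True),
            make_pair(qname="v3", scaffold2="scf2"),
            make_pair(qname="v4", strand2="+"),
            make_pair(qname="v5", m2=(5000, 5079)),  # inner 4821
        ]
        kept, rep = filter_pairs(pairs, inner_max=1000.0)
        assert rep.retained == 5
        assert tuple(rep.rule_counts().values()) == (1, 1, 1, 1, 1)
        assert rep.total == 10

    def test_empty_input(self):
        kept, rep = filter_pairs([])
        assert kept == [] and rep.total == 0

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 60),  # mapq
                st.booleans(),  # mate2 unmapped
                st.booleans(),  # different scaffold
                st.booleans(),  # same orientation
                st.integers(-100, 3000),  # inner distance via mate2 start
            ),
            max_size=40,
        )
    )
    def test_report_partitions_any_input(self, rows):
        pairs = [
            make_pair(
                qname=f"q{i}",
                mapq=mq,
                mate2_unmapped=unm,
                scaffold2="scf2" if diff else None,
                strand2="+" if same else "-",
                m2=(179 + d, 258 + d),
            )
            for i, (mq, unm, diff, same, d) in enumerate(rows)
        ]
        _, rep = filter_pairs(pairs, inner_max=1000.0)
        assert rep.total == len(pairs)


class TestAssociation:
    def _annotation(self, with_upstream=False):
        genes = [GeneModel("g", "scf1", "+", 10_000, 15_000)]
        if with_upstream:
            genes.append(GeneModel("up", "scf1", "+", 8_000, 9_550))
        return GenomeAnnotation(genes)

    def test_tag_in_2kb_window_is_associated(self):
        ann = self._annotation()
        assoc = associate_tags([make_pair(m1=(9_500, 9_600), m2=(10_500, 10_579))], ann)
        assert list(assoc["s1"]) == ["g"]

    def test_upstream_gene_truncates_the_window(self):
        ann = self._annotation(with_upstream=True)
        assert association_region(ann.get("g"), ann)[0] == 9_550
        assoc = associate_tags([make_pair(m1=(9_400, 9_540), m2=(10_500, 10_579))], ann)
        assert "g" not in assoc.get("s1", {})

    def test_strand_mismatch_is_not_associated(self):
        ann = self._annotation()
        pair = make_pair(strand1="-", strand2="+", m1=(10_500, 10_579), m2=(9_800, 9_879))
        assert associate_tags([pair], ann).get("s1", {}) == {}

    def test_minus_strand_region_extends_past_gene_end(self):
        ann = GenomeAnnotation([GeneModel("m", "scf1", "-", 10_000, 15_000)])
        assert association_region(ann.get("m"), ann) == (10_000, 17_000)

    def test_enlarging_the_region_never_loses_associations(self):
        # removing the upstream neighbor can only grow the region
        pairs = [
            make_pair(qname=f"q{i}", m1=(s, s + 79), m2=(s + 600, s + 679))
            for i, s in enumerate(range(8_000, 12_000, 137))
        ]
        small = associate_tags(pairs, self._annotation(with_upstream=True))
        large = associate_tags(pairs, self._annotation(with_upstream=False))
        got_small = set(small.get("s1", {}).get("g", np.array([], dtype=int)).tolist())
        got_large = set(large.get("s1", {}).get("g", np.array([], dtype=int)).tolist())
        assert got_small <= got_large

    def test_tag_spanning_two_regions_counts_for_both(self):
        ann = GenomeAnnotation(
            [
                GeneModel("g1", "scf1", "+", 1_000, 5_000),
                GeneModel("g2", "scf1", "+", 5_200, 9_000),
            ]
        )
        # g1 region [0? 1000-2000=0.. -> [0,5000); g2 region [5000, 9000)
        pair = make_pair(m1=(4_980, 5_059), m2=(5_600, 5_679))
        groups = pd.Series(["A"], index=["s1"])
        matrix = build_count_matrix(associate_tags([pair], ann), groups)
        assert matrix.counts.loc["g1", "s1"] == 1
        assert matrix.counts.loc["g2", "s1"] == 1


class TestCountMatrix:
    def test_no_pairs_gives_zero_matrix_with_keep_zeros(self, two_gene_annotation):
        groups = pd.Series(["A", "B"], index=["s1", "s2"])
        m = build_count_matrix({}, groups, two_gene_annotation, keep_zeros=True)
        assert m.counts.shape == (4, 2) and (m.counts == 0).all().all()

    def test_hand_placed_tags_give_exact_counts(self, two_gene_annotation):
        pairs = [
            make_pair(qname="a", m1=(1_100, 1_179), m2=(1_700, 1_779)),
            make_pair(qname="b", m1=(1_200, 1_279), m2=(1_800, 1_879)),
            make_pair(qname="c", sample_id="s2", m1=(5_100, 5_179), m2=(5_700, 5_779)),
        ]
        groups = pd.Series(["A", "B"], index=["s1", "s2"])
        m = build_count_matrix(associate_tags(pairs, two_gene_annotation), groups)
        assert m.counts.loc["gA", "s1"] == 2
        assert m.counts.loc["gB", "s2"] == 1
        assert m.library_sizes.tolist() == [2.0, 1.0]

    def test_duplicate_sample_ids_rejected(self):
        groups = pd.Series(["A", "B"], index=["s1", "s1"])
        with pytest.raises(BeeCageError, match="duplicate"):
            build_count_matrix({}, groups)


def _matrix(counts, groups=None):
    df = pd.DataFrame(counts, dtype=float)
    df.columns = [f"s{i + 1}" for i in range(df.shape[1])]
    df.index = [f"g{i + 1}" for i in range(df.shape[0])]
    if groups is None:
        half = df.shape[1] // 2
        groups = ["A"] * half + ["B"] * (df.shape[1] - half)
    return CountMatrix.from_counts(df, pd.Series(groups, index=df.columns))


class TestRescaleToMin:
    def test_larger_library_halved(self):
        m = rescale_to_min(_matrix([[60, 120], [40, 80]], ["A", "B"]))
        assert np.allclose(m.counts["s2"], [60, 40])
        assert np.allclose(m.library_sizes, 100.0)

    def test_equal_libraries_unchanged(self):
        m0 = _matrix([[60, 60], [40, 40]], ["A", "B"])
        assert rescale_to_min(m0).counts.equals(m0.counts)

    def test_single_sample_unchanged(self):
        m0 = _matrix([[6], [4]], ["A"])
        assert rescale_to_min(m0).counts.equals(m0.counts)

    def test_zero_library_is_an_error(self):
        with pytest.raises(BeeCageError, match="zero"):
            rescale_to_min(_matrix([[1, 0]], ["A", "B"]))


class TestFilterExpressed:
    def test_presence_needs_two_samples_in_one_group(self):
        m = _matrix([[5, 0, 7, 0], [3, 2, 0, 0]])
        kept = filter_expressed(m, mode="presence")
        assert list(kept.counts.index) == ["g2"]

    def test_cpm_boundary_inclusive(self):
        # library sizes 1e6 -> a count of 1 is exactly 1 CPM
        counts = np.zeros((2, 4))
        counts[0, :2] = 1
        counts[1, 0] = 1
        filler = np.full((1, 4), 1e6) - counts.sum(axis=0)
        m = _matrix(np.vstack([counts, filler]))
        kept = filter_expressed(m, mode="cpm")
        assert "g1" in kept.counts.index and "g2" not in kept.counts.index

    def test_all_zero_gene_removed_in_both_modes(self):
        m = _matrix([[0, 0, 0, 0], [5, 5, 5, 5]])
        for mode in ("presence", "cpm"):
            assert "g1" not in filter_expressed(m, mode=mode).counts.index

    def test_small_group_is_an_error_in_presence_mode(self):
        m = _matrix([[1, 2]], ["A", "B"])
        with pytest.raises(BeeCageError, match="fewer than 2"):
            filter_expressed(m, mode="presence")


class TestTmm:
    def test_proportional_libraries_give_unit_factors(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 500, size=50).astype(float)
        m = _matrix(np.column_stack([base, 2 * base]), ["A", "B"])
        assert np.allclose(tmm_factors(m), 1.0)

    def test_single_gene_matrix_unit_factors(self):
        m = _matrix([[10, 30]], ["A", "B"])
        assert np.allclose(tmm_factors(m), 1.0)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(1)
        counts = rng.negative_binomial(5, 0.1, size=(300, 6)).astype(float) + 1
        f = tmm_factors(_matrix(counts))
        assert abs(np.log(f).mean()) < 1e-12
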