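"""Block construction, learned gap statistics and the adaptive joining rule."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blockasm.assembly import (
    build_blocks,
    build_coverage,
    classify_blocks,
    compute_gap_stats,
    join_intergenic_blocks,
    joining_thresholds,
)
from blockasm.models import (
    AlignedRead,
    Annotation,
    AssemblyParams,
    Block,
    GeneModel,
)

from conftest import brute_force_blocks, pile, random_reads, spliced, unspliced


class TestBuildCoverage:
    def test_stacked_reads_add_depth(self):
        cov = build_coverage([unspliced("a", 100), unspliced("b", 100)], {"chrI": 500})
        track = cov[("chrI", "+")]
        assert track.depth[100:150].tolist() == [2] * 50
        assert track.depth[99] == 0 and track.depth[150] == 0

    def test_spliced_read_leaves_intron_uncovered(self):
        cov = build_coverage([spliced("a", (100, 129), (330, 349))], {"chrI": 500})
        track = cov[("chrI", "+")]
        assert track.depth[100:130].tolist() == [1] * 30
        assert track.depth[130:330].sum() == 0
        assert track.depth[330:350].tolist() == [1] * 20
        assert track.spliced_depth[100:130].tolist() == [1] * 30

    def test_empty_input_gives_zero_tracks(self):
        cov = build_coverage([], {"chrI": 100})
        assert cov.total_mass() == 0

    def test_segment_beyond_chromosome_is_fatal(self):
        with pytest.raises(ValueError, match="outside"):
            build_coverage([unspliced("a", 80)], {"chrI": 100})


class TestBuildBlocks:
    def test_overlapping_reads_form_one_block(self):
        params = AssemblyParams(min_reads=1)
        reads = [
            AlignedRead("a", "chrI", "+", ((1, 50),)),
            AlignedRead("b", "chrI", "+", ((30, 80),)),
        ]
        (block,) = build_blocks(reads, params)
        assert (block.start, block.end, block.read_count) == (1, 80, 2)

    def test_short_gap_is_force_joined(self):
        params = AssemblyParams(min_gap_forced_join=20, min_reads=1)
        reads = [
            AlignedRead("a", "chrI", "+", ((1, 50),)),
            AlignedRead("b", "chrI", "+", ((60, 110),)),  # gap 9 < 20
        ]
        (block,) = build_blocks(reads, params)
        assert (block.start, block.end) == (1, 110)

    def test_gap_at_threshold_stays_split(self):
        params = AssemblyParams(min_gap_forced_join=9, min_reads=1)
        reads = [
            AlignedRead("a", "chrI", "+", ((1, 50),)),
            AlignedRead("b", "chrI", "+", ((60, 110),)),  # gap 9, not < 9
        ]
        assert len(build_blocks(reads, params)) == 2

    def test_strands_never_mix(self):
        params = AssemblyParams(min_reads=1)
        reads = [unspliced("a", 1, 50, "+"), unspliced("b", 10, 51, "-")]
        blocks = build_blocks(reads, params)
        assert {b.strand for b in blocks} == {"+", "-"}
        assert len(blocks) == 2

    def test_min_reads_filters_noise_components(self):
        params = AssemblyParams(min_reads=5)
        reads = [unspliced(f"r{i}", 100 + i) for i in range(3)]
        assert build_blocks(reads, params) == []

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_union_oracle(self, seed):
        rng = np.random.default_rng(seed)
        reads = random_reads(rng, int(rng.integers(5, 400)))
        min_gap = int(rng.integers(1, 40))
        min_reads = int(rng.integers(1, 4))
        params = AssemblyParams(min_gap_forced_join=min_gap, min_reads=min_reads)
        got = sorted(
            (b.chrom, b.strand, b.start, b.end, b.read_count)
            for b in build_blocks(reads, params)
        )
        assert got == brute_force_blocks(reads, min_gap, min_reads)

    def test_raising_min_reads_never_adds_blocks(self):
        rng = np.random.default_rng(7)
        reads = random_reads(rng, 300)
        counts = [
            len(build_blocks(reads, AssemblyParams(min_reads=m)))
            for m in (1, 2, 5, 10)
        ]
        assert counts == sorted(counts, reverse=True)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        segs=st.lists(
            st.tuples(st.integers(1, 800), st.integers(10, 60)),
            min_size=1, max_size=60,
        ),
        min_gap=st.integers(1, 50),
    )
    def test_every_read_lands_in_exactly_one_block(self, segs, min_gap):
        """Read conservation: with the noise filter off, each read is
        contained in exactly one block."""
        reads = [unspliced(f"h{i}", s, l) for i, (s, l) in enumerate(segs)]
        params = AssemblyParams(min_gap_forced_join=min_gap, min_reads=1)
        blocks = build_blocks(reads, params)
        for r in reads:
            containing = [
                b for b in blocks if b.start <= r.start and r.end <= b.end
            ]
            assert len(containing) == 1

    def test_blocks_are_pairwise_disjoint(self):
        rng = np.random.default_rng(11)
        reads = random_reads(rng, 500)
        blocks = build_blocks(reads, AssemblyParams(min_reads=1))
        by_track: dict = {}
        for b in blocks:
            by_track.setdefault((b.chrom, b.strand), []).append(b)
        for track_blocks in by_track.values():
            track_blocks.sort(key=lambda b: b.start)
            for left, right in zip(track_blocks, track_blocks[1:]):
                assert left.end < right.start


class TestClassifyBlocks:
    def test_same_strand_overlap_assigns(self, simple_annotation):
        b = Block("chrI", "+", 1050, 1400, 10, 5.0)
        classify_blocks([b], simple_annotation)
        assert b.assigned_genes == ("YAL001C",)

    def test_antisense_overlap_does_not_assign(self, simple_annotation):
        b = Block("chrI", "-", 1050, 1400, 10, 5.0)
        classify_blocks([b], simple_annotation)
        assert b.assigned_genes == ()

    def test_block_spanning_two_genes_lists_both_in_order(self):
        ann = Annotation(
            [GeneModel("A", "chrI", 100, 200, "+"), GeneModel("B", "chrI", 300, 400, "+")]
        )
        b = Block("chrI", "+", 150, 350, 10, 5.0)
        classify_blocks([b], ann)
        assert b.assigned_genes == ("A", "B")


def _gene_blocks(gaps, coverages, gene_id="G1", start=100):
    """Consecutive same-gene blocks with the given inter-block gaps."""
    blocks = []
    pos = start
    for i, cov in enumerate(coverages):
        end = pos + 99
        blocks.append(
            Block("chrI", "+", pos, end, 10, cov, assigned_genes=(gene_id,))
        )
        if i < len(gaps):
            pos = end + 1 + gaps[i]
    return blocks


class TestGapStats:
    def test_sample_mean_and_sd_of_gaps(self):
        blocks = _gene_blocks([10, 20, 30], [5, 5, 5, 5])
        stats = compute_gap_stats(blocks)
        assert stats.n_pairs == 3
        assert stats.grbb_mean == pytest.approx(20.0)
        assert stats.grbb_sd == pytest.approx(10.0)  # sample SD of {10,20,30}

    def test_coverage_ratio_is_min_over_max(self):
        blocks = _gene_blocks([10], [10, 20]) + _gene_blocks([10], [30, 30], "G2", 5000)
        stats = compute_gap_stats(blocks)
        assert stats.crrbb_mean == pytest.approx((0.5 + 1.0) / 2)

    def test_no_multiblock_gene_triggers_fallback(self):
        stats = compute_gap_stats([Block("chrI", "+", 1, 99, 5, 3.0, ("G1",))])
        assert stats.n_pairs == 0
        params = AssemblyParams(min_gap_forced_join=25)
        max_gap, min_ratio = joining_thresholds(stats, params)
        assert max_gap == 125 and min_ratio == 0.5

    def test_pairs_require_a_shared_gene(self):
        blocks = _gene_blocks([10], [5, 5])
        blocks[1].assigned_genes = ("OTHER",)
        assert compute_gap_stats(blocks).n_pairs == 0


class TestJoinIntergenic:
    """Direct applications of the 2-SD rule (one-step hand oracle)."""

    def _setup(self, gap, cand_cov, ref_cov=20.0):
        # learned stats: gaps {10,30} -> mean 20 sd ~14.1 ; ratios {0.9,0.9}
        ann = Annotation([GeneModel("G1", "chrI", 100, 1200, "+"),
                          GeneModel("G2", "chrI", 4000, 5200, "+")])
        blocks = [
            Block("chrI", "+", 100, 500, 10, 20.0, ("G1",)),
            Block("chrI", "+", 511, 800, 10, 18.0, ("G1",)),
            Block("chrI", "+", 831, 1200, 10, 20.0, ("G1",)),
            Block("chrI", "+", 4000, 5200, 10, ref_cov, ("G2",)),
        ]
        cand_start = 5200 + gap + 1
        blocks.append(
            Block("chrI", "+", cand_start, cand_start + 199, 8, cand_cov)
        )
        cov = build_coverage([], {"chrI": 10000})
        # paint depth so merged means are well-defined
        cov[("chrI", "+")].depth[4000:5201] = int(ref_cov)
        cov[("chrI", "+")].depth[cand_start : cand_start + 200] = int(cand_cov)
        return blocks, ann, cov

    def test_qualifying_candidate_is_merged(self):
        blocks, ann, cov = self._setup(gap=15, cand_cov=18.0)
        out = join_intergenic_blocks(blocks, ann, cov, AssemblyParams())
        merged = [b for b in out if "G2" in b.assigned_genes]
        assert len(merged) == 1 and merged[0].end == 5200 + 15 + 200 + 1 - 1
        assert all(b.is_reference_based for b in out)

    def test_distant_candidate_stays_independent(self):
        blocks, ann, cov = self._setup(gap=500, cand_cov=18.0)
        out = join_intergenic_blocks(blocks, ann, cov, AssemblyParams())
        assert any(not b.is_reference_based for b in out)

    def test_dissimilar_coverage_blocks_joining(self):
        blocks, ann, cov = self._setup(gap=15, cand_cov=1.0)
        out = join_intergenic_blocks(blocks, ann, cov, AssemblyParams())
        assert any(not b.is_reference_based for b in out)

    def test_opposite_strand_never_merges(self):
        blocks, ann, cov = self._setup(gap=15, cand_cov=18.0)
        blocks[-1].strand = "-"
        out = join_intergenic_blocks(blocks, ann, cov, AssemblyParams())
        assert any(not b.is_reference_based for b in out)

    def test_fixed_point_and_disjointness(self):
        blocks, ann, cov = self._setup(gap=15, cand_cov=18.0)
        out = join_intergenic_blocks(blocks, ann, cov, AssemblyParams())
        again = join_intergenic_blocks(out, ann, cov, AssemblyParams())
        assert [(b.start, b.end) for b in again] == [(b.start, b.end) for b in out]
        for left, right in zip(out, out[1:]):
            if (left.chrom, left.strand) == (right.chrom, right.strand):
                assert left.end < right.start

    def test_higher_sd_multiplier_never_merges_less(self):
        blocks, ann, cov = self._setup(gap=60, cand_cov=18.0)
        n_strict = len(join_intergenic_blocks(blocks, ann, cov, AssemblyParams(sd_multiplier=1.0)))
        n_loose = len(join_intergenic_blocks(blocks, ann, cov, AssemblyParams(sd_multiplier=4.0)))
        assert n_loose <= n_strict
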