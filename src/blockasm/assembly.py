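"""Strand-specific block construction and adaptive intergenic joining.

The assembler first joins overlapping same-strand read segments into
*blocks*, force-bridging zero-coverage gaps shorter than
``min_gap_forced_join`` and discarding components with fewer than
``min_reads`` reads (background noise). Blocks overlapping a same-strand
annotated gene are *reference-based*; from consecutive reference-based
blocks of the same gene the run learns the gap-size distribution (GRBB +-
SD) and the coverage-ratio distribution (CRRBB +- SD). Unassigned blocks
adjacent to a reference-based block are absorbed when their gap and
coverage ratio fall within ``sd_multiplier`` standard deviations of those
learned distributions; the procedure repeats until a fixed point.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np

from .models import (
    AlignedRead,
    Annotation,
    AssemblyParams,
    Block,
    CoverageSet,
    GapStats,
    build_coverage,
)

__all__ = [
    "build_coverage",
    "build_blocks",
    "classify_blocks",
    "compute_gap_stats",
    "joining_thresholds",
    "join_intergenic_blocks",
]


def build_blocks(
    reads: Iterable[AlignedRead],
    params: AssemblyParams,
    coverage: Optional[CoverageSet] = None,
) -> list[Block]:
    """Join overlapping same-strand read segments into disjoint blocks.

    Two segments belong to one block when they overlap, touch, or are
    separated by a zero-coverage gap strictly shorter than
    ``params.min_gap_forced_join``. Components supported by fewer than
    ``params.min_reads`` distinct reads are dropped. Mean coverage is
    computed over the full block span (internal zero-depth bases included).
    """
    reads = list(reads)
    if coverage is None:
        lengths: dict[str, int] = {}
        for r in reads:
            lengths[r.chrom] = max(lengths.get(r.chrom, 0), r.end)
        coverage = build_coverage(reads, lengths)

    by_key: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for r in reads:
        for s, e in r.segments:
            by_key.setdefault((r.chrom, r.strand), []).append((s, e, r.read_id))

    blocks: list[Block] = []
    for (chrom, strand), segs in sorted(by_key.items()):
        segs.sort()
        track = coverage[(chrom, strand)]
        cur_start, cur_end = segs[0][0], segs[0][1]
        cur_reads = {segs[0][2]}
        for s, e, rid in segs[1:]:
            gap = s - cur_end - 1
            if gap < params.min_gap_forced_join:
                cur_end = max(cur_end, e)
                cur_reads.add(rid)
            else:
                _emit(blocks, chrom, strand, cur_start, cur_end, cur_reads, track, params)
                cur_start, cur_end, cur_reads = s, e, {rid}
        _emit(blocks, chrom, strand, cur_start, cur_end, cur_reads, track, params)
    blocks.sort(key=lambda b: (b.chrom, b.strand, b.start))
    return blocks


def _emit(blocks, chrom, strand, start, end, read_ids, track, params) -> None:
    if len(read_ids) < params.min_reads:
        return
    blocks.append(
        Block(
            chrom=chrom,
            strand=strand,
            start=start,
            end=end,
            read_count=len(read_ids),
            mean_coverage=track.mean_depth(start, end),
        )
    )


def classify_blocks(blocks: Sequence[Block], annotation: Annotation) -> list[Block]:
    """Fill ``assigned_genes`` with same-strand genes overlapping each block.

    A block is reference-based iff it overlaps at least one annotated gene
    on its own strand by at least one base; antisense overlap never assigns.
    """
    for b in blocks:
        genes = annotation.overlapping(b.chrom, b.strand, b.start, b.end)
        b.assigned_genes = tuple(g.gene_id for g in genes)
    return list(blocks)


def compute_gap_stats(blocks: Sequence[Block]) -> GapStats:
    """Learn gap and coverage-ratio statistics from within-gene block pairs.

    Samples are taken over immediately consecutive blocks on the same
    (chrom, strand) that are both reference-based and share at least one
    assigned gene: gap = right.start - left.end - 1 and ratio =
    min/max of the two mean coverages. Means and sample SDs are returned;
    with fewer than two pairs the SDs are 0 and the caller falls back to
    the documented conservative thresholds.
    """
    gaps: list[float] = []
    ratios: list[float] = []
    ordered = sorted(blocks, key=lambda b: (b.chrom, b.strand, b.start))
    for left, right in zip(ordered, ordered[1:]):
        if (left.chrom, left.strand) != (right.chrom, right.strand):
            continue
        if not (left.assigned_genes and right.assigned_genes):
            continue
        if not set(left.assigned_genes) & set(right.assigned_genes):
            continue
        gaps.append(right.start - left.end - 1)
        lo, hi = sorted((left.mean_coverage, right.mean_coverage))
        ratios.append(lo / hi if hi > 0 else 1.0)
    n = len(gaps)
    if n == 0:
        return GapStats(n_pairs=0)
    return GapStats(
        grbb_mean=float(np.mean(gaps)),
        grbb_sd=float(np.std(gaps, ddof=1)) if n >= 2 else 0.0,
        crrbb_mean=float(np.mean(ratios)),
        crrbb_sd=float(np.std(ratios, ddof=1)) if n >= 2 else 0.0,
        n_pairs=n,
    )


def joining_thresholds(
    stats: GapStats, params: AssemblyParams
) -> tuple[float, float]:
    """(max gap, min coverage ratio) for absorbing an intergenic block.

    With learned statistics: gap <= GRBB + k*GRBB-SD and ratio >= CRRBB -
    k*CRRBB-SD (k = ``sd_multiplier``). With fewer than two learned pairs
    the fallback thresholds apply: 5x the forced-join gap and a 0.5 ratio.
    """
    if stats.n_pairs >= 2:
        return (
            stats.grbb_mean + params.sd_multiplier * stats.grbb_sd,
            stats.crrbb_mean - params.sd_multiplier * stats.crrbb_sd,
        )
    return (params.min_gap_forced_join * 5.0, params.fallback_ratio_threshold)


def _pair_gap(left: Block, right: Block) -> int:
    return right.start - left.end - 1


def _pair_ratio(a: Block, b: Block) -> float:
    lo, hi = sorted((a.mean_coverage, b.mean_coverage))
    return lo / hi if hi > 0 else 1.0


def join_intergenic_blocks(
    blocks: Sequence[Block],
    annotation: Annotation,
    coverage: CoverageSet,
    params: AssemblyParams,
) -> list[Block]:
    """Recursively absorb unassigned blocks into adjacent reference-based ones.

    Each pass recomputes the gap statistics on the current block set, then
    scans every unassigned block: it is merged into an immediately adjacent
    same-strand reference-based neighbour when the gap and coverage-ratio
    thresholds of :func:`joining_thresholds` are met. When both neighbours
    qualify, the side with the smaller gap wins (tie: higher coverage
    ratio, then upstream). Merged blocks get recomputed span, coverage,
    read count and gene assignment. Passes repeat until none merges;
    surviving unassigned blocks are candidate novel/ncRNA transcripts.
    """
    current = sorted(blocks, key=lambda b: (b.chrom, b.strand, b.start))
    while True:
        stats = compute_gap_stats(current)
        max_gap, min_ratio = joining_thresholds(stats, params)
        merged_any = False
        result: list[Block] = []
        i = 0
        while i < len(current):
            b = current[i]
            if b.is_reference_based:
                result.append(b)
                i += 1
                continue
            left = result[-1] if result and _same_track(result[-1], b) else None
            right = (
                current[i + 1]
                if i + 1 < len(current) and _same_track(current[i + 1], b)
                else None
            )
            candidates = []
            for neighbour, side in ((left, "left"), (right, "right")):
                if neighbour is None or not neighbour.is_reference_based:
                    continue
                pair = (neighbour, b) if side == "left" else (b, neighbour)
                gap = _pair_gap(*pair)
                ratio = _pair_ratio(neighbour, b)
                if gap <= max_gap and ratio >= min_ratio:
                    candidates.append((gap, -ratio, 0 if side == "left" else 1, neighbour, side))
            if not candidates:
                result.append(b)
                i += 1
                continue
            candidates.sort()
            _, _, _, neighbour, side = candidates[0]
            merged_any = True
            if side == "left":
                result[-1] = _merge(result[-1], b, annotation, coverage)
                i += 1
            else:
                current[i + 1] = _merge(b, current[i + 1], annotation, coverage)
                i += 1  # merged block revisited as current[i+1]
        if not merged_any:
            return result
        current = result


def _same_track(a: Block, b: Block) -> bool:
    return (a.chrom, a.strand) == (b.chrom, b.strand)


def _merge(
    left: Block, right: Block, annotation: Annotation, coverage: CoverageSet
) -> Block:
    chrom, strand = left.chrom, left.strand
    start, end = min(left.start, right.start), max(left.end, right.end)
    track = coverage[(chrom, strand)]
    genes = annotation.overlapping(chrom, strand, start, end)
    return Block(
        chrom=chrom,
        strand=strand,
        start=start,
        end=end,
        read_count=left.read_count + right.read_count,
        mean_coverage=track.mean_depth(start, end),
        assigned_genes=tuple(g.gene_id for g in genes),
    )
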