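"""Transcript finalisation: introns, fragmentation removal, end trimming,
polycistronic validation and UTR measurement."""

from __future__ import annotations

import logging
import math
from collections import Counter
from typing import Iterable, Optional, Sequence

import numpy as np

from .models import (
    AlignedRead,
    Annotation,
    AssemblyParams,
    Block,
    CoverageSet,
    IntronCall,
    Transcript,
)

logger = logging.getLogger(__name__)


def detect_introns(
    reads: Iterable[AlignedRead],
    coverage: CoverageSet,
    params: AssemblyParams,
) -> list[IntronCall]:
    """Call introns from identical spliced-read junctions.

    Junctions are grouped by exact (chrom, strand, donor, acceptor);
    support is the number of spliced reads sharing the junction. The
    boundary unspliced depth is the mean unspliced depth at the two
    flanking exonic bases (donor-1, acceptor+1). A junction is accepted
    when support / boundary >= ``params.intron_ratio``; a zero boundary
    with positive support has no unspliced competition and is accepted
    with an infinite ratio.
    """
    support: Counter[tuple[str, str, int, int]] = Counter()
    for r in reads:
        if not r.spliced:
            continue
        for donor, acceptor in r.junctions():
            support[(r.chrom, r.strand, donor, acceptor)] += 1

    calls: list[IntronCall] = []
    for (chrom, strand, donor, acceptor), n in sorted(support.items()):
        track = coverage[(chrom, strand)]
        unspliced = track.unspliced()
        flanks = [p for p in (donor - 1, acceptor + 1) if 1 <= p <= track.chrom_length]
        boundary = float(np.mean([unspliced[p] for p in flanks])) if flanks else 0.0
        ratio = n / boundary if boundary > 0 else math.inf
        calls.append(
            IntronCall(
                chrom=chrom,
                strand=strand,
                donor=donor,
                acceptor=acceptor,
                spliced_support=n,
                boundary_unspliced=boundary,
                ratio=ratio,
                accepted=ratio >= params.intron_ratio,
            )
        )
    return calls


def _exonic_mean(
    coverage: CoverageSet,
    chrom: str,
    strand: str,
    start: int,
    end: int,
    introns: Sequence[tuple[int, int]],
) -> float:
    """Mean depth over [start, end] excluding intronic bases."""
    depth = coverage[(chrom, strand)].depth
    mask = np.ones(end - start + 1, dtype=bool)
    for d, a in introns:
        lo, hi = max(d, start), min(a, end)
        if lo <= hi:
            mask[lo - start : hi - start + 1] = False
    if not mask.any():
        return 0.0
    return float(depth[start : end + 1][mask].mean())


def _contained_introns(
    introns: Iterable[IntronCall] | Iterable[tuple[int, int]],
    chrom: str,
    strand: str,
    start: int,
    end: int,
) -> tuple[tuple[int, int], ...]:
    spans = []
    for it in introns:
        if isinstance(it, IntronCall):
            if not it.accepted or (it.chrom, it.strand) != (chrom, strand):
                continue
            d, a = it.donor, it.acceptor
        else:
            d, a = it
        if start < d and a < end:
            spans.append((d, a))
    return tuple(sorted(spans))


def merge_within_gene(
    blocks: Sequence[Block],
    introns: Sequence[IntronCall],
    annotation: Annotation,
    coverage: CoverageSet,
) -> list[Transcript]:
    """Merge consecutive same-gene blocks into draft transcripts.

    Fragmentation inside a gene comes from sequencing-bias coverage gaps;
    consecutive blocks assigned to a shared gene are merged across their
    gap. When an accepted intron falls inside the draft it is recorded and
    excluded from the exonic mean coverage. Surviving unassigned blocks
    become drafts with no covered genes (candidate ncRNA transcripts).
    """
    ordered = sorted(blocks, key=lambda b: (b.chrom, b.strand, b.start))
    drafts: list[Transcript] = []
    chain: list[Block] = []

    def flush() -> None:
        if not chain:
            return
        chrom, strand = chain[0].chrom, chain[0].strand
        start, end = chain[0].start, chain[-1].end
        genes = annotation.overlapping(chrom, strand, start, end)
        covered = tuple(g.gene_id for g in genes)
        spans = _contained_introns(introns, chrom, strand, start, end)
        drafts.append(
            Transcript(
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                mean_coverage=_exonic_mean(coverage, chrom, strand, start, end, spans),
                covered_genes=covered,
                introns=spans,
                polycistronic_status="candidate" if len(covered) >= 2 else "monocistronic",
            )
        )
        chain.clear()

    chain_genes: set[str] = set()
    for b in ordered:
        if not b.is_reference_based:
            flush()
            chain_genes = set()
            spans = _contained_introns(introns, b.chrom, b.strand, b.start, b.end)
            drafts.append(
                Transcript(
                    chrom=b.chrom,
                    strand=b.strand,
                    start=b.start,
                    end=b.end,
                    mean_coverage=_exonic_mean(
                        coverage, b.chrom, b.strand, b.start, b.end, spans
                    ),
                    introns=spans,
                )
            )
            continue
        if chain and (
            (chain[-1].chrom, chain[-1].strand) != (b.chrom, b.strand)
            or not chain_genes & set(b.assigned_genes)
        ):
            flush()
            chain_genes = set()
        chain.append(b)
        chain_genes |= set(b.assigned_genes)
    flush()
    drafts.sort(key=lambda t: (t.chrom, t.strand, t.start))
    return drafts


def trim_ends(
    draft: Transcript, coverage: CoverageSet, params: AssemblyParams
) -> Optional[Transcript]:
    """Trim low-coverage terminal tails of high-coverage transcripts.

    Only transcripts with mean coverage above
    ``params.high_coverage_threshold`` are touched: each end advances
    inward while the raw per-base depth is <= ``params.trim_depth``.
    Returns None (with a warning) when trimming consumes the whole span.
    Idempotent: the surviving terminal bases have depth above the cutoff.
    """
    if draft.mean_coverage <= params.high_coverage_threshold:
        return draft
    depth = coverage[(draft.chrom, draft.strand)].depth
    start, end = draft.start, draft.end
    while start <= end and depth[start] <= params.trim_depth:
        start += 1
    while end >= start and depth[end] <= params.trim_depth:
        end -= 1
    if start > end:
        logger.warning(
            "transcript %s:%d-%d(%s) entirely at depth <= %d; dropped",
            draft.chrom, draft.start, draft.end, draft.strand, params.trim_depth,
        )
        return None
    if (start, end) == (draft.start, draft.end):
        return draft
    spans = tuple((d, a) for d, a in draft.introns if start < d and a < end)
    return draft.replace(
        start=start,
        end=end,
        introns=spans,
        mean_coverage=_exonic_mean(
            coverage, draft.chrom, draft.strand, start, end, spans
        ),
    )


def validate_polycistronic(
    draft: Transcript,
    annotation: Annotation,
    coverage: CoverageSet,
    params: AssemblyParams,
) -> tuple[str, list[Transcript]]:
    """Check whether a multi-gene draft is a real polycistronic transcript.

    For every adjacent covered gene pair the inter-gene interval must have
    (a) no zero-depth base, (b) mean intergenic depth >= ``t_intergenic``
    of the shallower gene's mean depth, and (c) gene mean-depth ratio
    (min/max) >= ``t_genes``. If all pairs pass the draft is validated;
    otherwise it is rejected and split at the deepest (minimum-depth)
    intergenic base of the first failing pair, and the products are
    validated recursively. Returns (status of the input draft, final
    transcripts). Splitting conserves the covered-gene multiset.
    """
    if len(draft.covered_genes) < 2:
        return "monocistronic", [draft.replace(polycistronic_status="monocistronic")]
    depth = coverage[(draft.chrom, draft.strand)].depth
    genes = sorted(
        (annotation.by_id[g] for g in draft.covered_genes), key=lambda g: g.start
    )
    gene_means = {
        g.gene_id: float(depth[g.start : g.end + 1].mean()) for g in genes
    }
    for g1, g2 in zip(genes, genes[1:]):
        lo, hi = g1.end + 1, g2.start - 1
        if lo > hi:
            continue  # touching/overlapping genes: nothing to test between them
        inter = depth[lo : hi + 1]
        m1, m2 = gene_means[g1.gene_id], gene_means[g2.gene_id]
        min_depth = int(inter.min())
        ratio_intergenic = (
            float(inter.mean()) / min(m1, m2) if min(m1, m2) > 0 else 0.0
        )
        ratio_genes = min(m1, m2) / max(m1, m2) if max(m1, m2) > 0 else 0.0
        if (
            min_depth > 0
            and ratio_intergenic >= params.t_intergenic
            and ratio_genes >= params.t_genes
        ):
            continue
        split_at = lo + int(np.argmin(inter))
        products: list[Transcript] = []
        for s, e in ((draft.start, split_at - 1), (split_at + 1, draft.end)):
            if s > e:
                continue
            part_genes = tuple(
                g.gene_id for g in genes if s <= g.start and g.end <= e
            ) or tuple(
                g.gene_id for g in genes if not (g.end < s or g.start > e)
            )
            spans = tuple((d, a) for d, a in draft.introns if s < d and a < e)
            part = draft.replace(
                start=s,
                end=e,
                covered_genes=part_genes,
                introns=spans,
                mean_coverage=_exonic_mean(
                    coverage, draft.chrom, draft.strand, s, e, spans
                ),
            )
            products.extend(
                validate_polycistronic(part, annotation, coverage, params)[1]
            )
        return "rejected", products
    return "validated", [draft.replace(polycistronic_status="validated")]


def compute_utrs(
    t: Transcript, annotation: Annotation
) -> tuple[Optional[int], Optional[int]]:
    """Signed UTR lengths against the 5'-most / 3'-most covered genes.

    On '+' the 5'-UTR runs from the transcript start to the first gene's
    start; on '-' the orientation flips, so the 5'-UTR sits at the right
    (genomic end) of the span. Negative lengths flag transcripts truncated
    relative to the annotation. Undefined (None, None) without covered
    genes.
    """
    if not t.covered_genes:
        return None, None
    genes = sorted((annotation.by_id[g] for g in t.covered_genes), key=lambda g: g.start)
    first, last = genes[0], genes[-1]
    if t.strand == "+":
        return first.start - t.start, t.end - last.end
    return t.end - last.end, first.start - t.start
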