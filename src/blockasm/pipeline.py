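"""End-to-end assembly: reads + annotation -> classified transcripts."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .assembly import (
    build_blocks,
    build_coverage,
    classify_blocks,
    compute_gap_stats,
    join_intergenic_blocks,
)
from .classify import classify_transcript
from .models import (
    AlignedRead,
    Annotation,
    AssemblyParams,
    Block,
    CoverageSet,
    GapStats,
    IntronCall,
    Transcript,
)
from .refine import (
    compute_utrs,
    detect_introns,
    merge_within_gene,
    trim_ends,
    validate_polycistronic,
)


@dataclass
class AssemblyResult:
    transcripts: list[Transcript]
    coverage: CoverageSet
    blocks: list[Block]
    gap_stats: GapStats
    introns: list[IntronCall] = field(default_factory=list)


def assemble(
    reads: Sequence[AlignedRead],
    annotation: Annotation,
    chrom_lengths: dict[str, int],
    params: Optional[AssemblyParams] = None,
) -> AssemblyResult:
    """Run the full assembly on in-memory reads.

    Stages: per-strand coverage; block building with forced joining and
    the noise filter; block classification against the annotation;
    adaptive joining of intergenic blocks (2-SD rule, iterated to a fixed
    point); intron calling from spliced reads; within-gene fragmentation
    removal; optional end trimming of high-coverage transcripts;
    polycistronic validation (splitting false fusions); UTR measurement;
    and class assignment.
    """
    params = params or AssemblyParams()
    coverage = build_coverage(reads, chrom_lengths)
    blocks = build_blocks(reads, params, coverage)
    blocks = classify_blocks(blocks, annotation)
    blocks = join_intergenic_blocks(blocks, annotation, coverage, params)
    gap_stats = compute_gap_stats(blocks)
    introns = detect_introns(reads, coverage, params)
    drafts = merge_within_gene(blocks, introns, annotation, coverage)

    if params.trim_enabled:
        drafts = [t for t in (trim_ends(d, coverage, params) for d in drafts) if t]

    finalized: list[Transcript] = []
    for d in drafts:
        _, products = validate_polycistronic(d, annotation, coverage, params)
        finalized.extend(products)

    accepted_spans = [
        (t.chrom, t.strand, d, a) for t in finalized for d, a in t.introns
    ]
    out: list[Transcript] = []
    for t in finalized:
        utr5, utr3 = compute_utrs(t, annotation)
        t = t.replace(utr5_len=utr5, utr3_len=utr3)
        out.append(classify_transcript(t, annotation, accepted_spans, params))

    out.sort(key=lambda t: (t.chrom, t.start, t.strand))
    for i, t in enumerate(out, start=1):
        t.transcript_id = f"T{i:06d}"
    return AssemblyResult(
        transcripts=out,
        coverage=coverage,
        blocks=blocks,
        gap_stats=gap_stats,
        introns=introns,
    )
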