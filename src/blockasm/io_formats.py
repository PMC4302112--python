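"""Alignment and annotation input, transcript GFF and coverage-track output.

The transcript GFF dialect places the covered gene ID(s) in column 9 for
coding transcripts, ``ncRNA_anti_<geneID>`` for antisense non-coding
transcripts (SAUT) and ``ncRNAs_<closestGeneID>`` for intergenic ones
(SUT), with transcript length and mean coverage as ``note=`` entries.
Coverage tracks are plain one-integer-per-line files (Artemis userplot
convention), one file per chromosome and strand.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam
from gffutils.feature import feature_from_line

from .models import (
    CLASS_INTRONIC_NCRNA,
    CLASS_SAUT,
    CLASS_SUT,
    OTHER_NCRNA,
    PROTEIN_CODING,
    TRNA,
    AlignedRead,
    Annotation,
    CoverageSet,
    GeneModel,
    Transcript,
)

logger = logging.getLogger(__name__)

# GFF feature types accepted as gene-level records, with their class
_NCRNA_TYPES = {
    "ncRNA", "ncRNA_gene", "snoRNA", "snoRNA_gene", "snRNA", "snRNA_gene",
    "rRNA", "rRNA_gene",
}
_TRNA_TYPES = {"tRNA", "tRNA_gene"}
_GENE_TYPES = {"gene"} | _TRNA_TYPES | _NCRNA_TYPES


def read_alignments(
    path: str | os.PathLike,
    max_spliced_distance: int = 1000,
    deletion_gap_threshold: int = 10,
    valid_chroms: Optional[set[str]] = None,
) -> list[AlignedRead]:
    """Load uniquely mapped primary single-end alignments as AlignedReads.

    Reference skips (CIGAR N) longer than ``deletion_gap_threshold`` split
    the alignment into segments (spliced read); shorter skips and deletions
    are absorbed into the surrounding segment. Reads with any inter-segment
    gap above ``max_spliced_distance`` are discarded, as are unmapped,
    secondary, supplementary and multi-mapped (NH>1) records. Alignments on
    chromosomes outside ``valid_chroms`` (when given) are skipped with a
    warning.
    """
    reads: list[AlignedRead] = []
    skipped_chroms: set[str] = set()
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.has_tag("NH") and aln.get_tag("NH") > 1:
                continue
            chrom = aln.reference_name
            if valid_chroms is not None and chrom not in valid_chroms:
                if chrom not in skipped_chroms:
                    logger.warning(
                        "alignment chromosome %r absent from annotation; skipping",
                        chrom,
                    )
                    skipped_chroms.add(chrom)
                continue
            segments = _cigar_segments(
                aln.reference_start + 1, aln.cigartuples, deletion_gap_threshold
            )
            if segments is None:
                continue
            if any(
                s2 - e1 - 1 > max_spliced_distance
                for (_, e1), (s2, _) in zip(segments, segments[1:])
            ):
                continue
            reads.append(
                AlignedRead(
                    read_id=aln.query_name,
                    chrom=chrom,
                    strand="-" if aln.is_reverse else "+",
                    segments=tuple(segments),
                )
            )
    return reads


def _cigar_segments(
    pos: int,
    cigartuples: Optional[Sequence[tuple[int, int]]],
    deletion_gap_threshold: int,
) -> Optional[list[tuple[int, int]]]:
    """1-based inclusive reference segments from a CIGAR, splitting at long N."""
    if not cigartuples:
        return None
    segments: list[tuple[int, int]] = []
    seg_start = pos
    cursor = pos  # next reference base to consume
    for op, length in cigartuples:
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference within a segment
            cursor += length
        elif op == 3:  # N: reference skip
            if length <= deletion_gap_threshold:
                cursor += length  # alignment artifact, not an intron
            else:
                segments.append((seg_start, cursor - 1))
                cursor += length
                seg_start = cursor
        # I, S, H, P do not consume reference
    if cursor > seg_start:
        segments.append((seg_start, cursor - 1))
    return segments or None


def _feature_class(featuretype: str, attributes) -> str:
    if featuretype in _TRNA_TYPES:
        return TRNA
    if featuretype in _NCRNA_TYPES:
        return OTHER_NCRNA
    biotype = (attributes.get("biotype") or attributes.get("gene_biotype") or [None])[0]
    if biotype is None or biotype == "protein_coding":
        return PROTEIN_CODING
    if "tRNA" in biotype:
        return TRNA
    return OTHER_NCRNA


def read_annotation(path: str | os.PathLike) -> Annotation:
    """Parse gene-level features of a GFF3 file into an indexed Annotation.

    Missing ID attributes, duplicate IDs and end < start are fatal parse
    errors naming the offending line.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF columns")
            if fields[2] not in _GENE_TYPES:
                continue
            feat = feature_from_line(line)
            if "ID" not in feat.attributes:
                raise ValueError(f"{path}:{lineno}: gene feature lacks ID attribute")
            gene_id = feat.attributes["ID"][0]
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            if feat.end < feat.start:
                raise ValueError(f"{path}:{lineno}: end {feat.end} < start {feat.start}")
            name = feat.attributes.get("Name") or feat.attributes.get("gene")
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand,
                    feature_class=_feature_class(feat.featuretype, feat.attributes),
                    standard_name=name[0] if name else None,
                )
            )
    return Annotation(genes)


# ---------------------------------------------------------------------------
# transcript GFF dialect
# ---------------------------------------------------------------------------

_SOURCE = "blockasm"


def _gene_attribute(t: Transcript) -> str:
    if t.class_label == CLASS_SAUT:
        return f"ncRNA_anti_{t.attribute_gene}"
    if t.class_label in (CLASS_SUT, CLASS_INTRONIC_NCRNA):
        return f"ncRNAs_{t.attribute_gene}"
    return ",".join(t.covered_genes)


def transcript_to_gff_line(t: Transcript) -> str:
    attrs = [f"ID={t.transcript_id}", f"gene={_gene_attribute(t)}"]
    attrs.append(f"class={t.class_label}")
    attrs.append(f"status={t.polycistronic_status}")
    if t.utr5_len is not None:
        attrs.append(f"utr5={t.utr5_len}")
    if t.utr3_len is not None:
        attrs.append(f"utr3={t.utr3_len}")
    if t.introns:
        attrs.append("introns=" + ",".join(f"{d}-{a}" for d, a in t.introns))
    if t.antisense_genes:
        attrs.append("antisense=" + ",".join(t.antisense_genes))
    attrs.append(f"note=length {t.length},coverage {t.mean_coverage:.3f}")
    cols = [
        t.chrom,
        _SOURCE,
        "transcript",
        str(t.start),
        str(t.end),
        ".",
        t.strand,
        ".",
        ";".join(attrs),
    ]
    return "\t".join(cols)


def write_transcripts_gff(
    transcripts: Iterable[Transcript], path: str | os.PathLike
) -> None:
    """Write finalized transcripts in the assembler's GFF3 dialect."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            fh.write(transcript_to_gff_line(t) + "\n")


def read_transcripts_gff(path: str | os.PathLike) -> list[Transcript]:
    """Re-read a transcript GFF written by :func:`write_transcripts_gff`."""
    transcripts: list[Transcript] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = feature_from_line(line)
            attrs = feat.attributes
            label = attrs["class"][0]
            # gffutils splits comma-separated attribute values into lists
            gene_field = ",".join(attrs["gene"]) if "gene" in attrs else ""
            covered: tuple[str, ...] = ()
            attribute_gene = None
            if label == CLASS_SAUT:
                attribute_gene = gene_field.removeprefix("ncRNA_anti_")
            elif label in (CLASS_SUT, CLASS_INTRONIC_NCRNA):
                attribute_gene = gene_field.removeprefix("ncRNAs_")
            elif gene_field:
                covered = tuple(gene_field.split(","))
            note = ",".join(attrs["note"])
            coverage = float(note.split("coverage ")[1])
            introns: tuple[tuple[int, int], ...] = ()
            if "introns" in attrs:
                introns = tuple(
                    (int(d), int(a))
                    for d, a in (x.split("-") for x in attrs["introns"])
                )
            transcripts.append(
                Transcript(
                    chrom=feat.seqid,
                    strand=feat.strand,
                    start=feat.start,
                    end=feat.end,
                    mean_coverage=coverage,
                    covered_genes=covered,
                    introns=introns,
                    utr5_len=int(attrs["utr5"][0]) if "utr5" in attrs else None,
                    utr3_len=int(attrs["utr3"][0]) if "utr3" in attrs else None,
                    class_label=label,
                    polycistronic_status=attrs["status"][0],
                    antisense_genes=tuple(attrs["antisense"])
                    if "antisense" in attrs
                    else (),
                    attribute_gene=attribute_gene,
                    transcript_id=attrs["ID"][0],
                )
            )
    return transcripts


def write_coverage_tracks(
    cov: CoverageSet, out_dir: str | os.PathLike
) -> list[Path]:
    """Dump one plain-text per-base depth file per (chromosome, strand).

    Line k holds the total depth at position k (userplot convention for
    genome-browser inspection); 2 x n_chromosomes files are produced.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for (chrom, strand), track in sorted(cov.tracks.items()):
        suffix = "plus" if strand == "+" else "minus"
        path = out_dir / f"{chrom}.{suffix}.userplot"
        np.savetxt(path, track.depth[1:], fmt="%d")
        paths.append(path)
    return paths
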