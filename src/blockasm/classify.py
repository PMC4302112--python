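"""Transcript class assignment (six classes) and per-class summaries.

Classes: protein_coding, SAUT (stable antisense untranslated transcript,
non-coding and antisense to a protein-coding gene), SUT (stable
untranslated transcript in an intergenic region), tRNA, other_ncRNA
(snoRNA/snRNA-type genes) and intronic_ncRNA.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import (
    CLASS_INTRONIC_NCRNA,
    CLASS_OTHER_NCRNA,
    CLASS_PROTEIN_CODING,
    CLASS_SAUT,
    CLASS_SUT,
    CLASS_TRNA,
    PROTEIN_CODING,
    TRNA,
    TRANSCRIPT_CLASSES,
    Annotation,
    AssemblyParams,
    Transcript,
)

_FEATURE_TO_CLASS = {
    PROTEIN_CODING: CLASS_PROTEIN_CODING,
    TRNA: CLASS_TRNA,
}


def _antisense_overlap(t: Transcript, annotation: Annotation) -> tuple[int, list]:
    """Bases of t overlapped by opposite-strand protein-coding genes."""
    opposite = "-" if t.strand == "+" else "+"
    genes = [
        g
        for g in annotation.overlapping(t.chrom, opposite, t.start, t.end)
        if g.feature_class == PROTEIN_CODING
    ]
    covered = np.zeros(t.length, dtype=bool)
    for g in genes:
        lo, hi = max(g.start, t.start), min(g.end, t.end)
        covered[lo - t.start : hi - t.start + 1] = True
    return int(covered.sum()), genes


def classify_transcript(
    t: Transcript,
    annotation: Annotation,
    sibling_introns: Sequence[tuple[str, str, int, int]] = (),
    params: Optional[AssemblyParams] = None,
) -> Transcript:
    """Assign one of the six transcript classes (decision cascade).

    1. Covering >=1 same-strand annotated gene: the label follows the
       genes' feature class (protein_coding > tRNA > other_ncRNA).
    2. Else, a strict majority of the span antisense to protein-coding
       genes makes it a SAUT (named after the most-overlapped gene).
    3. Else, lying entirely inside an accepted intron of a same-strand
       transcript makes it an intronic ncRNA.
    4. Else it is a SUT, named after the closest annotated gene on either
       strand.

    ``sibling_introns`` are (chrom, strand, donor, acceptor) tuples of all
    accepted introns in the run, used by rule 3.
    """
    params = params or AssemblyParams()
    if t.covered_genes:
        classes = {annotation.by_id[g].feature_class for g in t.covered_genes}
        if PROTEIN_CODING in classes:
            label = CLASS_PROTEIN_CODING
        elif TRNA in classes:
            label = CLASS_TRNA
        else:
            label = CLASS_OTHER_NCRNA
        return t.replace(class_label=label)

    overlap, anti_genes = _antisense_overlap(t, annotation)
    if overlap > params.antisense_fraction * t.length:
        best = max(
            anti_genes,
            key=lambda g: (min(g.end, t.end) - max(g.start, t.start), g.gene_id),
        )
        return t.replace(
            class_label=CLASS_SAUT,
            antisense_genes=tuple(g.gene_id for g in anti_genes),
            attribute_gene=best.gene_id,
        )

    for chrom, strand, donor, acceptor in sibling_introns:
        if (chrom, strand) == (t.chrom, t.strand) and donor <= t.start and t.end <= acceptor:
            closest = annotation.closest_gene(t.chrom, t.start, t.end, t.strand)
            return t.replace(
                class_label=CLASS_INTRONIC_NCRNA,
                attribute_gene=closest.gene_id if closest else None,
            )

    closest = annotation.closest_gene(t.chrom, t.start, t.end, t.strand)
    return t.replace(
        class_label=CLASS_SUT,
        attribute_gene=closest.gene_id if closest else None,
    )


def class_summary(transcripts: Sequence[Transcript]) -> pd.DataFrame:
    """Per-class counts and coverage/length quartiles.

    Rows follow the fixed six-class order; empty classes report count 0
    and zero quartiles so the table shape is input-independent.
    """
    rows = []
    for label in TRANSCRIPT_CLASSES:
        members = [t for t in transcripts if t.class_label == label]
        if members:
            cov = np.array([t.mean_coverage for t in members])
            lengths = np.array([t.length for t in members])
            q = lambda a, p: float(np.percentile(a, p))
            rows.append(
                {
                    "class": label,
                    "count": len(members),
                    "coverage_q25": q(cov, 25),
                    "coverage_median": q(cov, 50),
                    "coverage_q75": q(cov, 75),
                    "length_q25": q(lengths, 25),
                    "length_median": q(lengths, 50),
                    "length_q75": q(lengths, 75),
                }
            )
        else:
            rows.append(
                {
                    "class": label,
                    "count": 0,
                    "coverage_q25": 0.0,
                    "coverage_median": 0.0,
                    "coverage_q75": 0.0,
                    "length_q25": 0.0,
                    "length_median": 0.0,
                    "length_q75": 0.0,
                }
            )
    return pd.DataFrame(rows).set_index("class")


def write_class_summary(transcripts: Sequence[Transcript], path) -> None:
    class_summary(transcripts).to_csv(path, sep="\t")
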