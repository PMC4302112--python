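"""Synthetic genomes, truth transcriptomes and strand-specific reads.

The generator emulates the salient properties of short-read strand-specific
RNA-seq of intron-poor genomes: ~50-base single-end reads, non-uniform
coverage with start-site hotspots, short zero-coverage dropouts inside gene
bodies, uniform low-rate background reads, and the loss of reads
overlapping the poly-A tail (which truncates the observed 3' end by up to
one read length). Every stage of the assembler can thus be tested against
a known truth without external data.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .models import (
    CLASS_PROTEIN_CODING,
    CLASS_SAUT,
    CLASS_SUT,
    CLASS_TRNA,
    OTHER_NCRNA,
    PROTEIN_CODING,
    TRNA,
    AlignedRead,
    GeneModel,
)

logger = logging.getLogger(__name__)


@dataclass
class TruthTranscript:
    """A ground-truth transcription unit the read simulator expresses."""

    chrom: str
    strand: str
    start: int
    end: int
    gene_ids: tuple[str, ...] = ()
    utr5: Optional[int] = None
    utr3: Optional[int] = None
    introns: tuple[tuple[int, int], ...] = ()
    class_label: str = CLASS_PROTEIN_CODING
    antisense_of: Optional[str] = None
    depth: Optional[float] = None  # overrides the SimParams depth model

    @property
    def exons(self) -> list[tuple[int, int]]:
        exons, pos = [], self.start
        for d, a in sorted(self.introns):
            exons.append((pos, d - 1))
            pos = a + 1
        exons.append((pos, self.end))
        return exons

    @property
    def mature_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass
class SimTruth:
    """A toy genome: chromosome sizes, gene models and truth transcripts."""

    chrom_lengths: dict[str, int]
    genes: list[GeneModel]
    transcripts: list[TruthTranscript]
    bicistronic_pairs: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0


@dataclass
class SimParams:
    """Read-simulation conditions.

    ``mean_depth`` with ``depth_sigma`` = 0 gives every transcript the same
    target depth; sigma > 0 draws per-transcript depths log-normally around
    the mean. Hotspots concentrate a fraction of read starts into narrow
    preferred windows; ``gap_count`` windows of ``gap_length_range`` bases
    are zeroed inside each gene body; ``noise_rate_per_kb`` plants
    uniform background reads genome-wide on random strands; ``polyA_loss``
    removes every read overlapping a transcript's 3'-terminal
    ``read_length`` bases, as sequencer pipelines that discard poly-A
    spanning reads do. Antisense (SAUT) truth transcripts are expressed at
    ``antisense_depth_factor`` of the model depth, reflecting their lower
    abundance.
    """

    read_length: int = 50
    mean_depth: float = 30.0
    depth_sigma: float = 0.0
    hotspot_count: int = 0
    hotspot_width: int = 100
    hotspot_weight: float = 0.0
    gap_count: int = 0
    gap_length_range: tuple[int, int] = (8, 15)
    gap_windows: tuple[tuple[int, int], ...] = ()
    noise_rate_per_kb: float = 0.0
    polyA_loss: bool = False
    antisense_depth_factor: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        for name in ("mean_depth", "hotspot_weight", "noise_rate_per_kb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def make_toy_genome(
    n_genes: int,
    include: Iterable[str] = (),
    seed: int = 0,
    *,
    chrom: str = "chrI",
    utr5_range: tuple[int, int] = (20, 200),
    utr3_range: tuple[int, int] = (50, 250),
    gene_length_range: tuple[int, int] = (500, 2000),
    intergenic_range: tuple[int, int] = (400, 900),
    utr5_shift: Optional[Mapping[int, int]] = None,
    antisense_gene_indices: Optional[Sequence[int]] = None,
    intron_gene_indices: Optional[Sequence[int]] = None,
    intergenic_nc_after: Optional[Sequence[int]] = None,
) -> SimTruth:
    """Place non-overlapping genes with hidden truth UTRs on one chromosome.

    The returned annotation covers gene spans only (no UTRs), so UTR
    recovery by the assembler is a genuine test. ``include`` may contain
    ``introns``, ``antisense_ncRNAs``, ``intergenic_ncRNAs``,
    ``bicistronic_pair`` and ``tRNAs``; the ``*_indices`` arguments pin the
    affected genes (defaults pick a deterministic subset). ``utr5_shift``
    adds extra 5'-UTR bases at selected gene indices, the handle used to
    build strain pairs with known UTR differences. Deterministic for a
    fixed seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    include = set(include)
    rng = np.random.default_rng(seed)
    rng_extra = np.random.default_rng((seed + 1_000_003) % 2**31)
    utr5_shift = dict(utr5_shift or {})

    if "introns" in include and intron_gene_indices is None:
        intron_gene_indices = list(range(0, n_genes, 5))
    intron_idx = set(intron_gene_indices or [])
    if "antisense_ncRNAs" in include and antisense_gene_indices is None:
        antisense_gene_indices = list(range(0, n_genes, 4))
    anti_idx = set(antisense_gene_indices or [])
    if "intergenic_ncRNAs" in include and intergenic_nc_after is None:
        intergenic_nc_after = list(range(1, n_genes, 5))
    sut_idx = set(intergenic_nc_after or [])

    genes: list[GeneModel] = []
    transcripts: list[TruthTranscript] = []
    cursor = 600
    for i in range(n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        glen = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
        utr5 = int(rng.integers(utr5_range[0], utr5_range[1] + 1)) + utr5_shift.get(i, 0)
        utr3 = int(rng.integers(utr3_range[0], utr3_range[1] + 1))
        left = utr5 if strand == "+" else utr3
        right = utr3 if strand == "+" else utr5
        t_start = cursor
        g_start = t_start + left
        g_end = g_start + glen - 1
        t_end = g_end + right
        gid = f"G{i:04d}"
        genes.append(GeneModel(gid, chrom, g_start, g_end, strand))

        introns: tuple[tuple[int, int], ...] = ()
        if i in intron_idx:
            ilen = int(rng.integers(100, min(400, glen // 3) + 1))
            donor = g_start + glen // 3
            introns = ((donor, donor + ilen - 1),)
        transcripts.append(
            TruthTranscript(
                chrom=chrom, strand=strand, start=t_start, end=t_end,
                gene_ids=(gid,), utr5=utr5, utr3=utr3, introns=introns,
                class_label=CLASS_PROTEIN_CODING,
            )
        )
        if i in anti_idx:
            a_len = max(200, int(glen * 0.5))
            a_start = g_start + max(20, glen // 5)
            a_end = min(a_start + a_len - 1, g_end - 20)
            transcripts.append(
                TruthTranscript(
                    chrom=chrom, strand="-" if strand == "+" else "+",
                    start=a_start, end=a_end,
                    class_label=CLASS_SAUT, antisense_of=gid,
                )
            )
        cursor = t_end + int(rng.integers(intergenic_range[0], intergenic_range[1] + 1))
        if i in sut_idx:
            n_len = int(rng_extra.integers(300, 601))
            n_start = cursor + 150
            transcripts.append(
                TruthTranscript(
                    chrom=chrom,
                    strand="+" if rng_extra.random() < 0.5 else "-",
                    start=n_start, end=n_start + n_len - 1,
                    class_label=CLASS_SUT,
                )
            )
            cursor = n_start + n_len + 300

    bicistronic_pairs: list[tuple[str, str]] = []
    if "bicistronic_pair" in include:
        utr5 = int(rng.integers(*utr5_range))
        utr3 = int(rng.integers(*utr3_range))
        len1 = int(rng.integers(500, 1200))
        len2 = int(rng.integers(500, 1200))
        t_start = cursor
        g1s = t_start + utr5
        g1e = g1s + len1 - 1
        g2s = g1e + 81  # 80-base transcribed inter-gene gap
        g2e = g2s + len2 - 1
        t_end = g2e + utr3
        id1, id2 = f"G{n_genes:04d}", f"G{n_genes + 1:04d}"
        genes.append(GeneModel(id1, chrom, g1s, g1e, "+"))
        genes.append(GeneModel(id2, chrom, g2s, g2e, "+"))
        transcripts.append(
            TruthTranscript(
                chrom=chrom, strand="+", start=t_start, end=t_end,
                gene_ids=(id1, id2), utr5=utr5, utr3=utr3,
                class_label=CLASS_PROTEIN_CODING,
            )
        )
        bicistronic_pairs.append((id1, id2))
        cursor = t_end + 600

    if "tRNAs" in include:
        for j in range(2):
            t_start = cursor
            t_end = t_start + 74
            gid = f"T{j:04d}"
            genes.append(GeneModel(gid, chrom, t_start, t_end, "+", feature_class=TRNA))
            transcripts.append(
                TruthTranscript(
                    chrom=chrom, strand="+", start=t_start, end=t_end,
                    gene_ids=(gid,), utr5=0, utr3=0, class_label=CLASS_TRNA,
                )
            )
            cursor = t_end + 400

    return SimTruth(
        chrom_lengths={chrom: cursor + 600},
        genes=genes,
        transcripts=transcripts,
        bicistronic_pairs=bicistronic_pairs,
        seed=seed,
    )


def _mature_to_genomic(
    exons: Sequence[tuple[int, int]], m_start: int, length: int
) -> tuple[tuple[int, int], ...]:
    """Map a mature-coordinate interval onto genomic exon segments."""
    segments: list[tuple[int, int]] = []
    remaining = length
    offset = m_start
    for s, e in exons:
        exon_len = e - s + 1
        if offset >= exon_len:
            offset -= exon_len
            continue
        take = min(remaining, exon_len - offset)
        segments.append((s + offset, s + offset + take - 1))
        remaining -= take
        offset = 0
        if remaining == 0:
            break
    return tuple(segments)


def simulate_reads(truth: SimTruth, params: SimParams) -> list[AlignedRead]:
    """Sample strand-specific aligned reads from the truth transcriptome.

    Per transcript, read starts are drawn in mature (spliced) coordinates
    from a uniform/hotspot mixture and mapped back to the genome, so reads
    crossing a truth intron come out as spliced alignments. Two anchor
    reads per transcript pin the exact 5' and 3' termini (they are removed
    like any other read by the poly-A filter and gap windows). Deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    rl = params.read_length
    reads: list[AlignedRead] = []

    gap_windows: list[tuple[str, int, int]] = []
    chrom0 = next(iter(truth.chrom_lengths))
    for s, e in params.gap_windows:
        gap_windows.append((chrom0, s, e))

    for ti, t in enumerate(truth.transcripts):
        if t.depth is not None:
            depth = t.depth
        elif params.depth_sigma > 0:
            mu = math.log(params.mean_depth) - params.depth_sigma**2 / 2
            depth = float(rng.lognormal(mu, params.depth_sigma))
        else:
            depth = params.mean_depth
        if t.class_label == CLASS_SAUT and t.depth is None:
            depth *= params.antisense_depth_factor
        if depth <= 0:
            logger.warning("transcript %d has depth 0; no reads", ti)
            continue
        exons = t.exons
        mature_len = t.mature_length
        if mature_len < rl:
            logger.warning("transcript %d shorter than a read; skipped", ti)
            continue

        # dropout windows inside the gene body only
        if params.gap_count > 0 and t.gene_ids:
            body = [g for g in truth.genes if g.gene_id in t.gene_ids]
            lo = min(g.start for g in body) + 50
            hi = max(g.end for g in body) - 50
            for _ in range(params.gap_count):
                glen = int(rng.integers(*params.gap_length_range, endpoint=True))
                if hi - glen <= lo:
                    continue
                ws = int(rng.integers(lo, hi - glen))
                gap_windows.append((t.chrom, ws, ws + glen - 1))

        max_start = mature_len - rl
        n_random = max(0, round(depth * mature_len / rl) - 2)
        starts = [0, max_start]
        if params.hotspot_count > 0 and params.hotspot_weight > 0:
            centres = rng.integers(0, max_start + 1, size=params.hotspot_count)
            use_hot = rng.random(n_random) < params.hotspot_weight
            uniform = rng.integers(0, max_start + 1, size=n_random)
            which = rng.integers(0, params.hotspot_count, size=n_random)
            jitter = rng.integers(
                -params.hotspot_width // 2, params.hotspot_width // 2 + 1, size=n_random
            )
            hot = np.clip(centres[which] + jitter, 0, max_start)
            starts.extend(np.where(use_hot, hot, uniform).tolist())
        else:
            starts.extend(rng.integers(0, max_start + 1, size=n_random).tolist())

        for k, m_start in enumerate(starts):
            segments = _mature_to_genomic(exons, int(m_start), rl)
            reads.append(
                AlignedRead(
                    read_id=f"t{ti}_{k}",
                    chrom=t.chrom,
                    strand=t.strand,
                    segments=segments,
                )
            )

    # uniform background noise on random strands
    if params.noise_rate_per_kb > 0:
        total = sum(truth.chrom_lengths.values())
        n_noise = round(params.noise_rate_per_kb * total / 1000)
        chroms = sorted(truth.chrom_lengths)
        weights = np.array([truth.chrom_lengths[c] for c in chroms], dtype=float)
        weights /= weights.sum()
        for k in range(n_noise):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            pos = int(rng.integers(1, truth.chrom_lengths[chrom] - rl + 2))
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(
                AlignedRead(
                    read_id=f"noise_{k}",
                    chrom=chrom,
                    strand=strand,
                    segments=((pos, pos + rl - 1),),
                )
            )

    if gap_windows:
        # a read is lost when any aligned segment touches a dropout window
        reads = [
            r
            for r in reads
            if not any(
                r.chrom == c and any(not (e2 < s or s2 > e) for s2, e2 in r.segments)
                for c, s, e in gap_windows
            )
        ]

    if params.polyA_loss:
        terminal: dict[int, tuple[str, int, int]] = {}
        for ti, t in enumerate(truth.transcripts):
            if t.strand == "+":
                terminal[ti] = (t.chrom, t.end - rl + 1, t.end)
            else:
                terminal[ti] = (t.chrom, t.start, t.start + rl - 1)

        def overlaps_polya(r: AlignedRead) -> bool:
            if not r.read_id.startswith("t"):
                return False
            ti = int(r.read_id[1:].split("_")[0])
            c, s, e = terminal[ti]
            return r.chrom == c and not (r.end < s or r.start > e)

        reads = [r for r in reads if not overlaps_polya(r)]

    return reads


def write_sam(
    reads: Sequence[AlignedRead],
    chrom_lengths: Mapping[str, int],
    path: str | os.PathLike,
) -> None:
    """Write reads as a valid SAM file with strand flags and N-gapped CIGARs."""
    chroms = sorted(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": chrom_lengths[c]} for c in chroms],
    }
    ref_ids = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = ref_ids[r.chrom]
            a.reference_start = r.start - 1
            a.mapping_quality = 255
            cigar: list[tuple[int, int]] = []
            prev_end = None
            for s, e in r.segments:
                if prev_end is not None:
                    cigar.append((3, s - prev_end - 1))
                cigar.append((0, e - s + 1))
                prev_end = e
            a.cigartuples = cigar
            a.set_tag("NH", 1)
            out.write(a)


def write_annotation_gff(truth: SimTruth, path: str | os.PathLike) -> None:
    """Write gene models (spans without UTRs) as GFF3."""
    type_of = {PROTEIN_CODING: "gene", TRNA: "tRNA", OTHER_NCRNA: "ncRNA"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in truth.genes:
            fh.write(
                "\t".join(
                    [
                        g.chrom, "sim", type_of[g.feature_class],
                        str(g.start), str(g.end), ".", g.strand, ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


def write_truth_tsv(truth: SimTruth, path: str | os.PathLike) -> None:
    """Tabulate truth transcripts (spans, UTRs, introns, classes) as TSV."""
    rows = []
    for t in truth.transcripts:
        rows.append(
            {
                "chrom": t.chrom,
                "strand": t.strand,
                "start": t.start,
                "end": t.end,
                "genes": ",".join(t.gene_ids),
                "utr5": t.utr5 if t.utr5 is not None else "",
                "utr3": t.utr3 if t.utr3 is not None else "",
                "introns": ";".join(f"{d}-{a}" for d, a in t.introns),
                "class": t.class_label,
                "antisense_of": t.antisense_of or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
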