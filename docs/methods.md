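# Methods

## Scope and model

`blockasm` reconstructs transcription units from strand-specific,
single-end RNA-seq alignments against an annotated reference, under two
assumptions that hold for budding yeasts and prokaryotes: introns are rare
(so a transcript is essentially one contiguous covered interval per
strand, occasionally interrupted by a splice), and alternative splicing is
negligible (so no isoform resolution is attempted). Paired-end information
is deliberately not used. Coordinates are 1-based inclusive throughout;
alignment input is converted at the file boundary only.

## Assembly procedure

1. **Coverage.** Per (chromosome, strand), `depth[p]` counts every aligned
   read segment covering p and `spliced_depth[p]` the portion contributed
   by spliced reads; their difference is the unspliced depth used by the
   intron rule. Reads flagged unmapped/secondary/supplementary, or
   multi-mapped (`NH > 1`), are excluded. CIGAR reference skips up to
   `deletion_gap_threshold` (default 10 bases) are treated as alignment
   artifacts and absorbed into the segment; longer skips split the read,
   and any skip above `max_spliced_distance` (default 1000 bases) discards
   it.

2. **Blocks.** Overlapping same-strand segments are unioned; zero-coverage
   gaps strictly shorter than `min_gap_forced_join` (default 25) are
   bridged, since short dropouts are sequencing bias rather than
   transcript ends. Components with fewer than `min_reads` (default 5)
   distinct reads are background noise and dropped. A block's mean
   coverage is taken over its full span, internal zero-depth bases
   included, which penalises spurious long merges. Both defaults were
   tuned for Saccharomyces-type short-read libraries and are CLI-exposed.

3. **Learned joining statistics.** Immediately consecutive blocks that
   share an assigned gene yield gap samples (GRBB, with sample SD) and
   coverage-ratio samples (CRRBB ± SD), where the ratio is min/max of the
   two mean coverages — a symmetric quantity in (0, 1]. Statistics are
   pooled genome-wide: dropout gaps are a library property, not a
   chromosomal one. An unassigned block adjacent to a reference-based one
   is absorbed when its gap is at most GRBB + k·GRBB-SD *and* its ratio at
   least CRRBB − k·CRRBB-SD (k = `sd_multiplier`, default 2). Statistics
   are recomputed once per pass (not after every single merge), and passes
   repeat to a fixed point; each merging pass strictly decreases the block
   count, so termination is bounded by the initial count. When a block
   qualifies on both sides, the smaller gap wins, then the higher ratio,
   then the upstream side. With fewer than two learned pairs the
   thresholds fall back to 5× the forced-join gap and a 0.5 ratio —
   conservative values that keep behaviour defined on toy inputs.

4. **Introns.** Junctions are grouped by exact (chrom, strand, donor,
   acceptor); no fuzzy clustering, since misaligned junction reads are
   handled by the acceptance ratio instead. The boundary unspliced depth
   is the mean at the two flanking exonic bases (donor−1, acceptor+1) — a
   minimal, symmetric reading of "the intron-exon boundary". A junction is
   accepted when support/boundary ≥ `intron_ratio` (default 0.1); a zero
   boundary with positive support is accepted with infinite ratio (no
   unspliced competition). For genomes where junction misalignment is
   frequent, a strict mode raises the ratio to 0.65.

5. **Fragmentation removal and trimming.** Consecutive blocks sharing a
   gene merge across their gap; an accepted intron inside the span is
   recorded and excluded from the exonic mean coverage. Transcripts with
   mean coverage above `high_coverage_threshold` (20) then have terminal
   bases with raw depth ≤ `trim_depth` (3) removed — low-coverage "tails"
   otherwise inflate UTR estimates. Trimming inspects raw per-base depth
   (no smoothing) and stops at the first deeper base, which makes it
   idempotent; low-coverage transcripts are left untouched because their
   boundary evidence is weak either way.

6. **Polycistronic validation.** A transcript spanning ≥2 same-strand
   genes is genuine only if, for every adjacent gene pair, the inter-gene
   interval has no zero-depth base, its mean depth is ≥ `t_intergenic`
   (0.5) of the shallower gene's mean, and the two genes' mean depths have
   ratio ≥ `t_genes` (0.5). Failing drafts split at the deepest
   intergenic base and the products are re-validated recursively; the
   covered-gene multiset is conserved by splitting. The two 0.5 thresholds
   are this package's stand-in for a published coverage-continuity test
   whose exact parameters are not public; both are CLI-exposed and should
   be treated as tunables.

7. **UTRs and classes.** UTR lengths are signed distances between the
   transcript ends and the annotated boundaries of its 5'-most/3'-most
   covered gene, strand-aware; negative values flag truncation and are
   deliberately not clamped. Classification cascades: covered gene →
   protein_coding/tRNA/other_ncRNA (protein_coding takes precedence over a
   multi-gene mix); else a *strict majority* of the span antisense to a
   protein-coding gene → SAUT (a majority rule avoids labelling incidental
   terminal overlap; exactly 50% does not qualify); else entirely inside
   an accepted intron of a same-strand transcript → intronic_ncRNA; else
   SUT, named after the gene with minimal boundary distance on either
   strand (ties resolve to the downstream gene on the transcript's
   strand).

## Cross-sample procedures

UTR comparison admits only genes whose transcript coverage exceeds 20 in
*every* sample; a sample pair is variable for a gene when 5'-UTR lengths
differ by ≥ 50 bases (the boundary value counts as variable — one
consistent rule). A gene is conserved with 0 variable pairs, variable with
1–5, and highly variable with ≥ 6 (no upper cap). A gene's 5'-UTR in a
sample is read off the transcript whose 5'-most covered gene it is,
taking the highest-coverage such transcript; genes covered only
mid-polycistron therefore do not enter the UTR table. A SAUT is conserved
when the (ortholog-mapped) gene carries an antisense SAUT in every sample
— a universal quantifier, so adding samples can only shrink the set.
Ortholog mapping is an input two-column TSV, not computed internally.
Bicistronic candidates are retained only when validated in *all*
conditions; condition-specific candidates are adjacent transcripts not
separated by an untranscribed gap, not fusion transcripts.

## The simulator

The generator emulates what short-read strand-specific libraries of these
genomes look like: 50-base single-end reads; per-transcript depth constant
(default 30×) or log-normal around the mean; optional start-site hotspots
(count/width/weight mixture); `gap_count` dropout windows of 8–15 bases
placed inside gene bodies (where real dropouts occur; UTRs are left
clean); uniform background reads at a configurable rate per kb on random
strands, name-tagged `noise_` so tests can verify the noise filter;
and optional poly-A loss, deleting every read overlapping a transcript's
3'-terminal read length — the sequencer-pipeline behaviour that
systematically truncates observed 3' ends by up to one read length while
leaving 5' ends unbiased. Reads are sampled in mature (spliced)
coordinates and mapped back through the exon structure, so junction
-crossing reads come out as gapped alignments. Two deterministic anchor
reads pin each transcript's exact termini; without them a Poisson sampler
misses the exact terminal base more often than not at 30×, and exact
boundary recovery would be unattainable even on noise-free data. Anchors
are subject to the poly-A and dropout filters like any other read.
Antisense (SAUT) truths are expressed at half the model depth, matching
their lower abundance relative to coding genes. Truth UTR ranges (5':
20–200, 3': 50–250 bases), gene lengths (500–2000) and intergenic spacing
(400–900) are generator choices of realistic yeast-scale magnitudes.

What the simulator does *not* model: sequencing errors and base
qualities, mappability/repeat structure, amplification biases beyond the
hotspot mixture, and real UTR-length distributions. Passing tests
therefore demonstrate the correctness of the assembly logic under the
stated coverage pathologies, not calibrated accuracy on real libraries.

## Verification problem sizes

The verification script (`scripts/acceptance.py`) uses 20-gene genomes
for boundary/dropout checks, 100 random read sets of 50–1000 reads for
the block-oracle comparison, 50 planted junctions for the intron rule,
100 random depth profiles for the trimming contract, a 200-gene genome
for the poly-A bias measurement, 40-gene strain pairs (10 genes shifted
by 80 bases) for UTR-variability recovery, and six 12-gene samples for
conserved-SAUT logic. These sizes make every property measurable in
seconds while leaving each statistic well away from small-sample
ambiguity.

## Known limitations

Very low-coverage transcripts — SUTs in particular — can fragment into
several predicted transcripts when their internal gaps exceed the
forced-join threshold; deeper sequencing is the only real remedy.
Intronic ncRNAs are only detectable when the host intron extends outside
annotated gene spans, since any same-strand overlap with a gene assigns
the block to that gene. The strand of a read is taken from the alignment
flag; libraries without strand specificity will produce spurious
antisense calls. Unique mapping is approximated by primary, non-secondary
alignments with `NH` ≤ 1 where the tag is present.
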