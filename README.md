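# blockasm

Strand-specific, reference-guided transcript assembly for intron-poor
genomes — budding yeasts, other lower eukaryotes and prokaryotes.

General-purpose transcript assemblers are built for heavily spliced
transcriptomes and, on organisms where most genes have no introns, they
fragment transcripts at every sequencing-bias coverage dip and fuse
neighbouring genes whose transcripts merely touch. `blockasm` instead
exploits the annotation: it learns, *from the data of each run*, how large
within-gene coverage gaps are and how similar the coverage of fragments of
one transcript is, and uses those learned distributions to decide what to
join. Its outputs are transcript boundaries (hence 5'/3'-UTR lengths),
intron calls, validated polycistronic transcripts, and a six-way transcript
classification including the antisense (SAUT) and intergenic (SUT)
non-coding classes — plus cross-sample procedures for UTR variability
between strains and conservation of antisense transcripts.

## Method

For each (chromosome, strand), overlapping aligned read segments are
joined into **blocks**; zero-coverage gaps shorter than a forced-join
threshold (default 25 bases) are bridged, and blocks with fewer than
`min_reads` (default 5) reads are discarded as background noise. Blocks
overlapping a same-strand annotated gene are *reference-based*. From
consecutive reference-based blocks of the same gene the run estimates the
gap-size distribution, GRBB ± GRBB-SD, and the coverage-ratio distribution
(min/max of the two blocks' mean depths), CRRBB ± CRRBB-SD. An unassigned
block *B* adjacent to a reference-based block *R* is absorbed when

    gap(B, R) <= GRBB + 2·GRBB-SD   and   ratio(B, R) >= CRRBB − 2·CRRBB-SD,

recursively until a fixed point; unabsorbed blocks are candidate novel
ncRNA transcripts. Introns are called from spliced reads: a junction is
accepted when spliced support / unspliced depth at the flanking exonic
bases ≥ `intron_ratio` (default 0.1; use 0.65 for genomes with
misalignment-prone junctions). Blocks within one gene not separated by an
accepted intron are merged; high-coverage transcripts (mean > 20) have
terminal bases at depth ≤ 3 trimmed; multi-gene transcripts are validated
as polycistronic by coverage continuity and similarity, and split at the
deepest intergenic base otherwise. UTR lengths are the signed distances
between transcript ends and annotated gene boundaries, strand-aware.

## Worked example

Simulate a small genome (with antisense ncRNAs), assemble it, and compare
two strains:

```bash
blockasm simulate --out sim_s1 --n-genes 6 --seed 4 --include antisense_ncRNAs
blockasm simulate --out sim_s2 --n-genes 6 --seed 5 --include antisense_ncRNAs
blockasm assemble --bam sim_s1/reads.sam --gff sim_s1/annotation.gff --out asm_s1
blockasm assemble --bam sim_s2/reads.sam --gff sim_s2/annotation.gff --out asm_s2
blockasm compare asm_s1/transcripts.gff asm_s2/transcripts.gff --out cmp
```

which prints, run by run:

```
6 genes, 8 truth transcripts, 6090 reads -> sim_s1
6 genes, 8 truth transcripts, 4390 reads -> sim_s2
assembled 8 transcripts from 6090 reads -> asm_s1
assembled 8 transcripts from 4390 reads -> asm_s2
6 genes compared, 2 conserved SAUT genes, 0 bicistronic pairs retained -> cmp
```

`asm_s1/transcripts.gff` holds one GFF3 record per transcript; column 9
names the covered gene(s) for coding transcripts, `ncRNA_anti_<geneID>`
for SAUTs and `ncRNAs_<closestGeneID>` for SUTs, with the transcript
length and mean coverage as `note=` entries, e.g.

```
chrI  blockasm  transcript  604   2769  .  -  .  ID=T000001;gene=G0000;class=protein_coding;status=monocistronic;utr5=109;utr3=235;note=length 2166,coverage 30.095
chrI  blockasm  transcript  1203  2113  .  +  .  ID=T000002;gene=ncRNA_anti_G0000;class=SAUT;status=monocistronic;antisense=G0000;note=length 911,coverage 14.984
```

— the first transcript covers gene `G0000` with a 109-base 5'-UTR and a
235-base 3'-UTR at mean depth 30; the second is an antisense non-coding
transcript over the same gene at roughly half that depth. Samples are
matched gene-by-gene through shared gene IDs, so `cmp/utr_compare.tsv`
lists every gene expressed above coverage 20 in both strains with its
per-strain 5'-UTR lengths and variability class, and
`cmp/conserved_sauts.txt` the genes carrying an antisense transcript in
every sample. `classes.tsv` tabulates
counts and coverage/length quartiles per class, and `coverage/` holds
per-base depth tracks (one integer per line, per chromosome and strand)
for genome-browser inspection.

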