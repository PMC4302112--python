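"""Cross-sample procedures: 5'-UTR variability classes, conserved antisense
transcripts and cross-condition polycistronic filtering."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .models import CLASS_SAUT, Transcript

logger = logging.getLogger(__name__)

CONSERVED = "conserved"
VARIABLE = "variable"
HIGHLY_VARIABLE = "highly_variable"


@dataclass
class UtrComparisonRow:
    """One gene's 5'-UTR lengths and coverage across all compared samples."""

    gene_id: str
    per_sample_utr5: dict[str, int] = field(default_factory=dict)
    per_sample_coverage: dict[str, float] = field(default_factory=dict)
    n_variable_comparisons: int = 0
    variability_class: str = CONSERVED


def classify_variability(
    n_variable_comparisons: int, highly_variable_min: int = 6
) -> str:
    """Variability class from the number of pairwise UTR differences.

    0 -> conserved; 1..highly_variable_min-1 -> variable; >= that many
    differing comparisons -> highly variable (no upper cap).
    """
    if n_variable_comparisons == 0:
        return CONSERVED
    if n_variable_comparisons < highly_variable_min:
        return VARIABLE
    return HIGHLY_VARIABLE


def _gene_utr_table(
    transcripts: Sequence[Transcript],
) -> dict[str, tuple[int, float]]:
    """gene_id -> (utr5_len, coverage) from one sample's transcripts.

    A gene's 5'-UTR is read off the transcript whose 5'-most covered gene
    it is; with several such transcripts the highest-coverage one wins.
    """
    table: dict[str, tuple[int, float]] = {}
    for t in transcripts:
        if not t.covered_genes or t.utr5_len is None:
            continue
        lead = t.covered_genes[0] if t.strand == "+" else t.covered_genes[-1]
        prev = table.get(lead)
        if prev is None or t.mean_coverage > prev[1]:
            table[lead] = (t.utr5_len, t.mean_coverage)
    return table


def compare_utrs(
    transcriptomes: Mapping[str, Sequence[Transcript]],
    utr_diff_threshold: int = 50,
    min_coverage: float = 20.0,
    ortholog_map: Optional[Mapping[str, Mapping[str, str]]] = None,
    highly_variable_min: int = 6,
) -> list[UtrComparisonRow]:
    """Pairwise 5'-UTR comparison of genes expressed in every sample.

    Only genes whose transcript coverage exceeds ``min_coverage`` in ALL
    samples enter the table. A sample pair is *variable* for a gene when
    the 5'-UTR lengths differ by at least ``utr_diff_threshold`` bases
    (boundary values count as variable). ``ortholog_map`` optionally maps
    sample-local gene IDs onto shared IDs (sample -> {local: shared}).
    """
    if len(transcriptomes) < 2:
        raise ValueError("compare_utrs needs at least two samples")
    samples = sorted(transcriptomes)
    tables: dict[str, dict[str, tuple[int, float]]] = {}
    for sample in samples:
        raw = _gene_utr_table(transcriptomes[sample])
        if ortholog_map and sample in ortholog_map:
            mapping = ortholog_map[sample]
            raw = {mapping[g]: v for g, v in raw.items() if g in mapping}
        tables[sample] = raw

    shared = set.intersection(*(set(t) for t in tables.values()))
    rows: list[UtrComparisonRow] = []
    for gene in sorted(shared):
        if any(tables[s][gene][1] <= min_coverage for s in samples):
            continue
        row = UtrComparisonRow(gene_id=gene)
        for s in samples:
            utr5, cov = tables[s][gene]
            row.per_sample_utr5[s] = utr5
            row.per_sample_coverage[s] = cov
        row.n_variable_comparisons = sum(
            abs(row.per_sample_utr5[a] - row.per_sample_utr5[b]) >= utr_diff_threshold
            for a, b in combinations(samples, 2)
        )
        row.variability_class = classify_variability(
            row.n_variable_comparisons, highly_variable_min
        )
        rows.append(row)
    return rows


def utr_comparison_frame(rows: Sequence[UtrComparisonRow]) -> pd.DataFrame:
    records = []
    for row in rows:
        rec: dict = {"gene_id": row.gene_id}
        for s, v in row.per_sample_utr5.items():
            rec[f"utr5_{s}"] = v
        for s, v in row.per_sample_coverage.items():
            rec[f"coverage_{s}"] = v
        rec["n_variable_comparisons"] = row.n_variable_comparisons
        rec["variability_class"] = row.variability_class
        records.append(rec)
    return pd.DataFrame(records)


def conserved_sauts(
    transcriptomes: Mapping[str, Sequence[Transcript]],
    ortholog_map: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> list[str]:
    """Genes with an antisense SAUT in every sample of the comparison.

    A gene counts in a sample when at least one SAUT-classified transcript
    overlaps it antisense. The conserved set is the intersection over all
    samples (after optional ortholog mapping), sorted by gene ID; adding a
    sample can only shrink it.
    """
    if not transcriptomes:
        raise ValueError("conserved_sauts needs at least one sample")
    per_sample: list[set[str]] = []
    for sample, transcripts in transcriptomes.items():
        genes: set[str] = set()
        for t in transcripts:
            if t.class_label != CLASS_SAUT:
                continue
            targets = t.antisense_genes or (
                (t.attribute_gene,) if t.attribute_gene else ()
            )
            genes.update(targets)
        if ortholog_map and sample in ortholog_map:
            mapping = ortholog_map[sample]
            genes = {mapping[g] for g in genes if g in mapping}
        per_sample.append(genes)
    return sorted(set.intersection(*per_sample))


def validated_pairs(transcripts: Iterable[Transcript]) -> set[tuple[str, str]]:
    """Adjacent covered-gene pairs of validated polycistronic transcripts."""
    pairs: set[tuple[str, str]] = set()
    for t in transcripts:
        if t.polycistronic_status != "validated" or len(t.covered_genes) < 2:
            continue
        for a, b in zip(t.covered_genes, t.covered_genes[1:]):
            pairs.add((a, b))
    return pairs


def filter_bicistronic_by_condition(
    calls: Mapping[str, Iterable],
) -> set[tuple[str, str]]:
    """Keep only gene pairs validated polycistronic in ALL conditions.

    Pairs seen in a single condition are read-through artefacts of closely
    spaced transcripts, not real fusion transcripts. ``calls`` maps a
    condition to either a set of gene-pair tuples or a transcript
    collection (pairs are then extracted from validated transcripts).
    """
    if not calls:
        raise ValueError("no conditions given")
    sets: list[set[tuple[str, str]]] = []
    for condition, value in calls.items():
        value = list(value)
        if value and isinstance(value[0], Transcript):
            sets.append(validated_pairs(value))
        else:
            sets.append({tuple(p) for p in value})
    if len(sets) == 1:
        logger.warning("single condition: bicistronic filter is a pass-through")
        return sets[0]
    return set.intersection(*sets)
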