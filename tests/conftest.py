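"""Shared fixtures: tiny annotated genomes and deterministic read sets."""

from __future__ import annotations

import numpy as np
import pytest

from blockasm.models import (
    AlignedRead,
    Annotation,
    AssemblyParams,
    GeneModel,
    build_coverage,
)


def unspliced(read_id: str, start: int, length: int = 50, strand: str = "+",
              chrom: str = "chrI") -> AlignedRead:
    return AlignedRead(read_id, chrom, strand, ((start, start + length - 1),))


def spliced(read_id: str, seg1: tuple[int, int], seg2: tuple[int, int],
            strand: str = "+", chrom: str = "chrI") -> AlignedRead:
    return AlignedRead(read_id, chrom, strand, (seg1, seg2))


def pile(start: int, end: int, depth: int, strand: str = "+", chrom: str = "chrI",
         prefix: str = "r", length: int = 50) -> list[AlignedRead]:
    """Tile staggered read layers so [start, end] is covered at ~`depth`."""
    reads = []
    k = 0
    last_start = end - length + 1
    assert last_start >= start, "span shorter than a read"
    for layer in range(depth):
        offset = (layer * length) // depth
        positions = list(range(start + offset, last_start + 1, length))
        if not positions or positions[0] != start:
            positions.insert(0, start)
        if positions[-1] != last_start:
            positions.append(last_start)
        for pos in positions:
            reads.append(unspliced(f"{prefix}{k}", pos, length, strand, chrom))
            k += 1
    return reads


@pytest.fixture
def simple_annotation() -> Annotation:
    return Annotation(
        [
            GeneModel("YAL001C", "chrI", 1000, 2000, "+"),
            GeneModel("YAL002W", "chrI", 3000, 4200, "-"),
            GeneModel("tL001", "chrI", 5000, 5074, "+", feature_class="tRNA"),
        ]
    )


@pytest.fixture
def default_params() -> AssemblyParams:
    return AssemblyParams()


def brute_force_blocks(reads, min_gap: int, min_reads: int):
    """Independent O(n^2) oracle: pairwise interval union with gap tolerance.

    Components of the graph where two segments are connected when they
    overlap or are separated by fewer than `min_gap` uncovered bases;
    components with fewer than `min_reads` distinct reads are dropped.
    Returns sorted (chrom, strand, start, end, n_reads).
    """
    items = []
    for r in reads:
        for s, e in r.segments:
            items.append([r.chrom, r.strand, s, e, {r.read_id}])
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            if items[i] is None:
                continue
            for j in range(i + 1, len(items)):
                if items[j] is None:
                    continue
                a, b = items[i], items[j]
                if (a[0], a[1]) != (b[0], b[1]):
                    continue
                gap = max(a[2], b[2]) - min(a[3], b[3]) - 1
                if gap < min_gap:
                    a[2] = min(a[2], b[2])
                    a[3] = max(a[3], b[3])
                    a[4] |= b[4]
                    items[j] = None
                    changed = True
    out = [
        (it[0], it[1], it[2], it[3], len(it[4]))
        for it in items
        if it is not None and len(it[4]) >= min_reads
    ]
    return sorted(out)


def random_reads(rng: np.random.Generator, n: int, genome_len: int = 2000,
                 read_len: int = 30) -> list[AlignedRead]:
    reads = []
    for i in range(n):
        start = int(rng.integers(1, genome_len - read_len))
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append(unspliced(f"x{i}", start, read_len, strand))
    return reads
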