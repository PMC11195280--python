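"""Shared fixtures and random-instance builders for the test suite.

Random instances deliberately allow overlapping/shared anchors and peaks —
the messy regime the sequential synthetic generator avoids — so the
brute-force oracle comparisons exercise general configurations.
"""

from __future__ import annotations

import numpy as np
import pytest

from chromaloop.core_io import (
    Gene,
    GenomicInterval,
    Loop,
    Peak,
    PeakSet,
    SampleDesign,
)


@pytest.fixture(scope="session")
def design() -> SampleDesign:
    return SampleDesign.two_by_two()


def random_interval(rng, chroms=("chr1", "chr2"), span=100_000, max_len=5000):
    chrom = chroms[rng.integers(len(chroms))]
    start = int(rng.integers(0, span))
    length = int(rng.integers(100, max_len))
    return GenomicInterval(chrom, start, start + length)


def random_loops(rng, n, design, chroms=("chr1", "chr2"), span=100_000):
    loops = []
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        s1 = int(rng.integers(0, span))
        a = GenomicInterval(chrom, s1, s1 + int(rng.integers(200, 4000)))
        s2 = int(rng.integers(0, span))
        b = GenomicInterval(chrom, s2, s2 + int(rng.integers(200, 4000)))
        counts = {s: int(rng.integers(0, 30)) for s in design.samples}
        loops.append(Loop(f"L{i}", a, b, counts))
    return loops


def random_genes(rng, n, chroms=("chr1", "chr2"), span=100_000):
    return [
        Gene(
            gene_id=f"G{i}",
            symbol=f"SYM{i}",
            chrom=chroms[rng.integers(len(chroms))],
            tss=int(rng.integers(0, span)),
            strand="+" if rng.random() < 0.5 else "-",
            regulation=("up", "down", "ns")[rng.integers(3)],
            expr_log2fc=float(np.round(rng.normal(), 3)),
        )
        for i in range(n)
    ]


def random_peaks(rng, n, chroms=("chr1", "chr2"), span=100_000):
    return PeakSet(
        Peak(random_interval(rng, chroms, span, max_len=2000), f"P{i}")
        for i in range(n)
    )


def interval_overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def promoter_window_interval(gene: Gene, w: int = 500) -> GenomicInterval:
    # inclusive [tss-w, tss+w] as a half-open interval
    return GenomicInterval(gene.chrom, max(0, gene.tss - w), gene.tss + w + 1)


def oracle_anchor_is_promoter(anchor, genes, w=500) -> bool:
    return any(
        interval_overlap_bp(anchor, promoter_window_interval(g, w)) >= 1
        for g in genes
    )


def oracle_tss_anchor_gap(anchor: GenomicInterval, tss: int) -> int:
    """Spec distance rule: 0 inside the anchor, else gap to the nearest edge
    (last covered base is end-1)."""
    if anchor.start <= tss < anchor.end:
        return 0
    if tss < anchor.start:
        return anchor.start - tss
    return tss - (anchor.end - 1)
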