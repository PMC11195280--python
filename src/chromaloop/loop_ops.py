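"""Replicate filtering, anchor/loop classification, loop-gene assignment.

Promoter definition: an anchor is a promoter if it intersects the window
[tss - w, tss + w] (inclusive of both ends, w = 500 bp by default) for any
gene. Loop-to-gene assignment uses the gap between the TSS and the nearest
anchor edge (0 when the TSS falls inside an anchor).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Literal, Sequence

from chromaloop.core_io import Gene, GenomicInterval, IntervalIndex, Loop, SampleDesign

__all__ = [
    "LoopGeneAssignment",
    "filter_by_replicate_support",
    "classify_anchor",
    "classify_loop",
    "classify_loops",
    "assign_loops_to_genes",
    "loop_summary",
]

PROMOTER_WINDOW_BP = 500


@dataclass(frozen=True)
class LoopGeneAssignment:
    loop_id: str
    gene_id: str
    window_kind: str  # promoter_5kb | distal_100kb | custom
    distance_bp: int


def filter_by_replicate_support(
    loops: Sequence[Loop], design: SampleDesign
) -> list[Loop]:
    """Keep loops with >= 1 read in every replicate of at least one condition.

    Generalizes the two-replicate rule to any replicate number: a loop
    survives iff some condition has all of its replicates non-zero.
    """
    kept = []
    by_condition = {c: design.samples_for(c) for c in design.conditions}
    for lp in loops:
        for samples in by_condition.values():
            if all(lp.counts.get(s, 0) >= 1 for s in samples):
                kept.append(lp)
                break
    return kept


def _promoter_window(gene: Gene, window_bp: int) -> GenomicInterval:
    # [tss - w, tss + w] inclusive -> half-open [tss - w, tss + w + 1)
    start = max(0, gene.tss - window_bp)
    return GenomicInterval(gene.chrom, start, gene.tss + window_bp + 1)


def build_promoter_index(
    genes: Sequence[Gene], promoter_window_bp: int = PROMOTER_WINDOW_BP
) -> IntervalIndex:
    """Index of promoter windows, one per gene."""
    return IntervalIndex(_promoter_window(g, promoter_window_bp) for g in genes)


def classify_anchor(
    anchor: GenomicInterval,
    genes: Sequence[Gene] | IntervalIndex,
    promoter_window_bp: int = PROMOTER_WINDOW_BP,
) -> Literal["promoter", "enhancer"]:
    """"promoter" iff the anchor intersects any gene's TSS +/- window."""
    if isinstance(genes, IntervalIndex):
        index = genes
    else:
        index = build_promoter_index(genes, promoter_window_bp)
    return "promoter" if index.query(anchor) else "enhancer"


def classify_loop(
    loop: Loop,
    genes: Sequence[Gene] | IntervalIndex,
    promoter_window_bp: int = PROMOTER_WINDOW_BP,
) -> str:
    """PP if both anchors are promoters, EE if neither, PE otherwise.

    Sets ``loop.loop_class`` and returns it; symmetric in anchor order.
    """
    if not isinstance(genes, IntervalIndex):
        genes = build_promoter_index(genes, promoter_window_bp)
    n_promoters = sum(
        classify_anchor(a, genes) == "promoter" for a in loop.anchors
    )
    loop.loop_class = {2: "PP", 1: "PE", 0: "EE"}[n_promoters]
    return loop.loop_class


def classify_loops(
    loops: Sequence[Loop],
    genes: Sequence[Gene],
    promoter_window_bp: int = PROMOTER_WINDOW_BP,
) -> list[Loop]:
    """Classify every loop in place with a shared promoter index."""
    index = build_promoter_index(genes, promoter_window_bp)
    for lp in loops:
        classify_loop(lp, index)
    return list(loops)


def tss_anchor_distance(gene: Gene, loop: Loop) -> int | None:
    """Minimum TSS-to-anchor edge gap over both anchors; None across chroms."""
    if gene.chrom != loop.chrom:
        return None
    return min(a.distance_to_point(gene.tss) for a in loop.anchors)


def assign_loops_to_genes(
    loops: Sequence[Loop], genes: Sequence[Gene], window_bp: int
) -> list[LoopGeneAssignment]:
    """Emit one (loop, gene) pair per gene whose TSS lies within ``window_bp``
    of either anchor. Distance is the edge gap, 0 inside an anchor."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    kind = {5000: "promoter_5kb", 100_000: "distal_100kb"}.get(window_bp, "custom")
    # Index anchors padded by the window so gene TSS lookups are O(log n).
    padded = IntervalIndex(
        GenomicInterval(a.chrom, max(0, a.start - window_bp), a.end + window_bp)
        for lp in loops
        for a in lp.anchors
    )
    by_chrom: dict[str, list[Loop]] = {}
    for lp in loops:
        by_chrom.setdefault(lp.chrom, []).append(lp)

    out: list[LoopGeneAssignment] = []
    for gene in genes:
        tss_iv = GenomicInterval(gene.chrom, gene.tss, gene.tss + 1)
        if not padded.query(tss_iv):
            continue
        for lp in by_chrom.get(gene.chrom, ()):
            d = tss_anchor_distance(gene, lp)
            if d is not None and d <= window_bp:
                out.append(LoopGeneAssignment(lp.loop_id, gene.gene_id, kind, d))
    out.sort(key=lambda a: (a.loop_id, a.gene_id))
    return out


def loop_summary(loops: Sequence[Loop]) -> dict:
    """Medians of anchor distance and anchor size plus class fractions.

    Anchor distance is midpoint-to-midpoint; anchor sizes pool both anchors.
    Even-length medians average the central pair.
    """
    if not loops:
        raise ValueError("loop_summary requires >= 1 loop")
    distances = [lp.anchor_distance_bp for lp in loops]
    sizes = [a.length for lp in loops for a in lp.anchors]
    classes = [lp.loop_class for lp in loops]
    n = len(loops)
    fractions = {
        cls: classes.count(cls) / n
        for cls in ("PP", "PE", "EE", "unset")
        if cls in classes
    }
    return {
        "n_loops": n,
        "median_anchor_distance_bp": statistics.median(distances),
        "median_anchor_size_bp": statistics.median(sizes),
        "class_fractions": fractions,
    }
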