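"""Promoter-proximity clustering and promoter-promoter connectivity.

Asks two questions about a gene subset (typically hormone-upregulated
genes): do their TSSs sit closer together along the genome than size-matched
random gene sets, and do nearby pairs physically interact through
promoter-promoter loops more often than random pairs? Null distributions
come from seeded resampling of size-matched control gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from chromaloop.core_io import Gene, GenomicInterval, IntervalIndex, Loop
from chromaloop.gene_stats import wilcoxon_rank_sum

__all__ = [
    "GenePair",
    "find_gene_pairs",
    "clustering_statistic",
    "pp_connectivity",
    "pp_connectivity_null",
]

MAX_PAIR_DIST_BP = 150_000


@dataclass(frozen=True)
class GenePair:
    gene_a: str
    gene_b: str
    tss_distance_bp: int
    pp_connected: bool = False


def find_gene_pairs(
    gene_subset: Sequence[Gene], max_dist_bp: int = MAX_PAIR_DIST_BP
) -> list[GenePair]:
    """All unordered same-chromosome gene pairs with TSS distance <= cutoff."""
    pairs: list[GenePair] = []
    by_chrom: dict[str, list[Gene]] = {}
    for g in gene_subset:
        by_chrom.setdefault(g.chrom, []).append(g)
    for genes in by_chrom.values():
        genes = sorted(genes, key=lambda g: (g.tss, g.gene_id))
        for i, ga in enumerate(genes):
            for gb in genes[i + 1 :]:
                d = gb.tss - ga.tss
                if d > max_dist_bp:
                    break
                a, b = sorted((ga.gene_id, gb.gene_id))
                pairs.append(GenePair(a, b, d))
    pairs.sort(key=lambda p: (p.gene_a, p.gene_b))
    return pairs


def _nearest_neighbor_distances(genes: Sequence[Gene]) -> tuple[list[float], int]:
    """Per-gene distance to the nearest other subset member on the same
    chromosome. Returns (distances, number of genes excluded for having no
    same-chromosome partner)."""
    by_chrom: dict[str, list[int]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g.tss)
    distances: list[float] = []
    excluded = 0
    for tss_list in by_chrom.values():
        if len(tss_list) < 2:
            excluded += len(tss_list)
            continue
        tss = np.sort(np.asarray(tss_list, dtype=float))
        gaps = np.diff(tss)
        left = np.concatenate([[np.inf], gaps])
        right = np.concatenate([gaps, [np.inf]])
        distances.extend(np.minimum(left, right).tolist())
    return distances, excluded


def clustering_statistic(
    gene_subset: Sequence[Gene],
    all_genes: Sequence[Gene],
    n_controls: int = 100,
    seed: int = 0,
) -> dict:
    """Nearest-neighbor TSS distances of the subset vs random control sets.

    Controls are seeded uniform draws without replacement from
    ``all_genes``, size-matched to the subset. The p-value is a two-sided
    rank-sum test of observed distances against the pooled control
    distances; clustering shows up as observed < control.
    """
    if len(gene_subset) < 2:
        raise ValueError("gene_subset must have >= 2 genes")
    if n_controls < 1:
        raise ValueError("n_controls must be >= 1")
    observed, excluded = _nearest_neighbor_distances(gene_subset)
    if not observed:
        raise ValueError("no same-chromosome neighbor in the subset")
    rng = np.random.default_rng(seed)
    all_genes = list(all_genes)
    control: list[float] = []
    for _ in range(n_controls):
        idx = rng.choice(len(all_genes), size=len(gene_subset), replace=False)
        d, _ = _nearest_neighbor_distances([all_genes[i] for i in idx])
        control.extend(d)
    if not control:
        raise ValueError("control draws produced no same-chromosome neighbors")
    test = wilcoxon_rank_sum(observed, control)
    return {
        "observed_distances": observed,
        "control_distances": control,
        "n_excluded": excluded,
        "statistic": test["statistic"],
        "pvalue": test["pvalue"],
    }


class PromoterLoopIndex:
    """Reusable lookup from a gene promoter window to touching loop anchors."""

    def __init__(
        self,
        loops: Sequence[Loop],
        genes: Sequence[Gene],
        promoter_window_bp: int = 500,
    ):
        self.window = promoter_window_bp
        self.tss = {g.gene_id: (g.chrom, g.tss) for g in genes}
        self.anchor_index = IntervalIndex(a for lp in loops for a in lp.anchors)
        self.key_to_loops: dict[tuple[str, int, int], set[tuple[str, int]]] = {}
        for lp in loops:
            for side, a in enumerate(lp.anchors):
                self.key_to_loops.setdefault(
                    (a.chrom, a.start, a.end), set()
                ).add((lp.loop_id, side))
        self._cache: dict[str, frozenset[tuple[str, int]]] = {}

    def touching(self, gene_id: str) -> frozenset[tuple[str, int]]:
        hit = self._cache.get(gene_id)
        if hit is None:
            chrom, pos = self.tss[gene_id]
            window = GenomicInterval(
                chrom, max(0, pos - self.window), pos + self.window + 1
            )
            out: set[tuple[str, int]] = set()
            for iv in self.anchor_index.query(window):
                out |= self.key_to_loops[(iv.chrom, iv.start, iv.end)]
            hit = self._cache[gene_id] = frozenset(out)
        return hit

    def connected(self, gene_a: str, gene_b: str) -> bool:
        hits_b = self.touching(gene_b)
        return any((lid, 1 - side) in hits_b for lid, side in self.touching(gene_a))


def pp_connectivity(
    pairs: Sequence[GenePair],
    loops: Sequence[Loop] | PromoterLoopIndex,
    genes: Sequence[Gene] = (),
    promoter_window_bp: int = 500,
) -> dict:
    """Fraction of gene pairs joined by a loop spanning both promoters.

    A pair is connected iff some loop has one anchor within
    ``promoter_window_bp`` of one gene's TSS and the other anchor within the
    window of the other gene's TSS. ``loops`` may be a prebuilt
    PromoterLoopIndex to amortize index construction over many calls.
    """
    if not pairs:
        raise ValueError("empty pair list")
    if isinstance(loops, PromoterLoopIndex):
        index = loops
    else:
        index = PromoterLoopIndex(loops, genes, promoter_window_bp)
    flagged: list[GenePair] = []
    n_connected = 0
    for pair in pairs:
        connected = index.connected(pair.gene_a, pair.gene_b)
        n_connected += connected
        flagged.append(
            GenePair(pair.gene_a, pair.gene_b, pair.tss_distance_bp, connected)
        )
    return {
        "fraction_connected": n_connected / len(pairs),
        "n_pairs": len(pairs),
        "n_connected": n_connected,
        "pairs": flagged,
    }


def pp_connectivity_null(
    gene_subset: Sequence[Gene],
    all_genes: Sequence[Gene],
    loops: Sequence[Loop],
    n_resamples: int = 100,
    seed: int = 0,
    max_dist_bp: int = MAX_PAIR_DIST_BP,
    promoter_window_bp: int = 500,
) -> dict:
    """Observed P-P connected fraction vs size-matched random gene sets.

    Each resample draws a random gene set the size of the subset, finds its
    pairs within the distance cutoff, and records the connected fraction
    (0, flagged, when a draw yields no pairs). Empirical p uses the add-one
    rule, so it can never reach 0.
    """
    if n_resamples < 100:
        raise ValueError("n_resamples must be >= 100")
    pairs = find_gene_pairs(gene_subset, max_dist_bp)
    if not pairs:
        raise ValueError("gene subset yields no pairs within the cutoff")
    all_genes = list(all_genes)
    index = PromoterLoopIndex(loops, all_genes, promoter_window_bp)
    observed = pp_connectivity(pairs, index)["fraction_connected"]
    rng = np.random.default_rng(seed)
    null_fractions = np.zeros(n_resamples)
    n_empty = 0
    for i in range(n_resamples):
        idx = rng.choice(len(all_genes), size=len(gene_subset), replace=False)
        draw = [all_genes[j] for j in idx]
        draw_pairs = find_gene_pairs(draw, max_dist_bp)
        if not draw_pairs:
            n_empty += 1
            continue  # fraction stays 0, flagged via n_empty
        null_fractions[i] = pp_connectivity(draw_pairs, index)["fraction_connected"]
    empirical_p = (1 + int(np.sum(null_fractions >= observed))) / (1 + n_resamples)
    return {
        "observed_fraction": observed,
        "null_fractions": null_fractions.tolist(),
        "empirical_p": empirical_p,
        "n_resamples": n_resamples,
        "n_empty_resamples": n_empty,
    }
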