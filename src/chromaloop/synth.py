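"""Seeded generator of a complete synthetic HiChIP-style dataset.

The generator emulates the downstream inputs of a two-condition HiChIP
experiment at desk scale: intra-chromosomal loops with log-normal anchor
sizes (median ~2.9 kb) and anchor distances (median 24 kb for
non-differential, 59 kb for differential loops), NB-distributed per-sample
counts with a planted fraction of differential loops (70% of them
increased), TF-binding peaks preferentially placed on differential anchors,
gene expression responses generated from a linear model on per-gene
differential loop counts, clustered upregulated genes joined by
promoter-promoter loops, and a labeled feature matrix for anchor
classification. Ground truth for every planted quantity is recorded so each
pipeline stage has a recovery test.

Loops are laid out sequentially with a minimum inter-loop gap, so anchors
of different (non-cluster) loops never overlap and a TSS placed inside an
anchor makes exactly that anchor a promoter. Real HiChIP anchors share and
overlap heavily; that regime is exercised by the randomized-instance oracle
tests rather than by this generator.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from chromaloop.core_io import (
    Gene,
    GenomicInterval,
    Loop,
    Peak,
    PeakSet,
    SampleDesign,
    write_bed,
    write_bedpe_loops,
    write_gene_table,
)
from chromaloop.feature_select import FeatureMatrix
from chromaloop.loop_ops import assign_loops_to_genes

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate"]


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions.

    Distances and sizes are log-normal, parametrized by median and sigma
    (of the underlying normal). Differential effects are applied
    multiplicatively to the treated-condition mean.
    """

    n_chromosomes: int = 5
    chrom_length_bp: int = 180_000_000
    n_loops: int = 5000
    n_genes: int = 800
    n_peaks: int = 400

    anchor_size_median_bp: float = 2900.0
    anchor_size_sigma: float = 0.35
    anchor_distance_median_bp: float = 24_000.0
    anchor_distance_median_diff_bp: float = 59_000.0
    anchor_distance_sigma: float = 0.7
    min_inter_loop_gap_bp: int = 5000

    frac_differential: float = 0.15
    frac_increased_among_differential: float = 0.70
    effect_log2fc_mean: float = 2.0
    effect_log2fc_sd: float = 0.15
    effect_log2fc_min: float = 0.5

    nb_mean_median: float = 80.0
    nb_mean_sigma: float = 0.6
    nb_dispersion: float = 0.1
    n_replicates: int = 2
    sample_depth_factors: tuple[float, ...] = (1.0, 1.3, 0.75, 1.1)

    peak_differential_enrichment: float = 6.0  # relative risk on diff anchors
    peak_size_range_bp: tuple[int, int] = (200, 1500)
    frac_peaks_on_anchors: float = 0.7  # the rest fall between loops

    beta_intercept: float = 0.2
    beta_ee: float = 0.10
    beta_pe: float = 0.08
    beta_pp: float = 0.05
    expr_noise_sd: float = 0.3
    regulation_up_threshold: float = 0.75
    assignment_window_bp: int = 100_000

    frac_genes_in_anchors: float = 0.6
    n_promoter_pair_loops: int = 40  # loops receiving a TSS in both anchors

    n_gene_clusters: int = 8
    genes_per_cluster: int = 3
    cluster_span_bp: int = 120_000
    cluster_pp_loop_prob: float = 0.9
    cluster_anchor_half_bp: int = 1500

    n_feature_rows_per_class: tuple[int, int] = (250, 750)  # (diff, nondiff)
    n_informative_features: int = 3
    n_noise_features: int = 8
    feature_effect_size: float = 1.0

    seed: int = 0


@dataclass
class SimulatedDataset:
    """In-memory dataset plus ground truth; ``write`` emits the file set."""

    config: SimulationConfig
    design: SampleDesign
    loops: list[Loop]
    genes: list[Gene]
    peaks: PeakSet
    features: FeatureMatrix
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "loops": outdir / "loops.bedpe",
            "genes": outdir / "genes.tsv",
            "peaks": outdir / "peaks.bed",
            "features": outdir / "features.tsv",
            "truth": outdir / "truth.json",
        }
        write_bedpe_loops(self.loops, self.design, paths["loops"])
        write_gene_table(self.genes, paths["genes"])
        write_bed(self.peaks, paths["peaks"])
        self.features.to_tsv(paths["features"])
        with open(paths["truth"], "w", encoding="utf-8") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        return paths


def _lognormal(rng: np.random.Generator, median: float, sigma: float, size=None):
    return np.exp(rng.normal(math.log(median), sigma, size=size))


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size: int):
    if mean <= 0:
        return np.zeros(size, dtype=int)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean), size=size)


def simulate(config: Optional[SimulationConfig] = None) -> SimulatedDataset:
    """Generate the full synthetic dataset from ``config`` (seeded)."""
    cfg = config or SimulationConfig()
    _validate(cfg)
    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_loops = np.random.default_rng(streams[0])
    rng_counts = np.random.default_rng(streams[1])
    rng_peaks = np.random.default_rng(streams[2])
    rng_expr = np.random.default_rng(streams[3])
    rng_feat = np.random.default_rng(streams[4])
    rng_cluster = np.random.default_rng(streams[5])

    design = _make_design(cfg)

    loops, loop_truth, gaps = _place_loops(cfg, rng_loops)
    genes, gene_anchor, cluster_loops, cluster_truth = _place_genes(
        cfg, rng_cluster, loops, gaps
    )
    all_loops = loops + cluster_loops
    for lp in cluster_loops:
        loop_truth[lp.loop_id] = {
            "status": "nondifferential",
            "direction": "ns",
            "true_log2fc": 0.0,
            "cluster_loop": True,
        }

    _draw_counts(cfg, rng_counts, all_loops, loop_truth, design)
    peak_truth = _place_peaks(cfg, rng_peaks, all_loops, loop_truth, gaps)
    peaks = PeakSet(
        Peak(
            GenomicInterval(p["chrom"], p["start"], p["end"]),
            p["peak_id"],
        )
        for p in peak_truth
    )
    truth_classes = _truth_loop_classes(all_loops, gene_anchor, cluster_loops)
    gene_truth, genes = _generate_expression(
        cfg, rng_expr, genes, all_loops, loop_truth, truth_classes, cluster_truth
    )
    features, feature_truth = _feature_matrix(cfg, rng_feat, all_loops, loop_truth)

    truth = {
        "seed": cfg.seed,
        "config": asdict(cfg),
        "samples": list(design.samples),
        "loops": loop_truth,
        "loop_classes": truth_classes,
        "peaks": peak_truth,
        "genes": gene_truth,
        "clusters": cluster_truth,
        "features": feature_truth,
        "betas": {
            "intercept": cfg.beta_intercept,
            "EE": cfg.beta_ee,
            "PE": cfg.beta_pe,
            "PP": cfg.beta_pp,
            "noise_sd": cfg.expr_noise_sd,
        },
    }
    return SimulatedDataset(
        config=cfg,
        design=design,
        loops=all_loops,
        genes=genes,
        peaks=peaks,
        features=features,
        truth=truth,
    )


def _validate(cfg: SimulationConfig) -> None:
    for name in (
        "frac_differential",
        "frac_increased_among_differential",
        "cluster_pp_loop_prob",
        "frac_genes_in_anchors",
    ):
        v = getattr(cfg, name)
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if cfg.chrom_length_bp <= 0 or cfg.n_loops <= 0:
        raise ValueError("lengths and counts must be positive")
    if len(cfg.sample_depth_factors) != 2 * cfg.n_replicates:
        raise ValueError("need one depth factor per sample")


def _make_design(cfg: SimulationConfig) -> SampleDesign:
    vehicle = tuple(f"vehicle_{i + 1}" for i in range(cfg.n_replicates))
    treated = tuple(f"treated_{i + 1}" for i in range(cfg.n_replicates))
    return SampleDesign.two_by_two(treated=treated, vehicle=vehicle)


def _place_loops(cfg: SimulationConfig, rng: np.random.Generator):
    """Sequentially pack loops onto chromosomes with a minimum gap.

    Returns (loops, per-loop truth, inter-loop gap intervals usable for
    gene placement).
    """
    n = cfg.n_loops
    differential = rng.random(n) < cfg.frac_differential
    increased = rng.random(n) < cfg.frac_increased_among_differential
    sizes = _lognormal(rng, cfg.anchor_size_median_bp, cfg.anchor_size_sigma, (n, 2))
    medians = np.where(
        differential, cfg.anchor_distance_median_diff_bp, cfg.anchor_distance_median_bp
    )
    distances = np.exp(
        rng.normal(np.log(medians), cfg.anchor_distance_sigma)
    )
    # keep the two anchors of a loop clear of each other (and of each
    # other's promoter windows)
    min_d = (sizes[:, 0] + sizes[:, 1]) / 2.0 + 2000.0
    distances = np.maximum(distances, min_d)

    loops: list[Loop] = []
    truth: dict[str, dict] = {}
    gaps: list[GenomicInterval] = []
    gap = cfg.min_inter_loop_gap_bp
    # round-robin across chromosomes; the tail of each chromosome stays free
    # for planted gene-cluster territories
    usable_end = cfg.chrom_length_bp - 10_000_000
    cursors = [gap] * cfg.n_chromosomes
    for i in range(n):
        chrom_idx = i % cfg.n_chromosomes
        s1, s2 = int(round(sizes[i, 0])), int(round(sizes[i, 1]))
        d = int(round(distances[i]))
        a1_start = cursors[chrom_idx]
        a1_end = a1_start + s1
        a2_mid = (a1_start + a1_end) // 2 + d
        a2_start = a2_mid - s2 // 2
        a2_end = a2_start + s2
        footprint_end = a2_end + gap
        if footprint_end > usable_end:
            raise ValueError(
                "infeasible packing: too many loops for the configured "
                "chromosome number/length"
            )
        chrom = f"chr{chrom_idx + 1}"
        loop_id = f"L{i:05d}"
        loops.append(
            Loop(
                loop_id=loop_id,
                anchor_a=GenomicInterval(chrom, a1_start, a1_end),
                anchor_b=GenomicInterval(chrom, a2_start, a2_end),
            )
        )
        if a2_start - a1_end > 4000:  # interior gap usable for gene placement
            gaps.append(GenomicInterval(chrom, a1_end + 2000, a2_start - 2000))
        if differential[i]:
            direction = "increased" if increased[i] else "decreased"
            effect = max(
                cfg.effect_log2fc_min,
                rng.normal(cfg.effect_log2fc_mean, cfg.effect_log2fc_sd),
            )
            log2fc = effect if direction == "increased" else -effect
        else:
            direction, log2fc = "ns", 0.0
        truth[loop_id] = {
            "status": "differential" if differential[i] else "nondifferential",
            "direction": direction,
            "true_log2fc": float(log2fc),
            "cluster_loop": False,
        }
        cursors[chrom_idx] = footprint_end
    return loops, truth, gaps


def _place_genes(cfg, rng, loops, gaps):
    """Place genes in anchors, in inter-anchor gaps, and in planted clusters.

    Returns (genes *without* expression yet, gene_id -> anchor key map,
    cluster P-P loops, cluster truth).
    """
    genes: list[Gene] = []
    gene_anchor: dict[str, tuple[str, int, int]] = {}
    strands = ("+", "-")

    n_cluster_genes = cfg.n_gene_clusters * cfg.genes_per_cluster
    n_regular = cfg.n_genes - n_cluster_genes
    if n_regular < 0:
        raise ValueError("n_genes too small for the configured clusters")
    n_in_anchor = int(round(cfg.frac_genes_in_anchors * n_regular))
    n_pair_loops = min(cfg.n_promoter_pair_loops, n_in_anchor // 2, len(loops))

    # promoter-pair loops: a TSS inside both anchors -> true P-P loops
    pair_loop_idx = rng.choice(len(loops), size=n_pair_loops, replace=False)
    taken_anchors: set[tuple[str, int, int]] = set()
    gid = 0

    def add_gene(chrom: str, tss: int, anchor_key=None) -> None:
        nonlocal gid
        g = Gene(
            gene_id=f"G{gid:04d}",
            symbol=f"GENE{gid:04d}",
            chrom=chrom,
            tss=tss,
            strand=strands[gid % 2],
        )
        genes.append(g)
        if anchor_key is not None:
            gene_anchor[g.gene_id] = anchor_key
        gid += 1

    def tss_in(anchor: GenomicInterval) -> int:
        lo, hi = anchor.start + 1, anchor.end - 2
        if hi <= lo:
            return anchor.start
        return int(rng.integers(lo, hi))

    for li in pair_loop_idx:
        for a in loops[li].anchors:
            key = (a.chrom, a.start, a.end)
            taken_anchors.add(key)
            add_gene(a.chrom, tss_in(a), key)
    n_single = n_in_anchor - 2 * n_pair_loops
    candidates = [
        (a.chrom, a.start, a.end, a)
        for lp in loops
        for a in lp.anchors
        if (a.chrom, a.start, a.end) not in taken_anchors
    ]
    pick = rng.choice(len(candidates), size=n_single, replace=False)
    for ci in pick:
        chrom, s, e, a = candidates[ci]
        add_gene(chrom, tss_in(a), (chrom, s, e))
    # remaining regular genes go into inter-anchor gaps (>= 2 kb from edges)
    n_in_gap = n_regular - n_in_anchor
    gap_pick = rng.choice(len(gaps), size=n_in_gap, replace=len(gaps) < n_in_gap)
    for giidx in gap_pick:
        g = gaps[giidx]
        add_gene(g.chrom, int(rng.integers(g.start, g.end)))

    # clusters: reserved territory near the end of each chromosome, past the
    # packed loops (the packer leaves the tail of every chromosome free)
    cluster_loops: list[Loop] = []
    cluster_truth: list[dict] = []
    half = cfg.cluster_anchor_half_bp
    span = cfg.cluster_span_bp
    for c in range(cfg.n_gene_clusters):
        chrom = f"chr{(c % cfg.n_chromosomes) + 1}"
        base = cfg.chrom_length_bp - (c // cfg.n_chromosomes + 1) * (span + 1_000_000)
        if base < 0:
            raise ValueError("chromosomes too short for cluster territories")
        step = span // max(1, cfg.genes_per_cluster - 1)
        members = []
        tss_list = []
        for m in range(cfg.genes_per_cluster):
            tss = base + m * step
            add_gene(chrom, tss)
            members.append(genes[-1].gene_id)
            tss_list.append(tss)
        connected = []
        for m in range(len(tss_list) - 1):
            if rng.random() < cfg.cluster_pp_loop_prob:
                lid = f"C{c:02d}_{m}"
                cluster_loops.append(
                    Loop(
                        loop_id=lid,
                        anchor_a=GenomicInterval(
                            chrom, tss_list[m] - half, tss_list[m] + half
                        ),
                        anchor_b=GenomicInterval(
                            chrom, tss_list[m + 1] - half, tss_list[m + 1] + half
                        ),
                    )
                )
                connected.append(lid)
        cluster_truth.append(
            {"cluster_id": c, "chrom": chrom, "members": members, "pp_loops": connected}
        )
    return genes, gene_anchor, cluster_loops, cluster_truth


def _draw_counts(cfg, rng, loops, loop_truth, design) -> None:
    base = _lognormal(rng, cfg.nb_mean_median, cfg.nb_mean_sigma, len(loops))
    depth = np.asarray(cfg.sample_depth_factors, dtype=float)
    n_veh = cfg.n_replicates
    for lp, mu in zip(loops, base):
        t = loop_truth[lp.loop_id]
        fold = 2.0 ** t["true_log2fc"]
        means = np.array([mu] * n_veh + [mu * fold] * n_veh) * depth
        counts = [
            int(_nb_draw(rng, m, cfg.nb_dispersion, 1)[0]) for m in means
        ]
        lp.counts = dict(zip(design.samples, counts))
        t["base_mean"] = float(mu)


def _place_peaks(cfg, rng, loops, loop_truth, gaps) -> list[dict]:
    """Peaks land on loop anchors (enriched at differential anchors) except
    for a configured fraction placed between loops, off any anchor."""
    anchors = []
    weights = []
    for lp in loops:
        is_diff = loop_truth[lp.loop_id]["status"] == "differential"
        for side, a in zip("ab", lp.anchors):
            anchors.append((lp.loop_id, side, a))
            weights.append(cfg.peak_differential_enrichment if is_diff else 1.0)
    weights = np.asarray(weights)
    p = weights / weights.sum()
    n_on = int(round(cfg.frac_peaks_on_anchors * cfg.n_peaks))
    chosen = rng.choice(len(anchors), size=n_on, replace=False, p=p)
    lo, hi = cfg.peak_size_range_bp
    out = []
    for ai in sorted(chosen.tolist()):
        loop_id, side, a = anchors[ai]
        size = min(int(rng.integers(lo, hi)), a.length - 2)
        start = int(rng.integers(a.start, a.end - size)) if a.end - size > a.start else a.start
        out.append(
            {
                "chrom": a.chrom,
                "start": start,
                "end": start + size,
                "anchor_loop": loop_id,
                "anchor_side": side,
            }
        )
    wide = [g for g in gaps if g.length > hi + 2000]
    pick = rng.choice(len(wide), size=cfg.n_peaks - n_on, replace=False)
    for gi in sorted(pick.tolist()):
        g = wide[gi]
        size = int(rng.integers(lo, hi))
        start = int(rng.integers(g.start + 1000, g.end - size - 1000))
        out.append(
            {
                "chrom": g.chrom,
                "start": start,
                "end": start + size,
                "anchor_loop": None,
                "anchor_side": None,
            }
        )
    out.sort(key=lambda d: (d["chrom"], d["start"]))
    for k, d in enumerate(out):
        d["peak_id"] = f"P{k:04d}"
    return out


def _truth_loop_classes(loops, gene_anchor, cluster_loops) -> dict[str, str]:
    """Loop classes implied by construction: an anchor is a promoter iff a
    TSS was planted in it (regular loops) or it is a cluster promoter anchor."""
    promoter_keys = set(gene_anchor.values())
    cluster_ids = {lp.loop_id for lp in cluster_loops}
    classes = {}
    for lp in loops:
        if lp.loop_id in cluster_ids:
            classes[lp.loop_id] = "PP"
            continue
        n_prom = sum(
            (a.chrom, a.start, a.end) in promoter_keys for a in lp.anchors
        )
        classes[lp.loop_id] = {2: "PP", 1: "PE", 0: "EE"}[n_prom]
    return classes


def _generate_expression(
    cfg, rng, genes, loops, loop_truth, truth_classes, cluster_truth
):
    """Expression log2fc from the planted linear model on per-gene counts of
    truly differential loops by class within the assignment window."""
    assignments = assign_loops_to_genes(loops, genes, cfg.assignment_window_bp)
    counts = {g.gene_id: {"EE": 0, "PE": 0, "PP": 0} for g in genes}
    for a in assignments:
        if loop_truth[a.loop_id]["status"] != "differential":
            continue
        counts[a.gene_id][truth_classes[a.loop_id]] += 1
    cluster_members = {m for c in cluster_truth for m in c["members"]}
    gene_truth = {}
    out_genes: list[Gene] = []
    noise = rng.normal(0.0, cfg.expr_noise_sd, len(genes))
    for g, eps in zip(genes, noise):
        c = counts[g.gene_id]
        mean = (
            cfg.beta_intercept
            + cfg.beta_ee * c["EE"]
            + cfg.beta_pe * c["PE"]
            + cfg.beta_pp * c["PP"]
        )
        expr = mean + eps
        if g.gene_id in cluster_members:
            regulation = "up"  # planted cluster label
        elif expr > cfg.regulation_up_threshold:
            regulation = "up"
        elif expr < -cfg.regulation_up_threshold:
            regulation = "down"
        else:
            regulation = "ns"
        out_genes.append(
            Gene(
                gene_id=g.gene_id,
                symbol=g.symbol,
                chrom=g.chrom,
                tss=g.tss,
                strand=g.strand,
                regulation=regulation,
                expr_log2fc=float(round(expr, 6)),
            )
        )
        gene_truth[g.gene_id] = {
            "true_mean_log2fc": float(mean),
            "diff_loop_counts": c,
            "cluster_member": g.gene_id in cluster_members,
        }
    return gene_truth, out_genes


def _feature_matrix(cfg, rng, loops, loop_truth):
    """Anchor-level feature matrix: informative features shift with the
    differential label; noise features do not. Class sizes are imbalanced to
    exercise the downsampling wrapper."""
    diff_anchors = []
    nondiff_anchors = []
    for lp in loops:
        is_diff = loop_truth[lp.loop_id]["status"] == "differential"
        for side in "ab":
            (diff_anchors if is_diff else nondiff_anchors).append(
                f"{lp.loop_id}_{side}"
            )
    n_diff, n_nondiff = cfg.n_feature_rows_per_class
    n_diff = min(n_diff, len(diff_anchors))
    n_nondiff = min(n_nondiff, len(nondiff_anchors))
    rows = [
        diff_anchors[i] for i in rng.choice(len(diff_anchors), n_diff, replace=False)
    ] + [
        nondiff_anchors[i]
        for i in rng.choice(len(nondiff_anchors), n_nondiff, replace=False)
    ]
    labels = np.array([1] * n_diff + [0] * n_nondiff)
    n_inf, n_noise = cfg.n_informative_features, cfg.n_noise_features
    names = [f"signal_{i}" for i in range(n_inf)] + [
        f"noise_{i}" for i in range(n_noise)
    ]
    values = rng.normal(0.0, 1.0, (len(rows), n_inf + n_noise))
    values[:, :n_inf] += cfg.feature_effect_size * labels[:, None]
    truth = {n: (i < n_inf) for i, n in enumerate(names)}
    matrix = FeatureMatrix(
        row_ids=rows, feature_names=names, values=values, labels=labels
    )
    return matrix, truth
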