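# Methods

This note documents the statistical procedures `chromaloop` implements, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and known limitations.

## Coordinates and distance rules

All intervals are 0-based half-open (BED convention); a TSS is a single
base. "Overlap" means ≥ 1 bp of intersection unless an operation exposes
`min_overlap_bp`. A promoter anchor is one that intersects the inclusive
window TSS ± 500 bp, applied symmetrically regardless of strand (no strand
rule is defined for these assays). TSS-to-anchor distance is 0 when the TSS
lies inside the anchor, otherwise the gap to the nearest covered base; the
5 kb and 100 kb gene-assignment windows use this edge-gap rule (a
midpoint-based alternative was considered and rejected as it penalizes
large anchors). Anchor-to-anchor loop distance uses midpoints. The median
of an even-sized sample is the mean of the central pair.

## Replicate-support filter

A loop is kept iff there exists a condition in which **every** replicate
has ≥ 1 read. With two replicates per condition this is the usual
both-replicates rule; the implementation generalizes to any replicate
number. The filter is monotone: adding reads never removes a loop.

## Differential testing

**Model.** Counts for loop *i*, sample *j* are NB(μ_ij, α) with
μ_ij = q_{i,g(j)} s_j and Var = μ + αμ². The two group means are free
parameters per loop (saturated two-group model, equivalent to an
intercept + condition-indicator GLM with log link and log s_j offsets).

**Size factors** are classical median-of-ratios: factor_j = median over
loops with positive geometric mean of count_ij / geomean_i.

**Dispersion.** `estimate_dispersion` provides the per-loop
method-of-moments estimator α = max(1e-8, (s² − m̄)/m̄²) on normalized
counts with condition means removed; it is accurate with many replicates
but pure noise on a 2 + 2 design (2 residual df). `call_differential`
therefore defaults to a single **pooled** dispersion maximizing the
Cox–Reid adjusted profile likelihood (the adjustment subtracts half the
log-determinant of the mean-parameter information, removing the downward
bias from profiling two means per loop). On simulated data with a true
common α = 0.1 this estimator recovers 0.099 where a naive pooled-moment
regression gave 0.156. No dispersion trend, fold-change shrinkage,
independent filtering, or outlier handling is applied — the stage is a
deliberately transparent counterpart to full RNA-seq-style machinery, and
numerical agreement with any specific external tool is not a goal.

**Test.** Wald z = (log q_t − log q_v) / SE with SE² = 1/I_t + 1/I_v from
the expected information I_g = Σ μ/(1+αμ), referred to a standard normal,
two-sided; BH adjustment; direction by the sign of log2FC at q < α
(default 0.05). A group with zero total counts gets a 0.5-read
pseudo-fraction for the reported fold change and the fit is flagged
"zero-inflated estimate"; an all-zero loop reports the null (p = 1).

**Calibration.** On a seeded 2 + 2 null (5,000 loops, α = 0.1) the raw
rejection rate at 0.05 is within 3 binomial SE of nominal and BH makes
essentially no discoveries; power for 4-fold changes at normalized mean
≥ 50 exceeds 0.9. Known limitation: with only 4 observations the normal
reference for the Wald statistic is tail-inflated (roughly 2× at
p ~ 1e-3), so the realized FDR among BH discoveries can run above nominal
(the end-to-end contract we validate is observed FDR ≤ 0.08 at q < 0.05,
and the measured value on the default dataset is ~0.05).

Two invariances hold exactly and are tested: swapping condition labels
negates every log2FC and preserves p-values; multiplying all size factors
by a constant changes nothing but the scale of the normalized means. Note
that rescaling **one** sample's counts together with its size factor is
*not* an invariance of a count-likelihood model — tripling a sample's reads
genuinely adds information — although it leaves the normalized means
unchanged.

## Peak (ERBS) integration

A peak "anchors" a loop when it overlaps either anchor by ≥ 1 bp.
Enrichment of peak-anchored loops among differential loops is an
upper-tail hypergeometric with the replicate-filtered loop set as the
universe (configurable; the appropriate universe is context-dependent).
ER-style connectivity classes: **primary** — either anchor overlaps a
peak; **secondary** — not primary, but an anchor overlaps an anchor of a
primary loop that relays to a peak. "Relays" is formalized as exactly one
intermediate loop; under the default `far_anchor` rule the intermediate
loop's opposite anchor must carry the peak (the chain anchor → shared
anchor → far anchor → peak), while `either_anchor` accepts any anchor
overlap with any primary loop. Deeper transitivity is deliberately
excluded. Redundancy metrics over target genes (upregulated genes with a
peak within 100 kb of the TSS): *multi-peak* — the promoter anchors ≥ 2
distinct P-E loops whose distal anchors overlap distinct peak ids;
*serial* — a peak on the distal anchor of one of the gene's P-E loops
connects through an E-E loop to an anchor carrying a second, distinct
peak. Peak distinctness means distinct ids even if the intervals are near.

## Gene-level statistics

The gene table counts loops interacting with each gene (either anchor
within the window of the TSS) stratified by class × status
(differential-up / differential-down / non-differential), optionally
restricted to primary (peak-anchored) loops. The regression
`expr_log2fc ~ EE + PE + PP` uses OLS with an intercept (the standard
`lm` default) and per-coefficient two-sided t-tests, df = n − p, on a
chosen gene subset (all / upregulated / downregulated; minimum 5 genes).

Preranked gene-set enrichment ranks genes by (increased − decreased)
loops within 100 kb, ties broken alphabetically so the ranking is
deterministic; the running-sum statistic increments |score|^w (w = 1
default, 0 available) normalized over set hits and decrements 1/(N − Nh)
at misses; significance comes from permuting set membership over rank
positions (gene-label permutation — appropriate for a preranked list),
enumerated exhaustively when C(N, Nh) is small and sampled (seeded)
otherwise, one-sided on the sign of the observed ES.

Rank-sum p-values are exact by enumeration when n_x + n_y ≤ 12 without
ties, otherwise normal with tie and continuity corrections. Fisher's
two-sided p sums tables with probability ≤ observed (small relative
tolerance), margins fixed. The hypergeometric upper tail is computed in
log space so extreme enrichments survive. ΔΔCt relative expression is
2^(−ΔΔCt) against a reference gene and calibrator condition; per-guide
hormone-response reduction is 100 × (response_ctrl − response_target) /
response_ctrl with response = fold_treated/fold_vehicle − 1, reported
unfloored (values < 0 or > 100 are meaningful).

## Promoter hubs

Gene pairs are unordered same-chromosome pairs with TSS distance ≤ 150 kb.
The clustering statistic compares each subset gene's nearest-neighbor TSS
distance (same chromosome; genes without a same-chromosome partner are
excluded and counted) against size-matched uniform draws from the full
annotation, two-sided rank-sum. With many pooled control draws the control
values are dependent (they share the finite gene universe) and the p-value
is mildly anticonservative — measured P(p ≤ 0.05) ≈ 0.07 under the null at
20 pooled draws; with a single control draw the two groups are
exchangeable under the null and the p-value is uniform (verified by KS
over 200 seeded runs). The pooling default (100) serves effect display;
calibration claims should use the exchangeable regime.

A pair is P-P connected when one loop has anchors within the promoter
window of both TSSs. The connectivity null redraws size-matched gene sets,
recomputes pairs and their connected fraction (a draw with no pairs
contributes 0 and is flagged), and reports the add-one empirical p, which
is bounded below by 1/(1 + n_resamples) and is super-uniform (conservative)
under the null because of ties at fraction 0.

## Feature selection

The Kruskal–Wallis screen applies scipy's tie-corrected H per feature with
BH q-values; constant features report H = 0, p = 1. The Boruta-style
selector appends a freshly shuffled shadow copy of every feature each
iteration, computes importances (injected callable; default a 50-tree
random-forest Gini importance, seeded), and scores a hit when a real
feature beats the **maximum** shadow importance. Decisions are made once
after the final iteration by binomial tests on hit counts with BH across
features — confirmation and rejection tested one-sided and corrected
separately. Two pitfalls motivated these choices, both measured during
development: deciding after every iteration is uncorrected sequential
peeking and confirmed chance-correlated noise columns in ~15% of
shuffled-label runs; and because the null hit probability is
~1/(n_features + 1), not 1/2, a joint two-sided correction lets the mass
of tiny rejection-side p-values inflate the BH threshold so borderline
flukes confirm. With end-of-run, split one-sided testing the shuffled-label
false-confirmation rate drops to a few percent — the residual cases are
columns whose sample correlation with the shuffled labels is genuinely
persistent in that finite dataset, which any all-relevant method will
flag. The downsampling wrapper balances classes by subsampling the larger
class to the smaller class's size each round (100 rounds default, 20
Boruta iterations per round) and aggregates per-feature confirmation
frequency and mean importance rank.

## Synthetic-data generator

One RNG stream per component (loops, counts, peaks, expression, features,
clusters) is spawned from the master seed, so changing one component's
parameters does not perturb the others. Defaults and what they emulate:

| parameter | default | rationale |
| --- | --- | --- |
| loops / genes / peaks | 5000 / 800 / 400 | desk-scale versions of the hundreds of thousands of loops a real experiment yields |
| anchor size | log-normal, median 2.9 kb (σ = 0.35) | typical H3K27ac HiChIP anchor size |
| anchor distance | log-normal, median 24 kb non-differential, 59 kb differential (σ = 0.7) | differential loops skew long-range |
| fraction differential | 0.15 | ~10% of loops changed in the motivating experiments |
| fraction increased | 0.70 | hormone treatment predominantly gains contacts |
| effect size | \|log2FC\| ~ N(2.0, 0.15), floor 0.5 | 4-fold planted changes, the regime the power contract is stated for |
| NB mean | log-normal, median 80 (σ = 0.6) | keeps most loops above normalized mean 50, where 2 + 2 testing has its stated power |
| NB dispersion | 0.1 | moderate biological variability |
| depth factors | (1.0, 1.3, 0.75, 1.1) | exercises size-factor estimation |
| peak placement | 70% on anchors, relative risk 6 on differential anchors | matches the observed ~70% of binding sites in loops and strong differential enrichment |
| expression | log2FC = 0.2 + 0.10·EE + 0.08·PE + 0.05·PP + N(0, 0.3) on per-gene truly-differential loop counts at 100 kb | the planted regression target |
| clusters | 8 clusters × 3 genes within 120 kb, adjacent promoters joined by P-P loops with probability 0.9 | promoter hubs of co-upregulated genes |
| features | 3 informative (1 SD shift) + 8 noise columns over 250 differential / 750 non-differential anchors | feature-selection target with class imbalance |

Loops are packed sequentially with a ≥ 5 kb inter-loop gap and round-robin
across chromosomes; gene TSSs are planted inside anchors (60% of regular
genes; 40 loops get a TSS in both anchors so true P-P loops with count
variation exist), in inter-anchor gaps ≥ 2 kb from any anchor, or in
reserved cluster territories at chromosome ends. This construction makes
the planted loop classes *provably* equal to what the promoter-window
classifier recomputes, which the truth-consistency tests exploit. Cluster
genes carry a planted "up" regulation label (their hub membership, not
their expression draw, defines them); other genes are labeled from their
expression value at ± 0.75.

What the generator deliberately does **not** emulate: shared and
overlapping anchors between loops (real HiChIP anchors overlap heavily —
that regime is covered by the randomized-instance oracle tests, not the
generator), restriction-fragment structure, distance-dependent contact
decay, ER secondary connectivity (sequential packing leaves no shared
anchors, so secondary/serial metrics are exercised on random instances
instead), and any sequence-level feature. Passing recovery tests therefore
demonstrates correctness of the statistics under the stated generative
model, not performance on real libraries.

## Numerical choices

Dispersion floor 1e-8; Newton/IRLS tolerance 1e-8 on the log-likelihood,
100 iterations maximum; dispersion optimization bounded on [1e-6, 10] in
log space. Hypergeometric tails in log space; Fisher tolerance the
conventional 1 + 1e-7 relative slack. Empirical resampling p-values use
the add-one rule and can never be 0. All seeds are recorded in run
manifests; every CLI stage writes outputs without timestamps so reruns are
byte-identical.
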