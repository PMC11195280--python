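"""Gene-centric statistics for loop/expression integration.

Builds the per-gene loop-count table (stratified by loop class, differential
status, and distance window), fits the expression-response regression,
ranks genes for preranked gene-set enrichment, and provides the enrichment,
rank-sum, Fisher, and qPCR (delta-delta-Ct) utilities used throughout the
pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from chromaloop.core_io import Gene, Loop
from chromaloop.loop_ops import assign_loops_to_genes

__all__ = [
    "GeneLoopTable",
    "OLSResult",
    "build_gene_table",
    "hypergeometric_enrichment",
    "ols_fit",
    "regression_report",
    "gsea_rank_metric",
    "preranked_es",
    "wilcoxon_rank_sum",
    "fisher_exact_2x2",
    "ddct_relative_expression",
    "e2_response_reduction",
]

LOOP_CLASSES = ("PP", "PE", "EE")
STATUSES = ("differential_up", "differential_down", "nondifferential")


@dataclass
class GeneLoopTable:
    """Per-gene loop counts by (class, status) for one assignment window.

    ``table`` is indexed by gene_id with columns ``<class>_<status>`` plus
    ``symbol``, ``regulation``, ``expr_log2fc``.
    """

    window_bp: int
    erbs_restricted: bool
    table: pd.DataFrame

    def counts(self, gene_id: str, loop_class: str, status: str) -> int:
        return int(self.table.loc[gene_id, f"{loop_class}_{status}"])

    def class_totals(self, gene_id: str) -> dict[str, int]:
        return {
            c: int(
                sum(self.table.loc[gene_id, f"{c}_{s}"] for s in STATUSES)
            )
            for c in LOOP_CLASSES
        }


@dataclass(frozen=True)
class CoefficientTest:
    estimate: float
    se: float
    t: float
    pvalue: float


@dataclass
class OLSResult:
    coefficients: dict[str, CoefficientTest]
    r_squared: float
    n: int


def _loop_status(lp: Loop) -> str:
    if lp.diff is None or lp.diff.direction == "ns":
        return "nondifferential"
    return "differential_up" if lp.diff.direction == "increased" else "differential_down"


def build_gene_table(
    genes: Sequence[Gene],
    loops: Sequence[Loop],
    window_bp: int,
    erbs_restricted: bool = False,
) -> GeneLoopTable:
    """Count loops interacting with each gene, stratified by class and status.

    A loop interacts with a gene when either anchor lies within ``window_bp``
    of its TSS (edge gap). With ``erbs_restricted`` only loops with
    ``er_class == "primary"`` are counted. Genes with no loops keep an
    all-zero row.
    """
    use_loops = [
        lp for lp in loops if not erbs_restricted or lp.er_class == "primary"
    ]
    cols = [f"{c}_{s}" for c in LOOP_CLASSES for s in STATUSES]
    table = pd.DataFrame(
        0,
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
        columns=cols,
    )
    loop_by_id = {lp.loop_id: lp for lp in use_loops}
    for a in assign_loops_to_genes(use_loops, genes, window_bp):
        lp = loop_by_id[a.loop_id]
        if lp.loop_class not in LOOP_CLASSES:
            raise ValueError(f"loop {lp.loop_id} is unclassified")
        table.loc[a.gene_id, f"{lp.loop_class}_{_loop_status(lp)}"] += 1
    table.insert(0, "symbol", [g.symbol for g in genes])
    table.insert(1, "regulation", [g.regulation for g in genes])
    table.insert(
        2,
        "expr_log2fc",
        [g.expr_log2fc if g.expr_log2fc is not None else np.nan for g in genes],
    )
    return GeneLoopTable(window_bp=window_bp, erbs_restricted=erbs_restricted, table=table)


def hypergeometric_enrichment(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric P(X >= k), X ~ Hypergeom(N, K, n).

    Computed in log space, so values like 1e-488 survive without underflow
    in the tail summation (the returned float still floors at ~5e-324).
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"invalid margins k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(np.exp(stats.hypergeom.logsf(k - 1, N, K, n)))


def log_hypergeometric_enrichment(k: int, K: int, n: int, N: int) -> float:
    """Natural-log upper-tail hypergeometric probability (for tiny p)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"invalid margins k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 0.0
    return float(stats.hypergeom.logsf(k - 1, N, K, n))


def ols_fit(
    response: Sequence[float],
    predictors: pd.DataFrame,
) -> OLSResult:
    """Ordinary least squares with intercept; per-coefficient two-sided
    t-tests with df = n - p."""
    y = np.asarray(response, dtype=float)
    X = sm.add_constant(predictors.astype(float), has_constant="add")
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than coefficients")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.loc[:, X.columns != "const"].corr().abs()
        np.fill_diagonal(corr.to_numpy(), 0.0)
        worst = corr.max().idxmax() if not corr.empty else "?"
        raise ValueError(f"design matrix is rank deficient (check column {worst!r})")
    fit = sm.OLS(y, X).fit()
    coefficients = {
        name: CoefficientTest(
            estimate=float(fit.params[name]),
            se=float(fit.bse[name]),
            t=float(fit.tvalues[name]),
            pvalue=float(fit.pvalues[name]),
        )
        for name in X.columns
    }
    return OLSResult(coefficients=coefficients, r_squared=float(fit.rsquared), n=len(y))


def regression_report(
    gene_table: GeneLoopTable,
    subset: str = "all",
    status: str = "differential",
) -> OLSResult:
    """Fit expr_log2fc ~ EE + PE + PP loop counts on a gene subset.

    ``subset`` is "upregulated", "downregulated", or "all" (genes with an
    expression value). ``status`` selects which loops are counted:
    "differential" (up + down), "nondifferential", or "all".
    """
    t = gene_table.table
    if subset == "upregulated":
        t = t[t.regulation == "up"]
    elif subset == "downregulated":
        t = t[t.regulation == "down"]
    elif subset != "all":
        raise ValueError(f"bad subset {subset!r}")
    t = t.dropna(subset=["expr_log2fc"])
    if len(t) < 5:
        raise ValueError(f"subset {subset!r} has {len(t)} genes; need >= 5")
    if status == "differential":
        statuses = ["differential_up", "differential_down"]
    elif status == "nondifferential":
        statuses = ["nondifferential"]
    elif status == "all":
        statuses = list(STATUSES)
    else:
        raise ValueError(f"bad status {status!r}")
    predictors = pd.DataFrame(
        {c: sum(t[f"{c}_{s}"] for s in statuses) for c in LOOP_CLASSES},
        index=t.index,
    )
    return ols_fit(t.expr_log2fc.to_numpy(), predictors)


def gsea_rank_metric(gene_table: GeneLoopTable) -> list[tuple[str, float]]:
    """Rank genes by differential-loop excess at the table's window.

    Score = (differential_up - differential_down) summed over loop classes;
    descending order, ties broken alphabetically by symbol.
    """
    t = gene_table.table
    up = sum(t[f"{c}_differential_up"] for c in LOOP_CLASSES)
    down = sum(t[f"{c}_differential_down"] for c in LOOP_CLASSES)
    score = (up - down).astype(float)
    order = sorted(
        zip(t.symbol, score), key=lambda x: (-x[1], x[0])
    )
    return [(sym, float(s)) for sym, s in order]


def preranked_es(
    ranked: Sequence[tuple[str, float]],
    gene_set: set[str],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Preranked GSEA enrichment score with a gene-label permutation p-value.

    The running statistic increments by |score|^weight (normalized over set
    hits) at set members and decrements by 1/(N - Nh) elsewhere; ES is the
    maximum deviation from zero, signed. The p-value permutes set membership
    over rank positions (two-sided on matching ES sign, as is conventional
    for preranked lists).
    """
    symbols = [g for g, _ in ranked]
    scores = np.array([s for _, s in ranked], dtype=float)
    hit = np.array([g in gene_set for g in symbols], dtype=bool)
    N = len(symbols)
    nh = int(hit.sum())
    if nh == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if nh == N:
        raise ValueError("gene set covers the whole ranked list; ES undefined")

    def es_for(hit_mask: np.ndarray) -> float:
        w = np.abs(scores) ** weight
        denom = w[hit_mask].sum()
        if denom == 0:  # all-zero scores at hits: fall back to unweighted
            steps_hit = np.full(N, 1.0 / hit_mask.sum())
        else:
            steps_hit = w / denom
        steps = np.where(hit_mask, steps_hit, -1.0 / (N - hit_mask.sum()))
        running = np.cumsum(steps)
        return float(running[np.argmax(np.abs(running))])

    es = es_for(hit)
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    # enumerate every membership exactly when that is cheaper than sampling
    if math.comb(N, nh) <= n_perm:
        from itertools import combinations

        perm_es = []
        for pos in combinations(range(N), nh):
            mask = np.zeros(N, dtype=bool)
            mask[list(pos)] = True
            perm_es.append(es_for(mask))
        perm_es = np.array(perm_es)
        extreme = int(np.sum(perm_es >= es) if es >= 0 else np.sum(perm_es <= es))
        pvalue = extreme / perm_es.size
        n_used = perm_es.size
        exact = True
    else:
        rng = np.random.default_rng(seed)
        perm_es = np.empty(n_perm)
        positions = np.arange(N)
        for i in range(n_perm):
            mask = np.zeros(N, dtype=bool)
            mask[rng.choice(positions, size=nh, replace=False)] = True
            perm_es[i] = es_for(mask)
        extreme = int(np.sum(perm_es >= es) if es >= 0 else np.sum(perm_es <= es))
        pvalue = (1 + extreme) / (1 + n_perm)
        n_used = n_perm
        exact = False
    return {"es": es, "pvalue": pvalue, "n_perm": n_used, "exact": exact, "n_hits": nh}


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> dict:
    """Two-sided rank-sum test; W is the rank sum of ``x`` with mid-ranks.

    Exact p by enumeration when n_x + n_y <= 12 and the pooled sample is
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0  # U -> rank sum
    return {"statistic": w, "pvalue": float(res.pvalue), "method": method}


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities no larger than the observed table's
    (with the conventional small relative tolerance), margins fixed.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cells must be non-negative integers")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def ddct_relative_expression(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the delta-delta-Ct method: 2^-ddCt."""
    for v in (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return 2.0 ** (-ddct)


def e2_response_reduction(
    fold_ctrl_e2: float,
    fold_ctrl_dmso: float,
    fold_tgt_e2: float,
    fold_tgt_dmso: float,
) -> float:
    """Percent reduction of the hormone response caused by a perturbation.

    The response under a guide condition is fold_e2 / fold_dmso - 1; the
    reduction is 100 * (response_ctrl - response_tgt) / response_ctrl. Not
    floored: values above 100 (over-ablation) or below 0 (potentiation) are
    reported as-is.
    """
    response_ctrl = fold_ctrl_e2 / fold_ctrl_dmso - 1.0
    if response_ctrl <= 0:
        raise ValueError("control response must be positive")
    response_tgt = fold_tgt_e2 / fold_tgt_dmso - 1.0
    return 100.0 * (response_ctrl - response_tgt) / response_ctrl
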