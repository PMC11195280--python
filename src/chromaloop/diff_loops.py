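"""Negative-binomial differential testing of loop counts between conditions.

The model: counts for loop i in sample j are NB-distributed with mean
``mu_ij = q_{i,g(j)} * s_j`` (group-specific normalized mean times a
per-sample size factor) and variance ``mu + alpha * mu**2``. The treated /
vehicle contrast is tested with a Wald statistic on
``log2fc = log2(q_treated / q_vehicle)``, whose standard error comes from
the expected Fisher information of the two group fits. Size factors use
median-of-ratios normalization; dispersion is method-of-moments, by default
pooled across loops because a 2 vs 2 design carries almost no per-loop
dispersion information. This is a deliberately transparent simplification of
the shrinkage machinery full RNA-seq-style packages apply (no dispersion
trend, no fold-change shrinkage, no outlier handling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from chromaloop.core_io import DifferentialResult, Loop, SampleDesign

__all__ = [
    "NBFit",
    "estimate_size_factors",
    "estimate_dispersion",
    "pooled_dispersion",
    "nb_wald_test",
    "adjust_bh",
    "call_differential",
]

DISPERSION_FLOOR = 1e-8
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100
LOG2 = math.log(2.0)


@dataclass
class NBFit:
    """Fitted two-group NB model for one loop."""

    mu_vehicle: float
    mu_treated: float
    dispersion: float
    log2fc: float
    se_log2fc: float
    wald_z: float
    pvalue: float
    flags: tuple[str, ...] = ()


def estimate_size_factors(count_matrix: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, one per sample (column).

    For each loop with a positive geometric mean, the ratio of each sample's
    count to that geometric mean is taken; the factor is the per-sample
    median ratio.
    """
    m = np.asarray(count_matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("count_matrix must be loops x samples")
    if np.any(m < 0):
        raise ValueError("counts must be non-negative")
    all_positive = np.all(m > 0, axis=1)
    if not np.any(all_positive):
        raise ValueError(
            "no loop with all-positive counts; median-of-ratios is undefined "
            "(consider a pseudo-reference fallback)"
        )
    log_geomean = np.mean(np.log(m[all_positive]), axis=1)
    ratios = np.log(m[all_positive]) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return factors


def estimate_dispersion(
    counts_for_loop: Sequence[float],
    size_factors: Sequence[float],
    design: SampleDesign,
) -> float:
    """Method-of-moments NB dispersion for one loop.

    Normalized counts are pooled across conditions after removing the
    condition means; ``alpha = max(floor, (s2 - mbar) / mbar**2)`` with
    ``mbar`` the grand normalized mean and ``s2`` the pooled residual
    variance (denominator n - n_conditions).
    """
    y = np.asarray(counts_for_loop, dtype=float)
    sf = np.asarray(size_factors, dtype=float)
    norm = y / sf
    if np.all(y == 0):
        return DISPERSION_FLOOR
    resid = np.empty_like(norm)
    groups = [
        [i for i, s in enumerate(design.samples) if design.condition[s] == c]
        for c in design.conditions
    ]
    for idx in groups:
        if len(idx) < 2:
            raise ValueError("need >=2 samples per condition for dispersion")
        resid[idx] = norm[idx] - norm[idx].mean()
    df = len(norm) - len(groups)
    s2 = float(np.sum(resid**2) / df)
    mbar = float(norm.mean())
    return max(DISPERSION_FLOOR, (s2 - mbar) / mbar**2)


def _fit_group_means_vectorized(
    counts: np.ndarray, sf: np.ndarray, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-loop MLE of the normalized group mean for one condition's columns.

    Returns (mu matrix on count scale, Fisher information of log-mean).
    All-zero loops get a 0.5-read pseudo-total so the log stays finite.
    """
    total = counts.sum(axis=1)
    beta = np.log(np.maximum(total, 0.5) / sf.sum())
    for _ in range(IRLS_MAX_ITER):
        mu = np.exp(beta)[:, None] * sf
        w = 1.0 + alpha * mu
        score = ((counts - mu) / w).sum(axis=1)
        info = (mu / w).sum(axis=1)
        step = np.where(total > 0, score / info, 0.0)
        beta = beta + step
        if np.max(np.abs(step)) < IRLS_TOL:
            break
    mu = np.exp(beta)[:, None] * sf
    info = (mu / (1.0 + alpha * mu)).sum(axis=1)
    return mu, info


def pooled_dispersion(
    count_matrix: np.ndarray,
    size_factors: np.ndarray,
    design: SampleDesign,
    bounds: tuple[float, float] = (1e-6, 10.0),
) -> float:
    """Single dispersion shared by all loops.

    Maximizes the Cox-Reid adjusted profile likelihood for a common NB
    dispersion, with the two group means profiled out per loop. The
    adjustment (minus half the log-determinant of the mean-parameter
    information) removes the downward bias the plain profile MLE suffers
    from estimating two means per loop; with few replicates the per-loop
    moment estimator is essentially noise, so sharing information across
    loops is what makes the Wald test usable on a 2 vs 2 design.
    """
    from scipy.optimize import minimize_scalar
    from scipy.special import gammaln

    m = np.asarray(count_matrix, dtype=float)
    sf = np.asarray(size_factors, dtype=float)
    informative = m.sum(axis=1) > 0
    if not np.any(informative):
        return DISPERSION_FLOOR
    m = m[informative]
    groups = [
        np.array(
            [i for i, s in enumerate(design.samples) if design.condition[s] == c]
        )
        for c in design.conditions
    ]

    def neg_crapl(log_alpha: float) -> float:
        alpha = math.exp(log_alpha)
        r = 1.0 / alpha
        ll = 0.0
        cr = 0.0
        for ii in groups:
            mu, info = _fit_group_means_vectorized(m[:, ii], sf[ii], alpha)
            y = m[:, ii]
            ll += float(
                np.sum(
                    gammaln(y + r)
                    - gammaln(r)
                    + y * np.log(mu / (mu + r))
                    + r * np.log(r / (mu + r))
                )
            )
            cr += 0.5 * float(np.sum(np.log(info)))
        return -(ll - cr)

    res = minimize_scalar(
        neg_crapl,
        bounds=(math.log(bounds[0]), math.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return max(DISPERSION_FLOOR, math.exp(res.x))


def _fit_group_mean(
    y: np.ndarray, sf: np.ndarray, alpha: float
) -> tuple[float, float, bool]:
    """MLE of the normalized group mean q (log-link Newton iterations).

    Returns (q, fisher_information_of_log_q, zero_group_flag). For an
    all-zero group the estimate sits on the boundary; a pseudo-fraction of
    0.5 reads is used and the fit flagged.
    """
    total = float(y.sum())
    if total == 0.0:
        q = 0.5 / float(sf.sum())
        mu = q * sf
        info = float(np.sum(mu / (1.0 + alpha * mu)))
        return q, info, True
    beta = math.log(total / float(sf.sum()))  # Poisson MLE start
    ll_old = None
    for _ in range(IRLS_MAX_ITER):
        mu = np.exp(beta) * sf
        w = 1.0 + alpha * mu
        score = float(np.sum((y - mu) / w))
        info = float(np.sum(mu / w))
        beta += score / info
        mu = np.exp(beta) * sf
        ll = float(np.sum(y * np.log(mu) - (y + 1.0 / alpha) * np.log1p(alpha * mu))) if alpha > 0 else float(np.sum(y * np.log(mu) - mu))
        if ll_old is not None and abs(ll - ll_old) < IRLS_TOL:
            break
        ll_old = ll
    mu = np.exp(beta) * sf
    info = float(np.sum(mu / (1.0 + alpha * mu)))
    return math.exp(beta), info, False


def nb_wald_test(
    loop: Loop,
    size_factors: Sequence[float],
    design: SampleDesign,
    dispersion: float,
) -> NBFit:
    """Two-group NB Wald test for one loop.

    Group means are fit by Newton iterations on the log scale with
    ``log(size_factor)`` offsets; the Wald z is the log-fold-change divided
    by its expected-information standard error, referred to a standard
    normal, two-sided.
    """
    sf = np.asarray(size_factors, dtype=float)
    y = np.asarray([loop.counts[s] for s in design.samples], dtype=float)
    alpha = max(dispersion, DISPERSION_FLOOR)
    idx = {
        c: np.array(
            [i for i, s in enumerate(design.samples) if design.condition[s] == c]
        )
        for c in design.conditions
    }
    q = {}
    info = {}
    flags: list[str] = []
    for cond, ii in idx.items():
        q[cond], info[cond], zero = _fit_group_mean(y[ii], sf[ii], alpha)
        if zero:
            flags.append("zero-inflated estimate")
    se_log = math.sqrt(1.0 / info["treated"] + 1.0 / info["vehicle"])
    log2fc = (math.log(q["treated"]) - math.log(q["vehicle"])) / LOG2
    se_log2fc = se_log / LOG2
    wald_z = log2fc / se_log2fc
    pvalue = 2.0 * stats.norm.sf(abs(wald_z))
    if np.all(y == 0):
        # no information at all: report the null
        log2fc, wald_z, pvalue = 0.0, 0.0, 1.0
        flags.append("all-zero loop")
    return NBFit(
        mu_vehicle=q["vehicle"],
        mu_treated=q["treated"],
        dispersion=alpha,
        log2fc=log2fc,
        se_log2fc=se_log2fc,
        wald_z=wald_z,
        pvalue=min(1.0, pvalue),
        flags=tuple(flags),
    )


def adjust_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    loops: Sequence[Loop],
    design: SampleDesign,
    alpha: float = 0.05,
    dispersion_mode: str = "pooled",
) -> dict:
    """Run the full differential stage and attach DifferentialResult to loops.

    dispersion_mode "pooled" (default) shares one moment-pooled dispersion
    across loops; "per_loop" uses the per-loop moment estimate (only
    sensible with many replicates).

    Returns a summary dict with the per-loop fits and the fraction of
    differential loops that increased.
    """
    if dispersion_mode not in ("pooled", "per_loop"):
        raise ValueError("dispersion_mode must be 'pooled' or 'per_loop'")
    loops = list(loops)
    if not loops:
        return {
            "n_loops": 0,
            "n_differential": 0,
            "fraction_increased": float("nan"),
            "fits": [],
            "size_factors": {},
        }
    matrix = np.array(
        [[lp.counts[s] for s in design.samples] for lp in loops], dtype=float
    )
    sf = estimate_size_factors(matrix)
    if dispersion_mode == "pooled":
        shared = pooled_dispersion(matrix, sf, design)
        dispersions = [shared] * len(loops)
    else:
        dispersions = [
            estimate_dispersion(row, sf, design) for row in matrix
        ]
    fits = [
        nb_wald_test(lp, sf, design, d) for lp, d in zip(loops, dispersions)
    ]
    qvalues = adjust_bh([f.pvalue for f in fits])
    n_up = n_down = 0
    for lp, fit, qv in zip(loops, fits, qvalues):
        if qv < alpha and fit.log2fc > 0:
            direction = "increased"
            n_up += 1
        elif qv < alpha and fit.log2fc < 0:
            direction = "decreased"
            n_down += 1
        else:
            direction = "ns"
        lp.diff = DifferentialResult(
            log2fc=fit.log2fc,
            pvalue=fit.pvalue,
            qvalue=float(qv),
            direction=direction,
        )
    n_diff = n_up + n_down
    return {
        "n_loops": len(loops),
        "n_differential": n_diff,
        "n_increased": n_up,
        "n_decreased": n_down,
        "fraction_increased": (n_up / n_diff) if n_diff else float("nan"),
        "fits": fits,
        "size_factors": dict(zip(design.samples, sf.tolist())),
        "dispersion_mode": dispersion_mode,
        "alpha": alpha,
    }
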