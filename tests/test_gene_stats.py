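"""Gene-centric statistics: tables, regression, GSEA, exact tests, qPCR."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from chromaloop.core_io import DifferentialResult, Gene, GenomicInterval, Loop
from chromaloop.gene_stats import (
    build_gene_table,
    ddct_relative_expression,
    e2_response_reduction,
    fisher_exact_2x2,
    gsea_rank_metric,
    hypergeometric_enrichment,
    ols_fit,
    preranked_es,
    regression_report,
    wilcoxon_rank_sum,
)
from conftest import oracle_tss_anchor_gap, random_genes, random_loops


def _gene(gene_id, tss, chrom="chr1", regulation="ns", fc=0.0):
    return Gene(gene_id, gene_id, chrom, tss, "+", regulation, fc)


def _classified_loop(lid, a, b, cls, direction="ns", chrom="chr1"):
    lp = Loop(lid, GenomicInterval(chrom, *a), GenomicInterval(chrom, *b))
    lp.loop_class = cls
    if direction == "ns":
        lp.diff = DifferentialResult(0.0, 0.5, 0.5, "ns")
    else:
        fc = 1.0 if direction == "increased" else -1.0
        lp.diff = DifferentialResult(fc, 1e-4, 1e-3, direction)
    return lp


class TestGeneTable:
    def test_single_increased_pe_loop_within_5kb(self):
        gene = _gene("G1", 10_000)
        lp = _classified_loop("L1", (9000, 9500), (50_000, 50_500), "PE", "increased")
        table = build_gene_table([gene], [lp], 5000)
        assert table.counts("G1", "PE", "differential_up") == 1
        assert table.table.drop(columns=["symbol", "regulation", "expr_log2fc"]).to_numpy().sum() == 1

    def test_gene_with_no_loops_keeps_zero_row(self):
        gene = _gene("G1", 10_000_000)
        lp = _classified_loop("L1", (9000, 9500), (50_000, 50_500), "EE")
        table = build_gene_table([gene], [lp], 5000)
        assert table.table.loc["G1", "EE_nondifferential"] == 0

    def test_erbs_restriction_keeps_only_primary_loops(self):
        gene = _gene("G1", 10_000)
        lp1 = _classified_loop("L1", (9000, 9500), (50_000, 50_500), "PE")
        lp2 = _classified_loop("L2", (9100, 9600), (70_000, 70_500), "PE")
        lp1.er_class, lp2.er_class = "primary", "unrelated"
        full = build_gene_table([gene], [lp1, lp2], 5000)
        restricted = build_gene_table([gene], [lp1, lp2], 5000, erbs_restricted=True)
        assert full.counts("G1", "PE", "nondifferential") == 2
        assert restricted.counts("G1", "PE", "nondifferential") == 1

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_recount(self, design, seed):
        from chromaloop.loop_ops import classify_loops

        rng = np.random.default_rng(seed)
        loops = random_loops(rng, 30, design)
        genes = random_genes(rng, 20)
        classify_loops(loops, genes)
        for lp in loops:
            d = ("ns", "increased", "decreased")[rng.integers(3)]
            fc = {"ns": 0.0, "increased": 1.0, "decreased": -1.0}[d]
            lp.diff = DifferentialResult(fc, 0.01, 0.01 if d != "ns" else 0.5, d)
        window = 20_000
        table = build_gene_table(genes, loops, window)
        status = {
            "increased": "differential_up",
            "decreased": "differential_down",
            "ns": "nondifferential",
        }
        for g in genes:
            for lp in loops:
                pass
            expected = {}
            for lp in loops:
                if lp.chrom != g.chrom:
                    continue
                if min(oracle_tss_anchor_gap(a, g.tss) for a in lp.anchors) <= window:
                    key = (lp.loop_class, status[lp.diff.direction])
                    expected[key] = expected.get(key, 0) + 1
            for cls in ("PP", "PE", "EE"):
                for st in status.values():
                    assert table.counts(g.gene_id, cls, st) == expected.get(
                        (cls, st), 0
                    )


def oracle_hypergeom_upper(k, K, n, N):
    total = Fraction(math.comb(N, n))
    acc = Fraction(0)
    for x in range(k, min(K, n) + 1):
        acc += Fraction(math.comb(K, x) * math.comb(N - K, n - x))
    return acc / total


class TestHypergeometric:
    def test_small_margin_value(self):
        assert hypergeometric_enrichment(2, 3, 3, 6) == pytest.approx(0.5, rel=1e-12)

    def test_k_zero_is_one(self):
        assert hypergeometric_enrichment(0, 5, 5, 20) == 1.0

    def test_margin_validation(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(4, 3, 3, 6)

    def test_matches_exact_summation_over_small_margins(self):
        for N in (5, 11, 17):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        got = hypergeometric_enrichment(k, K, n, N)
                        exp = float(oracle_hypergeom_upper(k, K, n, N))
                        assert got == pytest.approx(exp, abs=1e-10), (k, K, n, N)


class TestOLS:
    def test_perfect_line(self):
        res = ols_fit([1, 2, 3], pd.DataFrame({"x": [1.0, 2, 3]}))
        assert res.coefficients["x"].estimate == pytest.approx(1.0)
        assert res.coefficients["const"].estimate == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        y = rng.normal(size=30)
        r1 = ols_fit(y, X)
        perm = rng.permutation(30)
        r2 = ols_fit(y[perm], X.iloc[perm].reset_index(drop=True))
        for name in r1.coefficients:
            assert r2.coefficients[name].estimate == pytest.approx(
                r1.coefficients[name].estimate, rel=1e-9
            )
            assert r2.coefficients[name].pvalue == pytest.approx(
                r1.coefficients[name].pvalue, rel=1e-9
            )

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_pseudoinverse_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 40, 3
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=list("abc"))
        y = rng.normal(size=n)
        res = ols_fit(y, X)
        Xd = np.column_stack([np.ones(n), X.to_numpy()])
        beta = np.linalg.pinv(Xd) @ y
        resid = y - Xd @ beta
        sigma2 = resid @ resid / (n - p - 1)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(Xd.T @ Xd)))
        for j, name in enumerate(["const", "a", "b", "c"]):
            assert res.coefficients[name].estimate == pytest.approx(beta[j], abs=1e-8)
            assert res.coefficients[name].se == pytest.approx(se[j], abs=1e-8)

    def test_rank_deficiency_names_a_column(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError, match="rank deficient"):
            ols_fit([1, 2, 3, 4], X)


class TestRegressionReport:
    @staticmethod
    def _planted_table(rng, n=800, beta_ee=0.1, sigma=0.3):
        ee = rng.poisson(2.0, n)
        pe = rng.poisson(1.0, n)
        pp = rng.poisson(0.5, n)
        y = 0.2 + beta_ee * ee + 0.05 * pe + 0.02 * pp + rng.normal(0, sigma, n)
        from chromaloop.gene_stats import GeneLoopTable

        cols = {
            "symbol": [f"S{i}" for i in range(n)],
            "regulation": ["up"] * n,
            "expr_log2fc": y,
        }
        for cls, v in (("PP", pp), ("PE", pe), ("EE", ee)):
            cols[f"{cls}_differential_up"] = v
            cols[f"{cls}_differential_down"] = 0
            cols[f"{cls}_nondifferential"] = 0
        df = pd.DataFrame(cols, index=pd.Index([f"G{i}" for i in range(n)], name="gene_id"))
        return GeneLoopTable(window_bp=100_000, erbs_restricted=False, table=df)

    def test_recovers_planted_coefficient(self):
        rng = np.random.default_rng(2024)
        table = self._planted_table(rng)
        res = regression_report(table, "upregulated")
        ee = res.coefficients["EE"]
        assert abs(ee.estimate - 0.1) < 0.03
        assert ee.pvalue < 0.01

    def test_null_coefficients_calibrated(self):
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(200):
            table = self._planted_table(rng, n=120, beta_ee=0.0)
            res = regression_report(table, "all")
            pvals.append(res.coefficients["EE"].pvalue)
        from scipy import stats

        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_tiny_subset_is_an_error(self):
        rng = np.random.default_rng(1)
        table = self._planted_table(rng, n=3)
        with pytest.raises(ValueError, match="need >= 5"):
            regression_report(table, "upregulated")


class TestGseaRankMetric:
    def test_score_is_up_minus_down_at_window(self):
        gene = _gene("G1", 10_000)
        loops = [
            _classified_loop("L1", (9000, 9500), (50_000, 50_500), "PE", "increased"),
            _classified_loop("L2", (9100, 9600), (70_000, 70_500), "EE", "increased"),
            _classified_loop("L3", (9200, 9700), (80_000, 80_500), "EE", "increased"),
            _classified_loop("L4", (9300, 9800), (90_000, 90_500), "PP", "decreased"),
        ]
        table = build_gene_table([gene], loops, 100_000)
        assert gsea_rank_metric(table) == [("G1", 2.0)]

    def test_all_zero_scores_rank_alphabetically(self):
        genes = [_gene(g, 10_000 * (i + 1)) for i, g in enumerate(["B1", "A1", "C1"])]
        table = build_gene_table(genes, [], 5000)
        assert [g for g, _ in gsea_rank_metric(table)] == ["A1", "B1", "C1"]


class TestPrerankedES:
    def test_top_gene_singleton_set_weight_zero(self):
        ranked = [("A", 5.0), ("B", 3.0), ("C", 1.0), ("D", 0.5)]
        res = preranked_es(ranked, {"A"}, weight=0.0, n_perm=100, seed=1)
        assert res["es"] == pytest.approx(1.0)

    def test_set_covering_everything_is_an_error(self):
        ranked = [("A", 2.0), ("B", 1.0)]
        with pytest.raises(ValueError, match="whole ranked list"):
            preranked_es(ranked, {"A", "B"}, n_perm=100, seed=0)

    def test_empty_intersection_is_an_error(self):
        with pytest.raises(ValueError, match="intersect"):
            preranked_es([("A", 1.0)], {"Z"}, n_perm=100, seed=0)

    def test_small_list_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        scores = sorted(rng.normal(size=7).tolist(), reverse=True)
        ranked = [(f"G{i}", s) for i, s in enumerate(scores)]
        members = {"G1", "G4"}
        res = preranked_es(ranked, members, weight=1.0, n_perm=100, seed=0)
        assert res["exact"]

        # independent recomputation of the running statistic
        def es_of(hit_positions):
            w = [abs(s) for _, s in ranked]
            denom = sum(w[i] for i in hit_positions)
            run, best = 0.0, 0.0
            for i in range(len(ranked)):
                if i in hit_positions:
                    run += w[i] / denom
                else:
                    run -= 1.0 / (len(ranked) - len(hit_positions))
                if abs(run) > abs(best):
                    best = run
            return best

        obs = es_of({1, 4})
        assert res["es"] == pytest.approx(obs, rel=1e-12)
        perm = [
            es_of(set(c)) for c in itertools.combinations(range(7), 2)
        ]
        if obs >= 0:
            expected_p = sum(e >= obs for e in perm) / len(perm)
        else:
            expected_p = sum(e <= obs for e in perm) / len(perm)
        assert res["pvalue"] == pytest.approx(expected_p, rel=1e-12)

    def test_tied_genes_cannot_perturb_es_through_the_rank_metric(self):
        """ES depends on rank positions, so exchangeability of equal-score
        genes is guaranteed by gsea_rank_metric's deterministic alphabetical
        tie-break: reordering the gene table never changes the ranking."""
        genes = [_gene(g, 10_000 * (i + 1)) for i, g in enumerate(["B1", "A1", "C1"])]
        loops = [
            _classified_loop("L1", (9000, 9500), (50_000, 50_500), "PE", "increased"),
        ]
        t1 = build_gene_table(genes, loops, 100_000)
        t2 = build_gene_table(genes[::-1], loops, 100_000)
        ranked1, ranked2 = gsea_rank_metric(t1), gsea_rank_metric(t2)
        assert ranked1 == ranked2
        r1 = preranked_es(ranked1, {"A1"}, n_perm=100, seed=3)
        r2 = preranked_es(ranked2, {"A1"}, n_perm=100, seed=3)
        assert r1["es"] == pytest.approx(r2["es"])


def oracle_ranksum_exact(x, y):
    """Two-sided exact rank-sum p by enumerating label assignments."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    nx = len(x)
    ws = [
        sum(c) for c in itertools.combinations(range(1, len(pooled) + 1), nx)
    ]
    mean_w = nx * (len(pooled) + 1) / 2
    dev = abs(w_obs - mean_w)
    extreme = sum(abs(w - mean_w) >= dev - 1e-12 for w in ws)
    return extreme / len(ws)


class TestWilcoxon:
    def test_exact_small_sample(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res["method"] == "exact"
        assert res["statistic"] == 3.0
        assert res["pvalue"] == pytest.approx(1 / 3, rel=1e-12)

    def test_tied_singletons_give_p_one(self):
        assert wilcoxon_rank_sum([1.0], [1.0])["pvalue"] == 1.0

    @pytest.mark.parametrize("seed", range(60))
    def test_exact_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        nx = int(rng.integers(2, 6))
        ny = int(rng.integers(2, 13 - nx))
        vals = rng.permutation(100)[: nx + ny].tolist()  # tie-free
        x, y = vals[:nx], vals[nx:]
        res = wilcoxon_rank_sum(x, y)
        assert res["method"] == "exact"
        assert res["pvalue"] == pytest.approx(oracle_ranksum_exact(x, y), abs=1e-10)

    def test_large_sample_null_uniformity(self):
        from scipy import stats

        rng = np.random.default_rng(12)
        pvals = [
            wilcoxon_rank_sum(rng.normal(size=30), rng.normal(size=35))["pvalue"]
            for _ in range(1000)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


def oracle_fisher_two_sided(a, b, c, d):
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2
    total = Fraction(math.comb(N, c1))

    def prob(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return Fraction(0)
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x)) / total

    p_obs = prob(a)
    cutoff = p_obs * Fraction(10**7 + 1, 10**7)  # relative tolerance
    return float(sum(prob(x) for x in range(0, c1 + 1) if prob(x) <= cutoff))


class TestFisher:
    def test_diagonal_table(self):
        assert fisher_exact_2x2(2, 0, 0, 2) == pytest.approx(1 / 3, rel=1e-9)

    def test_balanced_table_is_one(self):
        assert fisher_exact_2x2(1, 1, 1, 1) == pytest.approx(1.0)

    def test_empty_margin_gives_one(self):
        assert fisher_exact_2x2(0, 0, 3, 4) == 1.0

    def test_matches_enumeration_over_small_margins(self):
        for a in range(0, 7):
            for b in range(0, 7):
                for c in range(0, 7):
                    for d in range(0, 7):
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        got = fisher_exact_2x2(a, b, c, d)
                        exp = oracle_fisher_two_sided(a, b, c, d)
                        assert got == pytest.approx(exp, abs=1e-10), (a, b, c, d)


class TestQPCR:
    def test_ddct_arithmetic(self):
        assert ddct_relative_expression(20, 18, 22, 18) == pytest.approx(4.0)

    def test_sample_equals_calibrator_gives_unit_fold(self):
        assert ddct_relative_expression(21, 19, 21, 19) == 1.0

    def test_reciprocity(self):
        f = ddct_relative_expression(20, 17, 23, 19)
        g = ddct_relative_expression(23, 19, 20, 17)
        assert f * g == pytest.approx(1.0)

    def test_response_reduction_examples(self):
        # control response 9 (10-fold over 1), targeted response 4 -> 55.6%
        assert e2_response_reduction(10, 1, 5, 1) == pytest.approx(100 * 5 / 9)
        assert e2_response_reduction(10, 1, 10, 1) == 0.0
        assert e2_response_reduction(10, 1, 1, 1) == pytest.approx(100.0)
        with pytest.raises(ValueError, match="control response"):
            e2_response_reduction(1, 1, 2, 1)
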