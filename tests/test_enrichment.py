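"""Enrichment and genomics tests: GSEA running sum against a direct
Kolmogorov-Smirnov oracle, exact hypergeometric/Fisher enumeration oracles,
MAF mutation comparison and burden counting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tmescore.containers import Unit
from tmescore.enrichment import (
    _enrichment_score,
    fisher_2x2,
    gsea,
    mutation_compare,
    ora_hypergeom,
    read_gmt,
    stratify_combination,
    tmb_from_maf,
    write_gmt,
)
from tmescore.synthetic import simulate_survival

from conftest import make_expression


# ---------------------------------------------------------------------------
# GMT IO
# ---------------------------------------------------------------------------

class TestGmt:
    def test_parse_and_dedup(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("SET_A\tdesc\tG1\tG2\nSET_B\tdesc\tG3\tG3\tG4\n")
        sets = read_gmt(p)
        assert sets["SET_A"] == ["G1", "G2"]
        assert sets["SET_B"] == ["G3", "G4"]

    def test_short_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("SET_A\tdesc\tG1\nBAD_LINE\tonly-desc\n")
        with pytest.raises(ValueError, match="line 2"):
            read_gmt(p)

    def test_round_trip_fifty_sets(self, tmp_path):
        rng = np.random.default_rng(0)
        sets = {f"SET_{i:02d}": [f"GENE{g}" for g in
                                 rng.choice(500, size=rng.integers(3, 30),
                                            replace=False)]
                for i in range(50)}
        p = tmp_path / "roundtrip.gmt"
        write_gmt(sets, p)
        assert read_gmt(p) == sets


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------

def _ks_oracle(metric, hit_idx):
    """Classical unweighted running-sum statistic, computed step by step."""
    order = np.argsort(-metric, kind="mergesort")
    hits = set(hit_idx.tolist())
    nh = len(hits)
    n = metric.size
    value, best = 0.0, 0.0
    for g in order:
        value += 1.0 / nh if g in hits else -1.0 / (n - nh)
        if abs(value) > abs(best):
            best = value
    return best


class TestGsea:
    def test_weight_zero_equals_ks_statistic(self):
        rng = np.random.default_rng(1)
        metric = rng.normal(size=200)
        for seed in range(5):
            hit_idx = np.random.default_rng(seed).choice(200, 25,
                                                         replace=False)
            es = _enrichment_score(metric, hit_idx, weight=0)
            assert es == pytest.approx(_ks_oracle(metric, hit_idx),
                                       abs=1e-12)

    def test_top_ranked_set_has_extreme_es(self):
        rng = np.random.default_rng(2)
        X = rng.normal(5, 1, size=(300, 20))
        pheno = pd.Series([1] * 10 + [0] * 10)
        X[:15, :10] += 3.0  # top genes of the ranking
        expr = make_expression(X, Unit.LOG2TPM)
        pheno.index = expr.sample_ids
        sets = {"TOP": [f"G{i}" for i in range(15)]}
        res = gsea(expr, pheno, sets, n_perm=50, seed=3)
        assert res.loc["TOP", "es"] > 0.9
        assert res.loc["TOP", "direction"] == "high-enriched"
        assert np.sign(res.loc["TOP", "nes"]) == np.sign(res.loc["TOP", "es"])

    def test_nominal_p_within_permutation_bounds(self):
        rng = np.random.default_rng(4)
        X = rng.normal(5, 1, size=(200, 16))
        expr = make_expression(X, Unit.LOG2TPM)
        pheno = pd.Series([1] * 8 + [0] * 8, index=expr.sample_ids)
        sets = {f"S{i}": [f"G{g}" for g in
                          rng.choice(200, 20, replace=False)]
                for i in range(10)}
        res = gsea(expr, pheno, sets, n_perm=40, seed=5)
        assert (res["nominal_p"] >= 1 / 41).all()
        assert (res["nominal_p"] <= 1.0).all()

    def test_es_matches_gseapy(self):
        """Weighted enrichment scores agree with an independent GSEA
        implementation on a planted fixture (NES differs only through the
        permutation draw, so only ES is compared exactly)."""
        import gseapy

        rng = np.random.default_rng(1)
        G, n = 300, 20
        X = rng.normal(5, 1, size=(G, n))
        X[:15, :10] += 2.0
        genes = [f"G{i}" for i in range(G)]
        df = pd.DataFrame(X, index=genes,
                          columns=[f"S{j}" for j in range(n)])
        gmt = {"TOP": genes[:15],
               "RAND": [genes[i] for i in
                        rng.choice(300, 30, replace=False)]}
        ref = gseapy.gsea(data=df, gene_sets=gmt,
                          cls=["high"] * 10 + ["low"] * 10,
                          permutation_type="phenotype", permutation_num=20,
                          method="signal_to_noise", threads=1, seed=7,
                          outdir=None, min_size=5, max_size=500)
        ref_es = ref.res2d.set_index("Term")["ES"].astype(float)

        from tmescore.containers import ExpressionMatrix
        expr = ExpressionMatrix(df, Unit.LOG2TPM)
        pheno = pd.Series([1] * 10 + [0] * 10, index=df.columns)
        mine = gsea(expr, pheno, gmt, n_perm=20, seed=7, min_size=5)
        for name in gmt:
            assert mine.loc[name, "es"] == pytest.approx(ref_es[name],
                                                         abs=1e-9)

    def test_undersized_sets_skipped(self):
        rng = np.random.default_rng(6)
        expr = make_expression(rng.normal(5, 1, (100, 12)), Unit.LOG2TPM)
        pheno = pd.Series([1] * 6 + [0] * 6, index=expr.sample_ids)
        sets = {"TINY": ["G0", "G1"],
                "OK": [f"G{i}" for i in range(20)]}
        with pytest.warns(UserWarning, match="TINY"):
            res = gsea(expr, pheno, sets, n_perm=20, seed=7)
        assert list(res.index) == ["OK"]


# ---------------------------------------------------------------------------
# ORA and Fisher
# ---------------------------------------------------------------------------

def _hypergeom_tail_oracle(overlap, n_universe, n_set, n_hits):
    total = 0.0
    for k in range(overlap, min(n_set, n_hits) + 1):
        total += (math.comb(n_set, k) * math.comb(n_universe - n_set,
                                                  n_hits - k)
                  / math.comb(n_universe, n_hits))
    return total


class TestOra:
    def test_matches_exact_tail_enumeration(self):
        universe = [f"g{i}" for i in range(100)]
        sets = {"S": universe[:10]}
        hits = universe[5:10] + universe[50:55]   # overlap 5
        out = ora_hypergeom(hits, universe, sets)
        assert out.loc["S", "overlap"] == 5
        assert out.loc["S", "p"] == pytest.approx(
            _hypergeom_tail_oracle(5, 100, 10, 10), rel=1e-12)

    def test_zero_overlap_is_not_enriched(self):
        universe = [f"g{i}" for i in range(50)]
        out = ora_hypergeom(universe[30:40], universe, {"S": universe[:10]})
        assert out.loc["S", "p"] >= 0.5

    def test_degenerate_full_overlap(self):
        universe = [f"g{i}" for i in range(20)]
        out = ora_hypergeom(universe, universe, {"S": universe})
        assert out.loc["S", "p"] == pytest.approx(1.0)

    def test_empty_hits_raise(self):
        with pytest.raises(ValueError):
            ora_hypergeom([], ["a"], {"S": ["a"]})


def _fisher_oracle(a, b, c, d):
    """Two-sided p by full enumeration of tables with the same margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)
                / math.comb(n, c1))

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_diagonal_table(self):
        odds, p = fisher_2x2([[2, 0], [0, 2]])
        assert p == pytest.approx(1 / 3)
        assert odds == np.inf

    def test_balanced_table(self):
        odds, p = fisher_2x2([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)
        assert odds == pytest.approx(1.0)

    @given(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8),
           st.integers(0, 8))
    def test_matches_enumeration_oracle(self, a, b, c, d):
        _, p = fisher_2x2([[a, b], [c, d]])
        assert p == pytest.approx(_fisher_oracle(a, b, c, d), rel=1e-9)

    @given(st.integers(0, 10), st.integers(0, 10), st.integers(0, 10),
           st.integers(0, 10))
    def test_symmetric_under_row_and_column_swap(self, a, b, c, d):
        _, p1 = fisher_2x2([[a, b], [c, d]])
        _, p2 = fisher_2x2([[d, c], [b, a]])
        assert p1 == pytest.approx(p2, rel=1e-12)


# ---------------------------------------------------------------------------
# MAF operations
# ---------------------------------------------------------------------------

def _maf(rows):
    return pd.DataFrame(rows, columns=["Hugo_Symbol", "Tumor_Sample_Barcode",
                                       "Variant_Classification",
                                       "Variant_Type"])


class TestMutationCompare:
    def test_balanced_gene_not_flagged(self):
        samples = [f"s{i}" for i in range(20)]
        groups = pd.Series(["high"] * 10 + ["low"] * 10, index=samples)
        rows = [("TP53", s, "Missense_Mutation", "SNP")
                for s in samples[:4] + samples[10:14]]
        out = mutation_compare(_maf(rows), groups)
        assert out.loc["TP53", "p"] == pytest.approx(1.0)
        assert not bool(out.loc["TP53", "differential"])

    def test_planted_differential_gene_flagged(self):
        rng = np.random.default_rng(8)
        samples = [f"s{i}" for i in range(400)]
        groups = pd.Series(["high"] * 200 + ["low"] * 200, index=samples)
        mutated = ([s for s in samples[:200] if rng.random() < 0.5]
                   + [s for s in samples[200:] if rng.random() < 0.05])
        rows = [("KRAS", s, "Missense_Mutation", "SNP") for s in mutated]
        out = mutation_compare(_maf(rows), groups)
        assert bool(out.loc["KRAS", "differential"])
        assert out.loc["KRAS", "freq_high"] > out.loc["KRAS", "freq_low"]

    def test_unmapped_barcodes_warn(self):
        groups = pd.Series(["high", "low"], index=["s0", "s1"])
        rows = [("EGFR", "s0", "Missense_Mutation", "SNP"),
                ("EGFR", "sX", "Missense_Mutation", "SNP")]
        with pytest.warns(UserWarning, match="unmapped"):
            out = mutation_compare(_maf(rows), groups)
        assert out.loc["EGFR", "mutated_high"] == 1


class TestTmb:
    def test_hand_count_excludes_silent(self):
        rows = [("A", "s1", "Missense_Mutation", "SNP"),
                ("B", "s1", "Silent", "SNP"),
                ("C", "s1", "Nonsense_Mutation", "SNP"),
                ("D", "s1", "Silent", "SNP"),
                ("E", "s2", "Silent", "SNP")]
        tmb = tmb_from_maf(_maf(rows), samples=["s1", "s2"])
        assert tmb["s1"] == 2
        assert tmb["s2"] == 0

    def test_empty_maf_gives_zeros(self):
        tmb = tmb_from_maf(_maf([]), samples=["a", "b"])
        assert (tmb == 0).all()

    def test_additive_over_maf_partitions(self):
        rng = np.random.default_rng(9)
        rows = [(f"G{rng.integers(5)}", f"s{rng.integers(10)}",
                 "Missense_Mutation", "SNP") for _ in range(200)]
        maf = _maf(rows)
        samples = [f"s{i}" for i in range(10)]
        whole = tmb_from_maf(maf, samples=samples)
        parts = (tmb_from_maf(maf.iloc[:100], samples=samples)
                 + tmb_from_maf(maf.iloc[100:], samples=samples))
        pd.testing.assert_series_equal(whole, parts, check_names=False)

    def test_unknown_classification_warns(self):
        rows = [("A", "s1", "Weird_Class", "SNP")]
        with pytest.warns(UserWarning, match="Weird_Class"):
            tmb = tmb_from_maf(_maf(rows), samples=["s1"])
        assert tmb["s1"] == 0


class TestStratifyCombination:
    def _cohort(self, seed=10, n=200):
        rng = np.random.default_rng(seed)
        score_groups = pd.Series(rng.choice(["high", "low"], n),
                                 index=[f"s{i}" for i in range(n)])
        marker = pd.Series(rng.normal(size=n), index=score_groups.index)
        return score_groups, marker

    def test_constant_marker_reduces_to_two_groups(self):
        from tmescore.survstats import logrank_test
        score_groups, _ = self._cohort()
        marker = pd.Series(1.0, index=score_groups.index)
        rng = np.random.default_rng(11)
        rate = np.where(score_groups == "high", 0.02, 0.01)
        rec = pd.DataFrame({"time": rng.exponential(1 / rate),
                            "event": 1}, index=score_groups.index)
        with pytest.warns(UserWarning):
            out = stratify_combination(score_groups, marker, rec)
        chi2_two, _, _ = logrank_test(score_groups, rec)
        assert out["logrank_chi2"] == pytest.approx(chi2_two, rel=1e-9)

    def test_four_strata_three_df(self):
        score_groups, marker = self._cohort(12)
        rng = np.random.default_rng(13)
        rec = pd.DataFrame({"time": rng.exponential(50, len(marker)) + 0.01,
                            "event": 1}, index=score_groups.index)
        out = stratify_combination(score_groups, marker, rec)
        assert out["logrank_df"] == 3

    def test_additive_effects_order_survival(self):
        rng = np.random.default_rng(14)
        n = 400
        score_groups = pd.Series(np.repeat(["high", "low"], n // 2),
                                 index=[f"s{i}" for i in range(n)])
        marker = pd.Series(np.tile([2.0, -2.0], n // 2),
                           index=score_groups.index)
        risk = ((score_groups == "high").astype(float)
                + (marker > 0).astype(float))
        rec = simulate_survival(risk.to_numpy(), log_hr=1.0,
                                baseline_rate=1e-3, censoring_rate=0.0,
                                seed=15)
        rec.index = score_groups.index
        out = stratify_combination(score_groups, marker, rec)
        med = rec.groupby(out["labels"])["time"].median()
        assert med.idxmin() == "high/marker-high"
        assert out["logrank_p"] < 0.01

    def test_response_table_reported(self):
        score_groups, marker = self._cohort(16)
        rng = np.random.default_rng(17)
        rec = pd.DataFrame({"time": rng.exponential(50, len(marker)) + 0.01,
                            "event": 1}, index=score_groups.index)
        response = pd.Series(rng.choice(["CR", "PR", "SD", "PD"],
                                        len(marker)),
                             index=score_groups.index)
        out = stratify_combination(score_groups, marker, rec,
                                   response=response)
        assert "response_rate" in out
        assert out["response_table"].to_numpy().sum() == len(marker)
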