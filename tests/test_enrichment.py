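"""eSNP detection, LD expansion, matched resampling and fold enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from atheroreg import enrichment, synth


def _meta(snps, chroms, positions, mafs=None):
    return pd.DataFrame(
        {"chrom": chroms, "pos": positions,
         "maf": mafs if mafs is not None else [0.3] * len(snps)},
        index=pd.Index(snps, name="snp"))


def _expanded(snps, chroms):
    table = pd.DataFrame({"snp": snps, "chrom": chroms, "pos": range(1, len(snps) + 1),
                          "provenance": "esnp", "seed_snp": snps, "r2": 1.0})
    return enrichment.ExpandedSnpSet(table=table)


class TestDetectCisEsnps:
    def _fixture(self, snp_pos, effect=0.0, n=60, seed=0):
        rng = np.random.default_rng(seed)
        dosage = pd.DataFrame([rng.binomial(2, 0.3, n)], index=["rs1"],
                              columns=[f"I{i}" for i in range(n)])
        meta = _meta(["rs1"], ["1"], [snp_pos])
        expr = pd.DataFrame(
            [effect * dosage.loc["rs1"].to_numpy() + 0.5 * rng.standard_normal(n)],
            index=["geneA"], columns=dosage.columns)
        return expr, dosage, meta, {"geneA": ("1", 2_000_000)}

    def test_window_boundary_exclusive_beyond_1mb(self):
        # TSS 2,000,000: a SNP at 3,000,001 is outside even with a huge effect
        expr, dosage, meta, tss = self._fixture(3_000_001, effect=5.0)
        out = enrichment.detect_cis_esnps(expr, dosage, meta, tss, ["geneA"])
        assert len(out.table) == 0

    def test_window_boundary_inclusive_at_1mb(self):
        expr, dosage, meta, tss = self._fixture(3_000_000, effect=5.0)
        out = enrichment.detect_cis_esnps(expr, dosage, meta, tss, ["geneA"])
        assert set(out.table["snp"]) == {"rs1"}

    def test_planted_effect_power(self):
        """cis effect 1.0, noise 0.5, n=156: detected in >= 95% of seeds."""
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            expr, dosage, meta, tss = self._fixture(2_000_100, effect=1.0, n=156, seed=seed)
            out = enrichment.detect_cis_esnps(expr, dosage, meta, tss, ["geneA"])
            hits += len(out.table) > 0
        assert hits >= 95

    def test_null_fdr_controlled(self):
        """No planted effects: the per-run detection rate stays near the
        BH level across seeds."""
        detections = 0
        n_seeds = 100
        for seed in range(n_seeds):
            expr, dosage, meta, tss = self._fixture(2_000_100, effect=0.0, seed=seed)
            out = enrichment.detect_cis_esnps(expr, dosage, meta, tss, ["geneA"])
            detections += len(out.table)
        assert detections / n_seeds <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_seeds)

    def test_too_few_shared_individuals_rejected(self):
        expr, dosage, meta, tss = self._fixture(2_000_100, n=60)
        with pytest.raises(ValueError, match="30"):
            enrichment.detect_cis_esnps(expr[expr.columns[:10]], dosage, meta, tss, ["geneA"])

    def test_monomorphic_snp_skipped(self):
        expr, dosage, meta, tss = self._fixture(2_000_100, effect=5.0)
        dosage.loc["rs1"] = 1
        out = enrichment.detect_cis_esnps(expr, dosage, meta, tss, ["geneA"])
        assert len(out.table) == 0


class TestExpandByLd:
    def _block_fixture(self, r2=0.95, seed=0, n=300):
        truth = synth.GenotypeTruth(
            snp_table=_meta([f"rs{i}" for i in range(8)], ["1"] * 8,
                            [10_000 * (i + 1) for i in range(8)]),
            ld_blocks=[["rs0", "rs1", "rs2", "rs3", "rs4"]], ld_r2=r2)
        dosage, meta, _, _ = synth.simulate_genotypes_gwas(truth, n, seed=seed)
        return dosage, meta

    def _esnps(self, snps):
        return enrichment.EsnpSet(table=pd.DataFrame({"snp": snps}))

    def test_duplicated_column_is_included(self):
        dosage, meta = self._block_fixture(r2=1.0)
        out = enrichment.expand_by_ld(self._esnps(["rs0"]), dosage, meta)
        assert {"rs0", "rs1", "rs2", "rs3", "rs4"} <= set(out.snps)

    def test_independent_snps_no_expansion(self):
        rng = np.random.default_rng(1)
        dosage = pd.DataFrame(rng.binomial(2, 0.3, (4, 500)),
                              index=[f"rs{i}" for i in range(4)])
        meta = _meta(dosage.index, ["1"] * 4, [10_000, 20_000, 30_000, 40_000])
        out = enrichment.expand_by_ld(self._esnps(["rs0"]), dosage, meta)
        assert out.snps == ["rs0"]

    def test_block_recovered_in_expectation(self):
        sizes = []
        for seed in range(20):
            dosage, meta = self._block_fixture(r2=0.98, seed=seed)
            out = enrichment.expand_by_ld(self._esnps(["rs0"]), dosage, meta)
            sizes.append(len(out.snps))
        assert abs(np.mean(sizes) - 5) < 1.5

    def test_window_limits_proxies(self):
        dosage, meta = self._block_fixture(r2=1.0)
        out = enrichment.expand_by_ld(self._esnps(["rs0"]), dosage, meta, ld_window=15_000)
        # rs0 at 10kb: only rs1 (20kb) and rs2 (25k... within 15kb) qualify
        assert all(abs(meta.loc[s, "pos"] - meta.loc["rs0", "pos"]) <= 15_000
                   for s in out.snps)

    def test_idempotent_at_same_threshold(self):
        dosage, meta = self._block_fixture(r2=0.97, seed=3)
        once = enrichment.expand_by_ld(self._esnps(["rs0"]), dosage, meta)
        twice = enrichment.expand_by_ld(self._esnps(once.snps), dosage, meta)
        assert set(twice.snps) == set(once.snps)

    def test_empty_input_empty_output(self):
        dosage, meta = self._block_fixture()
        out = enrichment.expand_by_ld(self._esnps([]), dosage, meta)
        assert out.snps == []


class TestSubtractOverlap:
    def test_subset_gives_empty(self):
        r = _expanded(["s1", "s2"], ["1", "1"])
        c = _expanded(["s1", "s2", "s3"], ["1", "1", "1"])
        assert enrichment.subtract_overlap(r, c).snps == []

    def test_disjoint_unchanged(self):
        r = _expanded(["s1"], ["1"])
        c = _expanded(["s9"], ["1"])
        assert enrichment.subtract_overlap(r, c).snps == ["s1"]

    def test_set_difference(self):
        r = _expanded(["s1", "s2", "s3"], ["1", "1", "1"])
        c = _expanded(["s2"], ["1"])
        assert enrichment.subtract_overlap(r, c).snps == ["s1", "s3"]


def _universe(n_per_chrom=50, chroms=("1", "2"), maf=0.3):
    rows = []
    for c in chroms:
        for i in range(n_per_chrom):
            rows.append((f"u{c}_{i}", c, (i + 1) * 1000, maf))
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "maf"]).set_index("snp")


class TestMatchedSets:
    def test_per_chromosome_counts_exact(self):
        obs = _expanded(["a1", "a2", "a3", "b1", "b2"], ["1", "1", "1", "2", "2"])
        sets = enrichment.sample_matched_sets(obs, _universe(), n_sets=50, seed=0)
        uni = _universe()
        for s in sets:
            counts = uni.loc[s, "chrom"].value_counts()
            assert counts["1"] == 3 and counts["2"] == 2

    def test_forced_draw_when_universe_exactly_matches(self):
        obs = _expanded(["x1"], ["1"])
        uni = pd.DataFrame({"chrom": ["1"], "pos": [100], "maf": [0.3]},
                           index=pd.Index(["only"], name="snp"))
        sets = enrichment.sample_matched_sets(obs, uni, n_sets=20, seed=1)
        assert all(list(s) == ["only"] for s in sets)

    def test_maf_filter_exhaustive(self):
        """Half the universe below 5% MAF never appears across 5000 sets."""
        uni = _universe(n_per_chrom=40, chroms=("1",))
        low = uni.index[:20]
        uni.loc[low, "maf"] = 0.01
        obs = _expanded(["z1", "z2", "z3"], ["1", "1", "1"])
        sets = enrichment.sample_matched_sets(obs, uni, n_sets=5000, seed=2)
        drawn = set().union(*(set(s) for s in sets))
        assert drawn.isdisjoint(set(low))

    def test_observed_snps_excluded_from_null(self):
        uni = _universe(n_per_chrom=10, chroms=("1",))
        obs = _expanded([uni.index[0]], ["1"])
        sets = enrichment.sample_matched_sets(obs, uni, n_sets=200, seed=3)
        assert all(uni.index[0] not in set(s) for s in sets)

    def test_insufficient_universe_names_chromosome(self):
        obs = _expanded(["a", "b"], ["7", "7"])
        with pytest.raises(ValueError, match="7"):
            enrichment.sample_matched_sets(obs, _universe(chroms=("1",)), n_sets=5, seed=0)


class TestFoldEnrichment:
    def _gwas(self, n=100, p=None, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"chr": "1", "pos": np.arange(1, n + 1) * 100,
             "p": p if p is not None else rng.uniform(size=n), "maf": 0.3},
            index=pd.Index([f"g{i}" for i in range(n)], name="snp"))

    def test_degenerate_gwas_all_p_one(self):
        gwas = self._gwas(p=np.ones(100) * 0.999)
        obs = _expanded(["g0", "g1"], ["1", "1"])
        sets = [np.array(["g5", "g6"]), np.array(["g7", "g8"])]
        res = enrichment.compute_fold_enrichment(obs, sets, gwas)
        assert res.observed_fraction == 0.0
        assert res.fold == 0.0
        assert not res.infinite_fold

    def test_empirical_p_bounds(self):
        gwas = self._gwas(seed=1)
        obs = _expanded(["g0", "g1", "g2"], ["1"] * 3)
        rng = np.random.default_rng(2)
        sets = [rng.choice([f"g{i}" for i in range(3, 100)], 3, replace=False)
                for _ in range(99)]
        res = enrichment.compute_fold_enrichment(obs, sets, gwas)
        assert 0 < res.empirical_p <= 1

    def test_fold_invariant_to_snp_relabeling(self):
        gwas = self._gwas(seed=3)
        obs = _expanded(["g0", "g1", "g2"], ["1"] * 3)
        sets = [np.array(["g10", "g11", "g12"]), np.array(["g20", "g21", "g22"])]
        res1 = enrichment.compute_fold_enrichment(obs, sets, gwas)
        relabel = {f"g{i}": f"snp_{i}" for i in range(100)}
        gwas2 = gwas.rename(index=relabel)
        obs2 = _expanded([relabel[s] for s in obs.snps], ["1"] * 3)
        sets2 = [np.array([relabel[s] for s in s_]) for s_ in sets]
        res2 = enrichment.compute_fold_enrichment(obs2, sets2, gwas2)
        assert res1.fold == res2.fold

    def test_null_observed_set_fold_near_one_and_uniform_p(self):
        """Observed set drawn from the null itself: fold ~ 1 and the
        empirical P is approximately Uniform over reseeded repeats."""
        n_uni = 1200
        uni = pd.DataFrame({"chrom": "1", "pos": np.arange(1, n_uni + 1) * 100, "maf": 0.3},
                           index=pd.Index([f"s{i}" for i in range(n_uni)], name="snp"))
        folds, emp_ps = [], []
        for seed in range(150):
            rng = np.random.default_rng(1000 + seed)
            gwas = pd.DataFrame({"chr": "1", "pos": uni["pos"], "p": rng.uniform(size=n_uni),
                                 "maf": 0.3}, index=uni.index)
            chosen = rng.choice(uni.index, 250, replace=False)
            obs = enrichment.ExpandedSnpSet(table=pd.DataFrame(
                {"snp": chosen, "chrom": "1", "pos": uni.loc[chosen, "pos"].to_numpy(),
                 "provenance": "esnp", "seed_snp": chosen, "r2": 1.0}))
            sets = enrichment.sample_matched_sets(obs, uni, n_sets=300, seed=seed)
            res = enrichment.compute_fold_enrichment(obs, sets, gwas)
            folds.append(res.fold)
            emp_ps.append(res.empirical_p)
        assert abs(np.mean(folds) - 1.0) < 0.1
        ks = stats.kstest(emp_ps, "uniform")
        assert ks.pvalue > 0.01
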