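"""Generator contracts: planted structure, noise levels, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from atheroreg import synth


def _panel(noise_sd=0.5, n_samples=38, edges=(("TF1", "G1", 1.0),)):
    return synth.MacrophagePanelTruth(
        tf_ids=["TF1"], edge_list=list(edges), noise_sd=noise_sd, n_samples=n_samples)


class TestMacrophagePanel:
    def test_zero_noise_edge_gives_perfect_correlation(self):
        expr = synth.simulate_macrophage_expression(_panel(noise_sd=0.0, n_samples=10), seed=0)
        r = np.corrcoef(expr.loc["TF1"], expr.loc["G1"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_null_panel_matches_empirical_null_correlation_level(self):
        """No edges: mean |off-diagonal r| at n=38 matches a reseeded empirical null."""
        genes = [f"N{i}" for i in range(100)]
        truth = synth.MacrophagePanelTruth(tf_ids=[], edge_list=[], noise_sd=0.5,
                                           n_samples=38, extra_genes=genes)
        # independent oracle: direct Gaussian resampling, no generator involved
        null_rng = np.random.default_rng(999)
        levels = []
        for _ in range(200):
            X = null_rng.standard_normal((100, 38))
            C = np.abs(np.corrcoef(X))
            levels.append(C[np.triu_indices(100, 1)].mean())
        expected = np.mean(levels)
        tol = 5 * np.std(levels)
        expr = synth.simulate_macrophage_expression(truth, seed=7)
        C = np.abs(np.corrcoef(expr.to_numpy()))
        observed = C[np.triu_indices(100, 1)].mean()
        assert abs(observed - expected) < tol

    def test_noisy_edge_attenuates_to_closed_form(self):
        """beta=1, noise 0.5: E[r] = 1/sqrt(1.25) ~ 0.894; mean r over 100 seeds within 0.1."""
        rs = []
        for seed in range(100):
            expr = synth.simulate_macrophage_expression(_panel(noise_sd=0.5), seed=seed)
            rs.append(np.corrcoef(expr.loc["TF1"], expr.loc["G1"])[0, 1])
        assert abs(np.mean(rs) - 1 / np.sqrt(1.25)) < 0.1

    def test_duplicate_gene_ids_rejected(self):
        truth = synth.MacrophagePanelTruth(tf_ids=["TF1"], edge_list=[("TF1", "G1", 1.0)],
                                           extra_genes=["G2", "G2"])
        with pytest.raises(ValueError, match="duplicate"):
            synth.simulate_macrophage_expression(truth, seed=0)

    def test_non_tf_regulator_rejected(self):
        with pytest.raises(ValueError, match="non-TF"):
            synth.MacrophagePanelTruth(tf_ids=["TF1"], edge_list=[("G9", "G1", 1.0)])

    def test_bit_reproducible(self):
        a = synth.simulate_macrophage_expression(_panel(), seed=3)
        b = synth.simulate_macrophage_expression(_panel(), seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestTimecourse:
    def test_null_design_arms_identical_in_distribution(self):
        design = synth.TimecourseDesign(n_genes=50, n_per_cell=4,
                                        planted_pcl_genes={"30": {"mGene00001": 0.0}})
        expr, ann = synth.simulate_timecourse_expression(design, seed=0)
        ctrl = ann.index[(ann.stage == "30") & (ann.group == "control")]
        after = ann.index[(ann.stage == "30") & (ann.group == "after_pcl")]
        # zero effect: pooled two-sample statistic should be unremarkable
        diff = expr[ctrl].mean(axis=1) - expr[after].mean(axis=1)
        assert abs(diff.mean()) < 0.2

    def test_planted_effect_recovered_in_group_means(self):
        """log2 effect 2, noise 0.1, 6/6: mean difference 2 +- 0.2 across seeds."""
        diffs = []
        for seed in range(100):
            design = synth.TimecourseDesign(
                n_genes=10, n_per_cell=6, noise_sd=0.1,
                planted_pcl_genes={"30": {"mGene00001": 2.0}})
            expr, ann = synth.simulate_timecourse_expression(design, seed=seed)
            after = ann.index[(ann.stage == "30") & (ann.group == "after_pcl")]
            ctrl = ann.index[(ann.stage == "30") & (ann.group == "control")]
            diffs.append(expr.loc["mGene00001", after].mean() - expr.loc["mGene00001", ctrl].mean())
        assert abs(np.mean(diffs) - 2.0) < 0.2

    def test_truth_bookkeeping_partitions(self):
        design = synth.TimecourseDesign(
            n_genes=20, n_per_cell=3,
            planted_pcl_genes={"30": {"mGene00001": 1.0}, "40": {"mGene00002": 1.0}},
            planted_reactive_genes={"30": {"mGene00003": 1.0}})
        assert set(design.planted_pcl_genes["30"]) == {"mGene00001"}
        assert set(design.planted_pcl_genes["40"]) == {"mGene00002"}
        assert set(design.planted_reactive_genes["30"]) == {"mGene00003"}

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            synth.TimecourseDesign(n_per_cell=1)


def _geno_truth(**kw):
    snp_table = pd.DataFrame(
        {"chrom": ["1"] * 6, "pos": [100, 200, 300, 400, 500, 600],
         "maf": [0.3, 0.3, 0.3, 0.3, 0.3, 0.3]},
        index=pd.Index([f"rs{i}" for i in range(6)], name="snp"))
    defaults = dict(snp_table=snp_table, gene_tss={"geneA": ("1", 150)})
    defaults.update(kw)
    return synth.GenotypeTruth(**defaults)


class TestGenotypes:
    def test_perfect_ld_block(self):
        truth = _geno_truth(ld_blocks=[["rs0", "rs1", "rs2"]], ld_r2=1.0)
        dosage, _, _, _ = synth.simulate_genotypes_gwas(truth, 200, seed=0)
        r2 = np.corrcoef(dosage.loc["rs0"], dosage.loc["rs1"])[0, 1] ** 2
        assert r2 == pytest.approx(1.0)

    def test_invalid_target_r2_rejected(self):
        with pytest.raises(ValueError, match="r²"):
            _geno_truth(ld_r2=1.5)

    def test_background_hit_rate_is_binomial(self):
        """No planting: fraction of GWAS P<0.05 ~ 0.05 within binomial tolerance."""
        n_snps, n_seeds = 6, 200
        hits = 0
        for seed in range(n_seeds):
            _, _, gwas, _ = synth.simulate_genotypes_gwas(_geno_truth(), 60, seed=seed)
            hits += int((gwas["p"] < 0.05).sum())
        total = n_snps * n_seeds
        p_hat = hits / total
        assert abs(p_hat - 0.05) < 4 * np.sqrt(0.05 * 0.95 / total)

    def test_planted_cis_effect_slope_recovered(self):
        """effect 1.0, noise 0.5, n=156: OLS slope 1.0 +- 0.15 over 100 seeds."""
        slopes = []
        for seed in range(100):
            truth = _geno_truth(cis_effects=[("geneA", "rs0", 1.0)], eqtl_noise_sd=0.5)
            dosage, _, _, expr = synth.simulate_genotypes_gwas(truth, 156, seed=seed)
            x = dosage.loc["rs0"].to_numpy()
            y = expr.loc["geneA"].to_numpy()
            slopes.append(np.polyfit(x, y, 1)[0])
        assert abs(np.mean(slopes) - 1.0) < 0.15

    def test_ld_block_r2_near_target(self):
        truth = _geno_truth(ld_blocks=[["rs0", "rs1", "rs2", "rs3", "rs4"]], ld_r2=0.95)
        r2s = []
        for seed in range(30):
            dosage, _, _, _ = synth.simulate_genotypes_gwas(truth, 500, seed=seed)
            r2s.append(np.corrcoef(dosage.loc["rs0"], dosage.loc["rs1"])[0, 1] ** 2)
        assert abs(np.mean(r2s) - 0.95) < 0.05

    def test_maf_and_position_invariants_enforced(self):
        bad = pd.DataFrame({"chrom": ["1", "1"], "pos": [200, 100], "maf": [0.3, 0.3]},
                           index=pd.Index(["a", "b"], name="snp"))
        with pytest.raises(ValueError, match="increasing"):
            synth.GenotypeTruth(snp_table=bad)


class TestPerturbationScreen:
    def _truth(self, **kw):
        panel = [f"P{i}" for i in range(30)]
        defaults = dict(panel_genes=panel, target_tf="P0")
        defaults.update(kw)
        return synth.PerturbationTruth(**defaults)

    def test_null_ce_shift(self):
        changes = []
        for seed in range(50):
            _, _, ce = synth.simulate_perturbation_screen(self._truth(ce_shift=0.0), 6, seed)
            changes.append(ce.loc[ce.arm == "knockdown", "ce"].mean()
                           - ce.loc[ce.arm == "control", "ce"].mean())
        assert abs(np.mean(changes)) < 2.0

    def test_planted_ce_shift_magnitude(self):
        """+12% shift, sd 10, n=6: mean change 12 +- 10 across seeds."""
        changes = []
        for seed in range(50):
            _, _, ce = synth.simulate_perturbation_screen(
                self._truth(ce_shift=0.12, ce_sd=10.0), 6, seed)
            changes.append(ce.loc[ce.arm == "knockdown", "ce"].mean()
                           - ce.loc[ce.arm == "control", "ce"].mean())
        assert abs(np.mean(changes) - 12.0) < 10.0

    def test_knockdown_fraction_linear_scale(self):
        """80% knockdown: target mean ~ 20% of control on the linear scale."""
        ratios = []
        for seed in range(50):
            ctrl, kd, _ = synth.simulate_perturbation_screen(
                self._truth(knockdown_fraction=0.8, noise_sd=0.05), 6, seed)
            ratios.append(2.0 ** (kd.loc["P0"].mean() - ctrl.loc["P0"].mean()))
        assert np.mean(ratios) == pytest.approx(0.2, abs=0.02)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="3"):
            synth.simulate_perturbation_screen(self._truth(), 2, 0)

    def test_target_outside_panel_rejected(self):
        with pytest.raises(ValueError, match="panel"):
            synth.PerturbationTruth(panel_genes=["a"], target_tf="b")


MEANS = {"grp1": {"sm22": 10, "collagen": 10, "cd68": 5, "oro": 5, "burden": 4},
         "grp2": {"sm22": 20, "collagen": 15, "cd68": 2, "oro": 2, "burden": 1}}
SDS = {g: {f: 1.0 for f in m} for g, m in MEANS.items()}


class TestHistology:
    def test_no_missing_gives_complete_table(self):
        t = synth.simulate_histology(MEANS, SDS, 10, missing_rate=0.0, seed=0)
        assert not t.isna().any().any()

    def test_missing_rate_binomial(self):
        """16% MCAR deletion over stain cells: count matches binomial expectation."""
        counts = []
        for seed in range(100):
            t = synth.simulate_histology(MEANS, SDS, 15, missing_rate=0.16, seed=seed)
            counts.append(int(t[["sm22", "collagen", "cd68", "oro"]].isna().sum().sum()))
        n_cells = 2 * 15 * 4
        assert abs(np.mean(counts) - 0.16 * n_cells) < 4 * np.sqrt(0.16 * 0.84 * n_cells / 100)

    def test_zero_sd_pins_values_to_group_mean(self):
        zero_sds = {g: {f: 0.0 for f in m} for g, m in MEANS.items()}
        t = synth.simulate_histology(MEANS, zero_sds, 5, missing_rate=0.0, seed=0)
        for g, means in MEANS.items():
            sub = t[t.group == g]
            for f, m in means.items():
                assert np.allclose(sub[f], m)

    def test_missing_rate_one_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_histology(MEANS, SDS, 5, missing_rate=1.0, seed=0)


class TestTruthRoundTrip:
    @pytest.mark.parametrize("truth", [
        _panel(),
        synth.TimecourseDesign(n_genes=20, planted_pcl_genes={"30": {"mGene00001": 1.5}}),
        _geno_truth(ld_blocks=[["rs0", "rs1"]], cis_effects=[("geneA", "rs0", 1.0)]),
        synth.PerturbationTruth(panel_genes=["a", "b"], target_tf="a",
                                affected_genes={"b": 1.0}, ce_shift=0.12),
    ], ids=lambda t: type(t).__name__)
    def test_save_load_identity(self, truth, tmp_path):
        path = tmp_path / "truth.json"
        synth.save_truth(truth, path)
        loaded = synth.load_truth(path)
        assert type(loaded) is type(truth)
        for f in truth.__dataclass_fields__:
            a, b = getattr(truth, f), getattr(loaded, f)
            if isinstance(a, pd.DataFrame):
                pd.testing.assert_frame_equal(a, b, check_names=False)
            else:
                assert a == b, f
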