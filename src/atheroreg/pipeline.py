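"""End-to-end pipeline: simulate inputs, then run every analysis stage.

Each stage gets a seed derived deterministically from the global seed
and the stage name, so a full run with a fixed config reproduces its
outputs byte-identically. The default configuration mirrors the study
conditions: a 38-sample macrophage co-expression panel, 4–6 mouse
profiles per timepoint cell, n = 156 genotyped individuals, 5000 matched
random SNP sets with MAF > 5%, a ±1 Mb cis window, LD expansion at
r² > 0.9 within 200 kb, a 673-gene perturbation panel, and mouse DE at
FDR < 0.30.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clr, enrichment, genesets, io, perturb, phenotype, synth


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """All pipeline knobs with study-condition defaults."""

    seed: int = 0
    outdir: str = "results/pipeline"
    # gene-set discovery
    mouse_fdr_threshold: float = 0.30
    fdr_method: str = "bh"
    excluded_samples: list[str] = field(default_factory=list)
    n_per_cell: int = 5
    n_mouse_genes: int = 6000
    planted_pcl_sizes: dict = field(default_factory=lambda: {"30": 238, "40": 1306, "50": 2231})
    planted_reactive_sizes: dict = field(default_factory=lambda: {"30": 42, "40": 300, "50": 600})
    pcl_effect: float = 1.5
    timecourse_noise_sd: float = 0.5
    # risk enrichment
    n_individuals: int = 156
    cis_window: int = 1_000_000
    ld_window: int = 200_000
    r2_threshold: float = 0.9
    esnp_fdr: float = 0.05
    n_random_sets: int = 5000
    maf_min: float = 0.05
    alpha: float = 0.05
    gwas_p_hit: float = 0.10
    # CLR network
    n_macrophage_samples: int = 38
    n_tfs: int = 20
    n_targets: int = 200
    macrophage_noise_sd: float = 0.5
    retain_fraction: float = 0.5
    top_k_hubs: int = 5
    # perturbation
    panel_size: int = 673
    screen_fdr: float = 0.1
    n_screen_replicates: int = 6
    ce_shift: float = 0.12
    ce_sd: float = 10.0
    knockdown_fraction: float = 0.8
    # phenotype
    n_mice_per_group: int = 8
    histology_missing_rate: float = 0.16

    def __post_init__(self):
        for name, lo, hi in (("mouse_fdr_threshold", 0, 1), ("esnp_fdr", 0, 1),
                             ("screen_fdr", 0, 1), ("alpha", 0, 1),
                             ("retain_fraction", 0, 1), ("maf_min", 0, 0.5),
                             ("r2_threshold", 0, 1), ("histology_missing_rate", 0, 1),
                             ("knockdown_fraction", 0, 1)):
            v = getattr(self, name)
            if not (lo < v < hi):
                raise ValueError(f"{name}={v} outside ({lo},{hi})")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ------------------------------------------------------------------ simulate


def build_genotype_truth(cfg: RunConfig, rng: np.random.Generator) -> synth.GenotypeTruth:
    """Genotype/GWAS truth: 5 chromosomes, LD blocks around planted cis SNPs.

    25 genes carry a planted cis-eQTL whose SNP anchors a 5-SNP LD block
    at r² 0.95; every block member is GWAS-enriched at p_hit, emulating
    risk concentrated at the loci regulating the causal gene set.
    """
    n_chrom, snps_per_chrom, spacing = 5, 400, 50_000
    rows = []
    for c in range(1, n_chrom + 1):
        for i in range(snps_per_chrom):
            rows.append((f"rs{c}_{i+1:04d}", str(c), (i + 1) * spacing,
                         float(rng.uniform(0.05, 0.5))))
    snp_table = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "maf"]).set_index("snp")
    genes, gene_tss, cis_effects, ld_blocks, enriched = [], {}, [], [], []
    snp_ids = {c: [s for s in snp_table.index if snp_table.loc[s, "chrom"] == c]
               for c in map(str, range(1, n_chrom + 1))}
    g = 0
    for c in map(str, range(1, n_chrom + 1)):
        for k in range(8):
            g += 1
            gene = f"hGene{g:03d}"
            anchor_i = 30 + k * 45  # keeps blocks separated along the chromosome
            anchor = snp_ids[c][anchor_i]
            gene_tss[gene] = (c, int(snp_table.loc[anchor, "pos"]) + 10_000)
            genes.append(gene)
            if g <= 25:  # planted cis genes
                cis_effects.append((gene, anchor, 1.0))
                block = snp_ids[c][anchor_i:anchor_i + 5]
                ld_blocks.append(block)
                enriched.extend(block)
    return synth.GenotypeTruth(snp_table=snp_table, ld_blocks=ld_blocks, ld_r2=0.95,
                               cis_effects=cis_effects, gwas_enriched_snps=enriched,
                               p_hit=cfg.gwas_p_hit, gene_tss=gene_tss,
                               eqtl_noise_sd=0.5, cis_window=cfg.cis_window)


def build_macrophage_truth(cfg: RunConfig, rng: np.random.Generator) -> synth.MacrophagePanelTruth:
    """Planted TF→target modules over the macrophage panel.

    Module sizes descend (17, 13, ...) so the top hubs have distinct
    degrees; remaining targets are unregulated background.
    """
    tfs = [f"TF{i+1:02d}" for i in range(cfg.n_tfs)]
    targets = [f"G{i+1:03d}" for i in range(cfg.n_targets)]
    module_sizes = [17, 13, 12, 9, 9] + [5] * 5
    edges, used = [], 0
    for tf, size in zip(tfs, module_sizes):
        for t in targets[used:used + size]:
            edges.append((tf, t, float(rng.uniform(0.8, 1.2))))
        used += size
    return synth.MacrophagePanelTruth(tf_ids=tfs, edge_list=edges,
                                      noise_sd=cfg.macrophage_noise_sd,
                                      n_samples=cfg.n_macrophage_samples,
                                      extra_genes=targets[used:])


def build_timecourse_design(cfg: RunConfig, rng: np.random.Generator) -> synth.TimecourseDesign:
    """Disjoint planted PCL/reactive gene blocks of the configured sizes."""
    total = (sum(cfg.planted_pcl_sizes.values())
             + sum(cfg.planted_reactive_sizes.values()))
    if total > cfg.n_mouse_genes:
        raise ValueError(f"planted sets ({total}) exceed gene universe ({cfg.n_mouse_genes})")
    genes = [f"mGene{i+1:05d}" for i in range(cfg.n_mouse_genes)]
    pcl, reactive, cursor = {}, {}, 0
    for stage in synth.STAGES:
        n = cfg.planted_pcl_sizes[stage]
        pcl[stage] = {g: cfg.pcl_effect * float(rng.choice([-1, 1]))
                      for g in genes[cursor:cursor + n]}
        cursor += n
    for stage in synth.STAGES:
        n = cfg.planted_reactive_sizes[stage]
        reactive[stage] = {g: cfg.pcl_effect * float(rng.choice([-1, 1]))
                           for g in genes[cursor:cursor + n]}
        cursor += n
    return synth.TimecourseDesign(n_per_cell=cfg.n_per_cell, n_genes=cfg.n_mouse_genes,
                                  noise_sd=cfg.timecourse_noise_sd,
                                  planted_pcl_genes=pcl, planted_reactive_genes=reactive)


HISTOLOGY_GROUPS = {
    # patterned on the aortic-root staining ranges reported per group
    "before_pcl": {"sm22": 4.0, "collagen": 6.0, "cd68": 5.1, "oro": 5.6, "burden": 4.3},
    "pcl_10wk": {"sm22": 6.0, "collagen": 10.0, "cd68": 1.0, "oro": 3.5, "burden": 1.5},
    "pcl_20wk": {"sm22": 7.0, "collagen": 11.0, "cd68": 0.2, "oro": 2.7, "burden": 0.5},
}


def simulate_all(cfg: RunConfig, datadir: Path) -> dict:
    """Generate every pipeline input under ``datadir``; returns the paths."""
    datadir.mkdir(parents=True, exist_ok=True)
    paths = {}
    param_rng = np.random.default_rng(stage_seed(cfg.seed, "truth_params"))

    mac_truth = build_macrophage_truth(cfg, param_rng)
    mac_expr = synth.simulate_macrophage_expression(mac_truth, stage_seed(cfg.seed, "macrophage"))
    io.write_expression_table(mac_expr, datadir / "macrophage_expression.tsv")
    synth.save_truth(mac_truth, datadir / "macrophage_truth.json")
    (datadir / "tf_list.txt").write_text("\n".join(mac_truth.tf_ids) + "\n")
    paths["macrophage_expression"] = datadir / "macrophage_expression.tsv"
    paths["tf_list"] = datadir / "tf_list.txt"

    design = build_timecourse_design(cfg, param_rng)
    tc_expr, tc_ann = synth.simulate_timecourse_expression(design, stage_seed(cfg.seed, "timecourse"))
    io.write_expression_table(tc_expr, datadir / "timecourse_expression.tsv")
    io.write_sample_annotations(tc_ann, datadir / "timecourse_annotations.tsv")
    synth.save_truth(design, datadir / "timecourse_truth.json")
    paths["timecourse_expression"] = datadir / "timecourse_expression.tsv"
    paths["timecourse_annotations"] = datadir / "timecourse_annotations.tsv"

    # ortholog table: ~90% of mouse genes map 1:1 to a human id
    genes = list(tc_expr.index)
    keep = param_rng.random(len(genes)) < 0.9
    ortho = pd.DataFrame({"mouse_id": np.array(genes)[keep],
                          "human_id": [f"h{g}" for g in np.array(genes)[keep]],
                          "source": "synthetic_homology"})
    ortho.to_csv(datadir / "orthologs.tsv", sep="\t", index=False)
    paths["orthologs"] = datadir / "orthologs.tsv"

    geno_truth = build_genotype_truth(cfg, param_rng)
    dosage, meta, gwas, eqtl_expr = synth.simulate_genotypes_gwas(
        geno_truth, cfg.n_individuals, stage_seed(cfg.seed, "genotypes"))
    io.write_dosage_tsv(dosage, meta, datadir / "genotypes.tsv")
    io.write_gwas_summary(gwas, datadir / "gwas.tsv")
    io.write_expression_table(eqtl_expr, datadir / "eqtl_expression.tsv")
    synth.save_truth(geno_truth, datadir / "genotype_truth.json")
    tss = pd.DataFrame([(g, c, t) for g, (c, t) in sorted(geno_truth.gene_tss.items())],
                       columns=["gene", "chrom", "tss"])
    tss.to_csv(datadir / "gene_tss.tsv", sep="\t", index=False)
    for key in ("genotypes", "gwas", "eqtl_expression", "gene_tss"):
        paths[key] = datadir / f"{key.replace('_expression','_expression')}.tsv"
    paths["genotypes"] = datadir / "genotypes.tsv"
    paths["gwas"] = datadir / "gwas.tsv"
    paths["eqtl_expression"] = datadir / "eqtl_expression.tsv"
    paths["gene_tss"] = datadir / "gene_tss.tsv"

    hist = synth.simulate_histology(
        HISTOLOGY_GROUPS,
        {g: {f: max(0.3 * m, 0.05) for f, m in means.items()} for g, means in HISTOLOGY_GROUPS.items()},
        n_mice=cfg.n_mice_per_group, missing_rate=cfg.histology_missing_rate,
        seed=stage_seed(cfg.seed, "histology"))
    hist.to_csv(datadir / "histology.tsv", sep="\t", float_format="%.10g")
    paths["histology"] = datadir / "histology.tsv"
    return paths


# -------------------------------------------------------------------- stages


def run_gene_sets(cfg: RunConfig, paths: dict, outdir: Path) -> dict[str, dict]:
    """Stage gene sets per timepoint, ortholog mapping, overlap table."""
    expr = io.read_expression_table(paths["timecourse_expression"])
    ann = io.read_sample_annotations(paths["timecourse_annotations"])
    ortho = io.read_ortholog_table(paths["orthologs"])
    de_cfg = genesets.DEConfig(fdr_method=cfg.fdr_method,
                               fdr_threshold=cfg.mouse_fdr_threshold,
                               excluded_samples=cfg.excluded_samples)
    results, long_frames, gmt_sets = {}, [], []
    for stage in synth.STAGES:
        pcl, reactive = genesets.define_stage_gene_sets(expr, ann, stage, de_cfg)
        human, unmapped = genesets.map_orthologs(pcl, ortho)
        results[stage] = {"pcl": pcl, "reactive": reactive,
                          "human_pcl": human, "n_unmapped": unmapped}
        long_frames += [pcl.to_long_frame(), reactive.to_long_frame()]
        gmt_sets += [pcl, reactive]
    outdir.mkdir(parents=True, exist_ok=True)
    pd.concat(long_frames).to_csv(outdir / "gene_sets.tsv", sep="\t", index=False,
                                  float_format="%.8g")
    io.write_gmt(genesets.gene_sets_to_gmt(gmt_sets), outdir / "gene_sets.gmt")
    overlaps = genesets.overlap_fractions(
        {f"w{s}": set(results[s]["pcl"].members) for s in synth.STAGES})
    overlaps.to_csv(outdir / "pcl_set_overlaps.tsv", sep="\t", index=False)
    overlaps.attrs["per_set"].to_csv(outdir / "pcl_set_unique_fractions.tsv", sep="\t")
    with open(outdir / "human_orthologs.json", "w") as fh:
        json.dump({s: {"human_pcl": results[s]["human_pcl"],
                       "n_unmapped": results[s]["n_unmapped"]} for s in synth.STAGES},
                  fh, indent=1, sort_keys=True)
        fh.write("\n")
    return results


def run_enrichment(cfg: RunConfig, paths: dict, outdir: Path,
                   gene_ids: list[str] | None = None) -> enrichment.EnrichmentResult:
    """eSNP detection → LD expansion → matched-null fold enrichment."""
    expr = io.read_expression_table(paths["eqtl_expression"])
    dosage, meta = io.read_genotypes(paths["genotypes"])
    gwas = io.read_gwas_summary(paths["gwas"])
    tss_tab = pd.read_csv(paths["gene_tss"], sep="\t", dtype={"chrom": str})
    gene_tss = {r.gene: (r.chrom, int(r.tss)) for r in tss_tab.itertuples()}
    gene_ids = gene_ids if gene_ids is not None else sorted(gene_tss)
    esnps = enrichment.detect_cis_esnps(expr, dosage, meta, gene_tss, gene_ids,
                                        cis_window=cfg.cis_window, fdr_threshold=cfg.esnp_fdr)
    expanded = enrichment.expand_by_ld(esnps, dosage, meta,
                                       r2_threshold=cfg.r2_threshold, ld_window=cfg.ld_window)
    universe = gwas.rename(columns={"chr": "chrom"})
    sets = enrichment.sample_matched_sets(expanded, universe, n_sets=cfg.n_random_sets,
                                          maf_min=cfg.maf_min,
                                          seed=stage_seed(cfg.seed, "matched_sets"))
    result = enrichment.compute_fold_enrichment(expanded, sets, gwas, alpha=cfg.alpha,
                                                seed=stage_seed(cfg.seed, "matched_sets"))
    outdir.mkdir(parents=True, exist_ok=True)
    expanded.table.to_csv(outdir / "expanded_snp_set.tsv", sep="\t", index=False,
                          float_format="%.8g")
    with open(outdir / "risk_enrichment.json", "w") as fh:
        json.dump(result.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return result


def run_network(cfg: RunConfig, paths: dict, outdir: Path) -> tuple[clr.TFNetwork, clr.HubTable]:
    """CLR network over the macrophage panel and hub ranking."""
    expr = io.read_expression_table(paths["macrophage_expression"])
    tfs = io.read_tf_list(paths["tf_list"])
    sim = clr.compute_similarity(expr)
    scores = clr.clr_transform(sim)
    pvals = clr.edge_pvalues(scores)
    network = clr.build_tf_network(scores, pvals, tfs, list(expr.index),
                                   retain_fraction=cfg.retain_fraction)
    hubs = clr.rank_master_regulators(network, top_k=cfg.top_k_hubs)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_network(network, outdir / "tf_network", fmt="sif")
    hubs.table.to_csv(outdir / "hubs.tsv", sep="\t", index=False)
    with open(outdir / "network_log.json", "w") as fh:
        json.dump({"p_threshold": network.p_threshold,
                   "retained_fraction": network.retained_fraction,
                   "member_count": network.member_count}, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return network, hubs


def run_perturbation(cfg: RunConfig, paths: dict, outdir: Path,
                     network: clr.TFNetwork, hubs: clr.HubTable) -> dict:
    """Silence the top hub over the panel; specificity and CE readouts."""
    members = sorted(network.nodes.index[network.nodes["degree"] >= 1])
    target = str(hubs.table["tf"].iloc[0])
    param_rng = np.random.default_rng(stage_seed(cfg.seed, "perturb_params"))
    fillers = [f"panel{i+1:03d}" for i in range(max(0, cfg.panel_size - len(members)))]
    panel = members + fillers
    affected_pool = [g for g in members if g != target]
    n_aff = min(15, len(affected_pool))
    chosen = list(param_rng.choice(affected_pool, size=n_aff, replace=False))
    truth = synth.PerturbationTruth(
        panel_genes=panel, target_tf=target, knockdown_fraction=cfg.knockdown_fraction,
        affected_genes={g: 1.5 * float(param_rng.choice([-1, 1])) for g in chosen},
        ce_shift=cfg.ce_shift, ce_sd=cfg.ce_sd)
    control, kd, ce = synth.simulate_perturbation_screen(
        truth, cfg.n_screen_replicates, stage_seed(cfg.seed, "screen"))
    screen = perturb.analyze_screen(control, kd, panel, target,
                                    networks={"panel_network": members}, fdr=cfg.screen_fdr)
    ce_res = perturb.ce_change_from_values(ce.loc[ce["arm"] == "control", "ce"].to_numpy(),
                                           ce.loc[ce["arm"] == "knockdown", "ce"].to_numpy())
    outdir.mkdir(parents=True, exist_ok=True)
    synth.save_truth(truth, outdir / "perturbation_truth.json")
    screen.per_network.to_csv(outdir / "screen_network_effects.tsv", sep="\t",
                              float_format="%.8g")
    with open(outdir / "perturbation.json", "w") as fh:
        json.dump({"target_tf": target,
                   "n_affected": len(screen.affected),
                   "knockdown_efficiency": screen.knockdown_efficiency,
                   "network_percent": int(screen.per_network.loc["panel_network", "percent"]),
                   "specificity_p": float(screen.per_network.loc["panel_network", "specificity_p"]),
                   "ce_percent_change": ce_res.percent_change,
                   "ce_p": ce_res.p_value}, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {"screen": screen, "ce": ce_res, "truth": truth}


def run_phenotype(cfg: RunConfig, paths: dict, outdir: Path) -> pd.DataFrame:
    """Impute histology, score plaque stability, compare groups."""
    hist = pd.read_csv(paths["histology"], sep="\t", index_col=0)
    completed, log = phenotype.impute_missing(hist, strategy="group_mean",
                                              seed=stage_seed(cfg.seed, "imputation"))
    scored = phenotype.score_histology_table(completed)
    outdir.mkdir(parents=True, exist_ok=True)
    scored.to_csv(outdir / "stability_scores.tsv", sep="\t", float_format="%.8g")
    log.to_csv(outdir / "imputation_log.tsv", sep="\t", index=False, float_format="%.8g")
    scored.attrs["group_summary"].to_csv(outdir / "stability_group_summary.tsv", sep="\t",
                                         float_format="%.8g")
    comparisons = []
    groups = list(dict.fromkeys(scored["group"]))
    for a, b in zip(groups[:-1], groups[1:]):
        va = scored.loc[(scored["group"] == a) & ~scored["score_undefined"], "normalized_score"]
        vb = scored.loc[(scored["group"] == b) & ~scored["score_undefined"], "normalized_score"]
        p, diff = phenotype.group_compare(vb, va)
        comparisons.append({"group_a": a, "group_b": b, "mean_diff_b_minus_a": diff, "p": p})
    pd.DataFrame(comparisons).to_csv(outdir / "stability_comparisons.tsv", sep="\t",
                                     index=False, float_format="%.8g")
    return scored


def write_run_manifest(cfg: RunConfig) -> None:
    """Checksum all present inputs/outputs under the run directory."""
    outdir = Path(cfg.outdir)
    datadir = outdir / "data"
    inputs = {str(p.relative_to(outdir)): io.file_sha256(p)
              for p in sorted(datadir.glob("*")) if p.is_file()}
    outputs = {}
    for sub in ("gene_sets", "enrichment", "network", "perturbation", "phenotype"):
        if (outdir / sub).exists():
            for p in sorted((outdir / sub).glob("*")):
                outputs[str(p.relative_to(outdir))] = io.file_sha256(p)
    # the output directory is not part of the scientific configuration
    cfg_dict = {k: v for k, v in cfg.to_dict().items() if k != "outdir"}
    io.write_manifest(outdir / "manifest.json", cfg_dict, cfg.seed, inputs, outputs)


def run_all(cfg: RunConfig) -> dict:
    """Simulate, then run every stage; write a reproducibility manifest."""
    outdir = Path(cfg.outdir)
    paths = simulate_all(cfg, outdir / "data")
    results = {"paths": paths}
    results["gene_sets"] = run_gene_sets(cfg, paths, outdir / "gene_sets")
    results["enrichment"] = run_enrichment(cfg, paths, outdir / "enrichment")
    network, hubs = run_network(cfg, paths, outdir / "network")
    results["network"], results["hubs"] = network, hubs
    results["perturbation"] = run_perturbation(cfg, paths, outdir / "perturbation", network, hubs)
    results["phenotype"] = run_phenotype(cfg, paths, outdir / "phenotype")
    write_run_manifest(cfg)
    return results
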