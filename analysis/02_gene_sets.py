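"""Define stage-specific PCL-responsive and regression-reactive gene sets.

For each lesion stage (30/40/50 weeks) the PCL-responsive set contrasts
high-cholesterol controls with mice profiled immediately after plasma
cholesterol lowering, and the regression-reactive set contrasts
immediately-after with 10-weeks-after profiles (Welch tests, BH
FDR<0.30). Members are mapped to human orthologs for the network and
risk-enrichment stages. Expect member counts to grow with stage, as the
planted sizes (238/1306/2231) do.
"""

from pathlib import Path

from atheroreg.pipeline import RunConfig, run_gene_sets, simulate_all

cfg = RunConfig(seed=1, outdir="results/pipeline")
paths = simulate_all(cfg, Path(cfg.outdir) / "data")
results = run_gene_sets(cfg, paths, Path(cfg.outdir) / "gene_sets")
for stage, r in results.items():
    print(f"week {stage}: {len(r['pcl'].members):4d} PCL-responsive, "
          f"{len(r['reactive'].members):4d} regression-reactive; "
          f"{len(r['human_pcl'])} human orthologs ({r['n_unmapped']} unmapped)")
print(f"\ntables under {cfg.outdir}/gene_sets/")
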