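"""Generate every synthetic input for the regression pipeline.

Writes, under results/pipeline/data/: the 38-sample macrophage
co-expression panel with planted TF->target modules, the three-stage
two-arm mouse timecourse with planted PCL-responsive and
regression-reactive genes, LD-blocked genotypes for 156 individuals with
planted cis-eQTLs and a GWAS carrying excess nominal hits at those loci,
a mouse->human ortholog table, and per-mouse histology with 16%
missingness. Ground-truth JSON accompanies each table.
"""

from pathlib import Path

from atheroreg.pipeline import RunConfig, simulate_all

cfg = RunConfig(seed=1, outdir="results/pipeline")
paths = simulate_all(cfg, Path(cfg.outdir) / "data")
for name, path in sorted(paths.items()):
    print(f"{name:26s} -> {path}")
print(f"\n{len(paths)} input files written; seed {cfg.seed}.")
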