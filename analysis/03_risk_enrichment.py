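"""CAD/MI risk enrichment of the causal (PCL-responsive) gene set.

Detects cis-eSNPs (dosage regression within +-1 Mb of each gene's TSS,
BH FDR<0.05), expands them with LD proxies (r^2>0.9 within 200 kb),
draws 5000 random SNP sets matched on size, chromosomal distribution
and MAF>5%, and reports the fold enrichment of nominal GWAS hits
(P<0.05). With the planted 10% hit rate at causal loci against a 5%
background, the expected fold is ~2, the magnitude seen for early
lesions.
"""

from pathlib import Path

from atheroreg.pipeline import RunConfig, run_enrichment, simulate_all

cfg = RunConfig(seed=1, outdir="results/pipeline")
paths = simulate_all(cfg, Path(cfg.outdir) / "data")
res = run_enrichment(cfg, paths, Path(cfg.outdir) / "enrichment")
print(f"expanded SNP set: {res.n_snps} SNPs ({res.n_dropped} absent from GWAS)")
print(f"observed significant fraction: {res.observed_fraction:.4f}")
print(f"null mean fraction:            {res.null_mean_fraction:.4f}")
print(f"fold enrichment:               {res.fold:.2f}")
print(f"empirical P ({res.n_random_sets} matched sets): {res.empirical_p:.3g}"
      + (f" (normal approx {res.normal_approx_p:.3g})" if res.normal_approx_p else ""))
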