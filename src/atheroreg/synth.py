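"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here with known
truth: TF→target modules in a macrophage-style co-expression panel,
PCL-responsive / regression-reactive genes in a two-arm mouse
timecourse, LD-blocked genotypes with cis-eQTLs and a GWAS carrying a
planted excess of nominal hits, siRNA knockdown screens over a fixed
gene panel, and per-mouse histology tables with missingness.

All generators are bit-reproducible given (parameters, seed); expression
noise is Gaussian on the log2 scale, the post-normalization scale the
downstream statistics assume.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STAGES = ("30", "40", "50")
GROUPS = ("control", "after_pcl", "regression_10wk")
HISTOLOGY_FIELDS = ("sm22", "collagen", "cd68", "oro", "burden")


# ------------------------------------------------------------- truth objects


@dataclass
class MacrophagePanelTruth:
    """Planted TF→target structure for the macrophage co-expression panel.

    ``edge_list`` holds (tf, target, beta) triples; targets are linear in
    their TF's expression with slope beta plus Gaussian noise of SD
    ``noise_sd``. ``n_samples`` defaults to 38, the size of the
    CAD-patient macrophage expression panel the real networks were
    inferred from.
    """

    tf_ids: list[str]
    edge_list: list[tuple[str, str, float]]
    noise_sd: float = 0.5
    n_samples: int = 38
    extra_genes: list[str] = field(default_factory=list)

    def __post_init__(self):
        tfs = set(self.tf_ids)
        for tf, target, beta in self.edge_list:
            if tf not in tfs:
                raise ValueError(f"edge ({tf!r}, {target!r}) has non-TF regulator endpoint")
            if not np.isfinite(beta):
                raise ValueError(f"non-finite effect size for edge ({tf!r}, {target!r})")
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = dict.fromkeys(self.tf_ids)
        for _, target, _ in self.edge_list:
            seen.setdefault(target)
        for g in self.extra_genes:
            seen.setdefault(g)
        return list(seen)


@dataclass
class TimecourseDesign:
    """Two-arm multi-timepoint design with planted DE genes.

    ``planted_pcl_genes[stage]`` maps gene→log2 effect between
    high-cholesterol controls and immediately-after-PCL samples;
    ``planted_reactive_genes[stage]`` between immediately-after-PCL and
    10-weeks-after samples. Default replication (5 per cell) sits inside
    the study's 3–6 profiles per timepoint.
    """

    timepoints: tuple[str, ...] = STAGES
    n_per_cell: int = 5
    n_genes: int = 1000
    noise_sd: float = 0.5
    planted_pcl_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_reactive_genes: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_per_cell < 2:
            raise ValueError("n_per_cell must be >= 2")
        if self.n_per_cell < 3:
            raise ValueError("replicate counts must be >= 3")


@dataclass
class GenotypeTruth:
    """SNP table, LD blocks, cis-eQTL effects and planted GWAS signal.

    ``ld_blocks`` are lists of SNP ids sharing a target pairwise r²;
    ``cis_effects`` are (gene, snp, effect) with the SNP inside the
    ±1 Mb cis window of the gene's TSS; ``gwas_enriched_snps`` get a
    nominal (P<0.05) hit probability of ``p_hit`` instead of 0.05.
    """

    snp_table: pd.DataFrame  # index snp, columns chrom, pos, maf
    ld_blocks: list[list[str]] = field(default_factory=list)
    ld_r2: float = 0.95
    cis_effects: list[tuple[str, str, float]] = field(default_factory=list)
    gwas_enriched_snps: list[str] = field(default_factory=list)
    p_hit: float = 0.10
    gene_tss: dict[str, tuple[str, int]] = field(default_factory=dict)  # gene -> (chrom, tss)
    eqtl_noise_sd: float = 0.5
    cis_window: int = 1_000_000

    def __post_init__(self):
        maf = self.snp_table["maf"]
        if ((maf <= 0) | (maf > 0.5)).any():
            raise ValueError("MAF must lie in (0, 0.5]")
        if not (0 < self.ld_r2 <= 1):
            raise ValueError("target r² must lie in (0, 1]")
        for chrom, grp in self.snp_table.groupby("chrom"):
            pos = grp["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")
        for gene, snp, _ in self.cis_effects:
            chrom, tss = self.gene_tss[gene]
            row = self.snp_table.loc[snp]
            if row["chrom"] != chrom or abs(int(row["pos"]) - tss) > self.cis_window:
                raise ValueError(f"planted cis SNP {snp!r} outside cis window of {gene!r}")


@dataclass
class PerturbationTruth:
    """siRNA screen ground truth over a fixed gene panel (default 673).

    ``knockdown_fraction`` is the relative mRNA reduction of the target
    (0.8 means the knockdown arm expresses the target at 20% of
    control); ``affected_genes`` maps downstream gene→log2 shift;
    ``ce_shift`` is the planted relative change in cholesterol-ester
    accumulation (+0.12 means +12%).
    """

    panel_genes: list[str]
    target_tf: str
    knockdown_fraction: float = 0.8
    affected_genes: dict[str, float] = field(default_factory=dict)
    ce_shift: float = 0.0
    ce_sd: float = 10.0
    noise_sd: float = 0.3

    def __post_init__(self):
        if not (0 < self.knockdown_fraction < 1):
            raise ValueError("knockdown_fraction must lie in (0, 1)")
        if self.target_tf not in self.panel_genes:
            raise ValueError(f"target TF {self.target_tf!r} not in panel")
        missing = set(self.affected_genes) - set(self.panel_genes)
        if missing:
            raise ValueError(f"affected genes outside panel: {sorted(missing)}")


# ---------------------------------------------------------------- generators


def simulate_macrophage_expression(truth: MacrophagePanelTruth, seed: int) -> pd.DataFrame:
    """Expression (genes x samples) with planted TF→target linear edges.

    TFs and non-target genes are independent standard Gaussians; each
    planted target is the sum of beta·TF over its regulators plus
    N(0, noise_sd). With a single edge of slope beta and noise sd s, the
    expected Pearson correlation is beta/sqrt(beta² + s²).
    """
    targets = list(dict.fromkeys(t for _, t, _ in truth.edge_list))
    for name, ids in (("tf_ids", truth.tf_ids), ("extra_genes", truth.extra_genes)):
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate gene identifiers in {name}")
    clash = set(truth.extra_genes) & (set(truth.tf_ids) | set(targets))
    if clash:
        raise ValueError(f"duplicate gene identifiers: {sorted(clash)}")
    genes = truth.genes
    rng = np.random.default_rng(seed)
    samples = [f"S{i+1:02d}" for i in range(truth.n_samples)]
    targets = {t for _, t, _ in truth.edge_list}
    expr = pd.DataFrame(
        rng.standard_normal((len(genes), truth.n_samples)), index=genes, columns=samples
    )
    for target in sorted(targets):
        signal = np.zeros(truth.n_samples)
        for tf, t, beta in truth.edge_list:
            if t == target:
                signal = signal + beta * expr.loc[tf].to_numpy()
        expr.loc[target] = signal + truth.noise_sd * rng.standard_normal(truth.n_samples)
    expr.index.name = "gene"
    return expr


def simulate_timecourse_expression(design: TimecourseDesign, seed: int):
    """Mouse timecourse expression and sample annotations.

    Returns ``(expr, annotations)`` where annotations carry ``stage``
    and ``group`` (control / after_pcl / regression_10wk). Planted
    PCL-responsive genes shift between control and after_pcl at their
    stage; regression-reactive genes shift between after_pcl and
    regression_10wk; all other gene/stage cells are exchangeable.
    """
    rng = np.random.default_rng(seed)
    genes = [f"mGene{i+1:05d}" for i in range(design.n_genes)]
    rows, sample_ids = [], []
    for stage in design.timepoints:
        for group in GROUPS:
            for rep in range(design.n_per_cell):
                sample_ids.append(f"w{stage}_{group}_{rep+1}")
                rows.append((stage, group))
    ann = pd.DataFrame(rows, index=sample_ids, columns=["stage", "group"])
    ann.index.name = "sample"
    base = rng.normal(7.0, 1.0, size=design.n_genes)  # log2 abundance baseline
    expr = base[:, None] + design.noise_sd * rng.standard_normal((design.n_genes, len(sample_ids)))
    expr = pd.DataFrame(expr, index=genes, columns=sample_ids)
    # the PCL response persists while plasma cholesterol stays low, so the
    # shift applies to both post-PCL groups; only reactive genes then move
    # between immediately-after and 10-weeks-after
    for stage, effects in design.planted_pcl_genes.items():
        cols = ann.index[(ann["stage"] == stage)
                         & ann["group"].isin(["after_pcl", "regression_10wk"])]
        for gene, eff in effects.items():
            expr.loc[gene, cols] = expr.loc[gene, cols] + eff
    for stage, effects in design.planted_reactive_genes.items():
        cols = ann.index[(ann["stage"] == stage) & (ann["group"] == "regression_10wk")]
        for gene, eff in effects.items():
            expr.loc[gene, cols] = expr.loc[gene, cols] + eff
    expr.index.name = "gene"
    return expr, ann


def _simulate_block_dosages(rng, mafs: np.ndarray, n: int, r2: float) -> np.ndarray:
    """Dosages for one LD block by haplotype copy-or-redraw.

    Each individual carries two haplotypes; the block's first SNP is the
    seed. Every other site copies the seed haplotype allele with
    probability sqrt(r2) and otherwise redraws Bernoulli(maf), which
    preserves MAF and targets pairwise allelic correlation sqrt(r2)
    (hence r² = r2) in expectation.
    """
    n_snp = len(mafs)
    copy_p = np.sqrt(r2)
    haps = np.empty((n_snp, 2 * n), dtype=np.int8)
    seed_hap = (rng.random(2 * n) < mafs[0]).astype(np.int8)
    haps[0] = seed_hap
    for j in range(1, n_snp):
        redraw = (rng.random(2 * n) < mafs[j]).astype(np.int8)
        copied = rng.random(2 * n) < copy_p
        haps[j] = np.where(copied, seed_hap, redraw)
    return (haps[:, 0::2] + haps[:, 1::2]).astype(np.int8)


def simulate_genotypes_gwas(truth: GenotypeTruth, n_individuals: int, seed: int):
    """Genotypes, GWAS summary and a cis-eQTL expression matrix.

    Returns ``(dosage, meta, gwas, expr)``. Dosages are 0/1/2 per MAF;
    LD-block members share haplotypes via copy-or-redraw at the block's
    target r²; genes with planted cis effects have
    expression = effect·dosage + N(0, eqtl_noise_sd); GWAS P-values are
    Uniform(0,1) except planted enriched SNPs, drawn so P<0.05 with
    probability ``p_hit``.
    """
    if n_individuals < 50:
        raise ValueError("n_individuals must be >= 50 for stable LD estimates")
    rng = np.random.default_rng(seed)
    snps = list(truth.snp_table.index)
    individuals = [f"I{i+1:03d}" for i in range(n_individuals)]
    mafs = truth.snp_table["maf"].to_numpy(dtype=float)
    idx = {s: i for i, s in enumerate(snps)}

    dosage = np.empty((len(snps), n_individuals), dtype=np.int8)
    in_block = set()
    for block in truth.ld_blocks:
        rows = [idx[s] for s in block]
        dosage[rows] = _simulate_block_dosages(rng, mafs[rows], n_individuals, truth.ld_r2)
        in_block.update(rows)
    for i, maf in enumerate(mafs):
        if i not in in_block:
            dosage[i] = rng.binomial(2, maf, size=n_individuals)
    dosage = pd.DataFrame(dosage, index=snps, columns=individuals, dtype=int)
    meta = truth.snp_table.copy()

    # cis-eQTL expression: planted genes linear in dosage, rest pure noise
    genes = sorted(truth.gene_tss)
    expr = pd.DataFrame(
        truth.eqtl_noise_sd * rng.standard_normal((len(genes), n_individuals)),
        index=genes, columns=individuals,
    )
    for gene, snp, effect in truth.cis_effects:
        expr.loc[gene] = expr.loc[gene] + effect * dosage.loc[snp].to_numpy()
    expr.index.name = "gene"

    enriched = set(truth.gwas_enriched_snps)
    pvals = rng.uniform(0.0, 1.0, size=len(snps))
    for s in sorted(enriched):
        i = idx[s]
        if rng.random() < truth.p_hit:
            pvals[i] = rng.uniform(0.0, 0.05)
        else:
            pvals[i] = rng.uniform(0.05, 1.0)
    gwas = pd.DataFrame(
        {"chr": meta["chrom"].to_numpy(), "pos": meta["pos"].to_numpy(),
         "p": pvals, "maf": meta["maf"].to_numpy()},
        index=pd.Index(snps, name="snp"),
    )
    return dosage, meta, gwas, expr


def simulate_perturbation_screen(truth: PerturbationTruth, n_replicates: int, seed: int):
    """Control and knockdown panel expression plus a CE readout table.

    Knockdown samples express the target at (1 − knockdown_fraction) of
    control on the linear scale (a log2 shift of
    log2(1 − knockdown_fraction)); affected genes get their planted log2
    shifts. CE values are Normal(100·(1+ce_shift), ce_sd) for knockdown
    and Normal(100, ce_sd) for control.
    """
    if n_replicates < 3:
        raise ValueError("n_replicates must be >= 3 (no variance estimate otherwise)")
    rng = np.random.default_rng(seed)
    genes = list(truth.panel_genes)
    base = rng.normal(8.0, 1.0, size=len(genes))
    ctrl_cols = [f"ctrl_{i+1}" for i in range(n_replicates)]
    kd_cols = [f"kd_{i+1}" for i in range(n_replicates)]
    control = pd.DataFrame(
        base[:, None] + truth.noise_sd * rng.standard_normal((len(genes), n_replicates)),
        index=genes, columns=ctrl_cols,
    )
    kd = pd.DataFrame(
        base[:, None] + truth.noise_sd * rng.standard_normal((len(genes), n_replicates)),
        index=genes, columns=kd_cols,
    )
    kd.loc[truth.target_tf] += np.log2(1.0 - truth.knockdown_fraction)
    for gene, shift in truth.affected_genes.items():
        kd.loc[gene] += shift
    control.index.name = kd.index.name = "gene"
    ce = pd.DataFrame({
        "arm": ["control"] * n_replicates + ["knockdown"] * n_replicates,
        "ce": np.concatenate([
            rng.normal(100.0, truth.ce_sd, size=n_replicates),
            rng.normal(100.0 * (1.0 + truth.ce_shift), truth.ce_sd, size=n_replicates),
        ]),
    })
    return control, kd, ce


def simulate_histology(group_means: dict[str, dict[str, float]],
                       group_sds: dict[str, dict[str, float]],
                       n_mice: int, missing_rate: float, seed: int) -> pd.DataFrame:
    """Per-mouse stained-area percentages with MCAR missingness.

    ``group_means[group][field]`` / ``group_sds`` give the Normal
    parameters per group for sm22, collagen, cd68, oro and burden; area
    percentages are clipped to [0, 100]. Cells (burden excluded from
    deletion so every scored mouse keeps its burden) are deleted
    completely at random at ``missing_rate``.
    """
    if missing_rate >= 1:
        raise ValueError("missing_rate must be < 1")
    for group, means in group_means.items():
        for fld, m in means.items():
            if fld != "burden" and not (0 <= m <= 100):
                raise ValueError(f"area percentage mean out of [0,100]: {group}/{fld}={m}")
    rng = np.random.default_rng(seed)
    rows = []
    mouse = 0
    for group in group_means:
        for _ in range(n_mice):
            mouse += 1
            row = {"mouse_id": f"m{mouse:03d}", "group": group}
            for fld in HISTOLOGY_FIELDS:
                val = rng.normal(group_means[group][fld], group_sds[group][fld])
                if fld != "burden":
                    val = float(np.clip(val, 0.0, 100.0))
                else:
                    val = float(max(val, 0.1))
                row[fld] = val
            rows.append(row)
    table = pd.DataFrame(rows).set_index("mouse_id")
    stain_cols = [f for f in HISTOLOGY_FIELDS if f != "burden"]
    mask = rng.random((len(table), len(stain_cols))) < missing_rate
    values = table[stain_cols].to_numpy()
    values[mask] = np.nan
    table[stain_cols] = values
    return table


# ------------------------------------------------------- truth serialization


def _encode(obj):
    if isinstance(obj, pd.DataFrame):
        flat = obj.reset_index()
        return {"__frame__": flat.to_dict(orient="list"),
                "__columns__": list(flat.columns), "__index__": flat.columns[0]}
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_truth(truth, path) -> None:
    """Serialize a truth dataclass to JSON (losslessly round-trippable)."""
    payload = {"__class__": type(truth).__name__,
               "fields": _encode(dataclasses.asdict(truth))}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


_TRUTH_CLASSES = None


def load_truth(path):
    global _TRUTH_CLASSES
    if _TRUTH_CLASSES is None:
        _TRUTH_CLASSES = {c.__name__: c for c in
                          (MacrophagePanelTruth, TimecourseDesign, GenotypeTruth, PerturbationTruth)}
    with open(path) as fh:
        payload = json.load(fh)
    cls = _TRUTH_CLASSES[payload["__class__"]]
    fields = payload["fields"]

    def _decode(v):
        if isinstance(v, dict) and "__frame__" in v:
            df = pd.DataFrame(v["__frame__"])[v["__columns__"]]
            return df.set_index(v["__index__"])
        if isinstance(v, list):
            return [_decode(x) for x in v]
        if isinstance(v, dict):
            return {k: _decode(x) for k, x in v.items()}
        return v

    kwargs = {k: _decode(v) for k, v in fields.items()}
    # tuples inside edge/effect lists and gene_tss arrive as lists from JSON
    for key in ("edge_list", "cis_effects"):
        if key in kwargs:
            kwargs[key] = [tuple(t) for t in kwargs[key]]
    if "gene_tss" in kwargs:
        kwargs["gene_tss"] = {g: tuple(v) for g, v in kwargs["gene_tss"].items()}
    if "timepoints" in kwargs:
        kwargs["timepoints"] = tuple(kwargs["timepoints"])
    return cls(**kwargs)
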