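"""Stage-specific gene-set discovery by differential expression.

PCL-responsive sets contrast high-cholesterol controls with mice
sacrificed immediately after plasma-cholesterol lowering (PCL);
regression-reactive sets contrast immediately-after-PCL with
10-weeks-after lesions. Gene membership is called at FDR < 0.30 by
Benjamini–Hochberg (default) or an empirical-null local-FDR procedure.
Mouse sets are mapped to human orthologs for the downstream network and
risk-enrichment stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

VARIANCE_FLOOR = 1e-12


@dataclass
class DEConfig:
    """Differential-expression settings.

    fdr_method is "bh" (Benjamini–Hochberg, default) or "efron_local"
    (normal empirical null fitted by central matching). The mouse
    contrasts use a deliberately permissive threshold of 0.30 to carry
    an adequately large true-positive fraction into the network stages.
    """

    fdr_method: str = "bh"
    fdr_threshold: float = 0.30
    excluded_samples: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold must lie in (0,1)")
        if self.fdr_method not in ("bh", "efron_local"):
            raise ValueError(f"unknown fdr_method {self.fdr_method!r}")


@dataclass
class GeneSet:
    """A differential-expression result for one stage and contrast.

    ``table`` has one row per gene with columns stat, p, fdr, direction;
    ``members`` are the genes passing the FDR threshold.
    """

    stage: str
    contrast: str
    table: pd.DataFrame
    fdr_threshold: float

    @property
    def members(self) -> list[str]:
        return list(self.table.index[self.table["fdr"] < self.fdr_threshold])

    def to_long_frame(self) -> pd.DataFrame:
        out = self.table.reset_index()
        out.insert(0, "contrast", self.contrast)
        out.insert(0, "stage", self.stage)
        return out


def welch_tests(expr: pd.DataFrame, group_a: list[str], group_b: list[str]) -> pd.DataFrame:
    """Per-gene Welch t statistic and two-sided p (group_a minus group_b).

    Genes with zero within-group variance in both groups fall back to a
    variance floor and are flagged; equal means under the floor give
    stat 0, p 1.
    """
    a = expr[list(group_a)].to_numpy(dtype=float)
    b = expr[list(group_b)].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    floored = (va <= VARIANCE_FLOOR) | (vb <= VARIANCE_FLOOR)
    both_floored = (va <= VARIANCE_FLOOR) & (vb <= VARIANCE_FLOOR)
    va = np.maximum(va, VARIANCE_FLOOR)
    vb = np.maximum(vb, VARIANCE_FLOOR)
    se2 = va / na + vb / nb
    stat = (ma - mb) / np.sqrt(se2)
    # Welch–Satterthwaite degrees of freedom
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(np.abs(stat), df)
    # identical degenerate groups: no evidence, not infinite evidence
    degenerate = both_floored & (np.abs(ma - mb) <= 1e-12)
    stat = np.where(degenerate, 0.0, stat)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {"stat": stat, "p": p, "mean_diff": ma - mb, "variance_floored": floored},
        index=expr.index,
    )


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    return multipletests(pvals, method="fdr_bh")[1]


def efron_local_fdr(pvals: np.ndarray, stats_sign: np.ndarray) -> np.ndarray:
    """Empirical-null local false discovery rate.

    z = Φ⁻¹(one-sided p) signed by the statistic; the empirical null
    N(δ̂, σ̂²) is fitted by central matching on the middle 50% of z
    (median for δ̂, half-IQR scaled to the normal for σ̂); the marginal
    density f̂ is a Gaussian KDE and local fdr = min(1, π̂₀ f₀(z)/f̂(z))
    with π̂₀ estimated from the central-z mass and capped at 1.
    """
    p_one = np.clip(pvals / 2.0, 1e-300, 1 - 1e-16)
    z = -stats.norm.ppf(p_one) * np.sign(np.where(stats_sign == 0, 1.0, stats_sign))
    q25, q50, q75 = np.percentile(z, [25, 50, 75])
    delta = q50
    sigma = max((q75 - q25) / (2.0 * stats.norm.ppf(0.75)), 1e-6)
    central = (z >= q25) & (z <= q75)
    # mass the fitted null assigns to the central half, vs the observed half
    null_central = stats.norm.cdf(q75, delta, sigma) - stats.norm.cdf(q25, delta, sigma)
    pi0 = min(1.0, float(np.mean(central)) / max(null_central, 1e-12))
    f_hat = stats.gaussian_kde(z)(z)
    f0 = stats.norm.pdf(z, delta, sigma)
    return np.minimum(1.0, pi0 * f0 / np.maximum(f_hat, 1e-300))


def differential_expression(expr: pd.DataFrame, group_a: list[str], group_b: list[str],
                            config: DEConfig | None = None,
                            stage: str = "", contrast: str = "") -> GeneSet:
    """Welch DE between two disjoint sample groups with FDR control.

    Returns a :class:`GeneSet` whose members pass
    ``fdr < config.fdr_threshold``; direction is the sign of the
    (group_a − group_b) statistic.
    """
    config = config or DEConfig()
    group_a = [s for s in group_a if s not in config.excluded_samples]
    group_b = [s for s in group_b if s not in config.excluded_samples]
    if set(group_a) & set(group_b):
        raise ValueError(f"groups overlap: {sorted(set(group_a) & set(group_b))}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    table = welch_tests(expr, group_a, group_b)
    if config.fdr_method == "bh":
        table["fdr"] = bh_fdr(table["p"].to_numpy())
    else:
        table["fdr"] = efron_local_fdr(table["p"].to_numpy(), table["stat"].to_numpy())
    table["direction"] = np.where(table["stat"] >= 0, "up", "down")
    return GeneSet(stage=stage, contrast=contrast, table=table,
                   fdr_threshold=config.fdr_threshold)


def collapse_transcripts(expr: pd.DataFrame, transcript_to_gene: pd.Series) -> pd.DataFrame:
    """Collapse transcript rows to genes, keeping each gene's maximum-variance transcript."""
    var = expr.var(axis=1)
    keep = (
        pd.DataFrame({"gene": transcript_to_gene.reindex(expr.index), "var": var})
        .sort_values(["gene", "var"], ascending=[True, False], kind="mergesort")
        .drop_duplicates("gene")
    )
    out = expr.loc[keep.index]
    out.index = keep["gene"].to_numpy()
    out.index.name = "gene"
    return out


def define_stage_gene_sets(expr: pd.DataFrame, annotations: pd.DataFrame, stage: str,
                           config: DEConfig | None = None) -> tuple[GeneSet, GeneSet]:
    """PCL-responsive and regression-reactive gene sets for one stage.

    PCL-responsive contrasts the stage's high-cholesterol controls with
    immediately-after-PCL samples; regression-reactive contrasts
    immediately-after-PCL with 10-weeks-after samples.
    """
    cells = {}
    for group in ("control", "after_pcl", "regression_10wk"):
        cells[group] = list(annotations.index[(annotations["stage"] == stage)
                                              & (annotations["group"] == group)])
        if not cells[group]:
            raise ValueError(f"no samples for stage {stage!r}, group {group!r}")
    pcl = differential_expression(expr, cells["control"], cells["after_pcl"],
                                  config, stage=stage, contrast="pcl_responsive")
    reactive = differential_expression(expr, cells["after_pcl"], cells["regression_10wk"],
                                       config, stage=stage, contrast="regression_reactive")
    return pcl, reactive


def map_orthologs(gene_set: GeneSet | list[str], table: pd.DataFrame) -> tuple[list[str], int]:
    """Map mouse gene members to deduplicated human ortholog ids.

    ``table`` has columns mouse_id, human_id (1:1, 1:many and many:1 all
    recorded as-is; many:1 collapses are deduplicated). Returns
    ``(human_ids, n_unmapped)``.
    """
    if len(table) == 0:
        raise ValueError("empty ortholog table")
    members = gene_set.members if isinstance(gene_set, GeneSet) else list(gene_set)
    mapping = table.groupby("mouse_id")["human_id"].apply(list)
    human: dict[str, None] = {}
    unmapped = 0
    for m in members:
        if m in mapping.index:
            for h in mapping[m]:
                human.setdefault(h)
        else:
            unmapped += 1
    return sorted(human), unmapped


def overlap_fractions(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Venn-style intersection-region counts and per-set unique fractions.

    Returns one row per non-empty region (a frozenset of set names) with
    its exclusive member count, plus per-set ``unique_percent`` rounded
    to whole percent.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    names = list(sets)
    universe = set().union(*sets.values())
    region_counts: dict[frozenset, int] = {}
    for g in universe:
        region = frozenset(n for n in names if g in sets[n])
        region_counts[region] = region_counts.get(region, 0) + 1
    rows = []
    for region, count in sorted(region_counts.items(), key=lambda kv: sorted(kv[0])):
        rows.append({"region": "&".join(sorted(region)), "n_sets": len(region), "count": count})
    regions = pd.DataFrame(rows)
    uniq = []
    for n in names:
        total = len(sets[n])
        only = region_counts.get(frozenset([n]), 0)
        uniq.append({"set": n, "size": total,
                     "unique_count": only,
                     "unique_percent": int(round(100.0 * only / total)) if total else 0})
    regions.attrs["per_set"] = pd.DataFrame(uniq).set_index("set")
    return regions


def gene_sets_to_gmt(gene_sets: list[GeneSet]) -> dict[str, list[str]]:
    """GMT payload keyed by "w<stage>_<contrast>"."""
    return {f"w{gs.stage}_{gs.contrast}": gs.members for gs in gene_sets}
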