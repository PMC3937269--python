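"""CLR (context likelihood of relatedness) TF-regulatory network inference.

Pairwise co-expression similarity (|Pearson r|) is background-corrected
per gene: each entry is converted to positive z-scores against the
mean/SD of its row and of its column, and the two are combined into the
joint score z_ij = sqrt(z_i² + z_j²). Candidate TF→gene edges are
ranked by an analytic tail p = exp(−z_ij²/2) (a permutation-null mode is
provided as ground truth), thresholded to the most probable half, and
hub TFs are ranked by degree as candidate master regulators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SimilarityMatrix:
    """Symmetric |Pearson r| gene x gene matrix; constant genes flagged."""

    M: pd.DataFrame
    constant_genes: list[str]

    @property
    def genes(self) -> list[str]:
        return list(self.M.index)


@dataclass
class ClrScores:
    """Joint background-corrected scores z_ij (symmetric, >= 0)."""

    z: pd.DataFrame
    flat_background_genes: list[str]

    @property
    def genes(self) -> list[str]:
        return list(self.z.index)


@dataclass
class TFNetwork:
    nodes: pd.DataFrame   # index gene; columns is_tf, degree
    edges: pd.DataFrame   # columns tf, partner, z_ij, edge_p
    p_threshold: float
    retained_fraction: float

    @property
    def member_count(self) -> int:
        return int((self.nodes["degree"] >= 1).sum())


@dataclass
class HubTable:
    table: pd.DataFrame            # columns tf, connections; sorted desc
    master_regulators: list[str]


def compute_similarity(expr: pd.DataFrame, gene_subset: list[str] | None = None) -> SimilarityMatrix:
    """|Pearson correlation| between all gene pairs across samples.

    Requires >= 4 samples. Constant genes get similarity 0 to all
    partners and are flagged.
    """
    if expr.shape[1] < 4:
        raise ValueError(f"need >= 4 samples, got {expr.shape[1]}")
    if gene_subset is not None:
        missing = [g for g in gene_subset if g not in expr.index]
        if missing:
            raise ValueError(f"genes absent from expression matrix: {missing[:5]}")
        expr = expr.loc[list(gene_subset)]
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1)
    constant = list(expr.index[sd == 0])
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((Xc**2).sum(axis=1))
    norm[norm == 0] = 1.0
    Xn = Xc / norm[:, None]
    M = np.abs(Xn @ Xn.T)
    np.fill_diagonal(M, 1.0)
    M = np.clip(M, 0.0, 1.0)
    if constant:
        idx = [expr.index.get_loc(g) for g in constant]
        M[idx, :] = 0.0
        M[:, idx] = 0.0
    return SimilarityMatrix(M=pd.DataFrame(M, index=expr.index, columns=expr.index),
                            constant_genes=constant)


def clr_transform(sim: SimilarityMatrix) -> ClrScores:
    """Background-corrected joint z-scores.

    For pair (i, j): z_i = max(0, (M[i,j] − μ_i)/σ_i) with μ_i, σ_i the
    mean and SD of row i excluding the diagonal (population SD); z_j
    analogous for row j; z_ij = sqrt(z_i² + z_j²). Rows with σ = 0 give
    z = 0 (flat background) and are flagged.
    """
    M = sim.M.to_numpy(dtype=float)
    n = M.shape[0]
    if n < 2:
        raise ValueError("similarity matrix needs >= 2 genes")
    off = M.copy()
    np.fill_diagonal(off, np.nan)
    mu = np.nanmean(off, axis=1)
    sd = np.nanstd(off, axis=1)
    flat = sd == 0
    sd_safe = np.where(flat, 1.0, sd)
    zi = np.maximum(0.0, (M - mu[:, None]) / sd_safe[:, None])  # row-referenced
    zi[flat, :] = 0.0
    z = np.sqrt(zi**2 + zi.T**2)
    np.fill_diagonal(z, 0.0)
    return ClrScores(z=pd.DataFrame(z, index=sim.M.index, columns=sim.M.columns),
                     flat_background_genes=list(sim.M.index[flat]))


def edge_pvalues(scores: ClrScores) -> pd.DataFrame:
    """Analytic edge tail probability exp(−z_ij²/2).

    The Rayleigh tail of the joint of two standard positive scores:
    parameter-free, monotone decreasing in z_ij, and p = 1 at z = 0.
    """
    z = scores.z.to_numpy(dtype=float)
    return pd.DataFrame(np.exp(-0.5 * z**2), index=scores.z.index, columns=scores.z.columns)


def permutation_edge_pvalues(expr: pd.DataFrame, gene_subset: list[str] | None = None,
                             n_permutations: int = 200, seed: int = 0) -> pd.DataFrame:
    """Permutation-null edge p-values for the CLR joint score.

    Each iteration permutes every gene's sample vector independently
    (destroying all gene-gene dependence while keeping marginals),
    recomputes the CLR scores, and pools the null z values across pairs
    and iterations; the per-pair p is (1 + #{null z >= z_obs})/(1 + N).
    """
    rng = np.random.default_rng(seed)
    sim = compute_similarity(expr, gene_subset)
    obs = clr_transform(sim).z.to_numpy(dtype=float)
    genes = sim.genes
    sub = expr.loc[genes].to_numpy(dtype=float)
    n_genes, n_samples = sub.shape
    iu = np.triu_indices(n_genes, k=1)
    null_pool = []
    for _ in range(n_permutations):
        perm = np.empty_like(sub)
        for g in range(n_genes):
            perm[g] = sub[g, rng.permutation(n_samples)]
        pdfr = pd.DataFrame(perm, index=genes)
        znull = clr_transform(compute_similarity(pdfr)).z.to_numpy(dtype=float)
        null_pool.append(znull[iu])
    null = np.sort(np.concatenate(null_pool))
    n_null = len(null)
    # p = (1 + #null >= obs) / (1 + N), vectorized via searchsorted
    ge = n_null - np.searchsorted(null, obs, side="left")
    p = (1.0 + ge) / (1.0 + n_null)
    np.fill_diagonal(p, 1.0)
    return pd.DataFrame(p, index=genes, columns=genes)


def build_tf_network(scores: ClrScores, edge_p: pd.DataFrame, tf_list: list[str],
                     gene_set: list[str], retain_fraction: float = 0.5) -> TFNetwork:
    """Threshold candidate TF-gene interactions to the most probable half.

    Candidates are all unordered (TF, gene) pairs within gene_set with a
    TF endpoint; the ``retain_fraction`` with smallest edge_p are kept
    (ties at the retention quantile are all kept, and the actually
    retained fraction is reported). Pairs with zero evidence
    (z_ij = 0, edge_p = 1) are never retained: on noisy data a large
    point mass of candidates clips to z = 0, and keeping that tie mass
    would make every network complete. p_threshold is the largest
    retained edge_p; member_count counts nodes with at least one
    retained edge.
    """
    genes = [g for g in gene_set if g in scores.z.index]
    tfs = sorted(set(tf_list) & set(genes))
    if not tfs:
        raise ValueError("no TFs present in the gene set")
    tf_set = set(tfs)
    cand = []
    for tf in tfs:
        for g in genes:
            if g == tf:
                continue
            if g in tf_set and g < tf:
                continue  # TF-TF pair counted once
            cand.append((tf, g))
    if not cand:
        raise ValueError("no candidate TF-gene pairs")
    ptab = pd.DataFrame(cand, columns=["tf", "partner"])
    ptab["z_ij"] = [float(scores.z.at[a, b]) for a, b in cand]
    ptab["edge_p"] = [float(edge_p.at[a, b]) for a, b in cand]
    ptab = ptab.sort_values(["edge_p", "tf", "partner"], kind="mergesort").reset_index(drop=True)
    k = int(round(retain_fraction * len(ptab)))
    k = max(k, 0)
    if k == 0:
        retained = ptab.iloc[0:0]
        p_threshold = 0.0
    else:
        cutoff = float(ptab["edge_p"].iloc[k - 1])
        keep = (ptab["edge_p"] <= cutoff) & (ptab["z_ij"] > 0)
        retained = ptab[keep].reset_index(drop=True)
        p_threshold = float(retained["edge_p"].max()) if len(retained) else 0.0
    degree = pd.Series(0, index=pd.Index(genes, name="gene"), dtype=int)
    for row in retained.itertuples(index=False):
        degree[row.tf] += 1
        degree[row.partner] += 1
    nodes = pd.DataFrame({"is_tf": [g in tf_set for g in genes], "degree": degree},
                         index=pd.Index(genes, name="gene"))
    return TFNetwork(nodes=nodes, edges=retained, p_threshold=p_threshold,
                     retained_fraction=len(retained) / len(ptab))


def rank_master_regulators(network: TFNetwork, top_k: int = 5) -> HubTable:
    """Rank TFs by degree in the thresholded network (hubs).

    Ties break lexicographically by gene id; an edgeless network returns
    an empty table.
    """
    if len(network.edges) == 0:
        return HubTable(table=pd.DataFrame(columns=["tf", "connections"]), master_regulators=[])
    tf_nodes = network.nodes[network.nodes["is_tf"]]
    tab = (pd.DataFrame({"tf": tf_nodes.index, "connections": tf_nodes["degree"].to_numpy()})
           .sort_values(["connections", "tf"], ascending=[False, True], kind="mergesort")
           .reset_index(drop=True))
    tab = tab[tab["connections"] > 0].reset_index(drop=True)
    return HubTable(table=tab.head(top_k) if top_k < len(tab) else tab, master_regulators=[])
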