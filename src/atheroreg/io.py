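"""Readers and writers for the pipeline's plain-text formats.

Expression matrices, sample annotations, genotype dosages (TSV or a
minimal GT-only VCF), GWAS summary tables, GMT gene sets and SIF/TSV
network exports. All readers validate and reject malformed input with
coordinates rather than silently coercing.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------- expression


def read_expression_table(path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column gene ids).

    Rejects duplicate gene ids, missing values and non-numeric cells,
    naming the offending row/column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate gene id {dup!r} in {path}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise FormatError(f"non-numeric cell at gene {bad!r}, sample {col!r} in {path}")
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        col = df.columns[df.isna().any(axis=0)][0]
        raise FormatError(f"missing value at gene {gene!r}, sample {col!r} in {path}")
    df.index = df.index.astype(str)
    df.index.name = "gene"
    return df.astype(float)


def write_expression_table(expr: pd.DataFrame, path) -> None:
    out = expr.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_sample_annotations(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    ann.index.name = "sample"
    return ann


def write_sample_annotations(ann: pd.DataFrame, path) -> None:
    out = ann.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


# ----------------------------------------------------------------- genotypes

DOSAGE_META_COLS = ("snp", "chrom", "pos", "maf")


def compute_maf(dosages: np.ndarray) -> float:
    """Minor-allele frequency from 0/1/2 dosages."""
    f = float(np.mean(dosages)) / 2.0
    return min(f, 1.0 - f)


def read_genotypes(path):
    """Read genotypes from a dosage TSV or a minimal GT-only VCF.

    Returns ``(dosage, meta)``: ``dosage`` is a SNPs x individuals
    DataFrame of 0/1/2 values, ``meta`` a per-SNP frame with columns
    chrom, pos, maf (MAF computed from dosages when absent).
    """
    path = Path(path)
    if path.suffix == ".vcf":
        return _read_minimal_vcf(path)
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "chrom": str})
    missing = [c for c in ("snp", "chrom", "pos") if c not in df.columns]
    if missing:
        raise FormatError(f"dosage TSV {path} lacks columns {missing}")
    df = df.set_index("snp")
    sample_cols = [c for c in df.columns if c not in ("chrom", "pos", "maf")]
    dosage = df[sample_cols].astype(float)
    if not dosage.isin([0, 1, 2]).all().all():
        raise FormatError(f"dosage values outside {{0,1,2}} in {path}")
    dosage = dosage.astype(int)
    meta = df[["chrom", "pos"]].copy()
    meta["pos"] = meta["pos"].astype(int)
    if "maf" in df.columns:
        meta["maf"] = df["maf"].astype(float)
    else:
        meta["maf"] = [compute_maf(dosage.loc[s].to_numpy()) for s in dosage.index]
    return dosage, meta


def write_dosage_tsv(dosage: pd.DataFrame, meta: pd.DataFrame, path) -> None:
    out = meta[["chrom", "pos"]].copy()
    out["maf"] = meta["maf"]
    out = out.join(dosage)
    out.index.name = "snp"
    out.to_csv(path, sep="\t", float_format="%.10g")


_GT_TO_DOSAGE = {"0/0": 0, "0|0": 0, "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1, "1/1": 2, "1|1": 2}


def _read_minimal_vcf(path):
    """Parse the minimal GT-only VCF emitted by :func:`write_minimal_vcf`.

    Multi-allelic sites and malformed lines are rejected with their line
    number.
    """
    rows, dosages, samples = [], [], None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                if len(fields) < 10:
                    raise FormatError(f"{path}:{lineno}: VCF header has no sample columns")
                samples = fields[9:]
                continue
            if samples is None:
                raise FormatError(f"{path}:{lineno}: data line before #CHROM header")
            if len(fields) != 9 + len(samples):
                raise FormatError(f"{path}:{lineno}: expected {9+len(samples)} fields, got {len(fields)}")
            chrom, pos, snp_id, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt:
                raise FormatError(f"{path}:{lineno}: multi-allelic site {snp_id!r} rejected")
            try:
                pos = int(pos)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer position {pos!r}") from None
            row = []
            for gt in fields[9:]:
                gt = gt.split(":")[0]
                if gt not in _GT_TO_DOSAGE:
                    raise FormatError(f"{path}:{lineno}: unsupported genotype {gt!r}")
                row.append(_GT_TO_DOSAGE[gt])
            rows.append((snp_id, chrom, pos))
            dosages.append(row)
    if samples is None:
        raise FormatError(f"{path}: no #CHROM header line")
    meta = pd.DataFrame(rows, columns=["snp", "chrom", "pos"]).set_index("snp")
    dosage = pd.DataFrame(dosages, index=meta.index, columns=samples, dtype=int)
    meta["maf"] = [compute_maf(dosage.loc[s].to_numpy()) for s in dosage.index]
    return dosage, meta


def write_minimal_vcf(dosage: pd.DataFrame, meta: pd.DataFrame, path) -> None:
    """Write a minimal GT-only VCF (unphased; dosage 1 becomes 0/1)."""
    back = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(dosage.columns) + "\n")
        for snp in dosage.index:
            gts = "\t".join(back[int(v)] for v in dosage.loc[snp])
            fh.write(f"{meta.loc[snp,'chrom']}\t{int(meta.loc[snp,'pos'])}\t{snp}\tA\tG\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------- GWAS


def read_gwas_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "chr": str})
    missing = [c for c in ("snp", "chr", "pos", "p", "maf") if c not in df.columns]
    if missing:
        raise FormatError(f"GWAS summary {path} lacks columns {missing}")
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        bad = df.loc[(df["p"] <= 0) | (df["p"] > 1), "snp"].iloc[0]
        raise FormatError(f"GWAS p outside (0,1] for SNP {bad!r} in {path}")
    return df.set_index("snp")


def write_gwas_summary(gwas: pd.DataFrame, path) -> None:
    out = gwas.reset_index()[["snp", "chr", "pos", "p", "maf"]]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ----------------------------------------------------------- gene sets / GMT


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, name] + sorted(members)) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    out = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise FormatError(f"GMT line with fewer than 2 fields in {path}")
            out[fields[0]] = fields[2:]
    return out


def read_ortholog_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("mouse_id", "human_id") if c not in df.columns]
    if missing:
        raise FormatError(f"ortholog table {path} lacks columns {missing}")
    if (df["mouse_id"].str.len() == 0).any() or (df["human_id"].str.len() == 0).any():
        raise FormatError(f"empty identifier in ortholog table {path}")
    return df


def read_tf_list(path) -> list[str]:
    with open(path) as fh:
        tfs = [line.strip() for line in fh if line.strip()]
    return tfs


# ------------------------------------------------------------------ networks


def write_network(network, path_prefix, fmt="sif") -> list[Path]:
    """Export a TF network as Cytoscape-loadable SIF plus a scored TSV.

    Rows are sorted (tf, partner) lexicographically so re-export after
    reload is byte-identical.
    """
    if fmt not in ("sif", "tsv"):
        raise ValueError(f"unknown network format {fmt!r}")
    prefix = Path(path_prefix)
    edges = network.edges.sort_values(["tf", "partner"], kind="mergesort").reset_index(drop=True)
    written = []
    if fmt == "sif":
        sif = prefix.with_suffix(".sif")
        with open(sif, "w") as fh:
            for row in edges.itertuples(index=False):
                fh.write(f"{row.tf}\tregulates\t{row.partner}\n")
        written.append(sif)
    tsv = prefix.with_suffix(".edges.tsv")
    edges[["tf", "partner", "z_ij", "edge_p"]].to_csv(tsv, sep="\t", index=False, float_format="%.10g")
    written.append(tsv)
    return written


def read_network_edges(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "partner": str})
    missing = [c for c in ("tf", "partner", "z_ij", "edge_p") if c not in df.columns]
    if missing:
        raise FormatError(f"network edge TSV {path} lacks columns {missing}")
    return df


# ------------------------------------------------------------------ manifest


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: dict, seed: int, inputs: dict[str, str], outputs: dict[str, str]) -> None:
    """Record config hash, seed, versions and file checksums for a run."""
    import atheroreg

    manifest = {
        "config_sha256": hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest(),
        "config": config,
        "seed": seed,
        "versions": {
            "atheroreg": atheroreg.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "input_checksums": inputs,
        "output_checksums": outputs,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
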