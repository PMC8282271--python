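"""Readers and writers for the formats the pipeline touches.

VCF v4.2 (GT field) for genotypes, header TSV for pool allele
frequencies / annotations / results, GMT for gene sets, and a 2-column
TSV edge list for protein-protein interaction networks.  Readers reject
schema violations rather than silently coercing; write -> read is the
identity on the internal model up to the fixed, documented printing
precision of floats.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import (
    MISSING,
    NOVEL_ID,
    CohortDataset,
    PoolAFTable,
    ValidationError,
    parse_regulome_score,
    validate_variant_table,
)

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_table",
    "write_pool_table",
    "write_results",
    "write_gene_sets",
    "write_edges",
    "ParseError",
]


class ParseError(ValidationError):
    """A file could not be parsed against its declared format."""


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Assigned gene">\n'
    '##INFO=<ID=REGION,Number=1,Type=String,Description="Genomic region class">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(dataset: CohortDataset, path: str | os.PathLike) -> None:
    """Write a cohort as VCF v4.2 with GT calls and GENE/REGION INFO tags.

    Records are emitted in deterministic (chromosome, position, alt)
    order; the case/control label is encoded in the sample name prefix
    (``case_``/``ctrl_``) so a round trip preserves the phenotype.
    """
    variants = dataset.variants.reset_index(drop=True)
    order = np.lexsort(
        (variants["alt"].to_numpy(), variants["pos"].to_numpy(), variants["chrom"].to_numpy())
    )
    samples = [
        f"{'case' if p == 1 else 'ctrl'}_{i:05d}" for i, p in enumerate(dataset.phenotype)
    ]
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j in order:
            row = variants.iloc[j]
            gts = "\t".join(_GT_STRING[int(g)] for g in dataset.genotypes[j])
            info = f"GENE={row['gene']};REGION={row['region']}"
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


def read_vcf(path: str | os.PathLike) -> CohortDataset:
    """Read a VCF v4.x with GT calls into the internal cohort model.

    1-based positions are preserved, ``./.`` maps to the missing
    sentinel, and multi-allelic sites are split into biallelic records
    (the dosage of each split record counts that alternate allele only).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    _require_gt_header(path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # malformed header
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    phenotype = np.array([1 if s.startswith("case") else 0 for s in samples])
    rows, genos = [], []
    for rec in vcf:
        gt = np.array(rec.genotypes, dtype=object)
        a0 = np.array([g[0] for g in gt])
        a1 = np.array([g[1] if len(g) > 2 else -1 for g in gt])
        gene = rec.INFO.get("GENE", "NA")
        region = rec.INFO.get("REGION", "intronic")
        for ai, alt in enumerate(rec.ALT, start=1):
            dos = (a0 == ai).astype(int) + (a1 == ai).astype(int)
            dos[(a0 < 0) | (a1 < 0)] = MISSING
            rows.append(
                {
                    "chrom": rec.CHROM,
                    "pos": rec.POS,
                    "id": rec.ID if rec.ID else NOVEL_ID,
                    "ref": rec.REF,
                    "alt": alt,
                    "gene": gene,
                    "region": region,
                }
            )
            genos.append(dos)
    variants = pd.DataFrame(
        rows, columns=["chrom", "pos", "id", "ref", "alt", "gene", "region"]
    )
    genotypes = (
        np.array(genos, dtype=np.int8)
        if genos
        else np.zeros((0, len(samples)), dtype=np.int8)
    )
    if len(variants):
        validate_variant_table(variants)
    return CohortDataset(variants, genotypes, phenotype)


def _require_gt_header(path: str) -> None:
    has_gt = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##"):
                if line.startswith("##FORMAT=<ID=GT,"):
                    has_gt = True
                continue
            if not line.startswith("#CHROM"):
                raise ParseError(
                    f"{path}:{lineno}: expected #CHROM header line, got {line[:40]!r}"
                )
            if not has_gt:
                raise ParseError(
                    f"{path}:{lineno}: VCF header declares no GT FORMAT field"
                )
            return
    raise ParseError(f"{path}: truncated VCF (no #CHROM header line)")


# ---------------------------------------------------------------------------
# Tabular schemas

_ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "regulome_score",
    "tf_or_dhs_overlap",
    "ago_evidence_count",
    "coding_effect",
]

_POOL_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "pool",
    "pool_size",
    "pool_phenotype",
    "pool_depth",
    "af",
]


def read_table(path: str | os.PathLike, schema: str):
    """Read a supporting table; ``schema`` selects validation and the
    return type.

    =============  =====================================================
    schema         returns
    =============  =====================================================
    ``pool_af``    :class:`~longevar.core.PoolAFTable`
    ``annotations``  DataFrame with parsed regulome class/subclass
    ``gene_sets``  dict name -> list of genes (GMT dialect)
    ``edges``      list of (node, node) tuples
    ``results``    DataFrame (generic TSV with header)
    =============  =====================================================
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    if schema == "gene_sets":
        return _read_gmt(path)
    if schema == "edges":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 2:
            raise ParseError(f"{path}: edge list needs 2 columns, found {df.shape[1]}")
        return list(zip(df[0], df[1]))
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str} if schema != "results" else None)
    if schema == "results":
        return df
    if schema == "annotations":
        _require_columns(df, _ANNOTATION_COLUMNS, path)
        classes, subclasses = zip(
            *(parse_regulome_score(s) for s in df["regulome_score"])
        ) if len(df) else ((), ())
        df = df.copy()
        df["regulome_class"] = list(classes)
        df["regulome_subclass"] = list(subclasses)
        if (df["ago_evidence_count"] < 0).any():
            raise ParseError(f"{path}: ago_evidence_count must be >= 0")
        df["tf_or_dhs_overlap"] = df["tf_or_dhs_overlap"].astype(bool)
        return df
    if schema == "pool_af":
        _require_columns(df, _POOL_COLUMNS, path)
        bad = df.index[(df["af"] < 0) | (df["af"] > 1)]
        if len(bad):
            raise ParseError(
                f"{path}: AF outside [0, 1] at row {int(bad[0])} (value {df['af'].iloc[bad[0]]})"
            )
        return _pool_table_from_long(df)
    raise ValueError(f"unknown schema {schema!r}")


def _require_columns(df: pd.DataFrame, cols, path: str) -> None:
    for col in cols:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")


def _read_gmt(path: str) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, genes = parts[0], [g for g in parts[2:] if g]
            if not genes:
                raise ParseError(f"{path}:{lineno}: empty gene set {name!r}")
            if len(set(genes)) != len(genes):
                raise ParseError(f"{path}:{lineno}: duplicate genes in set {name!r}")
            sets[name] = genes
    return sets


def write_gene_sets(sets: dict[str, list[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name in sets:
            fh.write("\t".join([name, "na", *sets[name]]) + "\n")


def write_edges(edges, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


def _pool_table_from_long(df: pd.DataFrame) -> PoolAFTable:
    key_cols = ["chrom", "pos", "ref", "alt"]
    meta_cols = ["gene", "region", "id"]
    keep = key_cols + [c for c in meta_cols if c in df.columns]
    variants = df[keep].drop_duplicates(subset=key_cols).reset_index(drop=True)
    for c in meta_cols:
        if c not in variants.columns:
            variants[c] = "NA" if c == "gene" else ("intronic" if c == "region" else NOVEL_ID)
    variants = variants[["chrom", "pos", "id", "ref", "alt", "gene", "region"]]
    pools = np.sort(df["pool"].unique())
    wide = df.pivot_table(index=key_cols, columns="pool", values="af", sort=False)
    key_index = pd.MultiIndex.from_frame(variants[key_cols])
    af = wide.loc[key_index, pools].to_numpy()
    meta = df.drop_duplicates(subset="pool").set_index("pool").loc[pools]
    return PoolAFTable(
        variants=variants,
        af=af,
        pool_sizes=meta["pool_size"].to_numpy(int),
        pool_phenotype=meta["pool_phenotype"].to_numpy(int),
        pool_depth=meta["pool_depth"].to_numpy(float),
    )


def write_pool_table(table: PoolAFTable, path: str | os.PathLike) -> None:
    """Long-format TSV: one row per (variant, pool) with pool metadata."""
    rows = []
    v = table.variants.reset_index(drop=True)
    for k in range(table.n_pools):
        for j in range(table.n_variants):
            rows.append(
                {
                    "chrom": v["chrom"][j],
                    "pos": int(v["pos"][j]),
                    "id": v["id"][j],
                    "ref": v["ref"][j],
                    "alt": v["alt"][j],
                    "gene": v["gene"][j],
                    "region": v["region"][j],
                    "pool": k,
                    "pool_size": int(table.pool_sizes[k]),
                    "pool_phenotype": int(table.pool_phenotype[k]),
                    "pool_depth": table.pool_depth[k],
                    "af": repr(float(table.af[j, k])),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Results

#: Columns formatted as p-values on output (fixed 4-decimal printing,
#: the convention of the association tables this mirrors).
_P_COLUMNS = ("p", "pvalue", "p_allelic", "p_genotypic", "p_value")


def write_results(results: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a results table as TSV with deterministic row/column order.

    P-value columns are printed with 4 decimal places (0.00531 renders
    as ``0.0053``); other floats keep full precision.
    """
    df = results.copy()
    for col in df.columns:
        if col in _P_COLUMNS and pd.api.types.is_numeric_dtype(df[col]):
            df[col] = df[col].map(lambda p: "" if pd.isna(p) else f"{p:.4f}")
    df.to_csv(path, sep="\t", index=False)
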