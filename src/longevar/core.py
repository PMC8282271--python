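"""Core data containers shared across the pipeline.

The internal data model is deliberately small: a variant table
(:class:`pandas.DataFrame` with a fixed column set), a dense genotype
matrix with a missing-value sentinel, and a pool-level allele-frequency
table for pooled-sequencing designs where individual genotypes are not
observed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Closed vocabulary of genomic region classes.
REGION_CLASSES = (
    "upstream",
    "exonic-synonymous",
    "exonic-nonsynonymous",
    "stopgain",
    "stoploss",
    "frameshift",
    "splicing",
    "intronic",
    "utr3",
    "utr5",
)

#: Coding-effect labels; ``none`` is the sentinel for non-coding variants.
CODING_EFFECTS = (
    "none",
    "synonymous",
    "nonsynonymous",
    "stopgain",
    "stoploss",
    "frameshift",
    "splicing",
)

#: Genotype value marking a missing call.
MISSING = -1

#: Identifier sentinel for novel (unnamed) variants.
NOVEL_ID = "."

#: Required columns of a variant table, in canonical order.
VARIANT_COLUMNS = ("chrom", "pos", "id", "ref", "alt", "gene", "region")

_REGULOME_RE = re.compile(r"^([1-7])([a-f]?)$")


class ValidationError(ValueError):
    """An input violated a schema or invariant."""


def parse_regulome_score(score: str) -> tuple[int, str]:
    """Split a RegulomeDB-style score such as ``"3a"`` into (3, "a").

    The leading integer carries the ordering (lower = more regulatory
    evidence); the letter subclass is retained but never used for
    ranking.
    """
    m = _REGULOME_RE.match(str(score).strip())
    if m is None:
        raise ValidationError(f"invalid RegulomeDB-style score: {score!r}")
    return int(m.group(1)), m.group(2)


def variant_key(row) -> tuple[str, int, str, str]:
    """Canonical (chrom, pos, ref, alt) key for a variant-table row."""
    return (str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))


def variant_keys(variants: pd.DataFrame) -> list[tuple[str, int, str, str]]:
    return [
        (str(c), int(p), str(r), str(a))
        for c, p, r, a in zip(
            variants["chrom"], variants["pos"], variants["ref"], variants["alt"]
        )
    ]


def validate_variant_table(variants: pd.DataFrame) -> None:
    for col in VARIANT_COLUMNS:
        if col not in variants.columns:
            raise ValidationError(f"variant table missing column {col!r}")
    if len(variants) == 0:
        return
    if (variants["pos"] < 1).any():
        raise ValidationError("variant positions must be >= 1 (1-based)")
    if (variants["ref"] == variants["alt"]).any():
        raise ValidationError("ref and alt alleles must differ")
    bad = set(variants["region"]) - set(REGION_CLASSES)
    if bad:
        raise ValidationError(f"unknown region class(es): {sorted(bad)}")


@dataclass
class CohortDataset:
    """Individual-level cohort: variants x individuals genotypes + phenotype.

    ``genotypes[j, i]`` is the alternate-allele dosage (0/1/2) of variant
    ``j`` in individual ``i``, or :data:`MISSING`.  ``phenotype`` is 1 for
    cases (centenarians) and 0 for controls.
    """

    variants: pd.DataFrame
    genotypes: np.ndarray
    phenotype: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        self.phenotype = np.asarray(self.phenotype)
        validate_variant_table(self.variants)
        if self.genotypes.ndim != 2:
            raise ValidationError("genotype matrix must be 2-D (variants x individuals)")
        if self.genotypes.shape[0] != len(self.variants):
            raise ValidationError(
                "genotype matrix rows must match the variant table length"
            )
        if self.genotypes.shape[1] != len(self.phenotype):
            raise ValidationError(
                "genotype matrix columns must match the phenotype length"
            )
        vals = set(np.unique(self.genotypes)) - {0, 1, 2, MISSING}
        if vals:
            raise ValidationError(f"genotype values outside {{0,1,2,missing}}: {vals}")
        if not set(np.unique(self.phenotype)) <= {0, 1}:
            raise ValidationError("phenotype must be binary 0/1")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[0]


@dataclass
class PoolAFTable:
    """Pool-level alternate-allele frequencies (pooled-sequencing design).

    ``af[j, k]`` is the estimated alternate-allele frequency of variant
    ``j`` in pool ``k``.  Pools are phenotype-homogeneous; ``depth`` is
    the per-pool read depth used for the binomial read-sampling model
    (``inf`` marks exact, noise-free frequencies).
    """

    variants: pd.DataFrame
    af: np.ndarray
    pool_sizes: np.ndarray
    pool_phenotype: np.ndarray
    pool_depth: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.af = np.asarray(self.af, dtype=float)
        self.pool_sizes = np.asarray(self.pool_sizes, dtype=int)
        self.pool_phenotype = np.asarray(self.pool_phenotype, dtype=int)
        if self.pool_depth is None:
            self.pool_depth = np.full(len(self.pool_sizes), np.inf)
        self.pool_depth = np.asarray(self.pool_depth, dtype=float)
        validate_variant_table(self.variants)
        if self.af.ndim != 2 or self.af.shape[0] != len(self.variants):
            raise ValidationError("AF table must be 2-D variants x pools")
        n_pools = self.af.shape[1]
        for name, arr in (
            ("pool_sizes", self.pool_sizes),
            ("pool_phenotype", self.pool_phenotype),
            ("pool_depth", self.pool_depth),
        ):
            if len(arr) != n_pools:
                raise ValidationError(f"{name} length must equal the pool count")
        if np.any((self.af < 0) | (self.af > 1)):
            raise ValidationError("pool AFs must lie in [0, 1]")
        if np.any(self.pool_sizes < 1):
            raise ValidationError("pool sizes must be >= 1")
        if not set(np.unique(self.pool_phenotype)) <= {0, 1}:
            raise ValidationError("pool phenotype must be binary 0/1")
        if np.any(self.pool_depth < 1):
            raise ValidationError("pool depths must be >= 1")

    @property
    def n_pools(self) -> int:
        return self.af.shape[1]

    @property
    def n_variants(self) -> int:
        return self.af.shape[0]
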