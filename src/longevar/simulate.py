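"""Synthetic case-control cohorts with the structure of a targeted
rare-variant sequencing study.

The generator emulates a two-group design (default 450 centenarians vs
500 controls), a rare-dominated allele-frequency spectrum (~81% of
variants with MAF < 0.05), the genomic-region mix observed in targeted
capture of gene loci (mostly intronic and upstream), designated causal
variants with group-specific allele frequencies, and pooled sequencing
in which only per-pool allele frequencies — optionally with binomial
read-sampling noise — are observed.

Genotypes are drawn per group under Hardy-Weinberg equilibrium at the
group allele frequency.  One global seed drives three named substreams
(genotypes, pooling, annotations) so each stage can be regenerated
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CODING_EFFECTS,
    REGION_CLASSES,
    CohortDataset,
    PoolAFTable,
    ValidationError,
)

__all__ = [
    "MafLaw",
    "Effect",
    "SimulationConfig",
    "AnnotationConfig",
    "PoolingPlan",
    "simulate_cohort",
    "make_pooling_plan",
    "pool_cohort",
    "simulate_annotations",
]

# Region-class mix observed in targeted capture of gene loci (2-kb
# upstream + exons + junctions): intronic 50.96%, upstream 13.36%,
# exonic 10.38% (split across coding-effect classes), remainder UTRs
# and splice sites.
DEFAULT_REGION_FRACTIONS = {
    "intronic": 0.5096,
    "upstream": 0.1336,
    "exonic-synonymous": 0.0450,
    "exonic-nonsynonymous": 0.0500,
    "stopgain": 0.0025,
    "stoploss": 0.0013,
    "frameshift": 0.0050,
    "splicing": 0.0100,
    "utr3": 0.1330,
    "utr5": 0.1100,
}

_SUBSTREAMS = {"genotypes": 0, "pooling": 1, "annotations": 2}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream generator derived from the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_SUBSTREAMS[stream],))
    )


@dataclass(frozen=True)
class MafLaw:
    """Two-component uniform mixture over minor-allele frequencies.

    ``rare_mass`` of the probability lies on ``rare_range`` (below the
    rare/common cutoff); the remainder on ``common_range``.  Defaults
    put 81% of variants below MAF 0.05, matching the rare-dominated
    spectrum of targeted sequencing of candidate gene regions.
    """

    rare_mass: float = 0.81
    rare_range: tuple[float, float] = (0.002, 0.05)
    common_range: tuple[float, float] = (0.05, 0.5)

    def validate(self) -> None:
        if not 0.0 <= self.rare_mass <= 1.0:
            raise ValidationError("maf_law.rare_mass must lie in [0, 1]")
        for name, (lo, hi) in (
            ("rare_range", self.rare_range),
            ("common_range", self.common_range),
        ):
            if not (0.0 <= lo <= hi <= 0.5):
                raise ValidationError(f"maf_law.{name} must satisfy 0 <= lo <= hi <= 0.5")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        rare = rng.random(n) < self.rare_mass
        out = np.empty(n)
        out[rare] = rng.uniform(*self.rare_range, size=int(rare.sum()))
        out[~rare] = rng.uniform(*self.common_range, size=int((~rare).sum()))
        return out


@dataclass(frozen=True)
class Effect:
    """A designated causal variant with group-specific allele frequencies."""

    gene: str
    variant_index: int  # index within the gene's variants
    maf_cases: float
    maf_controls: float


@dataclass(frozen=True)
class SimulationConfig:
    n_cases: int = 450
    n_controls: int = 500
    n_genes: int = 50
    variants_per_gene: int | tuple[int, int] = 20
    maf_law: MafLaw = field(default_factory=MafLaw)
    region_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_REGION_FRACTIONS)
    )
    effect_model: tuple[Effect, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("n_cases and n_controls must be >= 1")
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        vpg = self.variants_per_gene
        if isinstance(vpg, tuple):
            if not (1 <= vpg[0] <= vpg[1]):
                raise ValidationError("variants_per_gene range must satisfy 1 <= lo <= hi")
        elif vpg < 1:
            raise ValidationError("variants_per_gene must be >= 1")
        fr = self.region_fractions
        if any(v < 0 for v in fr.values()):
            raise ValidationError("region_fractions values must be nonnegative")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValidationError("region_fractions must sum to 1 (within 1e-9)")
        unknown = set(fr) - set(REGION_CLASSES)
        if unknown:
            raise ValidationError(f"region_fractions has unknown classes: {sorted(unknown)}")
        self.maf_law.validate()
        for eff in self.effect_model:
            for fld in ("maf_cases", "maf_controls"):
                v = getattr(eff, fld)
                if not 0.0 <= v <= 0.5:
                    raise ValidationError(
                        f"effect_model {fld} for {eff.gene}[{eff.variant_index}] "
                        f"must lie in [0, 0.5], got {v}"
                    )


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[CohortDataset, pd.DataFrame]:
    """Draw a cohort under the configured allele-frequency model.

    Returns the dataset and a truth table recording, per variant, the
    true population MAF in each group, the causal flag and the gene
    assignment — the ground truth for parameter-recovery tests.
    Identical config + seed gives bit-identical output.
    """
    config.validate()
    rng = _rng(config.seed, "genotypes")

    genes = [f"GENE{g + 1:03d}" for g in range(config.n_genes)]
    vpg = config.variants_per_gene
    if isinstance(vpg, tuple):
        counts = rng.integers(vpg[0], vpg[1] + 1, size=config.n_genes)
    else:
        counts = np.full(config.n_genes, int(vpg))
    n_var = int(counts.sum())

    gene_col = np.repeat(genes, counts)
    within = np.concatenate([np.arange(c) for c in counts])

    regions = list(config.region_fractions)
    probs = np.array([config.region_fractions[r] for r in regions], dtype=float)
    probs = probs / probs.sum()
    region_col = rng.choice(regions, size=n_var, p=probs)

    base_maf = config.maf_law.sample(n_var, rng)
    maf_cases = base_maf.copy()
    maf_controls = base_maf.copy()
    causal = np.zeros(n_var, dtype=bool)
    gene_offset = dict(zip(genes, np.concatenate([[0], np.cumsum(counts)[:-1]])))
    for eff in config.effect_model:
        if eff.gene not in gene_offset:
            raise ValidationError(f"effect_model references unknown gene {eff.gene!r}")
        gi = genes.index(eff.gene)
        if eff.variant_index >= counts[gi]:
            raise ValidationError(
                f"effect_model variant_index {eff.variant_index} out of range "
                f"for {eff.gene} ({counts[gi]} variants)"
            )
        j = gene_offset[eff.gene] + eff.variant_index
        maf_cases[j] = eff.maf_cases
        maf_controls[j] = eff.maf_controls
        causal[j] = True

    # one synthetic chromosome per gene block, 1-based positions
    chrom = np.repeat([f"chr{(gi % 22) + 1}" for gi in range(config.n_genes)], counts)
    pos = 1_000_000 + gene_offset_positions(counts)
    alleles = np.array(["A", "C", "G", "T"])
    ref = rng.choice(alleles, size=n_var)
    alt_shift = rng.integers(1, 4, size=n_var)
    alt = alleles[(np.searchsorted(alleles, ref) + alt_shift) % 4]

    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "id": np.where(rng.random(n_var) < 0.8, "rs" + pd.Series(np.arange(n_var)).astype(str), "."),
            "ref": ref,
            "alt": alt,
            "gene": gene_col,
            "region": region_col,
        }
    )

    n = config.n_cases + config.n_controls
    phenotype = np.concatenate(
        [np.ones(config.n_cases, dtype=int), np.zeros(config.n_controls, dtype=int)]
    )
    # Hardy-Weinberg sampling per group: dosage ~ Binomial(2, group MAF)
    g_cases = rng.binomial(2, maf_cases[:, None], size=(n_var, config.n_cases))
    g_controls = rng.binomial(2, maf_controls[:, None], size=(n_var, config.n_controls))
    genotypes = np.concatenate([g_cases, g_controls], axis=1).astype(np.int8)

    truth = pd.DataFrame(
        {
            "chrom": variants["chrom"],
            "pos": variants["pos"],
            "ref": variants["ref"],
            "alt": variants["alt"],
            "gene": gene_col,
            "variant_index": within,
            "maf_cases": maf_cases,
            "maf_controls": maf_controls,
            "causal": causal,
        }
    )
    return CohortDataset(variants, genotypes, phenotype), truth


def gene_offset_positions(counts: np.ndarray) -> np.ndarray:
    """Deterministic 1-based positions: genes spaced 1e6 apart, variants 100 bp."""
    out = []
    for gi, c in enumerate(counts):
        out.append(gi * 1_000_000 + 100 * np.arange(c))
    return np.concatenate(out) + 1


@dataclass(frozen=True)
class PoolingPlan:
    """Assignment of individuals to phenotype-homogeneous pools.

    ``pool_of[i]`` is the pool index of individual ``i``; ``depth`` is
    the per-pool read depth (``inf`` = exact allele frequencies).
    """

    pool_of: np.ndarray
    depth: np.ndarray
    seed: int = 0

    def validate(self, phenotype: np.ndarray) -> None:
        pool_of = np.asarray(self.pool_of)
        if len(pool_of) != len(phenotype):
            raise ValidationError("pooling plan must cover every individual")
        pools = np.unique(pool_of)
        if not np.array_equal(pools, np.arange(len(pools))):
            raise ValidationError("pool indices must be 0..n_pools-1 with no gaps")
        if len(np.asarray(self.depth)) != len(pools):
            raise ValidationError("depth must have one entry per pool")
        if np.any(np.asarray(self.depth, dtype=float) < 1):
            raise ValidationError("pool read depth must be >= 1")
        for k in pools:
            ph = np.unique(phenotype[pool_of == k])
            if len(ph) != 1:
                raise ValidationError(f"pool {k} mixes case and control individuals")


def make_pooling_plan(
    phenotype: np.ndarray,
    pool_size: int = 50,
    depth: float = np.inf,
    seed: int = 0,
) -> PoolingPlan:
    """Group individuals into phenotype-homogeneous pools of ~pool_size."""
    phenotype = np.asarray(phenotype)
    pool_of = np.empty(len(phenotype), dtype=int)
    next_pool = 0
    depths = []
    for cls in (1, 0):
        idx = np.flatnonzero(phenotype == cls)
        if len(idx) == 0:
            continue
        n_pools = int(np.ceil(len(idx) / pool_size))
        for k in range(n_pools):
            members = idx[k * pool_size : (k + 1) * pool_size]
            pool_of[members] = next_pool
            depths.append(depth)
            next_pool += 1
    return PoolingPlan(pool_of=pool_of, depth=np.array(depths, dtype=float), seed=seed)


def pool_cohort(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    plan: PoolingPlan,
    variants: pd.DataFrame | None = None,
) -> PoolAFTable:
    """Collapse individual genotypes to per-pool allele frequencies.

    The true pool AF is (sum of dosages) / (2 x pool size); at finite
    depth the observed AF is (binomial reads at the true AF) / depth,
    emulating pooled sequencing.  Infinite depth returns exact AFs.
    """
    genotypes = np.asarray(genotypes)
    phenotype = np.asarray(phenotype)
    plan.validate(phenotype)
    pool_of = np.asarray(plan.pool_of)
    depth = np.asarray(plan.depth, dtype=float)
    n_pools = len(depth)
    rng = _rng(plan.seed, "pooling")

    sizes = np.array([int((pool_of == k).sum()) for k in range(n_pools)])
    pool_ph = np.array([int(phenotype[pool_of == k][0]) for k in range(n_pools)])
    true_af = np.empty((genotypes.shape[0], n_pools))
    for k in range(n_pools):
        g = genotypes[:, pool_of == k]
        true_af[:, k] = g.sum(axis=1) / (2.0 * sizes[k])

    af = true_af.copy()
    for k in range(n_pools):
        if np.isfinite(depth[k]):
            d = int(depth[k])
            af[:, k] = rng.binomial(d, true_af[:, k]) / d

    if variants is None:
        variants = _placeholder_variants(genotypes.shape[0])
    return PoolAFTable(
        variants=variants,
        af=af,
        pool_sizes=sizes,
        pool_phenotype=pool_ph,
        pool_depth=depth,
    )


def _placeholder_variants(n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * n,
            "pos": np.arange(1, n + 1),
            "id": ["."] * n,
            "ref": ["A"] * n,
            "alt": ["C"] * n,
            "gene": ["GENE001"] * n,
            "region": ["intronic"] * n,
        }
    )


@dataclass(frozen=True)
class AnnotationConfig:
    """Prevalences for synthetic functional-evidence annotations.

    ``score_probs`` is a category distribution over RegulomeDB-style
    ordered labels (integer class 1-7, optional letter subclass);
    defaults put 40% of variants at integer class <= 5.
    ``tf_dhs_prob`` is the chance a variant overlaps a transcription
    factor binding site or DNase hypersensitive site; ``ago_mean`` the
    Poisson mean of Argonaute CLIP-seq evidence counts.
    """

    score_probs: dict = field(
        default_factory=lambda: {
            "1b": 0.02,
            "2b": 0.05,
            "3a": 0.08,
            "4": 0.10,
            "5": 0.15,
            "6": 0.35,
            "7": 0.25,
        }
    )
    tf_dhs_prob: float = 0.6
    ago_mean: float = 0.3

    def validate(self) -> None:
        if any(p < 0 for p in self.score_probs.values()):
            raise ValidationError("score_probs values must be nonnegative")
        if abs(sum(self.score_probs.values()) - 1.0) > 1e-9:
            raise ValidationError("score_probs must sum to 1 (within 1e-9)")
        if not 0.0 <= self.tf_dhs_prob <= 1.0:
            raise ValidationError("tf_dhs_prob must lie in [0, 1]")
        if self.ago_mean < 0:
            raise ValidationError("ago_mean must be >= 0")


_CODING_EFFECT_OF_REGION = {
    "exonic-synonymous": "synonymous",
    "exonic-nonsynonymous": "nonsynonymous",
    "stopgain": "stopgain",
    "stoploss": "stoploss",
    "frameshift": "frameshift",
    "splicing": "splicing",
}


def simulate_annotations(
    variants: pd.DataFrame,
    config: AnnotationConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """One synthetic annotation record per variant.

    Regulome scores are drawn from the configured category distribution;
    coding effects follow the region class (the none-sentinel for
    non-exonic variants); Ago counts are Poisson.  Same seed, same table.
    """
    if config is None:
        config = AnnotationConfig()
    config.validate()
    rng = _rng(seed, "annotations")
    n = len(variants)
    cats = list(config.score_probs)
    probs = np.array([config.score_probs[c] for c in cats])
    scores = rng.choice(cats, size=n, p=probs / probs.sum())
    tf_dhs = rng.random(n) < config.tf_dhs_prob
    ago = rng.poisson(config.ago_mean, size=n)
    effects = [
        _CODING_EFFECT_OF_REGION.get(r, "none") for r in variants["region"]
    ]
    assert set(effects) <= set(CODING_EFFECTS)
    return pd.DataFrame(
        {
            "chrom": variants["chrom"].to_numpy(),
            "pos": variants["pos"].to_numpy(),
            "ref": variants["ref"].to_numpy(),
            "alt": variants["alt"].to_numpy(),
            "regulome_score": scores,
            "tf_or_dhs_overlap": tf_dhs,
            "ago_evidence_count": ago,
            "coding_effect": effects,
        }
    )
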