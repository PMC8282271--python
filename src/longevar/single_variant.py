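"""Single-variant association: allelic and genotypic Fisher exact tests,
group allele frequencies, enrichment direction and pairwise LD r-squared.

Allele frequencies are carried as alternate-allele frequencies (no
minor-allele folding); folding happens only where a weighting function
demands a MAF.  Missing genotypes are excluded variant-wise
(complete-case per variant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, CohortDataset, PoolAFTable, ValidationError

__all__ = [
    "maf_by_group",
    "reconstruct_counts",
    "allelic_fisher",
    "genotypic_fisher",
    "ld_r2",
    "single_variant_scan",
]


def maf_by_group(dataset: CohortDataset | PoolAFTable) -> pd.DataFrame:
    """Per-variant alternate-allele frequency in cases and controls.

    For genotypes, AF = allele count / (2 x non-missing individuals);
    for pools, the pool-size-weighted mean of pool AFs per phenotype
    group.  A group with no informative observations gets NaN.
    """
    if isinstance(dataset, PoolAFTable):
        out = {}
        for label, cls in (("maf_cases", 1), ("maf_controls", 0)):
            sel = dataset.pool_phenotype == cls
            if not sel.any():
                out[label] = np.full(dataset.n_variants, np.nan)
            else:
                w = dataset.pool_sizes[sel].astype(float)
                out[label] = dataset.af[:, sel] @ w / w.sum()
        return pd.DataFrame(out)
    g = np.asarray(dataset.genotypes, dtype=float)
    g = np.where(g == MISSING, np.nan, g)
    out = {}
    for label, cls in (("maf_cases", 1), ("maf_controls", 0)):
        sub = g[:, dataset.phenotype == cls]
        n_obs = np.sum(~np.isnan(sub), axis=1)
        with np.errstate(invalid="ignore"):
            out[label] = np.where(
                n_obs > 0, np.nansum(sub, axis=1) / (2.0 * n_obs), np.nan
            )
    return pd.DataFrame(out)


def reconstruct_counts(maf: float, n_individuals: int) -> int:
    """Minor-allele count implied by a printed allele frequency.

    Round-half-up of ``maf * 2n`` — the minimal-assumption bridge from a
    3-decimal published frequency back to an integer allele count.
    """
    if not 0.0 <= maf <= 1.0:
        raise ValidationError(f"maf must lie in [0, 1], got {maf}")
    if n_individuals < 1:
        raise ValidationError("n_individuals must be >= 1")
    return int(math.floor(maf * 2 * n_individuals + 0.5))


def allelic_fisher(table) -> float:
    """Two-sided Fisher exact p for a 2x2 allele-count table.

    Rows are groups (cases, controls), columns allele classes.  The
    two-sided p follows the point-probability rule: the sum of
    hypergeometric probabilities of all tables, at the observed margins,
    no more probable than the observed one.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValidationError("contingency counts must be nonnegative")
    if t.sum(axis=1).min() == 0:
        raise ValidationError("both group (row) margins must be positive")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def genotypic_fisher(table, max_tables: int = 2_000_000) -> float:
    """Exact conditional p for a 2x3 genotype-count table.

    Enumerates every 2x3 table with the observed margins and sums the
    multivariate hypergeometric probabilities of tables no more probable
    than the observed one (point-probability rule).  Exact only at desk
    scale: enumeration beyond ``max_tables`` states raises, suggesting
    the allelic test instead.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 3):
        raise ValidationError(f"expected a 2x3 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValidationError("contingency counts must be nonnegative")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if row.min() == 0:
        raise ValidationError("both group (row) margins must be positive")
    n_states = (min(row[0], col[0]) + 1) * (min(row[0], col[1]) + 1)
    if n_states > max_tables:
        raise ValidationError(
            f"margins too large for exact 2x3 enumeration ({n_states} tables > "
            f"cap {max_tables}); use the allelic test"
        )
    # log P(a0,a1,a2) = sum_j log C(col_j, a_j) - log C(N, row_0)
    from scipy.special import gammaln

    def log_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    logp_obs = sum(log_choose(col[j], t[0, j]) for j in range(3))
    total = 0.0
    hits = 0.0
    base = math.lgamma(row.sum() + 1) - math.lgamma(row[0] + 1) - math.lgamma(row[1] + 1)
    a0_lo = max(0, row[0] - col[1] - col[2])
    for a0 in range(a0_lo, min(row[0], col[0]) + 1):
        r = row[0] - a0
        a1_lo = max(0, r - col[2])
        for a1 in range(a1_lo, min(r, col[1]) + 1):
            a2 = r - a1
            lp = (
                log_choose(col[0], a0)
                + log_choose(col[1], a1)
                + log_choose(col[2], a2)
            )
            p = math.exp(lp - base)
            total += p
            if lp <= logp_obs + 1e-7:
                hits += p
    # total sums to 1 up to float error; normalize defensively
    return float(min(1.0, hits / total))


def ld_r2(g1, g2) -> float:
    """Squared Pearson correlation of genotype dosages (LD r-squared).

    Computed over pairwise-complete individuals; NaN when either variant
    is monomorphic among the overlap (undefined-sentinel).
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("genotype vectors must have equal length")
    keep = (a != MISSING) & (b != MISSING)
    a, b = a[keep], b[keep]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass(frozen=True)
class SingleVariantResult:
    key: tuple
    maf_cases: float
    maf_controls: float
    p_allelic: float
    p_genotypic: float | None
    direction: str


def _direction(mc: float, mk: float) -> str:
    if np.isnan(mc) or np.isnan(mk) or mc == mk:
        return "equal"
    return "case-enriched" if mc > mk else "control-enriched"


def single_variant_scan(
    dataset: CohortDataset | PoolAFTable,
    genotypic: bool = False,
) -> pd.DataFrame:
    """Allelic Fisher test of every variant; one row per variant.

    For pooled input the allele-count table is reconstructed from the
    group frequencies and group sizes via :func:`reconstruct_counts`.
    Per-variant failures (e.g. a fully missing group) are recorded as
    NaN p-values, not raised.
    """
    mafs = maf_by_group(dataset)
    if isinstance(dataset, PoolAFTable):
        n_cases = int(dataset.pool_sizes[dataset.pool_phenotype == 1].sum())
        n_controls = int(dataset.pool_sizes[dataset.pool_phenotype == 0].sum())
    else:
        n_cases = int((dataset.phenotype == 1).sum())
        n_controls = int((dataset.phenotype == 0).sum())

    p_all, p_gen, direction = [], [], []
    for j in range(dataset.n_variants):
        mc = float(mafs["maf_cases"][j])
        mk = float(mafs["maf_controls"][j])
        direction.append(_direction(mc, mk))
        if np.isnan(mc) or np.isnan(mk):
            p_all.append(np.nan)
            p_gen.append(np.nan)
            continue
        if isinstance(dataset, PoolAFTable):
            a = reconstruct_counts(mc, n_cases)
            c = reconstruct_counts(mk, n_controls)
            table = [[a, 2 * n_cases - a], [c, 2 * n_controls - c]]
        else:
            g = dataset.genotypes[j]
            table = _allele_table(g, dataset.phenotype)
        try:
            p_all.append(allelic_fisher(table))
        except ValidationError:
            p_all.append(np.nan)
        if genotypic and not isinstance(dataset, PoolAFTable):
            try:
                p_gen.append(genotypic_fisher(_genotype_table(dataset.genotypes[j], dataset.phenotype)))
            except ValidationError:
                p_gen.append(np.nan)
        else:
            p_gen.append(np.nan)

    out = dataset.variants.reset_index(drop=True).copy()
    out["maf_cases"] = mafs["maf_cases"]
    out["maf_controls"] = mafs["maf_controls"]
    out["p_allelic"] = p_all
    out["p_genotypic"] = p_gen
    out["direction"] = direction
    return out


def _allele_table(g: np.ndarray, phenotype: np.ndarray):
    rows = []
    for cls in (1, 0):
        sub = g[(phenotype == cls) & (g != MISSING)]
        alt = int(sub.sum())
        rows.append([alt, 2 * len(sub) - alt])
    return rows


def _genotype_table(g: np.ndarray, phenotype: np.ndarray):
    rows = []
    for cls in (1, 0):
        sub = g[(phenotype == cls) & (g != MISSING)]
        rows.append([int((sub == k).sum()) for k in (0, 1, 2)])
    return rows
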