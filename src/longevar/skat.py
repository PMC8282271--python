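"""Gene-based rare-variant association: the SKAT family of
variance-component score tests, built from the quadratic-form
construction, plus a pooled-allele-frequency adaptation for
pooled-sequencing designs.

Model
-----
For a binary phenotype y (1 = case) with an intercept-only logistic
null (no covariates), mu-hat is the case fraction and the per-variant
score is S_j = sum_i (y_i - mu) g_ij.  The SKAT statistic is

    Q = sum_j w_j^2 S_j^2,

with w_j the Beta(1, 25) density evaluated at the folded sample MAF of
variant j (Beta(0.5, 0.5) for the common-variant block of the combined
test).  Under the null, Q is distributed as a positive linear
combination of 1-df chi-squares whose coefficients are the eigenvalues
of the weighted, null-variance-projected genotype cross-product; the
tail probability comes from characteristic-function inversion with a
moment-matching fallback.

The burden statistic is the squared weighted sum of scores (the rho=1
limit); SKAT-O scans a rho grid of convex combinations and combines the
per-rho minimum p through the standard one-dimensional mixing integral.
The pooled adaptation substitutes each pool's allele frequency for the
allele counts of the individuals it contains (dosage 2 x pool AF per
member, individual-level sample size retained) and is flagged as
anti-conservative: the within-pool genotype variance disappears from
the null spectrum while the group-contrast scores are preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .core import MISSING, CohortDataset, PoolAFTable, ValidationError

__all__ = [
    "SkatConfig",
    "NullModel",
    "GeneTestResult",
    "fit_null",
    "davies_pvalue",
    "skat",
    "burden",
    "skat_o",
    "skat_c",
    "pooled_skat",
    "gene_scan",
]

DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)


@dataclass(frozen=True)
class SkatConfig:
    """Tuning parameters of the SKAT family.

    ``weight_beta_rare``/``weight_beta_common`` are the Beta-density
    shape pairs evaluated at the folded sample MAF; the defaults
    (1, 25) and (0.5, 0.5) are the canonical choices that up-weight
    rare variants strongly and common variants mildly.
    ``rare_common_threshold`` (default 0.05) is the MAF cutoff defining
    "rare" throughout the pipeline.
    """

    weight_beta_rare: tuple[float, float] = (1.0, 25.0)
    weight_beta_common: tuple[float, float] = (0.5, 0.5)
    rare_common_threshold: float = 0.05
    rho_grid: tuple[float, ...] = DEFAULT_RHO_GRID

    def validate(self) -> None:
        for name in ("weight_beta_rare", "weight_beta_common"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValidationError(f"{name} shapes must be > 0")
        if not 0.0 < self.rare_common_threshold <= 0.5:
            raise ValidationError("rare_common_threshold must lie in (0, 0.5]")
        grid = tuple(self.rho_grid)
        if any(r < 0 or r > 1 for r in grid):
            raise ValidationError("rho_grid values must lie in [0, 1]")


@dataclass
class NullModel:
    """Intercept-only logistic null: mu-hat is the case fraction."""

    phenotype: np.ndarray
    mu: float
    residuals: np.ndarray
    variance: float  # mu (1 - mu)

    @property
    def n(self) -> int:
        return len(self.phenotype)


def fit_null(phenotype) -> NullModel:
    y = np.asarray(phenotype, dtype=float)
    classes = set(np.unique(y))
    if not classes <= {0.0, 1.0} or len(classes) != 2:
        raise ValidationError("phenotype must contain both cases and controls")
    mu = float(y.mean())
    return NullModel(
        phenotype=y, mu=mu, residuals=y - mu, variance=mu * (1.0 - mu)
    )


@dataclass
class GeneTestResult:
    gene: str
    method: str
    statistic: float
    pvalue: float
    n_variants: int
    eigenvalues: np.ndarray = field(repr=False, default=None)
    stratum: str = "all"
    pvalue_method: str = "davies"
    rho: float | None = None
    rho_grid: tuple[float, ...] | None = None
    warning: str | None = None


# ---------------------------------------------------------------------------
# Tail probability of a positive linear combination of chi-squares

def _imhof_tail(q: float, lam: np.ndarray) -> float:
    """P(sum lam_k chi2_1 >= q) by characteristic-function inversion.

    The inversion integrand oscillates with asymptotic frequency q/2 and
    decays like u^{-(p/2+1)}; the truncation point is chosen so the
    cancellation-corrected tail bound (envelope / frequency) is
    negligible, and the quadrature's own error estimate gates the
    fallback.  The tail is scale-invariant in (q, lam), so the spectrum
    is normalized by its largest eigenvalue first to keep the
    integrand's support at O(1).
    """
    scale = lam.max()
    lam = lam / scale
    q = q / scale

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        log_rho = 0.25 * np.sum(np.log1p((lam * u) ** 2))
        return float(np.sin(theta) / u * np.exp(-log_rho))

    def envelope(u):
        return np.exp(-0.25 * np.sum(np.log1p((lam * u) ** 2))) / u

    freq = max(q, lam.sum()) / 2.0
    upper = 10.0
    while envelope(upper) / (freq * np.pi) > 1e-9 and upper < 1e6:
        upper *= 1.4
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, abserr = integrate.quad(
            integrand, 0.0, upper, limit=3000, epsabs=1e-9, epsrel=1e-9
        )
    if abserr > 1e-6:
        raise ArithmeticError("characteristic-function inversion did not converge")
    return 0.5 + val / np.pi


def _liu_params(lam: np.ndarray):
    c1 = lam.sum()
    c2 = (lam**2).sum()
    c3 = (lam**3).sum()
    c4 = (lam**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2.0 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
    return c1, c2, df, delta


def _liu_tail(q: float, lam: np.ndarray) -> float:
    """Moment-matching approximation: map Q onto a (noncentral)
    chi-square matching mean, variance and skewness."""
    c1, c2, df, delta = _liu_params(lam)
    t = (q - c1) / np.sqrt(2.0 * c2)
    x = t * np.sqrt(2.0 * (df + 2.0 * delta)) + df + delta
    return float(stats.ncx2.sf(x, df, delta))


def _liu_quantile(prob_tail: float, lam: np.ndarray) -> float:
    """Quantile q with P(Q >= q) = prob_tail under moment matching."""
    c1, c2, df, delta = _liu_params(lam)
    x = stats.ncx2.isf(prob_tail, df, delta)
    t = (x - df - delta) / np.sqrt(2.0 * (df + 2.0 * delta))
    return float(t * np.sqrt(2.0 * c2) + c1)


def quadform_pvalue(q: float, eigenvalues) -> tuple[float, str]:
    """Tail probability and the method that produced it."""
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValidationError("at least one eigenvalue must be > 0")
    if q <= 0:
        return 1.0, "davies"
    if lam.size == 1:
        # exact single-eigenvalue limit
        return float(stats.chi2.sf(q / lam[0], df=1)), "davies"
    try:
        p = _imhof_tail(q, lam)
        if 0.0 < p <= 1.0:
            return float(min(p, 1.0)), "davies"
    except Exception:
        pass
    p = _liu_tail(q, lam)
    return float(min(max(p, np.finfo(float).tiny), 1.0)), "liu"


def davies_pvalue(q: float, eigenvalues) -> float:
    """P(sum lam_k chi2_1 >= q); falls back to moment matching when the
    inversion integral misbehaves."""
    return quadform_pvalue(q, eigenvalues)[0]


# ---------------------------------------------------------------------------
# Genotype preparation

def _prepare(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Impute missing dosages to the variant mean; return (G, sample AF)."""
    G = np.asarray(G, dtype=float).copy()
    af = np.empty(G.shape[0])
    for j in range(G.shape[0]):
        row = G[j]
        obs = row != MISSING
        mean = row[obs].mean() if obs.any() else 0.0
        row[~obs] = mean
        af[j] = mean / 2.0
    return G, af


def _beta_weights(af: np.ndarray, shape: tuple[float, float]) -> np.ndarray:
    maf = np.minimum(af, 1.0 - af)
    return stats.beta.pdf(maf, shape[0], shape[1])


def _score_and_kernel(G, null, weights):
    """Weighted scores U = w*S and their null covariance Z'Z.

    Z = sqrt(v) * centered(G^T) * diag(w): Cov(U) = v W Gc Gc^T W = Z^T Z.
    """
    X = G.T  # individuals x variants
    Xc = X - X.mean(axis=0, keepdims=True)
    Z = np.sqrt(null.variance) * Xc * weights[None, :]
    U = weights * (G @ null.residuals)
    return U, Z


def _truncate(lam: np.ndarray) -> np.ndarray:
    lam = lam[lam > 0]
    if lam.size == 0:
        return lam
    return lam[lam > 1e-10 * lam.max()]


def skat(
    G,
    null: NullModel,
    cfg: SkatConfig | None = None,
    gene: str = "",
    weights: np.ndarray | None = None,
    method: str = "SKAT",
) -> GeneTestResult:
    """SKAT variance-component test of one gene's variants.

    ``G`` is variants x individuals.  An all-monomorphic gene carries no
    information and returns p = 1 with a warning flag.
    """
    cfg = cfg or SkatConfig()
    cfg.validate()
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] < 1:
        raise ValidationError("G must be a variants x individuals matrix")
    if G.shape[1] != null.n:
        raise ValidationError("G columns must match the null-model sample size")
    G, af = _prepare(G)
    if weights is None:
        weights = _beta_weights(af, cfg.weight_beta_rare)
    U, Z = _score_and_kernel(G, null, weights)
    Q = float(U @ U)
    lam = _truncate(np.linalg.eigvalsh(Z.T @ Z))
    if lam.size == 0:
        return GeneTestResult(
            gene=gene, method=method, statistic=Q, pvalue=1.0,
            n_variants=G.shape[0], eigenvalues=lam,
            warning="no polymorphic variants",
        )
    p, how = quadform_pvalue(Q, lam)
    return GeneTestResult(
        gene=gene, method=method, statistic=Q, pvalue=p,
        n_variants=G.shape[0], eigenvalues=lam, pvalue_method=how,
    )


def burden(
    G,
    null: NullModel,
    cfg: SkatConfig | None = None,
    gene: str = "",
    weights: np.ndarray | None = None,
) -> GeneTestResult:
    """Weighted burden score test: Q_b = (sum_j w_j S_j)^2 against a
    single-eigenvalue chi-square (the rho = 1 limit of SKAT-O)."""
    cfg = cfg or SkatConfig()
    G = np.asarray(G, dtype=float)
    G, af = _prepare(G)
    if weights is None:
        weights = _beta_weights(af, cfg.weight_beta_rare)
    U, Z = _score_and_kernel(G, null, weights)
    Qb = float(U.sum() ** 2)
    zsum = Z.sum(axis=1)
    var = float(zsum @ zsum)
    if var <= 0:
        return GeneTestResult(
            gene=gene, method="burden", statistic=Qb, pvalue=1.0,
            n_variants=G.shape[0], eigenvalues=np.array([]),
            warning="no polymorphic variants",
        )
    p = float(stats.chi2.sf(Qb / var, df=1))
    return GeneTestResult(
        gene=gene, method="burden", statistic=Qb, pvalue=max(p, np.finfo(float).tiny),
        n_variants=G.shape[0], eigenvalues=np.array([var]),
    )


# ---------------------------------------------------------------------------
# SKAT-O

def _rho_kernel_eigs(Z: np.ndarray, rho: float) -> np.ndarray:
    """Eigenvalues of R_rho^{1/2} (Z'Z) R_rho^{1/2} with
    R_rho = (1-rho) I + rho 11'."""
    p = Z.shape[1]
    J = np.full((p, p), 1.0 / p)
    R_half = np.sqrt(1.0 - rho) * (np.eye(p) - J) + np.sqrt(1.0 - rho + p * rho) * J
    K = R_half @ (Z.T @ Z) @ R_half
    return _truncate(np.linalg.eigvalsh(K))


def skat_o(
    G,
    null: NullModel,
    cfg: SkatConfig | None = None,
    gene: str = "",
) -> GeneTestResult:
    """Optimal-rho combination of SKAT and burden statistics.

    Q_rho = (1-rho) Q_SKAT + rho Q_burden over the configured grid; the
    combined p accounts for the grid search through the one-dimensional
    mixing integral over the shared burden-direction chi-square.
    """
    cfg = cfg or SkatConfig()
    cfg.validate()
    G = np.asarray(G, dtype=float)
    if G.shape[1] != null.n:
        raise ValidationError("G columns must match the null-model sample size")
    G, af = _prepare(G)
    weights = _beta_weights(af, cfg.weight_beta_rare)
    U, Z = _score_and_kernel(G, null, weights)
    if _truncate(np.linalg.eigvalsh(Z.T @ Z)).size == 0:
        return GeneTestResult(
            gene=gene, method="SKAT-O", statistic=0.0, pvalue=1.0,
            n_variants=G.shape[0], eigenvalues=np.array([]),
            warning="no polymorphic variants",
        )
    grid = tuple(cfg.rho_grid)
    Q_skat = float(U @ U)
    Q_burd = float(U.sum() ** 2)

    p_rho, q_rho = [], []
    zsum = Z.sum(axis=1)
    burden_var = float(zsum @ zsum)
    for rho in grid:
        q = (1.0 - rho) * Q_skat + rho * Q_burd
        if rho == 1.0:
            # exact 1-df limit: R_1 is rank one with eigenvalue 1'Z'Z1
            p_rho.append(float(stats.chi2.sf(q / burden_var, df=1)))
        else:
            lam = _rho_kernel_eigs(Z, rho)
            p_rho.append(quadform_pvalue(q, lam)[0])
        q_rho.append(q)
    i_min = int(np.argmin(p_rho))
    T = p_rho[i_min]

    if len(grid) == 1:
        res = GeneTestResult(
            gene=gene, method="SKAT-O", statistic=q_rho[0], pvalue=T,
            n_variants=G.shape[0], eigenvalues=_rho_kernel_eigs(Z, min(grid[0], 0.999)),
            rho=grid[0], rho_grid=grid,
        )
        return res

    p_comb = _skat_o_combined_p(Z, grid, T)
    # the grid search cannot make the combined p smaller than the best
    # per-rho p nor larger than its Bonferroni bound
    p_comb = float(np.clip(p_comb, T, min(1.0, T * len(grid))))
    return GeneTestResult(
        gene=gene, method="SKAT-O", statistic=q_rho[i_min], pvalue=p_comb,
        n_variants=G.shape[0], eigenvalues=_rho_kernel_eigs(Z, min(grid[i_min], 0.999)),
        rho=grid[i_min], rho_grid=grid,
    )


def _skat_o_combined_p(Z: np.ndarray, grid, T: float) -> float:
    """Mixing-integral null of the minimum-p statistic.

    Decomposes each Q_rho into the burden-direction 1-df chi-square eta
    plus an independent remainder, then integrates the probability that
    every per-rho quantile condition holds over the density of eta.
    """
    n, p = Z.shape
    zbar = Z.mean(axis=1)
    zbar2 = float(zbar @ zbar)
    if zbar2 <= 0:
        return T
    M = np.outer(zbar, zbar) / zbar2
    Z2 = Z - M @ Z
    lam = _truncate(np.linalg.eigvalsh(Z2.T @ Z2))
    if lam.size == 0:
        return T
    mu_q = lam.sum()
    # cross-term variance between the projected and remainder parts
    A1 = (M @ Z).T @ (M @ Z)
    A2 = Z2.T @ Z2
    var_zeta = 4.0 * float(np.sum(A1 * A2))
    var_q = 2.0 * float(np.sum(lam**2)) + var_zeta
    df_q = 12.0 / (12.0 * float(np.sum(lam**4)) / float(np.sum(lam**2)) ** 2)

    grid_c = [min(r, 0.999) for r in grid]
    tau = np.array(
        [
            p**2 * r * zbar2 + (1.0 - r) * float(np.sum((zbar @ Z) ** 2)) / zbar2
            for r in grid_c
        ]
    )
    qmin = np.array(
        [_liu_quantile(T, _rho_kernel_eigs(Z, r)) for r in grid_c]
    )

    rho_arr = np.array(grid_c)

    def integrand(x):
        tmin = float(np.min((qmin - tau * x) / (1.0 - rho_arr)))
        # standardize the remainder through its matched chi-square
        z = (tmin - mu_q) / np.sqrt(var_q) * np.sqrt(2.0 * df_q) + df_q
        cdf = stats.chi2.cdf(z, df_q) if z > 0 else 0.0
        return float(cdf * stats.chi2.pdf(x, 1))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, 0.0, 40.0, limit=200)
    return 1.0 - val


# ---------------------------------------------------------------------------
# SKAT-C (combined rare + common)

def skat_c(
    G,
    null: NullModel,
    cfg: SkatConfig | None = None,
    gene: str = "",
) -> GeneTestResult:
    """Combined common-and-rare test: variants below the MAF threshold
    take the rare Beta weights, the rest the common ones; Q is the sum
    of the two weighted components (one concatenated kernel) and the
    null spectrum is that of the combined weighted cross-product."""
    cfg = cfg or SkatConfig()
    cfg.validate()
    G = np.asarray(G, dtype=float)
    Gp, af = _prepare(G)
    maf = np.minimum(af, 1.0 - af)
    rare = maf < cfg.rare_common_threshold
    weights = np.where(
        rare,
        _beta_weights(af, cfg.weight_beta_rare),
        _beta_weights(af, cfg.weight_beta_common),
    )
    res = skat(G, null, cfg, gene=gene, weights=weights, method="SKAT-C")
    return res


# ---------------------------------------------------------------------------
# Pooled adaptation

def pooled_skat(
    pool_table: PoolAFTable,
    cfg: SkatConfig | None = None,
    gene: str = "",
    variant_mask: np.ndarray | None = None,
) -> GeneTestResult:
    """SKAT on pool allele frequencies instead of individual genotypes.

    The pool allele frequency is substituted for the allele count of
    every individual the pool contains: individual i in pool k enters
    with dosage 2 x AF_k per variant, the phenotype stays at the
    individual level, and Beta weights come from the across-pool
    size-weighted MAF (which equals the sample MAF of the substituted
    matrix).  With unit pools and exact frequencies this is exactly the
    individual-level test.  With larger pools the per-variant scores
    are preserved (pools are phenotype-homogeneous) but the within-pool
    genotype variance vanishes from the null eigenvalue spectrum, so
    the p-value is systematically underestimated — the documented cost
    of losing individual genotype information, flagged on the result.
    """
    cfg = cfg or SkatConfig()
    cfg.validate()
    if len(np.unique(pool_table.pool_phenotype)) < 2:
        raise ValidationError("pooled test needs both case and control pools")
    if pool_table.n_pools < 2:
        raise ValidationError("pooled test needs at least two pools")
    af = pool_table.af if variant_mask is None else pool_table.af[variant_mask]
    sizes = pool_table.pool_sizes
    # variants x individuals matrix: every member carries the pool dosage
    X = np.repeat(2.0 * af, sizes, axis=1)
    y = np.repeat(pool_table.pool_phenotype, sizes)
    null = fit_null(y)
    w_sizes = sizes.astype(float)
    pooled_af = af @ w_sizes / w_sizes.sum()
    weights = _beta_weights(pooled_af, cfg.weight_beta_rare)
    res = skat(X, null, cfg, gene=gene, weights=weights, method="pooled-SKAT")
    res.warning = (res.warning + "; " if res.warning else "") + (
        "pool AFs substituted for individual genotypes: p-value may be anti-conservative"
    )
    return res


# ---------------------------------------------------------------------------
# Scanning

_METHOD_FN = {"SKAT": skat, "SKAT-O": skat_o, "SKAT-C": skat_c, "burden": burden}


def gene_scan(
    dataset: CohortDataset,
    cfg: SkatConfig | None = None,
    strata: dict[str, set] | None = None,
    methods: tuple[str, ...] = ("SKAT",),
) -> pd.DataFrame:
    """One test per (gene, stratum, method).

    ``strata`` maps stratum name -> set of variant keys
    (chrom, pos, ref, alt); absent means the single stratum ``all``.
    Strata with no variants in a gene yield an absent-marker row with a
    NaN p-value.  Per-gene failures are recorded, not fatal.
    """
    from .core import variant_keys

    cfg = cfg or SkatConfig()
    null = fit_null(dataset.phenotype)
    keys = np.array(variant_keys(dataset.variants), dtype=object)
    genes = dataset.variants["gene"].to_numpy()
    if strata is None:
        strata = {"all": set(map(tuple, keys))}
    rows = []
    for gname in pd.unique(genes):
        gmask = genes == gname
        for stratum, keyset in strata.items():
            smask = gmask & np.array(
                [tuple(k) in keyset for k in keys], dtype=bool
            )
            for method in methods:
                if not smask.any():
                    rows.append(
                        {
                            "gene": gname, "stratum": stratum, "method": method,
                            "statistic": np.nan, "p": np.nan, "n_variants": 0,
                            "note": "absent",
                        }
                    )
                    continue
                try:
                    res = _METHOD_FN[method](dataset.genotypes[smask], null, cfg, gene=gname)
                    rows.append(
                        {
                            "gene": gname, "stratum": stratum, "method": method,
                            "statistic": res.statistic, "p": res.pvalue,
                            "n_variants": res.n_variants,
                            "note": res.warning or "",
                        }
                    )
                except Exception as exc:  # recorded, not fatal
                    rows.append(
                        {
                            "gene": gname, "stratum": stratum, "method": method,
                            "statistic": np.nan, "p": np.nan,
                            "n_variants": int(smask.sum()), "note": f"error: {exc}",
                        }
                    )
    return pd.DataFrame(rows)
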