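"""SKAT family: null model, quadratic-form tail, reductions and the
pooled adaptation."""

import numpy as np
import pytest
from scipy import stats

import longevar as lv
from longevar.core import ValidationError
from longevar.skat import _beta_weights, _liu_tail, _prepare, quadform_pvalue
from conftest import rare_heavy_genotypes


# ------------------------------------------------------------ fit_null

def test_null_mu_is_case_fraction():
    y = np.array([1] * 50 + [0] * 50)
    assert lv.fit_null(y).mu == 0.5
    y2 = np.array([1] * 450 + [0] * 500)
    null = lv.fit_null(y2)
    assert null.mu == pytest.approx(450 / 950)
    assert null.residuals.sum() == pytest.approx(0.0, abs=1e-9)


def test_single_class_phenotype_rejected():
    with pytest.raises(ValidationError):
        lv.fit_null(np.ones(10))


# ------------------------------------------------------ davies_pvalue

def test_chi_square_closed_forms():
    assert lv.davies_pvalue(stats.chi2.isf(0.05, 1), [1.0]) == pytest.approx(0.05, abs=1e-4)
    assert lv.davies_pvalue(stats.chi2.isf(0.05, 2), [1.0, 1.0]) == pytest.approx(0.05, abs=1e-4)


def test_scaled_chi_square_exact():
    # sum of c * chi2_1 = c * chi2_1
    q = 2.5 * stats.chi2.isf(0.01, 1)
    assert lv.davies_pvalue(q, [2.5]) == pytest.approx(0.01, abs=1e-5)


def test_random_spectra_match_monte_carlo():
    rng = np.random.default_rng(31)
    for _ in range(5):
        lam = rng.uniform(0.2, 3.0, size=rng.integers(2, 8))
        q = 2.0 * lam.sum()  # a fixed point in the upper tail
        draws = (lam[:, None] * rng.chisquare(1, size=(len(lam), 1_000_000))).sum(axis=0)
        mc = (draws >= q).mean()
        se = np.sqrt(mc * (1 - mc) / len(draws))
        assert lv.davies_pvalue(q, lam) == pytest.approx(mc, abs=3 * se)


def test_fallback_agrees_for_well_conditioned_spectra():
    rng = np.random.default_rng(11)
    for _ in range(10):
        lam = rng.uniform(0.5, 2.0, size=6)  # condition number < 100
        q = lam.sum() * 2.0
        davies = lv.davies_pvalue(q, lam)
        liu = _liu_tail(q, lam)
        assert liu == pytest.approx(davies, rel=0.10)


def test_all_zero_eigenvalues_rejected():
    with pytest.raises(ValidationError):
        lv.davies_pvalue(1.0, [0.0, 0.0])


# ---------------------------------------------------------------- skat

def test_monomorphic_gene_p_one(null_model):
    res = lv.skat(np.zeros((3, null_model.n)), null_model)
    assert res.pvalue == 1.0
    assert res.warning


def test_single_variant_gene_equals_score_test():
    # one variant: Q/lambda ~ chi2_1, the classic 1-df score test
    rng = np.random.default_rng(23)
    g = rng.binomial(2, 0.2, size=300).astype(float)
    y = np.array([1] * 150 + [0] * 150)
    null = lv.fit_null(y)
    res = lv.skat(g[None, :], null)
    s = (y - null.mu) @ g
    var = null.variance * ((g - g.mean()) ** 2).sum()
    p_score = stats.chi2.sf(s**2 / var, df=1)
    assert res.pvalue == pytest.approx(p_score, abs=1e-6)


def test_skat_close_to_permutation_oracle():
    # the asymptotic p approximates the exact permutation distribution
    rng = np.random.default_rng(41)
    G = rare_heavy_genotypes(rng, n_variants=10, n=200)
    y = np.array([1] * 100 + [0] * 100)
    null = lv.fit_null(y)
    res = lv.skat(G, null)
    Gp, af = _prepare(G)
    w = _beta_weights(af, (1.0, 25.0))
    n_perm = 50_000
    P = np.array([rng.permutation(y) for _ in range(n_perm)]) - y.mean()
    Q = ((Gp @ P.T) * w[:, None]) ** 2
    p_perm = (Q.sum(axis=0) >= res.statistic - 1e-12).mean()
    # agreement is asymptotic: allow the normal-approximation gap on top
    # of Monte-Carlo error
    assert res.pvalue == pytest.approx(p_perm, abs=0.05)


def test_q_invariant_to_variant_order_and_allele_flip():
    rng = np.random.default_rng(8)
    G = rare_heavy_genotypes(rng, n_variants=6, n=120)
    y = np.array([1] * 60 + [0] * 60)
    null = lv.fit_null(y)
    base = lv.skat(G, null)
    perm = rng.permutation(6)
    shuffled = lv.skat(G[perm], null)
    assert shuffled.statistic == pytest.approx(base.statistic, rel=1e-12)
    assert shuffled.pvalue == pytest.approx(base.pvalue, rel=1e-9)
    flipped = G.copy()
    flipped[2] = 2 - flipped[2]  # weights recomputed from folded MAF
    assert lv.skat(flipped, null).statistic == pytest.approx(base.statistic, rel=1e-12)


def test_doubling_sample_size_decreases_median_p():
    pairs = [(0.01, 0.03), (0.02, 0.05)]
    med = {}
    for n in (200, 400):
        ps = []
        for rep in range(100):
            effects = tuple(
                lv.Effect("GENE001", j, mc, mk) for j, (mk, mc) in enumerate(pairs)
            )
            cfg = lv.SimulationConfig(
                n_cases=n, n_controls=n, n_genes=1, variants_per_gene=10,
                effect_model=effects, seed=rep,
            )
            ds, _ = lv.simulate_cohort(cfg)
            ps.append(lv.skat(ds.genotypes, lv.fit_null(ds.phenotype)).pvalue)
        med[n] = np.median(ps)
    assert med[400] < med[200]


# -------------------------------------------------------------- skat_o

def test_skat_o_rho_zero_is_skat(null_model, small_cohort):
    dataset, _ = small_cohort
    G = dataset.genotypes[:5].astype(float)
    a = lv.skat(G, null_model)
    b = lv.skat_o(G, null_model, lv.SkatConfig(rho_grid=(0.0,)))
    assert b.pvalue == pytest.approx(a.pvalue, abs=1e-10)


def test_skat_o_rho_one_is_burden(null_model, small_cohort):
    dataset, _ = small_cohort
    G = dataset.genotypes[:5].astype(float)
    a = lv.burden(G, null_model)
    b = lv.skat_o(G, null_model, lv.SkatConfig(rho_grid=(1.0,)))
    assert b.pvalue == pytest.approx(a.pvalue, abs=1e-8)


def test_skat_o_bonferroni_sandwich():
    rng = np.random.default_rng(19)
    y = np.array([1] * 100 + [0] * 100)
    null = lv.fit_null(y)
    cfg = lv.SkatConfig()
    for _ in range(10):
        G = rare_heavy_genotypes(rng, n_variants=12, n=200)
        res = lv.skat_o(G, null, cfg)
        per_rho = []
        for rho in cfg.rho_grid:
            per_rho.append(lv.skat_o(G, null, lv.SkatConfig(rho_grid=(rho,))).pvalue)
        t = min(per_rho)
        assert res.pvalue >= t - 1e-12
        assert res.pvalue <= len(cfg.rho_grid) * t + 1e-12


def test_burden_matches_analytic_oracle():
    rng = np.random.default_rng(2)
    G = rare_heavy_genotypes(rng, n_variants=8, n=150)
    y = np.array([1] * 75 + [0] * 75)
    null = lv.fit_null(y)
    res = lv.burden(G, null)
    Gp, af = _prepare(G)
    w = _beta_weights(af, (1.0, 25.0))
    b = w @ (Gp @ null.residuals)
    gc = Gp - Gp.mean(axis=1, keepdims=True)
    var = null.variance * w @ (gc @ gc.T) @ w
    assert res.pvalue == pytest.approx(stats.chi2.sf(b**2 / var, 1), rel=1e-10)


# -------------------------------------------------------------- skat_c

def test_skat_c_all_rare_reduces_to_rare_weights(null_model):
    rng = np.random.default_rng(4)
    maf = rng.uniform(0.002, 0.02, 6)
    G = rng.binomial(2, maf[:, None], size=(6, null_model.n)).astype(float)
    _, af = _prepare(G)
    assert (np.minimum(af, 1 - af) < 0.05).all()  # all rare in-sample
    a = lv.skat(G, null_model)
    b = lv.skat_c(G, null_model)
    assert b.pvalue == pytest.approx(a.pvalue, abs=1e-10)


def test_skat_c_all_common_reduces_to_common_weights(null_model):
    rng = np.random.default_rng(6)
    maf = rng.uniform(0.2, 0.45, 6)
    G = rng.binomial(2, maf[:, None], size=(6, null_model.n)).astype(float)
    cfg = lv.SkatConfig()
    _, af = _prepare(G)
    w_common = _beta_weights(af, cfg.weight_beta_common)
    a = lv.skat(G, null_model, cfg, weights=w_common)
    b = lv.skat_c(G, null_model, cfg)
    assert b.pvalue == pytest.approx(a.pvalue, abs=1e-10)


def test_skat_c_mixed_close_to_permutation_oracle():
    rng = np.random.default_rng(44)
    maf = np.concatenate([rng.uniform(0.005, 0.04, 5), rng.uniform(0.1, 0.4, 5)])
    G = rng.binomial(2, maf[:, None], size=(10, 200)).astype(float)
    y = np.array([1] * 100 + [0] * 100)
    null = lv.fit_null(y)
    res = lv.skat_c(G, null)
    cfg = lv.SkatConfig()
    Gp, af = _prepare(G)
    m = np.minimum(af, 1 - af)
    w = np.where(
        m < cfg.rare_common_threshold,
        _beta_weights(af, cfg.weight_beta_rare),
        _beta_weights(af, cfg.weight_beta_common),
    )
    P = np.array([rng.permutation(y) for _ in range(50_000)]) - y.mean()
    Q = (((Gp @ P.T) * w[:, None]) ** 2).sum(axis=0)
    p_perm = (Q >= res.statistic - 1e-12).mean()
    assert res.pvalue == pytest.approx(p_perm, abs=0.05)


# --------------------------------------------------------- pooled_skat

def test_unit_pools_exact_af_reproduce_individual_skat(small_cohort):
    dataset, _ = small_cohort
    null = lv.fit_null(dataset.phenotype)
    plan = lv.make_pooling_plan(dataset.phenotype, pool_size=1)
    table = lv.pool_cohort(dataset.genotypes, dataset.phenotype, plan, dataset.variants)
    a = lv.pooled_skat(table)
    b = lv.skat(dataset.genotypes.astype(float), null)
    assert a.pvalue == pytest.approx(b.pvalue, abs=1e-10)
    assert a.method == "pooled-SKAT"
    assert "anti-conservative" in a.warning


def test_identical_pool_afs_give_no_signal():
    import pandas as pd

    variants = pd.DataFrame(
        {
            "chrom": ["chr1"] * 3, "pos": [1, 2, 3], "id": ["."] * 3,
            "ref": ["A"] * 3, "alt": ["C"] * 3, "gene": ["G1"] * 3,
            "region": ["intronic"] * 3,
        }
    )
    table = lv.PoolAFTable(
        variants=variants,
        af=np.tile([[0.1], [0.2], [0.05]], (1, 4)),
        pool_sizes=np.array([10, 10, 10, 10]),
        pool_phenotype=np.array([1, 1, 0, 0]),
    )
    res = lv.pooled_skat(table)
    assert res.pvalue >= 0.5


def test_single_phenotype_pools_rejected():
    import pandas as pd

    variants = pd.DataFrame(
        {
            "chrom": ["chr1"], "pos": [1], "id": ["."], "ref": ["A"],
            "alt": ["C"], "gene": ["G1"], "region": ["intronic"],
        }
    )
    table = lv.PoolAFTable(
        variants=variants, af=np.array([[0.1, 0.2]]),
        pool_sizes=np.array([5, 5]), pool_phenotype=np.array([1, 1]),
    )
    with pytest.raises(ValidationError):
        lv.pooled_skat(table)


# ------------------------------------------------------------ gene_scan

def test_gene_scan_stratum_all_matches_direct_skat(small_cohort):
    dataset, _ = small_cohort
    null = lv.fit_null(dataset.phenotype)
    res = lv.gene_scan(dataset, methods=("SKAT",))
    g1 = dataset.variants["gene"] == "GENE001"
    direct = lv.skat(dataset.genotypes[g1.to_numpy()].astype(float), null)
    row = res[(res["gene"] == "GENE001")].iloc[0]
    assert row["p"] == pytest.approx(direct.pvalue, rel=1e-9)


def test_gene_scan_empty_stratum_marked_absent(small_cohort):
    dataset, _ = small_cohort
    strata = {"all": set(), "coding": set()}
    from longevar.core import variant_keys

    strata["all"] = set(variant_keys(dataset.variants))
    res = lv.gene_scan(dataset, strata=strata, methods=("SKAT",))
    absent = res[res["stratum"] == "coding"]
    assert (absent["note"] == "absent").all()
    assert absent["p"].isna().all()
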