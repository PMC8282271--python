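"""Fisher exact tests, group MAFs, LD r-squared, and the variant scan."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb

import longevar as lv
from longevar.core import MISSING, ValidationError
from longevar.single_variant import _allele_table


# ------------------------------------------------------------ oracles

def fisher_2x2_oracle(table):
    """Exhaustive hypergeometric enumeration with the point-probability rule."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d

    def prob(k):
        return (
            comb(c1, k, exact=True)
            * comb(n - c1, r1 - k, exact=True)
            / comb(n, r1, exact=True)
        )

    p_obs = prob(a)
    return sum(
        prob(k)
        for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
        if prob(k) <= p_obs * (1 + 1e-12)
    )


def fisher_2x3_oracle(table):
    """Brute-force enumeration over all 2x3 tables with fixed margins."""
    t = np.asarray(table)
    row, col = t.sum(axis=1), t.sum(axis=0)

    def prob(a):
        return math.prod(
            comb(col[j], a[j], exact=True) for j in range(3)
        ) / comb(row.sum(), row[0], exact=True)

    p_obs = prob(t[0])
    total = 0.0
    for a0 in range(col[0] + 1):
        for a1 in range(col[1] + 1):
            a2 = row[0] - a0 - a1
            if 0 <= a2 <= col[2]:
                p = prob((a0, a1, a2))
                if p <= p_obs * (1 + 1e-9):
                    total += p
    return total


# ------------------------------------------------------- maf_by_group

def test_maf_from_genotypes_simple():
    ds = lv.CohortDataset(
        variants=_vt(1),
        genotypes=np.array([[0, 1, 2, 0, 0, 0]], dtype=np.int8),
        phenotype=np.array([1, 1, 1, 0, 0, 0]),
    )
    mafs = lv.maf_by_group(ds)
    assert mafs["maf_cases"][0] == 0.5
    assert mafs["maf_controls"][0] == 0.0


def test_maf_from_pools_is_size_weighted():
    table = lv.PoolAFTable(
        variants=_vt(1),
        af=np.array([[0.1, 0.3, 0.2]]),
        pool_sizes=np.array([10, 10, 20]),
        pool_phenotype=np.array([1, 1, 0]),
    )
    mafs = lv.maf_by_group(table)
    assert mafs["maf_cases"][0] == pytest.approx(0.2)
    assert mafs["maf_controls"][0] == pytest.approx(0.2)


def test_maf_missing_group_undefined():
    ds = lv.CohortDataset(
        variants=_vt(1),
        genotypes=np.array([[MISSING, MISSING, 1, 0]], dtype=np.int8),
        phenotype=np.array([1, 1, 0, 0]),
    )
    mafs = lv.maf_by_group(ds)
    assert np.isnan(mafs["maf_cases"][0])
    assert mafs["maf_controls"][0] == 0.25


def test_maf_estimate_converges_to_truth():
    cfg = lv.SimulationConfig(
        n_cases=5000, n_controls=5000, n_genes=1, variants_per_gene=5,
        effect_model=(lv.Effect("GENE001", 0, 0.05, 0.05),), seed=21,
    )
    ds, truth = lv.simulate_cohort(cfg)
    mafs = lv.maf_by_group(ds)
    sd = np.sqrt(0.05 * 0.95 / 10_000)
    assert abs(mafs["maf_cases"][0] - 0.05) < 4 * sd


def _vt(n):
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": ["chr1"] * n, "pos": range(1, n + 1), "id": ["."] * n,
            "ref": ["A"] * n, "alt": ["C"] * n, "gene": ["G1"] * n,
            "region": ["intronic"] * n,
        }
    )


# -------------------------------------------------- reconstruct_counts

@pytest.mark.parametrize(
    "maf,n,expected", [(0.012, 450, 11), (0.001, 500, 1), (0.050, 450, 45), (0.023, 500, 23)]
)
def test_reconstruct_counts_round_half_up(maf, n, expected):
    assert lv.reconstruct_counts(maf, n) == expected


# ------------------------------------------------------ allelic_fisher

def test_published_upstream_variant_pvalues():
    # the two promoter-variant rows: counts reconstructed from printed
    # group MAFs at 450 cases / 500 controls
    t1 = [[11, 889], [1, 999]]
    assert f"{lv.allelic_fisher(t1):.4f}" == "0.0022"
    t2 = [[45, 855], [23, 977]]
    assert f"{lv.allelic_fisher(t2):.4f}" == "0.0018"


def test_identical_proportions_give_p_one():
    assert lv.allelic_fisher([[5, 5], [5, 5]]) == 1.0


def test_diagonal_table_matches_enumeration():
    assert lv.allelic_fisher([[3, 0], [0, 3]]) == pytest.approx(0.1, abs=1e-12)


def test_fisher_agrees_with_enumeration_oracle():
    rng = np.random.default_rng(17)
    for _ in range(100):
        t = rng.integers(0, 61, size=(2, 2))
        if t.sum(axis=1).min() == 0:
            continue
        assert lv.allelic_fisher(t) == pytest.approx(fisher_2x2_oracle(t), abs=1e-12)


@given(
    a=st.integers(0, 30), b=st.integers(0, 30),
    c=st.integers(0, 30), d=st.integers(0, 30),
)
@settings(max_examples=200, deadline=None)
def test_fisher_row_and_column_swap_invariance(a, b, c, d):
    if a + b == 0 or c + d == 0:
        return
    p = lv.allelic_fisher([[a, b], [c, d]])
    assert p == pytest.approx(lv.allelic_fisher([[c, d], [a, b]]), abs=1e-12)
    assert p == pytest.approx(lv.allelic_fisher([[b, a], [d, c]]), abs=1e-12)


def test_fisher_monotone_along_support():
    # moving the observed table outward at fixed margins never raises p
    r1 = c1 = 20
    n = 60
    ps = []
    for k in range(11, min(r1, c1) + 1):
        ps.append(lv.allelic_fisher([[k, r1 - k], [c1 - k, n - r1 - c1 + k]]))
    assert all(x >= y - 1e-12 for x, y in zip(ps, ps[1:]))


def test_zero_row_margin_rejected():
    with pytest.raises(ValidationError):
        lv.allelic_fisher([[0, 0], [1, 5]])


# ---------------------------------------------------- genotypic_fisher

def test_genotypic_identical_distribution_p_one():
    assert lv.genotypic_fisher([[4, 3, 3], [4, 3, 3]]) == pytest.approx(1.0)


def test_genotypic_matches_bruteforce_oracle():
    tables = [
        [[10, 0, 0], [0, 0, 10]],
        [[5, 3, 1], [2, 4, 4]],
        [[8, 1, 0], [5, 4, 2]],
    ]
    for t in tables:
        assert lv.genotypic_fisher(t) == pytest.approx(fisher_2x3_oracle(t), abs=1e-10)


def test_genotypic_collapses_to_2x2_when_class_empty():
    t = [[7, 3, 0], [2, 8, 0]]
    assert lv.genotypic_fisher(t) == pytest.approx(
        lv.allelic_fisher([[7, 3], [2, 8]]), abs=1e-10
    )


def test_genotypic_enumeration_cap():
    with pytest.raises(ValidationError, match="allelic"):
        lv.genotypic_fisher([[4000, 4000, 4000], [4000, 4000, 4000]], max_tables=100)


# --------------------------------------------------------------- ld_r2

def test_duplicated_column_gives_r2_one():
    g = np.array([0, 1, 2, 1, 0, 2, 1])
    assert lv.ld_r2(g, g) == pytest.approx(1.0)


def test_independent_variants_have_low_r2():
    rng = np.random.default_rng(3)
    g1 = rng.binomial(2, 0.3, size=10_000)
    g2 = rng.binomial(2, 0.3, size=10_000)
    assert lv.ld_r2(g1, g2) < 0.01


def test_monomorphic_gives_nan():
    assert np.isnan(lv.ld_r2(np.zeros(10), np.array([0, 1] * 5)))


def test_r2_symmetry_and_allele_flip_invariance():
    rng = np.random.default_rng(5)
    g1 = rng.binomial(2, 0.4, size=500)
    g2 = rng.binomial(2, 0.2, size=500)
    r = lv.ld_r2(g1, g2)
    assert r == pytest.approx(lv.ld_r2(g2, g1), abs=1e-12)
    assert r == pytest.approx(lv.ld_r2(2 - g1, g2), abs=1e-12)


def test_r2_uses_pairwise_complete():
    g1 = np.array([0, 1, 2, MISSING, 1])
    g2 = np.array([0, 1, 2, 2, MISSING])
    assert lv.ld_r2(g1, g2) == pytest.approx(1.0)


# ---------------------------------------------------------------- scan

def test_scan_direction_flags(small_cohort):
    dataset, _ = small_cohort
    scan = lv.single_variant_scan(dataset)
    enriched = scan[scan["maf_cases"] > scan["maf_controls"]]
    assert (enriched["direction"] == "case-enriched").all()
    assert len(scan) == dataset.n_variants


def test_scan_null_type_one_error_calibrated():
    # fraction of p < 0.05 under the null within 3 binomial SD of 0.05
    cfg = lv.SimulationConfig(
        n_cases=500, n_controls=500, n_genes=50, variants_per_gene=20,
        maf_law=lv.MafLaw(rare_mass=0.0, common_range=(0.1, 0.5)), seed=13,
    )
    ds, _ = lv.simulate_cohort(cfg)
    scan = lv.single_variant_scan(ds)
    frac = (scan["p_allelic"] < 0.05).mean()
    sd = np.sqrt(0.05 * 0.95 / len(scan))
    assert abs(frac - 0.05) < 3 * sd


def test_scan_null_pvalues_near_uniform():
    # Kolmogorov-Smirnov distance of null p-values from U(0,1); the
    # exact test is discrete so the comparison uses a loose 1% critical
    # value on 1,000 common variants
    cfg = lv.SimulationConfig(
        n_cases=500, n_controls=500, n_genes=50, variants_per_gene=20,
        maf_law=lv.MafLaw(rare_mass=0.0, common_range=(0.1, 0.5)), seed=29,
    )
    ds, _ = lv.simulate_cohort(cfg)
    scan = lv.single_variant_scan(ds)
    p = np.sort(scan["p_allelic"].to_numpy())
    grid = np.arange(1, len(p) + 1) / len(p)
    ks = np.max(np.abs(p - grid))
    # discrete exact p-values are stochastically larger than uniform;
    # the KS distance must stay below a generous 1.63/sqrt(n) + discreteness
    assert ks < 0.10


def test_scan_on_pooled_table_reconstructs_counts(small_cohort):
    dataset, _ = small_cohort
    plan = lv.make_pooling_plan(dataset.phenotype, pool_size=10)
    table = lv.pool_cohort(dataset.genotypes, dataset.phenotype, plan, dataset.variants)
    scan = lv.single_variant_scan(table)
    direct = lv.single_variant_scan(dataset)
    # exact AFs -> identical reconstructed counts -> identical p-values
    np.testing.assert_allclose(scan["p_allelic"], direct["p_allelic"], atol=1e-12)


def test_scan_table_matches_published_rows():
    # printed group MAFs at 450/500 reproduce the printed p-values
    rows = [
        (0.012, 0.001, "0.0022"),
        (0.050, 0.023, "0.0018"),
    ]
    for maf_case, maf_ctrl, printed in rows:
        a = lv.reconstruct_counts(maf_case, 450)
        c = lv.reconstruct_counts(maf_ctrl, 500)
        p = lv.allelic_fisher([[a, 900 - a], [c, 1000 - c]])
        assert f"{p:.4f}" == printed
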