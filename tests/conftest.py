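import numpy as np
import pytest

import longevar as lv


@pytest.fixture
def small_cohort():
    """110 individuals, 3 genes x 5 variants, no configured effects."""
    cfg = lv.SimulationConfig(
        n_cases=50, n_controls=60, n_genes=3, variants_per_gene=5, seed=11
    )
    dataset, truth = lv.simulate_cohort(cfg)
    return dataset, truth


@pytest.fixture
def null_model(small_cohort):
    dataset, _ = small_cohort
    return lv.fit_null(dataset.phenotype)


def rare_heavy_genotypes(rng, n_variants=20, n=200):
    """Genotype matrix with ~81% of variants below MAF 0.05 (HWE draws)."""
    maf = np.where(
        rng.random(n_variants) < 0.81,
        rng.uniform(0.002, 0.05, n_variants),
        rng.uniform(0.05, 0.5, n_variants),
    )
    return rng.binomial(2, maf[:, None], size=(n_variants, n)).astype(float)
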