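import numpy as np
import pytest

import strigakit as sk


@pytest.fixture(scope="session")
def clean_geno():
    """Moderate-structure inbred panel without hets or missing calls."""
    return sk.simulate_genotypes(
        n_lines=150, n_markers=800, n_chrom=10, n_subpops=3,
        fst=0.15, ld_rho=0.5, het_rate=0.0, missing_rate=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def clean_grm(clean_geno):
    return sk.vanraden_grm(sk.impute_missing(clean_geno))


@pytest.fixture(scope="session")
def related_geno():
    """Relatedness-rich panel (strong structure, long LD): kinship carries
    most of the predictive information."""
    return sk.simulate_genotypes(
        n_lines=200, n_markers=1000, n_chrom=10, n_subpops=5,
        fst=0.3, ld_rho=0.9, het_rate=0.0, missing_rate=0.0, seed=40,
    )


@pytest.fixture(scope="session")
def related_grm(related_geno):
    return sk.vanraden_grm(sk.impute_missing(related_geno))


@pytest.fixture(scope="session")
def trial():
    """Small multi-environment trial with known truth."""
    geno = sk.simulate_genotypes(120, 500, het_rate=0.0, missing_rate=0.0, seed=11)
    pheno, truth = sk.simulate_trial(geno, n_env=3, n_rep=2, block_size=5, seed=12)
    return geno, pheno, truth


def balanced_toy(n_lines=8, n_env=2, n_rep=2, seed=3):
    """Balanced plot table without incomplete blocks (single block per rep)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for j in range(n_lines):
        for e in range(n_env):
            for r in range(n_rep):
                rows.append((f"L{j}", f"env{e+1}", f"rep{r+1}", "b1", "y",
                             float(j) + 0.5 * e + rng.normal(0, 0.3)))
    return pd.DataFrame(rows, columns=["line", "env", "rep", "block", "trait", "value"])
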