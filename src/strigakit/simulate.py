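"""Synthetic inbred-panel genotypes and multi-environment trial phenotypes.

The generators emulate the statistical structure the downstream stages
assume: a near-homozygous biallelic SNP panel over 10 chromosomes with
subpopulation structure (Balding-Nichols) and distance-decaying LD (a
first-order copy-chain along each chromosome, giving the closed-form decay
r2(k steps) ~= ld_rho**(2k)), and plot-level phenotypes from an
alpha-lattice trial whose covariance has a genomic main effect, a GxE
deviation, design effects (replicate, incomplete block) and residual noise.
Emerged-parasite counts at 8/10/12 weeks after planting are drawn from a
negative-binomial trajectory tied to a genetic liability.

All generators are pure functions of their arguments including ``seed``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, SimTruth, PHENO_COLUMNS

__all__ = [
    "simulate_genotypes",
    "simulate_trial",
    "simulate_striga_counts",
    "simulate_multi_trait_panel",
    "make_fixture_dataset",
]


def _check_rate(name: str, value: float, upper: float) -> None:
    if not 0.0 <= value <= upper:
        raise ValueError(f"{name} must lie in [0, {upper}], got {value}")


def simulate_genotypes(
    n_lines: int,
    n_markers: int,
    n_chrom: int = 10,
    n_subpops: int = 3,
    fst: float = 0.2,
    ld_rho: float = 0.5,
    het_rate: float = 0.005,
    missing_rate: float = 0.01,
    spacing_bp: int = 1000,
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate an inbred SNP panel with structure and decaying LD.

    Ancestral allele frequencies are uniform on (0.1, 0.9); subpopulation
    frequencies follow a Balding-Nichols draw with divergence ``fst``.
    Within each chromosome a haplotype is a first-order Markov copy-chain:
    each allele is copied from the previous marker with probability
    ``ld_rho`` and otherwise drawn fresh at that marker's subpopulation
    frequency, so the squared correlation between markers k steps apart is
    approximately ``ld_rho**(2k)``.  Inbred genotypes are doubled
    haplotypes; heterozygous calls and missing calls are injected at the
    given rates.  Marker positions are equally spaced ``spacing_bp`` apart.
    """
    if n_lines <= 0 or n_markers <= 0 or n_chrom <= 0 or n_subpops <= 0:
        raise ValueError("dimensions must be positive")
    if not 0.0 <= fst < 1.0:
        raise ValueError("fst must lie in [0, 1)")
    if not 0.0 <= ld_rho < 1.0:
        raise ValueError("ld_rho must lie in [0, 1)")
    _check_rate("het_rate", het_rate, 0.05)
    _check_rate("missing_rate", missing_rate, 0.05)

    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.1, 0.9, size=n_markers)
    if fst > 0:
        ratio = (1.0 - fst) / fst
        p_sub = rng.beta(p_anc * ratio, (1.0 - p_anc) * ratio, size=(n_subpops, n_markers))
        p_sub = np.clip(p_sub, 1e-4, 1.0 - 1e-4)
    else:
        p_sub = np.tile(p_anc, (n_subpops, 1))

    pop = np.arange(n_lines) % n_subpops
    pf = p_sub[pop]  # (n_lines, n_markers) marker frequency per line's subpop

    # chromosome assignment: contiguous, near-equal blocks
    sizes = np.full(n_chrom, n_markers // n_chrom)
    sizes[: n_markers % n_chrom] += 1
    chrom = np.repeat(np.arange(1, n_chrom + 1), sizes)
    pos = np.concatenate([(np.arange(s) + 1) * spacing_bp for s in sizes])

    hap = np.empty((n_lines, n_markers), dtype=np.int8)
    fresh = rng.random((n_lines, n_markers)) < pf
    copy = rng.random((n_lines, n_markers)) < ld_rho
    start = 0
    for s in sizes:
        hap[:, start] = fresh[:, start]
        for k in range(start + 1, start + s):
            hap[:, k] = np.where(copy[:, k], hap[:, k - 1], fresh[:, k])
        start += s

    values = (2 * hap).astype(np.int8)
    if het_rate > 0:
        values[rng.random(values.shape) < het_rate] = 1
    missing = rng.random(values.shape) < missing_rate
    line_ids = [f"L{i:04d}" for i in range(n_lines)]
    return GenotypeMatrix(values=values, missing=missing, line_ids=line_ids, chrom=chrom, pos=pos)


def _scaled_effects(W: np.ndarray, effects: np.ndarray, target_var: float) -> tuple[np.ndarray, np.ndarray]:
    """Centered line values from marker effects, rescaled so the realized
    sample variance (ddof=1) equals ``target_var`` exactly."""
    g = W @ effects
    g = g - g.mean()
    sd = g.std(ddof=1)
    if target_var == 0.0 or sd == 0.0:
        return np.zeros_like(g), np.zeros_like(effects)
    scale = np.sqrt(target_var) / sd
    return g * scale, effects * scale


def simulate_trial(
    geno: GenotypeMatrix,
    n_env: int = 3,
    n_rep: int = 2,
    block_size: int = 5,
    mu: float = 10.0,
    sigma2_G: float = 1.0,
    sigma2_GE: float = 0.25,
    sigma2_E: float = 1.0,
    sigma2_rep: float = 0.1,
    sigma2_block: float = 0.1,
    sigma2_e: float = 1.0,
    n_qtl: int = 50,
    trait: str = "trait",
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a multi-environment alpha-lattice trial from a genotype panel.

    Line genetic main values come from additive effects at ``n_qtl``
    randomly chosen markers, rescaled so the realized variance equals
    ``sigma2_G`` exactly; environment-specific QTL deviations give a GxE
    variance of ``sigma2_GE`` per environment (implying a cross-environment
    genetic correlation of sigma2_G / (sigma2_G + sigma2_GE)).  Environments
    are fixed shifts with spread ``sigma2_E``; replicates nest in
    environments and incomplete blocks of ``block_size`` consecutive plots
    nest in replicates.  Returns the long-format plot table and the full
    ground truth.
    """
    for name, v in [
        ("sigma2_G", sigma2_G), ("sigma2_GE", sigma2_GE), ("sigma2_E", sigma2_E),
        ("sigma2_rep", sigma2_rep), ("sigma2_block", sigma2_block), ("sigma2_e", sigma2_e),
    ]:
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if n_env < 1 or n_rep < 1 or block_size < 1:
        raise ValueError("n_env, n_rep and block_size must be >= 1")

    rng = np.random.default_rng(seed)
    n = geno.n_lines
    n_qtl = min(n_qtl, geno.n_markers)
    qtl = np.sort(rng.choice(geno.n_markers, size=n_qtl, replace=False))
    W = geno.dosages()[:, qtl]
    # mean-impute any missing QTL calls for the truth computation
    col_mean = np.nanmean(W, axis=0)
    nan_r, nan_c = np.where(np.isnan(W))
    W[nan_r, nan_c] = col_mean[nan_c]

    g, a = _scaled_effects(W, rng.normal(size=n_qtl), sigma2_G)
    d = np.zeros((n_env, n))
    b_env = np.zeros((n_env, n_qtl))
    for i in range(n_env):
        d[i], b_env[i] = _scaled_effects(W, rng.normal(size=n_qtl), sigma2_GE)
    u = g[None, :] + d  # (n_env, n_lines) env-specific genetic values

    env_eff = rng.normal(0.0, np.sqrt(sigma2_E), size=n_env) if sigma2_E > 0 else np.zeros(n_env)
    envs = [f"env{i + 1}" for i in range(n_env)]
    if n % block_size != 0:
        warnings.warn(
            f"block_size {block_size} does not tile {n} lines; last block is smaller",
            stacklevel=2,
        )

    records = []
    for i, env in enumerate(envs):
        for k in range(n_rep):
            rep_eff = rng.normal(0.0, np.sqrt(sigma2_rep)) if sigma2_rep > 0 else 0.0
            order = rng.permutation(n)
            n_blocks = int(np.ceil(n / block_size))
            blk_eff = rng.normal(0.0, np.sqrt(sigma2_block), size=n_blocks) if sigma2_block > 0 else np.zeros(n_blocks)
            e = rng.normal(0.0, np.sqrt(sigma2_e), size=n) if sigma2_e > 0 else np.zeros(n)
            for plot, j in enumerate(order):
                o = plot // block_size
                records.append(
                    (
                        geno.line_ids[j],
                        env,
                        f"rep{k + 1}",
                        f"rep{k + 1}_b{o + 1}",
                        trait,
                        mu + env_eff[i] + u[i, j] + rep_eff + blk_eff[o] + e[j],
                    )
                )
    pheno = pd.DataFrame.from_records(records, columns=PHENO_COLUMNS)

    tot = sigma2_G + sigma2_GE
    truth = SimTruth(
        qtl_indices=qtl,
        qtl_effects=a,
        qtl_env_effects=b_env,
        true_breeding_values=pd.DataFrame(u.T, index=geno.line_ids, columns=envs),
        genetic_main_values=pd.Series(g, index=geno.line_ids),
        env_effects=env_eff,
        variance_components_true={
            "sigma2_G": sigma2_G,
            "sigma2_GE": sigma2_GE,
            "sigma2_E": sigma2_E,
            "sigma2_rep": sigma2_rep,
            "sigma2_block": sigma2_block,
            "sigma2_e": sigma2_e,
        },
        env_correlation=(sigma2_G / tot) if tot > 0 else 1.0,
    )
    return pheno, truth


def simulate_striga_counts(
    genetic_liability: np.ndarray,
    line_ids: list[str] | None = None,
    timepoints_wap: tuple[int, ...] = (8, 10, 12),
    baseline_means: tuple[float, ...] = (6.2, 30.0, 65.0),
    overdispersion: float = 0.3,
    liability_scale: float = 0.3,
    n_env: int = 1,
    n_rep: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Emerged Striga plant counts at successive weeks after planting.

    Counts are negative-binomial with log-mean equal to the timepoint
    baseline plus a scaled standardized genetic liability (minus the
    lognormal mean correction, so grand means match the baselines).
    ``overdispersion`` is the NB dispersion (variance = m + m^2 * od);
    zero gives Poisson counts.  Default baselines mirror the grand means
    of emerged-parasite counts at 8, 10 and 12 WAP in the study design
    this generator emulates (6.2, 30, 65).
    """
    liab = np.asarray(genetic_liability, dtype=float)
    if len(timepoints_wap) != len(baseline_means):
        raise ValueError("timepoints and baselines must have equal length")
    if any(b <= 0 for b in baseline_means):
        raise ValueError("baseline means must be positive")
    if any(b2 < b1 for b1, b2 in zip(baseline_means, baseline_means[1:])):
        raise ValueError("baseline_means must be non-decreasing over timepoints")
    if overdispersion < 0:
        raise ValueError("overdispersion must be >= 0")

    rng = np.random.default_rng(seed)
    n = liab.size
    if line_ids is None:
        line_ids = [f"L{i:04d}" for i in range(n)]
    sd = liab.std(ddof=1) if n > 1 else 0.0
    if sd > 0:
        z = (liab - liab.mean()) / sd
        s = liability_scale
    else:
        z = np.zeros(n)
        s = 0.0  # no liability spread: no lognormal mean correction needed

    records = []
    for i in range(n_env):
        for k in range(n_rep):
            for t, base in zip(timepoints_wap, baseline_means):
                m = base * np.exp(s * z - 0.5 * s * s)
                if overdispersion > 0:
                    lam = m * rng.gamma(1.0 / overdispersion, overdispersion, size=n)
                else:
                    lam = m
                counts = rng.poisson(lam)
                for j in range(n):
                    records.append(
                        (line_ids[j], f"env{i + 1}", f"rep{k + 1}", f"rep{k + 1}_b1",
                         f"nstr_{t}wap", float(counts[j]))
                    )
    return pd.DataFrame.from_records(records, columns=PHENO_COLUMNS)


def simulate_multi_trait_panel(
    grm,
    n_env: int = 3,
    n_traits: int = 4,
    trait_corr: float = 0.9,
    env_corr: float = 0.8,
    h2: float = 0.5,
    mu: float = 10.0,
    sigma2_G: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Line-level values for several correlated traits across environments.

    Genetic values are drawn from N(0, G * sigma2_G) so they are consistent
    with the supplied relationship matrix; traits share a common genetic
    factor with loading sqrt(trait_corr); environment-specific genetic
    deviations set the cross-environment correlation to ``env_corr``; line
    residuals set the within-column heritability to ``h2``.  Returns a wide
    lines x (trait, env) DataFrame (the collaborative-filtering input).

    ``trait_corr`` may also be 0 for traits genetically independent of the
    shared factor.
    """
    if not 0.0 <= trait_corr <= 1.0 or not 0.0 < env_corr <= 1.0 or not 0.0 < h2 <= 1.0:
        raise ValueError("trait_corr, env_corr, h2 must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n = grm.n_lines
    L = np.linalg.cholesky(grm.ridged())

    sigma2_GE = sigma2_G * (1.0 - env_corr) / env_corr
    var_u = sigma2_G + sigma2_GE
    sigma2_e = var_u * (1.0 - h2) / h2

    g_shared = L @ rng.normal(size=n)
    cols = {}
    for t in range(n_traits):
        g_own = L @ rng.normal(size=n)
        g = np.sqrt(trait_corr) * g_shared + np.sqrt(1.0 - trait_corr) * g_own
        g = g / g.std(ddof=1) * np.sqrt(sigma2_G)
        for i in range(n_env):
            d = L @ rng.normal(size=n)
            d = d / d.std(ddof=1) * np.sqrt(sigma2_GE) if sigma2_GE > 0 else np.zeros(n)
            e = rng.normal(0.0, np.sqrt(sigma2_e), size=n) if sigma2_e > 0 else np.zeros(n)
            cols[(f"trait{t + 1}", f"env{i + 1}")] = mu + g + d + e
    out = pd.DataFrame(cols, index=list(grm.line_ids))
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["trait", "env"])
    return out


def make_fixture_dataset(seed: int = 0):
    """Canonical small dataset (100 lines x 500 markers x 3 env) for tests
    and the ``fixtures`` CLI command.  Returns (genotypes, phenotypes, truth);
    the phenotype table carries one quantitative trait plus Striga count
    trajectories derived from the same genetic values."""
    geno = simulate_genotypes(
        n_lines=100, n_markers=500, n_chrom=10, n_subpops=3,
        fst=0.15, ld_rho=0.6, het_rate=0.005, missing_rate=0.01, seed=seed,
    )
    pheno, truth = simulate_trial(geno, n_env=3, n_rep=2, block_size=5, seed=seed + 1)
    counts = simulate_striga_counts(
        truth.genetic_main_values.to_numpy(),
        line_ids=geno.line_ids,
        n_env=3,
        n_rep=2,
        seed=seed + 2,
    )
    return geno, pd.concat([pheno, counts], ignore_index=True), truth
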