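"""Marker QC, relationship matrices, principal components and LD decay.

Mirrors the molecular workflow of an inbred association panel: filter SNPs
on minor allele frequency, missingness and heterozygosity; mean-impute the
survivors; build the VanRaden genomic relationship matrix
G = W W' / (2 sum p(1-p)) (W the allele-frequency-centred dosages); extract
principal components for structure correction; and summarise LD decay to
derive an effective number of independent tests and the corresponding
genome-wide significance threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, GRM

__all__ = [
    "filter_snps",
    "impute_missing",
    "vanraden_grm",
    "ibs_kinship",
    "pca",
    "ld_decay",
    "LdDecaySummary",
]


def filter_snps(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    missing_max: float = 0.05,
    het_max: float = 0.05,
) -> tuple[GenotypeMatrix, dict]:
    """Retain markers with MAF > ``maf_min``, missing fraction <
    ``missing_max`` and heterozygosity < ``het_max`` (all strict).
    Monomorphic markers are always dropped.  Returns the filtered panel and
    a report of counts per rule."""
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must lie in [0, 0.5]")
    if not 0.0 <= missing_max <= 1.0 or not 0.0 <= het_max <= 1.0:
        raise ValueError("missing_max and het_max must lie in [0, 1]")
    d = geno.dosages()
    n = geno.n_lines
    miss_frac = geno.missing.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(d, axis=0) / 2.0
        het_frac = np.nanmean(d == 1, axis=0)
    p = np.nan_to_num(p, nan=0.0)
    het_frac = np.nan_to_num(het_frac, nan=1.0)
    maf = np.minimum(p, 1.0 - p)
    polymorphic = (p > 0.0) & (p < 1.0)
    keep = (maf > maf_min) & (miss_frac < missing_max) & (het_frac < het_max) & polymorphic
    report = {
        "n_input": geno.n_markers,
        "n_retained": int(keep.sum()),
        "fail_maf": int((~(maf > maf_min) & polymorphic).sum()),
        "fail_missing": int((~(miss_frac < missing_max)).sum()),
        "fail_het": int((~(het_frac < het_max)).sum()),
        "monomorphic": int((~polymorphic).sum()),
    }
    if not keep.any():
        raise ValueError("all markers removed by the QC filters")
    return geno.subset(markers=np.where(keep)[0]), report


def impute_missing(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls by the marker mean dosage 2p (estimated from
    the observed calls).  The per-marker mean is preserved exactly."""
    if not geno.missing.any():
        return GenotypeMatrix(
            values=geno.values.astype(float), missing=np.zeros_like(geno.missing),
            line_ids=geno.line_ids, chrom=geno.chrom, pos=geno.pos,
            alleles=geno.alleles, imputed=True,
        )
    d = geno.dosages()
    all_missing = np.isnan(d).all(axis=0)
    if all_missing.any():
        raise ValueError(
            f"{int(all_missing.sum())} markers are fully missing; filter before imputing"
        )
    col_mean = np.nanmean(d, axis=0)
    r, c = np.where(np.isnan(d))
    d[r, c] = col_mean[c]
    return GenotypeMatrix(
        values=d, missing=np.zeros_like(geno.missing),
        line_ids=geno.line_ids, chrom=geno.chrom, pos=geno.pos,
        alleles=geno.alleles, imputed=True,
    )


def vanraden_grm(geno: GenotypeMatrix) -> GRM:
    """VanRaden genomic relationship matrix G = W W' / (2 sum_k p_k (1-p_k))
    with W the dosage matrix centred at 2p_k and p_k estimated from the
    sample.  Requires a panel without missing calls."""
    if geno.missing.any():
        raise ValueError("impute missing calls before building the GRM")
    M = geno.values.astype(float)
    p = M.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if poly.sum() < 2:
        raise ValueError("fewer than 2 polymorphic markers")
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    if denom == 0.0:
        raise ValueError("zero VanRaden denominator (all markers monomorphic)")
    W = M - 2.0 * p
    G = (W @ W.T) / denom
    return GRM(matrix=G, denominator=denom, allele_freqs=p, line_ids=geno.line_ids)


def ibs_kinship(geno: GenotypeMatrix) -> GRM:
    """Identity-by-state similarity: mean over markers of the per-marker
    allele-sharing fraction 1 - |d_i - d_j| / 2.  Exposed as the alternative
    kinship for the association scan."""
    if geno.missing.any():
        raise ValueError("impute missing calls before building the kinship")
    M = geno.values.astype(float)
    n, m = M.shape
    # 1 - |di - dj|/2 averaged over markers, computed via pairwise L1 distance
    K = np.empty((n, n))
    for i in range(n):
        K[i] = 1.0 - np.abs(M - M[i]).sum(axis=1) / (2.0 * m)
    K = (K + K.T) / 2.0
    p = M.mean(axis=0) / 2.0
    return GRM(matrix=K, denominator=float(m), allele_freqs=p, line_ids=geno.line_ids)


def pca(geno: GenotypeMatrix, n_pc: int = 3, scale: bool = False,
        ) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of the centred (optionally standardised)
    dosage matrix.  Returns (scores (n_lines x n_pc), variance-explained
    fractions).  Component signs are fixed by making the largest-magnitude
    loading of each score vector positive."""
    if geno.missing.any():
        raise ValueError("impute missing calls before PCA")
    if n_pc >= min(geno.n_lines, geno.n_markers):
        raise ValueError("n_pc must be smaller than min(lines, markers)")
    M = geno.values.astype(float)
    M = M - M.mean(axis=0)
    if scale:
        sd = M.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        M = M / sd
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    scores = U[:, :n_pc] * s[:n_pc]
    total = float(np.sum(s**2))
    explained = (s[:n_pc] ** 2) / total if total > 0 else np.zeros(n_pc)
    for j in range(n_pc):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return scores, explained


@dataclass
class LdDecaySummary:
    """Binned LD decay with threshold crossing distances and the effective
    number of independent tests n_eff = genome length / d(r2 = 0.1)."""

    pairs: pd.DataFrame  # columns dist_bp, r2 (one row per marker pair)
    binned: pd.DataFrame  # columns dist_bp (bin midpoint), mean_r2, n_pairs
    d_r2_01: float  # bp distance where mean r2 first falls below 0.1
    d_r2_02: float
    genome_length_bp: float
    n_effective_tests: float
    alpha: float = 0.05
    skipped_chromosomes: list = field(default_factory=list)

    @property
    def significance_threshold(self) -> float:
        return self.alpha / self.n_effective_tests


def _crossing(dist: np.ndarray, mean_r2: np.ndarray, level: float) -> float:
    """Distance of the first downward crossing of ``level`` by linear
    interpolation between bin midpoints; boundary bins fall back to the
    nearest midpoint."""
    below = np.where(mean_r2 < level)[0]
    if below.size == 0:
        return float(dist[-1])
    i = below[0]
    if i == 0:
        return float(dist[0])
    x0, x1 = dist[i - 1], dist[i]
    y0, y1 = mean_r2[i - 1], mean_r2[i]
    if y0 == y1:
        return float(x1)
    return float(x0 + (y0 - level) * (x1 - x0) / (y0 - y1))


def ld_decay(geno: GenotypeMatrix, max_dist_bp: int = 100_000,
             bin_bp: int | None = None, alpha: float = 0.05) -> LdDecaySummary:
    """Squared dosage correlation (composite LD) for marker pairs within
    ``max_dist_bp``, binned by physical distance.  Decay distances at
    r2 = 0.1 and 0.2 are the first downward crossings of the binned means;
    the effective number of tests is the total mapped genome length divided
    by the r2 = 0.1 distance."""
    if geno.missing.any():
        raise ValueError("impute missing calls before the LD summary")
    dists, r2s = [], []
    genome_length = 0.0
    skipped = []
    for c in np.unique(geno.chrom):
        idx = np.where(geno.chrom == c)[0]
        if idx.size < 2:
            skipped.append(c)
            warnings.warn(f"chromosome {c} has a single marker; skipped", stacklevel=2)
            continue
        pos = geno.pos[idx]
        genome_length += float(pos.max() - pos.min())
        M = geno.values[:, idx].astype(float)
        sd = M.std(axis=0)
        ok = sd > 0
        M, pos = M[:, ok], pos[ok]
        if pos.size < 2:
            continue
        Z = (M - M.mean(axis=0)) / M.std(axis=0)
        R = (Z.T @ Z) / Z.shape[0]
        iu, ju = np.triu_indices(pos.size, k=1)
        dd = pos[ju] - pos[iu]
        within = dd <= max_dist_bp
        dists.append(dd[within].astype(float))
        r2s.append(R[iu[within], ju[within]] ** 2)
    if not dists:
        raise ValueError("no marker pairs within the window")
    dist = np.concatenate(dists)
    r2 = np.concatenate(r2s)
    pairs = pd.DataFrame({"dist_bp": dist, "r2": r2})

    if bin_bp is None:
        bin_bp = max(int(np.min(dist)), 1)
    edges = np.arange(0, max_dist_bp + bin_bp, bin_bp)
    which = np.digitize(dist, edges) - 1
    rows = []
    for b in np.unique(which):
        sel = which == b
        rows.append({
            "dist_bp": (edges[b] + edges[b + 1]) / 2.0 if b + 1 < len(edges) else edges[b] + bin_bp / 2.0,
            "mean_r2": float(r2[sel].mean()),
            "n_pairs": int(sel.sum()),
        })
    binned = pd.DataFrame(rows).sort_values("dist_bp").reset_index(drop=True)

    d01 = _crossing(binned["dist_bp"].to_numpy(), binned["mean_r2"].to_numpy(), 0.1)
    d02 = _crossing(binned["dist_bp"].to_numpy(), binned["mean_r2"].to_numpy(), 0.2)
    n_eff = max(genome_length / d01, 1.0)
    return LdDecaySummary(
        pairs=pairs, binned=binned, d_r2_01=d01, d_r2_02=d02,
        genome_length_bp=genome_length, n_effective_tests=n_eff,
        alpha=alpha, skipped_chromosomes=skipped,
    )
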