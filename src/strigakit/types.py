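"""Core containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: column order of a long-format phenotype table
PHENO_COLUMNS = ["line", "env", "rep", "block", "trait", "value"]


@dataclass
class GenotypeMatrix:
    """Lines x markers biallelic genotypes coded as ALT-allele dosage 0/1/2.

    ``values`` holds the dosage codes; ``missing`` is a boolean mask of the
    same shape (True = no call).  ``chrom`` / ``pos`` give the marker map
    (1-based bp, strictly increasing within a chromosome).  ``imputed``
    relaxes the integer-code invariant: after marker-mean imputation the
    entries are fractional dosages in [0, 2] and the mask is all-False.
    """

    values: np.ndarray
    missing: np.ndarray
    line_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    alleles: np.ndarray | None = None  # (m, 2) ref/alt labels, optional
    imputed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.line_ids = list(self.line_ids)
        n, m = self.values.shape
        if self.missing.shape != (n, m):
            raise ValueError("missing mask shape does not match values")
        if len(self.line_ids) != n:
            raise ValueError("line_ids length does not match values")
        if len(set(self.line_ids)) != n:
            raise ValueError("line_ids must be unique")
        if self.chrom.shape != (m,) or self.pos.shape != (m,):
            raise ValueError("marker map length does not match values")
        obs = self.values[~self.missing]
        if obs.size:
            if obs.min() < 0 or obs.max() > 2:
                raise ValueError("genotype codes must lie in [0, 2]")
            if not self.imputed and not np.array_equal(obs, np.round(obs)):
                raise ValueError("non-imputed genotype codes must be integers 0/1/2")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def marker_names(self) -> list[str]:
        return [f"S{c}_{p}" for c, p in zip(self.chrom, self.pos)]

    def dosages(self) -> np.ndarray:
        """Float dosage matrix; missing entries become NaN."""
        d = self.values.astype(float).copy()
        d[self.missing] = np.nan
        return d

    def allele_freqs(self) -> np.ndarray:
        """Per-marker ALT allele frequency from non-missing calls."""
        d = self.dosages()
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def subset(self, lines=None, markers=None) -> "GenotypeMatrix":
        li = np.arange(self.n_lines) if lines is None else np.asarray(lines)
        mi = np.arange(self.n_markers) if markers is None else np.asarray(markers)
        return GenotypeMatrix(
            values=self.values[np.ix_(li, mi)],
            missing=self.missing[np.ix_(li, mi)],
            line_ids=[self.line_ids[i] for i in li],
            chrom=self.chrom[mi],
            pos=self.pos[mi],
            alleles=None if self.alleles is None else self.alleles[mi],
            imputed=self.imputed,
        )


@dataclass
class SimTruth:
    """Ground truth carried alongside a simulated trial.

    Used by parameter-recovery tests: the realized genetic values, the QTL
    that generated them, and the variance components the generator targeted.
    """

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray  # (n_qtl,) main effects after rescaling
    qtl_env_effects: np.ndarray  # (n_env, n_qtl) env-deviation effects
    true_breeding_values: pd.DataFrame  # lines x environments, u_ij = g_j + d_ij
    genetic_main_values: pd.Series  # g_j, indexed by line
    env_effects: np.ndarray  # fixed environment shifts used
    variance_components_true: dict[str, float]
    env_correlation: float

    def __post_init__(self) -> None:
        for k, v in self.variance_components_true.items():
            if v < 0:
                raise ValueError(f"negative true variance component {k}")
        if not -1.0 <= self.env_correlation <= 1.0:
            raise ValueError("env_correlation outside [-1, 1]")


@dataclass
class VarianceComponents:
    """REML variance components of the trial mixed model.

    ``sigma2_GE`` and ``sigma2_block`` may be absent (None) for
    within-environment fits / designs without incomplete blocks.
    Negative REML solutions are truncated at zero by the fitting code and
    recorded in ``truncated``.
    """

    sigma2_G: float
    sigma2_e: float
    sigma2_GE: float | None = None
    sigma2_block: float | None = None
    sigma2_rep: float | None = None
    n_env: int = 1
    n_rep: int = 1
    truncated: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("sigma2_G", "sigma2_e", "sigma2_GE", "sigma2_block", "sigma2_rep"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_env < 1 or self.n_rep < 1:
            raise ValueError("n_env and n_rep must be >= 1")


@dataclass
class GRM:
    """VanRaden genomic relationship matrix over lines.

    ``matrix`` is the raw G = W W' / (2 sum p(1-p)); solvers should use
    ``ridged()`` which adds a small diagonal jitter for numerical PSD.
    """

    matrix: np.ndarray
    denominator: float
    allele_freqs: np.ndarray
    line_ids: list[str]
    ridge: float = 1e-6

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("GRM must be square")
        if len(self.line_ids) != n:
            raise ValueError("line_ids length mismatch")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")

    @property
    def n_lines(self) -> int:
        return self.matrix.shape[0]

    def ridged(self) -> np.ndarray:
        return self.matrix + self.ridge * np.eye(self.n_lines)

    def indices_of(self, lines) -> np.ndarray:
        lookup = {l: i for i, l in enumerate(self.line_ids)}
        try:
            return np.array([lookup[l] for l in lines], dtype=int)
        except KeyError as e:  # pragma: no cover - message clarity
            raise KeyError(f"line {e.args[0]!r} not present in GRM") from None


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format phenotype table and return it with canonical dtypes."""
    missing = [c for c in PHENO_COLUMNS if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    out = pheno.copy()
    dup = out.duplicated(subset=["line", "env", "rep", "trait"])
    if dup.any():
        raise ValueError("duplicate (line, env, rep, trait) records")
    return out
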