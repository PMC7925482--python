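"""Single-marker association scans with structure and kinship correction.

The mixed linear model (Q + K) is y = X beta + m a + u + e with covariates
X (intercept plus principal-component scores), u ~ N(0, K sigma2_u) and
e ~ N(0, I sigma2_e).  Variance components are estimated once on the null
model (marker excluded) by exact spectral REML and then held fixed for the
per-marker generalized-least-squares t-tests — the standard P3D/EMMAX
speed-up.  The GLM path is the same scan with the kinship omitted.

Significance is declared against fixed genome-wide thresholds (defaults
2e-6 for Striga resistance traits, 5.6e-6 for grain yield) or against an
LD-based effective-number-of-tests threshold from :func:`strigakit.geno.ld_decay`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from ._reml import reml_two_component, TwoComponentResult
from .types import GenotypeMatrix, GRM

__all__ = [
    "MixedGwas",
    "GwasResult",
    "significant_hits",
    "variance_explained",
    "genomic_control_lambda",
    "STRIGA_TRAIT_THRESHOLD",
    "GY_THRESHOLD",
]

#: printed genome-wide significance thresholds for the two trait families
STRIGA_TRAIT_THRESHOLD = 2e-6
GY_THRESHOLD = 5.6e-6


class MixedGwas:
    """Genome scan for one line-level response (typically a BLUP).

    Parameters
    ----------
    y : response aligned with ``geno.line_ids`` (pd.Series indexed by line
        id, or a plain array in panel order).
    geno : imputed genotype panel (no missing calls).
    K : genomic relationship / kinship matrix, required for ``method="mlm"``.
    covariates : optional n x q matrix of structure covariates (PC scores);
        an intercept is always prepended.
    method : ``"mlm"`` (Q + K, P3D) or ``"glm"`` (structure only).
    """

    def __init__(self, y, geno: GenotypeMatrix, K: GRM | None = None,
                 covariates: np.ndarray | None = None, method: str = "mlm") -> None:
        if method not in ("mlm", "glm"):
            raise ValueError("method must be 'mlm' or 'glm'")
        if geno.missing.any():
            raise ValueError("impute missing calls before scanning")
        if isinstance(y, pd.Series):
            y = y.reindex(geno.line_ids).to_numpy(float)
        y = np.asarray(y, dtype=float).ravel()
        if y.size != geno.n_lines:
            raise ValueError("response length does not match the panel")
        if np.isnan(y).any():
            raise ValueError("response contains missing values")
        n = y.size
        X = np.ones((n, 1))
        if covariates is not None:
            covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
            if covariates.shape[0] != n:
                raise ValueError("covariate rows do not match the panel")
            X = np.hstack([X, covariates])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("collinear covariates")
        if method == "mlm":
            if K is None:
                raise ValueError("MLM requires a kinship matrix")
            idx = K.indices_of(geno.line_ids)
            self._K = K.ridged()[np.ix_(idx, idx)]
        else:
            self._K = None
        self.y = y
        self.X = X
        self.geno = geno
        self.method = method
        self.n_covariates = X.shape[1] - 1

    def fit_null(self) -> TwoComponentResult:
        """REML fit of the no-marker model (spectral, cached rotation)."""
        if self.method != "mlm":
            raise ValueError("the null variance-component fit applies to MLM only")
        return reml_two_component(self.y, self.X, self._K)

    def fit(self) -> "GwasResult":
        """Scan every marker; returns per-marker effects and p-values."""
        n, p = self.X.shape
        M = self.geno.values.astype(float)
        if self.method == "mlm":
            null = self.fit_null()
            w = null.weights()  # 1/diag(V) in the rotated basis
            sw = np.sqrt(w)
            yw = null.y_rot * sw
            Xw = null.X_rot * sw[:, None]
            Mw = (null.U.T @ M) * sw[:, None]
            ratio = null.sigma2_e / null.sigma2_u if null.sigma2_u > 0 else np.inf
            meta = {
                "sigma2_u": null.sigma2_u,
                "sigma2_e": null.sigma2_e,
                "lambda_ratio": ratio,
                "null_loglik": null.loglik,
            }
        else:
            yw, Xw, Mw = self.y, self.X, M
            meta = {}

        # residualize response and markers on the (whitened) covariates
        Q, _ = np.linalg.qr(Xw)
        y_r = yw - Q @ (Q.T @ yw)
        M_r = Mw - Q @ (Q.T @ Mw)
        den = np.einsum("ij,ij->j", M_r, M_r)
        zero_var = den <= 1e-12 * n
        den_safe = np.where(zero_var, 1.0, den)
        num = M_r.T @ y_r
        beta = num / den_safe
        yss = float(y_r @ y_r)
        rss = np.maximum(yss - beta * num, 0.0)
        dof = n - p - 1
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / den_safe)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df=dof)
        pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

        freq = M.mean(axis=0) / 2.0
        minor_is_alt = freq <= 0.5
        maf = np.minimum(freq, 1.0 - freq)
        eff_minor = np.where(minor_is_alt, beta, -beta)
        if self.geno.alleles is not None:
            ref, alt = self.geno.alleles[:, 0], self.geno.alleles[:, 1]
        else:
            ref = np.array(["A"] * self.geno.n_markers)
            alt = np.array(["B"] * self.geno.n_markers)
        minor_allele = np.where(minor_is_alt, alt, ref)
        major_allele = np.where(minor_is_alt, ref, alt)

        table = pd.DataFrame({
            "snp": self.geno.marker_names,
            "chrom": self.geno.chrom,
            "pos": self.geno.pos,
            "maf": maf,
            "effect": eff_minor,  # per copy of the minor allele
            "se": se,
            "p": pvals,
            "skipped": zero_var,
        })
        table.loc[zero_var, ["effect", "se", "p"]] = np.nan
        return GwasResult(table=table, method=self.method,
                          n_lines=n, n_covariates=self.n_covariates, meta=meta)


@dataclass
class GwasResult:
    """Per-marker scan output plus null-model metadata."""

    table: pd.DataFrame
    method: str
    n_lines: int
    n_covariates: int
    meta: dict

    @property
    def p_values(self) -> np.ndarray:
        return self.table["p"].to_numpy()

    def lambda_gc(self) -> float:
        return genomic_control_lambda(self.table["p"].dropna().to_numpy())

    def qq_data(self) -> pd.DataFrame:
        """Sorted -log10 p against expected uniform quantiles."""
        p = np.sort(self.table["p"].dropna().to_numpy())
        m = p.size
        exp = (np.arange(1, m + 1) - 0.5) / m
        return pd.DataFrame({"expected": -np.log10(exp), "observed": -np.log10(p)})

    def summary(self) -> str:
        t = self.table.dropna(subset=["p"])
        lines = [
            f"GWAS scan ({self.method.upper()}): {len(t)} markers tested, "
            f"{self.n_lines} lines, {self.n_covariates} covariates",
            f"  min p = {t['p'].min():.3e} at {t.loc[t['p'].idxmin(), 'snp']}",
            f"  genomic-control lambda = {self.lambda_gc():.3f}",
        ]
        if self.meta:
            lines.append(
                f"  null model: sigma2_u={self.meta['sigma2_u']:.4f}, "
                f"sigma2_e={self.meta['sigma2_e']:.4f} "
                f"(ratio {self.meta['lambda_ratio']:.3f})"
            )
        return "\n".join(lines)


def genomic_control_lambda(p: np.ndarray) -> float:
    """Median chi-square inflation factor of a p-value set."""
    chi2 = stats.chi2.isf(np.asarray(p, dtype=float), df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))


def significant_hits(res: GwasResult, threshold: float = STRIGA_TRAIT_THRESHOLD,
                     ) -> pd.DataFrame:
    """Markers with p strictly below the genome-wide threshold, sorted by
    position, with minor-allele orientation retained from the scan."""
    t = res.table.dropna(subset=["p"])
    hits = t[t["p"] < threshold].copy()
    hits = hits.sort_values(["chrom", "pos"]).reset_index(drop=True)
    hits["threshold"] = threshold
    return hits


def variance_explained(y, hit_dosages: np.ndarray, h2: float,
                       ) -> tuple[float, float, bool]:
    """Joint adjusted R2 of the significant markers and the fraction of
    genotypic variance they explain, p_G = R2_adj / h2.

    ``hit_dosages`` is the n x k dosage matrix of the significant markers
    (k may be 0: returns (0, 0, False)).  Aliased (linearly dependent)
    columns are dropped before the joint ordinary regression.  Returns
    (R2_adj, p_G, flagged) where ``flagged`` marks p_G > 1.
    """
    y = np.asarray(y, dtype=float).ravel()
    if hit_dosages is None or np.size(hit_dosages) == 0:
        return 0.0, 0.0, False
    D = np.atleast_2d(np.asarray(hit_dosages, dtype=float))
    if D.shape[0] != y.size:
        raise ValueError("dosage rows do not match the response")
    if D.shape[1] >= y.size:
        raise ValueError("more significant markers than lines; rank guard")
    # drop aliased columns by greedy QR pivoting
    keep: list[int] = []
    for j in range(D.shape[1]):
        cand = D[:, keep + [j]]
        if np.linalg.matrix_rank(np.column_stack([np.ones(y.size), cand])) == len(keep) + 2:
            keep.append(j)
    D = D[:, keep]
    fit = sm.OLS(y, sm.add_constant(D)).fit()
    r2_adj = float(np.clip(fit.rsquared_adj, 0.0, 1.0))
    if h2 <= 0:
        raise ValueError("h2 must be positive")
    p_g = r2_adj / h2
    return r2_adj, p_g, p_g > 1.0
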