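"""Stage-1 phenotypic analysis of the multi-environment alpha-lattice trial.

The plot-level model is

    Y_ijko = mu + G_i + E_j + (GE)_ij + R(E)_kj + B(R.E)_ojk + e_ijko

with environments and replications-within-environments fixed and the other
terms random.  :class:`TrialMixedModel` fits it by REML (average-information
with damped-EM fallback) either across environments or within one
environment, with the genotype term random (BLUPs) or fixed (BLUEs).
Entry-mean heritability, AUDPC/AUSNPC trait derivation, pairwise trait
correlations and residual-based outlier removal round out the stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import reml_fit, RemlResult
from .types import VarianceComponents, validate_phenotypes

__all__ = [
    "TrialMixedModel",
    "TrialMixedModelResults",
    "entry_mean_heritability",
    "audpc",
    "ausnpc",
    "trait_correlations",
    "remove_outliers",
    "select_environments",
]


def _dummies(codes: pd.Series, drop_first: bool) -> tuple[np.ndarray, list[str]]:
    cats = sorted(codes.unique())
    use = cats[1:] if drop_first else cats
    cols = np.column_stack([(codes == c).to_numpy(float) for c in use]) if use else np.empty((len(codes), 0))
    return cols, list(use)


def _incidence(codes: pd.Series) -> tuple[np.ndarray, list]:
    """n x q 0/1 incidence matrix for a factor, plus the level order."""
    cats = sorted(codes.unique())
    return np.column_stack([(codes == c).to_numpy(float) for c in cats]), cats


class TrialMixedModel:
    """Linear mixed model for one trait of a multi-environment trial.

    Parameters
    ----------
    pheno : long-format plot table with columns line, env, rep, block,
        trait, value.
    trait : trait name to analyse.
    scope : ``"across"`` for the across-environment model, or a single
        environment name for a within-environment fit.
    genotype_as : ``"random"`` (yields BLUPs and a genotypic variance) or
        ``"fixed"`` (yields BLUEs).
    """

    def __init__(self, pheno: pd.DataFrame, trait: str,
                 scope: str = "across", genotype_as: str = "random") -> None:
        pheno = validate_phenotypes(pheno)
        data = pheno[pheno["trait"] == trait].copy()
        if data.empty:
            raise ValueError(f"trait {trait!r} absent from the phenotype table")
        if scope != "across":
            data = data[data["env"] == scope]
            if data.empty:
                raise ValueError(f"environment {scope!r} absent for trait {trait!r}")
        data = data.dropna(subset=["value"]).reset_index(drop=True)
        envs = sorted(data["env"].unique())
        if scope == "across" and len(envs) < 2:
            raise ValueError("across-environment fit requires >= 2 environments")
        n_rep = data.groupby("env")["rep"].nunique().min()
        if int(n_rep) < 2 and scope != "across":
            raise ValueError("within-environment fits require >= 2 replicates")
        if genotype_as not in ("random", "fixed"):
            raise ValueError("genotype_as must be 'random' or 'fixed'")
        self.data = data
        self.trait = trait
        self.scope = scope
        self.genotype_as = genotype_as
        self.envs = envs
        self.n_env = len(envs)
        self.n_rep = int(data.groupby("env")["rep"].nunique().max())
        self.lines = sorted(data["line"].unique())

    # -- design ------------------------------------------------------------
    def _fixed_design(self) -> tuple[np.ndarray, dict]:
        d = self.data
        n = len(d)
        parts = [np.ones((n, 1))]
        meta: dict = {"env_cols": [], "rep_cols": [], "geno_cols": []}
        if self.scope == "across":
            env_d, env_names = _dummies(d["env"], drop_first=True)
            parts.append(env_d)
            meta["env_cols"] = env_names
            rep_key = d["env"].astype(str) + ":" + d["rep"].astype(str)
        else:
            rep_key = d["rep"].astype(str)
        # replicate (within environment) effects, one baseline dropped per env
        rep_d_full, rep_names = _dummies(rep_key, drop_first=False)
        if self.scope == "across":
            keep = [i for i, name in enumerate(rep_names)
                    if name.split(":")[1] != sorted(set(r.split(":")[1] for r in rep_names))[0]]
        else:
            keep = list(range(1, len(rep_names)))
        if keep:
            parts.append(rep_d_full[:, keep])
            meta["rep_cols"] = [rep_names[i] for i in keep]
        if self.genotype_as == "fixed":
            g_d, g_names = _dummies(d["line"], drop_first=True)
            parts.append(g_d)
            meta["geno_cols"] = g_names
        X = np.hstack(parts)
        return X, meta

    def _kernels(self) -> tuple[list[np.ndarray], list[str], dict]:
        d = self.data
        kernels, names, incid = [], [], {}
        if self.genotype_as == "random":
            Zg, g_levels = _incidence(d["line"])
            kernels.append(Zg @ Zg.T)
            names.append("sigma2_G")
            incid["G"] = (Zg, g_levels)
            if self.scope == "across":
                ge_key = d["line"].astype(str) + "@" + d["env"].astype(str)
                Zge, ge_levels = _incidence(ge_key)
                kernels.append(Zge @ Zge.T)
                names.append("sigma2_GE")
                incid["GE"] = (Zge, ge_levels)
        elif self.scope == "across":
            # genotype fixed: GxE stays random
            ge_key = d["line"].astype(str) + "@" + d["env"].astype(str)
            Zge, ge_levels = _incidence(ge_key)
            kernels.append(Zge @ Zge.T)
            names.append("sigma2_GE")
            incid["GE"] = (Zge, ge_levels)
        # incomplete blocks nested in replicate-within-environment
        blk_key = (d["env"].astype(str) + ":" + d["rep"].astype(str) + ":" + d["block"].astype(str))
        per_rep = d.assign(_b=blk_key).groupby(["env", "rep"])["_b"].nunique()
        if (per_rep > 1).any():
            Zb, b_levels = _incidence(blk_key)
            kernels.append(Zb @ Zb.T)
            names.append("sigma2_block")
            incid["block"] = (Zb, b_levels)
        return kernels, names, incid

    # -- fitting -----------------------------------------------------------
    def fit(self, max_iter: int = 200, tol: float = 1e-8) -> "TrialMixedModelResults":
        d = self.data
        y = d["value"].to_numpy(float)
        X, meta = self._fixed_design()
        kernels, names, incid = self._kernels()
        res = reml_fit(y, X, kernels, names=names, max_iter=max_iter, tol=tol)

        comp = dict(zip(res.names, res.sigma2))
        vc = VarianceComponents(
            sigma2_G=comp.get("sigma2_G", 0.0),
            sigma2_e=comp["sigma2_e"],
            sigma2_GE=comp.get("sigma2_GE"),
            sigma2_block=comp.get("sigma2_block"),
            n_env=self.n_env,
            n_rep=self.n_rep,
            truncated=res.truncated,
        )

        # mean level: intercept plus balanced averages of env and rep effects
        p0 = 1
        level = float(res.beta[0])
        n_env_cols = len(meta["env_cols"])
        if n_env_cols:
            level += float(res.beta[p0:p0 + n_env_cols].sum()) / self.n_env
        p0 += n_env_cols
        n_rep_cols = len(meta["rep_cols"])
        if n_rep_cols:
            # each env drops one rep baseline; average of all rep contrasts
            level += float(res.beta[p0:p0 + n_rep_cols].sum()) / (self.n_env * self.n_rep)
        p0 += n_rep_cols

        if self.genotype_as == "random":
            Zg, g_levels = incid["G"]
            u = vc.sigma2_G * (Zg.T @ res.Vinv_resid)
            line_values = pd.DataFrame({
                "line": g_levels,
                "value": level + u,
                "deviation": u,
            })
            kind = "blup"
        else:
            g_names = meta["geno_cols"]
            coefs = dict(zip(g_names, res.beta[p0:p0 + len(g_names)]))
            baseline = [l for l in self.lines if l not in coefs][0]
            effs = np.array([coefs.get(l, 0.0) for l in self.lines])
            # report marginal means; centre effects so level stays the grand mean
            line_values = pd.DataFrame({
                "line": self.lines,
                "value": level + effs,
                "deviation": effs - effs.mean(),
            })
            kind = "blue"
        return TrialMixedModelResults(
            model=self, vc=vc, line_values=line_values, kind=kind,
            reml=res, level=level,
        )


@dataclass
class TrialMixedModelResults:
    """REML fit of the trial model: variance components, line values and log."""

    model: TrialMixedModel
    vc: VarianceComponents
    line_values: pd.DataFrame  # columns line, value, deviation
    kind: str  # "blup" | "blue"
    reml: RemlResult
    level: float

    @property
    def loglik(self) -> float:
        return self.reml.loglik

    @property
    def converged(self) -> bool:
        return self.reml.converged

    @property
    def log(self) -> str:
        return "\n".join(self.reml.log)

    def heritability(self) -> float:
        return entry_mean_heritability(self.vc)

    def summary(self) -> str:
        m = self.model
        lines = [
            f"Trial mixed model: trait={m.trait!r}, scope={m.scope}, genotype {m.genotype_as}",
            f"  records: {len(m.data)}, lines: {len(m.lines)}, E={m.n_env}, R={m.n_rep}",
            f"  REML loglik {self.loglik:.4f}  ({self.reml.n_iter} iterations, "
            f"|grad| {self.reml.gradient_norm:.2e}, converged={self.converged})",
            "  variance components:",
            f"    sigma2_G     {self.vc.sigma2_G:10.5f}",
        ]
        if self.vc.sigma2_GE is not None:
            lines.append(f"    sigma2_GE    {self.vc.sigma2_GE:10.5f}")
        if self.vc.sigma2_block is not None:
            lines.append(f"    sigma2_block {self.vc.sigma2_block:10.5f}")
        lines.append(f"    sigma2_e     {self.vc.sigma2_e:10.5f}")
        if self.vc.truncated:
            lines.append(f"  components truncated at zero: {', '.join(self.vc.truncated)}")
        if self.kind == "blup" and self.vc.sigma2_G > 0:
            lines.append(f"  entry-mean heritability h2 = {self.heritability():.3f}")
        return "\n".join(lines)


def entry_mean_heritability(vc: VarianceComponents) -> float:
    """Entry-mean (line-mean) heritability h2 = s2G / (s2G + s2GE/E + s2e/(E R)).

    For within-environment components (no GxE term) this reduces to the
    repeatability s2G / (s2G + s2e/R).
    """
    s2ge = vc.sigma2_GE if vc.sigma2_GE is not None else 0.0
    denom = vc.sigma2_G + s2ge / vc.n_env + vc.sigma2_e / (vc.n_env * vc.n_rep)
    if denom <= 0:
        raise ValueError("all variance components are zero; heritability undefined")
    return vc.sigma2_G / denom


def audpc(values, times) -> float:
    """Area under a progress curve by the trapezoidal rule:
    sum_i ((y_i + y_{i+1}) / 2) * (t_{i+1} - t_i)."""
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.shape != t.shape:
        raise ValueError("values and times must have the same length")
    if y.size < 2:
        raise ValueError("at least two timepoints required")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(y, t))


def ausnpc(counts, wap=(8, 10, 12)) -> float:
    """Area under the Striga number progress curve from counts at the given
    weeks after planting, integrated on a days time base (WAP x 7)."""
    return audpc(counts, np.asarray(wap, dtype=float) * 7.0)


def trait_correlations(summaries: pd.DataFrame, traits: list[str] | None = None,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations between line-level trait values.

    ``summaries`` is a wide lines x traits frame.  Missing lines are handled
    pairwise-complete; each off-diagonal cell gets a two-sided p-value from
    t = r sqrt((n-2) / (1-r2)).  Pairs with fewer than 3 complete
    observations, and constant traits, yield NaN (with a warning).
    Returns (correlation matrix, p-value matrix).
    """
    if traits is None:
        traits = list(summaries.columns)
    k = len(traits)
    r = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((k, k)), index=traits, columns=traits)
    for a in range(k):
        for b in range(a + 1, k):
            x = summaries[traits[a]].to_numpy(float)
            y = summaries[traits[b]].to_numpy(float)
            ok = ~(np.isnan(x) | np.isnan(y))
            n = int(ok.sum())
            if n < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                warnings.warn(
                    f"correlation undefined for pair ({traits[a]}, {traits[b]})",
                    stacklevel=2,
                )
                rv, pv = np.nan, np.nan
            else:
                rv = float(np.corrcoef(x[ok], y[ok])[0, 1])
                if abs(rv) >= 1.0:
                    pv = 0.0
                else:
                    tstat = rv * np.sqrt((n - 2) / (1.0 - rv * rv))
                    pv = 2.0 * stats.t.sf(abs(tstat), df=n - 2)
            r.iloc[a, b] = r.iloc[b, a] = rv
            p.iloc[a, b] = p.iloc[b, a] = pv
    return r, p


def correlation_significance_threshold(n: int, alpha: float = 0.05) -> float:
    """Smallest |r| significant at ``alpha`` (two-sided) for sample size n."""
    tcrit = stats.t.isf(alpha / 2.0, df=n - 2)
    return float(tcrit / np.sqrt(n - 2 + tcrit**2))


def remove_outliers(pheno: pd.DataFrame, trait: str, z_max: float = 3.5,
                    ) -> tuple[pd.DataFrame, int]:
    """Drop records whose standardized residual from a preliminary
    fixed-effects fit (line + environment + replicate all fixed) exceeds
    ``z_max`` in absolute value.  Returns (filtered table, count removed)."""
    if not z_max > 0:
        raise ValueError("z_max must be positive")
    pheno = validate_phenotypes(pheno)
    sub = pheno[pheno["trait"] == trait].dropna(subset=["value"])
    if sub.empty or not np.isfinite(z_max):
        return pheno, 0
    y = sub["value"].to_numpy(float)
    parts = [np.ones((len(sub), 1))]
    for key in (sub["line"], sub["env"].astype(str) + ":" + sub["rep"].astype(str)):
        d, _ = _dummies(key, drop_first=True)
        if d.size:
            parts.append(d)
    X = np.hstack(parts)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(len(sub) - rank, 1)
    s = np.sqrt(resid @ resid / dof)
    if s == 0:
        return pheno, 0
    bad = sub.index[np.abs(resid / s) > z_max]
    return pheno.drop(index=bad), len(bad)


def select_environments(pheno: pd.DataFrame, trait: str,
                        min_repeatability: float = 0.1,
                        alpha: float = 0.05) -> tuple[list[str], pd.DataFrame]:
    """Screen environments before the across-environment analysis.

    An environment is retained when its within-environment repeatability
    (entry-mean basis) is at least ``min_repeatability`` and the
    likelihood-ratio test of the genotypic variance (0.5 chi2_1 boundary
    mixture) has p < ``alpha``.  Returns (selected environments, report).
    """
    pheno = validate_phenotypes(pheno)
    rows = []
    for env in sorted(pheno.loc[pheno["trait"] == trait, "env"].unique()):
        m = TrialMixedModel(pheno, trait, scope=env, genotype_as="random")
        full = m.fit()
        y = m.data["value"].to_numpy(float)
        X, _ = m._fixed_design()
        kernels, names, _ = m._kernels()
        drop = names.index("sigma2_G")
        null = reml_fit(y, X, [k for i, k in enumerate(kernels) if i != drop],
                        names=[n for i, n in enumerate(names) if i != drop])
        lrt = max(2.0 * (full.loglik - null.loglik), 0.0)
        p = 0.5 * stats.chi2.sf(lrt, df=1)
        rep = entry_mean_heritability(full.vc)
        rows.append({"env": env, "repeatability": rep, "lrt": lrt, "p_G": p,
                     "selected": (rep >= min_repeatability) and (p < alpha)})
    report = pd.DataFrame(rows)
    return report.loc[report["selected"], "env"].tolist(), report
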