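"""GBLUP genomic prediction, within and across environments, plus CV schemes.

Within one environment the model is y_j = mu + G_j + e_j with
G ~ N(0, G1 sigma2_G) (G1 the VanRaden relationship matrix); across
environments it gains a random environment main effect E_i ~ N(0, I sigma2_E)
and the interaction GE ~ N(0, G1 (x) I sigma2_GE), i.e. interaction effects
correlated across lines through G1 and independent across environments.
Variance components are estimated by REML (spectral for the two-component
single-environment model, average-information for the stacked
multi-environment system); out-of-sample cells are predicted through the
cross-covariance with the observed cells.

Cross-validation schemes:

* CV0 — leave one environment out; predict all lines in the held-out
  environment from the remaining environments.
* CV1 — k-fold over lines; test-fold lines are masked in *all*
  environments (brand-new lines).
* CV2 — same line folds; each test line is masked in a random non-empty
  proper subset of environments (lines observed somewhere, predicted
  elsewhere).
* across — k-fold over lines on a single across-environment response
  (e.g. BLUEs).

Accuracy is the Pearson correlation of predicted vs observed values in the
test partition, reported per (environment, repetition); CV1 and CV2 use
identical line partitions for a given seed so their accuracies are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from ._reml import reml_fit, reml_two_component
from .types import GRM

__all__ = ["Gblup", "GblupResults", "run_cv", "CvResult", "cv_partitions"]


def _as_long(data) -> pd.DataFrame:
    if isinstance(data, pd.Series):
        raise TypeError("multi-environment data must be a long DataFrame")
    d = data[["line", "env", "value"]].dropna(subset=["value"]).copy()
    if d.duplicated(subset=["line", "env"]).any():
        raise ValueError("duplicate (line, env) cells; aggregate to line level first")
    return d.reset_index(drop=True)


class Gblup:
    """Genomic BLUP model.

    Parameters
    ----------
    data : ``pd.Series`` indexed by line id (single-environment /
        across-environment response) or a long DataFrame with columns
        line, env, value (multi-environment).
    grm : relationship matrix covering every line to be fitted or predicted.
    model : ``"G"`` (genomic + environment main effects) or ``"G+GE"``
        (adds the interaction).  Ignored in single-environment mode.
    snp_covariates : optional DataFrame of marker dosages indexed by line
        id, fitted as fixed covariates (GWAS-hit augmentation).
    """

    def __init__(self, data, grm: GRM, model: str = "G+GE",
                 snp_covariates: pd.DataFrame | None = None) -> None:
        if model not in ("G", "G+GE"):
            raise ValueError("model must be 'G' or 'G+GE'")
        self.grm = grm
        self.model = model
        self.snp_covariates = snp_covariates
        if isinstance(data, pd.Series):
            data = data.dropna()
            if data.empty:
                raise ValueError("empty response")
            self.mode = "single-env"
            self.lines = list(data.index)
            self.y = data.to_numpy(float)
            self.envs = None
            self.obs_line_idx = grm.indices_of(self.lines)
            self.obs_env_idx = None
        else:
            d = _as_long(data)
            if d.empty:
                raise ValueError("empty response")
            self.mode = "multi-env"
            if d["env"].nunique() < 2:
                raise ValueError("multi-environment fit requires >= 2 environments")
            self.envs = sorted(d["env"].unique())
            env_pos = {e: i for i, e in enumerate(self.envs)}
            self.data = d
            self.y = d["value"].to_numpy(float)
            self.obs_line_idx = grm.indices_of(d["line"])
            self.obs_env_idx = np.array([env_pos[e] for e in d["env"]])

    def _fixed(self, line_idx: np.ndarray) -> np.ndarray:
        X = np.ones((line_idx.size, 1))
        if self.snp_covariates is not None:
            S = self.snp_covariates.reindex([self.grm.line_ids[i] for i in line_idx])
            if S.isna().any().any():
                raise ValueError("snp_covariates missing for some lines")
            X = np.hstack([X, S.to_numpy(float)])
        return X

    def fit(self, max_iter: int = 200, tol: float = 1e-8) -> "GblupResults":
        G = self.grm.ridged()
        li = self.obs_line_idx
        X = self._fixed(li)
        if self.mode == "single-env":
            K = G[np.ix_(li, li)]
            res = reml_two_component(self.y, X, K)
            vc = {"sigma2_G": res.sigma2_u, "sigma2_e": res.sigma2_e}
            w = res.weights()
            vinv_resid = res.U @ (w * (res.y_rot - res.X_rot @ res.beta))
            return GblupResults(
                model_obj=self, vc=vc, beta=res.beta, loglik=res.loglik,
                converged=True, vinv_resid=vinv_resid, log=[],
            )
        Kg = G[np.ix_(li, li)]
        same_env = (self.obs_env_idx[:, None] == self.obs_env_idx[None, :]).astype(float)
        kernels = [Kg, same_env]
        names = ["sigma2_G", "sigma2_E"]
        if self.model == "G+GE":
            kernels.append(Kg * same_env)
            names.append("sigma2_GE")
        res = reml_fit(self.y, X, kernels, names=names, max_iter=max_iter, tol=tol)
        vc = dict(zip(res.names, res.sigma2))
        return GblupResults(
            model_obj=self, vc=vc, beta=res.beta, loglik=res.loglik,
            converged=res.converged, vinv_resid=res.Vinv_resid, log=res.log,
        )


@dataclass
class GblupResults:
    """Fitted GBLUP: variance components and the cross-covariance predictor."""

    model_obj: Gblup
    vc: dict[str, float]
    beta: np.ndarray
    loglik: float
    converged: bool
    vinv_resid: np.ndarray
    log: list[str]

    def genetic_values(self) -> pd.Series:
        """BLUP of the genomic main effect for every line in the GRM."""
        m = self.model_obj
        G = m.grm.ridged()
        C = self.vc["sigma2_G"] * G[:, m.obs_line_idx]
        return pd.Series(C @ self.vinv_resid, index=m.grm.line_ids)

    def predict(self, lines, envs=None) -> np.ndarray:
        """Predicted response for (line, env) cells (env omitted in
        single-environment mode).  New lines are predicted through the
        relationship matrix; a previously unobserved environment
        contributes only the genomic main effect."""
        m = self.model_obj
        li = m.grm.indices_of(lines)
        G = m.grm.ridged()
        C = self.vc["sigma2_G"] * G[np.ix_(li, m.obs_line_idx)]
        if m.mode == "multi-env":
            if envs is None:
                raise ValueError("multi-environment predictions need environments")
            env_pos = {e: i for i, e in enumerate(m.envs)}
            ei = np.array([env_pos.get(e, -1) for e in envs])
            same = (ei[:, None] == m.obs_env_idx[None, :]).astype(float)
            C = C + self.vc["sigma2_E"] * same
            if "sigma2_GE" in self.vc:
                C = C + self.vc["sigma2_GE"] * G[np.ix_(li, m.obs_line_idx)] * same
        Xp = np.ones((li.size, 1))
        if m.snp_covariates is not None:
            S = m.snp_covariates.reindex(list(lines))
            if S.isna().any().any():
                raise ValueError("snp_covariates missing for some prediction lines")
            Xp = np.hstack([Xp, S.to_numpy(float)])
        return Xp @ self.beta + C @ self.vinv_resid

    def summary(self) -> str:
        m = self.model_obj
        head = (f"GBLUP ({m.mode}, model {m.model if m.mode == 'multi-env' else 'G'}): "
                f"{self.model_obj.y.size} observations")
        comps = ", ".join(f"{k}={v:.4f}" for k, v in self.vc.items())
        return f"{head}\n  REML loglik {self.loglik:.4f}; {comps}"


# ---------------------------------------------------------------------------
# cross-validation


def cv_partitions(line_ids: list[str], k_folds: int, seed: int, repetition: int,
                  ) -> list[np.ndarray]:
    """Deterministic k-fold partition of lines for one repetition.

    Drawn from a counter-based stream keyed by (seed, repetition) only, so
    different schemes (CV1/CV2) evaluated with the same seed share identical
    partitions and their accuracies are paired.
    """
    rng = np.random.default_rng([seed, repetition])
    order = rng.permutation(len(line_ids))
    return [np.sort(f) for f in np.array_split(order, k_folds)]


def _subsets_proper(n_env: int) -> list[tuple[int, ...]]:
    out = []
    for r in range(1, n_env):
        out.extend(combinations(range(n_env), r))
    return out


@dataclass
class CvResult:
    """Tidy per-(environment, repetition) prediction accuracies."""

    table: pd.DataFrame  # scheme, model, environment, repetition, correlation, n_test
    scheme: str
    model: str
    n_folds: int
    n_repetitions: int
    seed: int
    log: list[str] = field(default_factory=list)

    def mean_accuracy(self, by_env: bool = False):
        per_rep = self.table.groupby(["environment", "repetition"])["correlation"].mean()
        by = per_rep.groupby("environment").mean()
        return by if by_env else float(by.mean())

    def summary(self) -> str:
        by = self.mean_accuracy(by_env=True)
        rows = "\n".join(f"    {e}: {v:.3f}" for e, v in by.items())
        return (f"{self.scheme} / {self.model}: mean accuracy {self.mean_accuracy():.3f} "
                f"({self.n_repetitions} repetitions x {self.n_folds} folds)\n{rows}")


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def run_cv(
    data,
    grm: GRM,
    scheme: str,
    model: str = "G+GE",
    k_folds: int = 5,
    n_repetitions: int = 100,
    seed: int = 0,
    snp_covariates: pd.DataFrame | None = None,
    augment_selector=None,
) -> CvResult:
    """Cross-validated prediction accuracy for one trait.

    ``data`` is a long DataFrame (line, env, value) for CV0/CV1/CV2 or a
    ``pd.Series`` of across-environment line values for scheme
    ``"across"``.  ``snp_covariates`` adds fixed marker covariates fitted
    on the whole panel (the augmentation variant whose accuracy is known
    to be slightly optimistic, since the markers were chosen on all
    lines); ``augment_selector`` is the leakage-free alternative — a
    callable mapping the training line ids to a dosage DataFrame, invoked
    per fold.  Supplying both is an error.
    """
    if scheme not in ("CV0", "CV1", "CV2", "across"):
        raise ValueError("scheme must be CV0, CV1, CV2 or 'across'")
    if snp_covariates is not None and augment_selector is not None:
        raise ValueError("choose whole-panel or training-only augmentation, not both")
    log: list[str] = []
    rows = []

    def _fit_predict(train, test_cells, covs):
        """Fit on the training data and return predictions for test cells."""
        fit = Gblup(train, grm, model=model, snp_covariates=covs).fit()
        if isinstance(train, pd.Series):
            return fit.predict(test_cells)
        return fit.predict(test_cells["line"].tolist(), test_cells["env"].tolist())

    if scheme == "across":
        y = data.dropna()
        lines = list(y.index)
        for rep in range(n_repetitions):
            folds = cv_partitions(lines, k_folds, seed, rep)
            pred = pd.Series(np.nan, index=y.index)
            for fold in folds:
                test = [lines[i] for i in fold]
                train = y.drop(index=test)
                covs = snp_covariates
                if augment_selector is not None:
                    covs = augment_selector(list(train.index))
                pred[test] = _fit_predict(train, test, covs)
            r = _corr(pred.to_numpy(), y.to_numpy())
            rows.append(("across", rep, r, len(y)))
        table = pd.DataFrame(rows, columns=["environment", "repetition", "correlation", "n_test"])
        table.insert(0, "model", model)
        table.insert(0, "scheme", scheme)
        return CvResult(table, scheme, model, k_folds, n_repetitions, seed, log)

    d = _as_long(data)
    envs = sorted(d["env"].unique())
    lines = sorted(d["line"].unique())
    if scheme == "CV0":
        if len(envs) < 2:
            raise ValueError("CV0 needs >= 2 environments")
        for env in envs:
            train = d[d["env"] != env]
            test = d[d["env"] == env]
            covs = snp_covariates
            if augment_selector is not None:
                covs = augment_selector(sorted(train["line"].unique()))
            pred = _fit_predict(train, test, covs)
            r = _corr(pred, test["value"].to_numpy())
            rows.append((env, 0, r, len(test)))
        table = pd.DataFrame(rows, columns=["environment", "repetition", "correlation", "n_test"])
        table.insert(0, "model", model)
        table.insert(0, "scheme", scheme)
        return CvResult(table, scheme, model, k_folds, 1, seed, log)

    subsets = _subsets_proper(len(envs)) if scheme == "CV2" else None
    for rep in range(n_repetitions):
        folds = cv_partitions(lines, k_folds, seed, rep)
        preds = []  # (line, env, predicted, observed)
        for fold in folds:
            test_lines = {lines[i] for i in fold}
            if scheme == "CV1":
                mask = d["line"].isin(test_lines)
            else:
                mask_rng = np.random.default_rng([seed, rep, 1])
                masked_cells = set()
                for l in sorted(test_lines):
                    sub = subsets[mask_rng.integers(len(subsets))]
                    masked_cells.update((l, envs[i]) for i in sub)
                mask = pd.MultiIndex.from_frame(d[["line", "env"]]).isin(masked_cells)
            train, test = d[~mask], d[mask]
            if test.empty:
                continue
            covs = snp_covariates
            if augment_selector is not None:
                covs = augment_selector(sorted(train["line"].unique()))
            pred = _fit_predict(train, test, covs)
            preds.append(pd.DataFrame({
                "line": test["line"].to_numpy(), "env": test["env"].to_numpy(),
                "pred": pred, "obs": test["value"].to_numpy(),
            }))
        allp = pd.concat(preds, ignore_index=True)
        for env in envs:
            sub = allp[allp["env"] == env]
            r = _corr(sub["pred"].to_numpy(), sub["obs"].to_numpy())
            if np.isnan(r):
                log.append(f"rep {rep}, env {env}: correlation undefined "
                           f"({len(sub)} test cells); skipped")
                continue
            rows.append((env, rep, r, len(sub)))
    table = pd.DataFrame(rows, columns=["environment", "repetition", "correlation", "n_test"])
    table.insert(0, "model", model)
    table.insert(0, "scheme", scheme)
    return CvResult(table, scheme, model, k_folds, n_repetitions, seed, log)
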