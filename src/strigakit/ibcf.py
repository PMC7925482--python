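"""Item-based collaborative filtering over lines x (trait, environment).

Lines play the role of users and trait-environment combinations the role
of items.  Each observed column is standardized, z_ij = (y_ij - mu_j) / sigma_j
(sample SD), an item-item similarity matrix is built from pairwise-complete
Pearson correlations of the standardized columns, and a missing cell is
predicted as the similarity-weighted combination of the line's observed
items,

    z_hat_ij = sum_{j' in N_i(j)} z_ij' w_jj' / sum_{j' in N_i(j)} w_jj'
    y_hat_ij = mu_j + sigma_j z_hat_ij

with the *signed* weight sum in the denominator (an absolute-value variant
is available).  The neighborhood N_i(j) is all items the line has observed,
optionally restricted to other environments and/or the top-k by |w|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Ibcf", "IbcfResults", "standardize", "item_similarity",
           "predict_missing", "cv2_evaluate"]

#: predictions with |sum of weights| below this are undefined
_DENOM_EPS = 1e-8


def _check_matrix(M: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(M.columns, pd.MultiIndex) or M.columns.nlevels != 2:
        raise ValueError("matrix columns must be a (trait, env) MultiIndex")
    if M.columns.duplicated().any():
        raise ValueError("duplicate (trait, env) columns")
    return M


def standardize(M: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Column-standardize on the observed cells (sample SD, n-1).

    Constant or nearly-unobserved (< 3 values) columns are dropped with a
    warning.  Missing cells stay missing.  Returns (Z, mu, sigma).
    """
    M = _check_matrix(M)
    mu = M.mean(axis=0)
    sigma = M.std(axis=0, ddof=1)
    n_obs = M.notna().sum(axis=0)
    bad = (sigma.fillna(0.0) == 0.0) | (n_obs < 3)
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} constant/underobserved columns: "
            f"{list(M.columns[bad])}", stacklevel=2,
        )
        M, mu, sigma = M.loc[:, ~bad], mu[~bad], sigma[~bad]
    if M.shape[1] == 0:
        raise ValueError("no usable columns after dropping constants")
    return (M - mu) / sigma, mu, sigma


def item_similarity(Z: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between standardized columns.

    Pairs with fewer than ``min_pairs`` complete observations get a missing
    weight.  The diagonal is set to NaN: an item is never its own neighbor.
    """
    S = Z.corr(method="pearson", min_periods=min_pairs)
    np.fill_diagonal(S.values, np.nan)
    return S


def _neighborhood_predict(zrow: pd.Series, weights: pd.Series,
                          neighborhood, denominator: str,
                          drop_negative: bool) -> float:
    obs = zrow.dropna()
    w = weights.reindex(obs.index).dropna()
    obs = obs.reindex(w.index)
    if drop_negative:
        keep = w > 0
        w, obs = w[keep], obs[keep]
    if neighborhood != "all":
        k = int(neighborhood)
        top = w.abs().nlargest(k).index
        w, obs = w[top], obs[top]
    if len(w) == 0:
        return np.nan
    denom = float(w.sum()) if denominator == "signed" else float(w.abs().sum())
    if abs(denom) < _DENOM_EPS:
        return np.nan
    return float((obs * w).sum() / denom)


class Ibcf:
    """Collaborative-filtering model for a lines x (trait, env) matrix."""

    def __init__(self, matrix: pd.DataFrame) -> None:
        self.matrix = _check_matrix(matrix)

    def fit(self, min_pairs: int = 3) -> "IbcfResults":
        Z, mu, sigma = standardize(self.matrix)
        S = item_similarity(Z, min_pairs=min_pairs)
        return IbcfResults(matrix=self.matrix.loc[:, Z.columns], Z=Z,
                           mu=mu, sigma=sigma, similarity=S)


@dataclass
class IbcfResults:
    matrix: pd.DataFrame
    Z: pd.DataFrame
    mu: pd.Series
    sigma: pd.Series
    similarity: pd.DataFrame

    def predict_missing(self, neighborhood="all", restrict_to_other_envs: bool = False,
                        denominator: str = "signed", drop_negative: bool = False,
                        ) -> pd.DataFrame:
        """Predictions for every missing cell, as a long frame
        (line, trait, env, predicted, n_neighbors, flagged)."""
        if denominator not in ("signed", "abs"):
            raise ValueError("denominator must be 'signed' or 'abs'")
        records = []
        for col in self.Z.columns:
            trait, env = col
            targets = self.Z.index[self.Z[col].isna()]
            if len(targets) == 0:
                continue
            weights = self.similarity[col]
            if restrict_to_other_envs:
                weights = weights[[c for c in weights.index if c[1] != env]]
            for line in targets:
                zrow = self.Z.loc[line].drop(index=[col], errors="ignore")
                zhat = _neighborhood_predict(zrow, weights, neighborhood,
                                             denominator, drop_negative)
                flagged = np.isnan(zhat) and zrow.notna().any()
                records.append({
                    "line": line, "trait": trait, "env": env,
                    "predicted": self.mu[col] + self.sigma[col] * zhat,
                    "n_neighbors": int(zrow.reindex(weights.dropna().index).notna().sum()),
                    "flagged": bool(flagged),
                })
        return pd.DataFrame.from_records(
            records, columns=["line", "trait", "env", "predicted", "n_neighbors", "flagged"])

    def summary(self) -> str:
        n, m = self.matrix.shape
        frac = float(self.matrix.isna().to_numpy().mean())
        return (f"IBCF: {n} lines x {m} items, {frac:.1%} missing\n"
                f"  mean |item-item weight| = "
                f"{np.nanmean(np.abs(self.similarity.to_numpy())):.3f}")


def predict_missing(M: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Convenience wrapper: fit on ``M`` and predict its missing cells."""
    return Ibcf(M).fit().predict_missing(**kwargs)


def _predict_held_out(M: pd.DataFrame, cols: list[tuple], hold_lines,
                      **predict_kwargs) -> pd.DataFrame:
    """Mask the given lines in the target columns, refit, and return
    (line, trait, env, predicted, observed) rows for the held-out cells."""
    masked = M.copy()
    held = {}
    for c in cols:
        obs = M[c].dropna()
        obs = obs[obs.index.isin(hold_lines)]
        held[c] = obs
        masked.loc[obs.index, c] = np.nan
    if all(v.empty for v in held.values()):
        raise ValueError("nothing to hold out: target cells already missing")
    preds = Ibcf(masked).fit().predict_missing(**predict_kwargs)
    rows = []
    for (trait, env) in cols:
        obs = held[(trait, env)]
        sub = preds[(preds["trait"] == trait) & (preds["env"] == env)].set_index("line")
        for line in obs.index.intersection(sub.index):
            rows.append({"line": line, "trait": trait, "env": env,
                         "predicted": sub.at[line, "predicted"],
                         "observed": obs[line]})
    return pd.DataFrame(rows)


def cv2_evaluate(M: pd.DataFrame, target_env: str,
                 target_traits: list[str] | None = None,
                 k_folds: int = 5, n_repetitions: int = 1, seed: int = 0,
                 lines: list | None = None,
                 **predict_kwargs) -> pd.DataFrame:
    """Incomplete-field-trial evaluation: predict target traits in one
    environment for held-out line folds, training on those lines' records
    in the other environments plus all records of the remaining lines.

    Lines are split into ``k_folds`` folds (the same counter-based stream
    as the GBLUP cross-validation, so accuracies are paired for a given
    seed); each fold is masked in the target columns in turn and predicted
    from every other item.  ``lines`` instead supplies an explicit hold-out
    set (single evaluation, no folds).  Returns per-(trait, repetition)
    Pearson correlations of predicted vs held-out observed values.
    """
    from .gblup import cv_partitions

    M = _check_matrix(M)
    envs = {c[1] for c in M.columns}
    if target_env not in envs:
        raise ValueError(f"environment {target_env!r} absent from the matrix")
    if len(envs) < 3:
        raise ValueError("need >= 2 non-target environments")
    if target_traits is None:
        target_traits = sorted({c[0] for c in M.columns if c[1] == target_env})
    cols = [(t, target_env) for t in target_traits]
    missing_cols = [c for c in cols if c not in M.columns]
    if missing_cols:
        raise ValueError(f"target columns absent: {missing_cols}")

    all_lines = list(M.index)
    rows = []
    for rep in range(n_repetitions):
        if lines is not None:
            parts = [np.array([all_lines.index(l) for l in lines])]
        else:
            parts = cv_partitions(all_lines, k_folds, seed, rep)
        pieces = [
            _predict_held_out(M, cols, {all_lines[i] for i in fold}, **predict_kwargs)
            for fold in parts
        ]
        pooled = pd.concat(pieces, ignore_index=True)
        for (trait, env) in cols:
            sub = pooled[(pooled["trait"] == trait) & (pooled["env"] == env)]
            pr = sub["predicted"].to_numpy(float)
            ob = sub["observed"].to_numpy(float)
            ok = ~np.isnan(pr)
            r = (float(np.corrcoef(pr[ok], ob[ok])[0, 1])
                 if ok.sum() >= 3 and np.std(pr[ok]) > 0 and np.std(ob[ok]) > 0
                 else np.nan)
            rows.append({"trait": trait, "env": env, "repetition": rep,
                         "correlation": r, "n_held_out": int(ok.sum())})
        if lines is not None:
            break
    return pd.DataFrame(rows)
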