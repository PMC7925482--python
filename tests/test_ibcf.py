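"""Item-based collaborative filtering: standardization, similarities,
prediction formula, and the environment hold-out evaluation."""

import numpy as np
import pandas as pd
import pytest

import strigakit as sk
from strigakit.ibcf import Ibcf, IbcfResults, item_similarity, standardize
from strigakit.simulate import simulate_multi_trait_panel


def mcols(pairs):
    return pd.MultiIndex.from_tuples(pairs, names=["trait", "env"])


def small_matrix(seed=0, n=12, missing=None):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=n)
    cols = {
        ("t1", "e1"): base + rng.normal(0, 0.3, n),
        ("t1", "e2"): base + rng.normal(0, 0.3, n),
        ("t2", "e1"): -base + rng.normal(0, 0.3, n),
        ("t2", "e2"): base + rng.normal(0, 0.5, n),
    }
    M = pd.DataFrame(cols, index=[f"L{i}" for i in range(n)])
    M.columns = mcols(M.columns)
    if missing:
        for (line, col) in missing:
            M.loc[line, col] = np.nan
    return M


class TestStandardize:
    def test_hand_column_sample_sd(self):
        M = pd.DataFrame({("t", "e"): [1.0, 2.0, 3.0]}, index=list("abc"))
        M.columns = mcols(M.columns)
        Z, mu, sigma = standardize(M)
        assert mu.iloc[0] == 2.0
        assert sigma.iloc[0] == 1.0  # sample SD with n-1
        assert np.allclose(Z.iloc[:, 0], [-1.0, 0.0, 1.0])

    def test_idempotent_on_standardized_input(self):
        M = small_matrix(1)
        Z, _, _ = standardize(M)
        Z2, mu2, s2 = standardize(Z)
        assert np.allclose(Z2, Z, atol=1e-12)
        assert np.allclose(mu2, 0.0, atol=1e-12)
        assert np.allclose(s2, 1.0, atol=1e-12)

    def test_round_trip_on_observed_cells(self):
        M = small_matrix(2, missing=[("L0", ("t1", "e2"))])
        Z, mu, sigma = standardize(M)
        back = mu + sigma * Z
        pd.testing.assert_frame_equal(back, M.loc[:, Z.columns])

    def test_constant_column_dropped_with_warning(self):
        M = small_matrix(3)
        M[("t3", "e1")] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            Z, _, _ = standardize(M)
        assert ("t3", "e1") not in Z.columns


class TestSimilarity:
    def test_identical_and_negated_columns(self):
        M = small_matrix(4)
        Z, _, _ = standardize(M)
        S = item_similarity(Z)
        # t1@e1 vs t2@e1 is built as the negation plus noise
        assert S.loc[("t1", "e1"), ("t2", "e1")] < -0.8
        M2 = M.copy()
        M2[("t3", "e1")] = M[("t1", "e1")]
        Z2, _, _ = standardize(M2)
        S2 = item_similarity(Z2)
        assert S2.loc[("t1", "e1"), ("t3", "e1")] == pytest.approx(1.0)
        assert np.isnan(S2.loc[("t1", "e1"), ("t1", "e1")])  # no self-neighbor

    def test_matches_brute_force_pairwise_correlation(self):
        M = small_matrix(5, missing=[("L1", ("t1", "e1")), ("L3", ("t2", "e2"))])
        Z, _, _ = standardize(M)
        S = item_similarity(Z)
        cols = list(Z.columns)
        for a in range(len(cols)):
            for b in range(a + 1, len(cols)):
                x, y = Z[cols[a]], Z[cols[b]]
                ok = x.notna() & y.notna()
                expected = np.corrcoef(x[ok], y[ok])[0, 1]
                assert S.loc[cols[a], cols[b]] == pytest.approx(expected, abs=1e-12)


class TestPredict:
    def _results(self, Z, similarity, mu=None, sigma=None):
        cols = Z.columns
        mu = pd.Series(0.0, index=cols) if mu is None else mu
        sigma = pd.Series(1.0, index=cols) if sigma is None else sigma
        M = mu + sigma * Z
        return IbcfResults(matrix=M, Z=Z, mu=mu, sigma=sigma, similarity=similarity)

    def test_perfect_correlation_transfer(self):
        """Two items with weight 1: the observed z carries over, and the
        prediction de-standardizes with the target's mu and sigma."""
        cols = mcols([("t1", "e1"), ("t1", "e2")])
        Z = pd.DataFrame([[1.2, np.nan]], columns=cols, index=["L0"])
        S = pd.DataFrame([[np.nan, 1.0], [1.0, np.nan]], index=cols, columns=cols)
        mu = pd.Series([0.0, 7.0], index=cols)
        sigma = pd.Series([1.0, 2.0], index=cols)
        preds = self._results(Z, S, mu, sigma).predict_missing()
        assert len(preds) == 1
        assert preds["predicted"].iloc[0] == pytest.approx(7.0 + 1.2 * 2.0)

    def test_equal_weights_give_mean(self):
        cols = mcols([("t1", "e1"), ("t2", "e1"), ("t3", "e1"), ("t4", "e1")])
        Z = pd.DataFrame([[np.nan, 0.3, 0.9, -0.6]], columns=cols, index=["L0"])
        S = pd.DataFrame(0.5, index=cols, columns=cols)
        np.fill_diagonal(S.values, np.nan)
        preds = self._results(Z, S).predict_missing()
        assert preds["predicted"].iloc[0] == pytest.approx(np.mean([0.3, 0.9, -0.6]))

    def test_weighted_formula_arithmetic(self):
        """Weights (0.9, 0.3) on z = (1.0, -0.5):
        z_hat = (0.9 - 0.15) / 1.2 = 0.625."""
        cols = mcols([("t1", "e1"), ("t2", "e1"), ("t3", "e1")])
        Z = pd.DataFrame([[np.nan, 1.0, -0.5]], columns=cols, index=["L0"])
        S = pd.DataFrame(np.nan, index=cols, columns=cols)
        S.loc[("t1", "e1"), ("t2", "e1")] = S.loc[("t2", "e1"), ("t1", "e1")] = 0.9
        S.loc[("t1", "e1"), ("t3", "e1")] = S.loc[("t3", "e1"), ("t1", "e1")] = 0.3
        preds = self._results(Z, S).predict_missing()
        assert preds["predicted"].iloc[0] == pytest.approx(0.625)

    def test_single_neighbor_weight_cancels(self):
        """With one neighbor the weight cancels in the ratio: under the
        signed denominator the prediction is independent of w entirely;
        under the absolute-value variant only the sign of w survives."""
        cols = mcols([("t1", "e1"), ("t2", "e1")])
        for w in (0.9, 0.2, -0.4):
            Z = pd.DataFrame([[np.nan, 1.2]], columns=cols, index=["L0"])
            S = pd.DataFrame([[np.nan, w], [w, np.nan]], index=cols, columns=cols)
            signed = self._results(Z, S).predict_missing()
            assert signed["predicted"].iloc[0] == pytest.approx(1.2)
            absval = self._results(Z, S).predict_missing(denominator="abs")
            assert absval["predicted"].iloc[0] == pytest.approx(np.sign(w) * 1.2)

    def test_near_zero_weight_sum_flagged(self):
        cols = mcols([("t1", "e1"), ("t2", "e1"), ("t3", "e1")])
        Z = pd.DataFrame([[np.nan, 1.0, 1.0]], columns=cols, index=["L0"])
        S = pd.DataFrame(np.nan, index=cols, columns=cols)
        S.loc[("t1", "e1"), ("t2", "e1")] = S.loc[("t2", "e1"), ("t1", "e1")] = 0.5
        S.loc[("t1", "e1"), ("t3", "e1")] = S.loc[("t3", "e1"), ("t1", "e1")] = -0.5
        preds = self._results(Z, S).predict_missing()
        assert np.isnan(preds["predicted"].iloc[0])
        assert bool(preds["flagged"].iloc[0])
        # the absolute-denominator variant remains defined
        preds_abs = self._results(Z, S).predict_missing(denominator="abs")
        assert preds_abs["predicted"].iloc[0] == pytest.approx(0.0)

    def test_top_k_neighborhood(self):
        cols = mcols([("t1", "e1"), ("t2", "e1"), ("t3", "e1")])
        Z = pd.DataFrame([[np.nan, 1.0, -0.5]], columns=cols, index=["L0"])
        S = pd.DataFrame(np.nan, index=cols, columns=cols)
        S.loc[("t1", "e1"), ("t2", "e1")] = S.loc[("t2", "e1"), ("t1", "e1")] = 0.9
        S.loc[("t1", "e1"), ("t3", "e1")] = S.loc[("t3", "e1"), ("t1", "e1")] = 0.3
        preds = self._results(Z, S).predict_missing(neighborhood=1)
        assert preds["predicted"].iloc[0] == pytest.approx(1.0)  # only the 0.9 item

    def test_restrict_to_other_envs(self):
        cols = mcols([("t1", "e1"), ("t2", "e1"), ("t1", "e2")])
        Z = pd.DataFrame([[np.nan, 1.0, -0.5]], columns=cols, index=["L0"])
        S = pd.DataFrame(0.8, index=cols, columns=cols)
        np.fill_diagonal(S.values, np.nan)
        preds = self._results(Z, S).predict_missing(restrict_to_other_envs=True)
        # only t1@e2 is an eligible neighbor for the e1 target
        assert preds.set_index(["trait", "env"]).loc[("t1", "e1"), "predicted"] \
            == pytest.approx(-0.5)

    def test_affine_equivariance_of_target_column(self):
        """Scaling and shifting the target column transforms its predictions
        identically (positive scale under the signed denominator)."""
        M = small_matrix(6, missing=[("L0", ("t1", "e2")), ("L5", ("t1", "e2"))])
        p1 = Ibcf(M).fit().predict_missing()
        M2 = M.copy()
        M2[("t1", "e2")] = 3.0 * M2[("t1", "e2")] + 10.0
        p2 = Ibcf(M2).fit().predict_missing()
        a = p1[(p1["trait"] == "t1") & (p1["env"] == "e2")]["predicted"].to_numpy()
        b = p2[(p2["trait"] == "t1") & (p2["env"] == "e2")]["predicted"].to_numpy()
        assert np.allclose(b, 3.0 * a + 10.0, rtol=1e-10)


class TestCv2Evaluate:
    def test_high_cross_env_correlation_recovers(self, clean_grm):
        """Phenotypic cross-environment correlation ~0.9: hold-out recovery
        is high."""
        wide = simulate_multi_trait_panel(clean_grm, n_traits=4, trait_corr=0.9,
                                          env_corr=0.95, h2=0.95, seed=63)
        res = sk.cv2_evaluate(wide, "env2", n_repetitions=2, seed=4)
        assert res["correlation"].mean() >= 0.8

    def test_orthogonal_target_has_no_transfer(self, clean_grm):
        wide = simulate_multi_trait_panel(clean_grm, n_traits=4, trait_corr=0.0,
                                          env_corr=0.05, h2=0.5, seed=64)
        res = sk.cv2_evaluate(wide, "env2", target_traits=["trait1"],
                              n_repetitions=2, seed=4)
        assert abs(res["correlation"].mean()) < 0.25

    def test_refuses_when_nothing_to_mask(self):
        M = small_matrix(7)
        M[("t1", "e3")] = np.nan
        M[("t2", "e3")] = np.nan
        with pytest.raises(ValueError, match="nothing to hold out"):
            sk.cv2_evaluate(M, "e3")

    def test_needs_three_environments(self):
        M = small_matrix(8)
        with pytest.raises(ValueError, match="environments"):
            sk.cv2_evaluate(M, "e2")

    def test_explicit_line_mask(self, clean_grm):
        wide = simulate_multi_trait_panel(clean_grm, n_traits=3, trait_corr=0.8,
                                          env_corr=0.9, h2=0.8, seed=65)
        subset = list(wide.index[:40])
        res = sk.cv2_evaluate(wide, "env1", target_traits=["trait1"], lines=subset)
        assert res["n_held_out"].iloc[0] == 40
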