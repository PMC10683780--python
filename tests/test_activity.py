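"""Activity methods against independent closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grnbench import (
    CollinearityError,
    DataError,
    ExpressionMatrix,
    RegulonSet,
    build_weight_matrix,
    compute_activities,
    consensus_activity,
    mlm_activity,
    ulm_activity,
    viper_activity,
    wmean_activity,
    wsum_activity,
)
from grnbench.activity import ActivityMatrix, RegulonWeights


def _expr(arr, genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"G{i}" for i in range(arr.shape[0])]
    samples = samples or [f"S{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples))


def _weights(signed, genes=None, regs=None):
    signed = np.asarray(signed, dtype=float)
    genes = genes or [f"G{i}" for i in range(signed.shape[0])]
    regs = regs or [f"R{i}" for i in range(signed.shape[1])]
    mk = lambda a: pd.DataFrame(a, index=genes, columns=regs)
    return RegulonWeights(mk(signed), mk(np.abs(signed)), mk(np.sign(signed)))


def _ols_t(y, X):
    """Normal-equation oracle: t-values of an OLS fit with intercept."""
    M = np.column_stack([np.ones(len(y)), X])
    MtM_inv = np.linalg.inv(M.T @ M)
    beta = MtM_inv @ M.T @ y
    resid = y - M @ beta
    dof = len(y) - M.shape[1]
    sigma2 = resid @ resid / dof
    return beta / np.sqrt(sigma2 * np.diag(MtM_inv))


class TestWeightMatrix:
    def test_min_targets_drops_regulator(self, small_expr, two_reg_regulon):
        edges = two_reg_regulon.edges.copy()
        edges.loc[edges["regulator"] == "R1", "target"] = ["G1", "ZZ1", "ZZ2"]
        rs = RegulonSet(edges, source="synthetic")
        w = build_weight_matrix(rs, small_expr, min_targets=2)
        assert list(w.regulators) == ["R2"]
        assert w.log["regulators_kept"] == 1

    def test_single_target_retained_at_min_one(self, small_expr):
        rs = RegulonSet(pd.DataFrame([("R", "G1", 0.7, -1.0)],
                                     columns=["regulator", "target", "weight", "mor"]),
                        source="synthetic")
        w = build_weight_matrix(rs, small_expr, min_targets=1)
        assert w.signed.loc["G1", "R"] == pytest.approx(-0.7)

    def test_dense_matrix_matches_hand_layout(self, small_expr, two_reg_regulon):
        w = build_weight_matrix(two_reg_regulon, small_expr, min_targets=1)
        expected = np.array([
            [1.0, 0.0], [-0.5, 0.0], [0.8, 0.0],
            [0.0, 0.9], [0.0, 0.7], [0.0, -1.0]])
        assert np.allclose(w.signed.to_numpy(), expected)

    def test_no_survivor_is_error(self, small_expr, two_reg_regulon):
        with pytest.raises(DataError):
            build_weight_matrix(two_reg_regulon, small_expr, min_targets=5)


class TestUlm:
    def test_orthogonal_weight_gives_zero(self):
        expr = _expr(np.array([[3.0], [3.0], [5.0], [7.0]]))
        w = _weights(np.array([[1.0], [-1.0], [0.0], [0.0]]))
        t = ulm_activity(expr, w).values.iloc[0, 0]
        assert t == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            G = 30
            x = rng.standard_normal(G)
            wv = rng.standard_normal(G)
            t = ulm_activity(_expr(x[:, None]), _weights(wv[:, None])).values.iloc[0, 0]
            assert t == pytest.approx(_ols_t(x, wv[:, None])[1], abs=1e-8)

    def test_perfect_fit_capped(self):
        wv = np.array([1.0, -1.0, 0.5, 2.0])
        expr = _expr((3 * wv + 1)[:, None])
        am = ulm_activity(expr, _weights(wv[:, None]))
        assert am.values.iloc[0, 0] == pytest.approx(1e6)
        assert am.log["capped_perfect_fit"] == 1

    def test_zero_variance_weights_missing(self):
        expr = _expr(np.random.default_rng(0).standard_normal((5, 2)))
        w = _weights(np.ones((5, 1)))
        am = ulm_activity(expr, w)
        assert am.values.isna().all().all()
        assert am.log["zero_variance_weight_vectors"] == 1


class TestMlm:
    def test_matches_joint_ols_oracle(self):
        rng = np.random.default_rng(13)
        G, p, S = 40, 4, 3
        W = rng.standard_normal((G, p))
        X = rng.standard_normal((G, S))
        am = mlm_activity(_expr(X), _weights(W))
        for s in range(S):
            oracle = _ols_t(X[:, s], W)[1:]
            assert np.allclose(am.values.iloc[:, s], oracle, atol=1e-8)

    def test_orthogonal_weights_share_slopes_with_ulm(self):
        # orthogonal columns: joint slope estimates coincide with marginal ones
        G = 10
        w1 = np.zeros(G); w1[:5] = [1, -1, 2, -2, 0]    # zero-sum blocks with
        w2 = np.zeros(G); w2[5:] = [1, 1, -1, -1, 0]    # disjoint support
        assert abs(w1 @ w2) < 1e-12
        rng = np.random.default_rng(4)
        x = rng.standard_normal(G)
        joint = np.linalg.lstsq(np.column_stack([np.ones(G), w1, w2]), x, rcond=None)[0]
        for i, wv in enumerate([w1, w2]):
            marginal = np.linalg.lstsq(np.column_stack([np.ones(G), wv]), x, rcond=None)[0]
            assert joint[i + 1] == pytest.approx(marginal[1], abs=1e-10)

    def test_duplicate_regulators_raise_collinearity(self):
        G = 12
        rng = np.random.default_rng(5)
        wv = rng.standard_normal(G)
        W = np.column_stack([wv, wv])
        with pytest.raises(CollinearityError, match="R0~R1"):
            mlm_activity(_expr(rng.standard_normal((G, 2))), _weights(W))

    def test_null_t_values_calibrated(self):
        """Expression independent of the weights: t-values behave like t-draws."""
        rng = np.random.default_rng(7)
        G, p, n_samples = 200, 3, 100
        W = rng.standard_normal((G, p))
        X = rng.standard_normal((G, n_samples))
        am = mlm_activity(_expr(X), _weights(W))
        t = am.values.to_numpy()
        dof = G - (p + 1)
        expected_abs = stats.t(dof).expect(lambda v: abs(v))
        assert abs(np.mean(np.abs(t)) - expected_abs) < 0.1
        crit = stats.t(dof).ppf(1 - 0.025 / p)  # Bonferroni over regulators
        family_reject = (np.abs(t) > crit).any(axis=0).mean()
        assert family_reject <= 0.10


class TestViper:
    def test_constant_expression_gives_zero(self):
        expr = _expr(np.full((9, 2), 3.0))
        w = _weights(np.random.default_rng(0).standard_normal((9, 2)))
        am = viper_activity(expr, w)
        assert np.allclose(am.values, 0.0)

    def test_single_top_target_nes_is_normal_quantile(self):
        G = 9
        x = np.arange(1.0, G + 1)  # target G8 is top-ranked
        signed = np.zeros((G, 1)); signed[-1, 0] = 1.0
        am = viper_activity(_expr(x[:, None]), _weights(signed))
        assert am.values.iloc[0, 0] == pytest.approx(stats.norm.ppf(0.9), abs=1e-12)

    def test_mor_negation_flips_scores(self):
        rng = np.random.default_rng(8)
        G = 30
        X = rng.standard_normal((G, 4))
        signed = np.zeros((G, 2))
        signed[rng.choice(G, 10, replace=False), 0] = rng.uniform(0.5, 1, 10)
        signed[rng.choice(G, 10, replace=False), 1] = -rng.uniform(0.5, 1, 10)
        a1 = viper_activity(_expr(X), _weights(signed))
        a2 = viper_activity(_expr(X), _weights(-signed))
        assert np.allclose(a1.values, -a2.values, atol=1e-12)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(9)
        G, S = 25, 3
        X = rng.standard_normal((G, S))
        weight = np.zeros((G, 1)); mor = np.zeros((G, 1))
        tgt = rng.choice(G, 8, replace=False)
        weight[tgt, 0] = rng.uniform(0.2, 1, 8)
        mor[tgt, 0] = rng.choice([-1.0, 1.0, 0.5], 8)
        genes = [f"G{i}" for i in range(G)]
        mk = lambda a: pd.DataFrame(a, index=genes, columns=["R0"])
        w = RegulonWeights(mk(weight * mor), mk(weight), mk(mor))
        am = viper_activity(_expr(X, genes=genes), w)
        for s in range(S):
            r = stats.rankdata(X[:, s])
            q2 = stats.norm.ppf(r / (G + 1))
            q1 = stats.norm.ppf(0.5 + np.abs(r / (G + 1) - 0.5))
            num = sum(weight[i, 0] * mor[i, 0] * q2[i]
                      + weight[i, 0] * (1 - abs(mor[i, 0])) * q1[i] for i in tgt)
            es = num / weight[tgt, 0].sum()
            nes = es * np.sqrt((weight[tgt, 0] / weight[tgt, 0].max()).sum())
            assert am.values.iloc[0, s] == pytest.approx(nes, abs=1e-10)


class TestWsumWmean:
    def test_two_term_arithmetic(self):
        expr = _expr(np.array([[2.0], [1.0]]))
        w = _weights(np.array([[1.0], [-1.0]]))
        assert wsum_activity(expr, w).values.iloc[0, 0] == pytest.approx(1.0)
        assert wmean_activity(expr, w).values.iloc[0, 0] == pytest.approx(0.5)

    def test_constant_weights_reduce_to_mean(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(0, 5, size=(6, 3))
        w = _weights(np.full((6, 1), 0.5))
        am = wmean_activity(_expr(v), w)
        assert np.allclose(am.values.to_numpy()[0], v.mean(axis=0))

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(20)
        G, p, S = 20, 3, 4
        W = rng.standard_normal((G, p)) * (rng.random((G, p)) < 0.4)
        X = rng.standard_normal((G, S))
        ws = wsum_activity(_expr(X), _weights(W)).values.to_numpy()
        wm = wmean_activity(_expr(X), _weights(W)).values.to_numpy()
        for r in range(p):
            for s in range(S):
                acc = sum(W[g, r] * X[g, s] for g in range(G))
                assert abs(ws[r, s] - acc) < 1e-12
                assert abs(wm[r, s] - acc / sum(abs(W[g, r]) for g in range(G))) < 1e-12

    def test_scale_equivariance(self):
        rng = np.random.default_rng(21)
        X = rng.standard_normal((15, 5))
        W = rng.standard_normal((15, 2)) * (rng.random((15, 2)) < 0.5)
        W[:, 0][W[:, 0] == 0] = 0.0
        c = 3.7
        W2 = W.copy(); W2[:, 0] *= c
        ws1 = wsum_activity(_expr(X), _weights(W)).values
        ws2 = wsum_activity(_expr(X), _weights(W2)).values
        assert np.allclose(ws2.iloc[0], c * ws1.iloc[0], atol=1e-10)
        wm1 = wmean_activity(_expr(X), _weights(W)).values
        wm2 = wmean_activity(_expr(X), _weights(W2)).values
        assert np.allclose(wm2.iloc[0], wm1.iloc[0], atol=1e-10)
        u1 = ulm_activity(_expr(X), _weights(W)).values
        u2 = ulm_activity(_expr(X), _weights(W2)).values
        assert np.allclose(u1.iloc[0], u2.iloc[0], atol=1e-8)


class TestConsensus:
    def _am(self, arr, method):
        return ActivityMatrix(pd.DataFrame(
            np.asarray(arr, dtype=float),
            index=[f"R{i}" for i in range(len(arr))],
            columns=[f"S{j}" for j in range(len(arr[0]))]), method=method)

    def test_identical_inputs_give_standardized_matrix(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal((4, 3))
        z = (v - v.mean(axis=0)) / v.std(axis=0)
        cons = consensus_activity([self._am(v, "a"), self._am(v, "b")])
        assert np.allclose(cons.values, z, atol=1e-12)

    def test_zscore_negations_cancel(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal((5, 2))
        cons = consensus_activity([self._am(v, "a"), self._am(-v, "b")])
        assert np.allclose(cons.values, 0.0, atol=1e-12)

    def test_three_method_hand_computation(self):
        a = [[1.0, 0.0], [2.0, 1.0], [3.0, 2.0], [4.0, 3.0]]
        b = [[4.0, 2.0], [3.0, 2.0], [2.0, 2.0], [1.0, 2.0]]
        c = [[0.0, 1.0], [0.0, 1.0], [0.0, 5.0], [0.0, 1.0]]
        mats = [np.asarray(m) for m in (a, b, c)]
        zs = []
        for m in mats:
            mu, sd = m.mean(axis=0), m.std(axis=0)
            z = np.zeros_like(m)
            nz = sd > 0
            z[:, nz] = (m[:, nz] - mu[nz]) / sd[nz]
            zs.append(z)
        expected = np.mean(zs, axis=0)
        cons = consensus_activity([self._am(m, t) for m, t in zip(mats, "abc")])
        assert np.allclose(cons.values, expected, atol=1e-12)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(DataError):
            consensus_activity([self._am([[1, 2]], "a"),
                                self._am([[1, 2], [3, 4]], "b")])


def test_null_scores_center_on_zero():
    """Pure-noise expression independent of the regulon: every method's mean
    score across repeated draws is 0 within Monte-Carlo error."""
    rng = np.random.default_rng(123)
    G, p = 60, 3
    W = rng.standard_normal((G, p)) * (rng.random((G, p)) < 0.3)
    scores = {m: [] for m in ("ulm", "mlm", "viper", "wsum", "wmean")}
    reps, S = 100, 5
    for _ in range(reps):
        X = rng.standard_normal((G, S))
        w = _weights(W)
        acts = compute_activities(_expr(X), w,
                                  methods=("ulm", "mlm", "viper", "wsum", "wmean"))
        for m, am in acts.items():
            scores[m].append(am.values.to_numpy().ravel())
    for m, chunks in scores.items():
        v = np.concatenate(chunks)
        # |mean| within 4 standard errors of 0
        assert abs(v.mean()) < 4 * v.std() / np.sqrt(len(v)), m
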