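"""Dense co-attention layer semantics against hand computations and a
scalar-loop oracle that uses no matrix library calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcafusion.autograd import Tensor
from dcafusion.dca import (DCAStack, DCAWeights, affinity, attend,
                           attention_maps, dca_layer, reshape_to_dca,
                           stacked_dca)

# ---------------------------------------------------------------------------
# scalar-loop oracle: plain Python floats, no vectorized calls
# ---------------------------------------------------------------------------

def oracle_affinity(e, m, w):
    d, n_e, n_m = len(e), len(e[0]), len(m[0])
    a = [[0.0] * n_m for _ in range(n_e)]
    for r in range(n_e):
        for c in range(n_m):
            s = 0.0
            for k in range(d):
                for l in range(d):
                    s += e[k][r] * w[k][l] * m[l][c]
            a[r][c] = s
    return a


def oracle_row_softmax(a):
    import math
    out = []
    for row in a:
        mx = max(row)
        ex = [math.exp(v - mx) for v in row]
        z = sum(ex)
        out.append([v / z for v in ex])
    return out


def oracle_dca_layer(m, e, w):
    d, n_m, n_e = len(m), len(m[0]), len(e[0])
    a = oracle_affinity(e, m, w["W"].tolist())
    a_m = oracle_row_softmax(a)
    a_e = oracle_row_softmax([[a[r][c] for r in range(n_e)] for c in range(n_m)])
    # P_M = M A_M^T ; P_E = E A_E^T
    p_m = [[sum(m[k][j] * a_m[i][j] for j in range(n_m)) for i in range(n_e)]
           for k in range(d)]
    p_e = [[sum(e[k][j] * a_e[i][j] for j in range(n_e)) for i in range(n_m)]
           for k in range(d)]
    w_m, w_e = w["W_M"].tolist(), w["W_E"].tolist()
    b_m, b_e = w["b_M"].tolist(), w["b_E"].tolist()
    m_new = [[0.0] * n_m for _ in range(d)]
    e_new = [[0.0] * n_e for _ in range(d)]
    for k in range(d):
        for c in range(n_m):
            s = b_m[k][0]
            for l in range(d):
                s += w_m[k][l] * m[l][c] + w_m[k][d + l] * p_e[l][c]
            m_new[k][c] = max(s, 0.0) + m[k][c]
        for c in range(n_e):
            s = b_e[k][0]
            for l in range(d):
                s += w_e[k][l] * e[l][c] + w_e[k][d + l] * p_m[l][c]
            e_new[k][c] = max(s, 0.0) + e[k][c]
    return np.array(m_new), np.array(e_new)


def random_instance(rng, d=None, n_m=None, n_e=None):
    d = d or rng.integers(1, 9)
    n_m = n_m or rng.integers(1, 7)
    n_e = n_e or rng.integers(1, 7)
    m = rng.normal(size=(d, n_m))
    e = rng.normal(size=(d, n_e))
    w = DCAWeights.random(int(d), 1, rng).layers[0]
    w["b_M"] = rng.normal(size=(d, 1))
    w["b_E"] = rng.normal(size=(d, 1))
    return m, e, w


class TestAffinity:
    def test_hand_example(self):
        a = affinity(np.array([[1.0, 2.0]]), np.array([[3.0]]), np.array([[1.0]]))
        assert np.allclose(a, [[3.0], [6.0]])

    def test_zero_weight_annihilates(self, rng):
        e, m = rng.normal(size=(3, 2)), rng.normal(size=(3, 4))
        assert np.allclose(affinity(e, m, np.zeros((3, 3))), 0.0)

    def test_matches_loop_oracle(self, rng):
        e, m = rng.normal(size=(4, 3)), rng.normal(size=(4, 5))
        w = rng.normal(size=(4, 4))
        a = affinity(e, m, w)
        assert a.shape == (3, 5)
        assert np.allclose(a, oracle_affinity(e.tolist(), m.tolist(),
                                              w.tolist()), atol=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            affinity(rng.normal(size=(3, 2)), rng.normal(size=(4, 5)),
                     rng.normal(size=(3, 3)))


class TestAttentionMaps:
    def test_uniform_for_zero_affinity(self):
        a_m, a_e = attention_maps(np.zeros((2, 3)))
        assert np.allclose(a_m, 1.0 / 3)
        assert np.allclose(a_e, 1.0 / 2)
        assert a_m.shape == (2, 3) and a_e.shape == (3, 2)

    def test_closed_form_softmax(self):
        a_m, _ = attention_maps(np.array([[0.0, np.log(2.0)]]))
        assert np.allclose(a_m, [[1 / 3, 2 / 3]])

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            attention_maps(np.array([[np.nan, 0.0]]))

    @settings(deadline=None, max_examples=30)
    @given(st.integers(1, 5), st.integers(1, 5), st.integers(0, 10_000))
    def test_rows_stochastic(self, n_e, n_m, seed):
        a = np.random.default_rng(seed).normal(scale=30.0, size=(n_e, n_m))
        a_m, a_e = attention_maps(a)
        for maps in (a_m, a_e):
            assert np.all(maps >= 0) and np.all(maps <= 1)
            assert np.allclose(maps.sum(axis=1), 1.0, atol=1e-6)


class TestAttend:
    def test_uniform_attention_averages_columns(self, rng):
        m = rng.normal(size=(4, 5))
        e = rng.normal(size=(4, 2))
        a_m = np.full((2, 5), 1 / 5)
        a_e = np.full((5, 2), 1 / 2)
        p_m, p_e = attend(m, e, a_m, a_e)
        assert np.allclose(p_m, np.tile(m.mean(axis=1, keepdims=True), (1, 2)))
        assert np.allclose(p_e, np.tile(e.mean(axis=1, keepdims=True), (1, 5)))

    def test_one_hot_attention_selects_columns(self, rng):
        m = rng.normal(size=(3, 4))
        e = rng.normal(size=(3, 2))
        a_m = np.array([[0, 0, 1, 0], [1, 0, 0, 0]], dtype=float)
        a_e = np.array([[0, 1]] * 4, dtype=float)
        p_m, p_e = attend(m, e, a_m, a_e)
        assert np.allclose(p_m, m[:, [2, 0]])
        assert np.allclose(p_e, e[:, [1, 1, 1, 1]])

    def test_shapes(self, rng):
        m, e, w = random_instance(rng, 4, 5, 3)
        a_m, a_e = attention_maps(affinity(e, m, w["W"]))
        p_m, p_e = attend(m, e, a_m, a_e)
        assert p_m.shape == (4, 3) and p_e.shape == (4, 5)


class TestDCALayer:
    def test_zero_weights_identity(self, rng):
        m, e = rng.normal(size=(5, 3)), rng.normal(size=(5, 2))
        w = DCAWeights.zeros(5, 1).layers[0]
        m_i, e_i = dca_layer(m, e, w)
        assert np.array_equal(m_i, m) and np.array_equal(e_i, e)

    def test_matches_full_oracle(self, rng):
        for _ in range(10):
            m, e, w = random_instance(rng)
            m_i, e_i = dca_layer(m, e, w)
            m_o, e_o = oracle_dca_layer(m.tolist(), e.tolist(), w)
            assert np.allclose(m_i, m_o, atol=1e-8)
            assert np.allclose(e_i, e_o, atol=1e-8)

    def test_shape_preserved_for_random_draws(self, rng):
        for _ in range(20):
            m, e, w = random_instance(rng)
            m_i, e_i = dca_layer(m, e, w)
            assert m_i.shape == m.shape and e_i.shape == e.shape

    def test_residual_lower_bound(self, rng):
        """ReLU adds a nonnegative term, so outputs dominate inputs
        elementwise — always, by construction."""
        for _ in range(10):
            m, e, w = random_instance(rng)
            m_i, e_i = dca_layer(m, e, w)
            assert np.all(m_i - m >= 0)
            assert np.all(e_i - e >= 0)


class TestStack:
    def test_zero_layers_identity(self, rng):
        m, e = rng.normal(size=(3, 2)), rng.normal(size=(3, 4))
        m_n, e_n = stacked_dca(m, e, DCAWeights.zeros(3, 0))
        assert np.array_equal(m_n, m) and np.array_equal(e_n, e)

    def test_zero_weight_stack_identity_bitexact(self, rng):
        m, e = rng.normal(size=(4, 3)), rng.normal(size=(4, 2))
        for n in (1, 2, 5):
            m_n, e_n = stacked_dca(m, e, DCAWeights.zeros(4, n))
            assert np.array_equal(m_n, m) and np.array_equal(e_n, e)

    def test_composition_equals_manual_calls(self, rng):
        m, e = rng.normal(size=(4, 3)), rng.normal(size=(4, 2))
        w = DCAWeights.random(4, 3, rng)
        m_n, e_n = stacked_dca(m, e, w)
        mm, ee = m, e
        for layer in w.layers:
            mm, ee = dca_layer(mm, ee, layer)
        assert np.allclose(m_n, mm, atol=1e-12)
        assert np.allclose(e_n, ee, atol=1e-12)

    def test_module_agrees_with_functional(self, rng):
        stack = DCAStack(4, 2, rng=rng)
        m = rng.normal(size=(3, 4, 5))
        e = rng.normal(size=(3, 4, 2))
        m_t, e_t = stack(Tensor(m), Tensor(e))
        w = stack.export_weights()
        for b in range(3):
            m_f, e_f = stacked_dca(m[b], e[b], w)
            assert np.allclose(m_f, m_t.data[b], atol=1e-12)
            assert np.allclose(e_f, e_t.data[b], atol=1e-12)


class TestReshape:
    def test_divisible_reshape(self):
        v = np.arange(600.0)
        out = reshape_to_dca(v, 300)
        assert out.shape == (300, 2)
        assert out[0, 1] == 1.0  # row-major reassembly

    def test_identity_on_matching_shape(self, rng):
        x = rng.normal(size=(4, 3))
        assert np.array_equal(reshape_to_dca(x, 4), x)

    def test_indivisible_rejected_toward_projection_path(self):
        with pytest.raises(ValueError, match="projection"):
            reshape_to_dca(np.zeros(500), 300)

    def test_nonpositive_d_rejected(self):
        with pytest.raises(ValueError):
            reshape_to_dca(np.zeros(10), 0)
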