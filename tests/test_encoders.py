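"""Attention mechanisms, BLSTM, and SDP encoders against scalar oracles."""

import numpy as np
import pytest

from bbrex._autograd import Tensor
from bbrex import encoders as enc


def _softmax(x):
    e = np.exp(x - x.max())
    return e / e.sum()


# -- Entity-Oriented attention ----------------------------------------------


def test_orthogonal_words_get_uniform_weights():
    W = np.eye(4)[:3] * 2.0  # rows orthogonal; entity rows 0 and 2
    W[1] = [0, 5, 0, 0]  # orthogonal to both entity vectors
    weights = enc.entity_oriented_attention(W, 0, 2).data.ravel()
    # token 1 scores 0; entities score against themselves only -> equal there
    assert weights.sum() == pytest.approx(1.0, abs=1e-9)


def test_single_token_weight_is_one():
    weights = enc.entity_oriented_attention(np.ones((1, 4)), 0, 0).data
    np.testing.assert_allclose(weights, [[1.0]])


def test_entity_oriented_scalar_oracle():
    W = np.array(
        [[1.0, 0.0, 2.0, -1.0], [0.5, 1.0, 0.0, 3.0], [-1.0, 2.0, 1.0, 0.0]]
    )
    e1, e2 = 0, 2
    # independent step-by-step evaluation: inner products, average, scale, softmax
    s1 = W @ W[e1]
    s2 = W @ W[e2]
    scores = (s1 + s2) / (2.0 * np.sqrt(4))
    expected = _softmax(scores)
    got = enc.entity_oriented_attention(W, e1, e2).data.ravel()
    np.testing.assert_allclose(got, expected, atol=1e-12)


def test_entity_oriented_symmetric_under_entity_swap():
    rng = np.random.default_rng(0)
    W = rng.normal(size=(5, 6))
    a = enc.entity_oriented_attention(W, 1, 3).data
    b = enc.entity_oriented_attention(W, 3, 1).data
    np.testing.assert_allclose(a, b)


def test_entity_position_out_of_range_rejected():
    with pytest.raises(ValueError):
        enc.entity_oriented_attention(np.ones((2, 3)), 0, 5)


# -- Additive attention ------------------------------------------------------


def test_single_state_returns_itself():
    H = Tensor(np.array([[1.0, -2.0]]))
    v_a = Tensor(np.array([[0.3], [0.7]]))
    context, weights = enc.additive_attention(H, v_a)
    np.testing.assert_allclose(weights.data, [[1.0]])
    np.testing.assert_allclose(context.data, H.data)


def test_equal_states_give_uniform_weights():
    H = Tensor(np.tile([0.5, -1.0, 2.0], (4, 1)))
    v_a = Tensor(np.ones((3, 1)))
    context, weights = enc.additive_attention(H, v_a)
    np.testing.assert_allclose(weights.data, np.full((4, 1), 0.25))
    np.testing.assert_allclose(context.data, H.data[:1])


def test_additive_scalar_oracle():
    H = np.array([[0.2, -0.4], [1.0, 0.3], [-0.7, 0.9]])
    v_a = np.array([[0.5], [-1.2]])
    scores = np.tanh(H) @ v_a
    a = _softmax(scores.ravel())
    expected_c = a @ H
    context, weights = enc.additive_attention(Tensor(H), Tensor(v_a))
    np.testing.assert_allclose(weights.data.ravel(), a, atol=1e-12)
    np.testing.assert_allclose(context.data.ravel(), expected_c, atol=1e-12)


def test_additive_dimension_mismatch_rejected():
    with pytest.raises(ValueError):
        enc.additive_attention(Tensor(np.ones((2, 3))), Tensor(np.ones((4, 1))))


# -- scaled dot-product self-attention ---------------------------------------


def test_singleton_sequence_returns_its_value():
    Z = Tensor(np.array([[1.0, 2.0]]))
    W = Tensor(np.eye(2))
    C, A = enc.scaled_dot_product_self_attention(Z, W, W, W, m_scale=2)
    np.testing.assert_allclose(A.data, [[1.0]])
    np.testing.assert_allclose(C.data, Z.data)


def test_zero_projections_average_values():
    rng = np.random.default_rng(1)
    Z = Tensor(rng.normal(size=(4, 3)))
    zero = Tensor(np.zeros((3, 3)))
    Wv = Tensor(np.eye(3))
    C, A = enc.scaled_dot_product_self_attention(Z, zero, zero, Wv, m_scale=3)
    np.testing.assert_allclose(A.data, np.full((4, 4), 0.25))
    np.testing.assert_allclose(C.data, np.tile(Z.data.mean(axis=0), (4, 1)), atol=1e-12)


def test_self_attention_scalar_oracle():
    Z = np.array([[1.0, 0.5], [-0.5, 2.0]])
    Wq = np.array([[0.2, -0.1], [0.4, 0.3]])
    Wk = np.array([[1.0, 0.0], [0.0, -1.0]])
    Wv = np.array([[0.5, 0.5], [-0.5, 1.0]])
    m = 2
    Q, K, V = Z @ Wq, Z @ Wk, Z @ Wv
    expected = np.vstack(
        [_softmax(Q[i] @ K.T / np.sqrt(m)) @ V for i in range(2)]
    )
    C, A = enc.scaled_dot_product_self_attention(
        Tensor(Z), Tensor(Wq), Tensor(Wk), Tensor(Wv), m_scale=m
    )
    np.testing.assert_allclose(C.data, expected, atol=1e-12)
    np.testing.assert_allclose(A.data.sum(axis=1), np.ones(2), atol=1e-9)


def test_fully_masked_sequence_rejected():
    Z = Tensor(np.ones((2, 2)))
    W = Tensor(np.eye(2))
    with pytest.raises(ValueError):
        enc.scaled_dot_product_self_attention(Z, W, W, W, 2, mask=np.zeros(2, bool))


# -- Multi-Head SDP encoder --------------------------------------------------


def _mha_params(rng, dim, stacks, heads):
    cfg = enc.EncoderConfig(
        mha_stacks=stacks, mha_heads=heads, max_sdp_len=4, cnn_windows=(3,)
    )
    return enc.init_mha_params(rng, dim, cfg)


def test_feature_length_fixed_by_padding(rng):
    dim, L = 4, 6
    params = enc.init_mha_params(
        rng,
        dim,
        enc.EncoderConfig(mha_stacks=2, mha_heads=2, max_sdp_len=L, cnn_windows=(3,)),
    )
    for true_len in (2, 4, 6):
        mask = np.zeros(L, bool)
        mask[:true_len] = True
        Z = np.zeros((L, dim))
        Z[:true_len] = rng.normal(size=(true_len, dim))
        feat = enc.multi_head_sdp_encoder(Tensor(Z), mask, params, m_scale=dim)
        assert feat.shape == (L * dim,)


def test_masked_padding_never_changes_output(rng):
    dim, L = 4, 5
    params = _mha_params(rng, dim, 2, 2)
    mask = np.array([True, True, True, False, False])
    content = rng.normal(size=(3, dim))
    Z_clean = np.vstack([content, np.zeros((2, dim))])
    Z_dirty = np.vstack([content, rng.normal(size=(2, dim))])
    f_clean = enc.multi_head_sdp_encoder(Tensor(Z_clean), mask, params, dim).data
    f_dirty = enc.multi_head_sdp_encoder(Tensor(Z_dirty), mask, params, dim).data
    np.testing.assert_allclose(f_clean, f_dirty, atol=1e-12)


def test_single_stack_single_head_reduces_to_self_attention(rng):
    dim = 3
    Z = Tensor(rng.normal(size=(2, dim)))
    mask = np.ones(2, bool)
    params = [
        {
            "heads": [
                {
                    "Wq": Tensor(rng.normal(size=(dim, dim))),
                    "Wk": Tensor(rng.normal(size=(dim, dim))),
                    "Wv": Tensor(rng.normal(size=(dim, dim))),
                }
            ],
            "Wo": Tensor(np.eye(dim)),  # identity projection isolates the head
        }
    ]
    feat = enc.multi_head_sdp_encoder(Z, mask, params, m_scale=dim)
    head = params[0]["heads"][0]
    C, _ = enc.scaled_dot_product_self_attention(
        Z, head["Wq"], head["Wk"], head["Wv"], dim, mask
    )
    np.testing.assert_allclose(feat.data, (C.data + Z.data).ravel(), atol=1e-12)


def test_heads_must_divide_model_dimension(rng):
    with pytest.raises(ValueError):
        enc.init_mha_params(rng, 5, enc.EncoderConfig(mha_heads=2))


# -- CNN SDP encoder ---------------------------------------------------------


def test_cnn_feature_length_192_at_reference_config(rng):
    cfg = enc.EncoderConfig()  # windows (3,5,7) x 64 filters
    params = enc.init_cnn_params(rng, 6, cfg)
    Z = Tensor(rng.normal(size=(cfg.max_sdp_len, 6)))
    feat = enc.cnn_sdp_encoder(Z, np.ones(cfg.max_sdp_len, bool), params, cfg)
    assert feat.shape == (192,)


def test_constant_input_pooling_returns_central_activation(rng):
    cfg = enc.EncoderConfig(cnn_windows=(3,), cnn_filters=2, max_sdp_len=6)
    params = enc.init_cnn_params(rng, 3, cfg)
    Z = Tensor(np.tile([1.0, -0.5, 2.0], (6, 1)))
    feat = enc.cnn_sdp_encoder(Z, np.ones(6, bool), params, cfg).data
    # interior positions see identical windows; max equals that activation
    row = np.tile([1.0, -0.5, 2.0], 3)
    expected = np.maximum(row @ params["w3"]["W"].data + params["w3"]["b"].data.ravel(), 0)
    interior_ok = np.allclose(feat, np.maximum(feat, expected))
    assert interior_ok and np.all(feat >= 0)


def test_single_window_single_filter_matches_hand_convolution():
    cfg = enc.EncoderConfig(cnn_windows=(3,), cnn_filters=1, max_sdp_len=4)
    Z = np.array([[1.0], [2.0], [-1.0], [0.5]])
    W = np.array([[0.5], [1.0], [-0.5]])  # taps for offsets -1, 0, +1
    params = {"w3": {"W": Tensor(W), "b": Tensor(np.zeros((1, 1)))}}
    padded = np.concatenate([[0.0], Z.ravel(), [0.0]])
    conv = np.array(
        [padded[i] * 0.5 + padded[i + 1] * 1.0 + padded[i + 2] * -0.5 for i in range(4)]
    )
    expected = np.maximum(conv, 0.0).max()
    feat = enc.cnn_sdp_encoder(Tensor(Z), np.ones(4, bool), params, cfg).data
    np.testing.assert_allclose(feat, [expected], atol=1e-12)


def test_cnn_pad_invariance(rng):
    cfg = enc.EncoderConfig(cnn_windows=(3,), cnn_filters=4, max_sdp_len=6)
    params = enc.init_cnn_params(rng, 3, cfg)
    mask = np.array([True] * 3 + [False] * 3)
    content = rng.normal(size=(3, 3))
    clean = np.vstack([content, np.zeros((3, 3))])
    dirty = np.vstack([content, rng.normal(size=(3, 3))])
    f_clean = enc.cnn_sdp_encoder(Tensor(clean), mask, params, cfg).data
    f_dirty = enc.cnn_sdp_encoder(Tensor(dirty), mask, params, cfg).data
    np.testing.assert_allclose(f_clean, f_dirty, atol=1e-12)


def test_window_larger_than_padded_length_rejected():
    with pytest.raises(ValueError):
        enc.EncoderConfig(cnn_windows=(7,), max_sdp_len=4)


# -- BLSTM -------------------------------------------------------------------


def test_blstm_output_dimension_is_twice_hidden(rng):
    params_f = enc.init_lstm_params(rng, 8, 64)
    params_b = enc.init_lstm_params(rng, 8, 64)
    H = enc.blstm_encode(Tensor(rng.normal(size=(5, 8))), params_f, params_b)
    assert H.shape == (5, 128)


def test_blstm_rejects_empty_sequence(rng):
    params = enc.init_lstm_params(rng, 4, 3)
    with pytest.raises(ValueError):
        enc.blstm_encode(Tensor(np.zeros((0, 4))), params, params)


def test_length_one_sequence_equals_single_cell_step(rng):
    params = enc.init_lstm_params(rng, 4, 3)
    x = rng.normal(size=(1, 4))
    gates = x @ params["Wx"].data + params["b"].data
    h = 3
    i = 1 / (1 + np.exp(-gates[:, :h]))
    f = 1 / (1 + np.exp(-gates[:, h : 2 * h]))
    g = np.tanh(gates[:, 2 * h : 3 * h])
    o = 1 / (1 + np.exp(-gates[:, 3 * h :]))
    expected = o * np.tanh(i * g)
    (state,) = enc.lstm_run(Tensor(x), params)
    np.testing.assert_allclose(state.data, expected, atol=1e-12)


def test_identical_token_sequence_is_position_symmetric(rng):
    params_f = enc.init_lstm_params(rng, 4, 3)
    params_b = enc.init_lstm_params(rng, 4, 3)
    X = Tensor(np.tile(rng.normal(size=(1, 4)), (5, 1)))
    H = enc.blstm_encode(X, params_f, params_b).data
    fwd, bwd = H[:, :3], H[:, 3:]
    # with every token equal, backward states mirror forward states of the
    # OTHER direction's recurrence depth: depth k forward == depth k backward
    f_only = enc.blstm_encode(X, params_f, params_f).data
    np.testing.assert_allclose(f_only[:, :3], f_only[::-1, 3:], atol=1e-12)


def test_sdp_pad_truncates_keeping_endpoints():
    kept, mask = enc.sdp_pad([0, 3, 5, 7, 9, 11, 12], 4)
    assert kept[0] == 0 and kept[-1] == 12 and len(kept) == 4
    assert mask.all()
    kept2, mask2 = enc.sdp_pad([2, 4], 5)
    assert kept2 == [2, 4] and mask2.tolist() == [True, True, False, False, False]
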