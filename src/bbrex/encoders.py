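"""Neural feature extractors.

Three attention mechanisms share one contract — a non-negative weight
vector over sequence positions summing to 1:

* *Entity-Oriented* attention scores each token by its average inner-product
  similarity to the two entity word vectors, scaled by 2*sqrt(m) where m is
  the word-embedding dimension; the weights rescale the token embeddings
  before the recurrent encoder.
* *Additive* attention scores each BLSTM hidden state with a learned vector
  v_a through a tanh layer and returns the weighted-sum context vector.
* *Multi-Head* scaled dot-product self-attention encodes the shortest
  dependency path: per head, learned query/key/value projections, scores
  scaled by sqrt(m), per-query softmax over unmasked keys; head outputs are
  concatenated, projected back to the model dimension, and added to the
  stack input (residual).  Stacks are chained and the final feature is the
  concatenation of per-position outputs over the padded length, with masked
  positions contributing zeros.

A multiple-filter-width CNN over the padded SDP (same-padding convolution,
ReLU, max-pool over positions per filter) is provided as the alternative
SDP encoder.  All computation runs on the autograd :class:`Tensor`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._autograd import Tensor, concat, softmax

__all__ = [
    "EncoderConfig",
    "entity_oriented_attention",
    "apply_entity_oriented",
    "init_lstm_params",
    "lstm_run",
    "blstm_encode",
    "additive_attention",
    "scaled_dot_product_self_attention",
    "init_mha_params",
    "multi_head_sdp_encoder",
    "init_cnn_params",
    "cnn_sdp_encoder",
    "sdp_pad",
]

NEG_INF = -1e30


@dataclass
class EncoderConfig:
    blstm_hidden: int = 64  # 32 for the full-sentence-only variant
    mha_stacks: int = 3
    mha_heads: int = 2
    cnn_windows: tuple[int, ...] = (3, 5, 7)
    cnn_filters: int = 64
    max_sdp_len: int = 10

    def __post_init__(self) -> None:
        if self.max_sdp_len < 2:
            raise ValueError("max_sdp_len must be >= 2 (both entity endpoints)")
        if min(self.blstm_hidden, self.mha_stacks, self.mha_heads, self.cnn_filters) < 1:
            raise ValueError("encoder sizes must be positive")
        if any(w > self.max_sdp_len for w in self.cnn_windows):
            raise ValueError("convolution window larger than the padded SDP length")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, (fan_in, fan_out))


# ---------------------------------------------------------------------------
# Entity-Oriented attention
# ---------------------------------------------------------------------------


def entity_oriented_attention(
    word_matrix: Tensor | np.ndarray, entity1_pos: int, entity2_pos: int
) -> Tensor:
    """Similarity-based weights over the M tokens of a sentence.

    ``word_matrix`` holds the word-embedding part of each token, one row per
    token.  The score of token i averages its inner products with the two
    entity word vectors and scales by 2*sqrt(m); weights are the softmax
    over all tokens.  Returns an (M, 1) weight column.
    """
    W = word_matrix if isinstance(word_matrix, Tensor) else Tensor(word_matrix)
    m_tokens, m_dim = W.shape
    if not (0 <= entity1_pos < m_tokens and 0 <= entity2_pos < m_tokens):
        raise ValueError("entity positions out of range")
    e1 = W[entity1_pos : entity1_pos + 1]
    e2 = W[entity2_pos : entity2_pos + 1]
    scores = (W @ e1.T + W @ e2.T) * (1.0 / (2.0 * np.sqrt(m_dim)))
    return softmax(scores, axis=0)


def apply_entity_oriented(token_matrix: Tensor, weights: Tensor) -> Tensor:
    """Scale each token embedding by weight * M, preserving sequence magnitude."""
    m_tokens = token_matrix.shape[0]
    return token_matrix * (weights * float(m_tokens))


# ---------------------------------------------------------------------------
# BLSTM
# ---------------------------------------------------------------------------


def init_lstm_params(rng: np.random.Generator, input_dim: int, hidden: int) -> dict[str, Tensor]:
    """One direction's LSTM cell parameters; forget-gate bias starts at 1."""
    b = np.zeros((1, 4 * hidden))
    b[0, hidden : 2 * hidden] = 1.0
    return {
        "Wx": Tensor(_glorot(rng, input_dim, 4 * hidden), requires_grad=True),
        "Wh": Tensor(_glorot(rng, hidden, 4 * hidden), requires_grad=True),
        "b": Tensor(b, requires_grad=True),
    }


def lstm_run(X: Tensor, params: dict[str, Tensor]) -> list[Tensor]:
    """Run one LSTM direction over the rows of X; returns per-step (1, h) states."""
    n_steps = X.shape[0]
    hidden = params["Wh"].shape[0]
    h = Tensor(np.zeros((1, hidden)))
    c = Tensor(np.zeros((1, hidden)))
    states: list[Tensor] = []
    for t in range(n_steps):
        x = X[t : t + 1]
        gates = x @ params["Wx"] + h @ params["Wh"] + params["b"]
        i = gates[:, :hidden].sigmoid()
        f = gates[:, hidden : 2 * hidden].sigmoid()
        g = gates[:, 2 * hidden : 3 * hidden].tanh()
        o = gates[:, 3 * hidden :].sigmoid()
        c = f * c + i * g
        h = o * c.tanh()
        states.append(h)
    return states


def blstm_encode(X: Tensor, params_f: dict[str, Tensor], params_b: dict[str, Tensor]) -> Tensor:
    """Bidirectional encoding: h_k = [forward_k ; backward_k], shape (M, 2h)."""
    n_steps = X.shape[0]
    if n_steps == 0:
        raise ValueError("cannot encode an empty sequence")
    forward = lstm_run(X, params_f)
    reversed_X = X[list(range(n_steps - 1, -1, -1))]
    backward_rev = lstm_run(reversed_X, params_b)
    backward = backward_rev[::-1]
    return concat([concat([f, b], axis=1) for f, b in zip(forward, backward)], axis=0)


# ---------------------------------------------------------------------------
# Additive attention
# ---------------------------------------------------------------------------


def additive_attention(hidden_states: Tensor, v_a: Tensor) -> tuple[Tensor, Tensor]:
    """Context vector c = sum_i a_i h_i with a = softmax(v_a . tanh(h_i)).

    ``hidden_states`` is (K, d); ``v_a`` is (d, 1).  Returns (c of shape
    (1, d), weights of shape (K, 1)).
    """
    if hidden_states.shape[1] != v_a.shape[0]:
        raise ValueError(
            f"v_a dimension {v_a.shape[0]} != hidden dimension {hidden_states.shape[1]}"
        )
    scores = hidden_states.tanh() @ v_a
    weights = softmax(scores, axis=0)
    context = (hidden_states * weights).sum(axis=0, keepdims=True)
    return context, weights


# ---------------------------------------------------------------------------
# scaled dot-product self-attention / Multi-Head SDP encoder
# ---------------------------------------------------------------------------


def scaled_dot_product_self_attention(
    Z: Tensor,
    Wq: Tensor,
    Wk: Tensor,
    Wv: Tensor,
    m_scale: int,
    mask: np.ndarray | None = None,
) -> tuple[Tensor, Tensor]:
    """One attention head over the rows of Z.

    Projections are stored input-major: q_i = z_i @ Wq etc.  Scores between
    query i and key j are (q_i . k_j) / sqrt(m_scale) with m_scale the
    word-embedding dimensionality; masked key positions are excluded from
    every softmax.  Returns (contexts (N, d_head), weights (N, N)).
    """
    n = Z.shape[0]
    if mask is not None and not mask.any():
        raise ValueError("all positions are masked")
    Q, K, V = Z @ Wq, Z @ Wk, Z @ Wv
    scores = (Q @ K.T) * (1.0 / np.sqrt(m_scale))
    if mask is not None:
        bias = np.where(mask, 0.0, NEG_INF)[None, :]
        scores = scores + bias
    weights = softmax(scores, axis=1)
    return weights @ V, weights


def init_mha_params(
    rng: np.random.Generator, model_dim: int, config: EncoderConfig
) -> list[dict]:
    if model_dim % config.mha_heads:
        raise ValueError(
            f"heads ({config.mha_heads}) must divide the model dimension ({model_dim})"
        )
    head_dim = model_dim // config.mha_heads
    stacks = []
    for _ in range(config.mha_stacks):
        heads = [
            {
                "Wq": Tensor(_glorot(rng, model_dim, head_dim), requires_grad=True),
                "Wk": Tensor(_glorot(rng, model_dim, head_dim), requires_grad=True),
                "Wv": Tensor(_glorot(rng, model_dim, head_dim), requires_grad=True),
            }
            for _ in range(config.mha_heads)
        ]
        stacks.append(
            {
                "heads": heads,
                "Wo": Tensor(_glorot(rng, model_dim, model_dim), requires_grad=True),
            }
        )
    return stacks


def multi_head_sdp_encoder(
    Z: Tensor,
    mask: np.ndarray,
    params: list[dict],
    m_scale: int,
) -> Tensor:
    """Stacked Multi-Head self-attention over the padded SDP.

    Each stack runs its heads in parallel, concatenates the head outputs,
    projects back to the model dimension and adds the stack input
    (residual).  The feature is the flattened concatenation of per-position
    outputs over the padded length; masked positions contribute zeros.
    """
    X = Z
    for stack in params:
        head_outputs = [
            scaled_dot_product_self_attention(
                X, head["Wq"], head["Wk"], head["Wv"], m_scale, mask
            )[0]
            for head in stack["heads"]
        ]
        X = concat(head_outputs, axis=1) @ stack["Wo"] + X
    X = X * Tensor(mask.astype(float)[:, None])
    return X.reshape(-1)


# ---------------------------------------------------------------------------
# CNN SDP encoder
# ---------------------------------------------------------------------------


def init_cnn_params(
    rng: np.random.Generator, model_dim: int, config: EncoderConfig
) -> dict[str, dict[str, Tensor]]:
    return {
        f"w{w}": {
            "W": Tensor(_glorot(rng, w * model_dim, config.cnn_filters), requires_grad=True),
            "b": Tensor(np.zeros((1, config.cnn_filters)), requires_grad=True),
        }
        for w in config.cnn_windows
    }


def cnn_sdp_encoder(
    Z: Tensor,
    mask: np.ndarray,
    params: dict[str, dict[str, Tensor]],
    config: EncoderConfig,
) -> Tensor:
    """Multiple-filter-width convolution + max pooling over SDP positions.

    For every window size: same-padding 1-D convolution over positions,
    ReLU, then a max over the unmasked positions per filter.  Window
    features are concatenated (windows x filters long).
    """
    length, dim = Z.shape
    pooled: list[Tensor] = []
    mask_bias = Tensor(np.where(mask, 0.0, NEG_INF)[:, None])
    for w in config.cnn_windows:
        pad = w // 2
        zeros = Tensor(np.zeros((pad, dim)))
        Zpad = concat([zeros, Z, zeros], axis=0)
        windows = concat([Zpad[k : k + length] for k in range(w)], axis=1)
        activations = (windows @ params[f"w{w}"]["W"] + params[f"w{w}"]["b"]).relu()
        pooled.append((activations + mask_bias).max(axis=0))
    return concat(pooled, axis=0)


def sdp_pad(
    sdp_positions: Sequence[int], max_len: int
) -> tuple[list[int], np.ndarray]:
    """Pad/truncate SDP positions to ``max_len``.

    Longer paths truncate symmetrically around the midpoint, keeping both
    entity endpoints.  Returns (kept positions, boolean mask of length
    ``max_len``; padding entries are False and carry no position).
    """
    n = len(sdp_positions)
    if n > max_len:
        head = (max_len + 1) // 2
        tail = max_len - head
        kept = list(sdp_positions[:head]) + list(sdp_positions[n - tail :])
        return kept, np.ones(max_len, dtype=bool)
    mask = np.zeros(max_len, dtype=bool)
    mask[:n] = True
    return list(sdp_positions), mask
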