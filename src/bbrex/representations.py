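"""Per-token input representations.

Each token is represented by the concatenation
``z = [word (+ positional encoding, SDP tokens only) ; POS ; dist1 ; dist2]``.

*Word vectors* come from a pluggable provider: a static word2vec-format
table, a deterministic hash fallback for tests, or a contextual callable
returning one vector per token of a sentence.  *POS embeddings* are random
at initialization and trainable.  *Distance embeddings* ``D(l)`` encode the
signed relative distance ``l`` of a token to an entity: every component is
initialized to ``tanh(l / s)`` where ``s`` is the maximum absolute relative
distance in the dataset; the table is trainable afterwards.  *Positional
encodings* are the fixed sinusoid scheme and are summed into the word
component of SDP tokens.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Iterable, Protocol, TextIO

import numpy as np

from .candidates import CandidateInstance

__all__ = [
    "EmbeddingConfig",
    "ProviderContractError",
    "StaticWordVectors",
    "HashWordVectors",
    "ContextualWordVectors",
    "read_word2vec_text",
    "distance_embedding_init",
    "build_distance_table",
    "positional_encoding",
    "EmbeddingTables",
]


class ProviderContractError(ValueError):
    """A word-vector provider returned vectors of the wrong shape."""


@dataclass
class EmbeddingConfig:
    """Dimensions and vocabularies of the input representation.

    Defaults follow the reference setting: 200-dimensional context-free
    word vectors (400 when a contextual provider is plugged in), 100 for
    POS, 150 per entity for distance (300 total), positional encoding of
    the word dimension.
    """

    word_dim: int = 200
    pos_dim: int = 100
    dist_dim_per_entity: int = 150
    pe_dim: int | None = None
    max_distance: int = 30  # symbol s: max |relative distance| in the data
    vocab: dict[str, int] = field(default_factory=dict)
    pos_vocab: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pe_dim is None:
            self.pe_dim = self.word_dim
        if min(self.word_dim, self.pos_dim, self.dist_dim_per_entity, self.pe_dim) <= 0:
            raise ValueError("all embedding dimensions must be positive")
        if self.max_distance < 1:
            raise ValueError("max_distance (s) must be >= 1")
        if self.pe_dim % 2:
            raise ValueError("positional-encoding dimension must be even")

    @property
    def token_dim(self) -> int:
        """Length of the concatenated per-token vector z."""
        return self.word_dim + self.pos_dim + 2 * self.dist_dim_per_entity

    @classmethod
    def from_instances(
        cls, instances: Iterable[CandidateInstance], **overrides
    ) -> "EmbeddingConfig":
        """Build vocabularies and the distance range s from training instances."""
        vocab: dict[str, int] = {}
        pos_vocab: dict[str, int] = {}
        s = 1
        for inst in instances:
            for tok in inst.tokens:
                vocab.setdefault(tok, len(vocab))
            for tag in inst.pos_tags:
                pos_vocab.setdefault(tag, len(pos_vocab))
            s = max(
                s,
                max(abs(d) for d in inst.rel_dist1),
                max(abs(d) for d in inst.rel_dist2),
            )
        overrides.setdefault("max_distance", s)
        return cls(vocab=vocab, pos_vocab=pos_vocab, **overrides)


# ---------------------------------------------------------------------------
# word-vector providers
# ---------------------------------------------------------------------------


class WordVectorProvider(Protocol):
    dim: int

    def vectors(self, tokens: list[str]) -> np.ndarray: ...


def read_word2vec_text(stream: TextIO) -> tuple[dict[str, np.ndarray], int]:
    """Read a word2vec text-format table: header ``count dim`` then rows."""
    header = stream.readline().split()
    if len(header) != 2:
        raise ValueError("word2vec text format requires a 'count dim' header line")
    count, dim = int(header[0]), int(header[1])
    table: dict[str, np.ndarray] = {}
    for line in stream:
        parts = line.rstrip("\n").split(" ")
        if len(parts) < dim + 1:
            continue
        table[parts[0]] = np.asarray(parts[1 : dim + 1], dtype=np.float64)
    if len(table) != count:
        # tolerated: some released tables over/under-state the header count
        pass
    return table, dim


def _word_rng(word: str, seed: int) -> np.random.Generator:
    digest = hashlib.md5(word.encode("utf-8")).digest()
    return np.random.default_rng([seed, int.from_bytes(digest[:8], "little")])


class StaticWordVectors:
    """Context-free table lookup; OOV words get a cached seeded random vector."""

    def __init__(self, table: dict[str, np.ndarray], dim: int, seed: int = 0):
        self.table = table
        self.dim = dim
        self.seed = seed
        self._oov_cache: dict[str, np.ndarray] = {}

    @classmethod
    def from_word2vec_text(cls, stream: TextIO, seed: int = 0) -> "StaticWordVectors":
        table, dim = read_word2vec_text(stream)
        return cls(table, dim, seed)

    def vector(self, word: str) -> np.ndarray:
        hit = self.table.get(word)
        if hit is not None:
            return hit
        cached = self._oov_cache.get(word)
        if cached is None:
            # keyed by the word itself, so the draw is query-order independent
            cached = _word_rng(word, self.seed).normal(0.0, 0.1, self.dim)
            self._oov_cache[word] = cached
        return cached

    def vectors(self, tokens: list[str]) -> np.ndarray:
        return np.stack([self.vector(t) for t in tokens]) if tokens else np.zeros((0, self.dim))


class HashWordVectors:
    """Deterministic per-word random vectors (test fallback, no table needed)."""

    def __init__(self, dim: int, seed: int = 0):
        self.dim = dim
        self.seed = seed

    def vector(self, word: str) -> np.ndarray:
        return _word_rng(word, self.seed).normal(0.0, 0.5, self.dim)

    def vectors(self, tokens: list[str]) -> np.ndarray:
        return np.stack([self.vector(t) for t in tokens]) if tokens else np.zeros((0, self.dim))


class ContextualWordVectors:
    """Adapter for a contextual provider: full token sequence -> per-token vectors."""

    def __init__(self, fn: Callable[[list[str]], np.ndarray], dim: int):
        self.fn = fn
        self.dim = dim

    def vectors(self, tokens: list[str]) -> np.ndarray:
        out = np.asarray(self.fn(tokens), dtype=np.float64)
        if out.shape != (len(tokens), self.dim):
            raise ProviderContractError(
                f"contextual provider returned shape {out.shape}, "
                f"expected {(len(tokens), self.dim)}"
            )
        return out


# ---------------------------------------------------------------------------
# distance embeddings and positional encoding
# ---------------------------------------------------------------------------


def distance_embedding_init(l: int, config: EmbeddingConfig) -> np.ndarray:
    """Initial distance embedding D(l): every component tanh(l/s).

    Distances beyond [-s, s] clip to the boundary.
    """
    s = config.max_distance
    l = max(-s, min(s, l))
    return np.full(config.dist_dim_per_entity, np.tanh(l / s))


def build_distance_table(config: EmbeddingConfig) -> np.ndarray:
    """Rows for l = -s..s (index l + s); trainable after initialization."""
    s = config.max_distance
    return np.stack([distance_embedding_init(l, config) for l in range(-s, s + 1)])


def positional_encoding(position: int, dim: int) -> np.ndarray:
    """Fixed sinusoidal encoding: sin/cos pairs at geometric frequencies."""
    if position < 0:
        raise ValueError("position must be >= 0")
    if dim % 2:
        raise ValueError("positional-encoding dimension must be even")
    i = np.arange(dim // 2)
    angle = position / np.power(10000.0, 2.0 * i / dim)
    pe = np.empty(dim)
    pe[0::2] = np.sin(angle)
    pe[1::2] = np.cos(angle)
    return pe


class EmbeddingTables:
    """Initial (numpy) embedding tables, bit-reproducible from (config, seed).

    Trainable copies of these arrays are made by the model; the tables here
    are the deterministic initialization.
    """

    def __init__(self, config: EmbeddingConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        n_pos = max(1, len(config.pos_vocab))
        self.pos_table = rng.normal(0.0, 0.1, (n_pos, config.pos_dim))
        self.dist1_table = build_distance_table(config)
        self.dist2_table = build_distance_table(config)

    def distance_row(self, l: int) -> int:
        s = self.config.max_distance
        return max(-s, min(s, l)) + s

    def compose(
        self,
        word_vec: np.ndarray,
        pos_tag: str,
        l1: int,
        l2: int,
        position: int = 0,
        is_sdp: bool = False,
    ) -> np.ndarray:
        """Concatenated token vector z; SDP tokens get PE summed into the word part."""
        cfg = self.config
        if word_vec.shape != (cfg.word_dim,):
            raise ValueError(f"word vector has shape {word_vec.shape}, expected ({cfg.word_dim},)")
        word = word_vec
        if is_sdp:
            word = word + positional_encoding(position, cfg.pe_dim)
        pos_idx = cfg.pos_vocab.get(pos_tag, 0)
        return np.concatenate(
            [
                word,
                self.pos_table[pos_idx],
                self.dist1_table[self.distance_row(l1)],
                self.dist2_table[self.distance_row(l2)],
            ]
        )
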