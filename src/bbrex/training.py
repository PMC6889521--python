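"""Model assembly, training and prediction.

The classifier concatenates up to three feature blocks — the additive-
attention context over BLSTM states of the entity-blinded full sentence,
the Multi-Head (or CNN) encoding of the shortest dependency path, and an
optional fixed sentence embedding — applies dropout to the concatenation
during training, and maps it through a single affine layer to a softmax
over relation classes (p(c|s) = softmax(W0 . s + b0)).  Training minimizes
cross-entropy with minibatch Adam and early-stops on development F1.

Every source of randomness (parameter init, shuffling, dropout) derives
from ``TrainConfig.seed``, so runs are bit-reproducible.
"""

from __future__ import annotations

import io
import json
import logging
import zipfile
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np

from ._autograd import Tensor, concat
from .candidates import CandidateInstance
from .encoders import (
    EncoderConfig,
    additive_attention,
    apply_entity_oriented,
    blstm_encode,
    cnn_sdp_encoder,
    entity_oriented_attention,
    init_cnn_params,
    init_lstm_params,
    init_mha_params,
    multi_head_sdp_encoder,
    sdp_pad,
)
from .representations import (
    EmbeddingConfig,
    EmbeddingTables,
    HashWordVectors,
    positional_encoding,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "PredictionRecord",
    "RelationModel",
    "Adam",
    "classify",
    "cross_entropy",
    "train_model",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

LABEL_INDEX = {"negative": 0, "positive": 1}


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 4
    dropout: float = 0.5  # 0.1 for the full-sentence-only variant
    max_epochs: int = 20
    patience: int = 2
    seed: int = 0
    class_count: int = 2
    # ablation flags
    use_full_sentence: bool = True
    use_sdp: bool = True
    use_sentence_embedding: bool = True
    sdp_encoder: str = "mha"  # "mha" | "cnn"
    use_additive: bool = True
    use_entity_oriented: bool = True
    use_pe: bool = True
    sentence_embedding_dim: int = 768

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.sdp_encoder not in ("mha", "cnn"):
            raise ValueError("sdp_encoder must be 'mha' or 'cnn'")
        if not (self.use_full_sentence or self.use_sdp or self.use_sentence_embedding):
            raise ValueError("at least one feature block must be enabled")


@dataclass
class PredictionRecord:
    instance: CandidateInstance
    p_positive: float
    decision: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_positive <= 1.0:
            raise ValueError("p_positive must be a probability")


# ---------------------------------------------------------------------------
# standalone numeric ops (scalar contracts)
# ---------------------------------------------------------------------------


def classify(feature_blocks: Sequence[np.ndarray], W0: np.ndarray, b0: np.ndarray) -> np.ndarray:
    """softmax(W0 . concat(features) + b0); pure-numpy reference path."""
    s = np.concatenate([np.asarray(f, dtype=float).ravel() for f in feature_blocks])
    if W0.shape[1] != s.size:
        raise ValueError(f"W0 expects features of size {W0.shape[1]}, got {s.size}")
    logits = W0 @ s + b0
    e = np.exp(logits - logits.max())
    return e / e.sum()


def cross_entropy(y, p) -> float:
    """Binary cross-entropy J = -(y log p + (1-y) log(1-p)).

    Accepts scalars or arrays (mean over instances); probabilities clamp to
    [1e-7, 1 - 1e-7] for numerical safety.
    """
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), 1e-7, 1.0 - 1e-7)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


def _log_softmax(logits: Tensor) -> Tensor:
    shifted = logits - logits.data.max()
    return shifted - shifted.exp().sum(axis=-1, keepdims=True).log()


class RelationModel:
    """The hybrid full-sentence + SDP relation classifier.

    ``word_provider`` supplies vectors for words outside the trainable
    vocabulary table (and, for a contextual provider, the per-instance word
    vectors themselves); ``sentence_provider`` maps an instance to one fixed
    sentence-embedding vector (default: zeros).
    """

    def __init__(
        self,
        emb_config: EmbeddingConfig,
        enc_config: EncoderConfig,
        train_config: TrainConfig,
        word_provider=None,
        sentence_provider: Callable[[CandidateInstance], np.ndarray] | None = None,
        contextual: bool = False,
    ):
        self.emb_config = emb_config
        self.enc_config = enc_config
        self.train_config = train_config
        self.word_provider = word_provider or HashWordVectors(
            emb_config.word_dim, emb_config.seed
        )
        self.sentence_provider = sentence_provider
        self.contextual = contextual
        self.params: dict[str, Tensor] = {}
        self._init_params()

    # -- parameters ------------------------------------------------------

    def _init_params(self) -> None:
        cfg, enc, tc = self.emb_config, self.enc_config, self.train_config
        rng = np.random.default_rng(tc.seed)
        tables = EmbeddingTables(cfg)
        p: dict[str, Tensor] = {}
        if not self.contextual:
            words = sorted(cfg.vocab, key=cfg.vocab.get)
            init = (
                self.word_provider.vectors(words)
                if words
                else np.zeros((0, cfg.word_dim))
            )
            p["word_table"] = Tensor(init, requires_grad=True)
        p["pos_table"] = Tensor(tables.pos_table, requires_grad=True)
        p["dist1_table"] = Tensor(tables.dist1_table, requires_grad=True)
        p["dist2_table"] = Tensor(tables.dist2_table, requires_grad=True)

        d = cfg.token_dim
        feat_dim = 0
        if tc.use_full_sentence:
            for name, params in (
                ("lstm_f", init_lstm_params(rng, d, enc.blstm_hidden)),
                ("lstm_b", init_lstm_params(rng, d, enc.blstm_hidden)),
            ):
                for k, v in params.items():
                    p[f"{name}.{k}"] = v
            if tc.use_additive:
                p["v_a"] = Tensor(
                    rng.normal(0.0, 0.1, (2 * enc.blstm_hidden, 1)), requires_grad=True
                )
            feat_dim += 2 * enc.blstm_hidden
        if tc.use_sdp:
            if tc.sdp_encoder == "mha":
                for si, stack in enumerate(init_mha_params(rng, d, enc)):
                    for hi, head in enumerate(stack["heads"]):
                        for k, v in head.items():
                            p[f"mha.{si}.h{hi}.{k}"] = v
                    p[f"mha.{si}.Wo"] = stack["Wo"]
                feat_dim += enc.max_sdp_len * d
            else:
                for wname, wp in init_cnn_params(rng, d, enc).items():
                    p[f"cnn.{wname}.W"] = wp["W"]
                    p[f"cnn.{wname}.b"] = wp["b"]
                feat_dim += len(enc.cnn_windows) * enc.cnn_filters
        if tc.use_sentence_embedding:
            feat_dim += tc.sentence_embedding_dim
        bound = np.sqrt(6.0 / (feat_dim + tc.class_count))
        p["W0"] = Tensor(rng.uniform(-bound, bound, (feat_dim, tc.class_count)), requires_grad=True)
        p["b0"] = Tensor(np.zeros((1, tc.class_count)), requires_grad=True)
        self.params = p
        self.feature_dim = feat_dim

    def _mha_stacks(self) -> list[dict]:
        enc = self.enc_config
        return [
            {
                "heads": [
                    {k: self.params[f"mha.{si}.h{hi}.{k}"] for k in ("Wq", "Wk", "Wv")}
                    for hi in range(enc.mha_heads)
                ],
                "Wo": self.params[f"mha.{si}.Wo"],
            }
            for si in range(enc.mha_stacks)
        ]

    def _cnn_params(self) -> dict:
        return {
            f"w{w}": {
                "W": self.params[f"cnn.w{w}.W"],
                "b": self.params[f"cnn.w{w}.b"],
            }
            for w in self.enc_config.cnn_windows
        }

    # -- forward pass ------------------------------------------------------

    def _word_matrix(self, tokens: list[str]) -> Tensor:
        if self.contextual:
            return Tensor(self.word_provider.vectors(tokens))
        vocab = self.emb_config.vocab
        rows: list[Tensor] = []
        table = self.params["word_table"]
        for tok in tokens:
            idx = vocab.get(tok)
            if idx is not None:
                rows.append(table[idx : idx + 1])
            else:
                rows.append(Tensor(self.word_provider.vectors([tok])))
        return concat(rows, axis=0)

    def _component_matrices(self, inst: CandidateInstance) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        cfg = self.emb_config
        s = cfg.max_distance
        Wmat = self._word_matrix(inst.tokens)
        pos_idx = [cfg.pos_vocab.get(t, 0) for t in inst.pos_tags]
        POS = self.params["pos_table"][pos_idx]
        d1_idx = [max(-s, min(s, l)) + s for l in inst.rel_dist1]
        d2_idx = [max(-s, min(s, l)) + s for l in inst.rel_dist2]
        D1 = self.params["dist1_table"][d1_idx]
        D2 = self.params["dist2_table"][d2_idx]
        return Wmat, POS, D1, D2

    def feature_vector(
        self, inst: CandidateInstance, train: bool = False, dropout_rng=None
    ) -> Tensor:
        tc, enc, cfg = self.train_config, self.enc_config, self.emb_config
        Wmat, POS, D1, D2 = self._component_matrices(inst)
        blocks: list[Tensor] = []

        if tc.use_full_sentence:
            Z = concat([Wmat, POS, D1, D2], axis=1)
            if tc.use_entity_oriented:
                weights = entity_oriented_attention(Wmat, inst.entity1_pos, inst.entity2_pos)
                Z = apply_entity_oriented(Z, weights)
            H = blstm_encode(
                Z,
                {k: self.params[f"lstm_f.{k}"] for k in ("Wx", "Wh", "b")},
                {k: self.params[f"lstm_b.{k}"] for k in ("Wx", "Wh", "b")},
            )
            if tc.use_additive:
                context, _ = additive_attention(H, self.params["v_a"])
            else:
                context = H.mean(axis=0, keepdims=True)
            blocks.append(context.reshape(-1))

        if tc.use_sdp:
            kept, mask = sdp_pad(inst.sdp_indices, enc.max_sdp_len)
            Wsdp = Wmat[kept]
            if tc.use_pe:
                pe = np.stack([positional_encoding(pos, cfg.pe_dim) for pos in kept])
                Wsdp = Wsdp + Tensor(pe)
            Zsdp = concat([Wsdp, POS[kept], D1[kept], D2[kept]], axis=1)
            n_pad = enc.max_sdp_len - len(kept)
            if n_pad:
                Zsdp = concat([Zsdp, Tensor(np.zeros((n_pad, cfg.token_dim)))], axis=0)
            if tc.sdp_encoder == "mha":
                feat = multi_head_sdp_encoder(Zsdp, mask, self._mha_stacks(), cfg.word_dim)
            else:
                feat = cnn_sdp_encoder(Zsdp, mask, self._cnn_params(), enc)
            blocks.append(feat)

        if tc.use_sentence_embedding:
            if self.sentence_provider is not None:
                vec = np.asarray(self.sentence_provider(inst), dtype=float)
                if vec.shape != (tc.sentence_embedding_dim,):
                    raise ValueError(
                        f"sentence provider returned shape {vec.shape}, "
                        f"expected ({tc.sentence_embedding_dim},)"
                    )
            else:
                vec = np.zeros(tc.sentence_embedding_dim)
            blocks.append(Tensor(vec))

        s = concat(blocks, axis=0)
        if train and tc.dropout > 0.0:
            if dropout_rng is None:
                raise ValueError("training forward pass needs a dropout rng")
            keep = (dropout_rng.random(self.feature_dim) >= tc.dropout) / (1.0 - tc.dropout)
            s = s * Tensor(keep)
        return s

    def logits(self, inst: CandidateInstance, train: bool = False, dropout_rng=None) -> Tensor:
        s = self.feature_vector(inst, train=train, dropout_rng=dropout_rng)
        return s.reshape(1, -1) @ self.params["W0"] + self.params["b0"]

    def predict_proba(self, inst: CandidateInstance) -> np.ndarray:
        logits = self.logits(inst)
        e = np.exp(logits.data.ravel() - logits.data.max())
        return e / e.sum()

    def instance_loss(self, inst: CandidateInstance, train: bool = False, dropout_rng=None) -> Tensor:
        if inst.label is None:
            raise ValueError(f"instance {inst.pair_key} has no label")
        target = LABEL_INDEX.get(inst.label, None)
        if target is None:
            target = int(inst.label)
        logp = _log_softmax(self.logits(inst, train=train, dropout_rng=dropout_rng))
        return -logp[0, target]

    def batch_loss(self, batch: Sequence[CandidateInstance], train: bool = False, dropout_rng=None) -> Tensor:
        losses = [self.instance_loss(inst, train=train, dropout_rng=dropout_rng) for inst in batch]
        total = losses[0]
        for item in losses[1:]:
            total = total + item
        return total * (1.0 / len(losses))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = state[k].copy()


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, params: dict[str, Tensor], lr: float = 0.001,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad**2
            m_hat = self.m[k] / (1 - self.b1**self.t)
            v_hat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _dev_f1(model: RelationModel, dev: Sequence[CandidateInstance]) -> float:
    from .evaluation import instance_prf

    records = predict(model, dev, cutoff=0.5)
    labels = [inst.label for inst in dev]
    decisions = [r.decision for r in records]
    if "positive" not in labels:
        logger.warning("development set has no positive instances; F1 treated as 0")
        return 0.0
    return instance_prf(labels, decisions).f1


def train_model(
    train_instances: Sequence[CandidateInstance],
    dev_instances: Sequence[CandidateInstance] | None,
    emb_config: EmbeddingConfig,
    enc_config: EncoderConfig,
    train_config: TrainConfig,
    word_provider=None,
    sentence_provider=None,
    contextual: bool = False,
) -> tuple[RelationModel, list[dict]]:
    """Minibatch Adam with early stopping on development F1.

    Returns the model restored to its best-development checkpoint and the
    per-epoch history (mean training loss, development F1).
    """
    if not train_instances:
        raise ValueError("empty training set")
    model = RelationModel(
        emb_config, enc_config, train_config,
        word_provider=word_provider, sentence_provider=sentence_provider,
        contextual=contextual,
    )
    optimizer = Adam(model.params, lr=train_config.learning_rate)
    shuffle_rng = np.random.default_rng([train_config.seed, 1])
    dropout_rng = np.random.default_rng([train_config.seed, 2])

    history: list[dict] = []
    best_f1 = -1.0
    best_state = model.state_dict()
    stale = 0
    for epoch in range(1, train_config.max_epochs + 1):
        order = shuffle_rng.permutation(len(train_instances))
        epoch_losses: list[float] = []
        for start in range(0, len(order), train_config.batch_size):
            batch = [train_instances[i] for i in order[start : start + train_config.batch_size]]
            optimizer.zero_grad()
            loss = model.batch_loss(batch, train=True, dropout_rng=dropout_rng)
            loss.backward()
            optimizer.step()
            epoch_losses.append(loss.item())
        entry = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
        if dev_instances:
            f1 = _dev_f1(model, dev_instances)
            entry["dev_f1"] = f1
            if f1 > best_f1:
                best_f1 = f1
                best_state = model.state_dict()
                stale = 0
            else:
                stale += 1
        history.append(entry)
        if dev_instances and stale > train_config.patience:
            break
    if dev_instances:
        model.load_state_dict(best_state)
    return model, history


def predict(
    model: RelationModel, instances: Sequence[CandidateInstance], cutoff: float = 0.5
) -> list[PredictionRecord]:
    """Decisions at a probability cutoff: positive iff p_positive >= cutoff."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    records = []
    for inst in instances:
        probs = model.predict_proba(inst)
        p_pos = float(probs[LABEL_INDEX["positive"]])
        decision = "positive" if p_pos >= cutoff else "negative"
        inst.p_positive = p_pos
        inst.decision = decision
        records.append(PredictionRecord(instance=inst, p_positive=p_pos, decision=decision))
    return records


# ---------------------------------------------------------------------------
# checkpoints: one archive of named weight arrays + the config blocks as JSON
# ---------------------------------------------------------------------------


def _config_json(model: RelationModel) -> str:
    emb = asdict(model.emb_config)
    enc = asdict(model.enc_config)
    enc["cnn_windows"] = list(enc["cnn_windows"])
    return json.dumps(
        {
            "embedding": emb,
            "encoder": enc,
            "train": asdict(model.train_config),
            "contextual": model.contextual,
        },
        sort_keys=True,
    )


def save_checkpoint(model: RelationModel, path) -> None:
    """Write a deterministic zip archive (fixed timestamps, sorted entries)."""
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        info = zipfile.ZipInfo("config.json", date_time=(1980, 1, 1, 0, 0, 0))
        zf.writestr(info, _config_json(model))
        for name in sorted(model.params):
            buf = io.BytesIO()
            np.lib.format.write_array(buf, model.params[name].data, allow_pickle=False)
            info = zipfile.ZipInfo(f"{name}.npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())


def load_checkpoint(path, word_provider=None, sentence_provider=None) -> RelationModel:
    with zipfile.ZipFile(path) as zf:
        cfg = json.loads(zf.read("config.json"))
        emb = EmbeddingConfig(**cfg["embedding"])
        enc_kwargs = dict(cfg["encoder"])
        enc_kwargs["cnn_windows"] = tuple(enc_kwargs["cnn_windows"])
        enc = EncoderConfig(**enc_kwargs)
        tc = TrainConfig(**cfg["train"])
        model = RelationModel(
            emb, enc, tc,
            word_provider=word_provider, sentence_provider=sentence_provider,
            contextual=cfg["contextual"],
        )
        for name in model.params:
            with zf.open(f"{name}.npy") as fh:
                model.params[name].data = np.lib.format.read_array(fh, allow_pickle=False)
    return model
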