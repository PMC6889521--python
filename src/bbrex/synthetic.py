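"""Synthetic corpora with a planted, learnable relation rule.

The generator emits documents in the exact standoff + CoNLL-U formats the
real pipeline ingests.  Each sentence is a random projective-style
dependency tree (every non-root token governed by an earlier token) over
filler vocabulary, with single-token bacteria and location mentions and one
cue token (default ``inhabits``).  A pair's gold label is positive iff the
cue token lies on the shortest dependency path between the pair — a rule
that is deliberately invisible in the surface sentence (the cue occurs in
every sentence) and linearly visible on the SDP, so the SDP branch of the
model is necessary for ceiling performance.  Labels flip with probability
``label_noise``.

Also provides hand-built fixture documents for two canonical worked
examples used throughout the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .candidates import CandidateInstance, CandidateStats, generate_candidates
from .corpus_io import (
    Document,
    EntityCategory,
    EntityMention,
    ParsedSentence,
    RelationGold,
    Token,
    attach_parses,
    write_conllu,
    write_standoff,
)

__all__ = [
    "SynthConfig",
    "generate_corpus",
    "write_corpus",
    "corpus_to_instances",
    "generate_dataset",
    "helicobacter_japan_example",
    "mycobacteria_queensland_example",
    "make_worked_example_fixtures",
]

_FILLER_POS = ("NN", "JJ", "IN", "DT")


@dataclass
class SynthConfig:
    n_docs: int = 30
    sentences_per_doc: tuple[int, int] = (1, 3)
    sentence_len_range: tuple[int, int] = (8, 14)
    bacteria_per_sentence: tuple[int, int] = (1, 1)
    locations_per_sentence: tuple[int, int] = (1, 2)
    cue_token: str = "inhabits"
    label_noise: float = 0.0
    vocab_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sentence_len_range[0] < 4:
            raise ValueError("minimum sentence length must be >= 4")
        if self.vocab_size <= 10:
            raise ValueError("vocab_size must be > 10")
        if not 0.0 <= self.label_noise < 1.0:
            raise ValueError("label_noise must be in [0, 1)")
        needed = 2 + self.bacteria_per_sentence[1] + self.locations_per_sentence[1]
        if self.sentence_len_range[0] < needed:
            raise ValueError(
                f"sentences of length {self.sentence_len_range[0]} cannot hold "
                f"root + cue + up to {needed - 2} entities"
            )


def _generate_document(rng: np.random.Generator, doc_id: str, cfg: SynthConfig) -> Document:
    vocab = [f"w{k}" for k in range(cfg.vocab_size)]
    sentences: list[ParsedSentence] = []
    text_parts: list[str] = []
    mentions: list[EntityMention] = []
    relations: list[RelationGold] = []
    offset = 0
    mention_counter = 0
    n_sentences = int(rng.integers(cfg.sentences_per_doc[0], cfg.sentences_per_doc[1] + 1))
    for sent_index in range(n_sentences):
        length = int(rng.integers(cfg.sentence_len_range[0], cfg.sentence_len_range[1] + 1))
        n_bact = int(rng.integers(cfg.bacteria_per_sentence[0], cfg.bacteria_per_sentence[1] + 1))
        n_loc = int(rng.integers(cfg.locations_per_sentence[0], cfg.locations_per_sentence[1] + 1))
        if length < 2 + n_bact + n_loc:
            raise ValueError("entities exceed sentence length")
        # slot layout: index 0 is the root verb; the cue precedes every
        # location so each head points to an earlier token (guaranteed tree)
        cue_pos = int(rng.integers(1, length - n_loc))
        after_cue = [i for i in range(cue_pos + 1, length)]
        loc_pos = sorted(rng.choice(after_cue, size=n_loc, replace=False).tolist())
        remaining = [i for i in range(1, length) if i != cue_pos and i not in loc_pos]
        bact_pos = sorted(rng.choice(remaining, size=n_bact, replace=False).tolist())

        surfaces = [""] * length
        pos_tags = [""] * length
        heads = [0] * length
        surfaces[0] = str(rng.choice(vocab))
        pos_tags[0] = "VB"
        surfaces[cue_pos] = cfg.cue_token
        pos_tags[cue_pos] = "VB"
        heads[cue_pos] = 1
        for p in bact_pos:
            mention_counter += 1
            surfaces[p] = f"BACT{mention_counter}"
            pos_tags[p] = "NN"
            heads[p] = 1
        for p in loc_pos:
            mention_counter += 1
            surfaces[p] = f"LOC{mention_counter}"
            pos_tags[p] = "NN"
            # attaching under the cue puts the cue on the bacteria-location
            # SDP (positive); attaching under the root keeps it off
            heads[p] = cue_pos + 1 if rng.random() < 0.5 else 1
        for i in range(1, length):
            if surfaces[i]:
                continue
            surfaces[i] = str(rng.choice(vocab))
            pos_tags[i] = str(rng.choice(_FILLER_POS))
            heads[i] = int(rng.integers(1, i + 1))

        tree = nx.Graph((i, heads[i] - 1) for i in range(1, length))
        sent_mention_ids: dict[int, str] = {}
        for i, surface in enumerate(surfaces):
            start = offset
            text_parts.append(surface)
            offset += len(surface) + 1  # single space separator
            if i in bact_pos or i in loc_pos:
                mid = f"T{len(mentions) + 1}"
                if i in bact_pos:
                    category = EntityCategory.BACTERIA
                else:
                    category = (
                        EntityCategory.HABITAT
                        if rng.random() < 0.7
                        else EntityCategory.GEOGRAPHICAL
                    )
                mentions.append(
                    EntityMention(mid, category, start, start + len(surface), surface)
                )
                sent_mention_ids[i] = mid

        for bp in bact_pos:
            for lp in loc_pos:
                path = nx.shortest_path(tree, bp, lp)
                positive = cue_pos in path
                if cfg.label_noise > 0.0 and rng.random() < cfg.label_noise:
                    positive = not positive
                if positive:
                    relations.append(
                        RelationGold(sent_mention_ids[bp], sent_mention_ids[lp], "positive")
                    )
        sentences.append(
            ParsedSentence(
                sent_index=sent_index,
                tokens=[
                    Token(surface=s, pos_tag=t, head=h)
                    for s, t, h in zip(surfaces, pos_tags, heads)
                ],
            )
        )
    text = " ".join(text_parts)
    doc = Document(doc_id=doc_id, text=text, mentions=mentions, relations=relations)
    return attach_parses(doc, sentences)


def generate_corpus(cfg: SynthConfig) -> list[Document]:
    """Generate ``cfg.n_docs`` annotated, parsed documents (deterministic in seed)."""
    rng = np.random.default_rng(cfg.seed)
    return [_generate_document(rng, f"synth{i:04d}", cfg) for i in range(cfg.n_docs)]


def write_corpus(docs: list[Document], outdir) -> None:
    """Write each document as {id}.txt / .a1 / .a2 / .conllu."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        txt, a1, a2 = write_standoff(doc)
        (outdir / f"{doc.doc_id}.txt").write_text(txt)
        (outdir / f"{doc.doc_id}.a1").write_text(a1)
        (outdir / f"{doc.doc_id}.a2").write_text(a2)
        (outdir / f"{doc.doc_id}.conllu").write_text(write_conllu(doc.sentences))


def corpus_to_instances(
    docs: list[Document],
) -> tuple[list[CandidateInstance], CandidateStats]:
    """Run candidate generation over a corpus, summing the bookkeeping counters."""
    instances: list[CandidateInstance] = []
    stats = CandidateStats()
    for doc in docs:
        doc_instances, doc_stats = generate_candidates(doc, labeled=True)
        instances.extend(doc_instances)
        stats = stats + doc_stats
    return instances, stats


def generate_dataset(
    n_train: int, n_test: int, cfg: SynthConfig
) -> tuple[list[CandidateInstance], list[CandidateInstance]]:
    """Instance splits of the requested sizes from disjoint documents."""
    rng = np.random.default_rng(cfg.seed)
    instances: list[CandidateInstance] = []
    doc_counter = 0
    while len(instances) < n_train + n_test:
        doc = _generate_document(rng, f"synth{doc_counter:04d}", cfg)
        doc_counter += 1
        doc_instances, _ = generate_candidates(doc, labeled=True)
        instances.extend(doc_instances)
    return instances[:n_train], instances[n_train : n_train + n_test]


# ---------------------------------------------------------------------------
# worked-example fixtures
# ---------------------------------------------------------------------------


def helicobacter_japan_example() -> Document:
    """One bacteria and two location mentions in a single sentence.

    The sentence yields exactly two relation candidates; the dependency
    parse is hand-built (plausible Stanford-style attachments).
    """
    text = (
        "Long-term Helicobacter pylori infection and the development of "
        "atrophic gastritis and gastric cancer in Japan."
    )
    rows = [
        ("Long-term", "JJ", 4), ("Helicobacter", "NNP", 3), ("pylori", "NNP", 4),
        ("infection", "NN", 0), ("and", "CC", 7), ("the", "DT", 7),
        ("development", "NN", 4), ("of", "IN", 10), ("atrophic", "JJ", 10),
        ("gastritis", "NN", 7), ("and", "CC", 13), ("gastric", "JJ", 13),
        ("cancer", "NN", 10), ("in", "IN", 15), ("Japan", "NNP", 13),
        (".", ".", 4),
    ]
    sentence = ParsedSentence(
        sent_index=0,
        tokens=[Token(surface=s, pos_tag=p, head=h) for s, p, h in rows],
    )
    mentions = [
        EntityMention("T1", EntityCategory.BACTERIA,
                      text.index("Helicobacter"), text.index("Helicobacter") + len("Helicobacter pylori"),
                      "Helicobacter pylori"),
        EntityMention("T2", EntityCategory.HABITAT,
                      text.index("gastric cancer"), text.index("gastric cancer") + len("gastric"),
                      "gastric"),
        EntityMention("T3", EntityCategory.GEOGRAPHICAL,
                      text.index("Japan"), text.index("Japan") + len("Japan"), "Japan"),
    ]
    relations = [RelationGold("T1", "T2"), RelationGold("T1", "T3")]
    doc = Document(doc_id="helicobacter", text=text, mentions=mentions, relations=relations)
    return attach_parses(doc, [sentence])


def mycobacteria_queensland_example() -> Document:
    """A probe token ("in") 4 tokens after the bacteria and 1 before the location.

    The hand-built parse attaches "in" as a case marker under the location,
    so the probe is off the bacteria-location dependency path: its relative
    distances are (-4, 1) while it never appears on the SDP.
    """
    text = "The mycobacteria were found here in Queensland."
    rows = [
        ("The", "DT", 2), ("mycobacteria", "NNS", 4), ("were", "VBD", 4),
        ("found", "VBN", 0), ("here", "RB", 4), ("in", "IN", 7),
        ("Queensland", "NNP", 4), (".", ".", 4),
    ]
    sentence = ParsedSentence(
        sent_index=0,
        tokens=[Token(surface=s, pos_tag=p, head=h) for s, p, h in rows],
    )
    mentions = [
        EntityMention("T1", EntityCategory.BACTERIA,
                      text.index("mycobacteria"), text.index("mycobacteria") + len("mycobacteria"),
                      "mycobacteria"),
        EntityMention("T2", EntityCategory.GEOGRAPHICAL,
                      text.index("Queensland"), text.index("Queensland") + len("Queensland"),
                      "Queensland"),
    ]
    doc = Document(
        doc_id="mycobacteria", text=text, mentions=mentions,
        relations=[RelationGold("T1", "T2")],
    )
    return attach_parses(doc, [sentence])


def make_worked_example_fixtures() -> dict[str, Document]:
    return {
        "helicobacter": helicobacter_japan_example(),
        "mycobacteria": mycobacteria_queensland_example(),
    }
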