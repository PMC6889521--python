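"""Candidate-instance generation from parsed, annotated documents.

A classification instance is one intra-sentence (bacteria, habitat-or-
geographical) mention pair.  The sentence is entity-blinded (mention spans
collapsed to ``entity_1`` / ``entity_2``, everything else lowercased), the
shortest dependency path (SDP) between the two entity tokens is extracted
from the undirected dependency graph, and per-token relative distances to
each entity are recorded.  Pairs in different sentences produce no instance
but are counted for false-negative bookkeeping; pairs with no SDP are
dropped and counted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, TextIO

import networkx as nx

from .corpus_io import Document, EntityCategory, ParsedSentence

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateInstance",
    "CandidateStats",
    "BlindedSentence",
    "AlignmentError",
    "align_mentions_to_tokens",
    "blind_and_normalize",
    "build_dependency_graph",
    "shortest_dependency_path",
    "relative_distances",
    "generate_candidates",
    "gold_positive_pairs",
    "write_instances_jsonl",
    "read_instances_jsonl",
]

ENTITY_1 = "entity_1"
ENTITY_2 = "entity_2"


class AlignmentError(ValueError):
    """A mention cannot be mapped onto any sentence's tokens."""


@dataclass
class CandidateInstance:
    doc_id: str
    sent_index: int
    bacteria_id: str
    location_id: str
    tokens: list[str]
    pos_tags: list[str]
    entity1_pos: int
    entity2_pos: int
    sdp_indices: list[int]
    rel_dist1: list[int]
    rel_dist2: list[int]
    label: str | None = None  # "positive" | "negative" | None (unlabeled)
    p_positive: float | None = None
    decision: str | None = None

    def __post_init__(self) -> None:
        if self.entity1_pos == self.entity2_pos:
            raise ValueError("entity positions must differ")
        if len(self.tokens) != len(self.pos_tags):
            raise ValueError("tokens and pos_tags must align")
        if self.sdp_indices and {self.sdp_indices[0], self.sdp_indices[-1]} != {
            self.entity1_pos,
            self.entity2_pos,
        }:
            raise ValueError("SDP must start and end at the entity positions")

    @property
    def text(self) -> str:
        return " ".join(self.tokens)

    @property
    def pair_key(self) -> tuple[str, str, str]:
        return (self.doc_id, self.bacteria_id, self.location_id)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "CandidateInstance":
        return cls(**json.loads(line))


@dataclass
class CandidateStats:
    """Bookkeeping counters; pairs considered = instances + dropped."""

    n_instances: int = 0
    n_intra_pairs: int = 0
    n_no_sdp: int = 0
    n_overlap_skipped: int = 0
    n_alignment_failures: int = 0
    n_inter_sentence_gold: int = 0

    def __add__(self, other: "CandidateStats") -> "CandidateStats":
        return CandidateStats(
            *(getattr(self, f) + getattr(other, f) for f in self.__dataclass_fields__)
        )

    def reconciles(self) -> bool:
        return self.n_intra_pairs == self.n_instances + self.n_no_sdp + self.n_overlap_skipped


# ---------------------------------------------------------------------------
# mention/token alignment
# ---------------------------------------------------------------------------


def align_mentions_to_tokens(
    doc: Document,
) -> tuple[dict[str, tuple[int, tuple[int, int]]], list[str]]:
    """Map each mention to ``(sent_index, (token_start, token_stop))``.

    The token span is the minimal one whose character extent covers the
    mention.  Mentions crossing sentence boundaries or not covered by any
    sentence are skipped with a warning and returned in the failure list.
    """
    alignment: dict[str, tuple[int, tuple[int, int]]] = {}
    failures: list[str] = []
    for mention in doc.mentions:
        placed = False
        for sent in doc.sentences:
            if not (sent.char_start <= mention.char_start and mention.char_end <= sent.char_end):
                continue
            covered = [
                i
                for i, tok in enumerate(sent.tokens)
                if tok.char_end > mention.char_start and tok.char_start < mention.char_end
            ]
            if covered:
                alignment[mention.mention_id] = (
                    sent.sent_index,
                    (covered[0], covered[-1] + 1),
                )
                placed = True
            break
        if not placed:
            logger.warning(
                "%s: mention %s [%d,%d) not alignable to a single sentence; skipped",
                doc.doc_id, mention.mention_id, mention.char_start, mention.char_end,
            )
            failures.append(mention.mention_id)
    return alignment, failures


# ---------------------------------------------------------------------------
# entity blinding
# ---------------------------------------------------------------------------


@dataclass
class BlindedSentence:
    tokens: list[str]
    pos_tags: list[str]
    entity1_pos: int
    entity2_pos: int
    index_map: list[int] = field(repr=False, default_factory=list)  # old -> new


def blind_and_normalize(
    sentence_tokens: list[str],
    bacteria_span: tuple[int, int],
    location_span: tuple[int, int],
    pos_tags: list[str] | None = None,
) -> BlindedSentence:
    """Collapse the two mention spans to ``entity_1``/``entity_2``, lowercase the rest.

    The collapsed entity token inherits the POS tag of the mention's first
    original token.  Spans must be disjoint.
    """
    (b0, b1), (l0, l1) = bacteria_span, location_span
    if max(b0, l0) < min(b1, l1):
        raise ValueError(f"overlapping mention spans {bacteria_span} / {location_span}")
    if pos_tags is None:
        pos_tags = ["_"] * len(sentence_tokens)
    spans = {b0: (b1, ENTITY_1), l0: (l1, ENTITY_2)}
    tokens: list[str] = []
    tags: list[str] = []
    index_map: list[int] = []
    i = 0
    while i < len(sentence_tokens):
        if i in spans:
            stop, placeholder = spans[i]
            new_idx = len(tokens)
            tokens.append(placeholder)
            tags.append(pos_tags[i])
            index_map.extend([new_idx] * (stop - i))
            i = stop
        else:
            index_map.append(len(tokens))
            tokens.append(sentence_tokens[i].lower())
            tags.append(pos_tags[i])
            i += 1
    return BlindedSentence(
        tokens=tokens,
        pos_tags=tags,
        entity1_pos=index_map[b0],
        entity2_pos=index_map[l0],
        index_map=index_map,
    )


# ---------------------------------------------------------------------------
# dependency graph and shortest dependency path
# ---------------------------------------------------------------------------


def build_dependency_graph(sentence: ParsedSentence, index_map: list[int] | None = None) -> nx.Graph:
    """Undirected unit-weight graph over (blinded) token positions.

    Edges join each non-root token to its governor; edges internal to a
    collapsed mention vanish, external ones re-attach to the entity node.
    """
    n = len(sentence.tokens)
    if index_map is None:
        index_map = list(range(n))
    graph = nx.Graph()
    graph.add_nodes_from(range(max(index_map) + 1))
    for i, tok in enumerate(sentence.tokens):
        if tok.head == 0:
            continue
        a, b = index_map[i], index_map[tok.head - 1]
        if a != b:
            graph.add_edge(a, b, weight=1)
    return graph


def shortest_dependency_path(graph: nx.Graph, entity1_pos: int, entity2_pos: int) -> list[int] | None:
    """Minimum-edge path between the entity nodes, or None when disconnected.

    Ties are broken toward the lexicographically smallest index sequence so
    preprocessing is reproducible across runs and platforms.
    """
    if entity1_pos not in graph or entity2_pos not in graph:
        raise ValueError("entity positions must be graph nodes")
    try:
        dist = nx.single_source_dijkstra_path_length(graph, entity2_pos, weight="weight")
    except nx.NodeNotFound:  # pragma: no cover
        return None
    if entity1_pos not in dist:
        return None
    path = [entity1_pos]
    current = entity1_pos
    while current != entity2_pos:
        current = min(
            nbr for nbr in graph.neighbors(current) if dist.get(nbr, float("inf")) == dist[current] - 1
        )
        path.append(current)
    return path


def relative_distances(
    tokens: list[str], entity1_pos: int, entity2_pos: int
) -> tuple[list[int], list[int]]:
    """Per-token signed distances ``entity_position - token_position``.

    The sign convention puts negative values on tokens after the entity:
    a token 4 positions after the bacteria and 1 before the location gets
    (-4, 1).
    """
    if not (0 <= entity1_pos < len(tokens) and 0 <= entity2_pos < len(tokens)):
        raise ValueError("entity positions out of range")
    rel1 = [entity1_pos - i for i in range(len(tokens))]
    rel2 = [entity2_pos - i for i in range(len(tokens))]
    return rel1, rel2


# ---------------------------------------------------------------------------
# candidate generation
# ---------------------------------------------------------------------------


def _char_overlap(m1, m2) -> bool:
    return max(m1.char_start, m2.char_start) < min(m1.char_end, m2.char_end)


def generate_candidates(
    doc: Document, labeled: bool | None = None
) -> tuple[list[CandidateInstance], CandidateStats]:
    """All intra-sentence bacteria x location instances of a document.

    ``labeled=None`` infers labeling from the presence of gold relations;
    when labeled, a pair absent from the gold positives is negative.
    """
    if labeled is None:
        labeled = bool(doc.relations)
    gold_positive = {
        (r.bacteria_id, r.location_id) for r in doc.relations if r.label == "positive"
    }
    alignment, failures = align_mentions_to_tokens(doc)
    stats = CandidateStats(n_alignment_failures=len(failures))

    for rel in doc.relations:
        if rel.label != "positive":
            continue
        a = alignment.get(rel.bacteria_id)
        b = alignment.get(rel.location_id)
        if a is not None and b is not None and a[0] != b[0]:
            stats.n_inter_sentence_gold += 1

    by_sentence: dict[int, list] = {}
    for mention in doc.mentions:
        if mention.mention_id in alignment:
            by_sentence.setdefault(alignment[mention.mention_id][0], []).append(mention)

    instances: list[CandidateInstance] = []
    for sent in doc.sentences:
        group = by_sentence.get(sent.sent_index, [])
        bacteria = [m for m in group if m.category is EntityCategory.BACTERIA]
        locations = [m for m in group if m.category.is_location]
        surfaces = [t.surface for t in sent.tokens]
        tags = [t.pos_tag for t in sent.tokens]
        for bact in bacteria:
            for loc in locations:
                stats.n_intra_pairs += 1
                b_span = alignment[bact.mention_id][1]
                l_span = alignment[loc.mention_id][1]
                if _char_overlap(bact, loc) or max(b_span[0], l_span[0]) < min(
                    b_span[1], l_span[1]
                ):
                    logger.warning(
                        "%s: mentions %s/%s overlap; pair skipped",
                        doc.doc_id, bact.mention_id, loc.mention_id,
                    )
                    stats.n_overlap_skipped += 1
                    continue
                blinded = blind_and_normalize(surfaces, b_span, l_span, tags)
                graph = build_dependency_graph(sent, blinded.index_map)
                sdp = shortest_dependency_path(graph, blinded.entity1_pos, blinded.entity2_pos)
                if sdp is None:
                    stats.n_no_sdp += 1
                    continue
                rel1, rel2 = relative_distances(
                    blinded.tokens, blinded.entity1_pos, blinded.entity2_pos
                )
                label = None
                if labeled:
                    label = (
                        "positive"
                        if (bact.mention_id, loc.mention_id) in gold_positive
                        else "negative"
                    )
                instances.append(
                    CandidateInstance(
                        doc_id=doc.doc_id,
                        sent_index=sent.sent_index,
                        bacteria_id=bact.mention_id,
                        location_id=loc.mention_id,
                        tokens=blinded.tokens,
                        pos_tags=blinded.pos_tags,
                        entity1_pos=blinded.entity1_pos,
                        entity2_pos=blinded.entity2_pos,
                        sdp_indices=sdp,
                        rel_dist1=rel1,
                        rel_dist2=rel2,
                        label=label,
                    )
                )
                stats.n_instances += 1
    return instances, stats


def gold_positive_pairs(doc: Document) -> list[tuple[tuple[str, str, str], bool]]:
    """Gold positives as ``(pair_key, is_intra_sentence)`` for the scorer."""
    alignment, _ = align_mentions_to_tokens(doc)
    out = []
    for rel in doc.relations:
        if rel.label != "positive":
            continue
        a = alignment.get(rel.bacteria_id)
        b = alignment.get(rel.location_id)
        intra = a is not None and b is not None and a[0] == b[0]
        out.append(((doc.doc_id, rel.bacteria_id, rel.location_id), intra))
    return out


# ---------------------------------------------------------------------------
# instance serialization (JSON lines)
# ---------------------------------------------------------------------------


def write_instances_jsonl(instances: Iterable[CandidateInstance], stream: TextIO) -> None:
    for inst in instances:
        stream.write(inst.to_json() + "\n")


def read_instances_jsonl(stream: TextIO) -> list[CandidateInstance]:
    return [CandidateInstance.from_json(line) for line in stream if line.strip()]
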