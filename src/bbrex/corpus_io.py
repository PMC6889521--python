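"""Readers and writers for the corpus formats the pipeline touches.

Two formats are handled: BioNLP-ST standoff annotation (a document ``.txt``
with entity mentions in ``.a1`` and Lives_In relations in ``.a2``) and
CoNLL-U dependency parses.  This module only parses, validates and writes;
all linguistic computation lives downstream.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence, TextIO

logger = logging.getLogger(__name__)

__all__ = [
    "EntityCategory",
    "EntityMention",
    "RelationGold",
    "Token",
    "ParsedSentence",
    "Document",
    "FormatError",
    "ConsistencyError",
    "read_standoff",
    "write_standoff",
    "read_conllu",
    "write_conllu",
    "attach_parses",
    "write_predictions_a2",
    "read_predictions_a2",
]


class FormatError(ValueError):
    """A line of an input file does not match its format."""


class ConsistencyError(ValueError):
    """Annotations are well-formed but contradict the document text."""


class EntityCategory(str, Enum):
    BACTERIA = "Bacteria"
    HABITAT = "Habitat"
    GEOGRAPHICAL = "Geographical"

    @property
    def is_location(self) -> bool:
        return self in (EntityCategory.HABITAT, EntityCategory.GEOGRAPHICAL)


@dataclass(frozen=True)
class EntityMention:
    """An entity annotation: 0-based, half-open character offsets."""

    mention_id: str
    category: EntityCategory
    char_start: int
    char_end: int
    surface: str


@dataclass(frozen=True)
class RelationGold:
    """A gold Lives_In annotation between a bacteria and a location mention."""

    bacteria_id: str
    location_id: str
    label: str = "positive"  # "positive" | "negative"


@dataclass(frozen=True)
class Token:
    surface: str
    pos_tag: str
    head: int  # 0 = syntactic root, else 1-based index of the governor
    deprel: str = "dep"
    char_start: int = -1  # filled by attach_parses
    char_end: int = -1


@dataclass
class ParsedSentence:
    sent_index: int
    tokens: list[Token]
    char_start: int = -1
    char_end: int = -1

    def __post_init__(self) -> None:
        n = len(self.tokens)
        for tok in self.tokens:
            if not 0 <= tok.head <= n:
                raise ConsistencyError(
                    f"head index {tok.head} out of range for a {n}-token sentence"
                )


@dataclass
class Document:
    doc_id: str
    text: str
    mentions: list[EntityMention] = field(default_factory=list)
    relations: list[RelationGold] = field(default_factory=list)
    sentences: list[ParsedSentence] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.mention_id for m in self.mentions]
        if len(ids) != len(set(ids)):
            raise ConsistencyError(f"{self.doc_id}: duplicate mention ids")
        known = set(ids)
        for rel in self.relations:
            if rel.bacteria_id not in known or rel.location_id not in known:
                raise ConsistencyError(
                    f"{self.doc_id}: relation references unknown mention "
                    f"({rel.bacteria_id}, {rel.location_id})"
                )

    def mention(self, mention_id: str) -> EntityMention:
        for m in self.mentions:
            if m.mention_id == mention_id:
                return m
        raise KeyError(mention_id)


# ---------------------------------------------------------------------------
# standoff (.txt / .a1 / .a2)
# ---------------------------------------------------------------------------


def _parse_entity_line(line: str, lineno: int, text: str) -> EntityMention:
    parts = line.rstrip("\n").split("\t")
    if len(parts) != 3 or not parts[0].startswith("T"):
        raise FormatError(f"a1 line {lineno}: expected 'Tn<TAB>Category start end<TAB>surface'")
    mention_id, span_field, surface = parts
    fragments = span_field.split(";")
    head_fields = fragments[0].split()
    if len(head_fields) != 3:
        raise FormatError(f"a1 line {lineno}: malformed span field {span_field!r}")
    category_name = head_fields[0]
    try:
        category = EntityCategory(category_name)
    except ValueError as exc:
        raise FormatError(f"a1 line {lineno}: unknown category {category_name!r}") from exc
    try:
        start = int(head_fields[1])
        end = int(fragments[-1].split()[-1])
    except ValueError as exc:
        raise FormatError(f"a1 line {lineno}: non-integer offset") from exc
    if len(fragments) > 1:
        # Discontinuous mention: normalize to the covering span; the model
        # consumes contiguous token spans only.
        logger.warning(
            "a1 line %d: discontinuous mention %s normalized to covering span [%d, %d)",
            lineno, mention_id, start, end,
        )
        surface = text[start:end]
    if not 0 <= start < end <= len(text):
        raise ConsistencyError(
            f"a1 line {lineno}: offsets [{start}, {end}) outside document of length {len(text)}"
        )
    if text[start:end] != surface:
        raise ConsistencyError(
            f"a1 line {lineno}: surface {surface!r} != text slice {text[start:end]!r}"
        )
    return EntityMention(mention_id, category, start, end, surface)


def _parse_relation_line(line: str, lineno: int) -> RelationGold:
    parts = line.rstrip("\n").split("\t")
    if len(parts) != 2 or not parts[0].startswith("R"):
        raise FormatError(f"a2 line {lineno}: expected 'Rn<TAB>Lives_In ...'")
    fields = parts[1].split()
    if len(fields) != 3 or fields[0] != "Lives_In":
        raise FormatError(f"a2 line {lineno}: expected 'Lives_In Bacterium:Tx Location:Ty'")
    args = {}
    for item in fields[1:]:
        role, _, ref = item.partition(":")
        args[role] = ref
    if "Bacterium" not in args or "Location" not in args:
        raise FormatError(f"a2 line {lineno}: missing Bacterium/Location argument")
    return RelationGold(bacteria_id=args["Bacterium"], location_id=args["Location"])


def read_standoff(
    text_stream: TextIO,
    a1_stream: TextIO,
    a2_stream: TextIO | None = None,
    doc_id: str = "doc",
) -> Document:
    """Read a document from BioNLP-ST standoff streams.

    Mention surfaces are checked against the text slice; relations are
    present only when an ``.a2`` stream is supplied.
    """
    text = text_stream.read()
    mentions: list[EntityMention] = []
    for lineno, line in enumerate(a1_stream, start=1):
        if not line.strip():
            continue
        if not line.startswith("T"):
            logger.warning("a1 line %d: skipping non-entity annotation", lineno)
            continue
        mentions.append(_parse_entity_line(line, lineno, text))
    relations: list[RelationGold] = []
    if a2_stream is not None:
        for lineno, line in enumerate(a2_stream, start=1):
            if not line.strip():
                continue
            if not line.startswith("R"):
                logger.warning("a2 line %d: skipping non-relation annotation", lineno)
                continue
            relations.append(_parse_relation_line(line, lineno))
    for rel in relations:
        by_id = {m.mention_id: m for m in mentions}
        bact = by_id.get(rel.bacteria_id)
        loc = by_id.get(rel.location_id)
        if bact is None or loc is None:
            raise ConsistencyError(
                f"relation ({rel.bacteria_id}, {rel.location_id}) references a missing mention"
            )
        if bact.category is not EntityCategory.BACTERIA or not loc.category.is_location:
            raise ConsistencyError(
                f"relation ({rel.bacteria_id}, {rel.location_id}) violates category constraints"
            )
    return Document(doc_id=doc_id, text=text, mentions=mentions, relations=relations)


def write_standoff(doc: Document) -> tuple[str, str, str]:
    """Serialize a document back to (txt, a1, a2) standoff strings."""
    a1_lines = [
        f"{m.mention_id}\t{m.category.value} {m.char_start} {m.char_end}\t{m.surface}"
        for m in doc.mentions
    ]
    a2_lines = [
        f"R{i}\tLives_In Bacterium:{r.bacteria_id} Location:{r.location_id}"
        for i, r in enumerate(
            (r for r in doc.relations if r.label == "positive"), start=1
        )
    ]
    return doc.text, "\n".join(a1_lines) + ("\n" if a1_lines else ""), "\n".join(
        a2_lines
    ) + ("\n" if a2_lines else "")


# ---------------------------------------------------------------------------
# CoNLL-U
# ---------------------------------------------------------------------------


def read_conllu(stream: TextIO | str) -> list[ParsedSentence]:
    """Read CoNLL-U sentences (ID, FORM, UPOS/XPOS, HEAD, DEPREL used).

    Multiword-token ranges (``1-2``) and empty nodes (``1.1``) are skipped
    with a warning; XPOS substitutes when UPOS is missing.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    sentences: list[ParsedSentence] = []
    tokens: list[Token] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if line.startswith("#"):
            continue
        if not line.strip():
            if tokens:
                sentences.append(ParsedSentence(sent_index=len(sentences), tokens=tokens))
                tokens = []
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise FormatError(f"conllu line {lineno}: expected >=8 tab-separated columns")
        token_id = cols[0]
        if "-" in token_id or "." in token_id:
            logger.warning("conllu line %d: skipping multiword/empty-node line %r", lineno, token_id)
            continue
        form = cols[1]
        upos, xpos = cols[3], cols[4]
        pos = upos if upos not in ("", "_") else xpos
        try:
            head = int(cols[6])
        except ValueError as exc:
            raise FormatError(f"conllu line {lineno}: non-integer HEAD {cols[6]!r}") from exc
        tokens.append(Token(surface=form, pos_tag=pos, head=head, deprel=cols[7]))
    if tokens:
        sentences.append(ParsedSentence(sent_index=len(sentences), tokens=tokens))
    return sentences


def write_conllu(sentences: Iterable[ParsedSentence]) -> str:
    blocks = []
    for sent in sentences:
        lines = [
            "\t".join(
                [
                    str(i),
                    tok.surface,
                    "_",
                    tok.pos_tag,
                    tok.pos_tag,
                    "_",
                    str(tok.head),
                    tok.deprel,
                    "_",
                    "_",
                ]
            )
            for i, tok in enumerate(sent.tokens, start=1)
        ]
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


def attach_parses(doc: Document, sentences: Sequence[ParsedSentence]) -> Document:
    """Align parsed sentences to the document text and attach them.

    Token surfaces are matched left-to-right against the raw text (any
    whitespace between tokens is allowed), producing character spans per
    token and per sentence.  A token that cannot be found is a
    :class:`ConsistencyError` — the parse does not belong to this text.
    """
    cursor = 0
    attached: list[ParsedSentence] = []
    for sent in sentences:
        placed: list[Token] = []
        for tok in sent.tokens:
            found = doc.text.find(tok.surface, cursor)
            if found < 0 or doc.text[cursor:found].strip():
                raise ConsistencyError(
                    f"{doc.doc_id}: token {tok.surface!r} not found at text offset {cursor}"
                )
            placed.append(replace(tok, char_start=found, char_end=found + len(tok.surface)))
            cursor = found + len(tok.surface)
        attached.append(
            ParsedSentence(
                sent_index=sent.sent_index,
                tokens=placed,
                char_start=placed[0].char_start,
                char_end=placed[-1].char_end,
            )
        )
    return Document(
        doc_id=doc.doc_id,
        text=doc.text,
        mentions=list(doc.mentions),
        relations=list(doc.relations),
        sentences=attached,
    )


# ---------------------------------------------------------------------------
# predictions (.a2 output)
# ---------------------------------------------------------------------------


def write_predictions_a2(candidates: Iterable) -> str:
    """Write positive decisions as a2 relation lines, numbered densely from 1.

    Each candidate must expose ``decision`` ("positive"/"negative"),
    ``bacteria_id`` and ``location_id`` attributes; a missing decision is a
    state error.
    """
    lines = []
    n = 0
    for cand in candidates:
        decision = getattr(cand, "decision", None)
        if decision is None:
            raise ValueError("candidate without a decision cannot be written")
        if decision == "positive":
            n += 1
            lines.append(f"R{n}\tLives_In Bacterium:{cand.bacteria_id} Location:{cand.location_id}")
    return "\n".join(lines) + ("\n" if lines else "")


def read_predictions_a2(text: str) -> list[tuple[str, str]]:
    """Read an a2 predictions string back into (bacteria_id, location_id) pairs."""
    pairs = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        rel = _parse_relation_line(line, lineno)
        pairs.append((rel.bacteria_id, rel.location_id))
    return pairs
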