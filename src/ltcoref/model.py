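"""Document and annotation data model.

The resolver never sees raw text: its sole textual input is an
:class:`AnnotatedDocument` — sentences segmented into lexemes that carry a
lemma, a part of speech and (for nouns and pronouns) grammatical gender and
number, plus named-entity spans produced by an upstream NER step.  All spans
are 0-based character offsets expressed as ``(start, length)``.

The resolver's output is a list of :class:`CoreferenceLink` objects, each
tying a referent span (the anaphoric expression) to one or more mention
spans, typed by the six admissible (type, subtype) pairs.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, field, replace


class ValidationError(ValueError):
    """Input annotation violates the document schema or an invariant."""


class StructureError(ValidationError):
    """Spans are structurally inconsistent (overlaps, dangling references)."""


class ConfigurationError(ValueError):
    """Run configuration is incoherent (e.g. A5 without a publication date)."""


class Pos(str, enum.Enum):
    Noun = "Noun"
    Pronoun = "Pronoun"
    Preposition = "Preposition"
    Conjunction = "Conjunction"
    Comma = "Comma"
    OtherPunct = "OtherPunct"
    OtherWord = "OtherWord"


class PronounType(str, enum.Enum):
    Relative = "Relative"
    Demonstrative = "Demonstrative"
    Other = "Other"
    NotApplicable = "NotApplicable"


class Gender(str, enum.Enum):
    Masculine = "Masculine"
    Feminine = "Feminine"
    #: morphologically ambiguous forms (e.g. Lithuanian "man" can refer to a
    #: person of any gender); compatible with every gender in agreement checks
    Common = "Common"


class Number(str, enum.Enum):
    Singular = "Singular"
    Plural = "Plural"
    Unspecified = "Unspecified"


class NeClass(str, enum.Enum):
    Person = "Person"
    Organization = "Organization"
    Location = "Location"


class LinkType(str, enum.Enum):
    Pronominal = "Pronominal"
    Nominal = "Nominal"


class LinkSubtype(str, enum.Enum):
    Relative = "Relative"
    General = "General"
    Repetition = "Repetition"
    Hypernym_Hyponym = "Hypernym_Hyponym"
    Synonym = "Synonym"
    Feature = "Feature"


class LinkPosition(str, enum.Enum):
    Backward = "Backward"
    Forward = "Forward"
    Irrelevant = "Irrelevant"


class LinkGroup(str, enum.Enum):
    Single = "Single"
    Multiple = "Multiple"
    Ambiguous = "Ambiguous"


#: the six admissible (type, subtype) combinations
ALLOWED_TYPE_SUBTYPE = {
    (LinkType.Pronominal, LinkSubtype.Relative),
    (LinkType.Pronominal, LinkSubtype.General),
    (LinkType.Nominal, LinkSubtype.Repetition),
    (LinkType.Nominal, LinkSubtype.Hypernym_Hyponym),
    (LinkType.Nominal, LinkSubtype.Synonym),
    (LinkType.Nominal, LinkSubtype.Feature),
}


def genders_agree(a: Gender, b: Gender) -> bool:
    """Grammatical gender agreement; Common is compatible with any gender
    (for ambiguous pronoun forms only the number is compared)."""
    return a == Gender.Common or b == Gender.Common or a == b


def numbers_agree(a: Number, b: Number) -> bool:
    return a == Number.Unspecified or b == Number.Unspecified or a == b


@dataclass(frozen=True)
class Span:
    start: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length

    def __iter__(self):
        yield self.start
        yield self.length

    def as_dict(self) -> dict:
        return {"start": self.start, "length": self.length}


@dataclass(frozen=True)
class Lexeme:
    surface: str
    lemma: str
    pos: Pos
    start: int
    length: int
    pronoun_type: PronounType = PronounType.NotApplicable
    gender: Gender = Gender.Common
    number: Number = Number.Unspecified

    @property
    def span(self) -> Span:
        return Span(self.start, self.length)


@dataclass(frozen=True)
class Sentence:
    index: int
    start: int
    length: int
    lexemes: tuple[Lexeme, ...]

    @property
    def span(self) -> Span:
        return Span(self.start, self.length)


@dataclass(frozen=True)
class NamedEntity:
    ne_class: NeClass
    start: int
    length: int
    gender: Gender
    number: Number
    lexeme_refs: tuple[int, ...]  # document-wide lexeme indices, contiguous
    head_lemma: str

    @property
    def span(self) -> Span:
        return Span(self.start, self.length)

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class Mention:
    start: int
    length: int
    lexeme_refs: tuple[int, ...] = ()
    ne_ref: int | None = None

    @property
    def span(self) -> Span:
        return Span(self.start, self.length)


@dataclass(frozen=True)
class CoreferenceLink:
    ctype: LinkType
    subtype: LinkSubtype
    position: LinkPosition
    group: LinkGroup
    referent_start: int
    referent_length: int
    mentions: tuple[Mention, ...]
    rule_id: str  # "R1".."R12"

    def __post_init__(self) -> None:
        if (self.ctype, self.subtype) not in ALLOWED_TYPE_SUBTYPE:
            raise ValidationError(
                f"disallowed type/subtype pair ({self.ctype.value}, {self.subtype.value})"
            )
        if not self.mentions:
            raise ValidationError("a coreference link needs at least one mention")

    @property
    def referent_span(self) -> Span:
        return Span(self.referent_start, self.referent_length)

    def mention_spans(self) -> frozenset[Span]:
        return frozenset(m.span for m in self.mentions)

    def sort_key(self) -> tuple:
        return (self.referent_start, int(self.rule_id[1:]),
                tuple(sorted((m.start, m.length) for m in self.mentions)))


@dataclass(frozen=True)
class AnnotatedDocument:
    doc_id: str
    text: str
    sentences: tuple[Sentence, ...]
    named_entities: tuple[NamedEntity, ...] = ()
    publication_date: _dt.date | None = None

    def lexemes(self) -> tuple[Lexeme, ...]:
        """All lexemes in document order (document-wide indexing)."""
        return tuple(lx for s in self.sentences for lx in s.lexemes)

    def sentence_of_lexeme(self, idx: int) -> Sentence:
        n = 0
        for s in self.sentences:
            if idx < n + len(s.lexemes):
                return s
            n += len(s.lexemes)
        raise IndexError(idx)

    def sentence_of_span(self, span: Span) -> Sentence | None:
        for s in self.sentences:
            if span.start >= s.start and span.end <= s.start + s.length:
                return s
        return None

    def validate(self) -> None:
        """Check every structural invariant; raise on the first violation."""
        prev_end = -1
        for i, s in enumerate(self.sentences):
            if s.index != i:
                raise StructureError(f"sentences[{i}].index: expected {i}, got {s.index}")
            if s.start <= prev_end:
                raise StructureError(f"sentences[{i}]: overlaps the previous sentence")
            if s.start + s.length > len(self.text):
                raise StructureError(f"sentences[{i}]: span exceeds text length")
            prev_end = s.start + s.length - 1
            lx_end = s.start - 1
            for j, lx in enumerate(s.lexemes):
                path = f"sentences[{i}].lexemes[{j}]"
                if lx.length < 1:
                    raise StructureError(f"{path}: length must be >= 1")
                if lx.start <= lx_end:
                    raise StructureError(f"{path}: overlaps the previous lexeme")
                if lx.start < s.start or lx.start + lx.length > s.start + s.length:
                    raise StructureError(f"{path}: outside its sentence span")
                if (lx.pronoun_type != PronounType.NotApplicable) != (lx.pos == Pos.Pronoun):
                    raise ValidationError(
                        f"{path}: pronoun_type must be set iff pos is Pronoun"
                    )
                if self.text[lx.start:lx.start + lx.length] != lx.surface:
                    raise StructureError(f"{path}: surface does not match text at offset")
                lx_end = lx.start + lx.length - 1
        all_lex = self.lexemes()
        for k, ne in enumerate(self.named_entities):
            path = f"named_entities[{k}]"
            if not ne.lexeme_refs:
                raise StructureError(f"{path}: lexeme_refs must be non-empty")
            refs = list(ne.lexeme_refs)
            if refs != list(range(refs[0], refs[0] + len(refs))):
                raise StructureError(f"{path}: lexeme_refs must be contiguous")
            if refs[-1] >= len(all_lex):
                raise StructureError(f"{path}: lexeme_refs out of range")
            sent = self.sentence_of_span(ne.span)
            if sent is None:
                raise StructureError(f"{path}: span crosses a sentence boundary")
            for r in refs:
                lx = all_lex[r]
                if lx.start < ne.start or lx.start + lx.length > ne.end:
                    raise StructureError(f"{path}: lexeme_refs[{r}] outside the NE span")

    def ne_sentence_index(self, ne: NamedEntity) -> int:
        sent = self.sentence_of_span(ne.span)
        assert sent is not None
        return sent.index


def canonical_link_order(links: list[CoreferenceLink]) -> list[CoreferenceLink]:
    """Canonical ordering: by referent start, then rule number, then mentions."""
    return sorted(links, key=lambda l: l.sort_key())


def normalize_links(links: list[CoreferenceLink]) -> list[CoreferenceLink]:
    """Span-wise canonical form: mention bookkeeping (lexeme/NE references)
    dropped, canonical order applied.  Two link lists describe the same
    annotation iff their normalized forms are equal."""
    stripped = [
        replace(l, mentions=tuple(Mention(m.start, m.length) for m in l.mentions))
        for l in links
    ]
    return canonical_link_order(stripped)


def make_link(
    rule_id: str,
    ctype: LinkType,
    subtype: LinkSubtype,
    position: LinkPosition,
    group: LinkGroup,
    referent: Span,
    mentions: list[Mention],
) -> CoreferenceLink:
    return CoreferenceLink(
        ctype=ctype,
        subtype=subtype,
        position=position,
        group=group,
        referent_start=referent.start,
        referent_length=referent.length,
        mentions=tuple(mentions),
        rule_id=rule_id,
    )


__all__ = [
    "AnnotatedDocument", "Sentence", "Lexeme", "NamedEntity", "Mention",
    "CoreferenceLink", "Span", "Pos", "PronounType", "Gender", "Number",
    "NeClass", "LinkType", "LinkSubtype", "LinkPosition", "LinkGroup",
    "ALLOWED_TYPE_SUBTYPE", "ValidationError", "StructureError",
    "ConfigurationError", "genders_agree", "numbers_agree",
    "canonical_link_order", "normalize_links", "make_link", "replace",
]
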