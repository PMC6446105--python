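"""Standoff annotation I/O.

Documents and links are stored separately from plain JSON objects addressed
by character offsets.  Document schema (all offsets 0-based, spans are
``{"start": int, "length": int}``)::

    {
      "doc_id": "...",
      "publication_date": "2018-06-15",      # optional ISO date
      "text": "...",
      "sentences": [
        {"start": 0, "length": 37,
         "lexemes": [{"surface": "...", "lemma": "...", "pos": "Noun",
                      "pronoun_type": "NotApplicable", "gender": "Masculine",
                      "number": "Singular", "start": 0, "length": 5}, ...]},
        ...
      ],
      "named_entities": [
        {"ne_class": "Person", "start": 0, "length": 13,
         "gender": "Masculine", "number": "Singular",
         "lexeme_refs": [0, 1], "head_lemma": "Jonaitis"}, ...
      ]
    }

Link files pair a ``doc_id`` with a list of typed links.  A save/load
round-trip reproduces the link list bit-exactly after canonical ordering.
"""

from __future__ import annotations

import datetime as _dt
import json
from typing import IO, Any, Iterable

from .model import (
    AnnotatedDocument, CoreferenceLink, Gender, Lexeme, LinkGroup,
    LinkPosition, LinkSubtype, LinkType, Mention, NamedEntity, NeClass,
    Number, Pos, PronounType, Sentence, Span, StructureError,
    ValidationError, canonical_link_order,
)


def _req(obj: dict, key: str, path: str) -> Any:
    if key not in obj:
        raise ValidationError(f"{path}.{key}: missing required field")
    return obj[key]


def _enum(cls, value: str, path: str):
    try:
        return cls(value)
    except ValueError:
        raise ValidationError(
            f"{path}: {value!r} is not one of {[m.value for m in cls]}"
        ) from None


def _int(value, path: str) -> int:
    if not isinstance(value, int) or isinstance(value, bool):
        raise ValidationError(f"{path}: expected an integer, got {value!r}")
    return value


def _lexeme_from_dict(d: dict, path: str) -> Lexeme:
    return Lexeme(
        surface=str(_req(d, "surface", path)),
        lemma=str(_req(d, "lemma", path)),
        pos=_enum(Pos, _req(d, "pos", path), f"{path}.pos"),
        pronoun_type=_enum(PronounType, d.get("pronoun_type", "NotApplicable"),
                           f"{path}.pronoun_type"),
        gender=_enum(Gender, d.get("gender", "Common"), f"{path}.gender"),
        number=_enum(Number, d.get("number", "Unspecified"), f"{path}.number"),
        start=_int(_req(d, "start", path), f"{path}.start"),
        length=_int(_req(d, "length", path), f"{path}.length"),
    )


def document_from_dict(data: dict) -> AnnotatedDocument:
    if not isinstance(data, dict):
        raise ValidationError("$: document must be a JSON object")
    text = str(_req(data, "text", "$"))
    sentences = []
    raw_sents = _req(data, "sentences", "$")
    if not isinstance(raw_sents, list):
        raise ValidationError("$.sentences: expected a list")
    for i, sd in enumerate(raw_sents):
        path = f"$.sentences[{i}]"
        lexemes = tuple(
            _lexeme_from_dict(ld, f"{path}.lexemes[{j}]")
            for j, ld in enumerate(_req(sd, "lexemes", path))
        )
        sentences.append(Sentence(
            index=i,
            start=_int(_req(sd, "start", path), f"{path}.start"),
            length=_int(_req(sd, "length", path), f"{path}.length"),
            lexemes=lexemes,
        ))
    nes = []
    for k, nd in enumerate(data.get("named_entities", [])):
        path = f"$.named_entities[{k}]"
        nes.append(NamedEntity(
            ne_class=_enum(NeClass, _req(nd, "ne_class", path), f"{path}.ne_class"),
            start=_int(_req(nd, "start", path), f"{path}.start"),
            length=_int(_req(nd, "length", path), f"{path}.length"),
            gender=_enum(Gender, nd.get("gender", "Common"), f"{path}.gender"),
            number=_enum(Number, nd.get("number", "Unspecified"), f"{path}.number"),
            lexeme_refs=tuple(_int(r, f"{path}.lexeme_refs") for r in
                              _req(nd, "lexeme_refs", path)),
            head_lemma=str(_req(nd, "head_lemma", path)),
        ))
    pub = data.get("publication_date")
    if pub is not None:
        try:
            pub = _dt.date.fromisoformat(pub)
        except (TypeError, ValueError):
            raise ValidationError(
                f"$.publication_date: {pub!r} is not an ISO-8601 date"
            ) from None
    doc = AnnotatedDocument(
        doc_id=str(_req(data, "doc_id", "$")),
        text=text,
        sentences=tuple(sentences),
        named_entities=tuple(nes),
        publication_date=pub,
    )
    doc.validate()
    return doc


def document_to_dict(doc: AnnotatedDocument) -> dict:
    return {
        "doc_id": doc.doc_id,
        "publication_date": doc.publication_date.isoformat()
        if doc.publication_date else None,
        "text": doc.text,
        "sentences": [
            {
                "start": s.start,
                "length": s.length,
                "lexemes": [
                    {
                        "surface": lx.surface, "lemma": lx.lemma,
                        "pos": lx.pos.value, "pronoun_type": lx.pronoun_type.value,
                        "gender": lx.gender.value, "number": lx.number.value,
                        "start": lx.start, "length": lx.length,
                    }
                    for lx in s.lexemes
                ],
            }
            for s in doc.sentences
        ],
        "named_entities": [
            {
                "ne_class": ne.ne_class.value, "start": ne.start,
                "length": ne.length, "gender": ne.gender.value,
                "number": ne.number.value, "lexeme_refs": list(ne.lexeme_refs),
                "head_lemma": ne.head_lemma,
            }
            for ne in doc.named_entities
        ],
    }


def load_document(source: IO[str] | str) -> AnnotatedDocument:
    """Read one document from a JSON standoff stream (or path)."""
    if isinstance(source, str):
        with open(source, encoding="utf-8") as fh:
            data = json.load(fh)
    else:
        data = json.load(source)
    return document_from_dict(data)


def save_document(doc: AnnotatedDocument, sink: IO[str] | str) -> None:
    _dump(document_to_dict(doc), sink)


def _dump(data: dict, sink: IO[str] | str) -> None:
    if isinstance(sink, str):
        with open(sink, "w", encoding="utf-8") as fh:
            json.dump(data, fh, ensure_ascii=False, indent=1)
            fh.write("\n")
    else:
        json.dump(data, sink, ensure_ascii=False, indent=1)
        sink.write("\n")


def link_to_dict(link: CoreferenceLink) -> dict:
    return {
        "ctype": link.ctype.value,
        "subtype": link.subtype.value,
        "position": link.position.value,
        "group": link.group.value,
        "referent": {"start": link.referent_start, "length": link.referent_length},
        "mentions": [
            {"start": m.start, "length": m.length,
             "lexeme_refs": list(m.lexeme_refs), "ne_ref": m.ne_ref}
            for m in link.mentions
        ],
        "rule_id": link.rule_id,
    }


def link_from_dict(d: dict, path: str = "$") -> CoreferenceLink:
    ref = _req(d, "referent", path)
    mentions = tuple(
        Mention(
            start=_int(_req(md, "start", f"{path}.mentions[{i}]"), f"{path}.mentions[{i}].start"),
            length=_int(_req(md, "length", f"{path}.mentions[{i}]"), f"{path}.mentions[{i}].length"),
            lexeme_refs=tuple(md.get("lexeme_refs", ())),
            ne_ref=md.get("ne_ref"),
        )
        for i, md in enumerate(_req(d, "mentions", path))
    )
    return CoreferenceLink(
        ctype=_enum(LinkType, _req(d, "ctype", path), f"{path}.ctype"),
        subtype=_enum(LinkSubtype, _req(d, "subtype", path), f"{path}.subtype"),
        position=_enum(LinkPosition, _req(d, "position", path), f"{path}.position"),
        group=_enum(LinkGroup, _req(d, "group", path), f"{path}.group"),
        referent_start=_int(_req(ref, "start", f"{path}.referent"), f"{path}.referent.start"),
        referent_length=_int(_req(ref, "length", f"{path}.referent"), f"{path}.referent.length"),
        mentions=mentions,
        rule_id=str(_req(d, "rule_id", path)),
    )


def save_annotations(
    doc: AnnotatedDocument, links: Iterable[CoreferenceLink], sink: IO[str] | str
) -> None:
    """Write a link file for ``doc``; every span must resolve inside it."""
    links = canonical_link_order(list(links))
    text_len = len(doc.text)
    for i, link in enumerate(links):
        spans = [link.referent_span, *(m.span for m in link.mentions)]
        for sp in spans:
            if sp.start < 0 or sp.end > text_len:
                raise StructureError(
                    f"links[{i}]: span ({sp.start},{sp.length}) dangles outside the document"
                )
    _dump({"doc_id": doc.doc_id, "links": [link_to_dict(l) for l in links]}, sink)


def load_annotations(source: IO[str] | str) -> tuple[str, list[CoreferenceLink]]:
    """Read a link file; returns (doc_id, links in canonical order)."""
    if isinstance(source, str):
        with open(source, encoding="utf-8") as fh:
            data = json.load(fh)
    else:
        data = json.load(source)
    links = [
        link_from_dict(ld, f"$.links[{i}]")
        for i, ld in enumerate(_req(data, "links", "$"))
    ]
    return str(_req(data, "doc_id", "$")), canonical_link_order(links)


# ---------------------------------------------------------------------------
# Document builder: constructs offset-consistent documents from token specs.

NO_SPACE_BEFORE = {Pos.Comma, Pos.OtherPunct}


class Tok:
    """Token spec for :class:`DocumentBuilder` (fixtures and generators)."""

    __slots__ = ("surface", "lemma", "pos", "ptype", "gender", "number")

    def __init__(self, surface, lemma=None, pos=Pos.OtherWord,
                 ptype=None, gender=Gender.Common, number=Number.Unspecified):
        self.surface = surface
        self.lemma = lemma if lemma is not None else surface.lower()
        self.pos = pos
        if ptype is None:
            ptype = (PronounType.Other if pos == Pos.Pronoun
                     else PronounType.NotApplicable)
        self.ptype = ptype
        self.gender = gender
        self.number = number


def noun(surface, lemma=None, gender=Gender.Masculine, number=Number.Singular):
    return Tok(surface, lemma, Pos.Noun, gender=gender, number=number)


def pron(surface, lemma=None, ptype=PronounType.Other,
         gender=Gender.Common, number=Number.Singular):
    return Tok(surface, lemma, Pos.Pronoun, ptype=ptype,
               gender=gender, number=number)


def comma():
    return Tok(",", ",", Pos.Comma)


def punct(surface="."):
    return Tok(surface, surface, Pos.OtherPunct)


def prep(surface, lemma=None):
    return Tok(surface, lemma, Pos.Preposition)


def conj(surface, lemma=None):
    return Tok(surface, lemma, Pos.Conjunction)


def word(surface, lemma=None):
    return Tok(surface, lemma, Pos.OtherWord)


class DocumentBuilder:
    """Builds an :class:`AnnotatedDocument` from token specs, computing all
    character offsets (a space between tokens except before punctuation)."""

    def __init__(self, doc_id: str, publication_date: _dt.date | None = None):
        self.doc_id = doc_id
        self.publication_date = publication_date
        self._sentences: list[list[Lexeme]] = []
        self._text_parts: list[str] = []
        self._cursor = 0
        self._ne_specs: list[tuple] = []
        self._n_lexemes = 0

    def sentence(self, tokens: list[Tok],
                 nes: list[tuple] | None = None) -> "DocumentBuilder":
        """Append one sentence.

        ``nes`` items are ``(first_tok, last_tok, ne_class, gender, number,
        head_lemma)`` with token indices local to this sentence, inclusive.
        """
        if self._sentences:
            self._text_parts.append(" ")
            self._cursor += 1
        base = self._n_lexemes
        lexemes: list[Lexeme] = []
        for i, t in enumerate(tokens):
            if i > 0 and t.pos not in NO_SPACE_BEFORE:
                self._text_parts.append(" ")
                self._cursor += 1
            lx = Lexeme(
                surface=t.surface, lemma=t.lemma, pos=t.pos,
                pronoun_type=t.ptype, gender=t.gender, number=t.number,
                start=self._cursor, length=len(t.surface),
            )
            self._text_parts.append(t.surface)
            self._cursor += len(t.surface)
            lexemes.append(lx)
        self._sentences.append(lexemes)
        self._n_lexemes += len(lexemes)
        for spec in nes or []:
            first, last, ne_class, gender, number, head = spec
            self._ne_specs.append(
                (base + first, base + last, ne_class, gender, number, head)
            )
        return self

    def build(self) -> AnnotatedDocument:
        text = "".join(self._text_parts)
        sentences = []
        for i, lexemes in enumerate(self._sentences):
            start = lexemes[0].start
            end = lexemes[-1].start + lexemes[-1].length
            sentences.append(Sentence(
                index=i, start=start, length=end - start, lexemes=tuple(lexemes)
            ))
        all_lex = [lx for s in sentences for lx in s.lexemes]
        nes = []
        for first, last, ne_class, gender, number, head in self._ne_specs:
            start = all_lex[first].start
            end = all_lex[last].start + all_lex[last].length
            nes.append(NamedEntity(
                ne_class=ne_class, start=start, length=end - start,
                gender=gender, number=number,
                lexeme_refs=tuple(range(first, last + 1)), head_lemma=head,
            ))
        doc = AnnotatedDocument(
            doc_id=self.doc_id, text=text, sentences=tuple(sentences),
            named_entities=tuple(nes), publication_date=self.publication_date,
        )
        doc.validate()
        return doc


# ---------------------------------------------------------------------------
# Optional CoNLL-U import.

_UPOS_MAP = {
    "NOUN": Pos.Noun, "PROPN": Pos.Noun, "PRON": Pos.Pronoun,
    "ADP": Pos.Preposition, "CCONJ": Pos.Conjunction, "SCONJ": Pos.Conjunction,
}
_PRONTYPE_MAP = {"Rel": PronounType.Relative, "Dem": PronounType.Demonstrative}


def load_conllu(source: IO[str] | str, doc_id: str = "conllu",
                publication_date: _dt.date | None = None) -> AnnotatedDocument:
    """Minimal CoNLL-U import.

    Maps FORM/LEMMA/UPOS/FEATS onto lexemes; punctuation with form "," becomes
    a Comma.  A ``NE=Class`` entry in MISC opens or continues a named-entity
    span over consecutive tokens (``NE=Class-head`` marks its head lexeme).
    """
    if isinstance(source, str):
        with open(source, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    else:
        lines = source.read().splitlines()

    builder = DocumentBuilder(doc_id, publication_date)
    sent_tokens: list[Tok] = []
    sent_nes: list[tuple] = []
    open_ne: list | None = None  # [first, last, class, gender, number, head]

    def flush():
        nonlocal sent_tokens, sent_nes, open_ne
        if open_ne is not None:
            sent_nes.append(tuple(open_ne))
            open_ne = None
        if sent_tokens:
            builder.sentence(sent_tokens, sent_nes)
        sent_tokens, sent_nes = [], []

    for line in lines:
        line = line.strip("\n")
        if not line.strip():
            flush()
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 10 or "-" in cols[0] or "." in cols[0]:
            continue  # multiword-token ranges and empty nodes are skipped
        form, lemma, upos, feats, misc = cols[1], cols[2], cols[3], cols[5], cols[9]
        featmap = dict(
            kv.split("=", 1) for kv in feats.split("|") if "=" in kv
        ) if feats != "_" else {}
        if upos == "PUNCT":
            pos = Pos.Comma if form == "," else Pos.OtherPunct
        else:
            pos = _UPOS_MAP.get(upos, Pos.OtherWord)
        gender = {"Masc": Gender.Masculine, "Fem": Gender.Feminine}.get(
            featmap.get("Gender"), Gender.Common)
        number = {"Sing": Number.Singular, "Plur": Number.Plural}.get(
            featmap.get("Number"), Number.Unspecified)
        ptype = (_PRONTYPE_MAP.get(featmap.get("PronType"), PronounType.Other)
                 if pos == Pos.Pronoun else PronounType.NotApplicable)
        idx = len(sent_tokens)
        sent_tokens.append(Tok(form, lemma if lemma != "_" else form, pos,
                               ptype=ptype, gender=gender, number=number))
        ne_tag = None
        if misc != "_":
            for kv in misc.split("|"):
                if kv.startswith("NE="):
                    ne_tag = kv[3:]
        if ne_tag:
            head = ne_tag.endswith("-head")
            ne_class = NeClass(ne_tag[:-5] if head else ne_tag)
            if open_ne is not None and open_ne[2] == ne_class and open_ne[1] == idx - 1:
                open_ne[1] = idx
                if head:
                    open_ne[5] = lemma
                open_ne[3], open_ne[4] = gender, number
            else:
                if open_ne is not None:
                    sent_nes.append(tuple(open_ne))
                open_ne = [idx, idx, ne_class, gender, number, lemma]
        elif open_ne is not None:
            sent_nes.append(tuple(open_ne))
            open_ne = None
    flush()
    return builder.build()
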