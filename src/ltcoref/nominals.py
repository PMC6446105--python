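"""Nominal algorithms.

A3 — PRA (partial, repetition, acronym): links repeated named-entity
occurrences.  Exact repetition matches lemma sequences case-insensitively;
the partial/acronym dialect additionally matches shortened person forms
(initial + surname, bare surname) by head lemma and single-token uppercase
acronyms of multiword organisation names.  Chains stay sparse: each
occurrence links only to its *nearest* preceding match (B→A, C→B, never C→A).

A4 — HHS (hypernym/hyponym/synonym): links profession-name nouns that agree
in gender and number when the profession taxonomy relates their concepts
(directly broader/narrower → Hypernym_Hyponym; same concept via any name
variants → Synonym).

A5 — feature resolution: a Singular noun naming a public position held — on
the document's publication date — by a known person mentioned as a Person NE
in the text, agreeing with that person's gender; Backward when the NE
precedes the noun, Forward when it follows.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

from .kb import PersonsKB, ProfessionRelation, ProfessionTaxonomy
from .model import (
    AnnotatedDocument, ConfigurationError, CoreferenceLink, Gender, Lexeme,
    LinkGroup, LinkPosition, LinkSubtype, LinkType, Mention, NamedEntity,
    NeClass, Number, Pos, Span, genders_agree, make_link, numbers_agree,
)

ACRONYM_DIALECTS = ("default", "off")


def _ne_lexemes(doc: AnnotatedDocument, ne: NamedEntity) -> list[Lexeme]:
    all_lex = doc.lexemes()
    return [all_lex[i] for i in ne.lexeme_refs]


def _joined_lemma(doc: AnnotatedDocument, ne: NamedEntity) -> str:
    return " ".join(lx.lemma for lx in _ne_lexemes(doc, ne)).casefold()


def _is_initial(surface: str) -> bool:
    return len(surface) == 2 and surface[0].isupper() and surface[1] == "."


def _person_shape(doc: AnnotatedDocument, ne: NamedEntity) -> str:
    """'initial' (J. Jonaitis), 'surname' (bare Jonaitis) or 'full'."""
    lexemes = _ne_lexemes(doc, ne)
    if any(_is_initial(lx.surface) for lx in lexemes):
        return "initial"
    if len(lexemes) == 1:
        return "surname"
    return "full"


def _acronym_of(doc: AnnotatedDocument, ne: NamedEntity) -> str | None:
    """Concatenated word initials of a multiword NE, uppercased."""
    lexemes = _ne_lexemes(doc, ne)
    if len(lexemes) < 2:
        return None
    return "".join(lx.surface[0] for lx in lexemes).upper()


def _is_acronym_token(doc: AnnotatedDocument, ne: NamedEntity) -> str | None:
    lexemes = _ne_lexemes(doc, ne)
    if len(lexemes) == 1 and len(lexemes[0].surface) >= 2 \
            and lexemes[0].surface.isupper():
        return lexemes[0].surface
    return None


def repetition_match(doc: AnnotatedDocument, earlier: NamedEntity,
                     later: NamedEntity, acronyms: bool) -> bool:
    """Does the later NE occurrence repeat the earlier one?"""
    if earlier.ne_class != later.ne_class:
        return False
    if _joined_lemma(doc, earlier) == _joined_lemma(doc, later):
        return True
    if not acronyms:
        return False
    if earlier.ne_class == NeClass.Person:
        # partial person match: same surname lemma, at least one shortened form
        if earlier.head_lemma.casefold() != later.head_lemma.casefold():
            return False
        shapes = {_person_shape(doc, earlier), _person_shape(doc, later)}
        return shapes != {"full"}
    if earlier.ne_class == NeClass.Organization:
        token = _is_acronym_token(doc, later)
        return token is not None and token == _acronym_of(doc, earlier)
    return False  # locations: exact lemma only


def resolve_repetition(
    doc: AnnotatedDocument, acronym_dialect: str = "default"
) -> list[CoreferenceLink]:
    """A3 (Rule 8 + partial/acronym extension).

    Every NE occurrence after the first links to its nearest preceding
    match, so a cluster of k co-referring occurrences yields k-1 links.
    """
    if acronym_dialect not in ACRONYM_DIALECTS:
        raise ConfigurationError(f"unknown acronym dialect {acronym_dialect!r}")
    acronyms = acronym_dialect == "default"
    nes = sorted(doc.named_entities, key=lambda ne: ne.start)
    links: list[CoreferenceLink] = []
    for j, later in enumerate(nes):
        best: NamedEntity | None = None
        for earlier in nes[:j]:
            if repetition_match(doc, earlier, later, acronyms):
                if best is None or earlier.start > best.start:
                    best = earlier
        if best is not None:
            links.append(make_link(
                "R8", LinkType.Nominal, LinkSubtype.Repetition,
                LinkPosition.Irrelevant, LinkGroup.Single,
                referent=later.span,
                mentions=[Mention(best.start, best.length,
                                  lexeme_refs=best.lexeme_refs,
                                  ne_ref=doc.named_entities.index(best))],
            ))
    return links


@dataclass(frozen=True)
class ProfessionOccurrence:
    """A contiguous lexeme span matching a profession name variant; the head
    noun (last lexeme) supplies gender and number."""
    span: Span
    profession_id: str
    gender: Gender
    number: Number
    lexeme_refs: tuple[int, ...]


def profession_occurrences(
    doc: AnnotatedDocument, taxonomy: ProfessionTaxonomy
) -> list[ProfessionOccurrence]:
    """Leftmost-longest scan for taxonomy name variants whose matched span
    ends on a Noun lexeme."""
    occurrences: list[ProfessionOccurrence] = []
    offset = 0
    for sent in doc.sentences:
        lex = sent.lexemes
        i = 0
        while i < len(lex):
            matched = None
            for width in range(min(taxonomy.max_name_len, len(lex) - i), 0, -1):
                window = lex[i:i + width]
                if window[-1].pos != Pos.Noun:
                    continue
                pid = taxonomy.profession_of(tuple(w.lemma for w in window))
                if pid is not None:
                    matched = (width, pid)
                    break
            if matched is None:
                i += 1
                continue
            width, pid = matched
            head = lex[i + width - 1]
            start = lex[i].start
            occurrences.append(ProfessionOccurrence(
                span=Span(start, head.start + head.length - start),
                profession_id=pid,
                gender=head.gender,
                number=head.number,
                lexeme_refs=tuple(range(offset + i, offset + i + width)),
            ))
            i += width
        offset += len(lex)
    return occurrences


def resolve_profession(
    doc: AnnotatedDocument,
    taxonomy: ProfessionTaxonomy,
    orientation: str = "fol",
) -> list[CoreferenceLink]:
    """A4 (Rules 9-10): pair profession-name nouns agreeing in gender AND
    number; same concept → Synonym, directly related concepts →
    Hypernym_Hyponym.  Each occurrence pairs with its nearest preceding
    qualifying occurrence only.

    ``orientation='fol'`` assigns the referent span to the earlier noun as
    the rules' quantifier order does; ``'anaphor'`` flips it so the later
    occurrence (the anaphor) is the referent.
    """
    if orientation not in ("fol", "anaphor"):
        raise ConfigurationError(f"unknown nominal orientation {orientation!r}")
    occurrences = profession_occurrences(doc, taxonomy)
    links: list[CoreferenceLink] = []
    for j, later in enumerate(occurrences):
        best: tuple[ProfessionOccurrence, LinkSubtype] | None = None
        for earlier in occurrences[:j]:
            if not (genders_agree(earlier.gender, later.gender)
                    and numbers_agree(earlier.number, later.number)):
                continue
            if earlier.profession_id == later.profession_id:
                subtype = LinkSubtype.Synonym
            elif taxonomy._related(earlier.profession_id, later.profession_id):
                subtype = LinkSubtype.Hypernym_Hyponym
            else:
                continue
            if best is None or earlier.span.start > best[0].span.start:
                best = (earlier, subtype)
        if best is None:
            continue
        earlier, subtype = best
        if orientation == "fol":
            referent, mention_occ = earlier, later
        else:
            referent, mention_occ = later, earlier
        rule_id = "R10" if subtype == LinkSubtype.Synonym else "R9"
        links.append(make_link(
            rule_id, LinkType.Nominal, subtype,
            LinkPosition.Irrelevant, LinkGroup.Single,
            referent=referent.span,
            mentions=[Mention(mention_occ.span.start, mention_occ.span.length,
                              lexeme_refs=mention_occ.lexeme_refs)],
        ))
    return links


def resolve_feature(
    doc: AnnotatedDocument, persons_kb: PersonsKB
) -> list[CoreferenceLink]:
    """A5 (Rules 11-12): tie a position-title noun to the Person NE of the
    known person holding that position on the publication date.

    For each qualifying Singular noun the nearest preceding matching NE wins
    (Backward, Rule 11); only when none precedes is the nearest following NE
    taken (Forward, Rule 12).
    """
    if doc.publication_date is None:
        raise ConfigurationError(
            f"document {doc.doc_id!r}: feature resolution (A5) requires a "
            "publication date"
        )
    date = doc.publication_date
    person_nes = [ne for ne in doc.named_entities if ne.ne_class == NeClass.Person]
    links: list[CoreferenceLink] = []
    for lx in doc.lexemes():
        if lx.pos != Pos.Noun or lx.number != Number.Singular:
            continue
        candidates: list[NamedEntity] = []
        for ne in person_nes:
            for person, held in persons_kb.lookup_person(ne, date):
                if held.title_lemma.casefold() != lx.lemma.casefold():
                    continue
                if not genders_agree(lx.gender, person.gender):
                    continue
                candidates.append(ne)
                break
        if not candidates:
            continue
        preceding = [ne for ne in candidates if ne.start < lx.start]
        if preceding:
            ne = max(preceding, key=lambda n: n.start)
            rule_id, position = "R11", LinkPosition.Backward
        else:
            ne = min((n for n in candidates if n.start > lx.start),
                     key=lambda n: n.start)
            rule_id, position = "R12", LinkPosition.Forward
        links.append(make_link(
            rule_id, LinkType.Nominal, LinkSubtype.Feature,
            position, LinkGroup.Single,
            referent=lx.span,
            mentions=[Mention(ne.start, ne.length, lexeme_refs=ne.lexeme_refs,
                              ne_ref=doc.named_entities.index(ne))],
        ))
    return links
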