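"""Pronominal algorithms.

A1 — *specific rules* for relative-pronoun constructions with a rigid local
pattern ``[noun] [comma] [optional preposition] [relative pronoun]`` (Rule 1)
and its plural variant where the relative pronoun closes a coordinated noun
list ``noun (, noun)* conj noun , [prep] pronoun`` (Rule 2).

A2 — *general-purpose* resolution of non-demonstrative pronouns to person
named entities: nearest agreeing Person NE, searching backward through the
current and up to two preceding sentences, then forward through the current
and the next sentence.  A pronoun whose gender is morphologically ambiguous
(Common) is matched on number alone.
"""

from __future__ import annotations

from .model import (
    AnnotatedDocument, CoreferenceLink, Gender, Lexeme, LinkGroup,
    LinkPosition, LinkSubtype, LinkType, Mention, NamedEntity, NeClass,
    Number, Pos, PronounType, Sentence, genders_agree, make_link,
    numbers_agree,
)


def _sentence_lexeme_index(sentence: Sentence, pronoun: Lexeme) -> int:
    for i, lx in enumerate(sentence.lexemes):
        if lx.start == pronoun.start:
            return i
    raise ValueError("pronoun not in sentence")


def comma_pattern_anchor(sentence: Sentence, idx: int) -> int | None:
    """Index of the comma the pronoun at ``idx`` attaches to, if the lexeme
    pattern ``comma [preposition] pronoun`` holds; None otherwise."""
    lex = sentence.lexemes
    if idx >= 1 and lex[idx - 1].pos == Pos.Comma:
        return idx - 1
    if (idx >= 2 and lex[idx - 1].pos == Pos.Preposition
            and lex[idx - 2].pos == Pos.Comma):
        return idx - 2
    return None


def has_relative_pattern(sentence: Sentence, pronoun: Lexeme) -> bool:
    """True when the A1 trigger pattern precedes a Relative pronoun."""
    if pronoun.pronoun_type != PronounType.Relative:
        return False
    idx = _sentence_lexeme_index(sentence, pronoun)
    return comma_pattern_anchor(sentence, idx) is not None


def _list_nouns_before(sentence: Sentence, comma_idx: int) -> list[Lexeme] | None:
    """Match the coordinated list ``noun (, noun)* conj noun`` ending right
    before the comma at ``comma_idx``; nouns in text order, or None."""
    lex = sentence.lexemes
    i = comma_idx - 1
    if i < 0 or lex[i].pos != Pos.Noun:
        return None
    nouns = [lex[i]]
    i -= 1
    if i < 0 or lex[i].pos != Pos.Conjunction:
        return None
    i -= 1
    if i < 0 or lex[i].pos != Pos.Noun:
        return None
    nouns.append(lex[i])
    i -= 1
    while i >= 1 and lex[i].pos == Pos.Comma and lex[i - 1].pos == Pos.Noun:
        nouns.append(lex[i - 1])
        i -= 2
    nouns.reverse()
    return nouns


def resolve_relative_multiple(
    doc: AnnotatedDocument, sentence: Sentence, pronoun: Lexeme
) -> CoreferenceLink | None:
    """Rule 2: a Plural relative pronoun closing a coordinated noun list.

    No gender or per-noun number agreement is required — the coordinated
    nouns may mix genders and numbers.  The list is generalised to any
    n >= 2 nouns.
    """
    if pronoun.number != Number.Plural:
        return None
    idx = _sentence_lexeme_index(sentence, pronoun)
    comma_idx = comma_pattern_anchor(sentence, idx)
    if comma_idx is None:
        return None
    nouns = _list_nouns_before(sentence, comma_idx)
    if nouns is None:
        return None
    return make_link(
        "R2", LinkType.Pronominal, LinkSubtype.Relative,
        LinkPosition.Backward, LinkGroup.Multiple,
        referent=pronoun.span,
        mentions=[Mention(n.start, n.length) for n in nouns],
    )


def resolve_relative_single(
    doc: AnnotatedDocument, sentence: Sentence, pronoun: Lexeme
) -> CoreferenceLink | None:
    """Rule 1: relative pronoun after ``[noun] [comma] [opt. preposition]``,
    agreeing with that noun in gender and number."""
    idx = _sentence_lexeme_index(sentence, pronoun)
    comma_idx = comma_pattern_anchor(sentence, idx)
    if comma_idx is None:
        return None
    if comma_idx < 1:
        return None
    antecedent = sentence.lexemes[comma_idx - 1]
    if antecedent.pos != Pos.Noun:
        return None
    if not (genders_agree(pronoun.gender, antecedent.gender)
            and numbers_agree(pronoun.number, antecedent.number)):
        return None
    return make_link(
        "R1", LinkType.Pronominal, LinkSubtype.Relative,
        LinkPosition.Backward, LinkGroup.Single,
        referent=pronoun.span,
        mentions=[Mention(antecedent.start, antecedent.length)],
    )


def resolve_relative(
    doc: AnnotatedDocument, sentence: Sentence, pronoun: Lexeme
) -> CoreferenceLink | None:
    """A1 entry point: the plural list rule first, else the single-noun rule."""
    if pronoun.pronoun_type != PronounType.Relative:
        return None
    link = resolve_relative_multiple(doc, sentence, pronoun)
    if link is not None:
        return link
    return resolve_relative_single(doc, sentence, pronoun)


def _agrees(pronoun: Lexeme, ne: NamedEntity) -> bool:
    return (genders_agree(pronoun.gender, ne.gender)
            and numbers_agree(pronoun.number, ne.number))


def _person_nes_in_sentence(
    doc: AnnotatedDocument, sent_index: int
) -> list[NamedEntity]:
    out = []
    for ne in doc.named_entities:
        if ne.ne_class != NeClass.Person:
            continue
        if doc.ne_sentence_index(ne) == sent_index:
            out.append(ne)
    return out


def resolve_general_pronoun(
    doc: AnnotatedDocument, sentence: Sentence, pronoun: Lexeme
) -> CoreferenceLink | None:
    """A2 (Rules 3-7): resolve a non-demonstrative pronoun to the nearest
    agreeing Person NE.

    Search order: same sentence before the pronoun (Rule 3), the previous
    sentence (Rule 4), the sentence before that (Rule 5); failing all
    backward steps, same sentence after the pronoun (Rule 6), then the next
    sentence (Rule 7).  Backward steps take the candidate with the greatest
    start offset (no strictly closer agreeing candidate exists); forward
    steps take the smallest.  Organisation and location entities are never
    candidates.
    """
    if pronoun.pronoun_type == PronounType.Demonstrative:
        return None
    si = sentence.index

    def backward(nes: list[NamedEntity], bound: int | None) -> NamedEntity | None:
        cands = [ne for ne in nes if _agrees(pronoun, ne)
                 and (bound is None or ne.start < bound)]
        return max(cands, key=lambda ne: ne.start) if cands else None

    def forward(nes: list[NamedEntity], bound: int | None) -> NamedEntity | None:
        cands = [ne for ne in nes if _agrees(pronoun, ne)
                 and (bound is None or ne.start > bound)]
        return min(cands, key=lambda ne: ne.start) if cands else None

    steps: list[tuple[str, LinkPosition, NamedEntity | None]] = [
        ("R3", LinkPosition.Backward,
         backward(_person_nes_in_sentence(doc, si), pronoun.start)),
        ("R4", LinkPosition.Backward,
         backward(_person_nes_in_sentence(doc, si - 1), None) if si >= 1 else None),
        ("R5", LinkPosition.Backward,
         backward(_person_nes_in_sentence(doc, si - 2), None) if si >= 2 else None),
        ("R6", LinkPosition.Forward,
         forward(_person_nes_in_sentence(doc, si), pronoun.start)),
        ("R7", LinkPosition.Forward,
         forward(_person_nes_in_sentence(doc, si + 1), None)
         if si + 1 < len(doc.sentences) else None),
    ]
    for rule_id, position, ne in steps:
        if ne is not None:
            return make_link(
                rule_id, LinkType.Pronominal, LinkSubtype.General,
                position, LinkGroup.Single,
                referent=pronoun.span,
                mentions=[Mention(ne.start, ne.length,
                                  lexeme_refs=ne.lexeme_refs,
                                  ne_ref=doc.named_entities.index(ne))],
            )
    return None
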