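"""Brute-force declarative evaluator of the twelve resolution rules.

This module re-derives the link set of a document by exhaustive enumeration:
for every anaphor candidate it enumerates *all* candidate tuples (pronoun x
noun, pronoun x named entity, NE x NE, noun x noun, noun x NE x KB record)
and keeps those satisfying the first-order rule bodies, including the
negated-existential "no strictly closer candidate" conditions, checked
literally over the full candidate set.  It shares the data model and the
knowledge-base lookups with the engine but none of its sequential search
code, so agreement between the two is a meaningful cross-check; the test
suite relies on that.

Cross-rule priority mirrors the decision table: a relative pronoun matching
the comma pattern belongs to the specific rules (1-2) and is never offered
to the general-purpose rules; within the general-purpose family the backward
rules 3-5 preempt the forward rules 6-7 in distance order.
"""

from __future__ import annotations

from .kb import PersonsKB, ProfessionTaxonomy
from .model import (
    AnnotatedDocument, CoreferenceLink, Lexeme, LinkGroup, LinkPosition,
    LinkSubtype, LinkType, Mention, NamedEntity, NeClass, Number, Pos,
    PronounType, Sentence, canonical_link_order, genders_agree, make_link,
    numbers_agree,
)
from .nominals import profession_occurrences, repetition_match


def _immediately_follows(sentence: Sentence, a: Lexeme, b: Lexeme) -> bool:
    """follows(a, b): a is the lexeme right after b in the sentence."""
    lex = sentence.lexemes
    for i in range(1, len(lex)):
        if lex[i] is a and lex[i - 1] is b:
            return True
    return False


def _rule1_links(sentence: Sentence, p: Lexeme) -> list[CoreferenceLink]:
    links = []
    for c in sentence.lexemes:
        if c.pos != Pos.Comma:
            continue
        attached = _immediately_follows(sentence, p, c) or any(
            l1.pos == Pos.Preposition
            and _immediately_follows(sentence, l1, c)
            and _immediately_follows(sentence, p, l1)
            for l1 in sentence.lexemes
        )
        if not attached:
            continue
        for l2 in sentence.lexemes:
            if l2.pos != Pos.Noun:
                continue
            if not _immediately_follows(sentence, c, l2):
                continue  # the noun must immediately precede the comma
            if genders_agree(p.gender, l2.gender) and numbers_agree(p.number, l2.number):
                links.append(make_link(
                    "R1", LinkType.Pronominal, LinkSubtype.Relative,
                    LinkPosition.Backward, LinkGroup.Single,
                    referent=p.span, mentions=[Mention(l2.start, l2.length)],
                ))
    return links


def _rule2_links(sentence: Sentence, p: Lexeme) -> list[CoreferenceLink]:
    if p.number != Number.Plural:
        return []
    lex = sentence.lexemes
    links = []
    for ci, c1 in enumerate(lex):
        if c1.pos != Pos.Comma:
            continue
        attached = _immediately_follows(sentence, p, c1) or any(
            l.pos == Pos.Preposition
            and _immediately_follows(sentence, l, c1)
            and _immediately_follows(sentence, p, l)
            for l in lex
        )
        if not attached:
            continue
        # enumerate the coordinated list noun (comma noun)* conj noun right
        # before c1, walking every admissible backward extension
        if ci < 1 or lex[ci - 1].pos != Pos.Noun:
            continue
        nouns = [lex[ci - 1]]
        i = ci - 2
        if i < 0 or lex[i].pos != Pos.Conjunction:
            continue
        i -= 1
        if i < 0 or lex[i].pos != Pos.Noun:
            continue
        nouns.append(lex[i])
        i -= 1
        while i >= 1 and lex[i].pos == Pos.Comma and lex[i - 1].pos == Pos.Noun:
            nouns.append(lex[i - 1])
            i -= 2
        nouns.reverse()
        links.append(make_link(
            "R2", LinkType.Pronominal, LinkSubtype.Relative,
            LinkPosition.Backward, LinkGroup.Multiple,
            referent=p.span,
            mentions=[Mention(n.start, n.length) for n in nouns],
        ))
    return links


def _general_links(
    doc: AnnotatedDocument, sentence: Sentence, p: Lexeme
) -> list[CoreferenceLink]:
    person_nes = [ne for ne in doc.named_entities if ne.ne_class == NeClass.Person]

    def agreeing(sent_index: int) -> list[NamedEntity]:
        return [
            ne for ne in person_nes
            if doc.ne_sentence_index(ne) == sent_index
            and genders_agree(p.gender, ne.gender)
            and numbers_agree(p.number, ne.number)
        ]

    si = sentence.index
    # each tuple: (rule, position, candidate set, closer-candidate predicate)
    stages = [
        ("R3", LinkPosition.Backward,
         [ne for ne in agreeing(si) if ne.start < p.start],
         lambda e1, pool: any(e2.start > e1.start for e2 in pool)),
        ("R4", LinkPosition.Backward,
         agreeing(si - 1) if si >= 1 else [],
         lambda e1, pool: any(e2.start > e1.start for e2 in pool)),
        ("R5", LinkPosition.Backward,
         agreeing(si - 2) if si >= 2 else [],
         lambda e1, pool: any(e2.start > e1.start for e2 in pool)),
        ("R6", LinkPosition.Forward,
         [ne for ne in agreeing(si) if ne.start > p.start],
         lambda e1, pool: any(e2.start < e1.start for e2 in pool)),
        ("R7", LinkPosition.Forward,
         agreeing(si + 1) if si + 1 < len(doc.sentences) else [],
         lambda e1, pool: any(e2.start < e1.start for e2 in pool)),
    ]
    for rule_id, position, pool, closer_exists in stages:
        winners = [e1 for e1 in pool
                   if not closer_exists(e1, [e for e in pool if e is not e1])]
        if winners:
            assert len(winners) == 1  # offsets are strict, ties are vacuous
            ne = winners[0]
            return [make_link(
                rule_id, LinkType.Pronominal, LinkSubtype.General,
                position, LinkGroup.Single,
                referent=p.span,
                mentions=[Mention(ne.start, ne.length,
                                  lexeme_refs=ne.lexeme_refs,
                                  ne_ref=doc.named_entities.index(ne))],
            )]
    return []


def _relative_pattern(sentence: Sentence, p: Lexeme) -> bool:
    if p.pronoun_type != PronounType.Relative:
        return False
    return any(
        c.pos == Pos.Comma and (
            _immediately_follows(sentence, p, c) or any(
                l.pos == Pos.Preposition
                and _immediately_follows(sentence, l, c)
                and _immediately_follows(sentence, p, l)
                for l in sentence.lexemes
            )
        )
        for c in sentence.lexemes
    )


def _repetition_links(
    doc: AnnotatedDocument, acronym_dialect: str
) -> list[CoreferenceLink]:
    acronyms = acronym_dialect == "default"
    nes = sorted(doc.named_entities, key=lambda ne: ne.start)
    links = []
    for j, later in enumerate(nes):
        for i, earlier in enumerate(nes[:j]):
            if not repetition_match(doc, earlier, later, acronyms):
                continue
            # chain sparsity: no matching occurrence strictly between the two
            if any(repetition_match(doc, mid, later, acronyms)
                   and mid.start > earlier.start
                   for mid in nes[:j]):
                continue
            links.append(make_link(
                "R8", LinkType.Nominal, LinkSubtype.Repetition,
                LinkPosition.Irrelevant, LinkGroup.Single,
                referent=later.span,
                mentions=[Mention(earlier.start, earlier.length,
                                  lexeme_refs=earlier.lexeme_refs,
                                  ne_ref=doc.named_entities.index(earlier))],
            ))
    return links


def _profession_links(
    doc: AnnotatedDocument, taxonomy: ProfessionTaxonomy, orientation: str
) -> list[CoreferenceLink]:
    occs = profession_occurrences(doc, taxonomy)

    def qualifies(a, b) -> LinkSubtype | None:
        if not (genders_agree(a.gender, b.gender)
                and numbers_agree(a.number, b.number)):
            return None
        if a.profession_id == b.profession_id:
            return LinkSubtype.Synonym
        if taxonomy._related(a.profession_id, b.profession_id):
            return LinkSubtype.Hypernym_Hyponym
        return None

    links = []
    for j, later in enumerate(occs):
        for earlier in occs[:j]:
            subtype = qualifies(earlier, later)
            if subtype is None:
                continue
            if any(qualifies(mid, later) is not None
                   and mid.span.start > earlier.span.start
                   for mid in occs[:j]):
                continue
            referent, mention = ((earlier, later) if orientation == "fol"
                                 else (later, earlier))
            links.append(make_link(
                "R10" if subtype == LinkSubtype.Synonym else "R9",
                LinkType.Nominal, subtype,
                LinkPosition.Irrelevant, LinkGroup.Single,
                referent=referent.span,
                mentions=[Mention(mention.span.start, mention.span.length,
                                  lexeme_refs=mention.lexeme_refs)],
            ))
    return links


def _feature_links(
    doc: AnnotatedDocument, persons_kb: PersonsKB
) -> list[CoreferenceLink]:
    assert doc.publication_date is not None
    date = doc.publication_date
    links = []
    person_nes = [ne for ne in doc.named_entities if ne.ne_class == NeClass.Person]
    for lx in doc.lexemes():
        if lx.pos != Pos.Noun or lx.number != Number.Singular:
            continue

        def matches(ne: NamedEntity) -> bool:
            return any(
                held.title_lemma.casefold() == lx.lemma.casefold()
                and genders_agree(lx.gender, person.gender)
                for person, held in persons_kb.lookup_person(ne, date)
            )

        matching = [ne for ne in person_nes if matches(ne)]
        backward = [
            ne for ne in matching
            if ne.start < lx.start
            and not any(o.start < lx.start and o.start > ne.start
                        for o in matching)
        ]
        if backward:
            ne, rule_id, position = backward[0], "R11", LinkPosition.Backward
        else:
            forward = [
                ne for ne in matching
                if ne.start > lx.start
                and not any(o.start > lx.start and o.start < ne.start
                            for o in matching)
            ]
            if not forward:
                continue
            ne, rule_id, position = forward[0], "R12", LinkPosition.Forward
        links.append(make_link(
            rule_id, LinkType.Nominal, LinkSubtype.Feature,
            position, LinkGroup.Single,
            referent=lx.span,
            mentions=[Mention(ne.start, ne.length, lexeme_refs=ne.lexeme_refs,
                              ne_ref=doc.named_entities.index(ne))],
        ))
    return links


def evaluate_rules(
    doc: AnnotatedDocument,
    taxonomy: ProfessionTaxonomy | None = None,
    persons_kb: PersonsKB | None = None,
    algorithms: tuple[str, ...] = ("A1", "A2", "A3", "A4", "A5"),
    acronym_dialect: str = "default",
    orientation: str = "fol",
) -> list[CoreferenceLink]:
    """The full link set by exhaustive rule evaluation, canonical order."""
    algs = set(algorithms)
    links: list[CoreferenceLink] = []
    for sentence in doc.sentences:
        for p in sentence.lexemes:
            if p.pos != Pos.Pronoun or p.pronoun_type == PronounType.Demonstrative:
                continue
            if _relative_pattern(sentence, p):
                if "A1" not in algs:
                    continue
                found = _rule2_links(sentence, p) or _rule1_links(sentence, p)
                links.extend(found[:1])  # the exists-unique link per pronoun
            elif "A2" in algs:
                links.extend(_general_links(doc, sentence, p))
    if "A3" in algs:
        links.extend(_repetition_links(doc, acronym_dialect))
    if "A4" in algs and taxonomy is not None:
        links.extend(_profession_links(doc, taxonomy, orientation))
    if "A5" in algs and persons_kb is not None:
        links.extend(_feature_links(doc, persons_kb))
    return canonical_link_order(links)
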