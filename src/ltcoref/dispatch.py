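"""Decision-table dispatch.

Lexemes are scanned sequentially in two passes — pronouns first, then nouns —
and the first satisfied condition selects the algorithm for that lexeme:

========= =============================================================== =========
condition  meaning                                                         algorithm
========= =============================================================== =========
C1         the lexeme is a pronoun (category gate)                         —
C2         C1, Relative type, and the ``comma [preposition]`` pattern       A1
C3         C1 and not Demonstrative (and not C2)                            A2
C4         the lexeme is a noun (category gate)                             —
C6         C4 and inside a recognised named entity                          A3
C6         C4 and matching a profession-name variant                        A4
C7         C4 and matching a position title active on the publication date  A5
========= =============================================================== =========

Demonstrative pronouns fire the category gate C1 but no algorithm — they are
deliberately ignored.  A noun inside no NE that names both a profession and
an active position title is dispatched to A4; the resolver still offers it
to A5 as well, since the two readings are additive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .kb import PersonsKB, ProfessionTaxonomy
from .model import AnnotatedDocument, Pos, PronounType
from .nominals import profession_occurrences
from .pronouns import has_relative_pattern


class Condition(str, enum.Enum):
    C1 = "C1"
    C2 = "C2"
    C3 = "C3"
    C4 = "C4"
    C6 = "C6"
    C7 = "C7"
    NONE = "None"


class Algorithm(str, enum.Enum):
    A1 = "A1"
    A2 = "A2"
    A3 = "A3"
    A4 = "A4"
    A5 = "A5"
    NONE = "None"


@dataclass(frozen=True)
class DispatchDecision:
    lexeme_ref: int  # document-wide lexeme index
    condition_fired: Condition
    algorithm: Algorithm


def dispatch(
    doc: AnnotatedDocument,
    taxonomy: ProfessionTaxonomy | None = None,
    persons_kb: PersonsKB | None = None,
) -> list[DispatchDecision]:
    """Scan the document and decide, per pronoun/noun lexeme, which
    algorithm applies.  Pronoun conditions are tested over the whole text
    before noun conditions; within a pass lexemes appear in document order;
    the first satisfied condition wins."""
    decisions: list[DispatchDecision] = []
    all_lex = doc.lexemes()

    ne_lexeme_refs = {r for ne in doc.named_entities for r in ne.lexeme_refs}
    profession_refs: set[int] = set()
    if taxonomy is not None:
        for occ in profession_occurrences(doc, taxonomy):
            profession_refs.update(occ.lexeme_refs)
    active_titles: set[str] = set()
    if persons_kb is not None and doc.publication_date is not None:
        active_titles = persons_kb.titles_active_on(doc.publication_date)

    # pass 1: pronouns
    idx = 0
    for sent in doc.sentences:
        for lx in sent.lexemes:
            if lx.pos == Pos.Pronoun:
                if has_relative_pattern(sent, lx):
                    decisions.append(DispatchDecision(idx, Condition.C2, Algorithm.A1))
                elif lx.pronoun_type != PronounType.Demonstrative:
                    decisions.append(DispatchDecision(idx, Condition.C3, Algorithm.A2))
                else:
                    decisions.append(DispatchDecision(idx, Condition.C1, Algorithm.NONE))
            idx += 1

    # pass 2: nouns
    for idx, lx in enumerate(all_lex):
        if lx.pos != Pos.Noun:
            continue
        if idx in ne_lexeme_refs:
            decisions.append(DispatchDecision(idx, Condition.C6, Algorithm.A3))
        elif idx in profession_refs:
            decisions.append(DispatchDecision(idx, Condition.C6, Algorithm.A4))
        elif lx.lemma.casefold() in active_titles:
            decisions.append(DispatchDecision(idx, Condition.C7, Algorithm.A5))
        else:
            decisions.append(DispatchDecision(idx, Condition.NONE, Algorithm.NONE))
    return decisions
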