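"""Worked-example fixtures.

Each fixture re-encodes one published worked example of the resolution
method as a fully annotated document (lemma, part of speech, gender, number
hand-encoded from the example's glosses) paired with its gold link set.
Tokens that play no role in any rule are occasionally condensed; the
annotation carries the morphology the engine reads, not a full treebank
analysis.  Three extra fixtures exercise the backward/forward search
distances that the published examples leave implicit (same-sentence
backward, two-sentences-back, next-sentence forward).

The toy knowledge base (two known persons with date-ranged positions) and
the toy profession taxonomy (doctor / surgeon / chief-surgeon) shipped with
the package back the feature and profession fixtures.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from importlib import resources

from .kb import PersonsKB, ProfessionTaxonomy
from .model import (
    AnnotatedDocument, CoreferenceLink, Gender, LinkGroup, LinkPosition,
    LinkSubtype, LinkType, Mention, NeClass, Number, PronounType, Span,
    make_link,
)
from .standoff import (
    DocumentBuilder, comma, conj, noun, prep, pron, punct, word,
)

#: publication date shared by all fixture documents; inside the toy KB's
#: position intervals
FIXTURE_DATE = _dt.date(2018, 6, 15)

M, F, C = Gender.Masculine, Gender.Feminine, Gender.Common
SG, PL = Number.Singular, Number.Plural


def toy_persons_kb() -> PersonsKB:
    with resources.files("ltcoref.data").joinpath("persons.json").open(
            encoding="utf-8") as fh:
        return PersonsKB.from_json(fh)


def toy_taxonomy(transitive: bool = False) -> ProfessionTaxonomy:
    with resources.files("ltcoref.data").joinpath("professions.yaml").open(
            encoding="utf-8") as fh:
        return ProfessionTaxonomy.load(fh, transitive=transitive)


@dataclass(frozen=True)
class Fixture:
    name: str
    document: AnnotatedDocument
    gold: tuple[CoreferenceLink, ...]


def _lex_span(doc: AnnotatedDocument, sent: int, tok: int) -> Span:
    lx = doc.sentences[sent].lexemes[tok]
    return lx.span


def _ne_span(doc: AnnotatedDocument, idx: int) -> Span:
    return doc.named_entities[idx].span


def _ne_mention(doc: AnnotatedDocument, idx: int) -> Mention:
    ne = doc.named_entities[idx]
    return Mention(ne.start, ne.length, lexeme_refs=ne.lexeme_refs, ne_ref=idx)


def _backache_1() -> Fixture:
    # "A man who had a backache came today" — relative pronoun right after
    # the comma; antecedent is the noun before the comma.
    doc = (
        DocumentBuilder("backache-1", FIXTURE_DATE)
        .sentence([
            word("Šiandien"),
            word("atėjęs", "ateiti"),
            noun("vyras", "vyras", M, SG),
            comma(),
            pron("kuris", "kuris", PronounType.Relative, M, SG),
            word("skundėsi", "skųstis"),
            noun("nugaros", "nugara", F, SG),
            noun("skausmu", "skausmas", M, SG),
        ])
        .build()
    )
    gold = make_link(
        "R1", LinkType.Pronominal, LinkSubtype.Relative,
        LinkPosition.Backward, LinkGroup.Single,
        referent=_lex_span(doc, 0, 4), mentions=[Mention(*_lex_span(doc, 0, 2))],
    )
    return Fixture("backache-1", doc, (gold,))


def _backache_2() -> Fixture:
    # the preposition variant: "a man with whom we discussed a backache"
    doc = (
        DocumentBuilder("backache-2", FIXTURE_DATE)
        .sentence([
            word("Šiandien"),
            word("atėjęs", "ateiti"),
            noun("vyras", "vyras", M, SG),
            comma(),
            prep("su"),
            pron("kuriuo", "kuris", PronounType.Relative, M, SG),
            word("aptarėme", "aptarti"),
            noun("nugaros", "nugara", F, SG),
            noun("skausmą", "skausmas", M, SG),
        ])
        .build()
    )
    gold = make_link(
        "R1", LinkType.Pronominal, LinkSubtype.Relative,
        LinkPosition.Backward, LinkGroup.Single,
        referent=_lex_span(doc, 0, 5), mentions=[Mention(*_lex_span(doc, 0, 2))],
    )
    return Fixture("backache-2", doc, (gold,))


def _committee_1() -> Fixture:
    # a plural relative pronoun closing a four-noun coordinated list of
    # mixed genders; no agreement is required for the list members
    doc = (
        DocumentBuilder("committee-1", FIXTURE_DATE)
        .sentence([
            noun("Komisija", "komisija", F, SG),
            word("nerado", "rasti"),
            noun("panašumų", "panašumas", M, PL),
            prep("tarp"),
            noun("Tomo", "Tomas", M, SG),
            comma(),
            noun("Lino", "Linas", M, SG),
            comma(),
            noun("Petro", "Petras", M, SG),
            conj("ir"),
            noun("Eglės", "Eglė", F, SG),
            comma(),
            pron("kurių", "kuris", PronounType.Relative, C, PL),
            noun("sužalojimai", "sužalojimas", M, PL),
            word("atrodė", "atrodyti"),
            word("panašūs", "panašus"),
        ])
        .build()
    )
    gold = make_link(
        "R2", LinkType.Pronominal, LinkSubtype.Relative,
        LinkPosition.Backward, LinkGroup.Multiple,
        referent=_lex_span(doc, 0, 12),
        mentions=[Mention(*_lex_span(doc, 0, t)) for t in (4, 6, 8, 10)],
    )
    return Fixture("committee-1", doc, (gold,))


def _jonas_jis() -> Fixture:
    # "Jonas Jonaitis called a reception. He complained about headache."
    doc = (
        DocumentBuilder("jonas-jis", FIXTURE_DATE)
        .sentence(
            [
                noun("Jonas", "Jonas", M, SG),
                noun("Jonaitis", "Jonaitis", M, SG),
                word("skambino", "skambinti"),
                prep("į"),
                noun("registratūrą", "registratūra", F, SG),
                punct(),
            ],
            nes=[(0, 1, NeClass.Person, M, SG, "Jonaitis")],
        )
        .sentence([
            pron("Jis", "jis", PronounType.Other, M, SG),
            word("skundėsi", "skųstis"),
            noun("galvos", "galva", F, SG),
            noun("skausmu", "skausmas", M, SG),
            punct(),
        ])
        .build()
    )
    gold = make_link(
        "R4", LinkType.Pronominal, LinkSubtype.General,
        LinkPosition.Backward, LinkGroup.Single,
        referent=_lex_span(doc, 1, 0), mentions=[_ne_mention(doc, 0)],
    )
    return Fixture("jonas-jis", doc, (gold,))


def _analysis_forward() -> Fixture:
    # the quotation example: the ambiguous-gender pronoun "man" finds no
    # backward candidate and resolves forward to the person entity
    # "J. Jonaitis"; the location entity is never a candidate
    doc = (
        DocumentBuilder("analysis-forward", FIXTURE_DATE)
        .sentence(
            [
                word("Kiek"),
                pron("man", "aš", PronounType.Other, C, SG),
                word("teko", "tekti"),
                word("analizuoti"),
                comma(),
                word("tik"),
                noun("dalis", "dalis", F, SG),
                noun("Lietuvos", "Lietuva", F, SG),
                noun("ligoninių", "ligoninė", F, PL),
                word("sumažino", "sumažinti"),
                noun("etatus", "etatas", M, PL),
                comma(),
                word("teigė", "teigti"),
                noun("J.", "J.", M, SG),
                noun("Jonaitis", "Jonaitis", M, SG),
                punct(),
            ],
            nes=[
                (7, 7, NeClass.Location, F, SG, "Lietuva"),
                (13, 14, NeClass.Person, M, SG, "Jonaitis"),
            ],
        )
        .build()
    )
    gold = make_link(
        "R6", LinkType.Pronominal, LinkSubtype.General,
        LinkPosition.Forward, LinkGroup.Single,
        referent=_lex_span(doc, 0, 1), mentions=[_ne_mention(doc, 1)],
    )
    return Fixture("analysis-forward", doc, (gold,))


def _tomaitis_repetition() -> Fixture:
    # two occurrences of the same surname in different cases share a lemma
    doc = (
        DocumentBuilder("tomaitis-repetition", FIXTURE_DATE)
        .sentence(
            [
                noun("Tomaitis", "Tomaitis", M, SG),
                word("pateko", "patekti"),
                prep("į"),
                noun("avariją", "avarija", F, SG),
                punct(),
            ],
            nes=[(0, 0, NeClass.Person, M, SG, "Tomaitis")],
        )
        .sentence(
            [
                prep("Po"),
                noun("pietų", "pietūs", M, PL),
                noun("Tomaitį", "Tomaitis", M, SG),
                word("išvežė", "išvežti"),
                prep("į"),
                noun("operacinę", "operacinė", F, SG),
                punct(),
            ],
            nes=[(2, 2, NeClass.Person, M, SG, "Tomaitis")],
        )
        .build()
    )
    gold = make_link(
        "R8", LinkType.Nominal, LinkSubtype.Repetition,
        LinkPosition.Irrelevant, LinkGroup.Single,
        referent=_ne_span(doc, 1), mentions=[_ne_mention(doc, 0)],
    )
    return Fixture("tomaitis-repetition", doc, (gold,))


def _doctor_surgeon() -> Fixture:
    # doctors/surgeons: taxonomy-related professions agreeing in gender and
    # number yield a hypernym/hyponym link
    doc = (
        DocumentBuilder("doctor-surgeon", FIXTURE_DATE)
        .sentence([
            noun("Gydytojai", "gydytojas", M, PL),
            word("skundžiasi", "skųstis"),
            word("dideliu", "didelis"),
            noun("darbo", "darbas", M, SG),
            noun("krūviu", "krūvis", M, SG),
            punct(),
        ])
        .sentence([
            noun("Chirurgų", "chirurgas", M, PL),
            noun("darbo", "darbas", M, SG),
            noun("krūvis", "krūvis", M, SG),
            word("pats"),
            word("didžiausias", "didelis"),
            punct(),
        ])
        .build()
    )
    gold = make_link(
        "R9", LinkType.Nominal, LinkSubtype.Hypernym_Hyponym,
        LinkPosition.Irrelevant, LinkGroup.Single,
        referent=_lex_span(doc, 0, 0), mentions=[Mention(*_lex_span(doc, 1, 0))],
    )
    return Fixture("doctor-surgeon", doc, (gold,))


def _head_chief_surgeon() -> Fixture:
    # "head [surgeon]" and "chief surgeon" are variants of one profession
    doc = (
        DocumentBuilder("head-chief-surgeon", FIXTURE_DATE)
        .sentence(
            [
                noun("J.", "J.", M, SG),
                noun("Jonaitis", "Jonaitis", M, SG),
                word("buvo", "būti"),
                noun("operacijos", "operacija", F, SG),
                noun("vadovu", "vadovas", M, SG),
                punct(),
            ],
            nes=[(0, 1, NeClass.Person, M, SG, "Jonaitis")],
        )
        .sentence([
            word("Deja"),
            comma(),
            word("vyr.", "vyr."),
            noun("chirurgo", "chirurgas", M, SG),
            word("vykdoma", "vykdyti"),
            noun("operacija", "operacija", F, SG),
            word("buvo", "būti"),
            word("nesėkminga", "nesėkmingas"),
            punct(),
        ])
        .build()
    )
    vyr = _lex_span(doc, 1, 2)
    chirurgo = _lex_span(doc, 1, 3)
    multiword = Span(vyr.start, chirurgo.end - vyr.start)
    gold = make_link(
        "R10", LinkType.Nominal, LinkSubtype.Synonym,
        LinkPosition.Irrelevant, LinkGroup.Single,
        referent=_lex_span(doc, 0, 4),
        mentions=[Mention(multiword.start, multiword.length)],
    )
    return Fixture("head-chief-surgeon", doc, (gold,))


def _cardiologist() -> Fixture:
    # the cardiologist post held by S. Suskelis on the publication date;
    # entity precedes the title noun, so the link points backward
    doc = (
        DocumentBuilder("cardiologist", FIXTURE_DATE)
        .sentence(
            [
                word("Ką"),
                word("rekomenduoja", "rekomenduoti"),
                noun("S.", "S.", M, SG),
                noun("Suskelis", "Suskelis", M, SG),
                punct("?"),
            ],
            nes=[(2, 3, NeClass.Person, M, SG, "Suskelis")],
        )
        .sentence([
            word("Aptarkime", "aptarti"),
            noun("kardiologo", "kardiologas", M, SG),
            word("siūlomą", "siūlyti"),
            noun("gydymo", "gydymas", M, SG),
            noun("planą", "planas", M, SG),
            punct(),
        ])
        .build()
    )
    gold = make_link(
        "R11", LinkType.Nominal, LinkSubtype.Feature,
        LinkPosition.Backward, LinkGroup.Single,
        referent=_lex_span(doc, 1, 1), mentions=[_ne_mention(doc, 0)],
    )
    return Fixture("cardiologist", doc, (gold,))


def _family_doctor() -> Fixture:
    # the flipped variant: the title noun precedes the entity, so the
    # feature link points forward
    doc = (
        DocumentBuilder("family-doctor", FIXTURE_DATE)
        .sentence([
            word("Koks"),
            word("yra", "būti"),
            word("mano"),
            noun("šeimos", "šeima", F, SG),
            noun("gydytojas", "gydytojas", M, SG),
            punct("?"),
        ])
        .sentence(
            [
                noun("T.", "T.", M, SG),
                noun("Tomaitis", "Tomaitis", M, SG),
                word("yra", "būti"),
                word("labai"),
                word("patyręs", "patirti"),
                punct(),
            ],
            nes=[(0, 1, NeClass.Person, M, SG, "Tomaitis")],
        )
        .build()
    )
    gold = make_link(
        "R12", LinkType.Nominal, LinkSubtype.Feature,
        LinkPosition.Forward, LinkGroup.Single,
        referent=_lex_span(doc, 0, 4), mentions=[_ne_mention(doc, 0)],
    )
    return Fixture("family-doctor", doc, (gold,))


def _same_sentence_backward() -> Fixture:
    # same-sentence backward search: the nearest agreeing person entity
    # before the pronoun wins
    doc = (
        DocumentBuilder("same-sentence-backward", FIXTURE_DATE)
        .sentence(
            [
                word("Vakar"),
                noun("Jonaitienė", "Jonaitienė", F, SG),
                word("sakė", "sakyti"),
                comma(),
                conj("kad"),
                pron("ji", "jis", PronounType.Other, F, SG),
                word("serga", "sirgti"),
                punct(),
            ],
            nes=[(1, 1, NeClass.Person, F, SG, "Jonaitienė")],
        )
        .build()
    )
    gold = make_link(
        "R3", LinkType.Pronominal, LinkSubtype.General,
        LinkPosition.Backward, LinkGroup.Single,
        referent=_lex_span(doc, 0, 5), mentions=[_ne_mention(doc, 0)],
    )
    return Fixture("same-sentence-backward", doc, (gold,))


def _two_sentences_back() -> Fixture:
    doc = (
        DocumentBuilder("two-sentences-back", FIXTURE_DATE)
        .sentence(
            [
                noun("Petraitienė", "Petraitienė", F, SG),
                word("atvyko", "atvykti"),
                word("vakar"),
                punct(),
            ],
            nes=[(0, 0, NeClass.Person, F, SG, "Petraitienė")],
        )
        .sentence([
            noun("Tyrimai", "tyrimas", M, PL),
            word("užtruko", "užtrukti"),
            punct(),
        ])
        .sentence([
            pron("Ji", "jis", PronounType.Other, F, SG),
            word("laukė", "laukti"),
            noun("atsakymo", "atsakymas", M, SG),
            punct(),
        ])
        .build()
    )
    gold = make_link(
        "R5", LinkType.Pronominal, LinkSubtype.General,
        LinkPosition.Backward, LinkGroup.Single,
        referent=_lex_span(doc, 2, 0), mentions=[_ne_mention(doc, 0)],
    )
    return Fixture("two-sentences-back", doc, (gold,))


def _next_sentence_forward() -> Fixture:
    doc = (
        DocumentBuilder("next-sentence-forward", FIXTURE_DATE)
        .sentence([
            pron("Man", "aš", PronounType.Other, C, SG),
            word("skauda", "skaudėti"),
            noun("galvą", "galva", F, SG),
            punct(),
        ])
        .sentence(
            [
                word("Taip"),
                word("sakė", "sakyti"),
                noun("Kazlauskas", "Kazlauskas", M, SG),
                punct(),
            ],
            nes=[(2, 2, NeClass.Person, M, SG, "Kazlauskas")],
        )
        .build()
    )
    gold = make_link(
        "R7", LinkType.Pronominal, LinkSubtype.General,
        LinkPosition.Forward, LinkGroup.Single,
        referent=_lex_span(doc, 0, 0), mentions=[_ne_mention(doc, 0)],
    )
    return Fixture("next-sentence-forward", doc, (gold,))


def paper_examples() -> list[Fixture]:
    """All worked-example fixtures with their gold links."""
    return [
        _backache_1(),
        _backache_2(),
        _committee_1(),
        _jonas_jis(),
        _analysis_forward(),
        _tomaitis_repetition(),
        _doctor_surgeon(),
        _head_chief_surgeon(),
        _cardiologist(),
        _family_doctor(),
        _same_sentence_backward(),
        _two_sentences_back(),
        _next_sentence_forward(),
    ]
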