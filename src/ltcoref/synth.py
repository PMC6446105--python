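"""Seeded synthetic corpus generator with known gold links.

Documents are assembled from phenomenon templates — relative clause,
personal pronoun at sentence distance 0/1/2, named-entity repetition chains
of length 2-4 (persons or organisations with acronyms), profession pairs
from the toy taxonomy, and knowledge-base-backed feature pairs with the
publication date inside or outside the position's validity interval — plus
distractor material (gender-mismatched relative patterns, demonstrative
pronouns, location entities) that must not be linked.  Gold links are
recorded at insertion time.

The synthetic "Lithuanian" is a closed vocabulary with correct morphological
feature annotations rather than real inflection: the engine reads features
and lemmas, never surface strings, so linguistic realism is unnecessary.
Templates keep gender pools disjoint (the pronoun template's entities are
feminine, repetition and knowledge-base persons masculine), which makes each
inserted link unambiguous; every document's intended gold set is verified
against the brute-force rule evaluator at generation time and the document
is regenerated on a collision.
"""

from __future__ import annotations

import datetime as _dt
import random
from dataclasses import dataclass, fields

from .bruteforce import evaluate_rules
from .fixtures import toy_persons_kb, toy_taxonomy
from .model import (
    AnnotatedDocument, CoreferenceLink, Gender, LinkGroup, LinkPosition,
    LinkSubtype, LinkType, Mention, NeClass, Number, PronounType, Span,
    ValidationError, canonical_link_order, make_link, normalize_links,
)
from .standoff import DocumentBuilder, Tok, comma, conj, noun, prep, pron, punct, word

M, F, C = Gender.Masculine, Gender.Feminine, Gender.Common
SG, PL = Number.Singular, Number.Plural

IN_RANGE_DATE = _dt.date(2018, 6, 15)     # inside every toy-KB interval
OUT_OF_RANGE_DATE = _dt.date(2022, 6, 15)  # after the cardiologist post ends


@dataclass(frozen=True)
class GeneratorConfig:
    """Per-document probability of inserting each phenomenon."""

    relative_clause: float = 0.3
    pronoun: float = 0.3
    repetition: float = 0.3
    profession: float = 0.3
    feature: float = 0.3
    distractor: float = 0.5

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"density {f.name}={v} outside [0, 1]")


_FEM_SURNAMES = ["Jonaitienė", "Butkienė", "Kazlauskienė", "Urbonienė"]
_MASC_SURNAMES = ["Petrauskas", "Jankauskas", "Stankevičius", "Urbonas"]
_ORGS = [
    (("Kauno", "technologijos", "universitetas"), "KTU"),
    (("Vilniaus", "universiteto", "ligoninė"), "VUL"),
]
_FILLER_NOUNS = [
    ("dokumentas", M, SG), ("ataskaita", F, SG), ("kabinetas", M, SG),
    ("tyrimas", M, SG), ("procedūra", F, SG),
]
_FILLER_WORDS = ["vakar", "šiandien", "greitai", "netrukus", "papildomai"]
_VERBS = ["atvyko", "laukė", "kalbėjo", "dirbo", "ilsėjosi"]
_REL_NOUNS = [("pacientas", M), ("vairuotojas", M), ("kaimynė", F), ("slaugytoja", F)]
_LOCATIONS = ["Vilnius", "Klaipėda", "Šiauliai"]


class _DocPlan:
    """Accumulates sentences, named-entity specs and deferred gold links."""

    def __init__(self) -> None:
        self.sentences: list[tuple[list[Tok], list[tuple]]] = []
        # (rule_id, subtype, position, group, referent locator, mention locators)
        self.link_specs: list[tuple] = []
        self._ne_count = 0

    def add_sentence(self, tokens: list[Tok], nes: list[tuple] | None = None) -> int:
        self.sentences.append((tokens, nes or []))
        self._ne_count += len(nes or [])
        return len(self.sentences) - 1

    @property
    def next_ne_index(self) -> int:
        return self._ne_count

    def add_link(self, rule_id, subtype, position, group, referent, mentions):
        """Locators: ("tok", sent, first, last) token span or ("ne", idx)."""
        self.link_specs.append((rule_id, subtype, position, group, referent, mentions))


def _locate(doc: AnnotatedDocument, locator) -> tuple[Span, Mention | None]:
    kind = locator[0]
    if kind == "tok":
        _, si, first, last = locator
        lex = doc.sentences[si].lexemes
        start = lex[first].start
        end = lex[last].start + lex[last].length
        return Span(start, end - start), None
    _, idx = locator
    ne = doc.named_entities[idx]
    return ne.span, Mention(ne.start, ne.length, lexeme_refs=ne.lexeme_refs, ne_ref=idx)


def _materialise(plan: _DocPlan, doc_id: str,
                 date: _dt.date) -> tuple[AnnotatedDocument, list[CoreferenceLink]]:
    builder = DocumentBuilder(doc_id, date)
    for tokens, nes in plan.sentences:
        builder.sentence(tokens, nes)
    doc = builder.build()
    links = []
    for rule_id, subtype, position, group, ref_loc, men_locs in plan.link_specs:
        ref_span, _ = _locate(doc, ref_loc)
        mentions = []
        for loc in men_locs:
            span, ne_mention = _locate(doc, loc)
            mentions.append(ne_mention if ne_mention is not None
                            else Mention(span.start, span.length))
        ctype = (LinkType.Pronominal if rule_id in ("R1", "R2", "R3", "R4", "R5", "R6", "R7")
                 else LinkType.Nominal)
        links.append(make_link(rule_id, ctype, subtype, position, group,
                               referent=ref_span, mentions=mentions))
    return doc, canonical_link_order(links)


def _filler_sentence(rng: random.Random) -> list[Tok]:
    lemma, g, n = rng.choice(_FILLER_NOUNS)
    return [word(rng.choice(_FILLER_WORDS)), noun(lemma.capitalize(), lemma, g, n),
            word(rng.choice(_VERBS)), punct()]


def _add_relative_clause(plan: _DocPlan, rng: random.Random,
                         mismatch: bool = False) -> None:
    lemma, g = rng.choice(_REL_NOUNS)
    rel = "kuris" if g == M else "kuri"
    p_gender = (F if g == M else M) if mismatch else g
    use_prep = rng.random() < 0.5
    tokens = [
        word(rng.choice(_FILLER_WORDS)),
        word(rng.choice(_VERBS)),
        noun(lemma, lemma, g, SG),
        comma(),
    ]
    if use_prep:
        tokens.append(prep("su"))
    p_idx = len(tokens)
    tokens += [
        pron(rel if not mismatch else ("kuri" if p_gender == F else "kuris"),
             "kuris", PronounType.Relative, p_gender, SG),
        word(rng.choice(_VERBS)),
        punct(),
    ]
    si = plan.add_sentence(tokens)
    if not mismatch:
        plan.add_link("R1", LinkSubtype.Relative, LinkPosition.Backward,
                      LinkGroup.Single, ("tok", si, p_idx, p_idx),
                      [("tok", si, 2, 2)])


def _add_pronoun(plan: _DocPlan, rng: random.Random) -> None:
    surname = rng.choice(_FEM_SURNAMES)
    k = rng.choice([0, 1, 2])
    ne_idx = plan.next_ne_index
    if k == 0:
        tokens = [
            noun(surname, surname, F, SG),
            word("sakė", "sakyti"),
            comma(),
            conj("kad"),
            pron("ji", "jis", PronounType.Other, F, SG),
            word(rng.choice(_VERBS)),
            punct(),
        ]
        si = plan.add_sentence(tokens, [(0, 0, NeClass.Person, F, SG, surname)])
        plan.add_link("R3", LinkSubtype.General, LinkPosition.Backward,
                      LinkGroup.Single, ("tok", si, 4, 4), [("ne", ne_idx)])
        return
    plan.add_sentence(
        [noun(surname, surname, F, SG), word(rng.choice(_VERBS)), punct()],
        [(0, 0, NeClass.Person, F, SG, surname)],
    )
    for _ in range(k - 1):
        plan.add_sentence(_filler_sentence(rng))
    si = plan.add_sentence([
        pron("Ji", "jis", PronounType.Other, F, SG),
        word(rng.choice(_VERBS)),
        punct(),
    ])
    rule = "R4" if k == 1 else "R5"
    plan.add_link(rule, LinkSubtype.General, LinkPosition.Backward,
                  LinkGroup.Single, ("tok", si, 0, 0), [("ne", ne_idx)])


def _add_repetition(plan: _DocPlan, rng: random.Random,
                    max_length: int = 4) -> None:
    length = rng.choice([n for n in (2, 3, 4) if n <= max_length])
    if rng.random() < 0.5:
        surname = rng.choice(_MASC_SURNAMES)
        ne_indices = []
        for _ in range(length):
            ne_indices.append(plan.next_ne_index)
            plan.add_sentence(
                [noun(surname, surname, M, SG), word(rng.choice(_VERBS)), punct()],
                [(0, 0, NeClass.Person, M, SG, surname)],
            )
    else:
        org_words, acronym = rng.choice(_ORGS)
        ne_indices = [plan.next_ne_index]
        tokens = [noun(w, w.lower(), F if w.endswith("a") else M, SG)
                  for w in org_words]
        plan.add_sentence(
            tokens + [word(rng.choice(_VERBS)), punct()],
            [(0, len(org_words) - 1, NeClass.Organization, M, SG,
              org_words[-1].lower())],
        )
        for _ in range(length - 1):
            ne_indices.append(plan.next_ne_index)
            plan.add_sentence(
                [noun(acronym, acronym, M, SG), word(rng.choice(_VERBS)), punct()],
                [(0, 0, NeClass.Organization, M, SG, acronym)],
            )
    for prev, cur in zip(ne_indices, ne_indices[1:]):
        plan.add_link("R8", LinkSubtype.Repetition, LinkPosition.Irrelevant,
                      LinkGroup.Single, ("ne", cur), [("ne", prev)])


def _add_profession(plan: _DocPlan, rng: random.Random) -> None:
    if rng.random() < 0.5:
        s1 = plan.add_sentence([
            noun("Gydytojai", "gydytojas", M, PL),
            word("skundžiasi", "skųstis"), punct(),
        ])
        s2 = plan.add_sentence([
            noun("Chirurgai", "chirurgas", M, PL),
            word("dirba", "dirbti"), punct(),
        ])
        plan.add_link("R9", LinkSubtype.Hypernym_Hyponym, LinkPosition.Irrelevant,
                      LinkGroup.Single, ("tok", s1, 0, 0), [("tok", s2, 0, 0)])
    else:
        s1 = plan.add_sentence([
            noun("Vadovas", "vadovas", M, SG),
            word("operavo", "operuoti"), punct(),
        ])
        s2 = plan.add_sentence([
            Tok("vyr.", "vyr."),
            noun("chirurgas", "chirurgas", M, SG),
            word("pavargo", "pavargti"), punct(),
        ])
        plan.add_link("R10", LinkSubtype.Synonym, LinkPosition.Irrelevant,
                      LinkGroup.Single, ("tok", s1, 0, 0), [("tok", s2, 0, 1)])


def _add_feature(plan: _DocPlan, rng: random.Random, in_range: bool) -> None:
    ne_idx = plan.next_ne_index
    ne_first = rng.random() < 0.5
    ne_sentence = (
        [noun("S.", "S.", M, SG), noun("Suskelis", "Suskelis", M, SG),
         word(rng.choice(_VERBS)), punct()],
        [(0, 1, NeClass.Person, M, SG, "Suskelis")],
    )
    noun_sentence = [
        word(rng.choice(_FILLER_WORDS)),
        noun("kardiologas", "kardiologas", M, SG),
        word(rng.choice(_VERBS)), punct(),
    ]
    if ne_first:
        plan.add_sentence(*ne_sentence)
        sn = plan.add_sentence(noun_sentence)
        rule, position = "R11", LinkPosition.Backward
    else:
        sn = plan.add_sentence(noun_sentence)
        plan.add_sentence(*ne_sentence)
        rule, position = "R12", LinkPosition.Forward
    if in_range:
        plan.add_link(rule, LinkSubtype.Feature, position, LinkGroup.Single,
                      ("tok", sn, 1, 1), [("ne", ne_idx)])


def _add_distractors(plan: _DocPlan, rng: random.Random) -> None:
    kind = rng.randrange(3)
    if kind == 0:
        plan.add_sentence([
            pron("Tas", "tas", PronounType.Demonstrative, M, SG),
            word("yra", "būti"), word("aišku", "aiškus"), punct(),
        ])
    elif kind == 1:
        loc = rng.choice(_LOCATIONS)
        plan.add_sentence(
            [prep("Į"), noun(loc, loc, M, SG), word("atvyko", "atvykti"), punct()],
            [(1, 1, NeClass.Location, M, SG, loc)],
        )
    else:
        _add_relative_clause(plan, rng, mismatch=True)


#: documents are kept short so that exhaustive rule evaluation stays cheap
MAX_SENTENCES = 6


def _build_plan(rng: random.Random, config: GeneratorConfig) -> tuple[_DocPlan, _dt.date]:
    plan = _DocPlan()
    feature_on = rng.random() < config.feature
    feature_in_range = rng.random() < 0.5
    date = IN_RANGE_DATE if (not feature_on or feature_in_range) else OUT_OF_RANGE_DATE

    def room(n: int) -> bool:
        return len(plan.sentences) + n <= MAX_SENTENCES

    if rng.random() < config.pronoun:
        _add_pronoun(plan, rng)
    if rng.random() < config.relative_clause and room(1):
        _add_relative_clause(plan, rng)
    if rng.random() < config.repetition and room(2):
        _add_repetition(plan, rng,
                        max_length=min(4, MAX_SENTENCES - len(plan.sentences)))
    if rng.random() < config.profession and room(2):
        _add_profession(plan, rng)
    if feature_on and room(2):
        _add_feature(plan, rng, feature_in_range)
    if (rng.random() < config.distractor or not plan.sentences) and room(1):
        _add_distractors(plan, rng)
    if room(1):
        plan.add_sentence(_filler_sentence(rng))
    return plan, date


def generate_synthetic(
    config: GeneratorConfig | None,
    n_docs: int,
    seed: int,
) -> list[tuple[AnnotatedDocument, list[CoreferenceLink]]]:
    """Deterministic corpus of (document, gold links) pairs.

    The same (config, n_docs, seed) always yields an identical corpus.
    """
    config = config or GeneratorConfig()
    rng = random.Random(seed)
    persons = toy_persons_kb()
    taxonomy = toy_taxonomy()
    corpus = []
    for i in range(n_docs):
        for attempt in range(30):
            plan, date = _build_plan(rng, config)
            doc, gold = _materialise(plan, f"synthetic-{i:04d}", date)
            oracle = evaluate_rules(doc, taxonomy=taxonomy, persons_kb=persons)
            if normalize_links(oracle) == normalize_links(gold):
                break
        else:
            raise RuntimeError(
                f"document {i}: could not realise an unambiguous template mix"
            )
        corpus.append((doc, gold))
    return corpus
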