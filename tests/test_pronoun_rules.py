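"""Relative-pronoun rules and general pronoun resolution."""

import pytest

import ltcoref as lc
from ltcoref.pronouns import (
    resolve_general_pronoun, resolve_relative, resolve_relative_multiple,
    resolve_relative_single,
)
from ltcoref.standoff import (
    DocumentBuilder, comma, conj, noun, prep, pron, punct, word,
)

M, F, C = lc.Gender.Masculine, lc.Gender.Feminine, lc.Gender.Common
SG, PL = lc.Number.Singular, lc.Number.Plural


def _pronoun_in(doc, surface):
    for sent in doc.sentences:
        for lx in sent.lexemes:
            if lx.pos == lc.Pos.Pronoun and lx.surface == surface:
                return sent, lx
    raise AssertionError(surface)


def _span_text(doc, span):
    return doc.text[span.start:span.start + span.length]


def test_relative_pronoun_links_to_noun_before_comma(fixtures_by_name):
    fx = fixtures_by_name["backache-1"]
    sent, p = _pronoun_in(fx.document, "kuris")
    link = resolve_relative_single(fx.document, sent, p)
    assert link is not None
    assert _span_text(fx.document, link.referent_span) == "kuris"
    assert _span_text(fx.document, link.mentions[0].span) == "vyras"
    assert (link.ctype, link.subtype, link.position, link.group) == (
        lc.LinkType.Pronominal, lc.LinkSubtype.Relative,
        lc.LinkPosition.Backward, lc.LinkGroup.Single)


def test_preposition_variant_still_matches(fixtures_by_name):
    fx = fixtures_by_name["backache-2"]
    sent, p = _pronoun_in(fx.document, "kuriuo")
    link = resolve_relative_single(fx.document, sent, p)
    assert link is not None
    assert _span_text(fx.document, link.mentions[0].span) == "vyras"


def test_gender_disagreement_blocks_rule_1():
    doc = (DocumentBuilder("mismatch")
           .sentence([noun("moteris", "moteris", F, SG), comma(),
                      pron("kuris", "kuris", lc.PronounType.Relative, M, SG),
                      word("atėjo"), punct()])
           .build())
    sent, p = _pronoun_in(doc, "kuris")
    assert resolve_relative_single(doc, sent, p) is None


def test_committee_list_yields_one_link_with_four_mentions(fixtures_by_name):
    fx = fixtures_by_name["committee-1"]
    sent, p = _pronoun_in(fx.document, "kurių")
    link = resolve_relative_multiple(fx.document, sent, p)
    assert link is not None
    assert link.group == lc.LinkGroup.Multiple
    texts = [_span_text(fx.document, m.span) for m in link.mentions]
    assert texts == ["Tomo", "Lino", "Petro", "Eglės"]


def test_two_noun_list_matches_plural_relative():
    doc = (DocumentBuilder("duo")
           .sentence([noun("Tomas", "Tomas", M, SG), conj("ir"),
                      noun("Eglė", "Eglė", F, SG), comma(),
                      pron("kurie", "kuris", lc.PronounType.Relative, M, PL),
                      word("atvyko"), punct()])
           .build())
    sent, p = _pronoun_in(doc, "kurie")
    link = resolve_relative_multiple(doc, sent, p)
    assert link is not None
    assert [_span_text(doc, m.span) for m in link.mentions] == ["Tomas", "Eglė"]


def test_singular_relative_after_list_falls_back_to_single_rule():
    doc = (DocumentBuilder("fallback")
           .sentence([noun("Tomas", "Tomas", M, SG), conj("ir"),
                      noun("Linas", "Linas", M, SG), comma(),
                      pron("kuris", "kuris", lc.PronounType.Relative, M, SG),
                      word("atvyko"), punct()])
           .build())
    sent, p = _pronoun_in(doc, "kuris")
    assert resolve_relative_multiple(doc, sent, p) is None
    link = resolve_relative(doc, sent, p)
    assert link is not None and link.group == lc.LinkGroup.Single
    assert _span_text(doc, link.mentions[0].span) == "Linas"


def test_general_pronoun_previous_sentence(fixtures_by_name):
    fx = fixtures_by_name["jonas-jis"]
    sent, p = _pronoun_in(fx.document, "Jis")
    link = resolve_general_pronoun(fx.document, sent, p)
    assert link is not None and link.rule_id == "R4"
    assert _span_text(fx.document, link.mentions[0].span) == "Jonas Jonaitis"
    assert link.position == lc.LinkPosition.Backward


def test_forward_search_skips_location_entities(fixtures_by_name):
    fx = fixtures_by_name["analysis-forward"]
    sent, p = _pronoun_in(fx.document, "man")
    link = resolve_general_pronoun(fx.document, sent, p)
    assert link is not None and link.rule_id == "R6"
    assert _span_text(fx.document, link.mentions[0].span) == "J. Jonaitis"
    assert link.position == lc.LinkPosition.Forward


def test_ambiguous_gender_pronoun_compares_number_only():
    # a Common-gender singular pronoun accepts a feminine singular entity,
    # but a plural entity never matches
    for number, expect in [(SG, True), (PL, False)]:
        doc = (DocumentBuilder("common")
               .sentence([pron("Man", "aš", lc.PronounType.Other, C, SG),
                          word("skauda"), punct()])
               .sentence([noun("Butkienė", "Butkienė", F, number),
                          word("sakė"), punct()],
                         nes=[(0, 0, lc.NeClass.Person, F, number, "Butkienė")])
               .build())
        sent, p = _pronoun_in(doc, "Man")
        link = resolve_general_pronoun(doc, sent, p)
        assert (link is not None) is expect


def test_nearest_preceding_entity_wins():
    doc = (DocumentBuilder("near")
           .sentence([noun("Jonaitis", "Jonaitis", M, SG), word("ir"),
                      noun("Petraitis", "Petraitis", M, SG),
                      word("kalbėjo"), punct()],
                     nes=[(0, 0, lc.NeClass.Person, M, SG, "Jonaitis"),
                          (2, 2, lc.NeClass.Person, M, SG, "Petraitis")])
           .sentence([pron("Jis", "jis", lc.PronounType.Other, M, SG),
                      word("išėjo"), punct()])
           .build())
    sent, p = _pronoun_in(doc, "Jis")
    link = resolve_general_pronoun(doc, sent, p)
    assert _span_text(doc, link.mentions[0].span) == "Petraitis"


def test_no_entity_within_window_leaves_pronoun_unresolved():
    b = DocumentBuilder("window")
    b.sentence([noun("Kazlauskas", "Kazlauskas", M, SG), word("atvyko"), punct()],
               nes=[(0, 0, lc.NeClass.Person, M, SG, "Kazlauskas")])
    for _ in range(3):  # three sentences push the entity out of reach
        b.sentence([word("Tyrimas"), word("užtruko"), punct()])
    b.sentence([pron("Jis", "jis", lc.PronounType.Other, M, SG),
                word("laukė"), punct()])
    doc = b.build()
    sent, p = _pronoun_in(doc, "Jis")
    assert resolve_general_pronoun(doc, sent, p) is None


def test_demonstrative_is_never_resolved():
    doc = (DocumentBuilder("dem")
           .sentence([noun("Jonaitis", "Jonaitis", M, SG), word("atvyko"), punct()],
                     nes=[(0, 0, lc.NeClass.Person, M, SG, "Jonaitis")])
           .sentence([pron("Tas", "tas", lc.PronounType.Demonstrative, M, SG),
                      word("nustebino"), punct()])
           .build())
    sent, p = _pronoun_in(doc, "Tas")
    assert resolve_general_pronoun(doc, sent, p) is None


@pytest.mark.parametrize("fixture_name,rule", [
    ("same-sentence-backward", "R3"),
    ("jonas-jis", "R4"),
    ("two-sentences-back", "R5"),
    ("analysis-forward", "R6"),
    ("next-sentence-forward", "R7"),
])
def test_search_distance_selects_the_documented_rule(fixtures_by_name,
                                                     fixture_name, rule):
    fx = fixtures_by_name[fixture_name]
    [link] = fx.gold
    assert link.rule_id == rule
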