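"""Repetition/acronym, profession and feature rules."""

import datetime

import pytest

import ltcoref as lc
from ltcoref.nominals import (
    resolve_feature, resolve_profession, resolve_repetition,
)
from ltcoref.standoff import DocumentBuilder, Tok, noun, prep, punct, word

M, F = lc.Gender.Masculine, lc.Gender.Feminine
SG, PL = lc.Number.Singular, lc.Number.Plural
DATE = datetime.date(2018, 6, 15)


def _span_text(doc, span):
    return doc.text[span.start:span.start + span.length]


def _person_sentences(builder, surfaces, lemma):
    for s in surfaces:
        builder.sentence(
            [noun(s, lemma, M, SG), word("atvyko"), punct()],
            nes=[(0, 0, lc.NeClass.Person, M, SG, lemma)],
        )
    return builder


def test_same_lemma_different_case_forms_link(fixtures_by_name):
    doc = fixtures_by_name["tomaitis-repetition"].document
    [link] = resolve_repetition(doc)
    assert link.subtype == lc.LinkSubtype.Repetition
    assert link.position == lc.LinkPosition.Irrelevant
    assert _span_text(doc, link.referent_span) == "Tomaitį"
    assert _span_text(doc, link.mentions[0].span) == "Tomaitis"


def test_chain_links_nearest_preceding_only():
    doc = _person_sentences(
        DocumentBuilder("chain", DATE),
        ["Petrauskas", "Petrauską", "Petrauskui"], "Petrauskas").build()
    links = resolve_repetition(doc)
    nes = sorted(doc.named_entities, key=lambda n: n.start)
    pairs = {(l.referent_start, l.mentions[0].start) for l in links}
    # exactly B->A and C->B, never C->A: k occurrences give k-1 links
    assert pairs == {(nes[1].start, nes[0].start), (nes[2].start, nes[1].start)}


def test_distinct_lemmas_never_link():
    b = DocumentBuilder("distinct", DATE)
    _person_sentences(b, ["Petrauskas"], "Petrauskas")
    _person_sentences(b, ["Jankauskas"], "Jankauskas")
    assert resolve_repetition(b.build()) == []


def test_lemma_matching_is_case_insensitive():
    b = DocumentBuilder("case", DATE)
    _person_sentences(b, ["PETRAUSKAS"], "PETRAUSKAS")
    _person_sentences(b, ["Petrauskas"], "petrauskas")
    assert len(resolve_repetition(b.build())) == 1


def _initial_surname_doc():
    return (DocumentBuilder("initials", DATE)
            .sentence([noun("Jonas", "Jonas", M, SG),
                       noun("Jonaitis", "Jonaitis", M, SG),
                       word("skambino"), punct()],
                      nes=[(0, 1, lc.NeClass.Person, M, SG, "Jonaitis")])
            .sentence([noun("J.", "J.", M, SG),
                       noun("Jonaitis", "Jonaitis", M, SG),
                       word("atsakė"), punct()],
                      nes=[(0, 1, lc.NeClass.Person, M, SG, "Jonaitis")])
            .build())


def test_initial_plus_surname_matches_full_form():
    doc = _initial_surname_doc()
    [link] = resolve_repetition(doc)
    assert _span_text(doc, link.referent_span) == "J. Jonaitis"
    assert _span_text(doc, link.mentions[0].span) == "Jonas Jonaitis"


def test_acronym_dialect_off_disables_partial_matching():
    doc = _initial_surname_doc()
    assert resolve_repetition(doc, acronym_dialect="off") == []


def test_organization_acronym_matches_word_initials():
    doc = (DocumentBuilder("org", DATE)
           .sentence([noun("Kauno", "kaunas", M, SG),
                      noun("technologijos", "technologija", F, SG),
                      noun("universitetas", "universitetas", M, SG),
                      word("skelbia"), punct()],
                     nes=[(0, 2, lc.NeClass.Organization, M, SG, "universitetas")])
           .sentence([noun("KTU", "KTU", M, SG), word("patvirtino"), punct()],
                     nes=[(0, 0, lc.NeClass.Organization, M, SG, "KTU")])
           .build())
    [link] = resolve_repetition(doc)
    assert _span_text(doc, link.referent_span) == "KTU"
    assert _span_text(doc, link.mentions[0].span) == "Kauno technologijos universitetas"


def test_acronym_without_preceding_organization_stays_unlinked():
    doc = (DocumentBuilder("lonely", DATE)
           .sentence([noun("KTU", "KTU", M, SG), word("patvirtino"), punct()],
                     nes=[(0, 0, lc.NeClass.Organization, M, SG, "KTU")])
           .build())
    assert resolve_repetition(doc) == []


def test_locations_match_by_exact_lemma_only():
    b = DocumentBuilder("loc", DATE)
    b.sentence([noun("Naujoji", "naujoji", F, SG),
                noun("Akmenė", "Akmenė", F, SG), word("laukia"), punct()],
               nes=[(0, 1, lc.NeClass.Location, F, SG, "Akmenė")])
    b.sentence([noun("NA", "NA", F, SG), word("augo"), punct()],
               nes=[(0, 0, lc.NeClass.Location, F, SG, "NA")])
    assert resolve_repetition(b.build()) == []


def test_hypernym_pair_requires_gender_and_number_agreement(taxonomy):
    def build(number2):
        return (DocumentBuilder("prof", DATE)
                .sentence([noun("Gydytojai", "gydytojas", M, PL),
                           word("skundžiasi"), punct()])
                .sentence([noun("Chirurgas" if number2 == SG else "Chirurgai",
                                "chirurgas", M, number2),
                           word("dirba"), punct()])
                .build())
    [link] = resolve_profession(build(PL), taxonomy)
    assert link.subtype == lc.LinkSubtype.Hypernym_Hyponym
    assert resolve_profession(build(SG), taxonomy) == []


def test_synonym_via_distinct_name_variants(fixtures_by_name, taxonomy):
    doc = fixtures_by_name["head-chief-surgeon"].document
    [link] = resolve_profession(doc, taxonomy)
    assert link.subtype == lc.LinkSubtype.Synonym
    assert _span_text(doc, link.referent_span) == "vadovu"
    assert _span_text(doc, link.mentions[0].span) == "vyr. chirurgo"


def test_anaphor_orientation_flips_referent_and_mention(fixtures_by_name,
                                                        taxonomy):
    doc = fixtures_by_name["head-chief-surgeon"].document
    [link] = resolve_profession(doc, taxonomy, orientation="anaphor")
    assert _span_text(doc, link.referent_span) == "vyr. chirurgo"
    assert _span_text(doc, link.mentions[0].span) == "vadovu"


def test_identical_lemma_twice_is_synonym_not_hypernym(taxonomy):
    doc = (DocumentBuilder("same", DATE)
           .sentence([noun("Gydytojas", "gydytojas", M, SG), word("dirba"), punct()])
           .sentence([noun("gydytojas", "gydytojas", M, SG), word("ilsisi"), punct()])
           .build())
    [link] = resolve_profession(doc, taxonomy)
    assert link.subtype == lc.LinkSubtype.Synonym


def test_feature_backward_link(fixtures_by_name, persons_kb):
    doc = fixtures_by_name["cardiologist"].document
    [link] = resolve_feature(doc, persons_kb)
    assert link.rule_id == "R11"
    assert link.position == lc.LinkPosition.Backward
    assert _span_text(doc, link.referent_span) == "kardiologo"
    assert _span_text(doc, link.mentions[0].span) == "S. Suskelis"


def test_feature_forward_link(fixtures_by_name, persons_kb):
    doc = fixtures_by_name["family-doctor"].document
    [link] = resolve_feature(doc, persons_kb)
    assert link.rule_id == "R12"
    assert link.position == lc.LinkPosition.Forward


def _suskelis_doc(date, number=SG, noun_gender=M):
    return (DocumentBuilder("feat", date)
            .sentence([noun("S.", "S.", M, SG),
                       noun("Suskelis", "Suskelis", M, SG),
                       word("kalbėjo"), punct()],
                      nes=[(0, 1, lc.NeClass.Person, M, SG, "Suskelis")])
            .sentence([noun("kardiologas" if number == SG else "kardiologai",
                            "kardiologas", noun_gender, number),
                       word("pataria"), punct()])
            .build())


def test_publication_date_outside_position_interval_blocks_link(persons_kb):
    assert resolve_feature(_suskelis_doc(datetime.date(2021, 6, 1)),
                           persons_kb) == []
    assert len(resolve_feature(_suskelis_doc(DATE), persons_kb)) == 1


def test_feature_requires_singular_noun(persons_kb):
    assert resolve_feature(_suskelis_doc(DATE, number=PL), persons_kb) == []


def test_feature_requires_gender_agreement_with_person(persons_kb):
    assert resolve_feature(_suskelis_doc(DATE, noun_gender=F), persons_kb) == []


def test_feature_without_publication_date_is_a_configuration_error(persons_kb):
    doc = _suskelis_doc(DATE)
    undated = lc.AnnotatedDocument(
        doc_id=doc.doc_id, text=doc.text, sentences=doc.sentences,
        named_entities=doc.named_entities, publication_date=None)
    with pytest.raises(lc.ConfigurationError, match="publication date"):
        resolve_feature(undated, persons_kb)


def test_a3_a4_links_irrelevant_a5_links_directional(resolver):
    """Position constants: repetition and profession links are Irrelevant,
    feature links Backward or Forward, across fixtures and synthetic docs."""
    docs = [f.document for f in lc.paper_examples()]
    docs += [d for d, _ in lc.generate_synthetic(None, 30, 3)]
    for doc in docs:
        for link in resolver.resolve(doc):
            if link.subtype in (lc.LinkSubtype.Repetition,
                                lc.LinkSubtype.Hypernym_Hyponym,
                                lc.LinkSubtype.Synonym):
                assert link.position == lc.LinkPosition.Irrelevant
            elif link.subtype == lc.LinkSubtype.Feature:
                assert link.position in (lc.LinkPosition.Backward,
                                         lc.LinkPosition.Forward)
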