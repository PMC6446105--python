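"""Decision-table dispatch: condition order, exclusivity, algorithm choice."""

import itertools

import ltcoref as lc
from ltcoref.dispatch import Algorithm, Condition, dispatch
from ltcoref.standoff import DocumentBuilder, comma, noun, prep, pron, punct, word


def _decision_for(doc, lexeme_ref, taxonomy=None, persons_kb=None):
    decisions = dispatch(doc, taxonomy=taxonomy, persons_kb=persons_kb)
    return next(d for d in decisions if d.lexeme_ref == lexeme_ref)


def test_relative_pronoun_after_comma_goes_to_a1(fixtures_by_name):
    doc = fixtures_by_name["backache-1"].document
    d = _decision_for(doc, 4)
    assert (d.condition_fired, d.algorithm) == (Condition.C2, Algorithm.A1)


def test_relative_pronoun_with_preposition_goes_to_a1(fixtures_by_name):
    doc = fixtures_by_name["backache-2"].document
    d = _decision_for(doc, 5)
    assert d.algorithm == Algorithm.A1


def test_demonstrative_pronoun_is_ignored():
    doc = (DocumentBuilder("demo")
           .sentence([pron("Tas", "tas", lc.PronounType.Demonstrative,
                           lc.Gender.Masculine, lc.Number.Singular),
                      word("yra"), word("aišku"), punct()])
           .build())
    d = _decision_for(doc, 0)
    assert d.algorithm == Algorithm.NONE
    assert d.condition_fired == Condition.C1


def test_personal_pronoun_goes_to_a2(fixtures_by_name):
    doc = fixtures_by_name["jonas-jis"].document
    pron_ref = len(doc.sentences[0].lexemes)
    d = _decision_for(doc, pron_ref)
    assert (d.condition_fired, d.algorithm) == (Condition.C3, Algorithm.A2)


def test_noun_inside_person_ne_goes_to_a3(fixtures_by_name):
    doc = fixtures_by_name["tomaitis-repetition"].document
    d = _decision_for(doc, 0)
    assert (d.condition_fired, d.algorithm) == (Condition.C6, Algorithm.A3)


def test_profession_noun_goes_to_a4(fixtures_by_name, taxonomy):
    doc = fixtures_by_name["doctor-surgeon"].document
    d = _decision_for(doc, 0, taxonomy=taxonomy)
    assert (d.condition_fired, d.algorithm) == (Condition.C6, Algorithm.A4)


def test_active_title_noun_goes_to_a5(fixtures_by_name, persons_kb):
    doc = fixtures_by_name["cardiologist"].document
    lemmas = [lx.lemma for lx in doc.lexemes()]
    ref = lemmas.index("kardiologas")
    d = _decision_for(doc, ref, persons_kb=persons_kb)
    assert (d.condition_fired, d.algorithm) == (Condition.C7, Algorithm.A5)


def test_decisions_cover_every_pronoun_and_noun(fixtures_by_name, taxonomy,
                                                persons_kb):
    for fixture in fixtures_by_name.values():
        doc = fixture.document
        decisions = dispatch(doc, taxonomy=taxonomy, persons_kb=persons_kb)
        covered = {d.lexeme_ref for d in decisions}
        expected = {i for i, lx in enumerate(doc.lexemes())
                    if lx.pos in (lc.Pos.Pronoun, lc.Pos.Noun)}
        assert covered == expected


def test_at_most_one_algorithm_per_lexeme_over_synthetic_docs(taxonomy,
                                                              persons_kb):
    for doc, _ in lc.generate_synthetic(None, 40, 11):
        decisions = dispatch(doc, taxonomy=taxonomy, persons_kb=persons_kb)
        refs = [d.lexeme_ref for d in decisions]
        assert len(refs) == len(set(refs))


def test_pronoun_pass_precedes_noun_pass(fixtures_by_name, taxonomy,
                                         persons_kb):
    """All pronoun decisions come before any noun decision, each pass in
    document order."""
    doc = fixtures_by_name["cardiologist"].document
    decisions = dispatch(doc, taxonomy=taxonomy, persons_kb=persons_kb)
    lexemes = doc.lexemes()
    kinds = [lexemes[d.lexeme_ref].pos for d in decisions]
    first_noun = kinds.index(lc.Pos.Noun)
    assert all(k == lc.Pos.Noun for k in kinds[first_noun:])
    for pos_kind in (lc.Pos.Pronoun, lc.Pos.Noun):
        refs = [d.lexeme_ref for d in decisions
                if lexemes[d.lexeme_ref].pos == pos_kind]
        assert refs == sorted(refs)


def test_exhaustive_condition_combinations_on_synthetic_lexemes(taxonomy,
                                                                persons_kb):
    """Dispatch over all combinations of (pronoun type x comma pattern) and
    (NE membership / profession / title) picks the documented algorithm."""
    # pronoun side
    for ptype, with_comma in itertools.product(
            [lc.PronounType.Relative, lc.PronounType.Demonstrative,
             lc.PronounType.Other],
            [True, False]):
        tokens = [noun("vyras")]
        if with_comma:
            tokens.append(comma())
        tokens.append(pron("kuris", "kuris", ptype,
                           lc.Gender.Masculine, lc.Number.Singular))
        doc = DocumentBuilder("combo").sentence(tokens).build()
        d = _decision_for(doc, len(tokens) - 1)
        if ptype == lc.PronounType.Demonstrative:
            assert d.algorithm == Algorithm.NONE
        elif ptype == lc.PronounType.Relative and with_comma:
            assert d.algorithm == Algorithm.A1
        else:
            assert d.algorithm == Algorithm.A2
    # noun side: NE membership beats profession, profession beats title
    b = DocumentBuilder("nouncombo", lc.paper_examples()[0].document.publication_date)
    b.sentence(
        [noun("Tomaitis", "Tomaitis"), noun("gydytojas", "gydytojas"),
         noun("kardiologo", "kardiologas"), noun("stalas", "stalas"), punct()],
        nes=[(0, 0, lc.NeClass.Person, lc.Gender.Masculine,
              lc.Number.Singular, "Tomaitis")],
    )
    doc = b.build()
    algs = {d.lexeme_ref: d.algorithm
            for d in dispatch(doc, taxonomy=taxonomy, persons_kb=persons_kb)}
    assert algs[0] == Algorithm.A3
    assert algs[1] == Algorithm.A4   # "gydytojas" is a profession name
    assert algs[2] == Algorithm.A5   # "kardiologas" only matches a held title
    assert algs[3] == Algorithm.NONE
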