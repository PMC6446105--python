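# Methods

## The resolution model

The engine treats coreference resolution as deterministic rule application
over a preannotated document.  It assumes upstream processing has already
produced sentence segmentation, per-lexeme morphology (lemma, part of
speech, pronoun type, gender, number) and named-entity spans; it never
inspects surface strings except where a rule is explicitly about surface
shape (initials, acronyms).  Twelve rules grouped into five algorithms are
driven by a decision table:

* **C1/C2/C3 (pronoun pass).**  Every pronoun is examined in document
  order.  A Relative-type pronoun immediately preceded by a comma, or by a
  single preposition that follows a comma, goes to the specific rules (A1);
  any other non-demonstrative pronoun goes to general-purpose resolution
  (A2); demonstratives are deliberately ignored — they typically point
  outside the written text and carry no recoverable referent.
* **C4/C6/C7 (noun pass).**  A noun inside a recognised named entity goes
  to repetition matching (A3); otherwise a noun matching a profession-name
  variant goes to taxonomy matching (A4); otherwise a noun whose lemma
  equals a position title active on the publication date goes to feature
  resolution (A5).  The published account enumerates the conditions by
  name but the table's cell-level semantics had to be reconstructed from
  the algorithm descriptions and worked examples; the reconstruction above
  reproduces every worked example and is the package's committed reading.
  No condition "C5" is defined anywhere in the source material, and none is
  invented here.

A noun can name both a profession and an active position title; the
dispatcher records the A4 reading (its conditions are tested first), but the
resolver still offers such nouns to A5, because the two link types are
additive annotations rather than competitors.

### Rule semantics and deliberate readings

The rules' formal statements and their prose disagree in a few places; each
conflict is resolved once, as follows, and uniformly for the engine and the
brute-force evaluator:

* **R1 antecedent position.**  The antecedent noun immediately *precedes*
  the comma (the formalisation's `follows` literal points the other way,
  but the prose and both worked examples require precedence).
* **R3–R7 typing.**  General-purpose links carry subtype `General`, and the
  two forward rules carry position `Forward`, as the formal consequents
  state (the prose repeats `Relative`/`Backward` boilerplate).
* **Nearest candidate.**  The negated-existential conditions are read as
  "no strictly closer agreeing candidate in the same search region":
  greatest start offset for backward search, smallest for forward.  Ties
  are impossible because character offsets are strict, so the
  exists-unique requirement is always satisfiable.
* **R2 list length.**  The formalisation spells out three- and four-noun
  coordinated lists; the implementation generalises the pattern
  `noun (, noun)* conj noun` to any n ≥ 2 nouns, matching the construction
  rather than a fixed arity.  No gender or per-noun number agreement is
  required for list members — the motivating example mixes genders.
* **Agreement with ambiguous forms.**  Gender `Common` (morphologically
  ambiguous pronouns such as "man") is compatible with every gender, so
  only numbers are compared; `Unspecified` number behaves the same way.
* **A4 orientation.**  R9/R10 assign the referent span to the
  first-quantified noun; under a left-to-right scan that is the *earlier*
  occurrence, while the feature rules R11/R12 make the *later* title noun
  the referent.  The default (`nominal_orientation="fol"`) follows each
  rule's own literal span assignment and documents the asymmetry; setting
  `"anaphor"` flips R9/R10 so the later occurrence is always the referent.
  Both the fixtures and the generator encode gold in the default
  orientation.

### Search windows

Backward search spans the current sentence and at most two preceding ones;
forward search spans the current sentence and at most one following.  These
bounds are exactly the distances the five general-purpose rules encode —
there is no rule beyond them, so a pronoun with no agreeing person entity in
that window stays unresolved rather than being guessed.  The asymmetry
(two back, one forward) is inherited from the rule set as published.

### Repetition, partial and acronym matching

Exact repetition compares full lemma sequences case-insensitively within
one entity class.  The partial/acronym dialect (`acronym_dialect="default"`)
adds the minimal predicates the method sketches: person entities match on
surname lemma when at least one occurrence is a shortened form (initial +
surname, or bare surname) — two *full* forms with different given names
never match; an organization acronym is a single all-uppercase token equal
to the concatenated word initials of a preceding multiword organization
entity; locations match by exact lemma only.  `"off"` restricts A3 to exact
repetition.  Chains stay sparse: each occurrence links only to its nearest
preceding match (B→A, C→B, never C→A), so a cluster of k occurrences yields
exactly k−1 links.

### Knowledge-base semantics

Position intervals are inclusive on both ends (`from ≤ date ≤ to`); a
position lookup on the day after an appointment ends finds nothing.  An
entity is tied to a known person by lemma-level match of the entity's head
lemma against a recorded name form; disambiguation between two known
persons sharing a surname is out of scope.  Profession relatedness uses
*direct* broader/narrower edges only — the hypernym rule applies a single
predicate — with transitive closure available behind
`taxonomy_transitive=True` (off by default).  When a noun pair qualifies as
both synonym and hypernym/hyponym the synonym reading wins, same-profession
being the stronger statement; with an acyclic edge set and the
distinct-profession requirement this can only arise through pathological
name maps, but the precedence is fixed regardless.

## Evaluation

A predicted link is correct iff its referent span and mention span set
exactly equal a gold link's spans; subtype comparison is available behind a
strict flag.  Mentions here are plain character spans, so exact equality is
the natural criterion and no partial-credit clustering metric (MUC,
B-cubed, CEAF) is implemented.  `T` (total solvable expressions) is an
input supplied with the gold standard, never derived by the scorer.
Metrics are kept at full precision and reported half-up to three decimals.
The published experiment table that this package's metric layer reproduces
mixes rounding and truncation in its printed cells, so agreement is asserted
to within 0.001, which absorbs both conventions.

## The synthetic generator

`generate_synthetic` assembles documents from phenomenon templates —
relative clause (with or without preposition), personal pronoun at sentence
distance 0/1/2, entity repetition chains of length 2–4 (person surnames or
organization + acronym), profession pairs, and feature pairs whose
publication date falls inside or outside the position's validity interval —
plus distractors that must stay unlinked (gender-mismatched relative
patterns, demonstratives, location entities).  Phenomenon densities are
per-document insertion probabilities, 0.3 each by default with distractors
at 0.5: roughly one to two phenomena per document, which keeps every
document within six sentences so that exhaustive rule evaluation stays
cheap.  Gold links are recorded at insertion time; each document's gold set
is verified against the brute-force evaluator and the document is
regenerated on a collision, so generated gold is unambiguous by
construction.  Template vocabulary keeps gender pools disjoint (pronoun
templates feminine, repetition and knowledge-base persons masculine), which
is what makes single-candidate resolution provably unique.

What the generator does *not* emulate: real Lithuanian inflection (the
closed vocabulary carries correct feature annotations, not real paradigms),
annotation noise (wrong lemmas, missed entities), genuinely ambiguous
candidate sets, pleonastic pronouns, and document lengths beyond six
sentences.  Perfect scores on this corpus therefore demonstrate that the
engine implements its rules faithfully — not that the rules resolve real
clinical text perfectly; the published corpus-level scores (precision
around 0.78 at recall 0.45) are what the method achieves against real,
noisy, partially unsolvable data, and that corpus is not redistributable.

## Engine vs brute-force evaluator

The sequential engine resolves each anaphor by directed search (nearest
candidate per region, first matching region wins).  The brute-force
evaluator rederives the link set by enumerating *all* candidate tuples and
keeping those satisfying the rule bodies, including the no-closer-candidate
negations checked literally over the full candidate pool.  The two share
the data model and knowledge-base lookups but no search code; their exact
agreement over seeded 500-document corpora is asserted in the test suite.

## Numerical and degenerate-input choices

Offsets are 0-based `(start, length)` pairs.  Documents with zero sentences
or zero links are valid and round-trip.  Output link order is canonical
(referent start, rule number, mention spans), which makes repeated runs
byte-identical.  Metric zero conventions: R = 0 when T = 0, P = 0 when
F = 0, F1 = 0 when R + P = 0.  Knowledge-base dates must parse as ISO-8601
at load time — an unparseable date is an error, never a silent skip.

## Known limitations

* Only person entities can be pronoun antecedents (A2) and feature targets
  (A5); organization/location pronominal anaphora is unhandled.
* Cataphora reaches at most one sentence forward; no two-sentence forward
  rule exists.
* Feature resolution trusts the document-level publication date; text about
  past events held against a current database will mislink, and a stale
  persons database lowers recall — the database is an immutable input per
  run.
* Demonstratives and pleonastic pronouns are skipped by design.
* Position titles match single-lexeme lemmas; multiword titles must be
  modelled through their head noun.
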