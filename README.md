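# ltcoref

Rule-based coreference resolution for morphologically preannotated
Lithuanian text, built for settings where the linguistic resources that
machine-learned resolvers need (large annotated corpora, rich lexicons) do
not exist.  It was designed around clinical text — hospital-reception
transcripts and similar records — but the engine itself is language-neutral:
it reads morphological features and lemmas from its input annotations, never
surface strings, so any language with similar relative-clause and agreement
structure can be served by swapping the annotation layer.

## What it does

The input is a standoff-annotated document: sentences segmented into
lexemes, each with a lemma, part of speech, pronoun type, grammatical gender
and number, plus named-entity (NE) spans classed as person, organization or
location, and a publication date.  A decision table scans the lexemes —
pronouns first, then nouns — and activates one of five deterministic
algorithms:

| algorithm | target | rules |
|---|---|---|
| A1 | relative pronouns in the rigid pattern `noun , [preposition] pronoun`, including plural pronouns closing a coordinated noun list | R1–R2 |
| A2 | other non-demonstrative pronouns, resolved to the nearest person NE agreeing in gender and number (backward up to two sentences, then forward up to one) | R3–R7 |
| A3 | repeated named entities: exact lemma matches, shortened person forms ("Jonas Jonaitis" / "J. Jonaitis"), organization acronyms ("KTU") | R8 |
| A4 | profession nouns related through a profession taxonomy (hypernym/hyponym or synonym) | R9–R10 |
| A5 | "feature" references: a position-title noun (e.g. "kardiologas") tied to the known person who held that post on the publication date | R11–R12 |

Each resolved anaphor yields one typed link — `(type, subtype, position,
group)` plus the referent span and one or more mention spans.  Links are
deterministic functions of the input: same document, same configuration,
same output, byte for byte.

The evaluation layer scores predicted links against gold by exact span
equality and reports recall `R = C/T`, precision `P = C/F` and
`F1 = 2RP/(R+P)`, where `T` counts solvable expressions, `F` resolved ones
and `C` correctly resolved ones.

The package also ships, as first-class tested code, the two resources the
nominal algorithms need (a toy public-persons database with date-ranged
positions and a profession taxonomy), re-encodings of the method's worked
examples as fixtures with gold links, a seeded synthetic-corpus generator
with known gold annotations, and a brute-force evaluator that rederives the
link set by exhaustively checking every candidate tuple against the
first-order rule bodies — an independent cross-check on the sequential
engine.

## Worked example

```python
import ltcoref as lc

resolver = lc.CoreferenceResolver(persons_kb=lc.toy_persons_kb(),
                                  taxonomy=lc.toy_taxonomy())
for name in ("jonas-jis", "cardiologist"):
    fx = {f.name: f for f in lc.paper_examples()}[name]
    doc = fx.document
    print(doc.text)
    for link in resolver.resolve(doc):
        ref = doc.text[link.referent_start:link.referent_start + link.referent_length]
        for m in link.mentions:
            print(f"{link.rule_id} {link.ctype.value}/{link.subtype.value} "
                  f"({link.position.value}): {ref!r} -> "
                  f"{doc.text[m.start:m.start + m.length]!r}")
```

prints

```
Jonas Jonaitis skambino į registratūrą. Jis skundėsi galvos skausmu.
R4 Pronominal/General (Backward): 'Jis' -> 'Jonas Jonaitis'

Ką rekomenduoja S. Suskelis? Aptarkime kardiologo siūlomą gydymo planą.
R11 Nominal/Feature (Backward): 'kardiologo' -> 'S. Suskelis'
```

The first link is general-purpose pronoun resolution: "Jis" ("he") agrees in
gender and number with the person entity one sentence back.  The second is a
feature reference: "kardiologo" (genitive of "cardiologist") matches a
position S. Suskelis holds on the document's publication date in the persons
database, so the noun is linked backward to his entity mention.

## Command line

```bash
ltcoref fixtures -o fixtures/            # worked examples + toy KB files
ltcoref annotate fixtures/*.doc.json -o out/ \
    --persons-kb fixtures/persons.json --taxonomy fixtures/professions.yaml
ltcoref evaluate --gold fixtures/jonas-jis.gold.json \
    --pred out/jonas-jis.links.json
ltcoref evaluate --counts "648,371,289" --label full-system
```

The last command computes metrics from externally supplied counts:

```
configuration	T	F	C	R	P	F1
full-system	648	371	289	0.446	0.779	0.567
```

`annotate --algorithms A1,A2` restricts the run to a subset of algorithms,
reproducing ablation configurations; link sets are additive across
algorithms.

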