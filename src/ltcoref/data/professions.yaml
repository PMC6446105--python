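# Toy profession classification for fixtures and the synthetic generator.
# Name variants are lemma sequences; multiword variants match contiguous
# lexeme lemmas with the last (noun) lexeme supplying gender and number.
professions:
  - id: doctor
    names:
      - [gydytojas]
  - id: surgeon
    names:
      - [chirurgas]
  - id: chief-surgeon
    names:
      - [vadovas]
      - [vyr., chirurgas]
broadens:
  - [surgeon, doctor]
  - [chief-surgeon, surgeon]
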