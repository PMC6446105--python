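[
 {
  "person_id": "p-suskelis",
  "gender": "Masculine",
  "name_forms": ["Suskelis", "S. Suskelis"],
  "positions": [
   {"title_lemma": "kardiologas", "from_date": "2015-01-01", "to_date": "2020-12-31"}
  ]
 },
 {
  "person_id": "p-tomaitis-t",
  "gender": "Masculine",
  "name_forms": ["Tomaitis", "T. Tomaitis"],
  "positions": [
   {"title_lemma": "gydytojas", "from_date": "2010-01-01", "to_date": "2025-12-31"}
  ]
 }
]
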