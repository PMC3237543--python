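# Source mutation-description vocabulary -> structural mutation class.
# Matching is a case-insensitive prefix test, first entry wins.
# Kept as data (not code) because catalogue vocabularies drift.
mappings:
  - match: "Substitution - Missense"
    class: SubstitutionMutation
    sub_kind: missense
  - match: "Substitution - Nonsense"
    class: SubstitutionMutation
    sub_kind: nonsense
  - match: "Substitution - coding silent"
    class: SubstitutionMutation
    sub_kind: silent
  - match: "Substitution"
    class: SubstitutionMutation
    sub_kind: n/a
  - match: "Deletion"
    class: DeletionMutation
    sub_kind: n/a
  - match: "Insertion"
    class: InsertionMutation
    sub_kind: n/a
  - match: "Complex"
    class: ComplexMutation
    sub_kind: n/a
  - match: "Unknown"
    class: OtherMutation
    sub_kind: n/a
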