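# Counts of kinases having missense mutations per cancer type
SELECT ?h (COUNT(DISTINCT ?g) AS ?n)
WHERE {
  ?g pk:hasMutation ?m .
  ?m rdf:type pk:SubstitutionMutation ; pk:hasMutationType "Missense" .
  ?m pk:hasPrimaryHistology ?h .
}
GROUP BY ?h
ORDER BY DESC(?n) ?h
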