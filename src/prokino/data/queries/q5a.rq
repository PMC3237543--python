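# Counts of substitution missense mutations (at least 4) per cancer type
SELECT ?h (COUNT(DISTINCT ?m) AS ?n)
WHERE {
  ?m rdf:type pk:SubstitutionMutation ; pk:hasMutationType "Missense" .
  ?m pk:hasPrimaryHistology ?h .
}
GROUP BY ?h
HAVING (COUNT(DISTINCT ?m) >= 4)
ORDER BY DESC(?n) ?h
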