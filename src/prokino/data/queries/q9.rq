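# Counts of kinases (at least 2) with mutations per cancer type
SELECT ?h (COUNT(DISTINCT ?g) AS ?n)
WHERE {
  ?g pk:hasMutation ?m .
  ?m pk:hasPrimaryHistology ?h .
}
GROUP BY ?h
HAVING (COUNT(DISTINCT ?g) >= 2)
ORDER BY DESC(?n) ?h
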