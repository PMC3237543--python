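# Counts of mutated kinases per primary site
SELECT ?site (COUNT(DISTINCT ?g) AS ?n)
WHERE {
  ?g pk:hasMutation ?m .
  ?m pk:hasPrimarySite ?site .
}
GROUP BY ?site
ORDER BY DESC(?n) ?site
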