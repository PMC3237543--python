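# Counts of mutations of all types per sub-domain
SELECT ?label (COUNT(DISTINCT ?m) AS ?n)
WHERE {
  ?m pk:locatedIn ?sd .
  ?sd pk:hasSubDomainLabel ?label .
}
GROUP BY ?label
ORDER BY DESC(?n) ?label
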