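# Counts of FLT3 missense mutations per sub-domain (haematopoietic and lymphoid tissue)
SELECT ?label (COUNT(DISTINCT ?m) AS ?n)
WHERE {
  ?g pk:hasPrimaryName "FLT3" .
  ?g pk:hasMutation ?m .
  ?m rdf:type pk:SubstitutionMutation ; pk:hasMutationType "Missense" .
  ?m pk:hasPrimarySite "haematopoietic_and_lymphoid_tissue" .
  ?m pk:locatedIn ?sd .
  ?sd pk:hasSubDomainLabel ?label .
}
GROUP BY ?label
ORDER BY DESC(?n) ?label
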