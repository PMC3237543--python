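# Counts of pathways per mutated kinase (at least 4 pathways)
SELECT ?name (COUNT(DISTINCT ?p) AS ?n)
WHERE {
  ?g rdf:type/rdfs:subClassOf* pk:Gene ; pk:hasPrimaryName ?name .
  ?g pk:participatesIn ?p .
  ?g pk:hasMutation ?m .
}
GROUP BY ?name
HAVING (COUNT(DISTINCT ?p) >= 4)
ORDER BY DESC(?n) ?name
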