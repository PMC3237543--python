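# Counts of cancer types implicated per kinase
SELECT ?name (COUNT(DISTINCT ?h) AS ?n)
WHERE {
  ?g rdf:type/rdfs:subClassOf* pk:Gene ; pk:hasPrimaryName ?name .
  ?g pk:hasMutation ?m .
  ?m pk:hasPrimaryHistology ?h .
}
GROUP BY ?name
ORDER BY DESC(?n) ?name
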