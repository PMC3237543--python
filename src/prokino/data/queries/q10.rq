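# Counts of kinases (at least 4) per pathway
SELECT ?pname (COUNT(DISTINCT ?g) AS ?n)
WHERE {
  ?g pk:participatesIn ?p .
  ?p pk:hasName ?pname .
}
GROUP BY ?pname
HAVING (COUNT(DISTINCT ?g) >= 4)
ORDER BY DESC(?n) ?pname
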