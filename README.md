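# prokino

A protein-kinase knowledge graph for integrative cancer-mutation analysis.

Somatic mutations in protein kinases are catalogued separately from the
sequence, structure, function and pathway data needed to interpret them.
`prokino` unifies these into one OWL/RDF ontology: a terminology (TBox) of
kinase concepts — genes under the kinome classification
(group → family → subfamily), sequences, Hanks sub-domains, mutation kinds,
functional features, pathways/reactions/complexes, database
cross-references — and an automated population pipeline (ABox) that reads
four flat-file source dialects (kinome table + FASTA, protein annotation
blocks, a somatic-mutation catalogue TSV, and a pathway export) into RDF.
Aggregate SPARQL queries then answer questions such as *"how many distinct
missense mutations are implicated in each cancer type?"* or *"which
sub-domains harbour the most mutations?"* — questions that require all the
sources at once.

Three components do the scientific work:

* **Sub-domain annotation** (`prokino.subdomains`). The kinase catalytic
  domain is tiled by twelve conserved sub-domains (Hanks numbering I–XI
  with VIa/VIb). A transparent anchor model — one short motif pattern per
  sub-domain, built on the canonical kinase motifs GxGxxG (I), VAIK (II),
  HRD (VIb), DFG (VII) and APE (VIII) — is searched greedily in canonical
  order; anchors tile the sequence into 1-based inclusive intervals, and
  mutation positions map into them (`locatedIn`). Divergent sequences with
  fewer than four anchors are withheld rather than guessed.
* **Mutation grammar** (`prokino.sources`). Protein-level changes in
  HGVS-like p. notation (`p.L858M`, `p.E746_A750del`,
  `p.K745_E746insT`, `p.L747_A750delinsP`) are decoded into a typed change
  and classified into the five structural mutation classes (substitution /
  deletion / insertion / complex / other), description text first, decoded
  notation as fallback. Distinct mutations are identified by the
  (gene, amino-acid change) pair, so sample recurrence never inflates counts.
* **Named queries with oracles** (`prokino.queries`). Fifteen SPARQL
  aggregate queries (q1–q4, q5a/q5b, q6–q14) each ship with a brute-force
  record-level oracle; tests require exact agreement between the two routes
  on generated bundles with known ground truth.

## Worked example

```bash
prokino fixtures --out demo --seed 7      # synthetic 25-gene bundle + ground truth
prokino build --sources demo --out demo/kinome.ttl
prokino query --ontology demo/kinome.ttl --id q7 --top 5
```

The build report (stderr) summarizes the ingest:

```
wrote demo/kinome.ttl (turtle)
records: 25 genes, 25 sequences, 239 mutation rows (0 rejected), 6 pathways
```

and the query prints the five most-mutated kinases in this bundle —
distinct (gene, amino-acid change) pairs per gene, ranked descending with
lexicographic tie-breaks:

```
kinase	count
SRC	15
ALK	14
JAK2	14
KIT	14
TGFBR1	14
```

`--id q13` aggregates the same mutations by the sub-domain they fall in
(here sub-domain I, the glycine-rich loop region, tops the list with 22):

```
subdomain	count
I	22
VIa	16
VIII	15
X	14
II	13
```

Sub-domain annotation alone:

```bash
prokino subdomains --fasta demo/sequences.fasta   # 1-based inclusive TSV
```

The same machinery is available as a library: `prokino.schema.build_schema`,
`prokino.sources.read_bundle`, `prokino.subdomains.locate_anchors` /
`assign_subdomains`, `prokino.population.populate` / `export_graph`, and
`prokino.queries.run_named_query`.

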