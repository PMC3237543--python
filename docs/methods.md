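# Methods

## The knowledge model

The terminology is defined in a single tab-separated manifest
(`src/prokino/data/schema_manifest.tsv`), one row per class, object
property or data property, and compiled by `prokino.schema.build_schema`
into a validated `SchemaGraph` (unique names; parents declared; the
subclass relation an acyclic forest; every property domain/range
resolvable). The manifest bundled here is a **curated reconstruction**: it
carries the full core vocabulary of the kinase knowledge model — `Gene`,
`ProteinKinaseDomain`, `Sequence`, `SubDomain`, `Mutation` with its five
structural subclasses, `FunctionalFeature` with three subclasses,
`FunctionalDomain`, `Structure`, `Isoform`, `BiochemicalEvent` with
`Pathway`/`Reaction`, `Complex`, `DbXref` — plus a kinome classification
subtree (10 groups, 92 families, 49 subfamilies curated from the standard
human-kinome classification), for 173 classes, 13 object properties and 21
data properties in total. The schema statistics that tests check are the
manifest's own enumeration; extending the manifest (it is plain data)
changes them without touching code.

Design choices in the class model:

* **Genes and classification.** Gene individuals are typed by their most
  specific known classification class (subfamily > family > group >
  `ProteinKinaseDomain`), and `ProteinKinaseDomain` is declared a subclass
  of `Gene`, so properties with domain `Gene` (`hasMutation`,
  `participatesIn`, `hasSequence`, ...) remain domain-valid for every
  classified gene. Where a family or subfamily shares its parent's name
  (the CK1 and RGC groups each contain a same-named family, for example),
  the manifest disambiguates with a `Family`/`Subfamily` suffix;
  `SchemaGraph.classification_class` resolves plain source names against
  either spelling.
* **Missense/nonsense/silent are a data property** (`hasMutationType`) on
  `SubstitutionMutation` individuals, not subclasses: the five structural
  kinds partition mutations, while the substitution sub-kind is an
  attribute of one kind.
* **Cancer annotations are data properties** (`hasPrimarySite`,
  `hasPrimaryHistology`) on the mutation, not links to cancer-type
  individuals; a recurrent mutation simply carries several values.
* **Union domains.** A property used from several classes (`hasDbXref`,
  `hasStartPosition`, `hasName`) declares a `|`-separated domain union;
  the ABox validator accepts a subject whose class is a subclass of any
  member. OWL reasoning is out of scope, so the union is a validation
  rule, not an axiom set.

## IRIs and determinism

Every individual's IRI is derived from its natural key — gene symbol;
(gene, aa change) for mutations; (gene, label, start) for sub-domain
instances; (database, accession) for cross-references — by percent-encoding
each key part (with `_` additionally escaped) and joining with `_` under a
lowercase kind prefix (`gene_`, `mut_`, `subdom_`, ...). The encoding is
injective, so distinct keys cannot collide, no blank nodes exist anywhere,
and populating the same bundle twice yields a byte-identical serialization.
Graph equality in tests is therefore exact triple-set equality, and
export → reload round trips (Turtle and RDF/XML) are required to preserve
the triple set exactly.

## Mutation parsing and counting

`parse_p_notation` is total: it decodes substitutions
`p.<Ref><Pos><Alt>` (`*` = stop → nonsense; Ref = Alt → silent),
single/span deletions, insertions and deletion-insertions, and maps
anything else to kind `other` with the raw text retained.
`format_p_notation` is its inverse on the supported grammar (property
tested on generated strings). Classification consults the source
description field first, via a bundled prefix-matched mapping table
(`data/mutation_descriptions.yaml` — kept as data because catalogue
vocabularies drift), and falls back to the decoded notation; the final
fallback is `OtherMutation`, so the five classes partition all records.

A **distinct mutation is a distinct (gene, amino-acid change) pair**.
Recurrence across samples adds site/histology/sample values to the one
individual. "Cancer type" in the per-cancer-type queries means the
primary-histology field; q12 and q14 group by primary site instead — the
two fields answer different questions (tumour type vs anatomical origin).
Mutations naming a gene absent from the kinome table are logged and
skipped, never fatal; a domain/range violation is fatal because it can
only be a schema/population inconsistency.

## Sub-domain anchor model

One regular-expression anchor per sub-domain, in canonical order
(I, II, III, IV, V, VIa, VIb, VII, VIII, IX, X, XI). The anchors for I
(`G.G..G`), II (VAIK-type, lysine as anchor residue), VIb (`H[RK]D.`),
VII (`DFG`) and VIII (APE-type) are the canonical kinase motifs; the
remaining seven are short residue-class patterns standing in for the
weaker sub-domain signatures. The model is a plain serializable object
(`MotifModel.save`/`load`), deliberately replaceable by profile-derived
anchors without touching the assignment logic; profile-HMM or
structure-based assignment is a non-goal.

Search is **greedy and order-constrained**: each anchor is sought only
strictly downstream of the previous accepted match, taking the leftmost
hit (determinism); an anchor with no downstream match yields no hit,
never an out-of-order one. Tiling: each found sub-domain spans from its
anchor start to one residue before the next anchor start; the last one
closes 10 residues past its match (bounded by the sequence end); residues
before the first anchor are the N-terminal tail and residues after the
last sub-domain the C-terminal tail, so assigned intervals always tile
`[1, L]` disjointly. With fewer than 4 anchors the assignment is withheld
(empty list) — mirroring the fact that sub-domain boundaries cannot be
delineated for divergent and atypical kinases. The activation segment is
reported as named segments derived from the anchors: DFG start to APE
end, split at the integer midpoint into its N-terminal half (≙ sub-domain
VII; the glycine-rich loop likewise ≙ the sub-domain I match span). Named
segments overlap the tiling and are returned separately from it.

Parameter summary (all residue coordinates 1-based, spans inclusive):

| parameter | default | role |
|---|---|---|
| `min_anchors` | 4 | below this, assignment withheld |
| `last_extension` | 10 residues | closes the final sub-domain |
| tie-break | leftmost downstream match | determinism |

## Synthetic bundles and ground truth

`prokino.fixtures.generate_bundle` emits all source dialects for up to 47
genes drawn from a fixed catalogue of real kinome entries (symbol,
synonyms, group/family/subfamily, cytogenetic band). Sequences are built
from a uniform 20-letter background with concrete anchor literals planted
at recorded positions (inter-anchor gaps 8–25 residues, tails 15–40 /
5–30); the background is then *scrubbed* — any spurious anchor-pattern
match outside a planted site has one residue replaced by a pattern-inert
letter (T/C/N) until no pattern matches anywhere except where planted.
Planted-anchor recovery by the matcher is therefore exact by construction,
which is what makes a 100 % recovery requirement meaningful. A
configurable fraction of genes (default 0.12) are "atypical", receiving
1–3 anchors so that assignment is withheld.

Defaults follow the study conditions the tests exercise: 25 genes, 0–15
mutations per gene (70 % missense, 6 % nonsense, 4 % silent, 8 %
deletion, 5 % insertion, 4 % complex, 3 % unparseable), six weighted
histologies with realistic site pairings (carcinoma 0.40, glioma 0.13,
malignant melanoma 0.12, haematopoietic neoplasm 0.13, lymphoid neoplasm
0.10, adenoma 0.12), a 20 % chance of a recurrent second sample per
mutation, six pathways with membership density 0.25, up to 8 structures
and 4 isoforms per gene. A single `random.Random(seed)` drives
everything; the same (config, seed) gives byte-identical documents.

`GroundTruth` (planted anchors, expected tilings, all 15 expected query
tables) is computed during generation from the generator's own
bookkeeping, never by running the parsers or the graph pipeline, so the
pipeline and the ground truth are independent routes to the same tables.
What the generator does **not** emulate: mutational hotspots and
signatures, sequence homology within families, realistic pathway
topology. Passing tests therefore demonstrate correctness of parsing,
population, annotation and counting — not biological fidelity of any
particular count.

## Query semantics

q1 structures, q2 isoforms, q3 pathways and q4 implicated cancer types
per kinase; q5a missense mutations per cancer type with a **minimum
count of 4** (read as applying per cancer type); q5b kinases with
missense per cancer type (unfiltered); q6 missense per kinase within
haematopoietic neoplasm; q7/q8 all/missense mutations per kinase; q9
kinases per cancer type (minimum 2); q10 kinases per pathway (minimum
4); q11 pathways per mutated kinase (minimum 4); q12 mutated kinases per
primary site; q13 mutations per sub-domain (tails included — they are
real locations); q14 FLT3 missense per sub-domain restricted to the
haematopoietic-and-lymphoid primary site. Ordering is always descending
count with lexicographic tie-breaks. The SPARQL texts live in
`src/prokino/data/queries/*.rq` without PREFIX headers; the runner
injects the configured namespace. Because each individual carries exactly
one (most specific) `rdf:type`, queries over a superclass use the
property path `rdf:type/rdfs:subClassOf*`.

## Known limitations

* The schema manifest is a reconstruction subset; its statistics describe
  this package's vocabulary, not the full original one.
* The seven non-canonical anchor patterns are surrogates; on real
  divergent kinases they will miss or mislocate anchors more often than a
  profile model would, and the withheld-assignment rule is the guard.
* Exact historical sub-domain boundaries for real proteins are not
  reproducible; real-protein expectations (e.g. L858 in the activation
  segment) are encoded in the worked-example bundle with planted anchors
  rather than asserted against live databases.
* Live retrieval from the upstream databases, ontology versioning/diffing
  and OWL reasoning are out of scope.
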