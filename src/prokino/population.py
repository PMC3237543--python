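"""Population of the knowledge graph (ABox) from parsed source records.

Every individual gets a deterministic IRI derived from its natural key
(gene symbol; (gene, amino-acid change) for mutations; (gene, label, start)
for sub-domain instances; (database, accession) for cross-references), so
populating twice from the same bundle yields the identical graph and no
blank nodes ever appear.  Distinct mutations are identified by the
(gene, amino-acid change) pair: recurrence of the same change in further
samples adds sample/site/histology values to the one individual instead of
creating a new one.

Records that reference a gene symbol unknown to the kinome table are
logged and skipped — they never abort a build.  A domain/range violation,
by contrast, is a hard error: it means the schema and the population code
disagree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from urllib.parse import quote

import rdflib
from rdflib import OWL, RDF, RDFS, Literal, URIRef

from .schema import SchemaGraph, schema_to_rdf, DEFAULT_NAMESPACE
from .sources import (
    MutationRecord,
    SourceBundle,
    classify_mutation,
    parse_p_notation,
    resolve_gene,
)
from .subdomains import SubDomainInterval, map_position

logger = logging.getLogger(__name__)

__all__ = ["IRIPolicy", "KnowledgeGraph", "populate", "export_graph", "load_graph", "graph_stats"]


@dataclass(frozen=True)
class IRIPolicy:
    """Deterministic, injective mapping (kind, natural key) -> IRI.

    Each key part is percent-encoded (with ``_`` additionally escaped) and
    parts are joined with ``_``, so distinct keys can never collide; a
    lowercase kind prefix keeps individuals clear of the CamelCase class
    namespace.
    """

    base: str = DEFAULT_NAMESPACE

    @staticmethod
    def _part(text: str) -> str:
        return quote(str(text), safe="").replace("_", "%5F")

    def iri(self, kind: str, *key: object) -> URIRef:
        local = "_".join([kind] + [self._part(str(k)) for k in key])
        return URIRef(self.base + local)


@dataclass
class KnowledgeGraph:
    """A populated ontology: rdflib graph plus an individual-class index."""

    schema: SchemaGraph
    graph: rdflib.Graph
    individuals: dict[URIRef, str] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    @property
    def triples(self) -> set[tuple]:
        return set(self.graph)

    def add_individual(self, iri: URIRef, class_name: str) -> URIRef:
        known = self.individuals.get(iri)
        if known is None:
            self.individuals[iri] = class_name
            self.graph.add((iri, RDF.type, self.schema.class_iri(class_name)))
        elif known != class_name:
            raise ValueError(
                f"individual {iri} already typed {known!r}, refusing retype to {class_name!r}"
            )
        return iri

    def add_object(self, s: URIRef, prop: str, o: URIRef) -> None:
        self.graph.add((s, self.schema.property_iri(prop), o))

    def add_data(self, s: URIRef, prop: str, value: object) -> None:
        self.graph.add((s, self.schema.property_iri(prop), Literal(value)))

    def query(self, sparql: str):
        return self.graph.query(sparql, initNs={"pk": self.schema.ns})

    # -- validation -------------------------------------------------------

    def validate(self) -> "KnowledgeGraph":
        """Check every object-property triple against declared domain/range."""
        props = {self.schema.property_iri(p.name): p
                 for p in self.schema.properties.values()}
        for s, p, o in self.graph:
            pdef = props.get(p)
            if pdef is None or s not in self.individuals:
                continue
            s_cls = self.individuals[s]
            if not any(self.schema.is_subclass_of(s_cls, d) for d in pdef.domain):
                raise ValueError(
                    f"domain violation: {pdef.name} on {s_cls} individual {s}"
                )
            if pdef.kind == "object":
                o_cls = self.individuals.get(o)
                if o_cls is None or not self.schema.is_subclass_of(o_cls, pdef.range):
                    raise ValueError(
                        f"range violation: {pdef.name} -> {o_cls} individual {o}"
                    )
        return self


def populate(
    schema: SchemaGraph,
    bundle: SourceBundle,
    subdomain_results: dict[str, list[SubDomainInterval]] | None = None,
    policy: IRIPolicy | None = None,
) -> KnowledgeGraph:
    """Build the ABox for a parsed source bundle.

    ``subdomain_results`` maps gene symbols to their sub-domain tiling
    (possibly empty when assignment was withheld); mutations of genes
    without a tiling simply get no ``locatedIn`` edge.
    """
    policy = policy or IRIPolicy(schema.namespace)
    kg = KnowledgeGraph(schema=schema, graph=schema_to_rdf(schema))
    subdomain_results = subdomain_results or {}

    def xref(db: str, accession: str) -> URIRef:
        iri = policy.iri("xref", db, accession)
        if iri not in kg.individuals:
            kg.add_individual(iri, "DbXref")
            kg.add_data(iri, "hasSourceDatabase", db)
            kg.add_data(iri, "hasAccession", accession)
        return iri

    # genes ----------------------------------------------------------------
    gene_iris: dict[str, URIRef] = {}
    for rec in bundle.genes:
        cls = schema.classification_class(rec.group, rec.family, rec.subfamily)
        if cls is None:
            logger.warning("gene %s: classification group %r not in schema; "
                           "typing as ProteinKinaseDomain", rec.symbol, rec.group)
            cls = "ProteinKinaseDomain"
        iri = policy.iri("gene", rec.symbol)
        kg.add_individual(iri, cls)
        gene_iris[rec.symbol] = iri
        kg.add_data(iri, "hasPrimaryName", rec.symbol)
        for syn in rec.synonyms:
            kg.add_data(iri, "hasOtherName", syn)
        if rec.chromosomal_position:
            kg.add_data(iri, "hasChromosomalPosition", rec.chromosomal_position)

    def gene_iri_for(name: str, context: str) -> URIRef | None:
        symbol = resolve_gene(name, bundle.genes)
        if symbol is None or symbol not in gene_iris:
            msg = f"{context}: unknown gene {name!r}; record skipped"
            logger.warning(msg)
            kg.skipped.append(msg)
            return None
        return gene_iris[symbol]

    # sequences and sub-domain instances ------------------------------------
    seq_iris: dict[str, URIRef] = {}
    for seq in bundle.sequences:
        g_iri = gene_iri_for(seq.symbol, f"sequence {seq.symbol}")
        if g_iri is None:
            continue
        symbol = resolve_gene(seq.symbol, bundle.genes)
        iri = policy.iri("seq", symbol)
        kg.add_individual(iri, "Sequence")
        kg.add_data(iri, "hasResidueSequence", seq.residues)
        kg.add_data(iri, "hasSequenceLength", len(seq.residues))
        kg.add_object(g_iri, "hasSequence", iri)
        seq_iris[symbol] = iri

    subdom_iris: dict[tuple[str, str], URIRef] = {}
    for symbol, intervals in subdomain_results.items():
        for iv in intervals:
            iri = policy.iri("subdom", symbol, iv.label, iv.start)
            kg.add_individual(iri, "SubDomain")
            kg.add_data(iri, "hasSubDomainLabel", iv.label)
            kg.add_data(iri, "hasStartPosition", iv.start)
            kg.add_data(iri, "hasEndPosition", iv.end)
            if symbol in seq_iris:
                kg.add_object(seq_iris[symbol], "hasSubDomain", iri)
            subdom_iris[(symbol, iv.label)] = iri

    # protein annotations ----------------------------------------------------
    for ann in bundle.annotations:
        g_iri = gene_iri_for(ann.symbol, f"annotation {ann.symbol}")
        if g_iri is None:
            continue
        symbol = resolve_gene(ann.symbol, bundle.genes)
        for dom in ann.functional_domains:
            iri = policy.iri("fd", symbol, dom.name, dom.start)
            kg.add_individual(iri, "FunctionalDomain")
            kg.add_data(iri, "hasName", dom.name)
            kg.add_data(iri, "hasStartPosition", dom.start)
            kg.add_data(iri, "hasEndPosition", dom.end)
            kg.add_object(g_iri, "hasFunctionalDomain", iri)
            if dom.pfam_xref:
                kg.add_object(iri, "hasDbXref", xref("Pfam", dom.pfam_xref))
        for feat in ann.features:
            iri = policy.iri("ff", symbol, feat.kind, feat.start, feat.end)
            kg.add_individual(iri, feat.kind)
            kg.add_data(iri, "hasStartPosition", feat.start)
            kg.add_data(iri, "hasEndPosition", feat.end)
            if feat.description:
                kg.add_data(iri, "hasDescription", feat.description)
            kg.add_object(g_iri, "hasFunctionalFeature", iri)
        for pdb_id in ann.structures:
            iri = policy.iri("struct", symbol, pdb_id)
            kg.add_individual(iri, "Structure")
            kg.add_data(iri, "hasName", pdb_id)
            kg.add_object(g_iri, "hasStructure", iri)
            kg.add_object(iri, "hasDbXref", xref("PDB", pdb_id))
        for iso in ann.isoforms:
            iri = policy.iri("iso", symbol, iso.isoform_id)
            kg.add_individual(iri, "Isoform")
            kg.add_data(iri, "hasIsoformId", iso.isoform_id)
            if iso.name:
                kg.add_data(iri, "hasName", iso.name)
            kg.add_object(g_iri, "hasIsoform", iri)
        if ann.cellular_location:
            kg.add_data(g_iri, "hasCellularLocation", ann.cellular_location)
        if ann.tissue_specificity:
            kg.add_data(g_iri, "hasTissueSpecificity", ann.tissue_specificity)

    # mutations --------------------------------------------------------------
    for rec in bundle.mutations:
        g_iri = gene_iri_for(rec.symbol, f"mutation {rec.mutation_id or rec.aa_change}")
        if g_iri is None:
            continue
        symbol = resolve_gene(rec.symbol, bundle.genes)
        iri = policy.iri("mut", symbol, rec.aa_change)
        if iri not in kg.individuals:
            cls, sub_kind = classify_mutation(rec)
            kg.add_individual(iri, cls)
            kg.add_data(iri, "hasAAChange", rec.aa_change)
            if rec.nt_change:
                kg.add_data(iri, "hasCDSChange", rec.nt_change)
            if rec.description:
                kg.add_data(iri, "hasDescription", rec.description)
            if cls == "SubstitutionMutation" and sub_kind != "n/a":
                kg.add_data(iri, "hasMutationType", sub_kind.capitalize())
            kg.add_object(g_iri, "hasMutation", iri)
            change = parse_p_notation(rec.aa_change)
            if change.position is not None:
                kg.add_data(iri, "hasStartPosition", change.position)
                intervals = subdomain_results.get(symbol, [])
                label = map_position(change.position, intervals) if intervals else None
                if label is not None:
                    kg.add_object(iri, "locatedIn", subdom_iris[(symbol, label)])
        if rec.primary_site:
            kg.add_data(iri, "hasPrimarySite", rec.primary_site)
        if rec.primary_histology:
            kg.add_data(iri, "hasPrimaryHistology", rec.primary_histology)
        if rec.sample_id:
            kg.add_data(iri, "hasSampleName", rec.sample_id)
        for ref in rec.references:
            db, _, acc = ref.partition(":")
            if not acc:
                db, acc = "PubMed", ref
            kg.add_object(iri, "hasDbXref", xref(db, acc))

    # pathways ----------------------------------------------------------------
    cx_iris: dict[str, URIRef] = {}
    for cx in bundle.complexes:
        iri = policy.iri("cx", cx.complex_id)
        kg.add_individual(iri, "Complex")
        kg.add_data(iri, "hasName", cx.name)
        cx_iris[cx.complex_id] = iri
    pw_iris: dict[str, URIRef] = {}
    for pw in bundle.pathways:
        iri = policy.iri("pw", pw.pathway_id)
        kg.add_individual(iri, "Pathway")
        kg.add_data(iri, "hasName", pw.name)
        pw_iris[pw.pathway_id] = iri
        for member in pw.members:
            g_iri = gene_iri_for(member, f"pathway {pw.pathway_id} member")
            if g_iri is not None:
                kg.add_object(g_iri, "participatesIn", iri)
    for rx in bundle.reactions:
        iri = policy.iri("rx", rx.reaction_id)
        kg.add_individual(iri, "Reaction")
        kg.add_data(iri, "hasName", rx.name)
        kg.add_object(pw_iris[rx.pathway_id], "hasReaction", iri)
        for cid in rx.consumes:
            kg.add_object(iri, "consumes", cx_iris[cid])
        for cid in rx.produces:
            kg.add_object(iri, "produces", cx_iris[cid])

    return kg.validate()


_DIALECT_FORMATS = {"turtle": "turtle", "rdfxml": "xml"}


def export_graph(kg: KnowledgeGraph, dialect: str = "turtle", destination: str | None = None) -> str:
    """Serialize schema + individuals as one OWL document."""
    if dialect not in _DIALECT_FORMATS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECT_FORMATS)}")
    doc = kg.graph.serialize(format=_DIALECT_FORMATS[dialect])
    if destination is not None:
        with open(destination, "w") as fh:
            fh.write(doc)
    return doc


def load_graph(document: str, schema: SchemaGraph, dialect: str = "turtle") -> KnowledgeGraph:
    """Reload an exported document (text or path) into a KnowledgeGraph."""
    g = rdflib.Graph()
    fmt = _DIALECT_FORMATS.get(dialect, dialect)
    if "\n" in document or document.lstrip().startswith(("<", "@", "PREFIX", "prefix")):
        g.parse(data=document, format=fmt)
    else:
        g.parse(document, format=fmt)
    kg = KnowledgeGraph(schema=schema, graph=g)
    class_iris = {schema.class_iri(name): name for name in schema.classes}
    classes = set(class_iris)
    for s, _, o in g.triples((None, RDF.type, None)):
        if o in classes and s not in classes and (s, RDF.type, OWL.Class) not in g:
            kg.individuals[s] = class_iris[o]
    return kg


def graph_stats(kg: KnowledgeGraph) -> dict[str, int]:
    """Individual counts per class, aggregated up the class hierarchy.

    Each individual counts toward its most-specific class and all of its
    ancestors, so e.g. the ``Mutation`` count is the sum over the mutation
    subclasses.
    """
    counts: dict[str, int] = {}
    for cls in kg.individuals.values():
        counts[cls] = counts.get(cls, 0) + 1
        for anc in kg.schema.ancestors(cls):
            counts[anc] = counts.get(anc, 0) + 1
    return dict(sorted(counts.items()))
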