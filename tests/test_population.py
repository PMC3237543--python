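"""ABox population: worked-example triples, triple-count oracle, round trips."""

import io
from collections import Counter

import pytest
from rdflib import RDF

from prokino.fixtures import FixtureConfig, generate_bundle
from prokino.population import (
    IRIPolicy,
    export_graph,
    graph_stats,
    load_graph,
    populate,
)
from prokino.schema import schema_to_rdf
from prokino.sources import (
    SourceBundle,
    classify_mutation,
    parse_p_notation,
    read_bundle,
)
from prokino.subdomains import map_position

from conftest import run_pipeline


def test_worked_example_triples(fig1, schema):
    kg = fig1.kg
    ns = schema.ns
    pol = IRIPolicy(schema.namespace)
    expected = [
        (pol.iri("gene", "EGFR"), ns["hasMutation"], pol.iri("mut", "EGFR", "p.L858M")),
        (pol.iri("mut", "EGFR", "p.L858M"), ns["locatedIn"],
         pol.iri("subdom", "EGFR", "VII", 855)),
        (pol.iri("gene", "EGFR"), ns["participatesIn"], pol.iri("pw", "P1")),
        (pol.iri("pw", "P1"), ns["hasReaction"], pol.iri("rx", "R1")),
        (pol.iri("rx", "R1"), ns["consumes"], pol.iri("cx", "C1")),
        (pol.iri("rx", "R1"), ns["produces"], pol.iri("cx", "C2")),
    ]
    for triple in expected:
        assert triple in kg.triples
    # the mutated residue falls in sub-domain VII (activation-segment N-terminus)
    assert map_position(858, fig1.subdomains["EGFR"]) == "VII"


def test_empty_bundle_is_schema_only(schema):
    kg = populate(schema, SourceBundle())
    assert kg.triples == set(schema_to_rdf(schema))
    assert graph_stats(kg) == {}


def expected_predicate_counts(bundle, subdomains):
    """Independent per-record enumeration of ABox triples by predicate.

    Works on abstract (kind, key, predicate, value) tuples so the identical
    deduplication semantics of an RDF triple set apply, without reusing the
    population code path.
    """
    triples: set[tuple] = set()

    def gene_key(name):
        name = name.lower()
        for rec in bundle.genes:
            if rec.symbol.lower() == name:
                return rec.symbol
        for rec in bundle.genes:
            if name in (s.lower() for s in rec.synonyms):
                return rec.symbol
        return None

    for rec in bundle.genes:
        g = ("gene", rec.symbol)
        triples.add(g + ("type", "classified"))
        triples.add(g + ("hasPrimaryName", rec.symbol))
        for syn in rec.synonyms:
            triples.add(g + ("hasOtherName", syn))
        if rec.chromosomal_position:
            triples.add(g + ("hasChromosomalPosition", rec.chromosomal_position))
    for seq in bundle.sequences:
        sym = gene_key(seq.symbol)
        if sym is None:
            continue
        s = ("seq", sym)
        triples.add(s + ("type", "Sequence"))
        triples.add(s + ("hasResidueSequence", seq.residues))
        triples.add(s + ("hasSequenceLength", len(seq.residues)))
        triples.add(("gene", sym, "hasSequence", s))
    for sym, intervals in subdomains.items():
        for iv in intervals:
            sd = ("subdom", sym, iv.label, iv.start)
            triples.add(sd + ("type", "SubDomain"))
            triples.add(sd + ("hasSubDomainLabel", iv.label))
            triples.add(sd + ("hasStartPosition", iv.start))
            triples.add(sd + ("hasEndPosition", iv.end))
            triples.add(("seq", sym, "hasSubDomain", sd))
    for ann in bundle.annotations:
        sym = gene_key(ann.symbol)
        if sym is None:
            continue
        g = ("gene", sym)
        for d in ann.functional_domains:
            fd = ("fd", sym, d.name, d.start)
            triples.add(fd + ("type", "FunctionalDomain"))
            triples.add(fd + ("hasName", d.name))
            triples.add(fd + ("hasStartPosition", d.start))
            triples.add(fd + ("hasEndPosition", d.end))
            triples.add(g + ("hasFunctionalDomain", fd))
            if d.pfam_xref:
                triples.add(fd + ("hasDbXref", ("xref", "Pfam", d.pfam_xref)))
                triples.update(_xref("Pfam", d.pfam_xref))
        for f in ann.features:
            ff = ("ff", sym, f.kind, f.start, f.end)
            triples.add(ff + ("type", f.kind))
            triples.add(ff + ("hasStartPosition", f.start))
            triples.add(ff + ("hasEndPosition", f.end))
            if f.description:
                triples.add(ff + ("hasDescription", f.description))
            triples.add(g + ("hasFunctionalFeature", ff))
        for pdb in ann.structures:
            stx = ("struct", sym, pdb)
            triples.add(stx + ("type", "Structure"))
            triples.add(stx + ("hasName", pdb))
            triples.add(g + ("hasStructure", stx))
            triples.add(stx + ("hasDbXref", ("xref", "PDB", pdb)))
            triples.update(_xref("PDB", pdb))
        for iso in ann.isoforms:
            ix = ("iso", sym, iso.isoform_id)
            triples.add(ix + ("type", "Isoform"))
            triples.add(ix + ("hasIsoformId", iso.isoform_id))
            if iso.name:
                triples.add(ix + ("hasName", iso.name))
            triples.add(g + ("hasIsoform", ix))
        if ann.cellular_location:
            triples.add(g + ("hasCellularLocation", ann.cellular_location))
        if ann.tissue_specificity:
            triples.add(g + ("hasTissueSpecificity", ann.tissue_specificity))
    seen_mut: set[tuple] = set()
    for rec in bundle.mutations:
        sym = gene_key(rec.symbol)
        if sym is None:
            continue
        m = ("mut", sym, rec.aa_change)
        if m not in seen_mut:
            seen_mut.add(m)
            cls, sub_kind = classify_mutation(rec)
            triples.add(m + ("type", cls))
            triples.add(m + ("hasAAChange", rec.aa_change))
            if rec.nt_change:
                triples.add(m + ("hasCDSChange", rec.nt_change))
            if rec.description:
                triples.add(m + ("hasDescription", rec.description))
            if cls == "SubstitutionMutation" and sub_kind != "n/a":
                triples.add(m + ("hasMutationType", sub_kind.capitalize()))
            triples.add(("gene", sym, "hasMutation", m))
            pos = parse_p_notation(rec.aa_change).position
            if pos is not None:
                triples.add(m + ("hasStartPosition", pos))
                for iv in subdomains.get(sym, []):
                    if iv.start <= pos <= iv.end:
                        triples.add(m + ("locatedIn", ("subdom", sym, iv.label, iv.start)))
                        break
        if rec.primary_site:
            triples.add(m + ("hasPrimarySite", rec.primary_site))
        if rec.primary_histology:
            triples.add(m + ("hasPrimaryHistology", rec.primary_histology))
        if rec.sample_id:
            triples.add(m + ("hasSampleName", rec.sample_id))
        for ref in rec.references:
            db, _, acc = ref.partition(":")
            if not acc:
                db, acc = "PubMed", ref
            triples.add(m + ("hasDbXref", ("xref", db, acc)))
            triples.update(_xref(db, acc))
    for cx in bundle.complexes:
        c = ("cx", cx.complex_id)
        triples.add(c + ("type", "Complex"))
        triples.add(c + ("hasName", cx.name))
    for pw in bundle.pathways:
        p = ("pw", pw.pathway_id)
        triples.add(p + ("type", "Pathway"))
        triples.add(p + ("hasName", pw.name))
        for member in pw.members:
            sym = gene_key(member)
            if sym is not None:
                triples.add(("gene", sym, "participatesIn", p))
    for rx in bundle.reactions:
        r = ("rx", rx.reaction_id)
        triples.add(r + ("type", "Reaction"))
        triples.add(r + ("hasName", rx.name))
        triples.add(("pw", rx.pathway_id, "hasReaction", r))
        for cid in rx.consumes:
            triples.add(r + ("consumes", ("cx", cid)))
        for cid in rx.produces:
            triples.add(r + ("produces", ("cx", cid)))
    return Counter(t[-2] for t in triples)


def _xref(db, acc):
    x = ("xref", db, acc)
    return {x + ("type", "DbXref"), x + ("hasSourceDatabase", db),
            x + ("hasAccession", acc)}


def test_triple_counts_match_per_record_oracle(schema):
    docs, _ = generate_bundle(FixtureConfig(n_genes=12, seed=11))
    pipe = run_pipeline(docs, schema)
    expected = expected_predicate_counts(pipe.bundle, pipe.subdomains)
    tbox = set(schema_to_rdf(schema))
    abox = pipe.kg.triples - tbox
    got = Counter()
    prop_iris = {schema.property_iri(p): p for p in schema.properties}
    for s, p, o in abox:
        got[prop_iris.get(p, "type" if p == RDF.type else str(p))] += 1
    assert got == expected


def test_graph_stats_partition(seeded_pipeline):
    pipe, _ = seeded_pipeline
    stats = graph_stats(pipe.kg)
    subclasses = ["SubstitutionMutation", "DeletionMutation", "InsertionMutation",
                  "ComplexMutation", "OtherMutation"]
    assert stats["Mutation"] == sum(stats.get(c, 0) for c in subclasses)
    feature_subs = ["ModifiedResidue", "TopologicalDomain", "SignalPeptide"]
    assert stats["FunctionalFeature"] == sum(stats.get(c, 0) for c in feature_subs)


def test_graph_stats_worked_example(fig1):
    stats = graph_stats(fig1.kg)
    assert stats["Mutation"] == 1
    assert stats["SubstitutionMutation"] == 1
    assert stats["Pathway"] == 1
    assert stats["Reaction"] == 1
    assert stats["Complex"] == 2
    assert stats["Gene"] == 1


@pytest.mark.parametrize("dialect", ["turtle", "rdfxml"])
def test_export_reload_round_trip(fig1, schema, dialect):
    doc = export_graph(fig1.kg, dialect)
    back = load_graph(doc, schema, dialect)
    assert back.triples == fig1.kg.triples
    assert back.individuals == fig1.kg.individuals


def test_cross_dialect_equality(fig1, schema):
    ttl = load_graph(export_graph(fig1.kg, "turtle"), schema, "turtle")
    xml = load_graph(export_graph(fig1.kg, "rdfxml"), schema, "rdfxml")
    assert ttl.triples == xml.triples


def test_populate_is_idempotent(schema):
    docs, _ = generate_bundle(FixtureConfig(n_genes=8, seed=2))
    a = run_pipeline(docs, schema).kg
    b = run_pipeline(docs, schema).kg
    assert a.triples == b.triples


def test_unknown_gene_mutation_skipped_not_fatal(schema):
    bundle = read_bundle(
        "symbol\tsynonyms\tgroup\tfamily\tsubfamily\tchromosome\n"
        "EGFR\t\tTK\tEGFR\t-\t7p12\n",
        ">EGFR\nMKLT\n",
        io.StringIO(""),
        "gene\tmutation_id\taa_change\tcds_change\tdescription\t"
        "primary_site\tprimary_histology\tsample\tpubmed\n"
        "NOSUCH\tM1\tp.A1T\t\tSubstitution - Missense\tlung\tcarcinoma\tS1\t\n",
        io.StringIO(""),
    )
    kg = populate(schema, bundle)
    assert len(kg.skipped) == 1
    assert "unknown gene 'NOSUCH'" in kg.skipped[0]
    assert graph_stats(kg).get("Mutation", 0) == 0


def test_referential_closure(seeded_pipeline, schema):
    pipe, _ = seeded_pipeline
    props = {schema.property_iri(p.name) for p in schema.properties.values()
             if p.kind == "object"}
    for s, p, o in pipe.kg.triples:
        if p in props and s in pipe.kg.individuals:
            assert o in pipe.kg.individuals, f"dangling object of {p}"
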