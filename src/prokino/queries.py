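"""Named aggregate queries over the knowledge graph, with record oracles.

Fifteen named SPARQL queries (ids ``q1``–``q4``, ``q5a``, ``q5b``,
``q6``–``q14``) reproduce the integrative analyses the graph was built
for: structures/isoforms/pathways per kinase, mutation counts per cancer
type, per gene, per pathway, per primary site and per sub-domain, with the
stated minimum-count filters (>= 4 for q5a/q10/q11, >= 2 for q9).

Every named query is paired with a *brute-force oracle*: a record-level
counting procedure over the parsed source bundle that never touches RDF or
SPARQL.  Tests require the two routes to agree exactly.

Counting rule: a "distinct mutation" is a distinct (gene, amino-acid
change) pair — recurrence of the same change in further samples does not
multiply counts.  "Cancer type" means the primary-histology field
(q4–q6, q9); q12 and q14 use the primary-site field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable

from rdflib import RDF, RDFS

from .population import KnowledgeGraph
from .sources import (
    SourceBundle,
    classify_mutation,
    parse_p_notation,
    resolve_gene,
)
from .subdomains import SubDomainInterval, map_position

__all__ = [
    "QUERY_IDS",
    "NamedQuery",
    "QueryResultTable",
    "run_named_query",
    "run_oracle_query",
    "feature_context_query",
    "render_table",
    "get_query",
]

QUERY_IDS = (
    "q1", "q2", "q3", "q4", "q5a", "q5b", "q6", "q7",
    "q8", "q9", "q10", "q11", "q12", "q13", "q14",
)

#: Fixed literals baked into q6 and q14, mirroring the analyses they encode.
Q6_HISTOLOGY = "haematopoietic_neoplasm"
Q14_GENE = "FLT3"
Q14_SITE = "haematopoietic_and_lymphoid_tissue"


@dataclass(frozen=True)
class QueryResultTable:
    """Ordered (entity, count) table: descending count, ties lexicographic."""

    columns: tuple[str, str]
    rows: tuple[tuple[str, int], ...]

    @classmethod
    def from_counts(cls, columns: tuple[str, str], counts: dict[str, int]) -> "QueryResultTable":
        rows = tuple(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
        return cls(columns=columns, rows=rows)


@dataclass(frozen=True)
class NamedQuery:
    id: str
    title: str
    sparql: str
    oracle: Callable[[SourceBundle, dict[str, list[SubDomainInterval]]], QueryResultTable]


def _load_sparql(qid: str) -> tuple[str, str]:
    text = resources.files("prokino.data").joinpath("queries").joinpath(f"{qid}.rq").read_text()
    title = text.splitlines()[0].lstrip("# ").strip()
    return title, text


# ---------------------------------------------------------------------------
# record-level oracles
# ---------------------------------------------------------------------------

@dataclass
class _MutationView:
    """Deduplicated (gene, aa_change) mutation with merged sample fields."""

    gene: str
    aa_change: str
    mclass: str
    sub_kind: str
    position: int | None
    label: str | None
    sites: set[str] = field(default_factory=set)
    histologies: set[str] = field(default_factory=set)

    @property
    def is_missense(self) -> bool:
        return self.mclass == "SubstitutionMutation" and self.sub_kind == "missense"


def mutation_views(
    bundle: SourceBundle,
    subdomains: dict[str, list[SubDomainInterval]],
) -> list[_MutationView]:
    views: dict[tuple[str, str], _MutationView] = {}
    for rec in bundle.mutations:
        sym = resolve_gene(rec.symbol, bundle.genes)
        if sym is None:
            continue
        key = (sym, rec.aa_change)
        v = views.get(key)
        if v is None:
            mclass, sub_kind = classify_mutation(rec)
            pos = parse_p_notation(rec.aa_change).position
            intervals = subdomains.get(sym, [])
            label = map_position(pos, intervals) if (pos and intervals) else None
            v = views[key] = _MutationView(
                gene=sym, aa_change=rec.aa_change, mclass=mclass,
                sub_kind=sub_kind, position=pos, label=label,
            )
        if rec.primary_site:
            v.sites.add(rec.primary_site)
        if rec.primary_histology:
            v.histologies.add(rec.primary_histology)
    return list(views.values())


def _count(columns: tuple[str, str], counts: dict[str, int],
           minimum: int = 1) -> QueryResultTable:
    kept = {k: n for k, n in counts.items() if n >= minimum}
    return QueryResultTable.from_counts(columns, kept)


def _pathway_membership(bundle: SourceBundle) -> dict[str, set[str]]:
    """pathway_id -> set of resolved member gene symbols."""
    out: dict[str, set[str]] = {}
    for pw in bundle.pathways:
        members = {s for s in (resolve_gene(m, bundle.genes) for m in pw.members) if s}
        out[pw.pathway_id] = members
    return out


def _oracle_per_gene_entity_count(attr: str):
    def oracle(bundle: SourceBundle, subdomains) -> QueryResultTable:
        per_gene: dict[str, set] = {}
        for ann in bundle.annotations:
            sym = resolve_gene(ann.symbol, bundle.genes)
            if sym is None:
                continue
            items = getattr(ann, attr)
            # mirror the graph's natural keys: PDB id / isoform accession
            keys = {getattr(it, "isoform_id", it) for it in items}
            if keys:
                per_gene.setdefault(sym, set()).update(keys)
        return _count(("kinase", "count"), {g: len(s) for g, s in per_gene.items()})
    return oracle


def _oracle_q3(bundle: SourceBundle, subdomains) -> QueryResultTable:
    counts: dict[str, int] = {}
    for members in _pathway_membership(bundle).values():
        for sym in members:
            counts[sym] = counts.get(sym, 0) + 1
    return _count(("kinase", "count"), counts)


def _oracle_q4(bundle, subdomains) -> QueryResultTable:
    per_gene: dict[str, set[str]] = {}
    for v in mutation_views(bundle, subdomains):
        per_gene.setdefault(v.gene, set()).update(v.histologies)
    return _count(("kinase", "count"), {g: len(h) for g, h in per_gene.items() if h})


def _oracle_q5a(bundle, subdomains) -> QueryResultTable:
    counts: dict[str, int] = {}
    for v in mutation_views(bundle, subdomains):
        if v.is_missense:
            for h in v.histologies:
                counts[h] = counts.get(h, 0) + 1
    return _count(("cancer_type", "count"), counts, minimum=4)


def _oracle_q5b(bundle, subdomains) -> QueryResultTable:
    per_h: dict[str, set[str]] = {}
    for v in mutation_views(bundle, subdomains):
        if v.is_missense:
            for h in v.histologies:
                per_h.setdefault(h, set()).add(v.gene)
    return _count(("cancer_type", "count"), {h: len(g) for h, g in per_h.items()})


def _oracle_q6(bundle, subdomains) -> QueryResultTable:
    counts: dict[str, int] = {}
    for v in mutation_views(bundle, subdomains):
        if v.is_missense and Q6_HISTOLOGY in v.histologies:
            counts[v.gene] = counts.get(v.gene, 0) + 1
    return _count(("kinase", "count"), counts)


def _oracle_q7(bundle, subdomains) -> QueryResultTable:
    counts: dict[str, int] = {}
    for v in mutation_views(bundle, subdomains):
        counts[v.gene] = counts.get(v.gene, 0) + 1
    return _count(("kinase", "count"), counts)


def _oracle_q8(bundle, subdomains) -> QueryResultTable:
    counts: dict[str, int] = {}
    for v in mutation_views(bundle, subdomains):
        if v.is_missense:
            counts[v.gene] = counts.get(v.gene, 0) + 1
    return _count(("kinase", "count"), counts)


def _oracle_q9(bundle, subdomains) -> QueryResultTable:
    per_h: dict[str, set[str]] = {}
    for v in mutation_views(bundle, subdomains):
        for h in v.histologies:
            per_h.setdefault(h, set()).add(v.gene)
    return _count(("cancer_type", "count"), {h: len(g) for h, g in per_h.items()}, minimum=2)


def _oracle_q10(bundle, subdomains) -> QueryResultTable:
    names = {pw.pathway_id: pw.name for pw in bundle.pathways}
    by_name: dict[str, set[str]] = {}
    for pid, members in _pathway_membership(bundle).items():
        if members:
            by_name.setdefault(names[pid], set()).update(members)
    return _count(("pathway", "count"), {n: len(g) for n, g in by_name.items()}, minimum=4)


def _oracle_q11(bundle, subdomains) -> QueryResultTable:
    mutated = {v.gene for v in mutation_views(bundle, subdomains)}
    counts: dict[str, int] = {}
    for members in _pathway_membership(bundle).values():
        for sym in members:
            if sym in mutated:
                counts[sym] = counts.get(sym, 0) + 1
    return _count(("kinase", "count"), counts, minimum=4)


def _oracle_q12(bundle, subdomains) -> QueryResultTable:
    per_site: dict[str, set[str]] = {}
    for v in mutation_views(bundle, subdomains):
        for s in v.sites:
            per_site.setdefault(s, set()).add(v.gene)
    return _count(("primary_site", "count"), {s: len(g) for s, g in per_site.items()})


def _oracle_q13(bundle, subdomains) -> QueryResultTable:
    counts: dict[str, int] = {}
    for v in mutation_views(bundle, subdomains):
        if v.label is not None:
            counts[v.label] = counts.get(v.label, 0) + 1
    return _count(("subdomain", "count"), counts)


def _oracle_q14(bundle, subdomains) -> QueryResultTable:
    counts: dict[str, int] = {}
    for v in mutation_views(bundle, subdomains):
        if (v.gene == Q14_GENE and v.is_missense and Q14_SITE in v.sites
                and v.label is not None):
            counts[v.label] = counts.get(v.label, 0) + 1
    return _count(("subdomain", "count"), counts)


_ORACLES: dict[str, Callable] = {
    "q1": _oracle_per_gene_entity_count("structures"),
    "q2": _oracle_per_gene_entity_count("isoforms"),
    "q3": _oracle_q3,
    "q4": _oracle_q4,
    "q5a": _oracle_q5a,
    "q5b": _oracle_q5b,
    "q6": _oracle_q6,
    "q7": _oracle_q7,
    "q8": _oracle_q8,
    "q9": _oracle_q9,
    "q10": _oracle_q10,
    "q11": _oracle_q11,
    "q12": _oracle_q12,
    "q13": _oracle_q13,
    "q14": _oracle_q14,
}


def get_query(qid: str) -> NamedQuery:
    if qid not in QUERY_IDS:
        raise KeyError(f"unknown query id {qid!r}; valid ids: {', '.join(QUERY_IDS)}")
    title, sparql = _load_sparql(qid)
    return NamedQuery(id=qid, title=title, sparql=sparql, oracle=_ORACLES[qid])


_COLUMNS = {
    "q1": ("kinase", "count"), "q2": ("kinase", "count"), "q3": ("kinase", "count"),
    "q4": ("kinase", "count"), "q5a": ("cancer_type", "count"),
    "q5b": ("cancer_type", "count"), "q6": ("kinase", "count"),
    "q7": ("kinase", "count"), "q8": ("kinase", "count"),
    "q9": ("cancer_type", "count"), "q10": ("pathway", "count"),
    "q11": ("kinase", "count"), "q12": ("primary_site", "count"),
    "q13": ("subdomain", "count"), "q14": ("subdomain", "count"),
}


def run_named_query(kg: KnowledgeGraph, qid: str) -> QueryResultTable:
    """Execute a named SPARQL query on the graph; deterministic ordering."""
    nq = get_query(qid)
    res = kg.graph.query(
        nq.sparql,
        initNs={"pk": kg.schema.ns, "rdf": RDF, "rdfs": RDFS},
    )
    rows = tuple(sorted(
        ((str(r[0]), int(r[1])) for r in res),
        key=lambda kv: (-kv[1], kv[0]),
    ))
    return QueryResultTable(columns=_COLUMNS[qid], rows=rows)


def run_oracle_query(
    bundle: SourceBundle,
    subdomains: dict[str, list[SubDomainInterval]],
    qid: str,
) -> QueryResultTable:
    """Record-level brute-force twin of :func:`run_named_query`."""
    return get_query(qid).oracle(bundle, subdomains)


# ---------------------------------------------------------------------------
# feature context
# ---------------------------------------------------------------------------

def feature_context_query(
    kg: KnowledgeGraph,
    gene: str,
    cancer_type: str,
) -> list[tuple[str, str | None, tuple[str, ...]]]:
    """Structural/functional context of a gene's mutations in one cancer type.

    Returns one row per distinct mutation of ``gene`` annotated with the
    primary histology ``cancer_type``: ``(aa_change, sub-domain label or
    None, descriptions of positional features whose span contains the
    mutated residue)``.  Raises ``KeyError`` for a gene absent from the
    graph.
    """
    def lit(s: str) -> str:
        return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'

    known = kg.graph.query(
        f"ASK {{ ?g pk:hasPrimaryName {lit(gene)} }}", initNs={"pk": kg.schema.ns},
    )
    if not bool(known):
        raise KeyError(f"unknown gene {gene!r}")
    sparql = f"""
    SELECT ?aa ?pos ?label ?fdesc
    WHERE {{
      ?g pk:hasPrimaryName {lit(gene)} ; pk:hasMutation ?m .
      ?m pk:hasPrimaryHistology {lit(cancer_type)} ; pk:hasAAChange ?aa .
      OPTIONAL {{ ?m pk:hasStartPosition ?pos }}
      OPTIONAL {{ ?m pk:locatedIn ?sd . ?sd pk:hasSubDomainLabel ?label }}
      OPTIONAL {{
        ?g pk:hasFunctionalFeature ?f .
        ?f pk:hasStartPosition ?fs ; pk:hasEndPosition ?fe ; pk:hasDescription ?fdesc .
        FILTER (?fs <= ?pos && ?pos <= ?fe)
      }}
    }}
    """
    res = kg.graph.query(sparql, initNs={"pk": kg.schema.ns})
    acc: dict[str, tuple[str | None, set[str]]] = {}
    for row in res:
        aa = str(row.aa)
        label = str(row.label) if row.label is not None else None
        prev = acc.setdefault(aa, (label, set()))
        if row.fdesc is not None:
            prev[1].add(str(row.fdesc))
    return [
        (aa, label, tuple(sorted(feats)))
        for aa, (label, feats) in sorted(acc.items())
    ]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_table(table: QueryResultTable, top_n: int = 10, plot_path: str | None = None) -> str:
    """Render the top ``top_n`` rows as TSV text (deterministic bytes).

    When ``plot_path`` is given, additionally write a bar chart there
    (requires matplotlib).
    """
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    rows = table.rows[:top_n]
    lines = ["\t".join(table.columns)] + [f"{name}\t{n}" for name, n in rows]
    text = "\n".join(lines) + "\n"
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(8, 4))
        names = [r[0] for r in rows]
        values = [r[1] for r in rows]
        ax.bar(range(len(rows)), values, color="#4878d0")
        ax.set_xticks(range(len(rows)))
        ax.set_xticklabels(names, rotation=45, ha="right")
        ax.set_ylabel(table.columns[1])
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return text
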