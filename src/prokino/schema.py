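"""Terminology layer of the protein-kinase knowledge graph.

The schema (TBox) is defined declaratively in a tab-separated *manifest*:
one row per class, object property or data property.  The bundled manifest
(``data/schema_manifest.tsv``) carries the core concepts of the kinase
knowledge model — genes, sequences, sub-domains, mutations and their
structural kinds, functional features, pathways/reactions/complexes,
cross-references — together with the kinome classification subtree
(group → family → subfamily) rooted at ``ProteinKinaseDomain``.

Manifest format (tab-separated, ``#`` comments allowed)::

    class   <Name>    <Parent or ->   -              <description>
    object  <name>    <Domain[|Domain...]>  <RangeClass>   <description>
    data    <name>    <Domain[|Domain...]>  <xsd type>     <description>

A property domain may be a ``|``-separated union of classes.  Data-property
ranges are XSD literal type names (``string``, ``integer``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Iterable, Iterator

import rdflib
from rdflib import OWL, RDF, RDFS, XSD, Literal, Namespace, URIRef

__all__ = [
    "ClassDef",
    "PropertyDef",
    "SchemaGraph",
    "SchemaError",
    "DuplicateNameError",
    "DanglingParentError",
    "DanglingDomainError",
    "DanglingRangeError",
    "CyclicHierarchyError",
    "build_schema",
    "load_default_schema",
    "export_schema",
    "parse_schema",
    "schema_stats",
    "DEFAULT_NAMESPACE",
]

DEFAULT_NAMESPACE = "http://prokino.example.org/prokino#"

#: XSD literal types accepted as data-property ranges.
LITERAL_TYPES = {"string": XSD.string, "integer": XSD.integer}


class SchemaError(ValueError):
    """Base class for schema validation failures."""


class DuplicateNameError(SchemaError):
    pass


class DanglingParentError(SchemaError):
    pass


class DanglingDomainError(SchemaError):
    pass


class DanglingRangeError(SchemaError):
    pass


class CyclicHierarchyError(SchemaError):
    pass


@dataclass(frozen=True)
class ClassDef:
    """An OWL class: a named concept, optionally a subclass of ``parent``."""

    name: str
    parent: str | None = None
    description: str = ""


@dataclass(frozen=True)
class PropertyDef:
    """An object or data property with union domain and single range.

    ``kind`` is ``"object"`` or ``"data"``.  For data properties ``range``
    is an XSD literal type name (key of :data:`LITERAL_TYPES`).
    """

    name: str
    kind: str
    domain: tuple[str, ...]
    range: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("object", "data"):
            raise SchemaError(f"property {self.name!r}: unknown kind {self.kind!r}")


@dataclass
class SchemaGraph:
    """A validated terminology: classes (a subclass forest) plus properties."""

    namespace: str = DEFAULT_NAMESPACE
    classes: dict[str, ClassDef] = field(default_factory=dict)
    properties: dict[str, PropertyDef] = field(default_factory=dict)

    # -- construction -----------------------------------------------------

    def add_class(self, cdef: ClassDef) -> None:
        if cdef.name in self.classes:
            raise DuplicateNameError(f"duplicate class name: {cdef.name!r}")
        self.classes[cdef.name] = cdef

    def add_property(self, pdef: PropertyDef) -> None:
        if pdef.name in self.properties:
            raise DuplicateNameError(f"duplicate property name: {pdef.name!r}")
        self.properties[pdef.name] = pdef

    def validate(self) -> "SchemaGraph":
        """Check referential integrity and acyclicity; return self."""
        for cdef in self.classes.values():
            if cdef.parent is not None and cdef.parent not in self.classes:
                raise DanglingParentError(
                    f"class {cdef.name!r}: undeclared parent {cdef.parent!r}"
                )
        # acyclicity of the subclass relation
        for name in self.classes:
            seen = {name}
            cur = self.classes[name].parent
            while cur is not None:
                if cur in seen:
                    raise CyclicHierarchyError(
                        f"subclass cycle through {name!r}"
                    )
                seen.add(cur)
                cur = self.classes[cur].parent
        for pdef in self.properties.values():
            for dom in pdef.domain:
                if dom not in self.classes:
                    raise DanglingDomainError(
                        f"property {pdef.name!r}: undeclared domain {dom!r}"
                    )
            if pdef.kind == "object":
                if pdef.range not in self.classes:
                    raise DanglingRangeError(
                        f"property {pdef.name!r}: undeclared range {pdef.range!r}"
                    )
            elif pdef.range not in LITERAL_TYPES:
                raise DanglingRangeError(
                    f"property {pdef.name!r}: unknown literal type {pdef.range!r}"
                )
        return self

    # -- hierarchy queries ------------------------------------------------

    def ancestors(self, name: str) -> list[str]:
        """Proper ancestors of ``name``, nearest first."""
        out: list[str] = []
        cur = self.classes[name].parent
        while cur is not None:
            out.append(cur)
            cur = self.classes[cur].parent
        return out

    def is_subclass_of(self, name: str, ancestor: str) -> bool:
        """Reflexive-transitive subclass test."""
        return name == ancestor or ancestor in self.ancestors(name)

    def children(self, name: str | None) -> list[str]:
        return [c.name for c in self.classes.values() if c.parent == name]

    def descendants(self, name: str) -> list[str]:
        out: list[str] = []
        stack = self.children(name)
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self.children(n))
        return out

    def depth(self, name: str) -> int:
        return len(self.ancestors(name))

    # -- IRIs -------------------------------------------------------------

    @property
    def ns(self) -> Namespace:
        return Namespace(self.namespace)

    def class_iri(self, name: str) -> URIRef:
        return self.ns[name]

    def property_iri(self, name: str) -> URIRef:
        return self.ns[name]

    # -- classification lookup -------------------------------------------

    def classification_class(
        self,
        group: str,
        family: str | None = None,
        subfamily: str | None = None,
    ) -> str | None:
        """Most specific kinome-classification class for a gene.

        Matches by plain name, falling back to the ``<Name>Family`` /
        ``<Name>Subfamily`` aliases used in the manifest when a family or
        subfamily shares its parent's name.  Returns ``None`` when even the
        group is not part of the schema.
        """

        def resolve(name: str | None, suffix: str, parent: str | None) -> str | None:
            if not name:
                return None
            for cand in (name, name + suffix):
                cdef = self.classes.get(cand)
                if cdef is not None and (parent is None or cdef.parent == parent):
                    return cand
            return None

        g = resolve(group, "Group", "ProteinKinaseDomain")
        if g is None:
            return None
        f = resolve(family, "Family", g)
        if f is None:
            return g
        s = resolve(subfamily, "Subfamily", f)
        return s or f


def _rows(document: str | IO[str]) -> Iterator[tuple[int, list[str]]]:
    if isinstance(document, str):
        handle: IO[str] = io.StringIO(document) if "\t" in document or "\n" in document else open(document)
    else:
        handle = document
    with handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def build_schema(manifest: str | IO[str], namespace: str = DEFAULT_NAMESPACE) -> SchemaGraph:
    """Build and validate a :class:`SchemaGraph` from a manifest.

    ``manifest`` may be a path, a manifest document string, or a text stream.
    Raises a :class:`SchemaError` subclass naming the offending entry on
    duplicate names, dangling parents, or unresolved property domains/ranges.
    """
    schema = SchemaGraph(namespace=namespace)
    for lineno, fields_ in _rows(manifest):
        if len(fields_) < 4:
            raise SchemaError(f"manifest line {lineno}: expected >= 4 tab-separated fields")
        kind, name, col3, col4 = (f.strip() for f in fields_[:4])
        desc = fields_[4].strip() if len(fields_) > 4 else ""
        if kind == "class":
            parent = None if col3 in ("", "-") else col3
            schema.add_class(ClassDef(name=name, parent=parent, description=desc))
        elif kind in ("object", "data"):
            domain = tuple(sorted(d for d in (p.strip() for p in col3.split("|")) if d))
            schema.add_property(
                PropertyDef(name=name, kind=kind, domain=domain, range=col4, description=desc)
            )
        else:
            raise SchemaError(f"manifest line {lineno}: unknown record kind {kind!r}")
    return schema.validate()


def load_default_schema(namespace: str = DEFAULT_NAMESPACE) -> SchemaGraph:
    """Load the manifest bundled with the package."""
    text = resources.files("prokino.data").joinpath("schema_manifest.tsv").read_text()
    return build_schema(text, namespace=namespace)


_DIALECT_FORMATS = {"turtle": "turtle", "rdfxml": "xml"}


def schema_to_rdf(schema: SchemaGraph) -> rdflib.Graph:
    """Emit the TBox as an rdflib graph (no individuals)."""
    g = rdflib.Graph()
    ns = schema.ns
    g.bind("pk", ns)
    g.bind("owl", OWL)
    for cdef in schema.classes.values():
        iri = schema.class_iri(cdef.name)
        g.add((iri, RDF.type, OWL.Class))
        if cdef.parent is not None:
            g.add((iri, RDFS.subClassOf, schema.class_iri(cdef.parent)))
        if cdef.description:
            g.add((iri, RDFS.comment, Literal(cdef.description)))
    for pdef in schema.properties.values():
        iri = schema.property_iri(pdef.name)
        ptype = OWL.ObjectProperty if pdef.kind == "object" else OWL.DatatypeProperty
        g.add((iri, RDF.type, ptype))
        for dom in pdef.domain:
            g.add((iri, RDFS.domain, schema.class_iri(dom)))
        if pdef.kind == "object":
            g.add((iri, RDFS.range, schema.class_iri(pdef.range)))
        else:
            g.add((iri, RDFS.range, LITERAL_TYPES[pdef.range]))
        if pdef.description:
            g.add((iri, RDFS.comment, Literal(pdef.description)))
    return g


def export_schema(schema: SchemaGraph, dialect: str = "turtle", destination: str | None = None) -> str:
    """Serialize the schema as OWL; return the document text.

    ``dialect`` is ``"turtle"`` or ``"rdfxml"``.  When ``destination`` is
    given the document is also written there.
    """
    if dialect not in _DIALECT_FORMATS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECT_FORMATS)}")
    doc = schema_to_rdf(schema).serialize(format=_DIALECT_FORMATS[dialect])
    if destination is not None:
        with open(destination, "w") as fh:
            fh.write(doc)
    return doc


def _local(iri: URIRef, namespace: str) -> str | None:
    s = str(iri)
    return s[len(namespace):] if s.startswith(namespace) else None


def schema_from_rdf(g: rdflib.Graph, namespace: str = DEFAULT_NAMESPACE) -> SchemaGraph:
    """Rebuild a :class:`SchemaGraph` from a TBox-bearing RDF graph."""
    schema = SchemaGraph(namespace=namespace)
    for iri in sorted(set(g.subjects(RDF.type, OWL.Class))):
        name = _local(iri, namespace)
        if name is None:
            continue
        parent_iri = g.value(iri, RDFS.subClassOf)
        parent = _local(parent_iri, namespace) if parent_iri is not None else None
        desc = g.value(iri, RDFS.comment)
        schema.add_class(ClassDef(name=name, parent=parent, description=str(desc or "")))
    for ptype, kind in ((OWL.ObjectProperty, "object"), (OWL.DatatypeProperty, "data")):
        for iri in sorted(set(g.subjects(RDF.type, ptype))):
            name = _local(iri, namespace)
            if name is None:
                continue
            domain = tuple(sorted(
                d for d in (_local(x, namespace) for x in g.objects(iri, RDFS.domain)) if d
            ))
            rng_iri = g.value(iri, RDFS.range)
            if kind == "object":
                rng = _local(rng_iri, namespace) or ""
            else:
                rng = next((k for k, v in LITERAL_TYPES.items() if v == rng_iri), "string")
            desc = g.value(iri, RDFS.comment)
            schema.add_property(
                PropertyDef(name=name, kind=kind, domain=domain, range=rng, description=str(desc or ""))
            )
    return schema.validate()


def parse_schema(document: str, dialect: str = "turtle", namespace: str = DEFAULT_NAMESPACE) -> SchemaGraph:
    """Parse an OWL document (text or path) back into a :class:`SchemaGraph`."""
    g = rdflib.Graph()
    fmt = _DIALECT_FORMATS.get(dialect, dialect)
    if "\n" in document or document.lstrip().startswith(("<", "@", "PREFIX", "prefix")):
        g.parse(data=document, format=fmt)
    else:
        g.parse(document, format=fmt)
    return schema_from_rdf(g, namespace=namespace)


def schema_stats(schema: SchemaGraph) -> dict[str, int]:
    """Counts of classes, object properties and data properties."""
    return {
        "n_classes": len(schema.classes),
        "n_object_properties": sum(1 for p in schema.properties.values() if p.kind == "object"),
        "n_data_properties": sum(1 for p in schema.properties.values() if p.kind == "data"),
    }
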