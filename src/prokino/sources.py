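"""Parsers for the four flat-file source dialects feeding the knowledge graph.

The pipeline ingests four kinds of documents, mirroring the classes of
upstream resource it integrates:

* a kinome classification table plus protein FASTA (KinBase-style),
* record-oriented protein annotation blocks (UniProt-style),
* a somatic mutation catalogue TSV (COSMIC-style),
* a pathway/reaction/complex export (Reactome-style).

All residue coordinates are 1-based with inclusive spans (L858 is residue
858).  Parsers are *total* over their dialects: every input row is either
emitted as a typed record or rejected with a logged reason — never silently
dropped.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Iterable

import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
SYNONYM_DELIMITER = ";"


class SourceParseError(ValueError):
    """Raised on a hard violation of a source dialect."""


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KinaseGeneRecord:
    symbol: str
    synonyms: tuple[str, ...]
    group: str
    family: str
    subfamily: str | None
    chromosomal_position: str


@dataclass(frozen=True)
class SequenceRecord:
    symbol: str
    residues: str
    source_header: str = ""

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DomainAnnotation:
    name: str
    start: int
    end: int
    pfam_xref: str | None = None


@dataclass(frozen=True)
class FeatureAnnotation:
    kind: str  # ModifiedResidue | TopologicalDomain | SignalPeptide
    start: int
    end: int
    description: str


@dataclass(frozen=True)
class IsoformAnnotation:
    isoform_id: str
    name: str


@dataclass(frozen=True)
class ProteinAnnotationRecord:
    symbol: str
    functional_domains: tuple[DomainAnnotation, ...] = ()
    features: tuple[FeatureAnnotation, ...] = ()
    structures: tuple[str, ...] = ()
    isoforms: tuple[IsoformAnnotation, ...] = ()
    cellular_location: str | None = None
    tissue_specificity: str | None = None


@dataclass(frozen=True)
class MutationRecord:
    symbol: str
    mutation_id: str
    aa_change: str
    nt_change: str | None
    description: str
    primary_site: str
    primary_histology: str
    sample_id: str
    references: tuple[str, ...] = ()


@dataclass(frozen=True)
class MutationChange:
    """Decoded protein-level change from p. notation."""

    kind: str  # substitution | deletion | insertion | complex | other
    sub_kind: str = "n/a"  # missense | nonsense | silent | n/a
    ref: str = ""
    position: int | None = None
    end: int | None = None
    alt: str | None = None
    raw: str = ""


@dataclass(frozen=True)
class PathwayRecord:
    pathway_id: str
    name: str
    members: tuple[str, ...]


@dataclass(frozen=True)
class ReactionRecord:
    reaction_id: str
    name: str
    pathway_id: str
    consumes: tuple[str, ...]
    produces: tuple[str, ...]


@dataclass(frozen=True)
class ComplexRecord:
    complex_id: str
    name: str


@dataclass
class SourceBundle:
    """All parsed records of one input bundle."""

    genes: list[KinaseGeneRecord] = field(default_factory=list)
    sequences: list[SequenceRecord] = field(default_factory=list)
    annotations: list[ProteinAnnotationRecord] = field(default_factory=list)
    mutations: list[MutationRecord] = field(default_factory=list)
    pathways: list[PathwayRecord] = field(default_factory=list)
    reactions: list[ReactionRecord] = field(default_factory=list)
    complexes: list[ComplexRecord] = field(default_factory=list)
    rejected_mutations: list[tuple[int, str]] = field(default_factory=list)


def _as_handle(document: str | IO[str]) -> IO[str]:
    if not isinstance(document, str):
        return document
    if "\n" in document or "\t" in document or document.startswith(">"):
        return io.StringIO(document)
    return open(document)


# ---------------------------------------------------------------------------
# kinome table
# ---------------------------------------------------------------------------

KINOME_COLUMNS = ["symbol", "synonyms", "group", "family", "subfamily", "chromosome"]


def parse_kinome_table(document: str | IO[str]) -> list[KinaseGeneRecord]:
    """Parse the tab-separated kinome classification table.

    Header must carry the columns ``symbol, synonyms, group, family,
    subfamily, chromosome``.  Synonyms are ``;``-separated; subfamily may be
    empty or ``-``.
    """
    records: list[KinaseGeneRecord] = []
    seen: set[str] = set()
    with _as_handle(document) as fh:
        header_line = fh.readline()
        if not header_line:
            raise SourceParseError("kinome table: empty document (missing header)")
        header = [h.strip() for h in header_line.rstrip("\n").split("\t")]
        missing = [c for c in KINOME_COLUMNS if c not in header]
        if missing:
            raise SourceParseError(f"kinome table: missing required column(s) {missing}")
        idx = {c: header.index(c) for c in KINOME_COLUMNS}
        for rowno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            get = lambda c: cells[idx[c]].strip() if idx[c] < len(cells) else ""
            symbol = get("symbol")
            if not symbol:
                raise SourceParseError(f"kinome table row {rowno}: empty symbol")
            if symbol in seen:
                raise SourceParseError(f"kinome table row {rowno}: duplicate symbol {symbol!r}")
            seen.add(symbol)
            group, family = get("group"), get("family")
            if not group or not family:
                raise SourceParseError(f"kinome table row {rowno}: empty group/family for {symbol!r}")
            synonyms = tuple(s.strip() for s in get("synonyms").split(SYNONYM_DELIMITER) if s.strip())
            subfamily = get("subfamily")
            records.append(KinaseGeneRecord(
                symbol=symbol,
                synonyms=synonyms,
                group=group,
                family=family,
                subfamily=None if subfamily in ("", "-", "–") else subfamily,
                chromosomal_position=get("chromosome"),
            ))
    return records


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_fasta(document: str | IO[str]) -> list[SequenceRecord]:
    """Parse a multi-FASTA of protein sequences.

    The first whitespace-separated token of each header is the gene symbol.
    Residues are uppercased; empty sequences and letters outside the
    20-letter alphabet (plus X) are errors.
    """
    records: list[SequenceRecord] = []
    with _as_handle(document) as fh:
        for entry in SeqIO.parse(fh, "fasta"):
            residues = str(entry.seq).upper().replace(" ", "")
            if not residues:
                raise SourceParseError(f"FASTA entry {entry.id!r}: empty sequence")
            bad = set(residues) - AA_ALPHABET
            if bad:
                raise SourceParseError(
                    f"FASTA entry {entry.id!r}: illegal residue character(s) {sorted(bad)}"
                )
            records.append(SequenceRecord(
                symbol=entry.id, residues=residues, source_header=entry.description,
            ))
    return records


# ---------------------------------------------------------------------------
# protein annotation blocks
# ---------------------------------------------------------------------------

FEATURE_KINDS = {"ModifiedResidue", "TopologicalDomain", "SignalPeptide"}


def _span(start: str, end: str, where: str) -> tuple[int, int]:
    try:
        s, e = int(start), int(end)
    except ValueError as exc:
        raise SourceParseError(f"{where}: non-integer span ({start!r}, {end!r})") from exc
    if not (1 <= s <= e):
        raise SourceParseError(f"{where}: invalid span {s}..{e} (need 1 <= start <= end)")
    return s, e


def parse_annotations(document: str | IO[str]) -> list[ProteinAnnotationRecord]:
    """Parse record-oriented protein annotation blocks.

    One block per gene, started by a ``GENE`` line, with tab-separated typed
    lines ``DOMAIN``, ``FEATURE``, ``STRUCTURE``, ``ISOFORM``, ``LOCATION``,
    ``TISSUE``.  Unknown line types and invalid spans are hard errors.
    """
    records: list[ProteinAnnotationRecord] = []
    cur: dict | None = None

    def flush() -> None:
        nonlocal cur
        if cur is not None:
            records.append(ProteinAnnotationRecord(
                symbol=cur["symbol"],
                functional_domains=tuple(cur["domains"]),
                features=tuple(cur["features"]),
                structures=tuple(cur["structures"]),
                isoforms=tuple(cur["isoforms"]),
                cellular_location=cur["location"],
                tissue_specificity=cur["tissue"],
            ))
            cur = None

    with _as_handle(document) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            tag = parts[0]
            where = f"annotations line {lineno}"
            if tag == "GENE":
                flush()
                if len(parts) < 2 or not parts[1].strip():
                    raise SourceParseError(f"{where}: GENE line without symbol")
                cur = {"symbol": parts[1].strip(), "domains": [], "features": [],
                       "structures": [], "isoforms": [], "location": None, "tissue": None}
                continue
            if cur is None:
                raise SourceParseError(f"{where}: {tag!r} line before any GENE line")
            if tag == "DOMAIN":
                name, s, e = parts[1], parts[2], parts[3]
                pfam = parts[4].strip() if len(parts) > 4 and parts[4].strip() else None
                start, end = _span(s, e, where)
                cur["domains"].append(DomainAnnotation(name=name, start=start, end=end, pfam_xref=pfam))
            elif tag == "FEATURE":
                kind, s, e = parts[1], parts[2], parts[3]
                if kind not in FEATURE_KINDS:
                    raise SourceParseError(f"{where}: unknown feature kind {kind!r}")
                start, end = _span(s, e, where)
                desc = parts[4] if len(parts) > 4 else ""
                cur["features"].append(FeatureAnnotation(kind=kind, start=start, end=end, description=desc))
            elif tag == "STRUCTURE":
                cur["structures"].append(parts[1].strip())
            elif tag == "ISOFORM":
                cur["isoforms"].append(IsoformAnnotation(isoform_id=parts[1].strip(),
                                                         name=parts[2].strip() if len(parts) > 2 else ""))
            elif tag == "LOCATION":
                cur["location"] = parts[1]
            elif tag == "TISSUE":
                cur["tissue"] = parts[1]
            else:
                raise SourceParseError(f"{where}: unknown line type {tag!r}")
    flush()
    return records


# ---------------------------------------------------------------------------
# mutation catalogue
# ---------------------------------------------------------------------------

MUTATION_COLUMNS = [
    "gene", "mutation_id", "aa_change", "cds_change", "description",
    "primary_site", "primary_histology", "sample", "pubmed",
]


def parse_mutations(
    document: str | IO[str],
    rejections: list[tuple[int, str]] | None = None,
) -> list[MutationRecord]:
    """Parse the somatic-mutation catalogue TSV.

    Rows with an empty gene symbol or empty amino-acid change are rejected,
    not silently dropped: each rejection is appended to ``rejections`` (when
    given) as ``(row number, reason)`` and logged.  A missing required
    column is a hard error.
    """
    records: list[MutationRecord] = []
    with _as_handle(document) as fh:
        header_line = fh.readline()
        if not header_line.strip():
            return records
        header = [h.strip() for h in header_line.rstrip("\n").split("\t")]
        missing = [c for c in MUTATION_COLUMNS if c not in header]
        if missing:
            raise SourceParseError(f"mutation table: missing required column(s) {missing}")
        idx = {c: header.index(c) for c in MUTATION_COLUMNS}
        for rowno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            get = lambda c: cells[idx[c]].strip() if idx[c] < len(cells) else ""
            reason = None
            if not get("gene"):
                reason = "empty gene symbol"
            elif not get("aa_change"):
                reason = "empty amino-acid change"
            if reason is not None:
                logger.warning("mutation table row %d rejected: %s", rowno, reason)
                if rejections is not None:
                    rejections.append((rowno, reason))
                continue
            refs = tuple(r.strip() for r in get("pubmed").split(";") if r.strip())
            records.append(MutationRecord(
                symbol=get("gene"),
                mutation_id=get("mutation_id"),
                aa_change=get("aa_change"),
                nt_change=get("cds_change") or None,
                description=get("description"),
                primary_site=get("primary_site"),
                primary_histology=get("primary_histology"),
                sample_id=get("sample"),
                references=refs,
            ))
    return records


# ---------------------------------------------------------------------------
# p. notation
# ---------------------------------------------------------------------------

_AA = "[ACDEFGHIKLMNPQRSTVWY]"
_RE_SUB = re.compile(rf"^p\.({_AA})(\d+)({_AA}|\*)$")
_RE_DEL = re.compile(rf"^p\.({_AA})(\d+)(?:_({_AA})(\d+))?del$")
_RE_INS = re.compile(rf"^p\.({_AA})(\d+)_({_AA})(\d+)ins({_AA}+)$")
_RE_DELINS = re.compile(rf"^p\.({_AA})(\d+)(?:_({_AA})(\d+))?delins({_AA}+)$")


def parse_p_notation(aa_change: str) -> MutationChange:
    """Decode a protein-level change written in HGVS-like p. notation.

    Total function over the supported grammar: substitutions
    ``p.<Ref><Pos><Alt>`` (``*`` = stop, giving a nonsense sub-kind),
    deletions ``p.X1[_Y2]del``, insertions ``p.X1_Y2ins<seq>`` and
    deletion-insertions ``p.X1[_Y2]delins<seq>`` (classified *complex*).
    Anything else maps to ``kind="other"`` with the raw text retained.
    """
    text = aa_change.strip()
    m = _RE_SUB.match(text)
    if m:
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if alt == "*":
            sub_kind = "nonsense"
        elif alt == ref:
            sub_kind = "silent"
        else:
            sub_kind = "missense"
        return MutationChange(kind="substitution", sub_kind=sub_kind,
                              ref=ref, position=pos, end=pos, alt=alt, raw=text)
    m = _RE_DELINS.match(text)
    if m:
        start = int(m.group(2))
        end = int(m.group(4)) if m.group(4) else start
        ref = m.group(1) + (m.group(3) or "")
        return MutationChange(kind="complex", ref=ref, position=start, end=end,
                              alt=m.group(5), raw=text)
    m = _RE_DEL.match(text)
    if m:
        start = int(m.group(2))
        end = int(m.group(4)) if m.group(4) else start
        ref = m.group(1) + (m.group(3) or "")
        return MutationChange(kind="deletion", ref=ref, position=start, end=end, raw=text)
    m = _RE_INS.match(text)
    if m:
        return MutationChange(kind="insertion", ref=m.group(1) + m.group(3),
                              position=int(m.group(2)), end=int(m.group(4)),
                              alt=m.group(5), raw=text)
    return MutationChange(kind="other", raw=text)


def format_p_notation(change: MutationChange) -> str:
    """Inverse of :func:`parse_p_notation` on the supported grammar."""
    if change.kind == "substitution":
        return f"p.{change.ref}{change.position}{change.alt}"
    if change.kind == "deletion":
        if change.end is not None and change.end != change.position:
            return f"p.{change.ref[0]}{change.position}_{change.ref[1]}{change.end}del"
        return f"p.{change.ref}{change.position}del"
    if change.kind == "insertion":
        return f"p.{change.ref[0]}{change.position}_{change.ref[1]}{change.end}ins{change.alt}"
    if change.kind == "complex":
        if change.end is not None and change.end != change.position:
            return f"p.{change.ref[0]}{change.position}_{change.ref[1]}{change.end}delins{change.alt}"
        return f"p.{change.ref}{change.position}delins{change.alt}"
    return change.raw


# ---------------------------------------------------------------------------
# mutation classification
# ---------------------------------------------------------------------------

MUTATION_CLASSES = (
    "SubstitutionMutation", "DeletionMutation", "InsertionMutation",
    "ComplexMutation", "OtherMutation",
)

_KIND_TO_CLASS = {
    "substitution": "SubstitutionMutation",
    "deletion": "DeletionMutation",
    "insertion": "InsertionMutation",
    "complex": "ComplexMutation",
    "other": "OtherMutation",
}


def load_description_map() -> list[dict]:
    """Load the source-description → mutation-class mapping table.

    Kept as bundled data (``data/mutation_descriptions.yaml``) rather than
    code, because catalogue vocabularies drift between releases.
    """
    text = resources.files("prokino.data").joinpath("mutation_descriptions.yaml").read_text()
    return yaml.safe_load(text)["mappings"]


_DESCRIPTION_MAP: list[dict] | None = None


def classify_mutation(rec: MutationRecord) -> tuple[str, str]:
    """Assign a mutation record to exactly one structural mutation class.

    Returns ``(class name, sub_kind)`` where the class is one of
    :data:`MUTATION_CLASSES`.  The source description field is consulted
    first (prefix match against the bundled mapping table, case-insensitive);
    when it does not match, the decoded p. notation decides; the final
    fallback is ``OtherMutation``.
    """
    global _DESCRIPTION_MAP
    if _DESCRIPTION_MAP is None:
        _DESCRIPTION_MAP = load_description_map()
    desc = rec.description.strip().lower()
    change = parse_p_notation(rec.aa_change)
    if desc:
        for entry in _DESCRIPTION_MAP:
            if desc.startswith(entry["match"].lower()):
                sub_kind = entry.get("sub_kind", "n/a")
                return entry["class"], sub_kind
        # unknown description text: mirror a curator's caution and fall back
        # to the decoded change only when the description gave no signal
        return ("OtherMutation", "n/a") if change.kind == "other" else (
            _KIND_TO_CLASS[change.kind],
            change.sub_kind if change.kind == "substitution" else "n/a",
        )
    return _KIND_TO_CLASS[change.kind], change.sub_kind if change.kind == "substitution" else "n/a"


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------

def parse_pathways(
    document: str | IO[str],
) -> tuple[list[PathwayRecord], list[ReactionRecord], list[ComplexRecord]]:
    """Parse the three-section pathway export.

    Tab-separated lines: ``PATHWAY id name members`` (members ``;``-separated
    gene symbols), ``COMPLEX id name``, ``REACTION id name pathway_id
    consumes=ids produces=ids``.  Referential integrity (reaction → pathway,
    reaction → complexes) is enforced after reading, so declaration order is
    free.
    """
    pathways: list[PathwayRecord] = []
    reactions: list[ReactionRecord] = []
    complexes: list[ComplexRecord] = []
    with _as_handle(document) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            tag = parts[0]
            where = f"pathway export line {lineno}"
            if tag == "PATHWAY":
                members = tuple(m.strip() for m in (parts[3] if len(parts) > 3 else "").split(";") if m.strip())
                pathways.append(PathwayRecord(pathway_id=parts[1], name=parts[2], members=members))
            elif tag == "COMPLEX":
                complexes.append(ComplexRecord(complex_id=parts[1], name=parts[2]))
            elif tag == "REACTION":
                kw = {"consumes": (), "produces": ()}
                for cell in parts[4:]:
                    key, _, val = cell.partition("=")
                    if key not in kw:
                        raise SourceParseError(f"{where}: unknown reaction field {key!r}")
                    kw[key] = tuple(v.strip() for v in val.split(";") if v.strip())
                reactions.append(ReactionRecord(
                    reaction_id=parts[1], name=parts[2], pathway_id=parts[3],
                    consumes=kw["consumes"], produces=kw["produces"],
                ))
            else:
                raise SourceParseError(f"{where}: unknown line type {tag!r}")
    pw_ids = {p.pathway_id for p in pathways}
    cx_ids = {c.complex_id for c in complexes}
    for rx in reactions:
        if rx.pathway_id not in pw_ids:
            raise SourceParseError(f"reaction {rx.reaction_id!r}: dangling pathway id {rx.pathway_id!r}")
        for cid in rx.consumes + rx.produces:
            if cid not in cx_ids:
                raise SourceParseError(f"reaction {rx.reaction_id!r}: dangling complex id {cid!r}")
    return pathways, reactions, complexes


# ---------------------------------------------------------------------------
# gene name resolution
# ---------------------------------------------------------------------------

class AmbiguousSynonymError(SourceParseError):
    """A synonym maps to more than one gene."""


def resolve_gene(name: str, genes: Iterable[KinaseGeneRecord]) -> str | None:
    """Resolve a gene name or synonym to its primary symbol.

    Case-insensitive; primary symbols take precedence over synonyms.
    Returns ``None`` when the name is unknown; raises
    :class:`AmbiguousSynonymError` when a synonym points at two genes.
    """
    query = name.strip().lower()
    if not query:
        return None
    by_symbol: dict[str, str] = {}
    by_synonym: dict[str, list[str]] = {}
    for rec in genes:
        by_symbol[rec.symbol.lower()] = rec.symbol
        for syn in rec.synonyms:
            by_synonym.setdefault(syn.lower(), []).append(rec.symbol)
    if query in by_symbol:
        return by_symbol[query]
    if query in by_synonym:
        hits = sorted(set(by_synonym[query]))
        if len(hits) > 1:
            raise AmbiguousSynonymError(
                f"synonym {name!r} is ambiguous between {hits}"
            )
        return hits[0]
    return None


def read_bundle(
    kinome: str | IO[str],
    fasta: str | IO[str],
    annotations: str | IO[str],
    mutations: str | IO[str],
    pathways: str | IO[str],
) -> SourceBundle:
    """Parse all five documents of a source bundle."""
    bundle = SourceBundle()
    bundle.genes = parse_kinome_table(kinome)
    bundle.sequences = parse_fasta(fasta)
    bundle.annotations = parse_annotations(annotations)
    bundle.mutations = parse_mutations(mutations, rejections=bundle.rejected_mutations)
    bundle.pathways, bundle.reactions, bundle.complexes = parse_pathways(pathways)
    return bundle
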