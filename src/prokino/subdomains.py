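"""Motif-anchored location of kinase sub-domains in protein sequences.

The protein kinase catalytic domain is tiled by twelve conserved
sub-domains (Hanks numbering I–XI, with VIa/VIb splitting the sixth).
Several of them carry near-invariant motifs — the glycine-rich loop
``GxGxxG`` (I), the beta-3 lysine of the VAIK motif (II), the catalytic
loop ``HRD`` (VIb), the Mg-binding ``DFG`` (VII) and the
activation-segment-terminal ``APE`` (VIII).  This module implements a
transparent *anchor model*: one regular-expression anchor per sub-domain,
searched greedily in canonical order (each anchor only strictly downstream
of the previous accepted one), from which sub-domain intervals are tiled
over the full sequence.

The model is deliberately simple and fully serializable, so it can be
replaced wholesale (e.g. by profile-derived anchors) without touching the
assignment logic.  Sequences in which fewer than ``min_anchors`` anchors
are found — divergent and atypical kinases — are withheld from assignment.

Coordinates are 1-based with inclusive ends throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import yaml

__all__ = [
    "CANONICAL_LABELS",
    "MotifModel",
    "AnchorHit",
    "SubDomainInterval",
    "default_motif_model",
    "locate_anchors",
    "assign_subdomains",
    "named_segments",
    "map_position",
    "intervals_to_tsv",
]

#: Canonical Hanks sub-domain labels, in order along the sequence.
CANONICAL_LABELS = ("I", "II", "III", "IV", "V", "VIa", "VIb", "VII", "VIII", "IX", "X", "XI")

#: Flanking segments outside the catalytic domain proper.
N_TAIL = "N-terminal-tail"
C_TAIL = "C-terminal-tail"

#: Named segments derived from anchors (not part of the disjoint tiling).
GLYCINE_RICH_LOOP = "Glycine-rich-loop"
ACTIVATION_SEGMENT_NT = "Activation-Segment-NT"  # corresponds to sub-domain VII
ACTIVATION_SEGMENT_CT = "Activation-Segment-CT"

#: Residues appended to the last anchor's match when closing the final
#: sub-domain interval (bounded by the sequence end).
DEFAULT_LAST_EXTENSION = 10

#: Fewer recovered anchors than this and sub-domain assignment is withheld.
DEFAULT_MIN_ANCHORS = 4


@dataclass(frozen=True)
class Anchor:
    label: str
    pattern: str
    anchor_offset: int = 0

    @property
    def regex(self) -> re.Pattern[str]:
        return re.compile(self.pattern)


@dataclass(frozen=True)
class AnchorHit:
    subdomain_label: str
    start: int  # 1-based
    end: int    # 1-based inclusive
    matched_text: str


@dataclass(frozen=True)
class SubDomainInterval:
    label: str
    start: int
    end: int

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class MotifModel:
    """An ordered list of sub-domain anchors."""

    anchors: list[Anchor] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [a.label for a in self.anchors]
        order = {lab: i for i, lab in enumerate(CANONICAL_LABELS)}
        if any(lab not in order for lab in labels):
            bad = [lab for lab in labels if lab not in order]
            raise ValueError(f"unknown sub-domain label(s): {bad}")
        if [order[lab] for lab in labels] != sorted(order[lab] for lab in labels) or \
                len(set(labels)) != len(labels):
            raise ValueError("anchors must be unique and in canonical sub-domain order")
        if any(not a.pattern for a in self.anchors):
            raise ValueError("empty anchor pattern")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {"anchors": [
            {"label": a.label, "pattern": a.pattern, "anchor_offset": a.anchor_offset}
            for a in self.anchors
        ]}

    @classmethod
    def from_dict(cls, d: dict) -> "MotifModel":
        return cls(anchors=[
            Anchor(label=a["label"], pattern=a["pattern"],
                   anchor_offset=int(a.get("anchor_offset", 0)))
            for a in d["anchors"]
        ])

    def save(self, destination: str | IO[str]) -> None:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if isinstance(destination, str):
            with open(destination, "w") as fh:
                fh.write(text)
        else:
            destination.write(text)

    @classmethod
    def load(cls, source: str | IO[str]) -> "MotifModel":
        if isinstance(source, str):
            with open(source) as fh:
                d = yaml.safe_load(fh)
        else:
            d = yaml.safe_load(source)
        return cls.from_dict(d)


#: The bundled anchor patterns.  The motifs for I, II, VIb, VII and VIII are
#: the canonical kinase motifs; the remaining anchors are short
#: residue-class patterns standing in for the weaker sub-domain signatures.
_DEFAULT_ANCHORS = [
    ("I", "G.G..G", 0),            # glycine-rich loop GxGxxG
    ("II", "[VAIL]A[IVML]K", 3),   # VAIK; the beta-3 lysine is the anchor residue
    ("III", "[HYF]E[LIVMFY]", 1),  # alpha-C glutamate
    ("IV", "[LIVMF][LIVMF]E[FY]", 2),
    ("V", "[EQ]Y[LIVMA][PG]", 1),
    ("VIa", "[KR][LIVM][AG]D", 0),
    ("VIb", "H[RK]D[LIVMF]", 2),   # catalytic loop; the HRD aspartate is the anchor
    ("VII", "DFG", 0),             # Mg-binding DFG
    ("VIII", "[APS]PE", 2),        # activation-segment end (APE)
    ("IX", "D[LIVMFWY][WYF][SAG]", 0),
    ("X", "P[PILVMF][KRQ][WFY]", 0),
    ("XI", "[KR][LIVMF][LIVMF][EDQ]", 0),
]


def default_motif_model() -> MotifModel:
    """The bundled 12-anchor model in canonical order."""
    return MotifModel(anchors=[Anchor(lab, pat, off) for lab, pat, off in _DEFAULT_ANCHORS])


def locate_anchors(residues: str, model: MotifModel | None = None) -> list[AnchorHit]:
    """Find at most one hit per sub-domain, in canonical order.

    Greedy order-constrained search: each anchor is sought only strictly
    downstream of the previous accepted anchor's match (leftmost such match
    wins), so hits are non-overlapping and strictly increasing.  Anchors
    without a downstream match yield no hit — never an out-of-order one.
    """
    if model is None:
        model = default_motif_model()
    hits: list[AnchorHit] = []
    floor = 0  # 0-based index from which the next anchor may start
    for anchor in model.anchors:
        m = anchor.regex.search(residues, floor)
        if m is None:
            continue
        start0, end0 = m.start(), m.end()  # [start0, end0)
        hits.append(AnchorHit(
            subdomain_label=anchor.label,
            start=start0 + 1,
            end=end0,
            matched_text=m.group(0),
        ))
        floor = end0
    return hits


def assign_subdomains(
    hits: Sequence[AnchorHit],
    seq_length: int,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    last_extension: int = DEFAULT_LAST_EXTENSION,
) -> list[SubDomainInterval]:
    """Tile the sequence into sub-domain intervals from anchor hits.

    Each found sub-domain spans from its anchor start to one residue before
    the next anchor start; the last one ends ``last_extension`` residues
    past its anchor match (bounded by the sequence end).  Residues before
    the first anchor form the N-terminal tail, residues after the last
    sub-domain the C-terminal tail, so the returned intervals tile
    ``[1, seq_length]`` exactly and disjointly.

    With fewer than ``min_anchors`` hits the assignment is withheld and the
    empty list returned (divergent/atypical kinases).
    """
    if len(hits) < min_anchors:
        return []
    intervals: list[SubDomainInterval] = []
    first_start = hits[0].start
    if first_start > 1:
        intervals.append(SubDomainInterval(N_TAIL, 1, first_start - 1))
    for i, hit in enumerate(hits):
        if i + 1 < len(hits):
            end = hits[i + 1].start - 1
        else:
            end = min(hit.end + last_extension, seq_length)
        intervals.append(SubDomainInterval(hit.subdomain_label, hit.start, end))
    last_end = intervals[-1].end
    if last_end < seq_length:
        intervals.append(SubDomainInterval(C_TAIL, last_end + 1, seq_length))
    return intervals


def named_segments(hits: Sequence[AnchorHit]) -> list[SubDomainInterval]:
    """Named segments derived from the anchors.

    The glycine-rich loop is the sub-domain I match span.  The activation
    segment runs from the DFG anchor (VII) to the end of the APE anchor
    (VIII); its N- and C-terminal halves split at the integer midpoint.
    These intervals overlap the sub-domain tiling and are reported
    separately from it.
    """
    by_label = {h.subdomain_label: h for h in hits}
    out: list[SubDomainInterval] = []
    if "I" in by_label:
        h = by_label["I"]
        out.append(SubDomainInterval(GLYCINE_RICH_LOOP, h.start, h.end))
    if "VII" in by_label and "VIII" in by_label:
        dfg, ape = by_label["VII"], by_label["VIII"]
        mid = (dfg.start + ape.end) // 2
        out.append(SubDomainInterval(ACTIVATION_SEGMENT_NT, dfg.start, mid))
        out.append(SubDomainInterval(ACTIVATION_SEGMENT_CT, mid + 1, ape.end))
    return out


def map_position(pos: int, intervals: Iterable[SubDomainInterval]) -> str | None:
    """Label of the unique interval containing ``pos`` (1-based), or None."""
    if pos < 1:
        raise ValueError(f"residue position must be >= 1, got {pos}")
    for iv in intervals:
        if pos in iv:
            return iv.label
    return None


def intervals_to_tsv(per_sequence: dict[str, list[SubDomainInterval]]) -> str:
    """BED-like TSV (sequence id, start, end, label; 1-based inclusive)."""
    lines = ["#sequence\tstart\tend\tlabel"]
    for seq_id, intervals in per_sequence.items():
        if not intervals:
            lines.append(f"{seq_id}\t.\t.\twithheld")
            continue
        for iv in intervals:
            lines.append(f"{seq_id}\t{iv.start}\t{iv.end}\t{iv.label}")
    return "\n".join(lines) + "\n"
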