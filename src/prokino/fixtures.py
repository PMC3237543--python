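"""Deterministic synthetic source bundles with generation-time ground truth.

The generator emits the four source dialects the parsers read — kinome
classification table + protein FASTA, annotation blocks, a somatic-mutation
catalogue TSV and a pathway export — for a configurable number of kinase
genes drawn from a fixed catalogue of real kinome entries.  Alongside the
documents it returns a :class:`GroundTruth` computed *during generation*
from its own bookkeeping (planted anchor positions, placed mutations,
memberships), never by running the parsing/population pipeline, so it can
serve as an independent oracle for end-to-end tests.

Sequences carry planted sub-domain anchor motifs at recorded positions;
residues outside the planted motifs are sampled uniformly and then
*scrubbed* so that no anchor pattern matches anywhere except at a planted
site, which makes planted-anchor recovery exact.  A configurable fraction
of genes are "atypical": fewer than four anchors are planted and
sub-domain assignment is expected to be withheld for them.

What the generator emulates: the field layout of the four sources, kinome
classification, recurrent mutations across samples, histology/site
pairing.  What it does not emulate: mutational hotspots, sequence homology
within families, or realistic mutation spectra.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from importlib import resources

from .queries import QueryResultTable, QUERY_IDS, Q6_HISTOLOGY, Q14_GENE, Q14_SITE
from .subdomains import (
    CANONICAL_LABELS,
    C_TAIL,
    DEFAULT_LAST_EXTENSION,
    DEFAULT_MIN_ANCHORS,
    N_TAIL,
    SubDomainInterval,
    default_motif_model,
)

__all__ = ["FixtureConfig", "BundleDocuments", "GroundTruth", "generate_bundle", "fig1_bundle"]


# (symbol, synonyms, group, family, subfamily, chromosome)
GENE_CATALOGUE = [
    ("EGFR", "EGFRvIII;ERBB1;ERBB;mENA", "TK", "EGFR", "", "7p12"),
    ("ERBB2", "HER2;NEU", "TK", "EGFR", "", "17q12"),
    ("ABL1", "ABL;JTK7", "TK", "Abl", "", "9q34.1"),
    ("KIT", "CD117;SCFR", "TK", "PDGFR", "", "4q12"),
    ("FLT3", "CD135;FLK2;STK1", "TK", "PDGFR", "", "13q12"),
    ("PDGFRA", "CD140A", "TK", "PDGFR", "", "4q12"),
    ("JAK2", "JTK10", "TK", "Jak", "", "9p24"),
    ("SRC", "c-SRC;p60-Src", "TK", "Src", "SrcA", "20q12"),
    ("FYN", "SLK;SYN", "TK", "Src", "SrcA", "6q21"),
    ("LCK", "p56lck", "TK", "Src", "SrcB", "1p34.3"),
    ("FGFR1", "CEK;FLG", "TK", "FGFR", "", "8p11"),
    ("FGFR2", "BEK;KGFR", "TK", "FGFR", "", "10q26"),
    ("MET", "HGFR", "TK", "Met", "", "7q31"),
    ("RET", "PTC;CDHF12", "TK", "Ret", "", "10q11.2"),
    ("ALK", "CD246", "TK", "ALK", "", "2p23"),
    ("EPHA2", "ECK", "TK", "Eph", "", "1p36"),
    ("BRAF", "BRAF1;RAFB1", "TKL", "RAF", "", "7q34"),
    ("RAF1", "CRAF", "TKL", "RAF", "", "3p25"),
    ("IRAK1", "IRAK", "TKL", "IRAK", "", "Xq28"),
    ("RIPK1", "RIP1", "TKL", "RIPK", "", "6p25"),
    ("TGFBR1", "ALK5", "TKL", "STKR", "", "9q22"),
    ("CDK2", "p33", "CMGC", "CDK", "CDK1", "12q13"),
    ("CDK4", "PSK-J3", "CMGC", "CDK", "CDK4", "12q14"),
    ("GSK3B", "", "CMGC", "GSK", "", "3q13.3"),
    ("MAPK1", "ERK2;p42MAPK", "CMGC", "MAPK", "ERK", "22q11.2"),
    ("MAPK14", "p38alpha;CSBP1", "CMGC", "MAPK", "p38", "6p21.3"),
    ("AKT1", "PKB;RAC-alpha", "AGC", "Akt", "", "14q32.3"),
    ("AKT2", "PKB-beta", "AGC", "Akt", "", "19q13.2"),
    ("PRKACA", "PKACA", "AGC", "PKA", "", "19p13.1"),
    ("PRKCA", "PKC-alpha", "AGC", "PKC", "PKC-Alpha", "17q24"),
    ("RPS6KA1", "RSK1;MAPKAPK1A", "AGC", "RSK", "RSKp70", "1p36"),
    ("SGK1", "SGK", "AGC", "SGK", "", "6q23"),
    ("CAMK2A", "CAMKA", "CAMK", "CAMK2", "", "5q33"),
    ("CHEK1", "CHK1", "CAMK", "CAMKL", "CHK1", "11q24"),
    ("PIM1", "", "CAMK", "PIM", "", "6p21.2"),
    ("CSNK1A1", "CK1alpha", "CK1", "CK1", "", "5q32"),
    ("VRK1", "", "CK1", "VRK", "", "14q32"),
    ("CSNK2A1", "CK2alpha", "Other", "CK2", "", "20p13"),
    ("AURKA", "AURA;STK15", "Other", "AUR", "", "20q13"),
    ("PLK1", "STPK13", "Other", "PLK", "", "16p12"),
    ("NEK2", "NLK1", "Other", "NEK", "", "1q32.3"),
    ("MAP2K1", "MEK1", "STE", "STE7", "", "15q22"),
    ("MAP3K1", "MEKK1", "STE", "STE11", "", "5q11.2"),
    ("PAK1", "PAKalpha", "STE", "STE20", "PAKA", "11q13"),
    ("STK3", "MST2", "STE", "STE20", "MST", "8q22"),
    ("ATM", "TEL1", "Atypical", "PIKK", "ATM", "11q22.3"),
    ("ATR", "FRP1", "Atypical", "PIKK", "ATR", "3q23"),
]

#: Concrete instances of each default anchor pattern used for planting.
ANCHOR_LITERALS = {
    "I": ["GEGAFG", "GSGSFG", "GQGAHG"],
    "II": ["VAIK", "AAMK", "LAVK"],
    "III": ["HEL", "YEM", "FEI"],
    "IV": ["LLEF", "IVEY", "IMEF"],
    "V": ["EYLP", "QYAG", "EYMP"],
    "VIa": ["KLAD", "RIGD", "KVAD"],
    "VIb": ["HRDL", "HKDF", "HRDI"],
    "VII": ["DFG"],
    "VIII": ["APE", "SPE", "PPE"],
    "IX": ["DLWS", "DIWG", "DVYA"],
    "X": ["PIKW", "PLQF", "PVRY"],
    "XI": ["KLLE", "RIID", "KMLQ"],
}

#: Letters that occur in no anchor residue class; used to break spurious matches.
_INERT = "TCN"

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# (histology, weight, typical primary sites)
CANCER_TYPES = [
    ("carcinoma", 0.40, ("lung", "breast", "large_intestine")),
    ("glioma", 0.13, ("central_nervous_system",)),
    ("malignant_melanoma", 0.12, ("skin",)),
    (Q6_HISTOLOGY, 0.13, (Q14_SITE,)),
    ("lymphoid_neoplasm", 0.10, (Q14_SITE,)),
    ("adenoma", 0.12, ("large_intestine", "thyroid")),
]

PATHWAY_NAMES = [
    "Signaling by EGFR", "Signaling by FGFR", "MAPK cascade",
    "Signaling in immune system", "Cell cycle checkpoints",
    "PI3K-AKT signaling", "Apoptosis", "DNA damage response",
]

MODIFICATIONS = ["Phosphotyrosine", "Phosphoserine", "Phosphothreonine"]
LOCATIONS = ["Cell membrane", "Cytoplasm", "Nucleus"]
TISSUES = ["Ubiquitous", "Brain", "Haematopoietic cells", "Epithelium"]


class FixtureError(ValueError):
    """Inconsistent fixture configuration or generation failure."""


@dataclass(frozen=True)
class FixtureConfig:
    n_genes: int = 25
    mutations_per_gene: tuple[int, int] = (0, 15)
    cancer_types: tuple = tuple(CANCER_TYPES)
    n_pathways: int = 6
    membership_density: float = 0.25
    feature_density: float = 0.6
    atypical_fraction: float = 0.12
    recurrence_rate: float = 0.2
    structures_max: int = 8
    isoforms_max: int = 4
    seed: int = 0

    def validate(self) -> "FixtureConfig":
        if not (0 < self.n_genes <= len(GENE_CATALOGUE)):
            raise FixtureError(
                f"n_genes must be in 1..{len(GENE_CATALOGUE)}, got {self.n_genes}"
            )
        lo, hi = self.mutations_per_gene
        if lo < 0 or hi < lo:
            raise FixtureError(f"bad mutations_per_gene range {self.mutations_per_gene}")
        total = sum(w for _, w, _ in self.cancer_types)
        if abs(total - 1.0) > 1e-9:
            raise FixtureError(f"cancer-type weights sum to {total}, expected 1")
        for frac in (self.membership_density, self.feature_density,
                     self.atypical_fraction, self.recurrence_rate):
            if not (0 <= frac <= 1):
                raise FixtureError(f"fraction out of [0, 1]: {frac}")
        if self.n_pathways < 0 or self.structures_max < 0 or self.isoforms_max < 0:
            raise FixtureError("counts must be >= 0")
        return self


@dataclass
class BundleDocuments:
    """The five emitted documents (four dialects; the kinome source has two files)."""

    kinome: str
    fasta: str
    annotations: str
    mutations: str
    pathways: str

    def write(self, directory: str) -> dict[str, str]:
        import os
        os.makedirs(directory, exist_ok=True)
        paths = {}
        for name, text in [("kinome.tsv", self.kinome), ("sequences.fasta", self.fasta),
                           ("annotations.txt", self.annotations),
                           ("mutations.tsv", self.mutations), ("pathways.tsv", self.pathways)]:
            path = os.path.join(directory, name)
            with open(path, "w") as fh:
                fh.write(text)
            paths[name] = path
        return paths


@dataclass
class GroundTruth:
    """Expected results, derived from generation bookkeeping only."""

    anchors: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    tilings: dict[str, list[SubDomainInterval]] = field(default_factory=dict)
    tables: dict[str, QueryResultTable] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sequence construction
# ---------------------------------------------------------------------------

def _background(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(AA20) for _ in range(n))


def _scrub(seq: str, planted: list[tuple[str, int, int]], rng: random.Random) -> str:
    """Mutate background residues until anchor patterns match only at planted sites."""
    model = default_motif_model()
    patterns = [(a.label, a.regex) for a in model.anchors]
    planted_spans = {(lab, s, e) for lab, s, e in planted}
    planted_positions = set()
    for _, s, e in planted:
        planted_positions.update(range(s - 1, e))
    chars = list(seq)
    for _ in range(200):
        dirty = False
        text = "".join(chars)
        for label, regex in patterns:
            pos = 0
            while True:
                m = regex.search(text, pos)
                if m is None:
                    break
                span = (label, m.start() + 1, m.end())
                pos = m.start() + 1
                if span in planted_spans:
                    continue
                fixable = [i for i in range(m.start(), m.end()) if i not in planted_positions]
                if not fixable:
                    raise FixtureError(
                        f"spurious {label} match inside planted spans at {span[1]}"
                    )
                # pick a replacement that actually breaks this match (inert
                # letters pass through wildcard positions unchanged)
                for i in fixable:
                    old = chars[i]
                    chars[i] = _INERT[rng.randrange(len(_INERT))]
                    if not regex.match("".join(chars[m.start():m.end()])):
                        break
                    chars[i] = old
                else:
                    raise FixtureError(
                        f"could not break spurious {label} match at {span[1]}"
                    )
                dirty = True
                text = "".join(chars)
        if not dirty:
            return text
    raise FixtureError("sequence scrub did not converge")


def _make_sequence(
    rng: random.Random, labels: list[str]
) -> tuple[str, list[tuple[str, int, int]]]:
    parts: list[str] = []
    planted: list[tuple[str, int, int]] = []
    pos = 0
    n_tail = rng.randint(15, 40)
    parts.append(_background(rng, n_tail))
    pos += n_tail
    for label in CANONICAL_LABELS:
        if label not in labels:
            continue
        lit = rng.choice(ANCHOR_LITERALS[label])
        planted.append((label, pos + 1, pos + len(lit)))
        parts.append(lit)
        pos += len(lit)
        gap = rng.randint(8, 25)
        parts.append(_background(rng, gap))
        pos += gap
    c_tail = rng.randint(5, 30)
    parts.append(_background(rng, c_tail))
    return _scrub("".join(parts), planted, rng), planted


def _tile(
    planted: list[tuple[str, int, int]],
    seq_length: int,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    last_extension: int = DEFAULT_LAST_EXTENSION,
) -> list[SubDomainInterval]:
    """Expected sub-domain tiling from planted anchors (generation-side copy
    of the documented tiling rule, kept independent of the pipeline code)."""
    if len(planted) < min_anchors:
        return []
    out: list[SubDomainInterval] = []
    if planted[0][1] > 1:
        out.append(SubDomainInterval(N_TAIL, 1, planted[0][1] - 1))
    for i, (label, start, end) in enumerate(planted):
        if i + 1 < len(planted):
            stop = planted[i + 1][1] - 1
        else:
            stop = min(end + last_extension, seq_length)
        out.append(SubDomainInterval(label, start, stop))
    if out[-1].end < seq_length:
        out.append(SubDomainInterval(C_TAIL, out[-1].end + 1, seq_length))
    return out


def _label_of(pos: int, tiling: list[SubDomainInterval]) -> str | None:
    for iv in tiling:
        if iv.start <= pos <= iv.end:
            return iv.label
    return None


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

@dataclass
class _GenMutation:
    gene: str
    aa_change: str
    description: str
    is_missense: bool
    position: int | None
    label: str | None
    pairs: list[tuple[str, str]] = field(default_factory=list)  # (site, histology)


def _wrap_fasta(residues: str, width: int = 60) -> str:
    return "\n".join(residues[i:i + width] for i in range(0, len(residues), width))


def generate_bundle(cfg: FixtureConfig) -> tuple[BundleDocuments, GroundTruth]:
    """Generate one bundle; same config and seed give byte-identical output."""
    cfg.validate()
    rng = random.Random(cfg.seed)
    genes = GENE_CATALOGUE[: cfg.n_genes]
    truth = GroundTruth()

    # -- sequences --------------------------------------------------------
    sequences: dict[str, str] = {}
    n_atypical = round(cfg.atypical_fraction * cfg.n_genes)
    atypical = set(rng.sample(range(cfg.n_genes), n_atypical))
    for i, (symbol, *_rest) in enumerate(genes):
        if i in atypical:
            labels = rng.sample(CANONICAL_LABELS, rng.randint(1, DEFAULT_MIN_ANCHORS - 1))
            labels = [lab for lab in CANONICAL_LABELS if lab in labels]
        else:
            labels = list(CANONICAL_LABELS)
        seq, planted = _make_sequence(rng, labels)
        sequences[symbol] = seq
        truth.anchors[symbol] = planted
        truth.tilings[symbol] = _tile(planted, len(seq))

    # -- annotations ------------------------------------------------------
    ann_blocks: list[str] = []
    structures: dict[str, list[str]] = {}
    isoforms: dict[str, list[str]] = {}
    mods: dict[str, list[tuple[int, int, str]]] = {}  # positional features
    for symbol, *_rest in genes:
        seq = sequences[symbol]
        planted = truth.anchors[symbol]
        lines = [f"GENE\t{symbol}"]
        if planted:
            dom_start, dom_end = planted[0][1], min(planted[-1][2] + 10, len(seq))
            lines.append(f"DOMAIN\tProtein kinase\t{dom_start}\t{dom_end}\tPF00069")
        feats: list[tuple[str, int, int, str]] = []
        if rng.random() < cfg.feature_density:
            p = rng.randint(1, len(seq))
            feats.append(("ModifiedResidue", p, p, rng.choice(MODIFICATIONS)))
        if rng.random() < cfg.feature_density / 2:
            s = rng.randint(1, max(1, len(seq) - 30))
            feats.append(("TopologicalDomain", s, s + rng.randint(10, 30), "Cytoplasmic"))
        if rng.random() < cfg.feature_density / 3:
            feats.append(("SignalPeptide", 1, rng.randint(15, 25), ""))
        for kind, s, e, desc in feats:
            lines.append(f"FEATURE\t{kind}\t{s}\t{e}\t{desc}")
        mods[symbol] = [(s, e, d) for k, s, e, d in feats if d]
        pdb_ids = []
        for _ in range(rng.randint(0, cfg.structures_max)):
            pdb = f"{rng.randint(1, 9)}{''.join(rng.choice('ABCDEFGHKLMNPQRSTUVWXYZ') for _ in range(3))}"
            if pdb not in pdb_ids:
                pdb_ids.append(pdb)
                lines.append(f"STRUCTURE\t{pdb}")
        structures[symbol] = pdb_ids
        iso_ids = [f"{symbol}-{k + 1}" for k in range(rng.randint(0, cfg.isoforms_max))]
        for k, iso in enumerate(iso_ids):
            lines.append(f"ISOFORM\t{iso}\tIsoform {k + 1}")
        isoforms[symbol] = iso_ids
        lines.append(f"LOCATION\t{rng.choice(LOCATIONS)}")
        lines.append(f"TISSUE\t{rng.choice(TISSUES)}")
        ann_blocks.append("\n".join(lines))

    # -- mutations --------------------------------------------------------
    muts: list[_GenMutation] = []
    rows: list[tuple[str, ...]] = []
    mut_counter = 0
    sample_counter = 0
    histologies = [h for h, _, _ in cfg.cancer_types]
    weights = [w for _, w, _ in cfg.cancer_types]
    sites_of = {h: s for h, _, s in cfg.cancer_types}

    def draw_pair() -> tuple[str, str]:
        h = rng.choices(histologies, weights=weights)[0]
        return rng.choice(sites_of[h]), h

    for symbol, *_rest in genes:
        seq = sequences[symbol]
        tiling = truth.tilings[symbol]
        n_mut = rng.randint(*cfg.mutations_per_gene)
        used: set[str] = set()
        for _ in range(n_mut):
            for _attempt in range(20):
                pos = rng.randint(1, len(seq))
                ref = seq[pos - 1]
                r = rng.random()
                if r < 0.70:
                    alt = rng.choice([a for a in AA20 if a != ref])
                    aa, desc, mis = f"p.{ref}{pos}{alt}", "Substitution - Missense", True
                elif r < 0.76:
                    aa, desc, mis = f"p.{ref}{pos}*", "Substitution - Nonsense", False
                elif r < 0.80:
                    aa, desc, mis = f"p.{ref}{pos}{ref}", "Substitution - coding silent", False
                elif r < 0.88 and pos + 3 <= len(seq):
                    end = pos + rng.randint(1, 3)
                    aa = f"p.{ref}{pos}_{seq[end - 1]}{end}del"
                    desc, mis = "Deletion - In frame", False
                elif r < 0.93 and pos + 1 <= len(seq):
                    ins = "".join(rng.choice(AA20) for _ in range(rng.randint(1, 3)))
                    aa = f"p.{ref}{pos}_{seq[pos]}{pos + 1}ins{ins}"
                    desc, mis = "Insertion - In frame", False
                elif r < 0.97 and pos + 2 <= len(seq):
                    end = pos + rng.randint(1, 2)
                    alt = "".join(rng.choice(AA20) for _ in range(2))
                    aa = f"p.{ref}{pos}_{seq[end - 1]}{end}delins{alt}"
                    desc, mis = "Complex - deletion inframe", False
                else:
                    aa, desc, mis = "p.?", "Unknown", False
                    pos = None  # type: ignore[assignment]
                if aa not in used:
                    used.add(aa)
                    break
            else:
                continue
            label = _label_of(pos, tiling) if (pos and tiling) else None
            gm = _GenMutation(gene=symbol, aa_change=aa, description=desc,
                              is_missense=mis, position=pos, label=label)
            muts.append(gm)
            n_obs = 1 + (rng.random() < cfg.recurrence_rate)
            pair = draw_pair()
            for _obs in range(n_obs):
                if _obs and rng.random() < 0.5:
                    pair = draw_pair()
                gm.pairs.append(pair)
                mut_counter += 1
                sample_counter += 1
                rows.append((
                    symbol, f"COSM{mut_counter:05d}", aa,
                    f"c.{(pos or 1) * 3}A>T" if aa.startswith("p.") and pos else "",
                    desc, pair[0], pair[1], f"TCGA-{sample_counter:04d}",
                    f"PubMed:{rng.randint(10000000, 25000000)}",
                ))

    # -- pathways ---------------------------------------------------------
    n_pw = min(cfg.n_pathways, len(PATHWAY_NAMES))
    pw_lines: list[str] = []
    membership: dict[str, list[str]] = {}
    complexes_count = 0
    for p in range(n_pw):
        pid = f"PW{p + 1:03d}"
        members = [sym for sym, *_ in genes if rng.random() < cfg.membership_density]
        membership[pid] = members
        pw_lines.append(f"PATHWAY\t{pid}\t{PATHWAY_NAMES[p]}\t{';'.join(members)}")
        for rx_i in range(rng.randint(1, 3)):
            complexes_count += 2
            c_in, c_out = f"CX{complexes_count - 1:03d}", f"CX{complexes_count:03d}"
            pw_lines.append(f"COMPLEX\t{c_in}\tComplex {complexes_count - 1} [plasma membrane]")
            pw_lines.append(f"COMPLEX\t{c_out}\tComplex {complexes_count} [cytosol]")
            pw_lines.append(
                f"REACTION\tRX{p + 1:03d}{rx_i + 1}\t{PATHWAY_NAMES[p]} reaction {rx_i + 1}"
                f"\t{pid}\tconsumes={c_in}\tproduces={c_out}"
            )

    # -- documents --------------------------------------------------------
    kinome_lines = ["symbol\tsynonyms\tgroup\tfamily\tsubfamily\tchromosome"]
    for symbol, syn, group, fam, sub, chrom in genes:
        kinome_lines.append(f"{symbol}\t{syn}\t{group}\t{fam}\t{sub or '-'}\t{chrom}")
    fasta_lines = [f">{sym} synthetic kinase sequence\n{_wrap_fasta(sequences[sym])}"
                   for sym, *_ in genes]
    mut_lines = ["\t".join(["gene", "mutation_id", "aa_change", "cds_change", "description",
                            "primary_site", "primary_histology", "sample", "pubmed"])]
    mut_lines += ["\t".join(r) for r in rows]
    docs = BundleDocuments(
        kinome="\n".join(kinome_lines) + "\n",
        fasta="\n".join(fasta_lines) + "\n",
        annotations="\n\n".join(ann_blocks) + "\n",
        mutations="\n".join(mut_lines) + "\n",
        pathways="\n".join(pw_lines) + "\n",
    )

    truth.tables = _expected_tables(genes, structures, isoforms, membership,
                                    {f"PW{p + 1:03d}": PATHWAY_NAMES[p] for p in range(n_pw)},
                                    muts)
    return docs, truth


# ---------------------------------------------------------------------------
# expected query tables (generation-time enumeration)
# ---------------------------------------------------------------------------

def _table(columns: tuple[str, str], counts: dict[str, int], minimum: int = 1) -> QueryResultTable:
    return QueryResultTable.from_counts(columns, {k: v for k, v in counts.items() if v >= minimum})


def _expected_tables(genes, structures, isoforms, membership, pw_names, muts) -> dict[str, QueryResultTable]:
    tables: dict[str, QueryResultTable] = {}
    tables["q1"] = _table(("kinase", "count"), {g: len(s) for g, s in structures.items() if s})
    tables["q2"] = _table(("kinase", "count"), {g: len(s) for g, s in isoforms.items() if s})
    pw_count: dict[str, int] = {}
    for members in membership.values():
        for g in set(members):
            pw_count[g] = pw_count.get(g, 0) + 1
    tables["q3"] = _table(("kinase", "count"), pw_count)

    hist_of = {m_key: set() for m_key in range(len(muts))}
    site_of = {m_key: set() for m_key in range(len(muts))}
    for i, m in enumerate(muts):
        for site, hist in m.pairs:
            site_of[i].add(site)
            hist_of[i].add(hist)

    per_gene_hist: dict[str, set[str]] = {}
    q5a: dict[str, int] = {}
    q5b: dict[str, set[str]] = {}
    q6: dict[str, int] = {}
    q7: dict[str, int] = {}
    q8: dict[str, int] = {}
    q9: dict[str, set[str]] = {}
    q12: dict[str, set[str]] = {}
    q13: dict[str, int] = {}
    q14: dict[str, int] = {}
    for i, m in enumerate(muts):
        per_gene_hist.setdefault(m.gene, set()).update(hist_of[i])
        q7[m.gene] = q7.get(m.gene, 0) + 1
        if m.is_missense:
            q8[m.gene] = q8.get(m.gene, 0) + 1
            for h in hist_of[i]:
                q5a[h] = q5a.get(h, 0) + 1
                q5b.setdefault(h, set()).add(m.gene)
            if Q6_HISTOLOGY in hist_of[i]:
                q6[m.gene] = q6.get(m.gene, 0) + 1
        for h in hist_of[i]:
            q9.setdefault(h, set()).add(m.gene)
        for s in site_of[i]:
            q12.setdefault(s, set()).add(m.gene)
        if m.label is not None:
            q13[m.label] = q13.get(m.label, 0) + 1
            if m.gene == Q14_GENE and m.is_missense and Q14_SITE in site_of[i]:
                q14[m.label] = q14.get(m.label, 0) + 1
    tables["q4"] = _table(("kinase", "count"), {g: len(h) for g, h in per_gene_hist.items() if h})
    tables["q5a"] = _table(("cancer_type", "count"), q5a, minimum=4)
    tables["q5b"] = _table(("cancer_type", "count"), {h: len(g) for h, g in q5b.items()})
    tables["q6"] = _table(("kinase", "count"), q6)
    tables["q7"] = _table(("kinase", "count"), q7)
    tables["q8"] = _table(("kinase", "count"), q8)
    tables["q9"] = _table(("cancer_type", "count"), {h: len(g) for h, g in q9.items()}, minimum=2)
    by_name: dict[str, set[str]] = {}
    for pid, members in membership.items():
        if members:
            by_name.setdefault(pw_names[pid], set()).update(members)
    tables["q10"] = _table(("pathway", "count"), {n: len(g) for n, g in by_name.items()}, minimum=4)
    mutated = {m.gene for m in muts}
    tables["q11"] = _table(("kinase", "count"),
                           {g: n for g, n in pw_count.items() if g in mutated}, minimum=4)
    tables["q12"] = _table(("primary_site", "count"), {s: len(g) for s, g in q12.items()})
    tables["q13"] = _table(("subdomain", "count"), q13)
    tables["q14"] = _table(("subdomain", "count"), q14)
    assert set(tables) == set(QUERY_IDS)
    return tables


# ---------------------------------------------------------------------------
# the worked-example bundle
# ---------------------------------------------------------------------------

def fig1_bundle() -> BundleDocuments:
    """The static hand-written worked-example bundle shipped with the package.

    One gene (EGFR, with its literature synonyms), a sequence whose planted
    anchors put residue 858 in sub-domain VII, the p.L858M missense mutation
    annotated to carcinoma, and the Signaling-by-EGFR pathway with its
    dimerization reaction consuming EGF:EGFR and producing the dimer.
    """
    base = resources.files("prokino.data").joinpath("fig1")
    return BundleDocuments(
        kinome=base.joinpath("kinome.tsv").read_text(),
        fasta=base.joinpath("sequences.fasta").read_text(),
        annotations=base.joinpath("annotations.txt").read_text(),
        mutations=base.joinpath("mutations.tsv").read_text(),
        pathways=base.joinpath("pathways.tsv").read_text(),
    )
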