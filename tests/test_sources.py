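"""Source-dialect parsers, p.-notation grammar, mutation classification."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from prokino.sources import (
    AmbiguousSynonymError,
    MutationRecord,
    SourceParseError,
    classify_mutation,
    format_p_notation,
    parse_annotations,
    parse_fasta,
    parse_kinome_table,
    parse_mutations,
    parse_p_notation,
    parse_pathways,
    resolve_gene,
)

KINOME_HEADER = "symbol\tsynonyms\tgroup\tfamily\tsubfamily\tchromosome\n"


# -- kinome table -----------------------------------------------------------

def test_kinome_row_with_synonyms():
    doc = KINOME_HEADER + "EGFR\tEGFRvIII;ERBB1;ERBB;mENA\tTK\tEGFR\t-\t7p12\n"
    (rec,) = parse_kinome_table(doc)
    assert rec.symbol == "EGFR"
    assert rec.synonyms == ("EGFRvIII", "ERBB1", "ERBB", "mENA")
    assert rec.subfamily is None
    assert rec.chromosomal_position == "7p12"


def test_kinome_header_only_is_empty():
    assert parse_kinome_table(KINOME_HEADER) == []


def test_kinome_duplicate_symbol():
    doc = KINOME_HEADER + "ABL1\t\tTK\tAbl\t-\t9q34\nABL1\t\tTK\tAbl\t-\t9q34\n"
    with pytest.raises(SourceParseError, match="row 3.*ABL1"):
        parse_kinome_table(doc)


def test_kinome_missing_column():
    with pytest.raises(SourceParseError, match="missing required column"):
        parse_kinome_table("symbol\tgroup\tfamily\n")


# -- FASTA ------------------------------------------------------------------

def test_fasta_concatenates_lines():
    (rec,) = parse_fasta(">G1\nMKK\nLL\n")
    assert (rec.symbol, rec.residues) == ("G1", "MKKLL")


def test_fasta_preserves_order():
    recs = parse_fasta(">G1\nMK\n>G2\nLL\n")
    assert [r.symbol for r in recs] == ["G1", "G2"]


def test_fasta_illegal_residue():
    with pytest.raises(SourceParseError, match="illegal residue"):
        parse_fasta(">G1\nMK1L\n")


def test_fasta_empty_sequence():
    with pytest.raises(SourceParseError, match="empty sequence"):
        parse_fasta(">G1\n>G2\nMK\n")


# -- annotation blocks ------------------------------------------------------

def test_annotation_block_features_and_structures():
    doc = "GENE\tABL1\nFEATURE\tModifiedResidue\t253\t253\tPhosphotyrosine\n"
    doc += "".join(f"STRUCTURE\t{i}XYZ\n" for i in range(200))
    (rec,) = parse_annotations(doc)
    assert len(rec.features) == 1
    feat = rec.features[0]
    assert (feat.kind, feat.start, feat.end) == ("ModifiedResidue", 253, 253)
    assert feat.description == "Phosphotyrosine"
    assert len(rec.structures) == 200


def test_annotation_span_error():
    with pytest.raises(SourceParseError, match="invalid span"):
        parse_annotations("GENE\tG1\nFEATURE\tModifiedResidue\t10\t5\tx\n")


def test_annotation_unknown_feature_kind():
    with pytest.raises(SourceParseError, match="unknown feature kind"):
        parse_annotations("GENE\tG1\nFEATURE\tActiveSite\t1\t1\tx\n")


def test_annotation_unknown_line_type():
    with pytest.raises(SourceParseError, match="unknown line type"):
        parse_annotations("GENE\tG1\nWIBBLE\tfoo\n")


# -- mutation catalogue -----------------------------------------------------

MUT_HEADER = ("gene\tmutation_id\taa_change\tcds_change\tdescription\t"
              "primary_site\tprimary_histology\tsample\tpubmed\n")


def _mut_row(gene="EGFR", aa="p.L858M", desc="Substitution - Missense",
             site="lung", hist="carcinoma"):
    return f"{gene}\tM1\t{aa}\tc.1A>T\t{desc}\t{site}\t{hist}\tS1\tPubMed:1\n"


def test_mutation_row_parses():
    (rec,) = parse_mutations(MUT_HEADER + _mut_row())
    assert rec.symbol == "EGFR"
    assert rec.aa_change == "p.L858M"
    assert rec.primary_histology == "carcinoma"
    assert rec.references == ("PubMed:1",)


def test_mutation_empty_tsv(empty_stream):
    assert parse_mutations(empty_stream) == []


def test_mutation_rejections_are_logged_not_dropped():
    rows = [_mut_row(gene=f"G{i}") for i in range(8)]
    rows.insert(3, "\tM9\tp.A1T\t\td\ts\th\tS\t\n")      # empty gene
    rows.insert(7, "G9\tM10\t\t\td\ts\th\tS\t\n")         # empty aa change
    rejections = []
    recs = parse_mutations(MUT_HEADER + "".join(rows), rejections=rejections)
    assert len(recs) == 8
    assert len(rejections) == 2
    assert len(recs) + len(rejections) == 10
    assert {r[1] for r in rejections} == {"empty gene symbol", "empty amino-acid change"}


def test_mutation_missing_column():
    with pytest.raises(SourceParseError, match="missing required column"):
        parse_mutations("gene\taa_change\n")


# -- p. notation ------------------------------------------------------------

@pytest.mark.parametrize("text, kind, sub_kind, ref, pos, end, alt", [
    ("p.L858M", "substitution", "missense", "L", 858, 858, "M"),
    ("p.G12G", "substitution", "silent", "G", 12, 12, "G"),
    ("p.R100*", "substitution", "nonsense", "R", 100, 100, "*"),
    ("p.K745_E746insT", "insertion", "n/a", "KE", 745, 746, "T"),
    ("p.E746_A750del", "deletion", "n/a", "EA", 746, 750, None),
    ("p.L747del", "deletion", "n/a", "L", 747, 747, None),
    ("p.L747_A750delinsP", "complex", "n/a", "LA", 747, 750, "P"),
    ("p.?", "other", "n/a", "", None, None, None),
    ("c.1A>T", "other", "n/a", "", None, None, None),
])
def test_p_notation_grammar(text, kind, sub_kind, ref, pos, end, alt):
    c = parse_p_notation(text)
    assert (c.kind, c.sub_kind, c.ref, c.position, c.end, c.alt) == \
        (kind, sub_kind, ref, pos, end, alt)
    assert c.raw == text


AA = st.sampled_from("ACDEFGHIKLMNPQRSTVWY")
POS = st.integers(min_value=1, max_value=3000)


@st.composite
def p_strings(draw):
    kind = draw(st.sampled_from(["sub", "nonsense", "del", "dels", "ins", "delins"]))
    a, b = draw(AA), draw(AA)
    p = draw(POS)
    q = p + draw(st.integers(min_value=1, max_value=50))
    ins = "".join(draw(st.lists(AA, min_size=1, max_size=4)))
    if kind == "sub":
        return f"p.{a}{p}{b}"
    if kind == "nonsense":
        return f"p.{a}{p}*"
    if kind == "del":
        return f"p.{a}{p}del"
    if kind == "dels":
        return f"p.{a}{p}_{b}{q}del"
    if kind == "ins":
        return f"p.{a}{p}_{b}{p + 1}ins{ins}"
    return f"p.{a}{p}_{b}{q}delins{ins}"


@settings(max_examples=300, derandomize=True)
@given(p_strings())
def test_p_notation_round_trip(text):
    """format is a left inverse of parse over the supported grammar."""
    change = parse_p_notation(text)
    assert change.kind != "other"
    assert format_p_notation(change) == text


# -- classification ---------------------------------------------------------

@pytest.mark.parametrize("desc, aa, expected", [
    ("Substitution - Missense", "p.L858M", "SubstitutionMutation"),
    ("Substitution - Nonsense", "p.R100*", "SubstitutionMutation"),
    ("Deletion - In frame", "p.E746_A750del", "DeletionMutation"),
    ("Insertion - In frame", "p.K745_E746insT", "InsertionMutation"),
    ("Complex - deletion inframe", "p.L747_A750delinsP", "ComplexMutation"),
    ("", "p.E746_A750del", "DeletionMutation"),        # description fallback
    ("", "p.L858M", "SubstitutionMutation"),
    ("Whole gene deletion??", "p.?", "OtherMutation"),  # unknown text
    ("Unknown", "p.L858M", "OtherMutation"),
])
def test_classify_mutation(desc, aa, expected):
    rec = MutationRecord(symbol="G", mutation_id="M", aa_change=aa, nt_change=None,
                         description=desc, primary_site="s", primary_histology="h",
                         sample_id="S")
    cls, _ = classify_mutation(rec)
    assert cls == expected


@settings(max_examples=200, derandomize=True)
@given(st.text(max_size=30), p_strings() | st.just("p.?") | st.just("garbage"))
def test_classify_mutation_partitions(desc, aa):
    """Every record maps to exactly one of the five mutation classes."""
    rec = MutationRecord(symbol="G", mutation_id="M", aa_change=aa, nt_change=None,
                         description=desc, primary_site="s", primary_histology="h",
                         sample_id="S")
    cls, sub_kind = classify_mutation(rec)
    assert cls in {"SubstitutionMutation", "DeletionMutation", "InsertionMutation",
                   "ComplexMutation", "OtherMutation"}
    if sub_kind != "n/a":
        assert cls == "SubstitutionMutation"


# -- pathways ---------------------------------------------------------------

PW = (
    "PATHWAY\tP1\tSignaling by EGFR\tEGFR\n"
    "COMPLEX\tC1\tEGF:EGFR [plasma membrane]\n"
    "COMPLEX\tC2\tEGF:EGFR dimer [plasma membrane]\n"
    "REACTION\tR1\tEGFR dimerization\tP1\tconsumes=C1\tproduces=C2\n"
)


def test_pathway_worked_example():
    pathways, reactions, complexes = parse_pathways(PW)
    assert len(pathways) == 1 and len(reactions) == 1 and len(complexes) == 2
    assert pathways[0].members == ("EGFR",)
    assert reactions[0].consumes == ("C1",)
    assert reactions[0].produces == ("C2",)
    assert complexes[0].name == "EGF:EGFR [plasma membrane]"


def test_pathway_empty_document(empty_stream):
    assert parse_pathways(empty_stream) == ([], [], [])


def test_pathway_dangling_complex():
    with pytest.raises(SourceParseError, match="dangling complex id 'C9'"):
        parse_pathways(PW.replace("consumes=C1", "consumes=C9"))


def test_pathway_dangling_pathway():
    with pytest.raises(SourceParseError, match="dangling pathway id"):
        parse_pathways(PW.replace("\tP1\tconsumes", "\tP9\tconsumes"))


# -- gene resolution --------------------------------------------------------

def _genes(doc):
    return parse_kinome_table(KINOME_HEADER + doc)


def test_resolve_gene_by_synonym_and_symbol():
    genes = _genes("EGFR\tEGFRvIII;ERBB1;ERBB;mENA\tTK\tEGFR\t-\t7p12\n")
    assert resolve_gene("ERBB1", genes) == "EGFR"
    assert resolve_gene("EGFR", genes) == "EGFR"
    assert resolve_gene("egfr", genes) == "EGFR"
    assert resolve_gene("NOSUCHGENE", genes) is None


def test_resolve_gene_ambiguous_synonym():
    genes = _genes("G1\tALIAS\tTK\tAbl\t-\t1p\nG2\tALIAS\tTK\tAbl\t-\t2p\n")
    with pytest.raises(AmbiguousSynonymError, match="G1.*G2"):
        resolve_gene("alias", genes)
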