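"""Gene-model annotation checks: locations, coding consequences, census."""

import numpy as np
import pandas as pd
import pytest

from qtlbsa.annotate import (
    GeneIndex,
    GeneModel,
    RefMismatchError,
    annotate_variants,
    annotation_census,
    classify_exonic_effect,
    classify_location,
    ts_tv_ratio,
    variant_type,
)
from qtlbsa.validation import make_toy_locus, random_coding_variants, retranslation_effect

# hand-built locus: two genes on "c", CDS in capitals laid out by coordinate
#   geneA (+): exons 101-130 and 161-190 (intron 131-160)
#   geneB (-): exons 401-460
GENE_A = GeneModel("geneA", "c", "+", exons=[(101, 130), (161, 190)], cds=[(101, 130), (161, 190)])
GENE_B = GeneModel("geneB", "c", "-", exons=[(401, 460)], cds=[(401, 460)])
INDEX = GeneIndex([GENE_A, GENE_B], flank=100)


@pytest.mark.parametrize(
    "pos, expected, genes",
    [
        (110, "exonic", ["geneA"]),  # inside CDS
        (145, "intronic", ["geneA"]),  # middle of the intron
        (131, "splicing", ["geneA"]),  # first intron base (donor side)
        (132, "splicing", ["geneA"]),  # second intron base
        (133, "intronic", ["geneA"]),  # third base: outside the 2 bp window
        (160, "splicing", ["geneA"]),  # last intron base (acceptor side)
        (50, "upstream", ["geneA"]),  # 5' of a plus-strand gene start
        (250, "downstream", ["geneA"]),  # 3' of geneA, too far from geneB
        (350, "upstream", ["geneB"]),  # 5' of the minus-strand gene = right side? no: left
        (500, "upstream", ["geneB"]),  # minus strand: upstream lies at higher coords
        (700, "intergenic", []),
    ],
)
def test_location_classification(pos, expected, genes):
    loc, gids = classify_location("c", pos, "A", "T", INDEX, splice_window=2)
    if pos == 350:  # left of a minus-strand gene = its downstream side
        expected, genes = "downstream", ["geneB"]
    assert loc == expected
    assert gids == genes


def test_between_two_genes_is_upstream_slash_downstream():
    # plus-strand gene then minus-strand gene: the gap is downstream of both;
    # use two plus-strand genes to realize the mixed state
    g1 = GeneModel("g1", "c", "+", exons=[(100, 200)], cds=[(100, 200)])
    g2 = GeneModel("g2", "c", "+", exons=[(400, 500)], cds=[(400, 500)])
    idx = GeneIndex([g1, g2], flank=150)
    loc, gids = classify_location("c", 300, "A", "T", idx)
    assert loc == "upstream/downstream"
    assert set(gids) == {"g1", "g2"}


def test_location_precedence_exonic_beats_flank():
    # a variant exonic in one gene and within flank of another stays exonic
    g1 = GeneModel("g1", "c", "+", exons=[(100, 200)], cds=[(100, 200)])
    g2 = GeneModel("g2", "c", "+", exons=[(260, 350)], cds=[(260, 350)])
    idx = GeneIndex([g1, g2], flank=1000)
    loc, gids = classify_location("c", 190, "A", "T", idx)
    assert loc == "exonic" and gids == ["g1"]


def _locus_with_cds(mrna_like: str, strand: str = "+"):
    """Single-exon gene whose (coding-orientation) CDS is ``mrna_like``."""
    if strand == "-":
        comp = str.maketrans("ACGT", "TGCA")
        genomic = mrna_like.translate(comp)[::-1]
    else:
        genomic = mrna_like
    seq = "A" * 50 + genomic + "A" * 50
    gene = GeneModel("g", "c", strand, exons=[(51, 50 + len(genomic))], cds=[(51, 50 + len(genomic))])
    return gene, {"c": seq}


@pytest.mark.parametrize("strand", ["+", "-"])
def test_snp_consequences_on_both_strands(strand):
    # CDS: ATG GGA TAC TAA  (Met Gly Tyr Stop)
    gene, genome = _locus_with_cds("ATGGGATACTAA", strand)

    def gpos(mrna_idx):  # mRNA index -> genomic pos
        return 51 + mrna_idx if strand == "+" else 50 + 12 - mrna_idx

    def base(b):  # mRNA base -> genomic base at that position
        return b if strand == "+" else b.translate(str.maketrans("ACGT", "TGCA"))

    # GGA -> GAA: Gly -> Glu, nonsynonymous
    assert (
        classify_exonic_effect("c", gpos(4), base("G"), base("A"), gene, genome)
        == "nonsynonymous"
    )
    # TAC -> TAA: Tyr -> stop, stopgain
    assert (
        classify_exonic_effect("c", gpos(8), base("C"), base("A"), gene, genome)
        == "stopgain"
    )
    # GGA -> GGG: synonymous (both Gly)
    assert (
        classify_exonic_effect("c", gpos(5), base("A"), base("G"), gene, genome)
        == "synonymous"
    )
    # TAA -> CAA: stop -> Gln, stoploss
    assert (
        classify_exonic_effect("c", gpos(9), base("T"), base("C"), gene, genome)
        == "stoploss"
    )


def test_indel_consequences():
    gene, genome = _locus_with_cds("ATGGGATACGGATAA")
    seq = genome["c"]
    # 2 bp deletion inside the CDS: frameshift deletion
    assert (
        classify_exonic_effect("c", 54, seq[53:56], seq[53], gene, genome)
        == "frameshift deletion"
    )
    # 3 bp in-frame insertion of a sense codon: non-frameshift insertion
    assert (
        classify_exonic_effect("c", 56, seq[55], seq[55] + "GCA", gene, genome)
        == "non-frameshift insertion"
    )
    # 3 bp insertion of a stop codon: stopgain takes precedence
    assert (
        classify_exonic_effect("c", 56, seq[55], seq[55] + "TAA", gene, genome)
        == "stopgain"
    )
    # in-frame deletion spanning the terminal stop: stoploss
    assert (
        classify_exonic_effect("c", 62, seq[61:65], seq[61], gene, genome)
        == "stoploss"
    )
    # 4 bp insertion: frameshift insertion
    assert (
        classify_exonic_effect("c", 56, seq[55], seq[55] + "GCAT", gene, genome)
        == "frameshift insertion"
    )


def test_reference_mismatch_is_a_hard_error():
    gene, genome = _locus_with_cds("ATGGGATACTAA")
    wrong = "C" if genome["c"][54] != "C" else "G"
    with pytest.raises(RefMismatchError):
        classify_exonic_effect("c", 55, wrong, "T", gene, genome)


def test_classifier_matches_retranslation_oracle(rng):
    """Codon-local route vs whole-protein retranslation on randomized variants."""
    n_checked = 0
    for strand in ("+", "-"):
        for rep in range(3):
            gene, genome = make_toy_locus(
                rng, chrom=f"t{strand}{rep}", strand=strand, n_codons=80, n_exons=3
            )
            for v in random_coding_variants(gene, genome, 200, rng):
                got = classify_exonic_effect(v["chrom"], v["pos"], v["ref"], v["alt"], gene, genome)
                want = retranslation_effect(v["chrom"], v["pos"], v["ref"], v["alt"], gene, genome)
                assert got == want, f"{v} -> {got} != {want}"
                n_checked += 1
    assert n_checked >= 1000


def test_strand_symmetry_of_classification(rng):
    """Reverse-complementing genome, gene and alleles leaves effects unchanged."""
    gene, genome = make_toy_locus(rng, chrom="sym", strand="+", n_codons=60, n_exons=2)
    L = len(genome["sym"])
    comp = str.maketrans("ACGT", "TGCA")
    rc_seq = genome["sym"].translate(comp)[::-1]

    def mirror_iv(iv):
        a, b = iv
        return (L - b + 1, L - a + 1)

    rc_gene = GeneModel(
        "g_rc", "sym", "-",
        exons=[mirror_iv(iv) for iv in gene.exons],
        cds=[mirror_iv(iv) for iv in gene.cds],
    )
    rc_genome = {"sym": rc_seq}
    for v in random_coding_variants(gene, genome, 120, rng):
        fwd = classify_exonic_effect(v["chrom"], v["pos"], v["ref"], v["alt"], gene, genome)
        # mirrored variant: reverse-complement alleles, re-anchor at the left
        ref_rc = v["ref"].translate(comp)[::-1]
        alt_rc = v["alt"].translate(comp)[::-1]
        pos_rc = L - (v["pos"] + len(v["ref"]) - 1) + 1
        rev = classify_exonic_effect("sym", pos_rc, ref_rc, alt_rc, rc_gene, rc_genome)
        base = fwd.replace("insertion", "x").replace("deletion", "x")
        base_rev = rev.replace("insertion", "x").replace("deletion", "x")
        assert base == base_rev, f"{v}: {fwd} vs {rev}"


def test_annotate_variants_table_and_census(rng):
    gene, genome = make_toy_locus(rng, chrom="t1", strand="+", n_codons=60, n_exons=2)
    flank = 1000
    sites = pd.DataFrame(
        [
            {"chrom": "t1", "pos": gene.cds[0][0] + 3, "ref": genome["t1"][gene.cds[0][0] + 2], "alt": "N"},
            {"chrom": "t1", "pos": max(gene.start - 200, 1), "ref": genome["t1"][max(gene.start - 200, 1) - 1], "alt": "T"},
        ]
    )
    # make the SNP alt a real base different from ref
    sites.loc[0, "alt"] = "A" if sites.loc[0, "ref"] != "A" else "G"
    sites.loc[1, "alt"] = "A" if sites.loc[1, "ref"] != "A" else "G"
    ann = annotate_variants(sites, [gene], genome=genome, flank=flank)
    assert list(ann["location"])[0] == "exonic"
    assert list(ann["location"])[1] == "upstream"
    assert (ann["exonic_effect"] != "none").tolist() == [True, False]

    census = annotation_census(ann)
    assert census["total"] == 2
    assert sum(census["snp"]["locations"].values()) + sum(
        census["indel"]["locations"].values()
    ) == census["total"]


def test_census_partitions_locations_and_counts_ts_tv(small_cross, rng):
    _, truth, sites = small_cross
    sub = sites[["chrom", "pos", "ref", "alt"]].copy()
    sub["location"] = rng.choice(["intergenic", "intronic", "upstream"], len(sub))
    sub["exonic_effect"] = "none"
    sub["gene_ids"] = ""
    census = annotation_census(sub)
    assert (
        sum(census["snp"]["locations"].values())
        + sum(census["indel"]["locations"].values())
        == len(sub)
    )
    assert census["indel"]["insertions"] + census["indel"]["deletions"] == census["indel"]["total"]
    assert census["snp"]["transitions"] + census["snp"]["transversions"] == census["snp"]["total"]


def test_ts_tv_worked_values():
    # published transition/transversion totals give 1.749
    assert round(ts_tv_ratio(2_260_594, 1_292_240), 3) == 1.749
    # single A->G variant: transition only, ratio degenerates to infinity
    assert ts_tv_ratio(1, 0) == float("inf")
    # published insertion + deletion totals
    assert 398_001 + 420_787 == 818_788


def test_variant_type_invariants():
    assert variant_type("A", "T") == "SNP"
    assert variant_type("A", "AT") == "insertion"
    assert variant_type("AT", "A") == "deletion"
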