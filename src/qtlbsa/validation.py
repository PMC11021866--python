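"""Brute-force cross-checks for the coding-consequence classifier.

:func:`retranslation_effect` takes the slow, obviously-correct route: apply
the edit to the raw chromosome sequence, shift the gene model's coordinates,
re-extract and re-translate both complete proteins, and classify from the
protein diff. It shares no code path with
:func:`qtlbsa.annotate.classify_exonic_effect`, which works codon-locally in
spliced-mRNA coordinates, so agreement between the two is a meaningful check.

Also provides generators for small synthetic coding loci and randomized
coding variants used to exercise both routes.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .annotate import GeneModel, RefMismatchError, _fetch, _mrna, _translate

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def make_toy_locus(
    rng: np.random.Generator,
    chrom: str = "toy1",
    strand: str = "+",
    n_codons: int = 60,
    n_exons: int = 3,
    flank: int = 300,
) -> tuple[GeneModel, dict[str, str]]:
    """Build one protein-coding gene plus its chromosome sequence.

    The CDS is a run of sense codons terminated by a stop codon (as in a
    real complete CDS there is exactly one in-frame stop, at the end), split
    across ``n_exons`` exons by random intron insertion. Returns the gene
    model and a ``{chrom: sequence}`` dict.
    """
    codons = rng.choice(_SENSE_CODONS, size=n_codons - 1)
    stop = rng.choice(sorted(_STOPS))
    mrna = "".join(codons) + stop
    if strand == "-":
        comp = str.maketrans("ACGT", "TGCA")
        genomic_cds = mrna.translate(comp)[::-1]
    else:
        genomic_cds = mrna
    # split the genomic CDS into exon pieces (each >= 4 bp so indel
    # generators always find interior positions)
    n_exons = max(1, min(n_exons, len(genomic_cds) // 8))
    cuts = sorted(rng.choice(np.arange(4, len(genomic_cds) - 4), size=n_exons - 1, replace=False)) if n_exons > 1 else []
    pieces = []
    prev = 0
    for c in list(cuts) + [len(genomic_cds)]:
        pieces.append(genomic_cds[prev:c])
        prev = c
    seq_parts = [_rand_seq(rng, flank)]
    pos = flank
    cds: list[tuple[int, int]] = []
    for i, piece in enumerate(pieces):
        if i > 0:
            intron = _rand_seq(rng, int(rng.integers(50, 200)))
            seq_parts.append(intron)
            pos += len(intron)
        cds.append((pos + 1, pos + len(piece)))  # 1-based inclusive
        seq_parts.append(piece)
        pos += len(piece)
    seq_parts.append(_rand_seq(rng, flank))
    gene = GeneModel(
        gene_id=f"toygene_{chrom}_{strand}",
        chrom=chrom,
        strand=strand,
        exons=list(cds),
        cds=list(cds),
    )
    return gene, {chrom: "".join(seq_parts)}


def random_coding_variants(
    gene: GeneModel,
    genome: Mapping[str, str],
    n: int,
    rng: np.random.Generator,
    p_indel: float = 0.4,
) -> list[dict]:
    """Randomized SNVs and short indels falling inside the CDS of ``gene``.

    Indels are VCF-style (anchor base included) and kept strictly inside a
    single CDS segment, the regime both classification routes define.
    """
    out = []
    segs = np.asarray(gene.cds)
    weights = (segs[:, 1] - segs[:, 0] + 1).astype(float)
    weights /= weights.sum()
    while len(out) < n:
        a, b = segs[rng.choice(len(segs), p=weights)]
        if rng.random() >= p_indel:  # SNV
            pos = int(rng.integers(a, b + 1))
            ref = _fetch(genome, gene.chrom, pos, pos)
            alt = str(rng.choice([x for x in "ACGT" if x != ref]))
            out.append({"chrom": gene.chrom, "pos": pos, "ref": ref, "alt": alt})
        elif rng.random() < 0.5:  # insertion after the anchor
            if b - a < 1:
                continue
            pos = int(rng.integers(a, b))  # anchor in [a, b-1]
            ref = _fetch(genome, gene.chrom, pos, pos)
            ins = _rand_seq(rng, int(rng.integers(1, 7)))
            out.append({"chrom": gene.chrom, "pos": pos, "ref": ref, "alt": ref + ins})
        else:  # deletion of k bases after the anchor
            k = int(rng.integers(1, 7))
            if b - a < k:
                continue
            pos = int(rng.integers(a, b - k + 1))
            ref = _fetch(genome, gene.chrom, pos, pos + k)
            out.append({"chrom": gene.chrom, "pos": pos, "ref": ref, "alt": ref[0]})
    return out


def retranslation_effect(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    gene: GeneModel,
    genome: Mapping[str, str],
) -> str:
    """Classify a coding variant by whole-protein retranslation.

    Applies the edit to the chromosome string, shifts every gene-model
    coordinate downstream of the edit, re-extracts the mutant CDS and
    translates both full proteins; the classification falls out of the
    protein lengths and first-stop positions. Edits must lie within a single
    CDS segment.
    """
    observed = _fetch(genome, chrom, pos, pos + len(ref) - 1)
    if observed != ref.upper():
        raise RefMismatchError(f"{chrom}:{pos} expected {ref!r}, genome has {observed!r}")
    ref, alt = ref.upper(), alt.upper()
    diff = len(alt) - len(ref)
    e_start, e_end = pos, pos + len(ref) - 1
    if not any(a <= e_start and e_end <= b for a, b in gene.cds):
        raise ValueError("edit does not lie within a single CDS segment")
    if diff % 3 != 0:
        return "frameshift insertion" if diff > 0 else "frameshift deletion"

    seq = str(genome[chrom])
    mut_seq = seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]

    def shift(iv: tuple[int, int]) -> tuple[int, int]:
        a, b = iv
        if a <= e_start and e_end <= b:  # edit inside this segment
            return (a, b + diff)
        if a > e_end:
            return (a + diff, b + diff)
        return (a, b)

    mut_gene = GeneModel(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        exons=[shift(iv) for iv in gene.exons],
        cds=[shift(iv) for iv in gene.cds],
    )
    ref_aa = _translate(_mrna(gene, genome))
    mut_aa = _translate(_mrna(mut_gene, {chrom: mut_seq}))
    jr, jm, dc = ref_aa.find("*"), mut_aa.find("*"), diff // 3

    if len(ref) == 1 and len(alt) == 1:
        if ref_aa == mut_aa:
            return "synonymous"
        if jm != -1 and (jr == -1 or jm < jr):
            return "stopgain"
        if jr != -1 and (jm == -1 or jm > jr):
            return "stoploss"
        return "nonsynonymous"
    if jm != -1 and (jr == -1 or jm < jr + dc):
        return "stopgain"
    if jr != -1 and (jm == -1 or jm > jr + dc):
        return "stoploss"
    if diff == 0:
        return "synonymous" if ref_aa == mut_aa else "nonsynonymous"
    return "non-frameshift insertion" if diff > 0 else "non-frameshift deletion"
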