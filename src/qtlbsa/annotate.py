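"""Variant location and coding-consequence annotation.

Implements the classic gene-model annotation step of a resequencing
pipeline: each biallelic variant is assigned one genomic location
(exonic > splicing > intronic > upstream/downstream > intergenic, in that
precedence order) and, when exonic, a coding consequence (synonymous,
nonsynonymous, stop gain/loss, frameshift or in-frame insertion/deletion).

Consequences are computed by mapping the variant into spliced-mRNA
coordinates and editing only the affected codons; a brute-force cross-check
that re-translates whole proteins lives in :mod:`qtlbsa.validation`.

Coordinates are 1-based inclusive throughout, matching VCF and GFF3.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

LOCATIONS = (
    "exonic",
    "splicing",
    "intronic",
    "upstream",
    "downstream",
    "upstream/downstream",
    "intergenic",
)

EXONIC_EFFECTS = (
    "stopgain",
    "stoploss",
    "frameshift insertion",
    "frameshift deletion",
    "nonsynonymous",
    "non-frameshift insertion",
    "non-frameshift deletion",
    "synonymous",
)

#: Severity ranking used when a variant is exonic in several overlapping
#: gene models: the most severe consequence is reported.
_SEVERITY = {e: i for i, e in enumerate(EXONIC_EFFECTS)}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class RefMismatchError(ValueError):
    """Reference allele does not match the genome sequence (coordinate bug)."""


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def variant_type(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNP"
    return "insertion" if len(alt) > len(ref) else "deletion"


@dataclass
class GeneModel:
    """A single-transcript protein-coding gene model.

    ``exons`` and ``cds`` are sorted, non-overlapping lists of 1-based
    inclusive genomic intervals; CDS intervals must lie within exons.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: Sequence[tuple[int, int]]
    cds: Sequence[tuple[int, int]] = ()
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        self.cds = sorted((int(a), int(b)) for a, b in self.cds)
        if not self.transcript_id:
            self.transcript_id = self.gene_id + ".t1"
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            for (a, b) in ivs:
                if a > b:
                    raise ValueError(f"{name} interval ({a}, {b}) reversed")
            for (_, b0), (a1, _) in zip(ivs, ivs[1:]):
                if a1 <= b0:
                    raise ValueError(f"{name} intervals overlap")
        for (a, b) in self.cds:
            if not any(ea <= a and b <= eb for ea, eb in self.exons):
                raise ValueError("CDS interval not contained in an exon")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_len(self) -> int:
        return sum(b - a + 1 for a, b in self.cds)

    def introns(self) -> list[tuple[int, int]]:
        return [
            (b0 + 1, a1 - 1)
            for (_, b0), (a1, _) in zip(self.exons, self.exons[1:])
            if a1 - b0 > 1
        ]


# ---------------------------------------------------------------------------
# genome access
# ---------------------------------------------------------------------------


def _fetch(genome: Mapping[str, str], chrom: str, start: int, end: int) -> str:
    """Slice ``chrom[start..end]`` (1-based inclusive) from a mapping of
    chromosome name to sequence string (a plain dict or pyfaidx-style object)."""
    seq = genome[chrom]
    return str(seq[start - 1 : end]).upper()


# ---------------------------------------------------------------------------
# location classification
# ---------------------------------------------------------------------------


class GeneIndex:
    """Per-chromosome interval index over gene bodies (+/- flank)."""

    def __init__(self, genes: Iterable[GeneModel], flank: int = 1000):
        self.flank = int(flank)
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        for i, g in enumerate(self.genes):
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            # interval tree uses half-open coords; pad by flank on both sides
            tree.addi(g.start - self.flank, g.end + self.flank + 1, i)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(start, end + 1)
        return [self.genes[h.data] for h in sorted(hits, key=lambda h: h.data)]


def classify_location(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    index: GeneIndex,
    splice_window: int = 2,
) -> tuple[str, list[str]]:
    """Assign one location category and the associated gene ids.

    The affected genomic footprint is ``[pos, pos + len(ref) - 1]``.
    Precedence across genes and categories:
    exonic > splicing > intronic > upstream/downstream > intergenic.
    """
    v_start, v_end = pos, pos + len(ref) - 1
    exonic: list[str] = []
    splicing: list[str] = []
    intronic: list[str] = []
    upstream: list[str] = []
    downstream: list[str] = []
    for g in index.overlapping(chrom, v_start, v_end):
        if v_end < g.start or v_start > g.end:
            # flanking region (the index only returns genes within `flank`);
            # 5' of a plus-strand gene or 3' of a minus-strand gene = upstream
            before = v_end < g.start
            if (g.strand == "+") == before:
                upstream.append(g.gene_id)
            else:
                downstream.append(g.gene_id)
            continue
        if any(v_start <= b and v_end >= a for a, b in g.cds):
            exonic.append(g.gene_id)
            continue
        in_intron = False
        near_splice = False
        for ia, ib in g.introns():
            if v_start <= ib and v_end >= ia:
                in_intron = True
                if v_start - ia < splice_window or ib - v_end < splice_window:
                    near_splice = True
        if near_splice:
            splicing.append(g.gene_id)
        elif in_intron:
            intronic.append(g.gene_id)
        else:
            # inside the gene span but in a non-coding exon portion; grouped
            # with intronic (no separate UTR category in this vocabulary)
            intronic.append(g.gene_id)
    if exonic:
        return "exonic", exonic
    if splicing:
        return "splicing", splicing
    if intronic:
        return "intronic", intronic
    if upstream and downstream:
        return "upstream/downstream", sorted(set(upstream + downstream))
    if upstream:
        return "upstream", upstream
    if downstream:
        return "downstream", downstream
    return "intergenic", []


# ---------------------------------------------------------------------------
# coding consequence
# ---------------------------------------------------------------------------


def _cds_offsets(gene: GeneModel) -> list[tuple[int, int, int]]:
    """(genomic_start, genomic_end, offset-in-genomic-CDS) per CDS segment."""
    out = []
    off = 0
    for a, b in gene.cds:
        out.append((a, b, off))
        off += b - a + 1
    return out


def _map_to_cds(gene: GeneModel, pos: int) -> Optional[int]:
    """Genomic position -> index in the genomic-orientation spliced CDS."""
    for a, b, off in _cds_offsets(gene):
        if a <= pos <= b:
            return off + pos - a
    return None


def _mrna(gene: GeneModel, genome: Mapping[str, str]) -> str:
    seq = "".join(_fetch(genome, gene.chrom, a, b) for a, b in gene.cds)
    return _revcomp(seq) if gene.strand == "-" else seq


def _translate(seq: str) -> str:
    return str(Seq(seq).translate())


def _trim(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Strip the shared suffix then prefix of a VCF allele pair."""
    while len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 0 and len(alt) > 0 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def classify_exonic_effect(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    gene: GeneModel,
    genome: Mapping[str, str],
) -> str:
    """Coding consequence of a variant that overlaps the CDS of ``gene``.

    SNPs are classified by translating the reference and alternate codon
    (reverse-complementing on the minus strand); indels by frame (length
    difference mod 3) with stop gain/loss taking precedence for in-frame
    changes. Raises :class:`RefMismatchError` when the stated reference
    allele disagrees with the genome — a coordinate sanity check.
    """
    observed = _fetch(genome, chrom, pos, pos + len(ref) - 1)
    if observed != ref.upper():
        raise RefMismatchError(
            f"{chrom}:{pos} expected {ref!r}, genome has {observed!r}"
        )
    ref = ref.upper()
    alt = alt.upper()
    mrna = _mrna(gene, genome)
    L = len(mrna)
    if L % 3 != 0:
        raise ValueError(f"{gene.gene_id}: CDS length {L} not a multiple of 3")
    minus = gene.strand == "-"

    def m_idx(g_idx: int) -> Optional[int]:
        i = _map_to_cds(gene, g_idx)
        if i is None:
            return None
        return L - 1 - i if minus else i

    if len(ref) == 1 and len(alt) == 1:  # SNP
        i = m_idx(pos)
        if i is None:
            raise ValueError(f"{chrom}:{pos} does not fall in the CDS of {gene.gene_id}")
        alt_m = alt.translate(_COMPLEMENT) if minus else alt
        c = 3 * (i // 3)
        codon_ref = mrna[c : c + 3]
        codon_alt = codon_ref[: i - c] + alt_m + codon_ref[i - c + 1 :]
        aa_ref, aa_alt = _translate(codon_ref), _translate(codon_alt)
        if aa_ref == aa_alt:
            return "synonymous"
        if aa_alt == "*":
            return "stopgain"
        if aa_ref == "*":
            return "stoploss"
        return "nonsynonymous"

    # indel / block substitution
    diff = len(alt) - len(ref)
    kind = "insertion" if diff > 0 else "deletion"
    if diff % 3 != 0:
        return f"frameshift {kind}"

    p, r, a = _trim(pos, ref, alt)
    if r == "" and a == "":  # ref == alt after trimming; no change
        return "synonymous"
    a_m = _revcomp(a) if minus else a
    if r == "":  # pure insertion between p-1 and p
        left, right = m_idx(p - 1), m_idx(p)
        if left is None and right is None:
            raise ValueError(f"{chrom}:{pos} insertion outside the CDS of {gene.gene_id}")
        if minus:
            at = right + 1 if right is not None else left
        else:
            at = right if right is not None else left + 1
        mut = mrna[:at] + a_m + mrna[at:]
        w0, w1 = at, at  # first/last affected ref index (insertion point)
    else:
        idxs = [m_idx(x) for x in range(p, p + len(r))]
        if any(i is None for i in idxs):
            # edit extends beyond the CDS: frame information is all we have
            return f"non-frameshift {kind}" if diff else "nonsynonymous"
        w0, w1 = min(idxs), max(idxs)
        mut = mrna[:w0] + a_m + mrna[w1 + 1 :]

    # translate only the codon window the edit touches; downstream codons are
    # unchanged and stay in frame, so local stop positions decide gain/loss
    c0 = 3 * (w0 // 3)
    c1 = min(L, 3 * (w1 // 3) + 3)
    ref_aa = _translate(mrna[c0:c1])
    mut_aa = _translate(mut[c0 : c1 + diff])
    jr, jm, dc = ref_aa.find("*"), mut_aa.find("*"), diff // 3
    if jm != -1 and (jr == -1 or jm < jr + dc):
        return "stopgain"
    if jr != -1 and (jm == -1 or jm > jr + dc):
        return "stoploss"
    if diff == 0:
        return "synonymous" if mut_aa == ref_aa else "nonsynonymous"
    return f"non-frameshift {kind}"


# ---------------------------------------------------------------------------
# table-level driver and census
# ---------------------------------------------------------------------------


def annotate_variants(
    sites: pd.DataFrame,
    genes: Sequence[GeneModel],
    genome: Optional[Mapping[str, str]] = None,
    flank: int = 1000,
    splice_window: int = 2,
) -> pd.DataFrame:
    """Annotate a site table (columns ``chrom, pos, ref, alt``) in place-order.

    Adds ``location``, ``exonic_effect`` (the string ``"none"`` for
    non-exonic sites) and ``gene_ids`` (comma-joined). ``genome`` is required
    as soon as any variant is exonic.
    """
    index = GeneIndex(genes, flank=flank)
    by_id = {g.gene_id: g for g in genes}
    locations, effects, gene_ids = [], [], []
    for chrom, pos, ref, alt in zip(
        sites["chrom"], sites["pos"], sites["ref"], sites["alt"]
    ):
        loc, gids = classify_location(
            chrom, int(pos), ref, alt, index, splice_window=splice_window
        )
        eff = "none"
        if loc == "exonic":
            if genome is None:
                raise ValueError("a genome sequence is required to annotate exonic variants")
            cands = [
                classify_exonic_effect(chrom, int(pos), ref, alt, by_id[g], genome)
                for g in gids
            ]
            eff = min(cands, key=lambda e: _SEVERITY[e])
        locations.append(loc)
        effects.append(eff)
        gene_ids.append(",".join(gids))
    out = sites.copy()
    out["location"] = locations
    out["exonic_effect"] = effects
    out["gene_ids"] = gene_ids
    return out


def ts_tv_ratio(ts: int, tv: int) -> float:
    """Transition/transversion ratio; infinity when no transversions."""
    if tv == 0:
        return float("inf")
    return ts / tv


def annotation_census(annotated: pd.DataFrame) -> dict:
    """Category accounting over an annotated site table.

    Returns per-location and per-effect counts split by variant class
    (SNP vs InDel), transition/transversion counts and their ratio, and
    insertion/deletion totals. Location counts partition the variant set.
    """
    vtypes = [variant_type(r, a) for r, a in zip(annotated["ref"], annotated["alt"])]
    is_snp = np.array([t == "SNP" for t in vtypes])
    snp = annotated[is_snp]
    indel = annotated[~is_snp]
    ts = sum(
        1 for r, a in zip(snp["ref"], snp["alt"]) if (r.upper(), a.upper()) in TRANSITIONS
    )
    tv = len(snp) - ts
    census = {
        "snp": {
            "locations": dict(Counter(snp["location"])),
            "exonic_effects": dict(
                Counter(e for e in snp["exonic_effect"] if e != "none")
            ),
            "transitions": ts,
            "transversions": tv,
            "ts_tv": round(ts_tv_ratio(ts, tv), 3) if tv else float("inf"),
            "total": int(len(snp)),
        },
        "indel": {
            "locations": dict(Counter(indel["location"])),
            "exonic_effects": dict(
                Counter(e for e in indel["exonic_effect"] if e != "none")
            ),
            "insertions": int(sum(1 for t in vtypes if t == "insertion")),
            "deletions": int(sum(1 for t in vtypes if t == "deletion")),
            "total": int(len(indel)),
        },
        "total": int(len(annotated)),
    }
    return census
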