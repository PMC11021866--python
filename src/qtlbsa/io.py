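"""Readers and writers for the standard formats the pipeline speaks.

VCF (4.2, per-sample AD/DP) and GFF3 are read through cyvcf2 and gffutils;
the simulator's outputs are written as plain text. All in-memory coordinates
are 1-based inclusive; only BED output converts to 0-based half-open, and
that conversion lives here.

The canonical in-memory variant container is a pandas DataFrame ("site
table") with columns ``chrom, pos, ref, alt, vtype`` plus per-sample read
counts ``{sample}_ref`` and ``{sample}_alt``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import GeneModel, variant_type


def sample_columns(sample: str) -> tuple[str, str]:
    return f"{sample}_ref", f"{sample}_alt"


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(
    sites: pd.DataFrame,
    path: str | Path,
    samples: Sequence[str],
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> None:
    """Write a site table as a minimal multi-sample VCF 4.2 with AD and DP."""
    path = Path(path)
    lines = ["##fileformat=VCFv4.2", "##source=qtlbsa-simulate"]
    if chrom_sizes:
        for name, length in chrom_sizes.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Allelic depths for the ref and alt alleles">'
    )
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    cols = [sample_columns(s) for s in samples]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for row in sites.itertuples(index=False):
            d = row._asdict()
            fields = [
                str(d["chrom"]),
                str(int(d["pos"])),
                ".",
                d["ref"],
                d["alt"],
                ".",
                "PASS",
                ".",
                "AD:DP",
            ]
            for rc, ac in cols:
                r, a = int(d[rc]), int(d[ac])
                fields.append(f"{r},{a}:{r + a}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | Path, samples: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Read a multi-sample VCF with per-sample AD into a site table.

    Multi-allelic records are split into biallelic rows (ref depth = AD[0],
    alt depth = AD[k] for alternate allele k). Records without AD are skipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    names = list(vcf.samples)
    if samples is not None:
        missing = set(samples) - set(names)
        if missing:
            raise ValueError(f"samples not present in VCF: {sorted(missing)}")
        keep = [names.index(s) for s in samples]
        names = list(samples)
    else:
        keep = list(range(len(names)))
    rows = []
    for var in vcf:
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            continue
        ad = np.asarray(ad)
        for k, alt in enumerate(var.ALT):
            rec = {
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": alt,
                "vtype": variant_type(var.REF, alt),
            }
            for name, j in zip(names, keep):
                rc, ac = sample_columns(name)
                rec[rc] = max(int(ad[j, 0]), 0)
                rec[ac] = max(int(ad[j, k + 1]), 0)
            rows.append(rec)
    cols = ["chrom", "pos", "ref", "alt", "vtype"]
    for n in names:
        cols += list(sample_columns(n))
    return pd.DataFrame(rows, columns=cols)


def read_vcf_chrom_sizes(path: str | Path) -> dict[str, int]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    return dict(zip(vcf.seqnames, vcf.seqlens))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            s = str(seq)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        "qtlbsa",
                        "gene",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        "qtlbsa",
                        "mRNA",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.transcript_id};Parent={g.gene_id}",
                    ]
                )
                + "\n"
            )
            for a, b in g.exons:
                fh.write(
                    f"{g.chrom}\tqtlbsa\texon\t{a}\t{b}\t.\t{g.strand}\t.\t"
                    f"Parent={g.transcript_id}\n"
                )
            # phase of each CDS segment in translation order
            ordered = list(g.cds) if g.strand == "+" else list(g.cds)[::-1]
            off = 0
            phases = {}
            for a, b in ordered:
                phases[(a, b)] = (3 - off % 3) % 3
                off += b - a + 1
            for a, b in g.cds:
                fh.write(
                    f"{g.chrom}\tqtlbsa\tCDS\t{a}\t{b}\t.\t{g.strand}\t"
                    f"{phases[(a, b)]}\tParent={g.transcript_id}\n"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load single-transcript gene models from a GFF3 file via gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    for gene in db.features_of_type("gene"):
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
            cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
            genes.append(
                GeneModel(
                    gene_id=gene.id,
                    chrom=gene.seqid,
                    strand=gene.strand,
                    exons=exons or cds,
                    cds=cds,
                    transcript_id=mrna.id,
                )
            )
            break  # one transcript per gene in this data model
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


# ---------------------------------------------------------------------------
# tables, truth, BED
# ---------------------------------------------------------------------------


def write_phenotypes(phenos: pd.DataFrame, path: str | Path) -> None:
    phenos.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truth_dict: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth_dict, fh, indent=1, sort_keys=True)


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def intervals_to_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Candidate intervals as BED (0-based half-open conversion happens here)."""
    with open(path, "w") as fh:
        for row in intervals.itertuples(index=False):
            fh.write(f"{row.chrom}\t{int(row.start) - 1}\t{int(row.end)}\n")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV output (fixed float formatting, no index)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
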