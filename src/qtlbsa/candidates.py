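"""Candidate-gene screening from annotated polymorphic loci.

Genes are prioritized by the severity of the variants they host:

* tier 1 — stop gain/loss and frameshift indels,
* tier 2 — nonsynonymous substitutions and splice-site variants,
* tier 3 — upstream/downstream (regulatory-flank) variants; included by
  default since in practice candidate lists are dominated by them, with
  the tier label kept visible so the stated preference order is preserved.

Screening can run genome-wide or restricted to the candidate intervals
called by the association scan.
"""

from __future__ import annotations

from typing import Mapping, Optional

import pandas as pd

from .annotate import variant_type

TIER1_EFFECTS = {"stopgain", "stoploss", "frameshift insertion", "frameshift deletion"}
TIER2_EFFECTS = {"nonsynonymous"}
TIER3_LOCATIONS = {"upstream", "downstream", "upstream/downstream"}


def _tier(location: str, effect: str) -> int:
    if effect in TIER1_EFFECTS:
        return 1
    if effect in TIER2_EFFECTS or location == "splicing":
        return 2
    if location in TIER3_LOCATIONS:
        return 3
    return 0  # not a candidate


def screen_candidates(
    annotated: pd.DataFrame,
    intervals: Optional[pd.DataFrame] = None,
    mode: str = "genome-wide",
    include_updown: bool = True,
    descriptions: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Candidate-gene records from an annotated site table.

    One output row per (gene, variant) pair, deduplicated, sorted by tier
    then genomic position. ``mode="interval-restricted"`` keeps only
    variants inside the supplied candidate intervals; ``descriptions`` is an
    optional gene-id -> text sidecar passed through to the output.
    """
    if mode not in ("genome-wide", "interval-restricted"):
        raise ValueError("mode must be 'genome-wide' or 'interval-restricted'")
    rows = []
    for r in annotated.itertuples(index=False):
        tier = _tier(r.location, r.exonic_effect)
        if tier == 0 or (tier == 3 and not include_updown):
            continue
        in_interval = False
        if intervals is not None and len(intervals):
            for iv in intervals.itertuples(index=False):
                if iv.chrom == r.chrom and iv.start < r.pos <= iv.end:
                    in_interval = True
                    break
        if mode == "interval-restricted" and not in_interval:
            continue
        consequence = r.exonic_effect if r.location == "exonic" else r.location
        for gid in (r.gene_ids.split(",") if r.gene_ids else []):
            rows.append(
                {
                    "gene_id": gid,
                    "variant_class": "SNP" if variant_type(r.ref, r.alt) == "SNP" else "InDel",
                    "tier": tier,
                    "consequence": consequence,
                    "chrom": r.chrom,
                    "pos": int(r.pos),
                    "ref": r.ref,
                    "alt": r.alt,
                    "in_interval": in_interval,
                    "description": (descriptions or {}).get(gid, ""),
                }
            )
    cols = [
        "gene_id",
        "variant_class",
        "tier",
        "consequence",
        "chrom",
        "pos",
        "ref",
        "alt",
        "in_interval",
        "description",
    ]
    out = pd.DataFrame(rows, columns=cols)
    out = out.drop_duplicates(subset=["gene_id", "chrom", "pos", "ref", "alt"])
    return out.sort_values(["tier", "chrom", "pos", "gene_id"], kind="mergesort").reset_index(
        drop=True
    )


def summarize_screen(records: pd.DataFrame) -> dict:
    """Locus and gene counts for a candidate screen."""
    loci = records.drop_duplicates(["chrom", "pos", "ref", "alt"])
    by_class = loci.groupby("variant_class")["pos"].count().to_dict() if len(records) else {}
    per_chrom = (
        records.groupby("chrom")["gene_id"].nunique().to_dict() if len(records) else {}
    )
    return {
        "n_candidate_loci": int(len(loci)),
        "n_loci_by_class": {k: int(v) for k, v in by_class.items()},
        "n_candidate_genes": int(records["gene_id"].nunique()) if len(records) else 0,
        "n_annotated_genes": int(
            records.loc[records["description"] != "", "gene_id"].nunique()
        )
        if len(records)
        else 0,
        "genes_per_chromosome": {k: int(v) for k, v in per_chrom.items()},
    }
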