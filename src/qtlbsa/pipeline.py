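"""End-to-end pipeline: phenotypes -> annotation -> scans -> candidate genes.

``run_pipeline`` consumes a :class:`~qtlbsa.config.PipelineConfig`, executes
every stage on the three variant classes (SNP, InDel, All), writes all
tables (deterministically: fixed float formats, sorted JSON keys, no
timestamps) and returns a manifest of parameters and per-stage counts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as qio
from .annotate import annotate_variants, annotation_census
from .association import DeltaIndexScan, simulate_null_ci, default_depth_grid, compute_indices, filter_records, effective_depth
from .candidates import screen_candidates, summarize_screen
from .config import PipelineConfig
from .phenotypes import add_shape_index, screen_extremes, summarize_table
from .published import PARENT_TRAIT_MEANS

logger = logging.getLogger("qtlbsa")

__version__ = "0.1.0"


def phred_error(q: float) -> float:
    """Base-calling error probability at Phred quality q: 10^(-q/10)."""
    if q < 0:
        raise ValueError("quality scores are non-negative")
    return 10.0 ** (-q / 10.0)


def _check_chroms(vcf_chroms, gff_chroms) -> None:
    unknown = sorted(set(vcf_chroms) - set(gff_chroms))
    if unknown:
        raise ValueError(
            "chromosome names in the VCF are absent from the annotation: "
            + ", ".join(unknown)
        )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all outputs under ``config.out_dir``.

    Returns the manifest (also written as ``manifest.json``). A VCF with no
    usable variants produces empty outputs plus a manifest warning.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    roles = config.samples
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "window": config.window,
            "step": config.step,
            "min_index": config.min_index,
            "min_depth": config.min_depth,
            "flank": config.flank,
            "splice_window": config.splice_window,
            "ci_level": config.ci_level,
            "n_sims": config.n_sims,
            "pool_size": config.pool_size,
            "seg_model": config.seg_model,
            "candidate_mode": config.candidate_mode,
        },
        "samples": roles.as_dict(),
        "counts": {},
        "warnings": [],
    }

    # --- phenotypes -------------------------------------------------------
    phenos = qio.read_phenotypes(config.phenotypes)
    if "fruit_shape_index" not in phenos.columns:
        phenos = add_shape_index(phenos)
    traits = summarize_table(phenos, PARENT_TRAIT_MEANS)
    qio.write_table(traits, out / "trait_summary.tsv")
    screen = screen_extremes(phenos, n=config.pool_size)
    pools = pd.DataFrame(
        {
            "line_id": screen.large_ids + screen.small_ids,
            "pool": ["large"] * len(screen.large_ids) + ["small"] * len(screen.small_ids),
        }
    )
    qio.write_table(pools, out / "pools.tsv")
    qio.write_table(screen.summary, out / "pool_summary.tsv")
    manifest["counts"]["phenotyped_lines"] = int(len(phenos))

    # --- variants and annotation -----------------------------------------
    sites = qio.read_vcf(config.vcf)
    chrom_sizes = qio.read_vcf_chrom_sizes(config.vcf)
    genes = qio.read_gff3(config.gff3)
    manifest["counts"]["variants"] = int(len(sites))
    if len(sites) == 0:
        manifest["warnings"].append("VCF contains no usable variants; outputs are empty")
        _write_manifest(manifest, out)
        return manifest
    _check_chroms(sites["chrom"].unique(), {g.chrom for g in genes})
    genome = qio.read_fasta(config.fasta) if config.fasta else None
    annotated = annotate_variants(
        sites, genes, genome=genome, flank=config.flank, splice_window=config.splice_window
    )
    qio.write_table(annotated, out / "annotated_variants.tsv")
    census = annotation_census(annotated)
    manifest["counts"]["annotation"] = census

    # --- association scans ------------------------------------------------
    seed_seq = np.random.SeedSequence(config.seed)
    ci_seed = int(seed_seq.generate_state(1)[0] % (2**31))
    records_all = filter_records(
        compute_indices(sites, roles.pool_large, roles.pool_small),
        config.min_index,
        config.min_depth,
    )
    grid = default_depth_grid(
        effective_depth(records_all) if len(records_all) else np.array([10.0, 100.0])
    )
    ci = simulate_null_ci(
        grid,
        pool_size=config.pool_size,
        seg_model=config.seg_model,
        n_sims=config.n_sims,
        seed=ci_seed,
        min_index=config.min_index,
        min_depth=config.min_depth,
    )
    interval_frames = {}
    for vclass in ("SNP", "InDel", "All"):
        model = DeltaIndexScan(
            sites,
            chrom_sizes,
            large=roles.pool_large,
            small=roles.pool_small,
            pool_size=config.pool_size,
            seg_model=config.seg_model,
            variant_class=vclass,
            window=config.window,
            step=config.step,
            min_index=config.min_index,
            min_depth=config.min_depth,
            min_abs_delta=config.min_abs_delta,
        )
        res = model.fit(level=config.ci_level, ci=ci)
        tag = vclass.lower()
        qio.write_table(res.windows, out / f"scan_{tag}.tsv")
        iv = res.intervals(genes)
        qio.write_table(iv, out / f"intervals_{tag}.tsv")
        qio.intervals_to_bed(iv, out / f"intervals_{tag}.bed")
        interval_frames[vclass] = iv
        manifest["counts"][f"sites_{tag}"] = {
            "raw": int(res.n_sites_raw),
            "filtered": int(res.n_sites),
        }
        manifest["counts"][f"intervals_{tag}"] = int(len(iv))
        if config.make_plots:
            res.plot(path=out / f"scan_{tag}.png")

    # --- candidate genes --------------------------------------------------
    cands = screen_candidates(
        annotated,
        intervals=interval_frames["All"],
        mode=config.candidate_mode,
        include_updown=config.include_updown,
    )
    qio.write_table(cands, out / "candidates.tsv")
    manifest["counts"]["candidates"] = summarize_screen(cands)

    _write_manifest(manifest, out)
    logger.info("pipeline complete: %s", out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
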