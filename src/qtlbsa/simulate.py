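"""Synthetic F1-cross generator: markers, phenotypes, extreme pools, pooled reads.

The generative model emulates a QTL-seq study of an outbred F1 cross between
two heterozygous woody-perennial parents:

* Markers segregate as a pseudo-testcross by default (``1:1``: heterozygous
  in one parent, homozygous reference in the other; each progeny line
  carries 0 or 1 alternate alleles), or ``1:2:1`` with both parents
  heterozygous.
* The chromosome carrying the QTL is modelled as a single maternal linkage
  group: progeny inherit the informative parent's haplotype as a Markov
  chain along the chromosome with Haldane recombination (``cm_per_mb``
  cM/Mb), and every alternate allele rides the divergent (non-reference)
  haplotype — the coupling-phase configuration under which the raw
  alternate-read fraction is an informative index. All other chromosomes
  are unlinked background noise.
* Phenotype (in SD units) = additive QTL effect x centred dosage + polygenic
  term + Gaussian environmental noise, with variances chosen so that the
  genotypic fraction equals ``h2`` and the total variance is 1.
* Pooled sequencing draws per-site per-pool depths from a Poisson law and
  alternate-read counts from a binomial at the pool's true allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as qio
from .annotate import GeneModel
from .config import ROLES, SimConfig
from .published import PARENT_TRAIT_MEANS, F1_TRAIT_SCALE

_BASES = np.array(list("ACGT"))


@dataclass
class SimTruth:
    """Ground truth of one simulated cross, for recovery tests."""

    config: SimConfig
    markers: pd.DataFrame  # chrom, pos, vtype, ref, alt, het_parent
    genotypes: np.ndarray  # (n_progeny, n_markers) dosage of the alt allele
    phenotype: np.ndarray  # standardized scale (SD units)
    phenos: pd.DataFrame  # line_id + trait columns on measurement scales
    line_ids: np.ndarray
    qtl_dosage: Optional[np.ndarray] = None
    large_pool: list = field(default_factory=list)
    small_pool: list = field(default_factory=list)

    def pool_indices(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.large_pool or not self.small_pool:
            raise RuntimeError("pools not selected yet; call select_pools first")
        id_to_row = {lid: i for i, lid in enumerate(self.line_ids)}
        return (
            np.array([id_to_row[i] for i in self.large_pool]),
            np.array([id_to_row[i] for i in self.small_pool]),
        )

    def truth_dict(self) -> dict:
        c = self.config
        return {
            "seed": c.seed,
            "n_progeny": c.n_progeny,
            "seg_model": c.seg_model,
            "h2": c.h2,
            "qtl": None
            if c.qtl is None
            else {"chrom": c.qtl.chrom, "pos": c.qtl.pos, "effect": c.qtl.effect},
            "n_markers": int(len(self.markers)),
            "large_pool": [int(i) for i in self.large_pool],
            "small_pool": [int(i) for i in self.small_pool],
        }


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


def _haldane(dist_bp: np.ndarray, cm_per_mb: float) -> np.ndarray:
    """Recombination fraction between adjacent loci (Haldane map function)."""
    morgans = cm_per_mb * dist_bp / 1e6 / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * morgans))


def _meiosis_chain(
    rng: np.random.Generator, n_lines: int, positions: np.ndarray, cm_per_mb: float
) -> np.ndarray:
    """Inherited-haplotype indicator (n_lines, n_loci) for one parental meiosis."""
    m = len(positions)
    state0 = rng.integers(0, 2, size=(n_lines, 1), dtype=np.int8)
    if m == 1:
        return state0
    r = _haldane(np.diff(positions.astype(float)), cm_per_mb)
    switches = (rng.random((n_lines, m - 1)) < r).astype(np.int8)
    cum = np.cumsum(switches, axis=1, dtype=np.int32) % 2
    return np.concatenate([state0, (state0 + cum) % 2], axis=1).astype(np.int8)


def _alleles(rng: np.random.Generator, vtypes: np.ndarray) -> tuple[list, list]:
    refs, alts = [], []
    for vt in vtypes:
        base = str(_BASES[rng.integers(0, 4)])
        if vt == "SNP":
            refs.append(base)
            alts.append(str(rng.choice([b for b in "ACGT" if b != base])))
        elif vt == "insertion":
            refs.append(base)
            alts.append(base + "".join(_BASES[rng.integers(0, 4, rng.integers(1, 6))]))
        else:  # deletion
            refs.append(base + "".join(_BASES[rng.integers(0, 4, rng.integers(1, 6))]))
            alts.append(base)
    return refs, alts


def simulate_cross(config: SimConfig) -> SimTruth:
    """Simulate marker genotypes and phenotypes for the full F1 population."""
    rng = _rng(config, 0)
    n = config.n_progeny
    mean_d, var_g = config.dosage_moments()
    qtl = config.qtl
    if qtl is not None and config.h2 == 0 and qtl.effect != 0:
        raise ValueError("h2 = 0 is inconsistent with a nonzero QTL effect")

    marker_frames = []
    geno_blocks = []
    qtl_dosage = None
    for chrom, length in config.chromosomes:
        n_m = round(config.marker_density * length / 1e6)
        grid = np.arange(1, max(length - 12, 2), 12)
        pos = np.sort(rng.choice(grid, size=min(n_m, len(grid)), replace=False))
        vtypes = np.where(
            rng.random(len(pos)) < config.snp_fraction, "SNP", "indel"
        ).astype(object)
        indel_kind = rng.random(len(pos)) < 0.5
        vtypes[vtypes == "indel"] = np.where(
            indel_kind[vtypes == "indel"], "insertion", "deletion"
        )
        refs, alts = _alleles(rng, vtypes)

        on_qtl_chrom = qtl is not None and chrom == qtl.chrom
        if on_qtl_chrom:
            # one maternal linkage group: chain over markers + the QTL locus
            all_pos = np.sort(np.unique(np.append(pos, qtl.pos)))
            chain = _meiosis_chain(rng, n, all_pos, config.cm_per_mb)
            qtl_col = int(np.searchsorted(all_pos, qtl.pos))
            marker_cols = np.searchsorted(all_pos, pos)
            if config.seg_model == "1:1":
                dos = chain[:, marker_cols]
                qtl_dosage = chain[:, qtl_col].copy()
                het_parent = np.ones(len(pos), dtype=np.int8)
            else:
                chain2 = _meiosis_chain(rng, n, all_pos, config.cm_per_mb)
                dos = chain[:, marker_cols] + chain2[:, marker_cols]
                qtl_dosage = (chain[:, qtl_col] + chain2[:, qtl_col]).copy()
                het_parent = np.zeros(len(pos), dtype=np.int8)  # 0 = both
        else:
            if config.seg_model == "1:1":
                dos = rng.integers(0, 2, size=(n, len(pos)), dtype=np.int8)
                het_parent = rng.integers(1, 3, size=len(pos)).astype(np.int8)
            else:
                dos = rng.binomial(2, 0.5, size=(n, len(pos))).astype(np.int8)
                het_parent = np.zeros(len(pos), dtype=np.int8)
        marker_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos.astype(np.int64),
                    "vtype": vtypes,
                    "ref": refs,
                    "alt": alts,
                    "het_parent": het_parent,
                }
            )
        )
        geno_blocks.append(dos)

    markers = pd.concat(marker_frames, ignore_index=True)
    genotypes = np.concatenate(geno_blocks, axis=1)

    # phenotype on the standardized scale: total variance 1, genotypic
    # fraction h2, QTL allele-substitution effect in SD units
    if qtl is not None and qtl.effect != 0:
        var_qtl = qtl.effect**2 * var_g
        genetic = qtl.effect * (qtl_dosage.astype(float) - mean_d)
    else:
        var_qtl = 0.0
        genetic = np.zeros(n)
    poly_sd = float(np.sqrt(max(config.h2 - var_qtl, 0.0)))
    env_sd = float(np.sqrt(1.0 - config.h2))
    z = genetic + rng.normal(0.0, poly_sd, n) + rng.normal(0.0, env_sd, n)

    line_ids = np.arange(1, n + 1)
    w_mu, w_sd = F1_TRAIT_SCALE["single_fruit_weight_g"]
    l_mu, l_sd = F1_TRAIT_SCALE["fruit_length_mm"]
    d_mu, d_sd = F1_TRAIT_SCALE["fruit_diameter_mm"]
    e1 = rng.normal(0, 1, n)
    e2 = rng.normal(0, 1, n)
    weight = np.maximum(w_mu + w_sd * z, 0.5)
    length = np.maximum(l_mu + l_sd * (0.8 * z + 0.6 * e1), 5.0)
    diam = np.maximum(d_mu + d_sd * (0.8 * z + 0.6 * e2), 5.0)
    phenos = pd.DataFrame(
        {
            "line_id": line_ids,
            "single_fruit_weight_g": weight,
            "fruit_length_mm": length,
            "fruit_diameter_mm": diam,
            "fruit_shape_index": length / diam,
        }
    )
    return SimTruth(
        config=config,
        markers=markers,
        genotypes=genotypes,
        phenotype=z,
        phenos=phenos,
        line_ids=line_ids,
        qtl_dosage=qtl_dosage,
    )


def select_pools(
    truth: SimTruth, pool_size: Optional[int] = None
) -> tuple[list, list]:
    """Extreme pools: top/bottom ``pool_size`` lines by phenotype.

    Ties are broken deterministically by line id (ascending). The selection
    is recorded on ``truth`` and returned as (large_ids, small_ids).
    """
    k = pool_size if pool_size is not None else truth.config.pool_size
    n = len(truth.line_ids)
    if 2 * k > n:
        raise ValueError("pool_size x 2 exceeds the number of progeny lines")
    order = np.lexsort((truth.line_ids, truth.phenotype))
    small = [int(truth.line_ids[i]) for i in order[:k]]
    large = [int(truth.line_ids[i]) for i in order[::-1][:k]]
    truth.large_pool, truth.small_pool = large, small
    return large, small


def simulate_pool_reads(truth: SimTruth, config: Optional[SimConfig] = None) -> pd.DataFrame:
    """Pooled and parental read counts at every marker site.

    Per pool and site: depth ~ Poisson(depth_mean); alternate reads ~
    Binomial(depth, p) with p the pool's true alternate-allele frequency
    (mean pooled dosage / 2), optionally perturbed by a symmetric error
    rate. Parents are sampled the same way at parental depth from their
    known genotypes. Returns a site table ready for :func:`qtlbsa.io.write_vcf`.
    """
    config = config or truth.config
    rng = _rng(config, 1)
    large_idx, small_idx = truth.pool_indices()
    m = len(truth.markers)
    p_large = truth.genotypes[large_idx].mean(axis=0) / 2.0
    p_small = truth.genotypes[small_idx].mean(axis=0) / 2.0
    het = truth.markers["het_parent"].to_numpy()
    if config.seg_model == "1:1":
        p_f = np.where(het == 1, 0.5, 0.0)
        p_m = np.where(het == 2, 0.5, 0.0)
    else:
        p_f = np.full(m, 0.5)
        p_m = np.full(m, 0.5)

    e = config.error_rate

    def read_pair(p: np.ndarray, depth_mean: float) -> tuple[np.ndarray, np.ndarray]:
        depth = rng.poisson(depth_mean, m)
        p_obs = p * (1 - 2 * e) + e
        alt = rng.binomial(depth, p_obs)
        return depth - alt, alt

    sites = truth.markers[["chrom", "pos", "vtype", "ref", "alt"]].copy()
    for role, (p, d) in zip(
        ROLES,
        [
            (p_f, config.parent_depth_mean),
            (p_m, config.parent_depth_mean),
            (p_large, config.depth_mean),
            (p_small, config.depth_mean),
        ],
    ):
        ref_c, alt_c = qio.sample_columns(role)
        sites[ref_c], sites[alt_c] = read_pair(p, d)
    return sites


# ---------------------------------------------------------------------------
# genome sequence and gene models (for annotation-bearing runs)
# ---------------------------------------------------------------------------


def generate_genome(
    markers: pd.DataFrame,
    chromosomes: Sequence[tuple[str, int]],
    rng: np.random.Generator,
) -> dict[str, str]:
    """Random genome with every marker's reference allele planted in place."""
    genome = {}
    for chrom, length in chromosomes:
        arr = _BASES[rng.integers(0, 4, length)]
        sub = markers[markers["chrom"] == chrom]
        for pos, ref in zip(sub["pos"], sub["ref"]):
            arr[pos - 1 : pos - 1 + len(ref)] = list(ref)
        genome[chrom] = "".join(arr)
    return genome


def generate_gene_models(
    chromosomes: Sequence[tuple[str, int]],
    genes_per_mb: float,
    rng: np.random.Generator,
) -> list[GeneModel]:
    """Place non-overlapping single-transcript gene models along the genome.

    Coding length is always a multiple of 3; CDS spans the full exons (no
    UTRs in this data model). Strand and exon count are random.
    """
    genes = []
    for chrom, length in chromosomes:
        n_genes = max(0, round(genes_per_mb * length / 1e6))
        if n_genes == 0:
            continue
        spacing = length // (n_genes + 1)
        for i in range(n_genes):
            anchor = spacing * (i + 1)
            n_exons = int(rng.integers(1, 4))
            exons = []
            pos = anchor
            for j in range(n_exons):
                elen = 3 * int(rng.integers(40, 150))
                exons.append((pos + 1, pos + elen))
                pos += elen + int(rng.integers(100, 400))
            if exons[-1][1] >= length:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"gene_{chrom}_{i + 1:04d}",
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    cds=exons,
                )
            )
    return genes


def simulate_bundle(config: SimConfig, out_dir: str | Path) -> dict:
    """Run the full simulator and write a complete input bundle.

    Writes a 4-sample VCF, GFF3 gene models, the genome FASTA, the per-line
    phenotype TSV and a ground-truth JSON into ``out_dir``; returns the
    paths plus the in-memory truth object. Intended for modest genome sizes
    (the FASTA is written in full).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = simulate_cross(config)
    select_pools(truth)
    sites = simulate_pool_reads(truth)
    genome = generate_genome(truth.markers, config.chromosomes, _rng(config, 2))
    genes = generate_gene_models(config.chromosomes, config.genes_per_mb, _rng(config, 3))

    paths = {
        "vcf": out / "pools.vcf",
        "gff3": out / "genes.gff3",
        "fasta": out / "genome.fa",
        "phenotypes": out / "phenotypes.tsv",
        "truth": out / "truth.json",
    }
    qio.write_vcf(sites, paths["vcf"], samples=list(ROLES), chrom_sizes=dict(config.chromosomes))
    qio.write_gff3(genes, paths["gff3"])
    qio.write_fasta(genome, paths["fasta"])
    qio.write_phenotypes(truth.phenos, paths["phenotypes"])
    qio.write_truth(truth.truth_dict(), paths["truth"])
    return {"paths": paths, "truth": truth, "sites": sites, "genes": genes, "genome": genome}
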