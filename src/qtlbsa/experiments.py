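"""Canonical evaluation scenarios for the package's statistical guarantees.

Three seeded, self-contained experiments exercise the full stack on the
synthetic cross at its default study design (284 F1 lines, 30-line pools,
40x pooled depth, 1:1 pseudo-testcross segregation):

* :func:`null_calibration` — no-QTL genome; measures the fraction of
  filtered sites whose delta falls outside the simulated 95% envelope
  (should be ~5%).
* :func:`qtl_recovery` — one planted 1-SD QTL at h2 = 0.6; measures how
  often the called candidate intervals cover the true QTL position across
  replicates, and how far the peak window sits from it.
* :func:`oracle_agreement` — the codon-local consequence classifier versus
  whole-protein retranslation on randomized coding variants.
"""

from __future__ import annotations

import numpy as np

from .association import DeltaIndexScan
from .annotate import classify_exonic_effect
from .config import QtlSpec, SimConfig
from .simulate import select_pools, simulate_cross, simulate_pool_reads
from .validation import make_toy_locus, random_coding_variants, retranslation_effect


def _sub_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([int(seed), tag]).generate_state(1)[0] % (2**31))


def null_calibration(
    seed: int,
    n_chromosomes: int = 10,
    chrom_mb: float = 25.0,
    marker_density: float = 450.0,
    depth_mean: float = 40.0,
    n_sims: int = 20_000,
    level: float = 0.95,
) -> dict:
    """Site-level exceedance of the null envelope on a QTL-free genome."""
    cfg = SimConfig(
        chromosomes=[(f"chr{i + 1}", int(chrom_mb * 1e6)) for i in range(n_chromosomes)],
        marker_density=marker_density,
        qtl=None,
        depth_mean=depth_mean,
        seed=_sub_seed(seed, 1),
    )
    truth = simulate_cross(cfg)
    select_pools(truth)
    sites = simulate_pool_reads(truth)
    model = DeltaIndexScan(
        sites, dict(cfg.chromosomes), pool_size=cfg.pool_size, variant_class="All"
    )
    res = model.fit(n_sims=n_sims, seed=_sub_seed(seed, 2), level=level)
    return {
        "exceedance_pct": 100.0 * res.site_exceedance(level),
        "n_sites": res.n_sites,
        "n_sites_raw": res.n_sites_raw,
        "significant_window_fraction": float(res.windows["significant"].mean()),
    }


def qtl_recovery(
    seed: int,
    n_replicates: int = 20,
    effect: float = 1.0,
    h2: float = 0.6,
    depth_mean: float = 40.0,
    marker_density: float = 150.0,
    n_sims: int = 20_000,
) -> dict:
    """Interval coverage and peak localization of a planted QTL across replicates."""
    covered = 0
    peak_within_2mb = 0
    ci = None
    for rep in range(n_replicates):
        cfg = SimConfig(
            qtl=QtlSpec("chr1", 15_000_000, effect),
            h2=h2,
            depth_mean=depth_mean,
            marker_density=marker_density,
            seed=_sub_seed(seed, 100 + rep),
        )
        truth = simulate_cross(cfg)
        select_pools(truth)
        sites = simulate_pool_reads(truth)
        model = DeltaIndexScan(
            sites, dict(cfg.chromosomes), pool_size=cfg.pool_size, variant_class="SNP"
        )
        if ci is None:
            res = model.fit(n_sims=n_sims, seed=_sub_seed(seed, 3))
            ci = res.ci  # same design every replicate: reuse the envelope
        else:
            res = model.fit(ci=ci)
        iv = res.intervals()
        covered += any(
            (r.chrom == cfg.qtl.chrom) and (r.start < cfg.qtl.pos <= r.end)
            for r in iv.itertuples()
        )
        w = res.windows.dropna(subset=["mean_delta"])
        peak = w.loc[w["mean_delta"].abs().idxmax()]
        mid = (peak["start"] + peak["end"]) / 2.0
        peak_within_2mb += (peak["chrom"] == cfg.qtl.chrom) and abs(mid - cfg.qtl.pos) <= 2e6
    return {
        "coverage_pct": 100.0 * covered / n_replicates,
        "peak_within_2mb_pct": 100.0 * peak_within_2mb / n_replicates,
        "n_replicates": n_replicates,
    }


def oracle_agreement(seed: int, n_variants: int = 1_200) -> dict:
    """Agreement of the coding-consequence classifier with the retranslation oracle."""
    rng = np.random.default_rng(_sub_seed(seed, 4))
    per_locus = max(1, n_variants // 6)
    n_total = 0
    n_agree = 0
    for strand in ("+", "-"):
        for rep in range(3):
            gene, genome = make_toy_locus(
                rng, chrom=f"t{strand}{rep}", strand=strand, n_codons=80, n_exons=3
            )
            for v in random_coding_variants(gene, genome, per_locus, rng):
                got = classify_exonic_effect(
                    v["chrom"], v["pos"], v["ref"], v["alt"], gene, genome
                )
                want = retranslation_effect(
                    v["chrom"], v["pos"], v["ref"], v["alt"], gene, genome
                )
                n_total += 1
                n_agree += got == want
    return {"agreement_pct": 100.0 * n_agree / n_total, "n_variants": n_total}
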