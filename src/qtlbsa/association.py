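"""Pooled-read index statistics, sliding-window genome scan and interval calling.

The statistic is the classic bulked-segregant index: at each biallelic site
the per-pool index is the alternate-read fraction alt/(ref+alt), and

    delta = index(large pool) - index(small pool)

is ~0 at loci unlinked to the trait and moves toward the segregation-model
extremes at a causal locus. Sites are filtered with the standard rules
(drop when both pool indices are below ``min_index``, when both pool depths
are below ``min_depth``, or when either index is missing), then scanned
with a sliding window (1 Mb window, 1 kb step by default) whose mean delta
is compared to a null confidence envelope obtained by simulating pools of
the configured size under the no-QTL segregation model at matched read
depth.

The modelling surface follows the statsmodels convention: build a
:class:`DeltaIndexScan` from data, call :meth:`~DeltaIndexScan.fit`, and
read estimates, envelopes, intervals and ``summary()`` off the returned
:class:`DeltaIndexScanResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as qio
from .annotate import GeneModel

DEFAULT_WINDOW = 1_000_000
DEFAULT_STEP = 1_000
DEFAULT_MIN_INDEX = 0.3
DEFAULT_MIN_DEPTH = 7


# ---------------------------------------------------------------------------
# per-site records
# ---------------------------------------------------------------------------


def compute_indices(sites: pd.DataFrame, large: str, small: str) -> pd.DataFrame:
    """Per-site pool indices and delta from a site table.

    ``large``/``small`` are the sample names of the two pools. The index is
    missing (NaN) wherever a pool has zero depth; missingness is handled by
    :func:`filter_records`, not here.
    """
    lr, la = qio.sample_columns(large)
    sr, sa = qio.sample_columns(small)
    rec = sites.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        dl = rec[lr].to_numpy(float) + rec[la].to_numpy(float)
        ds = rec[sr].to_numpy(float) + rec[sa].to_numpy(float)
        il = np.where(dl > 0, rec[la].to_numpy(float) / np.where(dl > 0, dl, 1), np.nan)
        isml = np.where(ds > 0, rec[sa].to_numpy(float) / np.where(ds > 0, ds, 1), np.nan)
    rec["depth_large"] = dl.astype(int)
    rec["depth_small"] = ds.astype(int)
    rec["index_large"] = il
    rec["index_small"] = isml
    rec["delta"] = il - isml
    return rec


def filter_records(
    records: pd.DataFrame,
    min_index: float = DEFAULT_MIN_INDEX,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> pd.DataFrame:
    """Apply the three standard site filters.

    A record is dropped iff (both indices < ``min_index``) OR (both depths <
    ``min_depth``) OR (either index missing). Idempotent.
    """
    il = records["index_large"]
    ism = records["index_small"]
    dl = records["depth_large"]
    ds = records["depth_small"]
    drop = (
        ((il < min_index) & (ism < min_index))
        | ((dl < min_depth) & (ds < min_depth))
        | il.isna()
        | ism.isna()
    )
    return records.loc[~drop].reset_index(drop=True)


def effective_depth(records: pd.DataFrame) -> np.ndarray:
    """Per-site mean of the two pool depths.

    This is the scalar on which the null envelope is conditioned: the null
    simulation draws each pool's depth from a Poisson law around a nominal
    per-pool depth, so a site's envelope is looked up at the nominal depth
    its observed pair averages to. (Conditioning on the pair mean rather
    than, say, the harmonic mean matters because the index filter interacts
    with unequal depth pairs: the lower-depth pool's index is noisier, and
    surviving sites have heavier delta tails than balanced pairs would.)
    """
    dl = records["depth_large"].to_numpy(float)
    ds = records["depth_small"].to_numpy(float)
    return (dl + ds) / 2.0


# ---------------------------------------------------------------------------
# simulated null confidence envelope
# ---------------------------------------------------------------------------


@dataclass
class CiLookup:
    """Empirical null quantiles of delta indexed by nominal per-pool depth."""

    depths: np.ndarray
    levels: tuple[float, ...]
    lo: dict[float, np.ndarray]
    hi: dict[float, np.ndarray]
    pool_size: int
    seg_model: str
    n_sims: int

    def bounds(self, depth: np.ndarray | float, level: float) -> tuple[np.ndarray, np.ndarray]:
        """CI bounds at arbitrary depth, interpolated linearly in 1/depth."""
        if level not in self.lo:
            raise KeyError(f"level {level} not simulated (have {self.levels})")
        d = np.clip(np.atleast_1d(np.asarray(depth, float)), self.depths[0], self.depths[-1])
        x = 1.0 / d
        xg = 1.0 / self.depths[::-1]  # increasing in 1/depth
        lo = np.interp(x, xg, self.lo[level][::-1])
        hi = np.interp(x, xg, self.hi[level][::-1])
        return lo, hi


def _null_pool_freq(
    rng: np.random.Generator, pool_size: int, seg_model: str, n: int
) -> np.ndarray:
    """True alt-allele frequency of a random pool under the no-QTL model."""
    if seg_model == "1:1":
        return rng.binomial(pool_size, 0.5, n) / (2.0 * pool_size)
    return rng.binomial(2 * pool_size, 0.5, n) / (2.0 * pool_size)


def simulate_null_ci(
    depth_grid: Sequence[float],
    pool_size: int,
    seg_model: str = "1:1",
    n_sims: int = 10_000,
    levels: Sequence[float] = (0.95, 0.99),
    seed: Optional[int] = None,
    min_index: Optional[float] = DEFAULT_MIN_INDEX,
    min_depth: Optional[int] = DEFAULT_MIN_DEPTH,
) -> CiLookup:
    """Monte-Carlo null envelope of delta at each nominal depth on a grid.

    For each nominal per-pool depth d: draw two pools of ``pool_size``
    progeny under the no-QTL segregation model, draw each pool's realized
    depth from Poisson(d), sample alternate reads binomially at the pool's
    true allele frequency, compute delta, and apply the same site filters
    the real pipeline applies — so the envelope is the conditional null
    distribution of *surviving* sites, unequal depth pairs included. CI
    bounds are the empirical (1 +/- level)/2 quantiles.
    """
    if n_sims < 1_000:
        raise ValueError("n_sims too small: need at least 1,000 per depth")
    rng = np.random.default_rng(seed)
    depths = np.sort(np.unique(np.asarray(depth_grid, float)))
    lo = {lev: np.empty(len(depths)) for lev in levels}
    hi = {lev: np.empty(len(depths)) for lev in levels}
    for i, d in enumerate(depths):
        pl = _null_pool_freq(rng, pool_size, seg_model, n_sims)
        ps = _null_pool_freq(rng, pool_size, seg_model, n_sims)
        dl = rng.poisson(d, n_sims)
        ds = rng.poisson(d, n_sims)
        ok = (dl > 0) & (ds > 0)  # zero depth = missing index = filtered
        pl, ps, dl, ds = pl[ok], ps[ok], dl[ok], ds[ok]
        il = rng.binomial(dl, pl) / dl
        ism = rng.binomial(ds, ps) / ds
        keep = np.ones(len(il), dtype=bool)
        if min_index is not None:
            keep &= ~((il < min_index) & (ism < min_index))
        if min_depth is not None:
            keep &= ~((dl < min_depth) & (ds < min_depth))
        delta = (il - ism)[keep]
        if delta.size < 100:
            raise ValueError(
                f"nearly all null draws at depth {d} were filtered out; "
                "raise n_sims or adjust the depth grid"
            )
        for lev in levels:
            a = (1.0 - lev) / 2.0
            lo[lev][i] = np.quantile(delta, a)
            hi[lev][i] = np.quantile(delta, 1.0 - a)
    return CiLookup(
        depths=depths,
        levels=tuple(levels),
        lo=lo,
        hi=hi,
        pool_size=pool_size,
        seg_model=seg_model,
        n_sims=n_sims,
    )


def default_depth_grid(
    eff_depths: np.ndarray, d_min: float = 4.0, d_max: Optional[float] = None
) -> np.ndarray:
    """Geometric depth grid (ratio ~sqrt(2)) spanning the observed depths."""
    finite = eff_depths[np.isfinite(eff_depths)]
    hi = float(d_max if d_max is not None else (finite.max() if finite.size else 100.0))
    hi = max(hi, d_min * 2)
    grid = [d_min]
    while grid[-1] < hi:
        grid.append(grid[-1] * np.sqrt(2.0))
    grid[-1] = hi
    return np.unique(np.round(grid, 2))


# ---------------------------------------------------------------------------
# sliding-window scan
# ---------------------------------------------------------------------------


def _window_starts(length: int, window: int, step: int) -> np.ndarray:
    if length <= window:
        return np.array([0], dtype=np.int64)
    n_full = (length - window) // step + 1
    starts = np.arange(n_full, dtype=np.int64) * step
    if (length - window) % step:
        starts = np.append(starts, n_full * step)  # final truncated window
    return starts


def sliding_window_scan(
    records: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    ci: Optional[CiLookup] = None,
    level: float = 0.95,
    depth_stat: str = "harmonic",
    min_abs_delta: float = 0.0,
) -> pd.DataFrame:
    """Mean delta in sliding windows of ``window`` bp stepped by ``step`` bp.

    Windows are half-open ``[start, end)`` on the 0-based coordinate line
    (a 1-based site at position p falls in the window iff start < p <= end).
    Windows with no sites carry NaN statistics and are never significant.
    With a :class:`CiLookup`, each window gains envelope bounds evaluated at
    its aggregate depth (harmonic mean of per-site effective depths by
    default, arithmetic mean with ``depth_stat="mean"``) and a significance
    flag: mean delta outside the envelope and |mean| >= ``min_abs_delta``.
    """
    if window < step or step <= 0:
        raise ValueError("require window >= step > 0")
    if depth_stat not in ("harmonic", "mean"):
        raise ValueError("depth_stat must be 'harmonic' or 'mean'")
    frames = []
    for chrom in chrom_sizes:
        length = int(chrom_sizes[chrom])
        sub = records[records["chrom"] == chrom].sort_values("pos")
        pos = sub["pos"].to_numpy(np.int64)
        delta = sub["delta"].to_numpy(float)
        eff = effective_depth(sub) if len(sub) else np.empty(0)
        starts = _window_starts(length, window, step)
        ends = np.minimum(starts + window, length)
        lo_i = np.searchsorted(pos, starts, side="right")
        hi_i = np.searchsorted(pos, ends, side="right")
        cnt = hi_i - lo_i
        cs_delta = np.concatenate([[0.0], np.cumsum(delta)])
        mean_delta = np.full(len(starts), np.nan)
        nz = cnt > 0
        mean_delta[nz] = (cs_delta[hi_i[nz]] - cs_delta[lo_i[nz]]) / cnt[nz]
        if depth_stat == "harmonic":
            cs_inv = np.concatenate([[0.0], np.cumsum(1.0 / eff)])
            wdep = np.full(len(starts), np.nan)
            wdep[nz] = cnt[nz] / (cs_inv[hi_i[nz]] - cs_inv[lo_i[nz]])
        else:
            cs_d = np.concatenate([[0.0], np.cumsum(eff)])
            wdep = np.full(len(starts), np.nan)
            wdep[nz] = (cs_d[hi_i[nz]] - cs_d[lo_i[nz]]) / cnt[nz]
        frame = pd.DataFrame(
            {
                "chrom": chrom,
                "start": starts,
                "end": ends,
                "n_sites": cnt,
                "mean_delta": mean_delta,
                "eff_depth": wdep,
            }
        )
        frames.append(frame)
    scan = pd.concat(frames, ignore_index=True)
    if ci is not None:
        for lev in ci.levels:
            lo, hi = ci.bounds(np.where(np.isnan(scan["eff_depth"]), ci.depths[-1], scan["eff_depth"]), lev)
            pct = int(round(lev * 100))
            scan[f"ci{pct}_low"] = lo
            scan[f"ci{pct}_high"] = hi
        pct = int(round(level * 100))
        md = scan["mean_delta"]
        scan["significant"] = (
            (scan["n_sites"] > 0)
            & ((md < scan[f"ci{pct}_low"]) | (md > scan[f"ci{pct}_high"]))
            & (md.abs() >= min_abs_delta)
        )
    return scan


def call_intervals(
    scan: pd.DataFrame, genes: Optional[Sequence[GeneModel]] = None
) -> pd.DataFrame:
    """Merge overlapping/abutting significant windows into candidate intervals.

    Returns one row per maximal interval with its size in Mb, the window
    count, the peak |mean delta|, and (when gene models are supplied) the
    ids and number of genes whose span intersects the interval.
    """
    cols = [
        "chrom",
        "start",
        "end",
        "size_mb",
        "n_windows",
        "peak_delta",
        "n_genes",
        "gene_ids",
    ]
    if "significant" not in scan.columns:
        raise ValueError("scan has no significance flags; fit with a CI envelope first")
    sig = scan[scan["significant"]].sort_values(["chrom", "start"])
    rows = []
    for chrom, sub in sig.groupby("chrom", sort=True):
        cur = None
        for r in sub.itertuples(index=False):
            if cur is not None and r.start <= cur["end"]:
                cur["end"] = max(cur["end"], int(r.end))
                cur["n_windows"] += 1
                if abs(r.mean_delta) > abs(cur["peak_delta"]):
                    cur["peak_delta"] = float(r.mean_delta)
            else:
                if cur is not None:
                    rows.append(cur)
                cur = {
                    "chrom": chrom,
                    "start": int(r.start),
                    "end": int(r.end),
                    "n_windows": 1,
                    "peak_delta": float(r.mean_delta),
                }
        if cur is not None:
            rows.append(cur)
    for row in rows:
        row["size_mb"] = interval_size_mb(row["start"], row["end"])
        gids = []
        if genes is not None:
            for g in genes:
                # interval is half-open [start, end); gene span 1-based inclusive
                if g.chrom == row["chrom"] and g.start <= row["end"] and g.end > row["start"]:
                    gids.append(g.gene_id)
        row["gene_ids"] = ",".join(gids)
        row["n_genes"] = len(gids)
    return pd.DataFrame(rows, columns=cols)


def interval_size_mb(start: int, end: int) -> float:
    """Interval size in Mb under the half-open convention: (end - start)/1e6."""
    return (end - start) / 1e6


def all_index_records(
    snp_records: pd.DataFrame, indel_records: pd.DataFrame
) -> pd.DataFrame:
    """Union of filtered SNP and InDel records for the combined-index scan."""
    both = pd.concat([snp_records, indel_records], ignore_index=True)
    return both.sort_values(["chrom", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class DeltaIndexScan:
    """Sliding-window delta-index scan model over one class of variants.

    Parameters
    ----------
    sites
        Site table with per-sample read counts (see :mod:`qtlbsa.io`).
    chrom_sizes
        Mapping of chromosome name to length in bp.
    large, small
        Sample names of the large- and small-phenotype pools.
    pool_size, seg_model
        Design of the pools, used by the null simulation.
    variant_class
        "SNP", "InDel" or "All" — which sites enter the scan.
    """

    def __init__(
        self,
        sites: pd.DataFrame,
        chrom_sizes: Mapping[str, int],
        large: str = "pool_large",
        small: str = "pool_small",
        pool_size: int = 30,
        seg_model: str = "1:1",
        variant_class: str = "All",
        window: int = DEFAULT_WINDOW,
        step: int = DEFAULT_STEP,
        min_index: float = DEFAULT_MIN_INDEX,
        min_depth: int = DEFAULT_MIN_DEPTH,
        depth_stat: str = "harmonic",
        min_abs_delta: float = 0.0,
    ):
        if variant_class not in ("SNP", "InDel", "All"):
            raise ValueError("variant_class must be 'SNP', 'InDel' or 'All'")
        if variant_class == "SNP":
            sites = sites[sites["vtype"] == "SNP"]
        elif variant_class == "InDel":
            sites = sites[sites["vtype"] != "SNP"]
        self.sites = sites.reset_index(drop=True)
        self.chrom_sizes = dict(chrom_sizes)
        self.large, self.small = large, small
        self.pool_size = int(pool_size)
        self.seg_model = seg_model
        self.variant_class = variant_class
        self.window, self.step = int(window), int(step)
        self.min_index, self.min_depth = float(min_index), int(min_depth)
        self.depth_stat = depth_stat
        self.min_abs_delta = float(min_abs_delta)
        self.records = compute_indices(self.sites, large, small)

    @classmethod
    def from_vcf(
        cls,
        vcf_path,
        large: str,
        small: str,
        chrom_sizes: Optional[Mapping[str, int]] = None,
        **kwargs,
    ) -> "DeltaIndexScan":
        sites = qio.read_vcf(vcf_path)
        if chrom_sizes is None:
            chrom_sizes = qio.read_vcf_chrom_sizes(vcf_path)
            if not chrom_sizes:
                raise ValueError(
                    "VCF header has no contig lengths; pass chrom_sizes explicitly"
                )
        return cls(sites, chrom_sizes, large=large, small=small, **kwargs)

    def fit(
        self,
        levels: Sequence[float] = (0.95, 0.99),
        level: float = 0.95,
        n_sims: int = 10_000,
        depth_grid: Optional[Sequence[float]] = None,
        ci: Optional[CiLookup] = None,
        seed: Optional[int] = None,
    ) -> "DeltaIndexScanResults":
        """Filter sites, simulate the null envelope and run the window scan."""
        filtered = filter_records(self.records, self.min_index, self.min_depth)
        eff = effective_depth(filtered) if len(filtered) else np.array([10.0, 100.0])
        if ci is None:
            if depth_grid is None:
                depth_grid = default_depth_grid(eff)
            ci = simulate_null_ci(
                depth_grid,
                pool_size=self.pool_size,
                seg_model=self.seg_model,
                n_sims=n_sims,
                levels=levels,
                seed=seed,
                min_index=self.min_index,
                min_depth=self.min_depth,
            )
        scan = sliding_window_scan(
            filtered,
            self.chrom_sizes,
            window=self.window,
            step=self.step,
            ci=ci,
            level=level,
            depth_stat=self.depth_stat,
            min_abs_delta=self.min_abs_delta,
        )
        return DeltaIndexScanResults(self, filtered, scan, ci, level)


@dataclass
class DeltaIndexScanResults:
    """Fitted scan: filtered records, window statistics, envelopes, intervals."""

    model: DeltaIndexScan
    records: pd.DataFrame  # filtered per-site records
    windows: pd.DataFrame
    ci: CiLookup
    level: float
    _intervals: Optional[pd.DataFrame] = field(default=None, repr=False)

    @property
    def n_sites(self) -> int:
        return len(self.records)

    @property
    def n_sites_raw(self) -> int:
        return len(self.model.records)

    def site_bounds(self, level: Optional[float] = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site null envelope at each site's effective depth."""
        lev = level if level is not None else self.level
        return self.ci.bounds(effective_depth(self.records), lev)

    def site_exceedance(self, level: Optional[float] = None) -> float:
        """Fraction of filtered sites whose delta falls outside the envelope.

        Under the null this is calibrated to ``1 - level``; at a real QTL
        the linked sites push it up.
        """
        lo, hi = self.site_bounds(level)
        d = self.records["delta"].to_numpy(float)
        return float(np.mean((d < lo) | (d > hi)))

    def intervals(self, genes: Optional[Sequence[GeneModel]] = None) -> pd.DataFrame:
        if genes is not None or self._intervals is None:
            self._intervals = call_intervals(self.windows, genes)
        return self._intervals

    def summary(self) -> str:
        m = self.model
        sig = self.windows["significant"].sum() if "significant" in self.windows else 0
        iv = self.intervals()
        lines = [
            f"Delta-index scan ({m.variant_class} sites)",
            "=" * 44,
            f"pools: {m.large} vs {m.small}  (n={m.pool_size} lines each, {m.seg_model})",
            f"window / step: {m.window:,} / {m.step:,} bp; CI level {self.level:.0%}"
            f" ({self.ci.n_sims:,} sims/depth)",
            f"sites: {self.n_sites_raw:,} raw -> {self.n_sites:,} after filtering"
            f" (min_index {m.min_index}, min_depth {m.min_depth})",
            f"windows: {len(self.windows):,} total, {int(sig):,} significant",
            f"candidate intervals: {len(iv)}",
        ]
        for r in iv.itertuples(index=False):
            lines.append(
                f"  {r.chrom}:{r.start:,}-{r.end:,}  size {r.size_mb:.2f} Mb"
                f"  peak delta {r.peak_delta:+.3f}"
                + (f"  genes {r.n_genes}" if r.gene_ids else "")
            )
        return "\n".join(lines)

    def plot(self, path=None, chroms: Optional[Sequence[str]] = None):
        from .plotting import plot_scan

        return plot_scan(self, path=path, chroms=chroms)
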