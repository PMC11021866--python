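"""Index statistics, filters, windows, null envelopes and interval calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from qtlbsa.association import (
    CiLookup,
    DeltaIndexScan,
    all_index_records,
    call_intervals,
    compute_indices,
    default_depth_grid,
    effective_depth,
    filter_records,
    interval_size_mb,
    simulate_null_ci,
    sliding_window_scan,
)


def _sites(rows):
    """Site table from (chrom, pos, large_ref, large_alt, small_ref, small_alt)."""
    recs = []
    for chrom, pos, lr, la, sr, sa in rows:
        recs.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": "A",
                "alt": "T",
                "vtype": "SNP",
                "pool_large_ref": lr,
                "pool_large_alt": la,
                "pool_small_ref": sr,
                "pool_small_alt": sa,
            }
        )
    return pd.DataFrame(recs)


def test_compute_indices_worked_values():
    sites = _sites(
        [
            ("c", 100, 10, 10, 10, 10),  # index 0.5 both pools
            ("c", 200, 2, 18, 18, 2),  # delta 0.9 - 0.1 = 0.8
            ("c", 300, 20, 0, 5, 0),  # alt 0 in both -> delta 0
            ("c", 400, 0, 0, 10, 10),  # zero depth -> missing index
        ]
    )
    rec = compute_indices(sites, "pool_large", "pool_small")
    assert rec.loc[0, "index_large"] == 0.5
    assert rec.loc[1, "delta"] == pytest.approx(0.8)
    assert rec.loc[2, "delta"] == 0.0
    assert np.isnan(rec.loc[3, "index_large"])


FILTER_TRUTH_TABLE = [
    # (index_large, index_small, depth_large, depth_small, kept)
    (0.25, 0.28, 50, 50, False),  # both indices below 0.3
    (0.25, 0.90, 50, 50, True),  # only one below: the rule needs both
    (0.90, 0.25, 50, 50, True),  # symmetric case
    (0.30, 0.20, 50, 50, True),  # 0.30 is not < 0.3: boundary kept
    (0.299, 0.299, 50, 50, False),  # strictly below on both sides
    (0.5, 0.5, 6, 6, False),  # both depths below 7
    (0.5, 0.5, 7, 6, True),  # one depth at the boundary: kept
    (0.5, 0.5, 6, 50, True),  # only one shallow pool
    (np.nan, 0.5, 0, 50, False),  # missing index in one pool
    (0.5, np.nan, 50, 0, False),
    (0.05, 0.95, 40, 40, True),  # strong signal site survives
]


def test_filter_truth_table():
    """The three filter clauses against hand-computed keep/drop decisions."""
    rec = pd.DataFrame(
        [
            {
                "index_large": il,
                "index_small": ism,
                "depth_large": dl,
                "depth_small": ds,
                "delta": (il - ism) if not (np.isnan(il) or np.isnan(ism)) else np.nan,
                "pos": i,
                "chrom": "c",
            }
            for i, (il, ism, dl, ds, _) in enumerate(FILTER_TRUTH_TABLE)
        ]
    )
    kept = filter_records(rec)
    expected = [i for i, row in enumerate(FILTER_TRUTH_TABLE) if row[4]]
    assert sorted(kept["pos"]) == expected


@given(
    st.lists(
        st.tuples(
            st.integers(min_value=0, max_value=60),
            st.integers(min_value=0, max_value=60),
            st.integers(min_value=0, max_value=60),
            st.integers(min_value=0, max_value=60),
        ),
        min_size=1,
        max_size=40,
    )
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_filter_is_idempotent_and_contractive(counts):
    sites = _sites([("c", 10 * (i + 1), lr, la, sr, sa) for i, (lr, la, sr, sa) in enumerate(counts)])
    rec = compute_indices(sites, "pool_large", "pool_small")
    once = filter_records(rec)
    twice = filter_records(once)
    assert len(once) <= len(rec)
    pd.testing.assert_frame_equal(once, twice)


def test_pool_label_swap_negates_delta_and_mirrors_envelope(small_cross):
    _, _, sites = small_cross
    fwd = filter_records(compute_indices(sites, "pool_large", "pool_small"))
    rev = filter_records(compute_indices(sites, "pool_small", "pool_large"))
    merged = fwd.merge(rev, on=["chrom", "pos"], suffixes=("_f", "_r"))
    assert len(merged) == len(fwd) == len(rev)  # filters are pool-symmetric
    assert np.allclose(merged["delta_f"], -merged["delta_r"])
    ci = simulate_null_ci([40], 25, n_sims=50_000, seed=3)
    lo, hi = ci.bounds(np.full(len(merged), 40.0), 0.95)
    out_f = (merged["delta_f"] < lo) | (merged["delta_f"] > hi)
    # the envelope is symmetric up to Monte-Carlo noise; compare against its mirror
    out_r = (merged["delta_r"] < -hi) | (merged["delta_r"] > -lo)
    assert (out_f == out_r).all()


def test_window_count_formula():
    rec = _sites([("c", 1, 10, 10, 10, 10)])
    rec = compute_indices(rec, "pool_large", "pool_small")
    scan = sliding_window_scan(rec, {"c": 2_000_000}, window=1_000_000, step=1_000)
    assert len(scan) == 1001
    assert scan["start"].iloc[0] == 0 and scan["start"].iloc[-1] == 1_000_000


def test_final_partial_window_is_truncated():
    rec = compute_indices(_sites([("c", 1, 10, 10, 10, 10)]), "pool_large", "pool_small")
    scan = sliding_window_scan(rec, {"c": 1_500_500}, window=1_000_000, step=1_000)
    assert scan["end"].iloc[-1] == 1_500_500
    assert scan["start"].iloc[-1] == 501_000  # one step past the last full start


def test_short_chromosome_yields_single_window():
    rec = compute_indices(_sites([("c", 1, 10, 10, 10, 10)]), "pool_large", "pool_small")
    scan = sliding_window_scan(rec, {"c": 400_000}, window=1_000_000, step=1_000)
    assert len(scan) == 1
    assert (scan["start"].iloc[0], scan["end"].iloc[0]) == (0, 400_000)


def test_constant_delta_fills_every_nonempty_window():
    rows = [("c", p, 10, 10, 10, 10) for p in range(50_000, 950_000, 50_000)]
    rec = compute_indices(_sites(rows), "pool_large", "pool_small")
    rec["delta"] = 0.37
    scan = sliding_window_scan(rec, {"c": 1_000_000}, window=200_000, step=100_000)
    nz = scan["n_sites"] > 0
    assert np.allclose(scan.loc[nz, "mean_delta"], 0.37)
    assert np.isnan(scan.loc[~nz, "mean_delta"]).all()


def test_single_site_window_membership():
    rec = compute_indices(_sites([("c", 350_000, 10, 10, 10, 10)]), "pool_large", "pool_small")
    scan = sliding_window_scan(rec, {"c": 1_000_000}, window=200_000, step=100_000)
    hit = scan[scan["n_sites"] > 0]
    # half-open windows [start, end): position 350,000 sits in [200,300) and [300,400) kb
    assert list(hit["start"]) == [200_000, 300_000]


def test_window_smaller_than_step_rejected():
    rec = compute_indices(_sites([("c", 1, 1, 1, 1, 1)]), "pool_large", "pool_small")
    with pytest.raises(ValueError):
        sliding_window_scan(rec, {"c": 10_000}, window=100, step=200)


def test_null_ci_properties():
    ci = simulate_null_ci([7, 30, 120], 30, n_sims=30_000, seed=1)
    for lev in (0.95, 0.99):
        width = ci.hi[lev] - ci.lo[lev]
        assert width[0] > width[1] > width[2]  # envelope shrinks with depth
        # null symmetry: |mean of bounds| is small
        assert abs(ci.hi[lev][1] + ci.lo[lev][1]) < 0.05
    # 95% envelope nested inside the 99% envelope at every depth
    assert (ci.lo[0.99] <= ci.lo[0.95]).all()
    assert (ci.hi[0.99] >= ci.hi[0.95]).all()
    with pytest.raises(ValueError):
        simulate_null_ci([40], 30, n_sims=500)


def test_ci_lookup_interpolates_between_grid_depths():
    ci = CiLookup(
        depths=np.array([10.0, 40.0]),
        levels=(0.95,),
        lo={0.95: np.array([-0.4, -0.2])},
        hi={0.95: np.array([0.4, 0.2])},
        pool_size=30,
        seg_model="1:1",
        n_sims=1000,
    )
    lo, hi = ci.bounds(np.array([10.0, 40.0, 16.0]), 0.95)
    assert lo[0] == -0.4 and hi[1] == 0.2
    # 1/16 is exactly half way between 1/10 and 1/40
    assert hi[2] == pytest.approx(0.3)
    # depths beyond the grid clamp to the end points
    lo_c, hi_c = ci.bounds(np.array([5.0, 400.0]), 0.95)
    assert hi_c[0] == 0.4 and hi_c[1] == 0.2


def test_interval_merging_and_size():
    scan = pd.DataFrame(
        {
            "chrom": ["c"] * 3,
            "start": [0, 500_000, 3_000_000],
            "end": [1_000_000, 1_500_000, 4_000_000],
            "n_sites": [5, 5, 5],
            "mean_delta": [0.5, 0.6, -0.4],
            "significant": [True, True, True],
        }
    )
    iv = call_intervals(scan)
    assert len(iv) == 2
    assert iv.loc[0, "start"] == 0 and iv.loc[0, "end"] == 1_500_000
    assert iv.loc[0, "size_mb"] == pytest.approx(1.50)
    assert iv.loc[0, "peak_delta"] == pytest.approx(0.6)
    assert iv.loc[1, "peak_delta"] == pytest.approx(-0.4)

    # no significant windows -> empty interval set
    scan["significant"] = False
    assert len(call_intervals(scan)) == 0


def test_published_interval_size():
    # combined-index interval at 30.72-32.23 Mb spans 1.51 Mb
    assert interval_size_mb(30_720_000, 32_230_000) == pytest.approx(1.51)


def test_all_index_union_behavior(small_cross):
    cfg, _, sites = small_cross
    snp = filter_records(compute_indices(sites[sites["vtype"] == "SNP"], "pool_large", "pool_small"))
    indel = filter_records(
        compute_indices(sites[sites["vtype"] != "SNP"], "pool_large", "pool_small")
    )
    # empty indel set: the combined scan equals the SNP scan
    combined = all_index_records(snp, indel.iloc[0:0])
    pd.testing.assert_frame_equal(
        combined,
        snp.sort_values(["chrom", "pos"]).reset_index(drop=True),
    )
    # disjoint site sets: window site counts add
    sizes = dict(cfg.chromosomes)
    s1 = sliding_window_scan(snp, sizes)
    s2 = sliding_window_scan(indel, sizes)
    s3 = sliding_window_scan(all_index_records(snp, indel), sizes)
    assert (s3["n_sites"].to_numpy() == s1["n_sites"].to_numpy() + s2["n_sites"].to_numpy()).all()


def test_model_results_surface(small_cross):
    cfg, truth, sites = small_cross
    model = DeltaIndexScan(
        sites, dict(cfg.chromosomes), pool_size=cfg.pool_size, variant_class="SNP"
    )
    res = model.fit(n_sims=5_000, seed=2)
    assert res.n_sites <= res.n_sites_raw
    assert {"chrom", "start", "end", "n_sites", "mean_delta", "significant"} <= set(
        res.windows.columns
    )
    txt = res.summary()
    assert "sites" in txt and "candidate intervals" in txt.lower()
    iv = res.intervals()
    assert set(iv.columns) >= {"chrom", "start", "end", "size_mb", "n_genes"}
    # the planted QTL is recovered by the candidate intervals
    assert any(
        (r.chrom == cfg.qtl.chrom) and (r.start < cfg.qtl.pos <= r.end)
        for r in iv.itertuples()
    )


def test_all_index_interval_contains_snp_peak(small_cross):
    cfg, _, sites = small_cross
    snp_res = DeltaIndexScan(
        sites, dict(cfg.chromosomes), pool_size=cfg.pool_size, variant_class="SNP"
    ).fit(n_sims=5_000, seed=2)
    all_res = DeltaIndexScan(
        sites, dict(cfg.chromosomes), pool_size=cfg.pool_size, variant_class="All"
    ).fit(n_sims=5_000, seed=2)
    w = snp_res.windows.dropna(subset=["mean_delta"])
    peak = w.loc[w["mean_delta"].abs().idxmax()]
    top = all_res.intervals().sort_values("peak_delta", key=abs, ascending=False).iloc[0]
    assert top["chrom"] == peak["chrom"]
    assert top["start"] <= (peak["start"] + peak["end"]) / 2 <= top["end"]


def test_default_depth_grid_spans_observations():
    grid = default_depth_grid(np.array([9.0, 35.0, 80.0]))
    assert grid[0] <= 9.0 or grid[0] == 4.0
    assert grid[-1] >= 80.0
    assert (np.diff(grid) > 0).all()
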