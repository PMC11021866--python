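"""Genetic-variation statistics for fruit-size traits and the extreme-line screen.

For each trait measured on an F1 population and its two parents this module
computes the classical quantitative-genetics descriptors:

* coefficient of variation  CV% = 100 * s / x̄   (sample SD, n−1),
* mid-parent value          V_MP = (P1 + P2) / 2,
* mid-parent heterosis rate R_Hm% = 100 * (F1 − V_MP) / V_MP,
* over-high-parent rate     HH% = 100 * #{F1 > max(P1, P2)} / n,
* excess kurtosis and the third-moment skewness coefficient
  (both bias-corrected, as SPSS-style descriptives report them).

Extreme pools are screened on single fruit weight as the main index with
fruit length and diameter as optional auxiliary consistency filters.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (ties away from zero), the reporting convention.

    Values are first snapped to 10 decimal places so that binary-float noise
    (e.g. 13.595 stored as 13.5949999...) does not flip a true half tie.
    """
    d = Decimal(repr(float(x))).quantize(Decimal("1e-10"), rounding=ROUND_HALF_UP)
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def cv_pct(mean: float, sd: float) -> float:
    """Coefficient of variation in percent. Undefined for a zero mean."""
    if mean == 0:
        raise ZeroDivisionError("CV is undefined when the trait mean is zero")
    return 100.0 * sd / mean


def mid_parent_value(p1_mean: float, p2_mean: float) -> float:
    return (p1_mean + p2_mean) / 2.0


def heterosis_rate(f1_mean: float, p1_mean: float, p2_mean: float) -> float:
    """Mid-parent heterosis rate R_Hm in percent."""
    v_mp = mid_parent_value(p1_mean, p2_mean)
    if v_mp == 0:
        raise ZeroDivisionError("heterosis rate undefined for a zero mid-parent value")
    return 100.0 * (f1_mean - v_mp) / v_mp


def interpretive_ta_pct(rhm_pct: float) -> float:
    """Interpretive derived column: 100 − |R_Hm|.

    Some published trait-genetics tables carry a "Ta (%)" column that is
    numerically 100 minus the absolute heterosis rate; the defining formula
    is not standard, so this reading is offered as an optional derived
    column only and carries no analytical weight.
    """
    return 100.0 - abs(rhm_pct)


def shape_index(length: float, diameter: float) -> float:
    """Fruit shape index: length / diameter."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    return length / diameter


@dataclass
class TraitSummary:
    trait: str
    p1_mean: float
    p2_mean: float
    v_mp: float
    f1_mean: float
    f1_sd: float
    f1_min: float
    f1_max: float
    cv_pct: float
    hh_pct: float
    rhm_pct: float
    kurtosis: float
    skewness: float
    n: int

    def as_dict(self) -> dict:
        return asdict(self)

    def rounded(self, ndigits: int = 2) -> dict:
        out = {}
        for k, v in self.as_dict().items():
            out[k] = round_half_up(v, ndigits) if isinstance(v, float) else v
        return out


def summarize_trait(
    f1_values: Sequence[float], p1_mean: float, p2_mean: float, trait: str = ""
) -> TraitSummary:
    """Full genetic-variation summary of one trait.

    Requires at least three F1 observations (sample moments up to order four).
    """
    x = np.asarray(f1_values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 F1 values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    high = max(p1_mean, p2_mean)
    with warnings.catch_warnings():
        # degenerate (constant) samples: scipy warns and yields NaN shape
        # statistics, which is the honest answer
        warnings.simplefilter("ignore", RuntimeWarning)
        kurt = float(stats.kurtosis(x, fisher=True, bias=False))
        skew = float(stats.skew(x, bias=False))
    return TraitSummary(
        trait=trait,
        p1_mean=float(p1_mean),
        p2_mean=float(p2_mean),
        v_mp=mid_parent_value(p1_mean, p2_mean),
        f1_mean=mean,
        f1_sd=sd,
        f1_min=float(x.min()),
        f1_max=float(x.max()),
        cv_pct=cv_pct(mean, sd),
        hh_pct=100.0 * float(np.mean(x > high)),
        rhm_pct=heterosis_rate(mean, p1_mean, p2_mean),
        kurtosis=kurt,
        skewness=skew,
        n=int(x.size),
    )


def summarize_table(
    phenos: pd.DataFrame,
    parent_means: dict[str, tuple[float, float]],
    traits: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Summaries for every trait column; ``parent_means[trait] = (p1, p2)``."""
    traits = list(traits or parent_means)
    rows = [
        summarize_trait(phenos[t].to_numpy(), *parent_means[t], trait=t).as_dict()
        for t in traits
    ]
    return pd.DataFrame(rows)


def add_shape_index(
    phenos: pd.DataFrame,
    length_col: str = "fruit_length_mm",
    diameter_col: str = "fruit_diameter_mm",
    out_col: str = "fruit_shape_index",
) -> pd.DataFrame:
    out = phenos.copy()
    if (out[diameter_col] <= 0).any():
        raise ValueError("diameter must be positive for every line")
    out[out_col] = out[length_col] / out[diameter_col]
    return out


def trait_histogram(values: Sequence[float], bins: int = 15) -> pd.DataFrame:
    """Frequency-distribution table; bin counts sum to n by construction."""
    counts, edges = np.histogram(np.asarray(values, dtype=float), bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


@dataclass
class PoolScreen:
    """Result of the extreme-line screen: pool membership plus per-pool ranges."""

    large_ids: list
    small_ids: list
    summary: pd.DataFrame  # per pool x trait: min, max, mean, sd


def screen_extremes(
    phenos: pd.DataFrame,
    n: int,
    weight_col: str = "single_fruit_weight_g",
    aux_cols: Sequence[str] = ("fruit_length_mm", "fruit_diameter_mm"),
    id_col: str = "line_id",
    aux_slack: Optional[float] = None,
) -> PoolScreen:
    """Select the two extreme pools of ``n`` lines each.

    Lines are ranked on single fruit weight (the main screening index), ties
    broken deterministically by line id. With ``aux_slack=q`` a line must
    additionally sit in the matching tail (upper/lower ``q`` quantile) for
    each auxiliary trait; the default applies no auxiliary filter.
    """
    if len(phenos) < 2 * n:
        raise ValueError("fewer than 2n lines available")
    df = phenos.sort_values([weight_col, id_col], kind="mergesort").reset_index(drop=True)

    def tail_ok(row, upper: bool) -> bool:
        if aux_slack is None:
            return True
        for c in aux_cols:
            if c not in phenos.columns:
                continue
            q = phenos[c].quantile(1 - aux_slack if upper else aux_slack)
            if (row[c] < q) if upper else (row[c] > q):
                return False
        return True

    small, large = [], []
    for _, row in df.iterrows():
        if len(small) < n and tail_ok(row, upper=False):
            small.append(row[id_col])
    for _, row in df.iloc[::-1].iterrows():
        if len(large) < n and tail_ok(row, upper=True) and row[id_col] not in small:
            large.append(row[id_col])
    if len(small) < n or len(large) < n:
        raise ValueError("auxiliary screen too strict: not enough qualifying lines")

    cols = [weight_col] + [c for c in aux_cols if c in phenos.columns]
    recs = []
    for name, ids in (("small", small), ("large", large)):
        sub = phenos[phenos[id_col].isin(ids)]
        for c in cols:
            recs.append(
                {
                    "pool": name,
                    "trait": c,
                    "min": float(sub[c].min()),
                    "max": float(sub[c].max()),
                    "mean": float(sub[c].mean()),
                    "sd": float(sub[c].std(ddof=1)),
                    "n": len(sub),
                }
            )
    return PoolScreen(large_ids=large, small_ids=small, summary=pd.DataFrame(recs))
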