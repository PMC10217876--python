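"""Descriptive and inferential statistics for monitoring panels.

Pooled per-analyte summaries, mean-to-background ratios, Spearman rank
correlation with significance tiers, Shapiro–Wilk normality, and land-use
group comparisons by rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .background import LandUseAssignment
from .data import GBTable, SamplePanel

TIER_THRESHOLDS = (0.0001, 0.001, 0.01, 0.05)


def _tier(p: float) -> str:
    for t in TIER_THRESHOLDS:
        if p < t:
            return f"p<{t}"
    return "ns"


def summarize(panel: SamplePanel, min_n: int = 2) -> pd.DataFrame:
    """Per-analyte min/mean/median/max/sd/skew/kurtosis/IQR over all
    site-years pooled.

    Sample sd (n−1); adjusted Fisher–Pearson skewness; excess kurtosis;
    IQR = Q3 − Q1 with linear-interpolation quantiles.  Analytes with fewer
    than ``min_n`` observations are skipped with a warning; a constant
    series reports skew/kurtosis 0 with a ``degenerate`` flag.
    """
    rows = []
    for analyte, grp in panel.data.groupby("analyte", sort=False):
        x = grp["value"].to_numpy(dtype=float)
        if len(x) < min_n:
            warnings.warn(f"{analyte}: fewer than {min_n} observations; skipped")
            continue
        q1, q3 = np.percentile(x, [25, 75])
        degenerate = np.ptp(x) == 0
        if degenerate:
            skew = kurt = 0.0
        else:
            skew = float(sps.skew(x, bias=False))
            kurt = float(sps.kurtosis(x, bias=False))
        rows.append(
            {
                "analyte": analyte,
                "n": len(x),
                "min": float(x.min()),
                "mean": float(x.mean()),
                "median": float(np.median(x)),
                "max": float(x.max()),
                "sd": float(x.std(ddof=1)),
                "skew": skew,
                "kurtosis": kurt,
                "iqr": float(q3 - q1),
                "flag": "degenerate" if degenerate else "",
            }
        )
    return pd.DataFrame(rows).set_index("analyte")


def _round_half_up(x: float, digits: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -digits, rounding=ROUND_HALF_UP))


def mean_background_ratio(
    means: "pd.Series | dict[str, float]",
    gb_means: "pd.Series | dict[str, float]",
    digits: int = 2,
) -> pd.Series:
    """Mean concentration divided by mean geochemical background, per
    analyte, rounded half-up to ``digits`` decimals.

    ``means`` comes from :func:`summarize` (the ``mean`` column) or a
    published summary; ``gb_means`` from :meth:`GBTable.site_means` or a
    published background summary.
    """
    means = pd.Series(means, dtype=float)
    gb_means = pd.Series(gb_means, dtype=float)
    common = [a for a in means.index if a in gb_means.index]
    if (gb_means[common] == 0).any():
        bad = [a for a in common if gb_means[a] == 0]
        raise ZeroDivisionError(f"zero background mean for {bad}")
    ratio = means[common] / gb_means[common]
    return ratio.map(lambda v: _round_half_up(v, digits))


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman correlations with p-values and significance tiers."""

    rho: pd.DataFrame
    p: pd.DataFrame
    tier: pd.DataFrame
    n: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        cols = list(self.rho.columns)
        rows = []
        for i, a in enumerate(cols):
            for b in cols[:i]:
                rows.append(
                    {
                        "analyte_a": a,
                        "analyte_b": b,
                        "rho": self.rho.loc[a, b],
                        "p": self.p.loc[a, b],
                        "tier": self.tier.loc[a, b],
                        "n": self.n.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


def spearman_matrix(panel: SamplePanel, analytes: list[str] | None = None, min_n: int = 5) -> CorrelationMatrix:
    """Spearman rank correlation over pairwise-complete site-year samples.

    Average ranks for ties; two-sided p-values; tiers at the four standard
    thresholds.  Pairs with fewer than ``min_n`` complete observations are
    flagged ``insufficient_n`` with NaN coefficients.
    """
    wide = panel.pivot(analytes)
    cols = list(wide.columns)
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    tier = pd.DataFrame("", index=cols, columns=cols)
    n = pd.DataFrame(0, index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i):
            b = cols[j]
            pair = wide[[a, b]].dropna()
            n.loc[a, b] = n.loc[b, a] = len(pair)
            if len(pair) < min_n:
                rho.loc[a, b] = rho.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                tier.loc[a, b] = tier.loc[b, a] = "insufficient_n"
                continue
            r, pv = sps.spearmanr(pair[a], pair[b])
            rho.loc[a, b] = rho.loc[b, a] = r
            p.loc[a, b] = p.loc[b, a] = pv
            tier.loc[a, b] = tier.loc[b, a] = _tier(pv)
    return CorrelationMatrix(rho=rho, p=p, tier=tier, n=n)


def normality(panel: SamplePanel, min_n: int = 3, max_n: int = 5000) -> pd.DataFrame:
    """Shapiro–Wilk W and p per analyte; out-of-range sample sizes are
    flagged rather than tested."""
    rows = []
    for analyte, grp in panel.data.groupby("analyte", sort=False):
        x = grp["value"].to_numpy(dtype=float)
        if not (min_n <= len(x) <= max_n):
            rows.append({"analyte": analyte, "n": len(x), "W": np.nan, "p": np.nan, "flag": "n_out_of_range"})
            continue
        w, pv = sps.shapiro(x)
        rows.append({"analyte": analyte, "n": len(x), "W": float(w), "p": float(pv), "flag": ""})
    return pd.DataFrame(rows).set_index("analyte")


def group_compare(
    panel: SamplePanel,
    landuse: LandUseAssignment,
    min_group_n: int = 3,
    test: str = "rank_sum",
) -> pd.DataFrame:
    """Pairwise land-use group comparisons per analyte.

    Two-sided Mann–Whitney rank-sum by default (independent groups of
    sites); ``test='signed_rank'`` switches to Wilcoxon signed-rank on
    paired, equally sized groups.  Group means/medians are returned
    alongside p-values.  Undersized groups are skipped with a warning.
    """
    cat = pd.Series(landuse.categories, name="category")
    df = panel.data.merge(cat.rename_axis("site_id").reset_index(), on="site_id", how="inner")
    rows = []
    for analyte, grp in df.groupby("analyte", sort=False):
        groups = {g: sub["value"].to_numpy(dtype=float) for g, sub in grp.groupby("category")}
        names = sorted(groups)
        for i, ga in enumerate(names):
            for gb_ in names[:i]:
                xa, xb = groups[ga], groups[gb_]
                if len(xa) < min_group_n or len(xb) < min_group_n:
                    warnings.warn(f"{analyte} {ga} vs {gb_}: undersized group; skipped")
                    continue
                if test == "signed_rank":
                    k = min(len(xa), len(xb))
                    stat, pv = sps.wilcoxon(xa[:k], xb[:k])
                else:
                    stat, pv = sps.mannwhitneyu(xa, xb, alternative="two-sided")
                rows.append(
                    {
                        "analyte": analyte,
                        "group_a": ga,
                        "group_b": gb_,
                        "n_a": len(xa),
                        "n_b": len(xb),
                        "mean_a": float(np.mean(xa)),
                        "mean_b": float(np.mean(xb)),
                        "median_a": float(np.median(xa)),
                        "median_b": float(np.median(xb)),
                        "statistic": float(stat),
                        "p": float(pv),
                        "tier": _tier(float(pv)),
                    }
                )
    return pd.DataFrame(rows)


def holm_adjust(pvalues: "pd.Series") -> pd.Series:
    """Holm step-down adjustment (optional; raw p-values are the default
    reporting convention here)."""
    p = pvalues.to_numpy(dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return pd.Series(adj, index=pvalues.index)
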