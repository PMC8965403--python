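"""Cross-feature stability summaries.

Joins the per-feature phylogenetic-signal medians (D) with the per-feature
gain/loss rate medians (log10), correlates them (Kendall's tau-b), bins them
into the conventional stability classes, and aggregates per catalogue
category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import FeatureCatalog

__all__ = [
    "FeatureStability",
    "kendall_tau",
    "bin_D",
    "bin_rate",
    "category_medians",
    "overall_summary",
    "stability_table",
]

D_BINS = ("overclumped", "signal", "random", "overdispersed")
RATE_BINS = ("slow", "medium", "fast")


@dataclass(frozen=True)
class FeatureStability:
    """Per-feature stability record: posterior-median signal and rates."""

    feature: str
    median_D: float | None
    median_log_gain: float
    median_log_loss: float

    @property
    def D_bin(self) -> str | None:
        return None if self.median_D is None else bin_D(self.median_D)

    @property
    def gain_bin(self) -> str:
        return bin_rate(self.median_log_gain)

    @property
    def loss_bin(self) -> str:
        return bin_rate(self.median_log_loss)


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Kendall's tau-b with a normal-approximation p-value.

    Pairs where either entry is undefined (None/NaN) are dropped.
    """
    xa = np.array([np.nan if v is None else float(v) for v in x])
    ya = np.array([np.nan if v is None else float(v) for v in y])
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    if xa.size < 3:
        raise ValueError("need at least 3 defined pairs")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ValueError("all-tied input: tau undefined")
    res = stats.kendalltau(xa, ya, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def bin_D(median_D: float) -> str:
    """Four signal classes: D<0 overclumped, [0,0.5] signal, (0.5,1] random,
    >1 overdispersed.  Boundaries are closed on the signal side."""
    if median_D < 0.0:
        return "overclumped"
    if median_D <= 0.5:
        return "signal"
    if median_D <= 1.0:
        return "random"
    return "overdispersed"


def bin_rate(median_log_rate: float) -> str:
    """Three rate classes on the log10 scale with cutoffs at +-0.5 (closed
    interval assigned to medium)."""
    if median_log_rate < -0.5:
        return "slow"
    if median_log_rate <= 0.5:
        return "medium"
    return "fast"


def stability_table(records: Sequence[FeatureStability]) -> pd.DataFrame:
    """Tidy per-feature table with values and bins."""
    return pd.DataFrame(
        {
            "feature": [r.feature for r in records],
            "median_D": [r.median_D for r in records],
            "median_log_gain": [r.median_log_gain for r in records],
            "median_log_loss": [r.median_log_loss for r in records],
            "D_bin": [r.D_bin for r in records],
            "gain_bin": [r.gain_bin for r in records],
            "loss_bin": [r.loss_bin for r in records],
        }
    ).set_index("feature")


def category_medians(
    records: Sequence[FeatureStability],
    catalog: FeatureCatalog,
    axis: str = "functional_category",
) -> pd.DataFrame:
    """Per-category medians of D and the log rates on one catalogue axis."""
    tab = stability_table(records)
    catalog.check_features(list(tab.index))
    cats = catalog.table.loc[tab.index, axis]
    rows = {}
    for cat, grp in tab.groupby(cats):
        rows[cat] = {
            "median_D": grp["median_D"].dropna().median(),
            "median_log_gain": grp["median_log_gain"].median(),
            "median_log_loss": grp["median_log_loss"].median(),
            "n_features": len(grp),
            "n_undefined_D": int(grp["median_D"].isna().sum()),
        }
    df = pd.DataFrame(rows).T
    df.index.name = axis
    df["n_features"] = df["n_features"].astype(int)
    df["n_undefined_D"] = df["n_undefined_D"].astype(int)
    return df


def overall_summary(records: Sequence[FeatureStability]) -> dict[str, pd.DataFrame | pd.Series]:
    """Order statistics, bin proportions, and the coarse above/below splits.

    ``dispersion`` has min/median/max/sd per metric; ``d_bins`` and
    ``rate_bins`` hold proportions over the fine classes; ``coarse`` reports
    the share of features with D below 0.5 and with log rates below 0.
    """
    tab = stability_table(records)
    metrics = ["median_D", "median_log_gain", "median_log_loss"]
    disp = pd.DataFrame(
        {
            m: {
                "min": tab[m].min(),
                "median": tab[m].median(),
                "max": tab[m].max(),
                "sd": tab[m].std(ddof=1) if tab[m].notna().sum() > 1 else 0.0,
            }
            for m in metrics
        }
    )
    d_def = tab["D_bin"].dropna()
    d_bins = d_def.value_counts(normalize=True).reindex(list(D_BINS)).fillna(0.0)
    rate_bins = pd.DataFrame(
        {
            "gain": tab["gain_bin"].value_counts(normalize=True),
            "loss": tab["loss_bin"].value_counts(normalize=True),
        }
    ).reindex(list(RATE_BINS)).fillna(0.0)
    dvals = tab["median_D"].dropna()
    coarse = pd.Series(
        {
            "D_below_0.5": float((dvals < 0.5).mean()) if len(dvals) else np.nan,
            "D_above_0.5": float((dvals >= 0.5).mean()) if len(dvals) else np.nan,
            "gain_below_0": float((tab["median_log_gain"] < 0).mean()),
            "loss_below_0": float((tab["median_log_loss"] < 0).mean()),
        }
    )
    return {"dispersion": disp, "d_bins": d_bins, "rate_bins": rate_bins, "coarse": coarse}
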