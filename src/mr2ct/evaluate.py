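"""Per-tissue quantitative evaluation: mean/SD/CV, histograms, comparisons.

The homogeneity metric throughout is the coefficient of variation,
CV = 100 * SD / |mean|, with the population SD (divide by N) and the
absolute mean so that negative-HU tissues (fat, lung) report positive CVs.
Reported CVs are rounded to two decimals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume import TISSUE_NAMES, TissueLabelMap, Volume


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation in percent, 100*sd/|mean|, 2-decimal rounded."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return round(100.0 * sd / abs(mean), 2)


@dataclass
class TissueStats:
    """Per-tissue mean / SD / CV% / voxel count at volume or slice scope."""

    table: pd.DataFrame          # columns: tissue, mean, sd, cv_percent, count
    scope: str = "volume"        # "volume" or "slice"

    def for_tissue(self, code: int) -> pd.Series:
        rows = self.table[self.table.tissue == code]
        if rows.empty:
            raise KeyError(f"no stats for tissue {code}")
        return rows.iloc[0]


def _stats_rows(data: np.ndarray, labels: np.ndarray, scope) -> list[dict]:
    rows = []
    for code in sorted(TISSUE_NAMES):
        vals = data[labels == code]
        if vals.size == 0:
            warnings.warn(f"tissue {code} ({TISSUE_NAMES[code]}) has no voxels "
                          f"in scope {scope}; omitted")
            continue
        mean = float(vals.mean())
        sd = float(vals.std())                       # population SD
        rows.append({"tissue": code, "mean": mean, "sd": sd,
                     "cv_percent": cv_percent(mean, sd) if mean != 0 else np.nan,
                     "count": int(vals.size)})
    return rows


def tissue_stats(vol: Volume, labels: TissueLabelMap,
                 per_slice: bool = False) -> TissueStats:
    """Mean, population SD, CV% and voxel count per tissue class.

    With ``per_slice`` the statistics pool the voxels of each class within
    each axial slice (rows gain a ``slice`` column).
    """
    if vol.shape != labels.shape:
        raise ValueError("volume and label grids differ")
    if not per_slice:
        return TissueStats(pd.DataFrame(_stats_rows(vol.data, labels.labels,
                                                    "volume")))
    rows = []
    for s in range(vol.n_slices):
        for r in _stats_rows(vol.data[s], labels.labels[s], f"slice {s}"):
            r["slice"] = s
            rows.append(r)
    return TissueStats(pd.DataFrame(rows), scope="slice")


def intensity_histogram(vol: Volume, mask: np.ndarray | None = None,
                        bins: int = 100,
                        range: tuple[float, float] | None = None):
    """Histogram counts and edges over an optional mask.

    A fixed explicit ``range`` makes before/after histograms comparable;
    values outside it are clipped into the edge bins so counts always sum
    to the masked voxel count.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    vals = vol.data[mask] if mask is not None else vol.data.ravel()
    if vals.size == 0:
        raise ValueError("empty mask")
    if range is None:
        range = (float(vals.min()), float(vals.max()))
    lo, hi = range
    counts, edges = np.histogram(np.clip(vals, lo, hi), bins=bins,
                                 range=(lo, hi))
    return counts, edges


@dataclass
class ComparisonReport:
    """Per-tissue difference of means between two volumes (a - b)."""

    mean_difference: dict[int, float]
    stats_a: TissueStats
    stats_b: TissueStats
    per_slice: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for code, diff in self.mean_difference.items():
            a = self.stats_a.for_tissue(code)
            b = self.stats_b.for_tissue(code)
            rows.append({"tissue": code, "name": TISSUE_NAMES[code],
                         "mean_a": a["mean"], "mean_b": b["mean"],
                         "mean_difference": diff,
                         "sd_a": a["sd"], "sd_b": b["sd"],
                         "cv_a": a["cv_percent"], "cv_b": b["cv_percent"]})
        return pd.DataFrame(rows)


def compare_volumes(a: Volume, b: Volume, labels: TissueLabelMap,
                    per_slice: bool = False) -> ComparisonReport:
    """Per-tissue mean(a) - mean(b) with both stats tables embedded.

    With ``per_slice`` the report carries a per-slice mean/SD series for
    each volume and tissue (the substrate for error-bar plots).
    """
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValueError("grids must match")
    sa = tissue_stats(a, labels)
    sb = tissue_stats(b, labels)
    diffs = {}
    for code in sorted(TISSUE_NAMES):
        try:
            diffs[code] = float(sa.for_tissue(code)["mean"]
                                - sb.for_tissue(code)["mean"])
        except KeyError:
            continue
    series = None
    if per_slice:
        pa = tissue_stats(a, labels, per_slice=True).table.assign(volume="a")
        pb = tissue_stats(b, labels, per_slice=True).table.assign(volume="b")
        series = pd.concat([pa, pb], ignore_index=True)
    return ComparisonReport(mean_difference=diffs, stats_a=sa, stats_b=sb,
                            per_slice=series)


def plot_mean_sd_series(stats: TissueStats, path, title: str = "") -> None:
    """Mean ± SD error-bar series per tissue across slices (optional plot)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if "slice" not in stats.table.columns:
        raise ValueError("per-slice stats required")
    fig, ax = plt.subplots(figsize=(7, 4))
    for code, grp in stats.table.groupby("tissue"):
        ax.errorbar(grp["slice"], grp["mean"], yerr=grp["sd"], capsize=2,
                    label=TISSUE_NAMES[int(code)])
    ax.set_xlabel("slice")
    ax.set_ylabel("intensity")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
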