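"""IHC h-score quantification and tumor/spheroid morphometrics.

Per-cell mean DAB intensities are binned into low/medium/high tertiles of
all cells pooled across every tissue (nearest-rank quantiles, boundary
ties to the lower bin), and each tissue is scored with

    h = 100 * (3*high_n + 2*medium_n + 1*low_n) / (high_n + medium_n + low_n + total_n)

where total_n is the tissue's classified-cell count. With every cell
binned this compresses the range to [50, 150] (all-low -> 50, all-high ->
150, balanced tertiles -> 100); the classical 100*(3h+2m+l)/total variant
with range [100, 300] is available behind ``classical=True``.

Tumor volume is computed from the caliper diameter as V = pi * (d/2)^3,
and spheroid volume from the projected area via the circular-projection
diameter d = 2*sqrt(A/pi).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import GroupTestResult, wilcoxon_rank_sum

__all__ = [
    "assign_stain_bins",
    "tissue_hscore",
    "hscore_group_test",
    "tumor_volume",
    "spheroid_volume_from_area",
    "percent_change_series",
]


def assign_stain_bins(stains: pd.DataFrame, compartment: str = "nuclear") -> pd.DataFrame:
    """Assign low/medium/high tertile bins on the pooled DAB intensities.

    Cut points are nearest-rank 1/3 and 2/3 quantiles of all cells of the
    requested compartment across all tissues; values at a cut point fall
    into the lower bin. Returns a copy restricted to the compartment with
    a ``bin`` column; cut points are recorded in ``frame.attrs``.
    """
    sub = stains[stains["compartment"] == compartment].copy()
    if len(sub) < 3:
        raise ValueError(f"need >= 3 cells of compartment {compartment!r}")
    vals = sub["dab_mean"].to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("dab_mean must be nonnegative")
    degenerate = bool(np.all(vals == vals[0]))
    if degenerate:
        sub["bin"] = "medium"
        q1 = q2 = float(vals[0])
    else:
        q1, q2 = (float(q) for q in np.quantile(vals, [1 / 3, 2 / 3], method="inverted_cdf"))
        sub["bin"] = np.where(vals <= q1, "low", np.where(vals <= q2, "medium", "high"))
    sub.attrs["cut_points"] = (q1, q2)
    sub.attrs["degenerate"] = degenerate
    return sub


def tissue_hscore(binned: pd.DataFrame, classical: bool = False) -> pd.DataFrame:
    """Per-tissue h-score from a binned stain table.

    ``total_n`` is the number of classified cells in the tissue. Tissues
    with zero cells are absent from the grouped input by construction;
    phase and patient labels are carried through.
    """
    if "bin" not in binned.columns:
        raise ValueError("stain table has no bin column; run assign_stain_bins first")
    rows = []
    for tissue, grp in binned.groupby("tissue_id", observed=True):
        low_n = int((grp["bin"] == "low").sum())
        med_n = int((grp["bin"] == "medium").sum())
        high_n = int((grp["bin"] == "high").sum())
        total_n = len(grp)
        weighted = 3 * high_n + 2 * med_n + 1 * low_n
        if classical:
            h = 100.0 * weighted / total_n
        else:
            h = 100.0 * weighted / (high_n + med_n + low_n + total_n)
        rows.append(
            (tissue, grp["patient_id"].iloc[0], grp["phase"].iloc[0],
             low_n, med_n, high_n, total_n, h)
        )
    return pd.DataFrame(
        rows,
        columns=["tissue_id", "patient_id", "phase", "low_n", "medium_n",
                 "high_n", "total_n", "h"],
    ).set_index("tissue_id")


def hscore_group_test(scores: pd.DataFrame) -> GroupTestResult:
    """Two-sided rank-sum on per-tissue h between naive and post tissues."""
    naive = scores.loc[scores["phase"] == "naive", "h"].to_numpy()
    post = scores.loc[scores["phase"] == "post", "h"].to_numpy()
    if len(naive) < 2 or len(post) < 2:
        raise ValueError("each phase needs at least 2 tissues")
    return wilcoxon_rank_sum(post, naive)


def tumor_volume(d) -> float | np.ndarray:
    """Caliper-diameter tumor volume, V = pi * (d/2)^3 (applied verbatim)."""
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("diameter must be nonnegative")
    v = np.pi * (d / 2.0) ** 3
    return float(v) if v.ndim == 0 else v


def spheroid_volume_from_area(area) -> float | np.ndarray:
    """Spheroid volume from projected area, assuming a circular projection."""
    area = np.asarray(area, dtype=float)
    if (area < 0).any():
        raise ValueError("area must be nonnegative")
    d = 2.0 * np.sqrt(area / np.pi)
    return tumor_volume(d)


def percent_change_series(measurements: pd.DataFrame, baseline_day: int) -> pd.DataFrame:
    """Per-animal, per-flank percent change in tumor volume versus baseline.

    ``measurements`` needs columns animal_id, flank, day and either volume
    or diameter (volume is derived from diameter if absent). Series whose
    baseline volume is 0 are flagged and excluded; a missing baseline day
    is an error.
    """
    df = measurements.copy()
    if "volume" not in df.columns:
        if "diameter" not in df.columns:
            raise ValueError("need a volume or diameter column")
        df["volume"] = tumor_volume(df["diameter"].to_numpy(dtype=float))
    out = []
    excluded = []
    for (animal, flank), grp in df.groupby(["animal_id", "flank"], observed=True):
        base = grp.loc[grp["day"] == baseline_day, "volume"]
        if base.empty:
            raise ValueError(f"series ({animal}, {flank}) has no day-{baseline_day} baseline")
        v0 = float(base.iloc[0])
        if v0 == 0:
            excluded.append((animal, flank))
            continue
        later = grp[grp["day"] != baseline_day]
        for _, row in later.iterrows():
            out.append((animal, flank, int(row["day"]),
                        100.0 * (float(row["volume"]) - v0) / v0))
    res = pd.DataFrame(out, columns=["animal_id", "flank", "day", "pct_change"])
    res.attrs["excluded_zero_baseline"] = excluded
    return res
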