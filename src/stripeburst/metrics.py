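"""Spatial-temporal burst summaries over decoded promoter paths.

All operations take a "decoded" long-format table with one row per
(movie_id, nucleus_id, frame) carrying at least ``t_s``, the decoded
promoter-ON count ``s`` and a registered AP position ``ap``.  A *burst* is a
maximal run of frames with ``s >= 1``.  AP maps are binned at 1% egg length
(left-closed bins at exact percent boundaries) and the time axis keeps the
native frame grid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "kinetic_fingerprint",
    "fraction_on_map",
    "mean_fluorescence_map",
    "fraction_bursted_before",
    "find_never_on",
    "activity_difference_events",
    "weighted_parameter_profile",
    "stripe_center_trajectory",
    "stripe_velocity",
]


def _runs_on(s: np.ndarray):
    """(start, length) of maximal runs with s >= 1."""
    on = np.asarray(s) >= 1
    if on.size == 0:
        return []
    edges = np.diff(on.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if on[0]:
        starts = [0] + starts
    if on[-1]:
        ends = ends + [on.size]
    return list(zip(starts, [e - s for s, e in zip(starts, ends)]))


def kinetic_fingerprint(decoded: pd.DataFrame) -> pd.DataFrame:
    """Catalogue every burst: start time, duration, AP at start, peak count.

    Returns columns movie_id, nucleus_id, t_start_s, duration_s, ap_start,
    max_promoters.
    """
    rows = []
    for (movie, nuc), g in decoded.groupby(["movie_id", "nucleus_id"], sort=True):
        g = g.sort_values("t_s")
        s = g["s"].to_numpy()
        t = g["t_s"].to_numpy(float)
        ap = g["ap"].to_numpy(float)
        dt = t[1] - t[0] if t.size > 1 else np.nan
        for start, length in _runs_on(s):
            rows.append(
                {
                    "movie_id": movie,
                    "nucleus_id": nuc,
                    "t_start_s": t[start],
                    "duration_s": length * dt,
                    "ap_start": ap[start],
                    "max_promoters": int(s[start : start + length].max()),
                }
            )
    cols = ["movie_id", "nucleus_id", "t_start_s", "duration_s", "ap_start", "max_promoters"]
    return pd.DataFrame(rows, columns=cols)


def _ap_bin(ap: np.ndarray, ap_bin_frac: float) -> np.ndarray:
    """Left-closed bins with edges at exact multiples of the bin width."""
    return np.floor(np.asarray(ap, float) / ap_bin_frac).astype(int)


def _binned_map(decoded: pd.DataFrame, value: pd.Series, agg: str, ap_bin_frac: float):
    d = decoded.assign(_bin=_ap_bin(decoded["ap"].to_numpy(), ap_bin_frac), _v=value)
    table = d.pivot_table(index="t_s", columns="_bin", values="_v", aggfunc=agg)
    table.columns = table.columns * ap_bin_frac  # bin left edges (AP fraction)
    return table


def fraction_on_map(decoded: pd.DataFrame, ap_bin_frac: float = 0.01) -> pd.DataFrame:
    """Instantaneous fraction of nuclei in the ON state per (time, AP bin).

    Cell (t, bin) = #nuclei with s >= 1 / #nuclei present; empty cells NaN.
    """
    return _binned_map(decoded, (decoded["s"] >= 1).astype(float), "mean", ap_bin_frac)


def mean_fluorescence_map(dataset: pd.DataFrame, ap_bin_frac: float = 0.01) -> pd.DataFrame:
    """Mean fluorescence of the nuclei in each (time, AP) bin."""
    return _binned_map(dataset, dataset["fluo_au"], "mean", ap_bin_frac)


def fraction_bursted_before(decoded: pd.DataFrame, ap_bin_frac: float = 0.01) -> pd.DataFrame:
    """Fraction of nuclei whose first burst started at or before t, per AP bin.

    Nuclei are attributed to the AP bin of their first burst (never-ON nuclei
    to the bin of their mean position, counting 0 everywhere); rows are
    non-decreasing in t.
    """
    t_grid = np.sort(decoded["t_s"].unique())
    first_burst: list[tuple[int, float | None]] = []
    for (_, _), g in decoded.groupby(["movie_id", "nucleus_id"], sort=True):
        g = g.sort_values("t_s")
        s = g["s"].to_numpy()
        onset = np.flatnonzero(s >= 1)
        if onset.size:
            i = onset[0]
            first_burst.append((_ap_bin(g["ap"].to_numpy()[i : i + 1], ap_bin_frac)[0],
                                g["t_s"].to_numpy()[i]))
        else:
            first_burst.append((_ap_bin([np.nanmean(g["ap"])], ap_bin_frac)[0], None))
    bins = sorted({b for b, _ in first_burst})
    out = pd.DataFrame(0.0, index=t_grid, columns=[b * ap_bin_frac for b in bins])
    counts = {b: 0 for b in bins}
    for b, _ in first_burst:
        counts[b] += 1
    for b in bins:
        started = np.zeros(t_grid.size)
        for bb, t0 in first_burst:
            if bb == b and t0 is not None:
                started += t_grid >= t0
        out[b * ap_bin_frac] = started / counts[b]
    out.index.name = "t_s"
    return out


def find_never_on(decoded: pd.DataFrame) -> pd.DataFrame:
    """Nuclei never decoded ON at any frame, with their position tracks.

    Returns the rows of ``decoded`` belonging to never-ON nuclei.
    """
    ever = decoded.assign(_on=decoded["s"] >= 1).groupby(["movie_id", "nucleus_id"])["_on"].any()
    never = ever[~ever].index
    idx = pd.MultiIndex.from_frame(decoded[["movie_id", "nucleus_id"]])
    return decoded[idx.isin(never)].copy()


def activity_difference_events(
    decoded: pd.DataFrame, window_min: float = 10.0
) -> pd.DataFrame:
    """ON-fraction change around each burst start.

    At every frame where a new burst initiates, Δ = (fraction of frames with
    s >= 1 in the next ``window_min`` minutes) − (same over the preceding
    ``window_min``).  Events without a full window on both sides are dropped.
    Returns movie_id, nucleus_id, t_start_s, ap_start, delta_activity.
    """
    rows = []
    for (movie, nuc), g in decoded.groupby(["movie_id", "nucleus_id"], sort=True):
        g = g.sort_values("t_s")
        s = (g["s"].to_numpy() >= 1).astype(float)
        t = g["t_s"].to_numpy(float)
        ap = g["ap"].to_numpy(float)
        if t.size < 2:
            continue
        dt = t[1] - t[0]
        halfw = int(round(window_min * 60.0 / dt))
        for start, _ in _runs_on(g["s"].to_numpy()):
            if start - halfw < 0 or start + halfw > s.size:
                continue
            before = s[start - halfw : start].mean()
            after = s[start : start + halfw].mean()
            rows.append(
                {
                    "movie_id": movie,
                    "nucleus_id": nuc,
                    "t_start_s": t[start],
                    "ap_start": ap[start],
                    "delta_activity": after - before,
                }
            )
    cols = ["movie_id", "nucleus_id", "t_start_s", "ap_start", "delta_activity"]
    return pd.DataFrame(rows, columns=cols)


def weighted_parameter_profile(
    bin_table: pd.DataFrame,
    counts: pd.DataFrame,
    params: tuple[str, ...] = ("kon_per_min", "koff_per_min", "r_au_per_min"),
) -> pd.DataFrame:
    """Burst parameters along the AP axis, weighting bins by local occupancy.

    ``bin_table`` holds one row per (stripe, bin) with parameter columns (the
    fluorescence-binned inference output); ``counts`` holds one row per
    (stripe, bin, ap_bin) with an ``n`` column giving how many nuclei of that
    fluorescence bin sit at that AP position.  The profile at an AP bin is
    the count-weighted mean over fluorescence bins:
    θ(AP) = Σ_b n_{AP,b} θ_b / Σ_b n_{AP,b}.
    """
    merged = counts.merge(bin_table, on=["stripe", "bin"], how="inner")
    out_rows = []
    for (stripe, ap_bin), g in merged.groupby(["stripe", "ap_bin"]):
        n = g["n"].to_numpy(float)
        if n.sum() == 0:
            continue
        row = {"stripe": stripe, "ap_bin": ap_bin, "n": n.sum()}
        for p in params:
            row[p] = float(np.average(g[p], weights=n))
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def stripe_center_trajectory(
    decoded: pd.DataFrame, stripe_col: str = "consensus_stripe"
) -> pd.DataFrame:
    """Registered stripe center over time: mean AP of bursting member nuclei.

    Uses frames with s >= 1 of nuclei assigned to the stripe; cells with no
    bursting nucleus are absent.  Columns: stripe, t_s, ap_center, n.
    """
    on = decoded[decoded["s"] >= 1]
    g = on.groupby([stripe_col, "t_s"])["ap"]
    out = g.agg(ap_center="mean", n="size").reset_index()
    return out.rename(columns={stripe_col: "stripe"})


def stripe_velocity(
    centers: pd.DataFrame, t_range_s: tuple[float, float] | None = None
) -> float:
    """Least-squares stripe-center velocity in percent egg length per minute.

    ``centers`` has columns t_s and ap_center (one stripe).  Anterior
    movement is negative.
    """
    d = centers
    if t_range_s is not None:
        d = d[(d["t_s"] >= t_range_s[0]) & (d["t_s"] <= t_range_s[1])]
    if len(d) < 2:
        raise ValueError("need at least two center points to fit a velocity")
    t_min = d["t_s"].to_numpy(float) / 60.0
    ap_pct = d["ap_center"].to_numpy(float) * 100.0
    slope = np.polyfit(t_min, ap_pct, 1)[0]
    return float(slope)
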