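"""Dynamic stripe assignment, position modeling and cross-movie registration.

Stripes are located by Gaussian-mixture clustering of actively transcribing
nucleus-frames in overlapping time windows (tied covariance, one component
per stripe), their tilt relative to the image y-axis is estimated from median
positions in the top and bottom halves of the field, a fixed-slope line per
window yields stripe position (x at y = 128) versus time, and a linear model
of those intercepts lets every nucleus-frame be assigned to its nearest
stripe at every time point.  Movies are finally registered onto a common AP
axis by anchoring each stripe's center at 35 min to the cross-movie mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

__all__ = [
    "StripeModel",
    "cluster_time_windows",
    "fit_stripe_orientation",
    "fit_stripe_position_model",
    "map_to_ap_and_reorient",
    "assign_nuclei_to_stripes",
    "register_stripes_across_movies",
    "bootstrap_registration",
    "analyze_movie_stripes",
]

Y_MID_PX = 128.0


@dataclass
class StripeModel:
    """Per-movie linear model of one stripe's position over time.

    ``x(t, y) = c0 + c1 * t_s + slope_x_per_y * (y - 128)``; the registration
    offset is an additive AP correction shared by all frames.
    """

    movie_id: str
    stripe_id: int
    slope_x_per_y: float
    c0_px: float  # x at y=128 at t=0
    c1_px_per_s: float  # velocity along x
    t_min_s: float = 0.0
    t_max_s: float = np.inf
    registration_offset_ap: float = 0.0
    flagged: bool = False

    def x_at(self, t_s, y_px=Y_MID_PX):
        """Predicted stripe x position at time t and image row y."""
        return self.c0_px + self.c1_px_per_s * np.asarray(t_s, float) + self.slope_x_per_y * (
            np.asarray(y_px, float) - Y_MID_PX
        )

    def to_dict(self) -> dict:
        return {
            "movie_id": self.movie_id,
            "stripe_id": self.stripe_id,
            "slope_x_per_y": self.slope_x_per_y,
            "c0_px": self.c0_px,
            "c1_px_per_s": self.c1_px_per_s,
            "t_min_s": self.t_min_s,
            "t_max_s": self.t_max_s if np.isfinite(self.t_max_s) else None,
            "registration_offset_ap": self.registration_offset_ap,
            "flagged": self.flagged,
        }


def _windows(t_lo: float, t_hi: float, window_s: float, step_s: float):
    """Overlapping [start, start + window] intervals covering [t_lo, t_hi]."""
    starts = np.arange(t_lo, t_hi, step_s)
    if starts.size == 0:
        starts = np.array([t_lo])
    return [(s, s + window_s) for s in starts]


def cluster_time_windows(
    df: pd.DataFrame,
    n_stripes: int,
    window_s: float = 428.0,
    step_s: float = 214.0,
    start_min: float = 25.0,
    activity_threshold_au: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Preliminary per-frame stripe labels for actively transcribing nuclei.

    A Gaussian mixture with ``n_stripes`` components and tied covariance is
    fitted to the (x, y) positions of active nucleus-frames in each
    overlapping time window from ``start_min`` onward; components are ordered
    anterior to posterior by mean x (stripes never cross, so rank order
    matches components across windows).  A nucleus-frame keeps a label iff it
    receives the same one in a majority of the windows that contain it.

    ``df`` needs columns t_s, x_px, y_px, fluo_au; returns a copy of the
    active subset with a 0-based ``stripe_local`` column (-1 = unassigned).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    active = df[(df["fluo_au"] > activity_threshold_au) & np.isfinite(df["fluo_au"])].copy()
    t_lo = start_min * 60.0
    pts = active[active["t_s"] >= t_lo]
    if pts.empty:
        raise ValueError(f"no active points at or after {start_min} min")
    t_hi = float(pts["t_s"].max())
    votes = np.zeros((len(active), n_stripes), dtype=np.int32)
    covered = np.zeros(len(active), dtype=np.int32)
    tvals = active["t_s"].to_numpy()
    xy = active[["x_px", "y_px"]].to_numpy(float)
    for lo, hi in _windows(t_lo, t_hi, window_s, step_s):
        mask = (tvals >= lo) & (tvals <= hi)
        if mask.sum() < n_stripes:
            warnings.warn(f"window [{lo:.0f}, {hi:.0f}] s has too few active points; skipped",
                          stacklevel=2)
            continue
        pts_w = xy[mask]
        # stripes separate along x (the AP axis), so seed component means at
        # x-quantiles; a k-means init can lock onto the larger y-variance
        q = (np.arange(n_stripes) + 0.5) / n_stripes
        means0 = np.column_stack(
            [np.quantile(pts_w[:, 0], q), np.full(n_stripes, pts_w[:, 1].mean())]
        )
        gmm = GaussianMixture(
            n_components=n_stripes,
            covariance_type="tied",
            means_init=means0,
            random_state=int(rng.integers(2**31 - 1)),
        )
        labels = gmm.fit_predict(pts_w)
        order = np.argsort(gmm.means_[:, 0])  # anterior (small x) -> posterior
        rank = np.empty(n_stripes, dtype=int)
        rank[order] = np.arange(n_stripes)
        votes[np.flatnonzero(mask), rank[labels]] += 1
        covered[mask] += 1
    best = votes.argmax(axis=1)
    majority = votes[np.arange(len(active)), best] * 2 > covered
    active["stripe_local"] = np.where((covered > 0) & majority, best, -1)
    return active


def fit_stripe_orientation(x_px, y_px) -> float:
    """Stripe tilt as run-over-rise of median positions in the two half-images.

    slope = (median x_top - median x_bottom) / (median y_top - median y_bottom)
    with top = y > 128 and bottom = y < 128.  An empty half yields slope 0
    with a warning.
    """
    x = np.asarray(x_px, float)
    y = np.asarray(y_px, float)
    bot = y < Y_MID_PX
    top = y > Y_MID_PX
    if not bot.any() or not top.any():
        warnings.warn("empty half-image; stripe orientation set to 0", stacklevel=2)
        return 0.0
    dy = np.median(y[top]) - np.median(y[bot])
    if dy == 0:
        return 0.0
    return float((np.median(x[top]) - np.median(x[bot])) / dy)


def fit_stripe_position_model(
    labeled: pd.DataFrame,
    slope: float,
    movie_id: str,
    stripe_id: int,
    window_s: float = 428.0,
    step_s: float = 214.0,
) -> StripeModel:
    """Linear position-versus-time model from fixed-slope window fits.

    Per time window, the least-squares intercept of the fixed-slope line is
    the mean of ``x - slope * (y - 128)`` over that window's points; ordinary
    least squares of intercept against the window's mean point time (exact
    for linear motion, unlike the window midpoint) gives the linear model.
    A single usable window yields a constant (flagged) model.
    """
    t = labeled["t_s"].to_numpy(float)
    x0 = labeled["x_px"].to_numpy(float) - slope * (labeled["y_px"].to_numpy(float) - Y_MID_PX)
    mids, intercepts = [], []
    for lo, hi in _windows(t.min(), t.max(), window_s, step_s):
        m = (t >= lo) & (t <= hi)
        if m.sum() == 0:
            continue
        mids.append(t[m].mean())
        intercepts.append(x0[m].mean())
    if not mids:
        raise ValueError("no window contained labeled points")
    if len(mids) == 1:
        return StripeModel(movie_id, stripe_id, slope, intercepts[0], 0.0,
                           t_min_s=t.min(), t_max_s=t.max(), flagged=True)
    c1, c0 = np.polyfit(mids, intercepts, 1)
    return StripeModel(movie_id, stripe_id, slope, float(c0), float(c1),
                       t_min_s=t.min(), t_max_s=t.max())


def map_to_ap_and_reorient(
    df: pd.DataFrame,
    models: dict[int, StripeModel],
    stripe_col: str,
    pole_x_anterior_px: float,
    pole_x_posterior_px: float,
) -> np.ndarray:
    """Tilt-corrected AP position per row.

    Each nucleus keeps its x-offset to its stripe's (tilted) line but is
    moved to the line's position at y = 128, which amounts to
    ``corrected_x = x - slope * (y - 128)`` with the assigned stripe's slope;
    unassigned rows use slope 0.  AP fraction is the linear pole map.
    """
    if pole_x_anterior_px == pole_x_posterior_px:
        raise ValueError("anterior and posterior pole x coordinates must differ")
    x = df["x_px"].to_numpy(float)
    y = df["y_px"].to_numpy(float)
    slope = np.zeros(len(df))
    lab = df[stripe_col].to_numpy()
    for sid, m in models.items():
        slope[lab == sid] = m.slope_x_per_y
    corrected = x - slope * (y - Y_MID_PX)
    return (corrected - pole_x_anterior_px) / (pole_x_posterior_px - pole_x_anterior_px)


def assign_nuclei_to_stripes(
    df: pd.DataFrame,
    models: dict[int, StripeModel],
    freeze_min: float = 25.0,
) -> pd.DataFrame:
    """Assign every nucleus-frame (active or not) to its nearest stripe.

    The distance is along x to each stripe's predicted line at the nucleus's
    y; before ``freeze_min`` the stripe positions are frozen at their
    ``freeze_min`` values (stripes are not all formed earlier).  Ties go to
    the more anterior stripe.  The per-nucleus consensus is the modal label,
    ties again anterior.

    Returns a copy of ``df`` with ``stripe`` and ``consensus_stripe`` columns.
    """
    out = df.copy()
    t = np.maximum(out["t_s"].to_numpy(float), freeze_min * 60.0)
    y = out["y_px"].to_numpy(float)
    x = out["x_px"].to_numpy(float)
    sids = sorted(models)  # anterior stripes have smaller ids
    dists = np.stack([np.abs(x - models[s].x_at(t, y)) for s in sids], axis=1)
    out["stripe"] = np.asarray(sids)[dists.argmin(axis=1)]  # argmin takes first=anterior on ties
    consensus = (
        out.groupby(["movie_id", "nucleus_id"])["stripe"]
        .agg(lambda s: s.value_counts().sort_index().idxmax())
        .rename("consensus_stripe")
    )
    out = out.merge(consensus, on=["movie_id", "nucleus_id"], how="left")
    return out


def register_stripes_across_movies(
    models_by_movie: dict[str, dict[int, StripeModel]],
    poles_by_movie: dict[str, tuple[float, float]],
    anchor_min: float = 35.0,
) -> pd.DataFrame:
    """Additive AP offsets aligning each stripe's 35-min center across movies.

    The offset of (movie, stripe) is the cross-movie mean AP of that stripe
    at the anchor time minus this movie's value; it is stored on the
    StripeModel and returned as a table.  A movie whose model does not cover
    the anchor time is evaluated at its nearest modeled time and flagged.
    """
    t_anchor = anchor_min * 60.0
    rows = []
    for movie, models in models_by_movie.items():
        x_ant, x_post = poles_by_movie[movie]
        for sid, m in models.items():
            t_eval = float(np.clip(t_anchor, m.t_min_s, m.t_max_s))
            flagged = t_eval != t_anchor
            ap = (m.x_at(t_eval) - x_ant) / (x_post - x_ant)
            rows.append({"movie_id": movie, "stripe_id": sid, "ap_at_anchor": ap,
                         "flagged": flagged})
    table = pd.DataFrame(rows)
    mean_ap = table.groupby("stripe_id")["ap_at_anchor"].transform("mean")
    table["registration_offset_ap"] = mean_ap - table["ap_at_anchor"]
    for _, row in table.iterrows():
        m = models_by_movie[row["movie_id"]][row["stripe_id"]]
        m.registration_offset_ap = float(row["registration_offset_ap"])
        m.flagged = m.flagged or bool(row["flagged"])
    return table


def bootstrap_registration(
    models_by_movie: dict[str, dict[int, StripeModel]],
    poles_by_movie: dict[str, tuple[float, float]],
    anchor_min: float = 35.0,
    n_boot: int = 100,
    seed: int | np.random.Generator | None = None,
) -> dict:
    """Robustness of registration to the movie sample.

    Movies are resampled with replacement; each resample re-derives the
    per-stripe anchor mean, and the statistic is the displacement of the
    registered stripe centers relative to the full-sample registration.
    Returns per-stripe and pooled standard deviations (AP fraction).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    full = register_stripes_across_movies(models_by_movie, poles_by_movie, anchor_min)
    base = full.groupby("stripe_id")["ap_at_anchor"].mean()
    movie_ids = sorted(models_by_movie)
    disp: dict[int, list[float]] = {sid: [] for sid in base.index}
    for _ in range(n_boot):
        picked = [movie_ids[i] for i in rng.integers(0, len(movie_ids), len(movie_ids))]
        sub = full[full["movie_id"].isin(set(picked))]
        # weight by multiplicity of the resampled movies
        counts = pd.Series(picked).value_counts()
        for sid, g in sub.groupby("stripe_id"):
            wts = g["movie_id"].map(counts).to_numpy(float)
            disp[sid].append(float(np.average(g["ap_at_anchor"], weights=wts) - base[sid]))
    per_stripe = {int(sid): float(np.std(v)) for sid, v in disp.items() if v}
    pooled = float(np.std(np.concatenate([np.asarray(v) for v in disp.values() if v])))
    return {"per_stripe_sd_ap": per_stripe, "pooled_sd_ap": pooled}


def analyze_movie_stripes(
    df_movie: pd.DataFrame,
    stripe_ids: list[int],
    window_s: float = 428.0,
    step_s: float = 214.0,
    start_min: float = 25.0,
    activity_threshold_au: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> dict[int, StripeModel]:
    """Cluster one movie's active frames and fit a StripeModel per stripe.

    ``stripe_ids`` are the (anterior-to-posterior) global stripe numbers the
    movie covers; cluster ranks map onto them in order.
    """
    movie_id = str(df_movie["movie_id"].iloc[0])
    labeled = cluster_time_windows(
        df_movie, len(stripe_ids), window_s, step_s, start_min,
        activity_threshold_au, seed,
    )
    models: dict[int, StripeModel] = {}
    for rank, sid in enumerate(sorted(stripe_ids)):
        pts = labeled[labeled["stripe_local"] == rank]
        if pts.empty:
            warnings.warn(f"no points assigned to stripe {sid} in movie {movie_id}",
                          stacklevel=2)
            continue
        slope = fit_stripe_orientation(pts["x_px"], pts["y_px"])
        models[sid] = fit_stripe_position_model(pts, slope, movie_id, sid, window_s, step_s)
    return models
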