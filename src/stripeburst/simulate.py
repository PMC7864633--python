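"""Seeded synthetic-data generator: telegraph promoter paths, noisy MS2
traces, and multi-movie embryo datasets with stripe-patterned bursting.

The embryo generator emulates the statistical structure the downstream
analysis assumes: several movies each imaging a window of the blastoderm
covering a few stripes; ~50 min of nc14 sampled every 20 s; transcription
onset a few minutes into the cycle; burst initiation rate ``k_on`` and
loading rate ``r`` elevated in Gaussian stripe profiles while ``k_off`` is
spatially flat; a fraction of interstripe nuclei that never burst; slow
nuclear drift in the image plane; and anterior treadmilling of the stripe
profiles themselves.  It emits a trace table in the interchange CSV schema
and a matched ground-truth table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .pulse import ModelConfig, fluorescence_from_states
from .trace_io import NucleusTrace, frame_to_traces

__all__ = [
    "SimulationConfig",
    "EmbryoDataset",
    "simulate_promoter_path",
    "simulate_trace",
    "simulate_embryo_dataset",
]

IMAGE_W_PX = 1024
IMAGE_H_PX = 256

# canonical AP positions of the seven stripes (fraction of egg length),
# evenly spread over the trunk region where the pattern forms
DEFAULT_STRIPE_CENTERS = (0.33, 0.40, 0.47, 0.53, 0.60, 0.67, 0.74)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of the synthetic embryo.

    Rates are per minute; positions are AP fractions of egg length unless
    suffixed ``_px``.  ``drift_ap_pct_per_min`` is the anterior treadmilling
    velocity of the *posterior-most* stripe in percent egg length per minute
    (anterior movement positive here, applied as decreasing AP), active from
    ``drift_start_min`` once stripes are established.  Velocity scales
    linearly with stripe index so the anterior-most stripe is static and the
    posterior-most moves at the full rate — anterior stripes hold their
    positions while the last stripe treadmills strongly.
    """

    n_movies: int = 3
    stripes_per_movie: int = 3
    n_nuclei_per_movie: int = 120
    duration_min: float = 50.0
    dt_s: float = 20.0
    onset_time_min: float = 5.0
    stripe_centers_ap: tuple[float, ...] = DEFAULT_STRIPE_CENTERS
    stripe_width_ap: float = 0.015
    kon_peak: float = 0.60
    kon_baseline: float = 0.05
    koff: float = 0.60
    r_peak: float = 67.0
    r_baseline: float = 20.0
    never_on_interstripe_frac: float = 0.6
    drift_ap_pct_per_min: float = 1.0 / 3.0
    drift_start_min: float = 25.0
    nuclear_drift_px_per_min: float = 1.0
    noise_sd_au: float = 15.0
    t_elong_s: float = 140.0
    n_promoters: int = 2
    promoter_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("kon_peak", "kon_baseline", "koff", "r_peak", "r_baseline"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.never_on_interstripe_frac <= 1:
            raise ValueError("never_on_interstripe_frac must be in [0, 1]")
        if not 0 <= self.promoter_correlation <= 1:
            raise ValueError("promoter_correlation must be in [0, 1]")
        centers = np.asarray(self.stripe_centers_ap)
        if np.any(np.diff(centers) <= 0):
            raise ValueError("stripe_centers_ap must be sorted anterior to posterior")
        if np.any(np.diff(centers) < 2 * self.stripe_width_ap):
            warnings.warn("stripe centers closer than 2 sd: stripes overlap", stacklevel=2)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_min * 60.0 / self.dt_s)) + 1

    def stripe_centers_at(self, t_s) -> np.ndarray:
        """Ground-truth stripe centers (AP fraction) at times ``t_s`` (seconds).

        Shape (n_times, n_stripes); anterior treadmilling after
        ``drift_start_min`` at a velocity growing linearly from 0 (first
        stripe) to ``drift_ap_pct_per_min`` (last stripe).
        """
        t_min = np.atleast_1d(np.asarray(t_s, float)) / 60.0
        centers0 = np.asarray(self.stripe_centers_ap)
        n = centers0.size
        scale = np.arange(n) / (n - 1) if n > 1 else np.ones(1)
        drift = (self.drift_ap_pct_per_min / 100.0) * np.maximum(
            0.0, t_min - self.drift_start_min
        )
        return centers0[None, :] - drift[:, None] * scale[None, :]

    def model_config(self) -> ModelConfig:
        return ModelConfig(
            dt_s=self.dt_s,
            t_elong_s=self.t_elong_s,
            n_promoters=self.n_promoters,
            r_au_per_min=self.r_peak,
        )


def _switch_probs(kon: np.ndarray, koff: float, dt_min: float):
    """Exact interval transition probabilities of the telegraph process.

    For constant rates over an interval of ``dt_min`` minutes,
    P(OFF->ON) = kon/s * (1 - e^{-s dt}) and P(ON->OFF) = koff/s * (1 - e^{-s dt})
    with s = kon + koff; this makes the sampled chain exactly Markov with
    transition matrix expm(Q dt).
    """
    s = kon + koff
    with np.errstate(divide="ignore", invalid="ignore"):
        decay = -np.expm1(-s * dt_min)
        p01 = np.where(s > 0, kon / np.where(s > 0, s, 1.0) * decay, 0.0)
        p10 = np.where(s > 0, koff / np.where(s > 0, s, 1.0) * decay, 0.0)
    return p01, p10


def _single_promoter_path(
    kon_t: np.ndarray, koff: float, dt_min: float, rng: np.random.Generator,
    u: np.ndarray | None = None,
) -> np.ndarray:
    """Binary ON/OFF path on the frame grid; frame 0 from the local stationary
    distribution.  ``u`` optionally supplies the per-frame uniform draws
    (used to correlate sister promoters)."""
    n = kon_t.size
    if u is None:
        u = rng.random(n)
    state = np.zeros(n, dtype=np.int64)
    s0 = kon_t[0] + koff
    p_on0 = kon_t[0] / s0 if s0 > 0 else 0.0
    state[0] = 1 if u[0] < p_on0 else 0
    p01, p10 = _switch_probs(kon_t, koff, dt_min)
    for t in range(1, n):
        if state[t - 1] == 0:
            state[t] = 1 if u[t] < p01[t] else 0
        else:
            state[t] = 0 if u[t] < p10[t] else 1
    return state


def simulate_promoter_path(
    kon_per_min,
    koff_per_min: float,
    n_frames: int,
    dt_s: float = 20.0,
    n_promoters: int = 2,
    seed: int | np.random.Generator | None = None,
    promoter_correlation: float = 0.0,
) -> np.ndarray:
    """Sample a promoter-ON-count path from independent telegraph promoters.

    ``kon_per_min`` may be a scalar or a per-frame array (rates held constant
    within each frame interval).  With ``promoter_correlation = rho`` the
    sister promoters share each frame's random draw with probability rho
    (rho = 1 makes them identical, rho = 0 independent).
    """
    kon_t = np.broadcast_to(np.asarray(kon_per_min, float), (n_frames,)).copy()
    if kon_t.min() < 0 or koff_per_min < 0:
        raise ValueError("rates must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt_min = dt_s / 60.0
    u1 = rng.random(n_frames)
    path = _single_promoter_path(kon_t, koff_per_min, dt_min, rng, u=u1)
    if n_promoters == 2:
        u2 = rng.random(n_frames)
        if promoter_correlation > 0:
            shared = rng.random(n_frames) < promoter_correlation
            u2 = np.where(shared, u1, u2)
        path = path + _single_promoter_path(kon_t, koff_per_min, dt_min, rng, u=u2)
    elif n_promoters != 1:
        raise ValueError("n_promoters must be 1 or 2")
    return path


def simulate_trace(
    path,
    config: ModelConfig,
    noise_sd_au: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Noiseless forward-model fluorescence plus i.i.d. Gaussian noise."""
    if noise_sd_au < 0:
        raise ValueError("noise_sd_au must be >= 0")
    f = fluorescence_from_states(path, config)
    if noise_sd_au == 0:
        return f
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return f + rng.normal(0.0, noise_sd_au, size=f.size)


@dataclass
class EmbryoDataset:
    """Trace table + ground truth + per-movie geometry for one synthetic embryo."""

    traces: pd.DataFrame  # interchange CSV schema
    truth: pd.DataFrame  # movie_id,nucleus_id,frame,s_true,kon_true,koff_true,r_true,stripe_true
    movies: dict  # movie_id -> {pole_x_anterior_px, pole_x_posterior_px, stripe_ids}
    config: SimulationConfig

    def nucleus_traces(self) -> list[NucleusTrace]:
        return frame_to_traces(self.traces)

    def write(self, traces_path, truth_path, sidecar_path=None) -> None:
        self.traces.to_csv(traces_path, index=False, float_format="%.6g")
        self.truth.to_csv(truth_path, index=False, float_format="%.6g")
        if sidecar_path is not None:
            meta = {"config": asdict(self.config), "movies": self.movies}
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=1, default=list)


def simulate_embryo_dataset(sim: SimulationConfig) -> EmbryoDataset:
    """Generate a multi-movie synthetic embryo dataset.

    Each movie images a contiguous block of ``stripes_per_movie`` stripes with
    a margin of interstripe on either side.  Nuclei sit on a jittered lattice
    in image coordinates and drift slowly in a random direction.  Per
    nucleus-frame, ``k_on`` and ``r`` are the baseline plus Gaussian stripe
    bumps (centers treadmilling anteriorly after ``drift_start_min``), while
    ``k_off`` is flat.  Interstripe nuclei are silenced entirely with
    probability ``never_on_interstripe_frac``; all nuclei are silent before
    ``onset_time_min``.
    """
    rng = np.random.default_rng(sim.seed)
    n_frames = sim.n_frames
    t_s = sim.dt_s * np.arange(n_frames)
    t_min = t_s / 60.0
    centers0 = np.asarray(sim.stripe_centers_ap)
    n_stripes_total = centers0.size
    centers_t = sim.stripe_centers_at(t_s)  # (n_frames, n_stripes)

    mcfg = sim.model_config()
    dt_min = sim.dt_s / 60.0
    trace_rows = []
    truth_rows = []
    movies: dict = {}

    for m in range(sim.n_movies):
        movie_id = f"m{m + 1:02d}"
        first = (m * sim.stripes_per_movie) % max(1, n_stripes_total - sim.stripes_per_movie + 1)
        stripe_ids = np.arange(first, min(first + sim.stripes_per_movie, n_stripes_total))
        ap_lo = centers0[stripe_ids[0]] - 4 * sim.stripe_width_ap
        ap_hi = centers0[stripe_ids[-1]] + 4 * sim.stripe_width_ap
        # linear image->AP map; poles generally fall outside the field of view
        px_per_ap = IMAGE_W_PX / (ap_hi - ap_lo)
        pole_ant_px = -ap_lo * px_per_ap
        pole_post_px = (1.0 - ap_lo) * px_per_ap
        movies[movie_id] = {
            "pole_x_anterior_px": float(pole_ant_px),
            "pole_x_posterior_px": float(pole_post_px),
            "stripe_ids": [int(s) + 1 for s in stripe_ids],
        }

        # jittered lattice filling the field of view
        n_nuc = sim.n_nuclei_per_movie
        aspect = IMAGE_W_PX / IMAGE_H_PX
        ny = max(1, int(round(np.sqrt(n_nuc / aspect))))
        nx = int(np.ceil(n_nuc / ny))
        gx, gy = np.meshgrid(
            (np.arange(nx) + 0.5) * IMAGE_W_PX / nx, (np.arange(ny) + 0.5) * IMAGE_H_PX / ny
        )
        order = rng.permutation(nx * ny)[:n_nuc]
        x0 = gx.ravel()[order] + rng.normal(0, 0.15 * IMAGE_W_PX / nx, n_nuc)
        y0 = gy.ravel()[order] + rng.normal(0, 0.15 * IMAGE_H_PX / ny, n_nuc)
        theta = rng.uniform(0, 2 * np.pi, n_nuc)
        vx = sim.nuclear_drift_px_per_min * np.cos(theta)
        vy = sim.nuclear_drift_px_per_min * np.sin(theta)

        for i in range(n_nuc):
            nucleus_id = f"n{i + 1:04d}"
            x_t = x0[i] + vx[i] * t_min
            y_t = y0[i] + vy[i] * t_min
            ap_t = (x_t - pole_ant_px) / (pole_post_px - pole_ant_px)
            # Gaussian stripe weight of the *covered* stripes, following the drift
            d2 = (ap_t[:, None] - centers_t[:, stripe_ids]) ** 2
            g = np.exp(-d2 / (2 * sim.stripe_width_ap**2))
            g_max = g.max(axis=1)
            kon_t = sim.kon_baseline + (sim.kon_peak - sim.kon_baseline) * g_max
            r_t = sim.r_baseline + (sim.r_peak - sim.r_baseline) * g_max

            # stripe label: modal nearest stripe over frames, if the nucleus
            # ever comes within 2 sd of a (possibly drifting) stripe center
            ever_core = g_max.max() >= np.exp(-2.0)
            if ever_core:
                per_frame = stripe_ids[np.argmax(g, axis=1)]
                stripe_true = int(np.bincount(per_frame).argmax()) + 1
            else:
                stripe_true = 0  # interstripe
            never_on = (not ever_core) and (rng.random() < sim.never_on_interstripe_frac)

            if never_on:
                s = np.zeros(n_frames, dtype=np.int64)
            else:
                s = simulate_promoter_path(
                    kon_t,
                    sim.koff,
                    n_frames,
                    dt_s=sim.dt_s,
                    n_promoters=sim.n_promoters,
                    seed=rng,
                    promoter_correlation=sim.promoter_correlation,
                )
                s[t_min < sim.onset_time_min] = 0

            # per-frame loading rate while ON; fluorescence uses the local r
            pulse = (r_t / 60.0) * sim.dt_s * s
            kernel = np.ones(mcfg.w)
            f_clean = np.convolve(pulse, kernel)[:n_frames]
            fluo = f_clean
            if sim.noise_sd_au > 0:
                fluo = f_clean + rng.normal(0, sim.noise_sd_au, n_frames)

            trace_rows.append(
                pd.DataFrame(
                    {
                        "movie_id": movie_id,
                        "nucleus_id": nucleus_id,
                        "frame": np.arange(n_frames),
                        "t_s": t_s,
                        "x_px": x_t,
                        "y_px": y_t,
                        "ap_frac": np.clip(ap_t, 0.0, 1.0),
                        "fluo_au": fluo,
                    }
                )
            )
            truth_rows.append(
                pd.DataFrame(
                    {
                        "movie_id": movie_id,
                        "nucleus_id": nucleus_id,
                        "frame": np.arange(n_frames),
                        "s_true": s,
                        "kon_true": kon_t,
                        "koff_true": sim.koff,
                        "r_true": r_t,
                        "stripe_true": stripe_true,
                    }
                )
            )

    traces = pd.concat(trace_rows, ignore_index=True)
    truth = pd.concat(truth_rows, ignore_index=True)
    return EmbryoDataset(traces=traces, truth=truth, movies=movies, config=sim)
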