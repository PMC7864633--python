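"""Pipeline orchestration: staged analysis from trace table to burst metrics.

Stage order mirrors the analysis: simulate (optional) → filter → transit →
stripes (assignment + registration) → fit → decode → metrics.  Every stage
reads and writes plain CSV/JSON under one artifact directory and records a
manifest entry (parameters, seed, input hashes) so stages can be re-run
individually and reproducibly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cphmm, metrics, stripes, transit
from .pulse import ModelConfig
from .simulate import SimulationConfig, simulate_embryo_dataset
from .trace_io import filter_traces, frame_to_traces, read_traces, traces_to_frame, write_traces

log = logging.getLogger("stripeburst")

STAGES = ["simulate", "filter", "transit", "stripes", "fit", "decode", "metrics"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, loadable from one YAML/JSON file."""

    outdir: str = "results/pipeline"
    traces_csv: str | None = None  # input; defaults to the simulate stage output
    seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # movie geometry: movie_id -> {"stripe_ids": [...], "poles": [x_ant, x_post]}
    movies: dict = field(default_factory=dict)
    # stripe-geometry settings
    window_s: float = 428.0
    step_s: float = 214.0
    cluster_start_min: float = 25.0
    anchor_min: float = 35.0
    activity_threshold_au: float = 0.0
    n_boot_registration: int = 100
    # cpHMM settings
    K: int = 2
    w: int = 7
    n_restarts: int = 5
    max_iter: int = 500
    tol_per_1000: float = 1e-4
    n_bins: int = 5
    min_points: int = 1000
    subset_size: int = 3000
    n_boot_bins: int = 10
    binned: bool = False
    # filters
    min_span_s: float = 2000.0
    max_speed_px_per_min: float = 4.5
    # transit
    d_max: int = 20
    n_boot_transit: int = 100

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "model" in kwargs:
            kwargs["model"] = ModelConfig(**kwargs["model"])
        if "sim" in kwargs:
            kwargs["sim"] = SimulationConfig(**kwargs["sim"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def _sidecar(path: Path, cfg: PipelineConfig, stage: str, extra: dict | None = None) -> None:
    meta = {"stage": stage, "seed": cfg.seed, "config_hash": cfg.config_hash()}
    if extra:
        meta.update(extra)
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class Pipeline:
    """Runs stages against one artifact directory."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.outdir = Path(cfg.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self._rng = np.random.default_rng(cfg.seed)

    def _stage_rng(self, stage: str) -> np.random.Generator:
        # stage-scoped substream so stages re-run independently yet reproducibly
        return np.random.default_rng([self.cfg.seed, STAGES.index(stage)])

    def _record(self, stage: str, outputs: list[Path], params: dict, t0: float) -> None:
        manifest = []
        if self.manifest_path.exists():
            manifest = json.loads(self.manifest_path.read_text())
        manifest = [m for m in manifest if m["stage"] != stage]
        manifest.append(
            {
                "stage": stage,
                "outputs": {p.name: _file_hash(p) for p in outputs},
                "params": {k: str(v) for k, v in params.items()},
                "seed": self.cfg.seed,
                "config_hash": self.cfg.config_hash(),
                "elapsed_s": round(time.time() - t0, 2),
            }
        )
        self.manifest_path.write_text(json.dumps(manifest, indent=1))
        log.info("stage %s finished in %.1f s", stage, time.time() - t0)

    # ------------------------------------------------------------------
    def _traces_path(self) -> Path:
        if self.cfg.traces_csv:
            p = Path(self.cfg.traces_csv)
        else:
            p = self.outdir / "traces.csv"
        if not p.exists():
            raise StageError("filter", f"input trace table not found: {p}")
        return p

    def simulate(self) -> Path:
        t0 = time.time()
        sim = dataclasses.replace(self.cfg.sim, seed=self.cfg.seed)
        ds = simulate_embryo_dataset(sim)
        traces_path = self.outdir / "traces.csv"
        truth_path = self.outdir / "truth.csv"
        sidecar = self.outdir / "simulation.json"
        ds.write(traces_path, truth_path, sidecar)
        # auto-populate movie geometry for downstream stages
        self.cfg.movies = {
            mid: {"stripe_ids": meta["stripe_ids"],
                  "poles": [meta["pole_x_anterior_px"], meta["pole_x_posterior_px"]]}
            for mid, meta in ds.movies.items()
        }
        if self.cfg.activity_threshold_au == 0.0 and sim.noise_sd_au > 0:
            self.cfg.activity_threshold_au = 2.0 * sim.noise_sd_au
        self._record("simulate", [traces_path, truth_path, sidecar],
                     {"n_movies": sim.n_movies, "seed": sim.seed}, t0)
        return traces_path

    def filter(self) -> Path:
        t0 = time.time()
        traces = read_traces(self._traces_path())
        kept, report = filter_traces(traces, self.cfg.min_span_s, self.cfg.max_speed_px_per_min)
        out = self.outdir / "filtered.csv"
        write_traces(kept, out)
        rep = self.outdir / "filter_report.json"
        rep.write_text(json.dumps(report, indent=1))
        _sidecar(out, self.cfg, "filter")
        self._record("filter", [out, rep], report, t0)
        return out

    def _filtered(self) -> list:
        p = self.outdir / "filtered.csv"
        if not p.exists():
            raise StageError("transit", f"filtered traces not found: {p}; run 'filter' first")
        return read_traces(p)

    def transit(self) -> Path:
        t0 = time.time()
        self._load_sim_sidecar()
        traces = self._filtered()
        # the estimator expects detected-spot observations: real trace tables
        # only hold fluorescence where a spot was found, whereas synthetic
        # tables also record quiet frames whose differenced measurement noise
        # anticorrelates at lag 1.  Emulate detection: keep transcribing
        # nuclei and mask frames below the detection threshold as missing.
        thr = self.cfg.activity_threshold_au
        if thr > 0:
            masked = []
            for tr in traces:
                if np.mean(np.nan_to_num(tr.fluo_au) > thr) >= 0.25:
                    tr = dataclasses.replace(
                        tr, fluo_au=np.where(tr.fluo_au > thr, tr.fluo_au, np.nan)
                    )
                    masked.append(tr)
            traces = masked
        rng = self._stage_rng("transit")
        est = transit.bootstrap_transit_time(
            traces, d_max=self.cfg.d_max, n_boot=self.cfg.n_boot_transit, seed=rng
        )
        out = self.outdir / "transit.json"
        out.write_text(
            json.dumps(
                {
                    "t_elong_s": est.t_elong_s,
                    "rho": est.rho.tolist(),
                    "d_max": est.d_max,
                    "n_boot": self.cfg.n_boot_transit,
                    "argmin_distribution": est.argmin_distribution.tolist(),
                },
                indent=1,
            )
        )
        _sidecar(out, self.cfg, "transit")
        self._record("transit", [out], {"d_max": self.cfg.d_max}, t0)
        return out

    def _load_sim_sidecar(self) -> None:
        """Recover movie geometry and noise level from a simulate-stage run."""
        sidecar = self.outdir / "simulation.json"
        if not sidecar.exists():
            return
        meta = json.loads(sidecar.read_text())
        if not self.cfg.movies:
            self.cfg.movies = {
                mid: {"stripe_ids": m["stripe_ids"],
                      "poles": [m["pole_x_anterior_px"], m["pole_x_posterior_px"]]}
                for mid, m in meta["movies"].items()
            }
        noise = meta.get("config", {}).get("noise_sd_au", 0.0)
        if self.cfg.activity_threshold_au == 0.0 and noise > 0:
            self.cfg.activity_threshold_au = 2.0 * noise

    def stripes(self) -> Path:
        t0 = time.time()
        self._load_sim_sidecar()
        if not self.cfg.movies:
            raise StageError("stripes", "no movie geometry configured (movies mapping empty)")
        df = traces_to_frame(self._filtered())
        rng = self._stage_rng("stripes")
        models_by_movie: dict[str, dict[int, stripes.StripeModel]] = {}
        poles = {}
        assigned_parts = []
        for mid, geo in self.cfg.movies.items():
            dfm = df[df["movie_id"] == mid]
            if dfm.empty:
                warnings.warn(f"movie {mid} has no traces after filtering", stacklevel=2)
                continue
            models = stripes.analyze_movie_stripes(
                dfm,
                geo["stripe_ids"],
                window_s=self.cfg.window_s,
                step_s=self.cfg.step_s,
                start_min=self.cfg.cluster_start_min,
                activity_threshold_au=self.cfg.activity_threshold_au,
                seed=rng,
            )
            models_by_movie[mid] = models
            poles[mid] = tuple(geo["poles"])
            asg = stripes.assign_nuclei_to_stripes(dfm, models, self.cfg.cluster_start_min)
            asg["ap_registered"] = stripes.map_to_ap_and_reorient(
                asg, models, "stripe", *poles[mid]
            )
            assigned_parts.append(asg)
        if not models_by_movie:
            raise StageError("stripes", "no movie could be analyzed")
        reg_table = stripes.register_stripes_across_movies(
            models_by_movie, poles, self.cfg.anchor_min
        )
        boot = stripes.bootstrap_registration(
            models_by_movie, poles, self.cfg.anchor_min,
            n_boot=self.cfg.n_boot_registration, seed=rng,
        )
        assigned = pd.concat(assigned_parts, ignore_index=True)
        # apply registration offsets
        off = {(r.movie_id, r.stripe_id): r.registration_offset_ap
               for r in reg_table.itertuples()}
        assigned["ap_registered"] += [
            off.get((m, s), 0.0) for m, s in zip(assigned["movie_id"], assigned["stripe"])
        ]
        out = self.outdir / "assignment.csv"
        cols = ["movie_id", "nucleus_id", "frame", "t_s", "x_px", "y_px", "ap_frac",
                "fluo_au", "stripe", "consensus_stripe", "ap_registered"]
        assigned[cols].to_csv(out, index=False, float_format="%.6g")
        models_json = self.outdir / "stripe_models.json"
        models_json.write_text(
            json.dumps(
                {
                    mid: [m.to_dict() for m in models.values()]
                    for mid, models in models_by_movie.items()
                }
                | {"registration_bootstrap": boot},
                indent=1,
            )
        )
        _sidecar(out, self.cfg, "stripes")
        self._record("stripes", [out, models_json],
                     {"window_s": self.cfg.window_s, "anchor_min": self.cfg.anchor_min}, t0)
        return out

    def _assignment(self) -> pd.DataFrame:
        p = self.outdir / "assignment.csv"
        if not p.exists():
            raise StageError("fit", f"stripe assignment not found: {p}; run 'stripes' first")
        return pd.read_csv(p, dtype={"movie_id": str, "nucleus_id": str})

    def fit(self) -> Path:
        t0 = time.time()
        rng = self._stage_rng("fit")
        if self.cfg.binned:
            asg = self._assignment()
            fluos, labels = [], []
            for (_, _), g in asg.groupby(["movie_id", "nucleus_id"], sort=True):
                fluos.append(g.sort_values("t_s")["fluo_au"].to_numpy(float))
                labels.append(int(g["consensus_stripe"].iloc[0]))
            table = cphmm.infer_by_fluorescence_bins(
                fluos, labels,
                n_bins=self.cfg.n_bins, min_points=self.cfg.min_points,
                subset_size=self.cfg.subset_size, n_boot=self.cfg.n_boot_bins,
                K=self.cfg.K, w=self.cfg.w, dt_s=self.cfg.model.dt_s, seed=rng,
                n_restarts=self.cfg.n_restarts, max_iter=self.cfg.max_iter,
            )
            out = self.outdir / "bin_parameters.csv"
            table.to_csv(out, index=False, float_format="%.6g")
            _sidecar(out, self.cfg, "fit")
            self._record("fit", [out], {"binned": True, "n_bins": self.cfg.n_bins}, t0)
            return out
        traces = self._filtered()
        fluos = [tr.fluo_au for tr in traces]
        model, traj = cphmm.em_fit(
            fluos, K=self.cfg.K, w=self.cfg.w, dt_s=self.cfg.model.dt_s,
            max_iter=self.cfg.max_iter, tol_per_1000=self.cfg.tol_per_1000,
            n_restarts=self.cfg.n_restarts, seed=rng,
        )
        out = self.outdir / "model.json"
        bp = cphmm.effective_two_state(model)
        out.write_text(
            json.dumps(
                model.to_dict()
                | {"effective": {"kon_per_min": bp.kon, "koff_per_min": bp.koff,
                                 "r_au_per_min": bp.r}},
                indent=1,
            )
        )
        _sidecar(out, self.cfg, "fit")
        self._record("fit", [out], {"K": self.cfg.K, "w": self.cfg.w,
                                    "loglik": round(model.loglik, 2)}, t0)
        return out

    def decode(self) -> Path:
        t0 = time.time()
        model_path = self.outdir / "model.json"
        if not model_path.exists():
            raise StageError("decode", f"fitted model not found: {model_path}; run 'fit' first")
        model = cphmm.CompoundHMM.from_dict(json.loads(model_path.read_text()))
        traces = self._filtered()
        rows = []
        for tr in traces:
            s_hat = cphmm.viterbi_decode(model, tr.fluo_au)
            frame = np.rint(tr.t_s / tr.dt_s).astype(int)
            rows.append(
                pd.DataFrame(
                    {"movie_id": tr.movie_id, "nucleus_id": tr.nucleus_id,
                     "frame": frame, "t_s": tr.t_s, "s_hat": s_hat}
                )
            )
        out = self.outdir / "decoded.csv"
        pd.concat(rows, ignore_index=True).to_csv(out, index=False, float_format="%.6g")
        _sidecar(out, self.cfg, "decode")
        self._record("decode", [out], {"n_traces": len(traces)}, t0)
        return out

    def metrics(self) -> Path:
        t0 = time.time()
        dec_path = self.outdir / "decoded.csv"
        if not dec_path.exists():
            raise StageError("metrics", f"decoded paths not found: {dec_path}; run 'decode' first")
        decoded = pd.read_csv(dec_path, dtype={"movie_id": str, "nucleus_id": str})
        asg = self._assignment()
        merged = decoded.merge(
            asg[["movie_id", "nucleus_id", "frame", "ap_registered", "stripe",
                 "consensus_stripe", "fluo_au"]],
            on=["movie_id", "nucleus_id", "frame"], how="inner",
        ).rename(columns={"s_hat": "s", "ap_registered": "ap"})
        outs = []

        fp = metrics.kinetic_fingerprint(merged)
        outs.append(self.outdir / "fingerprint.csv")
        fp.to_csv(outs[-1], index=False, float_format="%.6g")

        for name, table in [
            ("fraction_on", metrics.fraction_on_map(merged)),
            ("mean_fluorescence", metrics.mean_fluorescence_map(merged)),
            ("fraction_bursted_before", metrics.fraction_bursted_before(merged)),
        ]:
            long = table.reset_index().melt(id_vars="t_s", var_name="ap_bin", value_name="value")
            outs.append(self.outdir / f"{name}.csv")
            long.dropna(subset=["value"]).to_csv(outs[-1], index=False, float_format="%.6g")

        never = metrics.find_never_on(merged)
        outs.append(self.outdir / "never_on.csv")
        never.to_csv(outs[-1], index=False, float_format="%.6g")

        ad = metrics.activity_difference_events(merged)
        outs.append(self.outdir / "activity_difference.csv")
        ad.to_csv(outs[-1], index=False, float_format="%.6g")

        centers = metrics.stripe_center_trajectory(merged)
        outs.append(self.outdir / "stripe_centers.csv")
        centers.to_csv(outs[-1], index=False, float_format="%.6g")
        # treadmilling velocity over the late window (stripes are mature and
        # moving then; early in nc14 positions are frozen by construction)
        t_hi = float(centers["t_s"].max())
        t_lo = max(25.0 * 60.0, t_hi / 2.0)
        velocities = {}
        for stripe, g in centers.groupby("stripe"):
            g = g[g["t_s"] >= t_lo]
            if len(g) >= 2:
                velocities[int(stripe)] = metrics.stripe_velocity(g)
        # alternative center definition: the fitted position model's x(y=128)
        # line, converted to AP through each movie's pole map and averaged
        # across movies (robust to baseline bursting far from the stripe)
        model_vel: dict[int, list[float]] = {}
        models_path = self.outdir / "stripe_models.json"
        if models_path.exists():
            self._load_sim_sidecar()
            payload = json.loads(models_path.read_text())
            for mid, geo in self.cfg.movies.items():
                x_ant, x_post = geo["poles"]
                for m in payload.get(mid, []):
                    v = m["c1_px_per_s"] * 60.0 / (x_post - x_ant) * 100.0
                    model_vel.setdefault(int(m["stripe_id"]), []).append(v)
        vel = self.outdir / "stripe_velocities.json"
        vel.write_text(json.dumps(
            {
                "pct_el_per_min": velocities,
                "pct_el_per_min_from_position_model": {
                    s: float(np.mean(v)) for s, v in sorted(model_vel.items())
                },
                "t_range_s": [t_lo, t_hi],
            },
            indent=1,
        ))
        outs.append(vel)

        for p in outs:
            _sidecar(p, self.cfg, "metrics")
        self._record("metrics", outs, {"n_events": len(fp)}, t0)
        return self.outdir

    def run_all(self, simulate_first: bool = True) -> Path:
        if simulate_first:
            self.simulate()
        self.filter()
        self.transit()
        self.stripes()
        self.fit()
        self.decode()
        self.metrics()
        return self.outdir
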