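"""Trace-table I/O, interpolation to the analysis grid, and data filtering.

The interchange format is a flat CSV with one row per (movie, nucleus, frame):

    movie_id,nucleus_id,frame,t_s,x_px,y_px,ap_frac,fluo_au

``fluo_au`` may be empty (spot not detected / frame missing).  Traces are kept
in memory as :class:`NucleusTrace` objects on a strictly uniform time grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NucleusTrace",
    "TraceParseError",
    "read_traces",
    "write_traces",
    "traces_to_frame",
    "frame_to_traces",
    "interpolate_to_grid",
    "filter_traces",
]

CSV_COLUMNS = ["movie_id", "nucleus_id", "frame", "t_s", "x_px", "y_px", "ap_frac", "fluo_au"]

#: physical pixel size, recorded as metadata only (filters operate in pixels)
PIXEL_SIZE_UM = 0.2


class TraceParseError(ValueError):
    """Raised when a trace table violates the schema."""


@dataclass
class NucleusTrace:
    """One nucleus's fluorescence and position time series on a uniform grid."""

    movie_id: str
    nucleus_id: str
    t_s: np.ndarray
    fluo_au: np.ndarray  # NaN where missing
    x_px: np.ndarray
    y_px: np.ndarray
    ap_frac: np.ndarray

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.fluo_au = np.asarray(self.fluo_au, dtype=float)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        self.ap_frac = np.asarray(self.ap_frac, dtype=float)
        n = self.t_s.size
        for name in ("fluo_au", "x_px", "y_px", "ap_frac"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length != t_s length for nucleus {self.key}")
        if n >= 2:
            steps = np.diff(self.t_s)
            if steps.min() <= 0:
                raise ValueError(f"t_s not strictly increasing for nucleus {self.key}")
        finite_ap = self.ap_frac[np.isfinite(self.ap_frac)]
        if finite_ap.size and (finite_ap.min() < 0 or finite_ap.max() > 1):
            raise ValueError(f"ap_frac outside [0, 1] for nucleus {self.key}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.movie_id, self.nucleus_id)

    @property
    def dt_s(self) -> float:
        if self.t_s.size < 2:
            raise ValueError("dt undefined for a single-frame trace")
        return float(self.t_s[1] - self.t_s[0])

    @property
    def is_uniform(self) -> bool:
        if self.t_s.size < 2:
            return True
        steps = np.diff(self.t_s)
        return bool(np.allclose(steps, steps[0], rtol=1e-6, atol=1e-6))

    @property
    def n_frames(self) -> int:
        return int(self.t_s.size)

    def span_s(self) -> float:
        """Observed time span, last minus first frame time."""
        return float(self.t_s[-1] - self.t_s[0])

    def mean_speed_px_per_min(self) -> float:
        """Mean speed as total path length / elapsed time.

        Path length is the sum of Euclidean frame-to-frame displacements; a
        path-based definition is stricter than net displacement and
        deterministic.
        """
        if self.t_s.size < 2:
            return 0.0
        steps = np.hypot(np.diff(self.x_px), np.diff(self.y_px))
        minutes = self.span_s() / 60.0
        return float(np.nansum(steps) / minutes)


def traces_to_frame(traces: Iterable[NucleusTrace]) -> pd.DataFrame:
    """Flatten traces into the long CSV schema (sorted by movie, nucleus, t)."""
    rows = []
    for tr in traces:
        frame_idx = np.rint(tr.t_s / tr.dt_s).astype(int) if tr.t_s.size >= 2 else np.zeros(tr.t_s.size, int)
        rows.append(
            pd.DataFrame(
                {
                    "movie_id": tr.movie_id,
                    "nucleus_id": tr.nucleus_id,
                    "frame": frame_idx,
                    "t_s": tr.t_s,
                    "x_px": tr.x_px,
                    "y_px": tr.y_px,
                    "ap_frac": tr.ap_frac,
                    "fluo_au": tr.fluo_au,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=CSV_COLUMNS)
    df = pd.concat(rows, ignore_index=True)
    return df.sort_values(["movie_id", "nucleus_id", "t_s"], kind="stable").reset_index(drop=True)


def frame_to_traces(df: pd.DataFrame) -> list[NucleusTrace]:
    """Group a long-format table into NucleusTrace objects (schema-checked)."""
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TraceParseError(f"missing required column(s): {', '.join(missing)}")
    dup = df.duplicated(subset=["movie_id", "nucleus_id", "t_s"], keep=False)
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise TraceParseError(
            "duplicate (movie_id, nucleus_id, t_s) key: "
            f"({row['movie_id']}, {row['nucleus_id']}, {row['t_s']})"
        )
    traces = []
    for (movie, nuc), g in df.groupby(["movie_id", "nucleus_id"], sort=True):
        g = g.sort_values("t_s")
        t = g["t_s"].to_numpy(float)
        if t.size >= 2 and not np.allclose(np.diff(t), t[1] - t[0], rtol=1e-6, atol=1e-6):
            raise TraceParseError(f"non-uniform time grid for nucleus ({movie}, {nuc})")
        try:
            traces.append(
                NucleusTrace(
                    movie_id=str(movie),
                    nucleus_id=str(nuc),
                    t_s=g["t_s"].to_numpy(float),
                    fluo_au=g["fluo_au"].to_numpy(float),
                    x_px=g["x_px"].to_numpy(float),
                    y_px=g["y_px"].to_numpy(float),
                    ap_frac=g["ap_frac"].to_numpy(float),
                )
            )
        except ValueError as exc:
            raise TraceParseError(str(exc)) from exc
    return traces


def read_traces(path) -> list[NucleusTrace]:
    """Read a trace CSV; raises :class:`TraceParseError` on schema violations."""
    df = pd.read_csv(path, dtype={"movie_id": str, "nucleus_id": str})
    return frame_to_traces(df)


def write_traces(traces: Iterable[NucleusTrace], path) -> None:
    """Write traces in the CSV schema; missing fluorescence as empty fields."""
    df = traces_to_frame(traces)
    df.to_csv(path, index=False, float_format="%.6g")


def interpolate_to_grid(trace: NucleusTrace, dt_target_s: float = 20.0) -> NucleusTrace:
    """Linearly interpolate a natively-sampled trace onto a uniform grid.

    The target grid starts at the first native sample and spans the native
    time range; no extrapolation beyond the endpoints.  Native times need not
    be uniform, only strictly increasing.
    """
    t = np.asarray(trace.t_s, float)
    if t.size < 2:
        raise ValueError("interpolation requires at least 2 native samples")
    if np.diff(t).min() <= 0:
        raise ValueError("native times must be strictly increasing")
    n_steps = int(np.floor((t[-1] - t[0]) / dt_target_s + 1e-9))
    grid = t[0] + dt_target_s * np.arange(n_steps + 1)

    def interp(v):
        v = np.asarray(v, float)
        ok = np.isfinite(v)
        if ok.sum() < 2:
            return np.full_like(grid, np.nan)
        out = np.interp(grid, t[ok], v[ok])
        # mark grid points outside the observed (finite) range as missing
        out[(grid < t[ok][0]) | (grid > t[ok][-1])] = np.nan
        return out

    return NucleusTrace(
        movie_id=trace.movie_id,
        nucleus_id=trace.nucleus_id,
        t_s=grid,
        fluo_au=interp(trace.fluo_au),
        x_px=interp(trace.x_px),
        y_px=interp(trace.y_px),
        ap_frac=interp(trace.ap_frac),
    )


def filter_traces(
    traces: Sequence[NucleusTrace],
    min_span_s: float = 2000.0,
    max_speed_px_per_min: float = 4.5,
) -> tuple[list[NucleusTrace], dict]:
    """Apply the quality filters: short observation spans and fast movers.

    Traces spanning less than ``min_span_s`` (strictly) are dropped, as are
    nuclei whose mean speed exceeds ``max_speed_px_per_min`` (strictly).
    Returns the retained traces plus a report of before/after counts.
    """
    kept: list[NucleusTrace] = []
    dropped_by_span = 0
    dropped_by_speed = 0
    obs_before = 0
    obs_after = 0
    for tr in traces:
        obs_before += tr.n_frames
        if tr.span_s() < min_span_s:
            dropped_by_span += 1
            continue
        if tr.mean_speed_px_per_min() > max_speed_px_per_min:
            dropped_by_speed += 1
            continue
        kept.append(tr)
        obs_after += tr.n_frames
    report = {
        "observations_before": obs_before,
        "observations_after": obs_after,
        "nuclei_before": len(traces),
        "nuclei_after": len(kept),
        "dropped_by_span": dropped_by_span,
        "dropped_by_speed": dropped_by_speed,
    }
    return kept, report
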