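#!/usr/bin/env python
"""Derive the spatial-kinetic summaries from the decoded promoter states:
the kinetic fingerprint (every burst's time, AP position and duration),
instantaneous fraction-ON and mean-fluorescence maps in 1% EL bins, the
cumulative fraction of nuclei that have bursted, never-ON nuclei, activity
differences around burst starts, and stripe-center trajectories with their
treadmilling velocities.
"""

import argparse
import json

import pandas as pd

from stripeburst.pipeline import Pipeline, PipelineConfig


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", default="results/embryo")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    pipe = Pipeline(PipelineConfig(outdir=args.outdir, seed=args.seed))
    pipe.metrics()
    fp = pd.read_csv(pipe.outdir / "fingerprint.csv")
    never = pd.read_csv(pipe.outdir / "never_on.csv")
    vel = json.loads((pipe.outdir / "stripe_velocities.json").read_text())
    n_never = never.groupby(["movie_id", "nucleus_id"]).ngroups
    print(f"{len(fp)} bursts catalogued; median duration "
          f"{fp.duration_s.median():.0f} s; {n_never} never-ON nuclei")
    mv = vel.get("pct_el_per_min_from_position_model", {})
    for stripe, v in sorted(vel["pct_el_per_min"].items(), key=lambda kv: int(kv[0])):
        extra = f", position model {mv[stripe]:+.3f}" if stripe in mv else ""
        print(f"stripe {stripe}: burst-center velocity {v:+.3f}% EL/min"
              f"{extra} ({v * 3:+.2f}% EL per 3 min)")


if __name__ == "__main__":
    main()
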