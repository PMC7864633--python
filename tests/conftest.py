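import math
from itertools import product

import numpy as np
import pytest

from stripeburst import ModelConfig, NucleusTrace, simulate_promoter_path, simulate_trace
from stripeburst.cphmm import CompoundHMM


def brute_force_loglik(model: CompoundHMM, F) -> float:
    """Enumeration oracle: sum the joint density over every state sequence."""
    F = np.asarray(F, float)
    K, w, T = model.K, model.w, F.size
    total = 0.0
    for seq in product(range(K), repeat=T):
        p = model.pi[seq[0]]
        for t in range(1, T):
            p *= model.A[seq[t - 1], seq[t]]
        for t in range(T):
            if not np.isfinite(F[t]):
                continue
            mu = model.pulse_au * sum(seq[max(0, t - w + 1) : t + 1])
            p *= math.exp(-0.5 * ((F[t] - mu) / model.sigma_au) ** 2) / (
                model.sigma_au * math.sqrt(2 * math.pi)
            )
        total += p
    return math.log(total)


def brute_force_viterbi(model: CompoundHMM, F) -> np.ndarray:
    """Enumeration oracle for the maximum-probability state sequence."""
    F = np.asarray(F, float)
    K, w, T = model.K, model.w, F.size
    best, best_lp = None, -np.inf
    for seq in product(range(K), repeat=T):
        lp = math.log(model.pi[seq[0]] + 1e-300)
        for t in range(1, T):
            lp += math.log(model.A[seq[t - 1], seq[t]] + 1e-300)
        for t in range(T):
            if not np.isfinite(F[t]):
                continue
            mu = model.pulse_au * sum(seq[max(0, t - w + 1) : t + 1])
            lp += -0.5 * ((F[t] - mu) / model.sigma_au) ** 2
        if lp > best_lp:
            best_lp, best = lp, seq
    return np.asarray(best)


def make_traces(fluos, dt_s=20.0, movie="m01", x=None, y=None, ap=0.5):
    """Wrap raw fluorescence arrays as NucleusTrace objects at fixed positions."""
    out = []
    for i, f in enumerate(fluos):
        f = np.asarray(f, float)
        n = f.size
        out.append(
            NucleusTrace(
                movie_id=movie,
                nucleus_id=f"n{i:04d}",
                t_s=dt_s * np.arange(n),
                fluo_au=f,
                x_px=np.full(n, 100.0) if x is None else np.asarray(x, float),
                y_px=np.full(n, 128.0) if y is None else np.asarray(y, float),
                ap_frac=np.full(n, ap),
            )
        )
    return out


@pytest.fixture(scope="session")
def default_trace_set():
    """200 noisy two-sister traces at the genome-wide parameter estimates."""
    rng = np.random.default_rng(11)
    cfg = ModelConfig()
    fluos = []
    for _ in range(200):
        path = simulate_promoter_path(0.6, 0.6, 181, n_promoters=2, seed=rng)
        fluos.append(simulate_trace(path, cfg, noise_sd_au=15.0, seed=rng))
    return make_traces(fluos)


@pytest.fixture(scope="session")
def small_embryo():
    """A compact 2-movie synthetic embryo shared by the slower tests."""
    from stripeburst.simulate import SimulationConfig, simulate_embryo_dataset

    sim = SimulationConfig(
        n_movies=2, stripes_per_movie=3, n_nuclei_per_movie=80, duration_min=40.0, seed=5
    )
    return simulate_embryo_dataset(sim)
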