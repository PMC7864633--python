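"""Compound-state hidden Markov model for bursting inference.

The promoter-count process ``s_t ∈ {0..K-1}`` is a first-order Markov chain,
but the observed fluorescence depends on the whole recent window
``(s_{t-w+1}, ..., s_t)`` because each loading pulse persists for ``w``
frames.  Embedding that window as a *compound state* restores the Markov
property: the ``K^w`` compound states form a shift register in which each
state has exactly ``K`` successors (drop the oldest symbol, append the new
one), the transition probability is the base-chain entry ``A[s_t, s_{t+1}]``,
and the Gaussian emission mean of a compound state is ``(r/60)·dt·Σ_i s_i`` —
the summed height of the pulses still at the locus.

This module implements the forward/backward recursions, Baum–Welch EM for
``(A, π, r, σ)``, Viterbi decoding of promoter paths, lumping of the fitted
chain into effective two-state burst parameters ``(k_on, k_off, r)``, and the
stripe-and-fluorescence-binned inference used for spatial parameter profiles.
All recursions exploit the shift-register structure (predecessor sums via a
reshape over the oldest symbol) and are batched across traces, which keeps
even the 3^7-state two-promoter model tractable in pure numpy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import logm

__all__ = [
    "CompoundHMM",
    "BurstParameters",
    "build_compound_model",
    "trace_log_likelihood",
    "forward_backward",
    "em_fit",
    "viterbi_decode",
    "effective_two_state",
    "infer_by_fluorescence_bins",
]

_LOG2PI = math.log(2 * math.pi)


@dataclass
class CompoundHMM:
    """Promoter-count chain with shift-register compound states."""

    K: int
    w: int
    A: np.ndarray  # (K, K) per-frame base transition matrix, row-stochastic
    pi: np.ndarray  # (K,) initial distribution over base states
    r_au_per_min: float
    sigma_au: float
    dt_s: float = 20.0
    converged: bool = True
    loglik: float = np.nan
    rate_conversion: str = "logm"

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, float)
        self.pi = np.asarray(self.pi, float)
        if self.K not in (2, 3):
            raise ValueError("K must be 2 or 3 (promoter-count states)")
        if self.w < 1:
            raise ValueError("w must be >= 1")
        if self.A.shape != (self.K, self.K) or np.any(self.A < -1e-12):
            raise ValueError("A must be a non-negative KxK matrix")
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("rows of A must sum to 1")
        if self.pi.shape != (self.K,) or not np.isclose(self.pi.sum(), 1.0, atol=1e-10):
            raise ValueError("pi must be a distribution over K base states")
        if self.sigma_au <= 0:
            raise ValueError("sigma_au must be positive")

    @property
    def n_states(self) -> int:
        return self.K**self.w

    @property
    def pulse_au(self) -> float:
        """Per-frame fluorescence of one ON promoter, (r/60)*dt."""
        return self.r_au_per_min / 60.0 * self.dt_s

    def emission_means(self) -> np.ndarray:
        """Emission mean per compound state: pulse x (digit sum of the word)."""
        return self.pulse_au * _n_on(self.K, self.w)

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "w": self.w,
            "dt_s": self.dt_s,
            "A": self.A.ravel().tolist(),
            "pi": self.pi.tolist(),
            "r_au_per_min": float(self.r_au_per_min),
            "sigma_au": float(self.sigma_au),
            "converged": bool(self.converged),
            "loglik": float(self.loglik),
            "rate_conversion": self.rate_conversion,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CompoundHMM":
        return cls(
            K=d["K"],
            w=d["w"],
            A=np.asarray(d["A"], float).reshape(d["K"], d["K"]),
            pi=np.asarray(d["pi"], float),
            r_au_per_min=d["r_au_per_min"],
            sigma_au=d["sigma_au"],
            dt_s=d["dt_s"],
            converged=d.get("converged", True),
            loglik=d.get("loglik", np.nan),
            rate_conversion=d.get("rate_conversion", "logm"),
        )


@dataclass
class BurstParameters:
    """Effective two-state burst kinetics (rates per minute, r in AU/min)."""

    kon: float
    koff: float
    r: float
    se_kon: float | None = None
    se_koff: float | None = None
    se_r: float | None = None
    n_datapoints: int | None = None


def build_compound_model(K, w, A, pi, r_au_per_min, sigma_au, dt_s=20.0) -> CompoundHMM:
    """Validated constructor (see :class:`CompoundHMM`)."""
    return CompoundHMM(K=K, w=w, A=A, pi=pi, r_au_per_min=r_au_per_min,
                       sigma_au=sigma_au, dt_s=dt_s)


# ---------------------------------------------------------------------------
# shift-register index bookkeeping
# ---------------------------------------------------------------------------

def _n_on(K: int, w: int) -> np.ndarray:
    """Digit sum (promoter-ON count summed over the window) per compound index."""
    v = np.arange(K**w)
    total = np.zeros(K**w, dtype=np.int64)
    for _ in range(w):
        total += v % K
        v = v // K
    return total


class _Index:
    """Precomputed index arrays for the K^w shift-register state space.

    Words are encoded oldest-symbol-most-significant, so the shift is
    ``v' = (v mod K^(w-1)) * K + new`` and the predecessors of ``v'`` are
    ``{old * K^(w-1) + (v'//K) : old in 0..K-1}``, all sharing the last
    symbol ``(v'//K) mod K``.
    """

    _cache: dict = {}

    def __new__(cls, K: int, w: int):
        if (K, w) not in cls._cache:
            cls._cache[(K, w)] = super().__new__(cls)
            cls._cache[(K, w)]._init(K, w)
        return cls._cache[(K, w)]

    def _init(self, K: int, w: int) -> None:
        self.K, self.w = K, w
        S = K**w
        v = np.arange(S)
        self.prefix = v // K  # index into predecessor sums
        self.last = v % K  # newest symbol of v
        self.prev_last = self.prefix % K  # predecessor's newest symbol
        self.low = v % (K ** (w - 1)) if w > 1 else np.zeros(S, dtype=np.int64)
        self.n_on = _n_on(K, w)
        gidx = self.prev_last * K + self.last
        self.base_onehot = np.zeros((S, K * K))
        self.base_onehot[np.arange(S), gidx] = 1.0
        self.non_onehot = np.zeros((S, int(self.n_on.max()) + 1))
        self.non_onehot[np.arange(S), self.n_on] = 1.0

    def trans_flat(self, A: np.ndarray) -> np.ndarray:
        """Incoming transition probability A[prev_last, last] per state."""
        return A[self.prev_last, self.last]


def _log_emis_by_count(F: np.ndarray, n_counts: int, pulse: float, sigma: float) -> np.ndarray:
    """(..., n_counts) Gaussian log-densities N(F; n*pulse, sigma).

    Missing frames (NaN) get log-density 0 for every count (likelihood 1).
    """
    mu = pulse * np.arange(n_counts)
    with np.errstate(invalid="ignore"):
        z = (F[..., None] - mu) / sigma
        loge = -0.5 * z**2 - math.log(sigma) - 0.5 * _LOG2PI
    return np.where(np.isfinite(F)[..., None], loge, 0.0)


def _pad_traces(fluos: Sequence[np.ndarray]):
    """Stack variable-length fluorescence arrays into (T_max, n) plus lengths.

    Traces are sorted by length descending so the traces still running at any
    frame form a contiguous leading block of columns; padding is NaN.
    Returns (F, lengths, order) with ``order[col]`` the input index in
    column ``col``.
    """
    order = np.argsort([-np.asarray(f).size for f in fluos], kind="stable")
    lengths = np.array([np.asarray(fluos[i]).size for i in order])
    T = int(lengths.max())
    F = np.full((T, len(fluos)), np.nan)
    for col, i in enumerate(order):
        f = np.asarray(fluos[i], float)
        F[: f.size, col] = f
    if np.isinf(F).any():
        raise ValueError("fluorescence contains infinite values")
    return F, lengths, order


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------

def _forward(model: CompoundHMM, F: np.ndarray, lengths: np.ndarray):
    """Scaled batched forward pass.

    Returns ``alpha`` (T, n, S; rows normalized per frame), raw scales ``c``
    (T, n), per-frame emission offsets, scaled emissions ``emis``
    (exp(log e - offset)) and the per-trace log-likelihoods.  History before
    frame 0 is all-OFF: the frame-0 compound state is a word (0,..,0,s_0)
    with probability pi[s_0].
    """
    K, S = model.K, model.n_states
    idx = _Index(K, model.w)
    T, n = F.shape
    loge_c = _log_emis_by_count(F, int(idx.n_on.max()) + 1, model.pulse_au, model.sigma_au)
    offset = loge_c.max(axis=2)  # (T, n)
    emis = np.exp(loge_c - offset[..., None])[:, :, idx.n_on]  # (T, n, S)

    trans = idx.trans_flat(model.A)
    alpha = np.zeros((T, n, S))
    c = np.ones((T, n))
    a0 = np.zeros((n, S))
    a0[:, :K] = model.pi[None, :]
    a = a0 * emis[0]
    c0 = a.sum(axis=1)
    c0 = np.where(c0 > 0, c0, np.finfo(float).tiny)
    alpha[0] = a / c0[:, None]
    c[0] = c0
    for t in range(1, T):
        na = int((lengths > t).sum())
        if na == 0:
            break
        prev = alpha[t - 1, :na]
        if model.w == 1:
            # compound space = base space; plain matrix-vector propagation
            a = emis[t, :na] * (prev @ model.A)
        else:
            ssum = prev.reshape(na, K, S // K).sum(axis=1)  # over oldest symbol
            a = emis[t, :na] * trans[None, :] * ssum[:, idx.prefix]
        ct = a.sum(axis=1)
        ct = np.where(ct > 0, ct, np.finfo(float).tiny)
        alpha[t, :na] = a / ct[:, None]
        c[t, :na] = ct
    logc = np.log(c) + offset
    loglik = np.array([logc[: lengths[i], i].sum() for i in range(n)])
    return alpha, c, offset, emis, loglik


def trace_log_likelihood(model: CompoundHMM, fluo) -> float:
    """Log-likelihood of one trace (forward algorithm over compound states).

    Missing frames (NaN) contribute emission likelihood 1.
    """
    F, lengths, _ = _pad_traces([fluo])
    *_, loglik = _forward(model, F, lengths)
    return float(loglik[0])


def forward_backward(model: CompoundHMM, fluo):
    """Posterior marginals over compound states for one trace.

    Returns ``(gamma, loglik)`` with gamma of shape (T, K^w); every row sums
    to 1.
    """
    F, lengths, _ = _pad_traces([fluo])
    K, S = model.K, model.n_states
    idx = _Index(K, model.w)
    alpha, c, offset, emis, loglik = _forward(model, F, lengths)
    T = F.shape[0]
    gamma = np.zeros((T, S))
    beta = np.ones((1, S))
    gamma[T - 1] = alpha[T - 1, 0] * beta[0]
    for t in range(T - 1, 0, -1):
        eb = emis[t] * beta
        if model.w == 1:
            beta = (eb @ model.A.T) / c[t, 0]
        else:
            B = eb.reshape(1, S // K, K) @ model.A.T
            beta = B[:, idx.low, idx.last] / c[t, 0]
        gamma[t - 1] = alpha[t - 1, 0] * beta[0]
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma, float(loglik[0])


# ---------------------------------------------------------------------------
# EM (Baum–Welch)
# ---------------------------------------------------------------------------

def _e_step_stats(model: CompoundHMM, F: np.ndarray, lengths: np.ndarray):
    """One E-step over a padded batch: expected sufficient statistics.

    Returns (loglik_total, base transition counts (K,K), frame-0 base-state
    weights (K,), emission moment accumulators Sw/Sf/Sf2 indexed by window
    ON-count over observed frames).
    """
    K, S = model.K, model.n_states
    idx = _Index(K, model.w)
    T, n = F.shape
    alpha, c, offset, emis, loglik = _forward(model, F, lengths)
    trans = idx.trans_flat(model.A)

    ncounts = int(idx.n_on.max()) + 1
    Sw = np.zeros(ncounts)
    Sf = np.zeros(ncounts)
    Sf2 = np.zeros(ncounts)
    trans_counts = np.zeros(K * K)
    pi_counts = np.zeros(K)

    observed = np.isfinite(F)  # (T, n)
    beta = np.ones((n, S))

    def accumulate_gamma(t: int, gamma_t: np.ndarray, na: int) -> None:
        obs = observed[t, :na]
        if obs.any():
            gn = gamma_t[obs] @ idx.non_onehot  # (n_obs, ncounts)
            f = F[t, :na][obs]
            Sw[:] += gn.sum(axis=0)
            Sf[:] += f @ gn
            Sf2[:] += (f**2) @ gn

    # frame T-1 gammas for traces of maximal length
    na_last = int((lengths > T - 1).sum())
    g_last = alpha[T - 1, :na_last] * beta[:na_last]
    accumulate_gamma(T - 1, g_last, na_last)

    for t in range(T - 1, 0, -1):
        na = int((lengths > t).sum())  # traces with a transition (t-1 -> t)
        # traces ending exactly at frame t: (re)initialize their beta to 1
        beta[na:] = 1.0
        eb = emis[t, :na] * beta[:na]
        prev = alpha[t - 1, :na]
        if model.w == 1:
            beta_prev = (eb @ model.A.T) / c[t, :na, None]
            ebc = eb / c[t, :na, None]
            trans_counts += (
                np.einsum("ni,nj->ij", prev, ebc) * model.A
            ).ravel()
        else:
            B = eb.reshape(na, S // K, K) @ model.A.T
            beta_prev = B[:, idx.low, idx.last] / c[t, :na, None]
            # xi aggregated to base (i, j): all predecessors of v share prev_last
            ssum = prev.reshape(na, K, S // K).sum(axis=1)
            contrib = ssum[:, idx.prefix] * trans[None, :] * eb / c[t, :na, None]
            trans_counts += contrib.sum(axis=0) @ idx.base_onehot
        beta[:na] = beta_prev
        # gamma at frame t-1 for every trace of length > t-1 (all first na2)
        na2 = int((lengths > t - 1).sum())
        g = alpha[t - 1, :na2] * beta[:na2]
        accumulate_gamma(t - 1, g, na2)
        if t == 1:
            pi_counts += g[:, :K].sum(axis=0)
    if T == 1:
        pi_counts += g_last[:, :K].sum(axis=0)
    return float(loglik.sum()), trans_counts.reshape(K, K), pi_counts, Sw, Sf, Sf2


def _m_step(model: CompoundHMM, trans_counts, pi_counts, Sw, Sf, Sf2, sigma_floor):
    """Closed-form M-step updates for (A, pi, r, sigma)."""
    K = model.K
    rows = trans_counts.sum(axis=1, keepdims=True)
    A = np.where(rows > 0, trans_counts / np.where(rows > 0, rows, 1.0), np.eye(K))
    A /= A.sum(axis=1, keepdims=True)
    pi = pi_counts / pi_counts.sum() if pi_counts.sum() > 0 else np.full(K, 1.0 / K)
    counts = np.arange(Sw.size)
    den = float((counts**2) @ Sw)
    pulse = float(counts @ Sf) / den if den > 0 else model.pulse_au
    pulse = max(pulse, 0.0)
    total_w = Sw.sum()
    ss = float(Sf2.sum() - 2 * pulse * (counts @ Sf) + pulse**2 * (counts**2) @ Sw)
    sigma = math.sqrt(max(ss, 0.0) / total_w) if total_w > 0 else model.sigma_au
    sigma_floored = sigma < sigma_floor
    sigma = max(sigma, sigma_floor)
    r = pulse * 60.0 / model.dt_s
    return CompoundHMM(
        K=K, w=model.w, A=A, pi=pi, r_au_per_min=r, sigma_au=sigma, dt_s=model.dt_s,
        rate_conversion=model.rate_conversion,
    ), sigma_floored


def _random_init(K, w, dt_s, F_all, rng) -> CompoundHMM:
    """Random but data-scaled starting point for one EM restart."""
    A = rng.dirichlet(np.full(K, 2.0), size=K)
    # bias toward persistence: bursting chains are sticky at 20 s frames
    A = 0.5 * A + 0.5 * np.eye(K)
    A /= A.sum(axis=1, keepdims=True)
    pi = rng.dirichlet(np.ones(K))
    finite = F_all[np.isfinite(F_all)]
    scale = np.percentile(finite, 97.5) if finite.size else 1.0
    scale = max(scale, 1e-6)
    pulse0 = scale / ((K - 1) * w) * rng.uniform(0.6, 1.4)
    sigma0 = max(float(finite.std()) * rng.uniform(0.2, 0.6), 1e-6) if finite.size else 1.0
    return CompoundHMM(K=K, w=w, A=A, pi=pi, r_au_per_min=pulse0 * 60.0 / dt_s,
                       sigma_au=sigma0, dt_s=dt_s)


def em_fit(
    fluos: Sequence[np.ndarray],
    K: int = 2,
    w: int = 7,
    dt_s: float = 20.0,
    init: CompoundHMM | None = None,
    max_iter: int = 500,
    tol_per_1000: float = 1e-4,
    n_restarts: int = 5,
    seed: int | np.random.Generator | None = None,
    min_total_frames: int = 1000,
    chunk_elems: int = 6_000_000,
) -> tuple[CompoundHMM, np.ndarray]:
    """Baum–Welch fit of the compound HMM to a set of fluorescence traces.

    Parameters are shared across traces ("global" inference).  The best of
    ``n_restarts`` random initializations is returned (plus the supplied
    ``init``, if any, as an extra candidate).  Convergence is declared when
    the log-likelihood improves by less than ``tol_per_1000`` per 1000
    observed frames; the emission sd is floored at 1e-3 times the data sd.

    Returns the fitted model and its log-likelihood trajectory.
    """
    fluos = [np.asarray(f, float) for f in fluos]
    if not fluos:
        raise ValueError("no traces supplied")
    F, lengths, _ = _pad_traces(fluos)
    n_obs = int(np.isfinite(F).sum())
    if n_obs < min_total_frames:
        raise ValueError(
            f"only {n_obs} observed frames; at least {min_total_frames} required "
            "(pass min_total_frames to override)"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    finite = F[np.isfinite(F)]
    sigma_floor = max(1e-3 * float(finite.std()), 1e-12)
    tol = tol_per_1000 * n_obs / 1000.0

    # chunk the trace batch to bound the (T, n, K^w) alpha array
    S = K**w
    T = F.shape[0]
    ncols = max(1, min(F.shape[1], chunk_elems // max(1, T * S)))
    col_chunks = [slice(i, min(i + ncols, F.shape[1])) for i in range(0, F.shape[1], ncols)]

    def run(model0: CompoundHMM):
        model = model0
        traj = []
        converged = False
        floored = False
        for _ in range(max_iter):
            ll = 0.0
            tc = np.zeros((K, K))
            pc = np.zeros(K)
            Sw = Sf = Sf2 = 0.0
            stats = None
            for sl in col_chunks:
                part = _e_step_stats(model, F[:, sl], lengths[sl])
                ll += part[0]
                tc += part[1]
                pc += part[2]
                if stats is None:
                    stats = [part[3].copy(), part[4].copy(), part[5].copy()]
                else:
                    for k in range(3):
                        stats[k] += part[3 + k]
            traj.append(ll)
            if len(traj) >= 2 and abs(traj[-1] - traj[-2]) < tol:
                converged = True
                break
            model, fl = _m_step(model, tc, pc, *stats, sigma_floor)
            floored |= fl
        # final likelihood of the returned parameters
        final_ll = traj[-1]
        model = CompoundHMM(
            K=K, w=w, A=model.A, pi=model.pi, r_au_per_min=model.r_au_per_min,
            sigma_au=model.sigma_au, dt_s=dt_s, converged=converged, loglik=final_ll,
            rate_conversion=model.rate_conversion,
        )
        if floored:
            warnings.warn("emission sigma hit its floor during EM", stacklevel=2)
        if not converged:
            warnings.warn("EM did not converge within max_iter", stacklevel=2)
        return model, np.asarray(traj)

    candidates = []
    if init is not None:
        candidates.append(run(init))
    for _ in range(n_restarts):
        candidates.append(run(_random_init(K, w, dt_s, F, rng)))
    best = max(candidates, key=lambda mt: mt[0].loglik)
    return best


# ---------------------------------------------------------------------------
# Viterbi
# ---------------------------------------------------------------------------

def viterbi_decode(model: CompoundHMM, fluo) -> np.ndarray:
    """Maximum-probability promoter-count path for one trace.

    Runs Viterbi over the compound state space and reads off the newest
    window symbol per frame.  Missing frames carry no emission term.
    """
    f = np.asarray(fluo, float)
    if np.isinf(f).any():
        raise ValueError("fluorescence contains infinite values")
    K, S = model.K, model.n_states
    idx = _Index(K, model.w)
    T = f.size
    loge_c = _log_emis_by_count(f, int(idx.n_on.max()) + 1, model.pulse_au, model.sigma_au)
    loge = loge_c[:, idx.n_on]  # (T, S)
    with np.errstate(divide="ignore"):
        logtrans = np.log(idx.trans_flat(model.A))
        logpi = np.log(model.pi)
    delta = np.full(S, -np.inf)
    delta[:K] = logpi
    delta += loge[0]
    psi = np.zeros((T, S), dtype=np.int8)
    for t in range(1, T):
        if model.w == 1:
            scores = delta[:, None] + np.log(model.A + 1e-300)  # [u, v]
            best_old = np.argmax(scores, axis=0)
            delta = loge[t] + scores[best_old, np.arange(S)]
            psi[t] = best_old.astype(np.int8)
        else:
            m = delta.reshape(K, S // K)  # [oldest symbol, lower word]
            best_old = np.argmax(m, axis=0)
            best_val = m[best_old, np.arange(S // K)]
            delta = loge[t] + logtrans + best_val[idx.prefix]
            psi[t] = best_old[idx.prefix].astype(np.int8)
    v = int(np.argmax(delta))
    states = np.empty(T, dtype=np.int64)
    states[T - 1] = v % K
    for t in range(T - 1, 0, -1):
        old = int(psi[t, v])
        v = old * (S // K) + v // K
        states[t - 1] = v % K
    return states


# ---------------------------------------------------------------------------
# effective two-state lumping
# ---------------------------------------------------------------------------

def _generator_from_A(A: np.ndarray, dt_min: float) -> tuple[np.ndarray, str]:
    """Continuous-time generator Q (per minute) from the per-frame matrix.

    Prefers Q = logm(A)/dt projected onto valid generators (negative
    off-diagonals clipped, diagonal rebalanced); falls back to the linear
    approximation (A - I)/dt when the matrix logarithm is not real.
    """
    method = "logm"
    try:
        L = logm(A)
        if np.max(np.abs(np.imag(L))) > 1e-8:
            raise ValueError("complex logarithm")
        Q = np.real(L) / dt_min
    except Exception:
        Q = (A - np.eye(A.shape[0])) / dt_min
        method = "linear"
    Q = Q.copy()
    off = ~np.eye(A.shape[0], dtype=bool)
    Q[off] = np.clip(Q[off], 0.0, None)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q, method


def _stationary(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a generator (least-squares null vector)."""
    K = Q.shape[0]
    M = np.vstack([Q.T, np.ones(K)])
    b = np.zeros(K + 1)
    b[-1] = 1.0
    p, *_ = np.linalg.lstsq(M, b, rcond=None)
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def effective_two_state(model: CompoundHMM) -> BurstParameters:
    """Lump the promoter-count chain into effective two-state burst kinetics.

    The locus is ON whenever at least one promoter is ON.  Rates come from
    the continuous-time generator: ``kon = Q[0,1] + Q[0,2]``;
    ``koff`` is the occupancy-weighted rate of falling back to 0; the
    effective loading rate is the occupancy-weighted mean of r and 2r.
    For K = 2 this reduces to the plain rates and r.
    """
    dt_min = model.dt_s / 60.0
    Q, method = _generator_from_A(model.A, dt_min)
    model.rate_conversion = method
    if model.K == 2:
        return BurstParameters(kon=float(Q[0, 1]), koff=float(Q[1, 0]),
                               r=float(model.r_au_per_min))
    p = _stationary(Q)
    if p[1] + p[2] <= 0:
        warnings.warn("ON states unreachable; koff/r undefined, returning 0", stacklevel=2)
        return BurstParameters(kon=float(Q[0, 1] + Q[0, 2]), koff=0.0, r=0.0)
    kon = float(Q[0, 1] + Q[0, 2])
    koff = float((p[1] * Q[1, 0] + p[2] * Q[2, 0]) / (p[1] + p[2]))
    r_eff = float(model.r_au_per_min * (p[1] + 2 * p[2]) / (p[1] + p[2]))
    return BurstParameters(kon=kon, koff=koff, r=r_eff)


# ---------------------------------------------------------------------------
# stripe x fluorescence-bin inference
# ---------------------------------------------------------------------------

def infer_by_fluorescence_bins(
    fluos: Sequence[np.ndarray],
    stripe_labels: Sequence[int],
    n_bins: int = 5,
    min_points: int = 1000,
    subset_size: int = 3000,
    n_boot: int = 10,
    K: int = 2,
    w: int = 7,
    dt_s: float = 20.0,
    seed: int | np.random.Generator | None = None,
    **em_kwargs,
):
    """Burst parameters per (stripe, mean-fluorescence bin).

    Nuclei are grouped by stripe and by quantile bin of their per-nucleus
    mean fluorescence.  Groups with fewer than ``min_points`` observed frames
    are skipped.  Within each group, EM runs on bootstrap subsets of about
    ``subset_size`` data points (nuclei drawn with replacement until the
    subset reaches that size); the reported estimate is the mean over
    subsets and the SE their standard deviation.

    Returns a pandas DataFrame with columns
    stripe, bin, kon_per_min, koff_per_min, r_au_per_min, se_kon, se_koff,
    se_r, n_points.
    """
    import pandas as pd

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fluos = [np.asarray(f, float) for f in fluos]
    stripe_labels = np.asarray(stripe_labels)
    mean_f = np.array([np.nanmean(f) for f in fluos])
    rows = []
    for stripe in np.unique(stripe_labels):
        sel = np.flatnonzero(stripe_labels == stripe)
        if sel.size == 0:
            continue
        qs = np.quantile(mean_f[sel], np.linspace(0, 1, n_bins + 1))
        bins = np.clip(np.searchsorted(qs, mean_f[sel], side="right") - 1, 0, n_bins - 1)
        for b in range(n_bins):
            members = sel[bins == b]
            pts = int(sum(np.isfinite(fluos[i]).sum() for i in members))
            if pts < min_points:
                continue
            boots = []
            for _ in range(n_boot):
                chosen, tot = [], 0
                while tot < subset_size:
                    i = int(rng.choice(members))
                    chosen.append(fluos[i])
                    tot += int(np.isfinite(fluos[i]).sum())
                model, _ = em_fit(
                    chosen, K=K, w=w, dt_s=dt_s, seed=rng,
                    min_total_frames=min(1000, subset_size), **em_kwargs,
                )
                boots.append(effective_two_state(model))
            kons = np.array([bp.kon for bp in boots])
            koffs = np.array([bp.koff for bp in boots])
            rs = np.array([bp.r for bp in boots])
            rows.append(
                {
                    "stripe": int(stripe),
                    "bin": int(b),
                    "kon_per_min": kons.mean(),
                    "koff_per_min": koffs.mean(),
                    "r_au_per_min": rs.mean(),
                    "se_kon": kons.std(ddof=1) if n_boot > 1 else np.nan,
                    "se_koff": koffs.std(ddof=1) if n_boot > 1 else np.nan,
                    "se_r": rs.std(ddof=1) if n_boot > 1 else np.nan,
                    "n_points": pts,
                }
            )
    if not rows:
        warnings.warn("no (stripe, bin) group met the minimum point count", stacklevel=2)
        return pd.DataFrame(
            columns=["stripe", "bin", "kon_per_min", "koff_per_min", "r_au_per_min",
                     "se_kon", "se_koff", "se_r", "n_points"]
        )
    return pd.DataFrame(rows)
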