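"""Sampling form of the ideal observer: Gibbs over sequence partitions.

The posterior over transition probabilities marginalizes the unknown
partition of the sequence into chunks.  Each partition is scored by its
prior (independent per-position jump probability p_J) times the product of
per-chunk marginal likelihoods, which are analytic under the flat
Beta prior: ML(chunk) = B(N_A|B+1, N_B|B+1) * B(N_B|A+1, N_A|A+1).
A single-site Gibbs sampler over the jump indicators J_2..J_t draws
partitions from this posterior; theta posteriors are mixtures of the
sampled partitions' last-chunk conjugate Beta posteriors.

The sweep kernel is numba-compiled; randomness enters only through a
pre-generated array of uniforms so results are reproducible given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit
from scipy.special import betaln

__all__ = [
    "GibbsConfig",
    "chunk_log_marginal_likelihood",
    "conditional_jump_probability",
    "gibbs_sample",
    "marginal_theta_posterior",
    "windowed_jump_likelihood",
    "chunk_length_stats",
    "transition_cumcounts",
]


@dataclass(frozen=True)
class GibbsConfig:
    n_iterations: int = 200
    n_warmup: int = 20
    p_jump: float = 1.0 / 75.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.n_warmup < self.n_iterations:
            raise ValueError("n_warmup must be below n_iterations")
        if not (0.0 <= self.p_jump < 1.0):
            raise ValueError("p_jump must lie in [0, 1)")


def chunk_log_marginal_likelihood(counts) -> float:
    """log ML of one chunk from its (N_A|B, N_B|B, N_B|A, N_A|A) counts."""
    n_ab, n_bb, n_ba, n_aa = counts
    if min(n_ab, n_bb, n_ba, n_aa) < 0:
        raise ValueError("transition counts must be non-negative")
    return float(betaln(n_ab + 1, n_bb + 1) + betaln(n_ba + 1, n_aa + 1)) - 2 * float(
        betaln(1, 1)
    )


def transition_cumcounts(y: np.ndarray) -> np.ndarray:
    """Cumulative transition counts C[j, c]: transitions at positions 2..j.

    Type codes c: 0 = B->A, 1 = B->B, 2 = A->B, 3 = A->A.  The counts of a
    chunk spanning 1-based positions [s, e] are ``C[e] - C[s]`` (its first
    stimulus contributes no transition).
    """
    y = np.asarray(y, dtype=np.int64)
    t = len(y)
    C = np.zeros((t + 1, 4), dtype=np.int64)
    if t >= 2:
        prev, curr = y[:-1], y[1:]
        code = np.where(
            prev == 0, np.where(curr == 1, 0, 1), np.where(curr == 0, 2, 3)
        )
        onehot = np.zeros((t - 1, 4), dtype=np.int64)
        onehot[np.arange(t - 1), code] = 1
        C[2:] = np.cumsum(onehot, axis=0)
    return C


def _counts_between(C: np.ndarray, start: int, end: int) -> tuple[int, int, int, int]:
    c = C[end] - C[start]
    return int(c[0]), int(c[1]), int(c[2]), int(c[3])


def conditional_jump_probability(
    jumps: np.ndarray, i: int, y: np.ndarray, p_jump: float
) -> float:
    """p(J_i = 1 | J_-i, y): the Gibbs full conditional at position i.

    ``jumps`` is a boolean vector indexed 2..t via ``jumps[i - 2]``; the
    chunk containing i under J_i = 0 is split at i and the two-hypothesis
    posterior formed from the chunk marginal likelihoods and the prior.
    """
    y = np.asarray(y, dtype=np.int64)
    t = len(y)
    if not (2 <= i <= t):
        raise ValueError("position i must lie in 2..t")
    if p_jump == 0.0:
        return 0.0
    C = transition_cumcounts(y)
    a = 1
    for s in range(i - 1, 1, -1):
        if jumps[s - 2]:
            a = s
            break
    b = t
    for s in range(i + 1, t + 1):
        if jumps[s - 2]:
            b = s - 1
            break
    lm_full = chunk_log_marginal_likelihood(_counts_between(C, a, b))
    lm_left = chunk_log_marginal_likelihood(_counts_between(C, a, i - 1))
    lm_right = chunk_log_marginal_likelihood(_counts_between(C, i, b))
    log_odds = (
        math.log(p_jump) - math.log1p(-p_jump) + lm_left + lm_right - lm_full
    )
    return 1.0 / (1.0 + math.exp(-log_odds))


@njit(cache=True)
def _log_ml(C, start, end):  # pragma: no cover - exercised via the sampler
    n_ab = C[end, 0] - C[start, 0]
    n_bb = C[end, 1] - C[start, 1]
    n_ba = C[end, 2] - C[start, 2]
    n_aa = C[end, 3] - C[start, 3]
    return (
        math.lgamma(n_ab + 1.0)
        + math.lgamma(n_bb + 1.0)
        - math.lgamma(n_ab + n_bb + 2.0)
        + math.lgamma(n_ba + 1.0)
        + math.lgamma(n_aa + 1.0)
        - math.lgamma(n_ba + n_aa + 2.0)
    )


@njit(cache=True)
def _sweep_kernel(C, n_iterations, n_warmup, log_pj, log_qj, u):
    t = C.shape[0] - 1
    jumps = np.zeros(t + 1, dtype=np.uint8)  # initialized without jumps
    out = np.zeros((n_iterations - n_warmup, t - 1), dtype=np.uint8)
    for it in range(n_iterations):
        for i in range(2, t + 1):
            a = 1
            for s in range(i - 1, 1, -1):
                if jumps[s]:
                    a = s
                    break
            b = t
            for s in range(i + 1, t + 1):
                if jumps[s]:
                    b = s - 1
                    break
            log_odds = (
                log_pj
                - log_qj
                + _log_ml(C, a, i - 1)
                + _log_ml(C, i, b)
                - _log_ml(C, a, b)
            )
            p = 1.0 / (1.0 + math.exp(-log_odds))
            jumps[i] = 1 if u[it, i - 2] < p else 0
        if it >= n_warmup:
            for i in range(2, t + 1):
                out[it - n_warmup, i - 2] = jumps[i]
    return out


def gibbs_sample(
    y: np.ndarray, config: GibbsConfig, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Post-warmup partition samples for the prefix ``y``.

    Returns a (n_iterations - n_warmup, t - 1) uint8 array of jump
    indicators for positions 2..t (column k is position k + 2).
    """
    y = np.asarray(y, dtype=np.int64)
    t = len(y)
    if t < 2:
        raise ValueError("need a prefix of at least two stimuli")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    C = transition_cumcounts(y)
    u = rng.random((config.n_iterations, t - 1))
    log_pj = math.log(config.p_jump) if config.p_jump > 0 else -np.inf
    log_qj = math.log1p(-config.p_jump)
    return _sweep_kernel(
        C, config.n_iterations, config.n_warmup, log_pj, log_qj, u
    )


def _last_chunk_starts(samples: np.ndarray) -> np.ndarray:
    """1-based start position of the current chunk, per sample."""
    n, m = samples.shape
    rev = samples[:, ::-1].astype(bool)
    has = rev.any(axis=1)
    first = np.argmax(rev, axis=1)  # offset of last jump from the end
    starts = np.where(has, (m - 1 - first) + 2, 1)
    return starts.astype(np.int64)


def marginal_theta_posterior(samples: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Mixture posterior of the current transition probabilities.

    Each sample contributes its last chunk's conjugate Beta posterior; the
    mixture mean and variance are exact (no grid).  Confidence is the
    negative log of the mixture variance.
    """
    if len(samples) == 0:
        raise ValueError("no samples given")
    y = np.asarray(y, dtype=np.int64)
    t = len(y)
    C = transition_cumcounts(y)
    starts = _last_chunk_starts(samples)
    counts = C[t] - C[starts]  # (n_samples, 4)
    out: dict[str, float] = {}
    for name, (i_succ, i_fail) in (("A_given_B", (0, 1)), ("B_given_A", (2, 3))):
        a = counts[:, i_succ] + 1.0
        b = counts[:, i_fail] + 1.0
        mus = a / (a + b)
        vars_ = a * b / ((a + b) ** 2 * (a + b + 1.0))
        mu = float(np.mean(mus))
        var = float(np.mean(vars_ + mus**2) - mu**2)
        out[f"mean_{name}"] = mu
        out[f"var_{name}"] = var
        out[f"confidence_{name}"] = -math.log(var)
    return out


def windowed_jump_likelihood(
    samples: np.ndarray, k: int, window: int = 5
) -> float:
    """Posterior probability of >= 1 jump within ``k +/- window`` stimuli."""
    t = samples.shape[1] + 1
    lo = max(2, k - window)
    hi = min(t, k + window)
    if hi < lo:
        return 0.0
    return float(samples[:, lo - 2 : hi - 1].any(axis=1).mean())


def chunk_length_stats(samples: np.ndarray) -> tuple[float, float]:
    """Sample mean and variance of the current chunk's length."""
    t = samples.shape[1] + 1
    lengths = t - _last_chunk_starts(samples) + 1
    return float(lengths.mean()), float(lengths.var())
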