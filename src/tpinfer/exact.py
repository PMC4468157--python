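"""Exact ideal-observer inference by exhaustive partition enumeration.

For a short sequence prefix y_1:t the posterior over jump configurations
J in {0,1}^(t-1) can be enumerated directly: each configuration is weighted
by its prior p_J^k (1-p_J)^(t-1-k) times the product of per-chunk marginal
likelihoods.  This is exponential in t and only intended as an independent
reference for the sampling (Gibbs) and grid (forward-backward) observers on
sequences of a dozen stimuli or so.

Two marginal-likelihood backends are available: the analytic Beta-integral
("beta", matching the samplers' continuous flat prior) and midpoint-grid
quadrature ("grid", matching the forward-backward observer's discretized
prior node for node).
"""

from __future__ import annotations

from itertools import product
from typing import Literal, Optional

import numpy as np
from scipy.special import betaln

__all__ = ["ExactPosterior", "enumerate_posterior", "chunk_counts"]


def chunk_counts(y: np.ndarray, start: int, end: int) -> tuple[int, int, int, int]:
    """Transition counts (N_A|B, N_B|B, N_B|A, N_A|A) of chunk [start, end].

    ``start``/``end`` are 1-based inclusive stimulus positions; the chunk's
    first stimulus contributes no transition.
    """
    seg_prev = y[start - 1 : end - 1]
    seg_curr = y[start:end]
    n_ab = int(np.sum((seg_prev == 0) & (seg_curr == 1)))
    n_bb = int(np.sum((seg_prev == 0) & (seg_curr == 0)))
    n_ba = int(np.sum((seg_prev == 1) & (seg_curr == 0)))
    n_aa = int(np.sum((seg_prev == 1) & (seg_curr == 1)))
    return n_ab, n_bb, n_ba, n_aa


def _log_ml_beta(counts: tuple[int, int, int, int]) -> float:
    n_ab, n_bb, n_ba, n_aa = counts
    return float(
        betaln(n_ab + 1, n_bb + 1)
        - betaln(1, 1)
        + betaln(n_ba + 1, n_aa + 1)
        - betaln(1, 1)
    )


class _GridBackend:
    def __init__(self, grid_k: int):
        self.nodes = (np.arange(grid_k) + 0.5) / grid_k

    def log_ml(self, counts: tuple[int, int, int, int]) -> float:
        n_ab, n_bb, n_ba, n_aa = counts
        x = self.nodes
        m1 = np.mean(x**n_ab * (1 - x) ** n_bb)
        m2 = np.mean(x**n_ba * (1 - x) ** n_aa)
        return float(np.log(m1) + np.log(m2))

    def moments(self, a: int, b: int) -> tuple[float, float]:
        """Mean/variance of the grid posterior with likelihood x^a (1-x)^b."""
        x = self.nodes
        w = x**a * (1 - x) ** b
        w = w / w.sum()
        mu = float(np.sum(w * x))
        return mu, float(np.sum(w * (x - mu) ** 2))


def _beta_moments(a: int, b: int) -> tuple[float, float]:
    """Mean/variance of Beta(a+1, b+1) (flat prior plus counts a, b)."""
    aa, bb = a + 1.0, b + 1.0
    mu = aa / (aa + bb)
    var = aa * bb / ((aa + bb) ** 2 * (aa + bb + 1.0))
    return mu, var


class ExactPosterior:
    """Posterior summaries of the enumerated partition posterior at y_1:t."""

    def __init__(
        self,
        weights: np.ndarray,
        configs: np.ndarray,
        y: np.ndarray,
        backend,
    ):
        self.weights = weights  # normalized, one per jump configuration
        self.configs = configs  # (n_config, t-1) booleans, J_2..J_t
        self.y = y
        self.t = len(y)
        self._backend = backend

    def jump_marginals(self) -> np.ndarray:
        """p(J_k = 1 | y_1:t) for k = 2..t (array of length t-1)."""
        return self.weights @ self.configs

    def windowed_jump_probability(self, k: int, w: int = 5) -> float:
        """Posterior probability of >= 1 jump within k +/- w."""
        lo = max(2, k - w)
        hi = min(self.t, k + w)
        if hi < lo:
            return 0.0
        any_jump = self.configs[:, lo - 2 : hi - 1].any(axis=1)
        return float(self.weights @ any_jump)

    def _last_chunk_starts(self) -> np.ndarray:
        starts = np.ones(len(self.configs), dtype=np.int64)
        for j, cfg in enumerate(self.configs):
            idx = np.flatnonzero(cfg)
            if len(idx):
                starts[j] = idx[-1] + 2  # config column 0 is position 2
        return starts

    def theta_summary(self) -> dict[str, float]:
        """Mixture mean/variance of the current (last-chunk) thetas."""
        mus = np.empty((len(self.configs), 2))
        vars_ = np.empty((len(self.configs), 2))
        for j, start in enumerate(self._last_chunk_starts()):
            n_ab, n_bb, n_ba, n_aa = chunk_counts(self.y, int(start), self.t)
            if self._backend is None:
                mus[j, 0], vars_[j, 0] = _beta_moments(n_ab, n_bb)
                mus[j, 1], vars_[j, 1] = _beta_moments(n_ba, n_aa)
            else:
                mus[j, 0], vars_[j, 0] = self._backend.moments(n_ab, n_bb)
                mus[j, 1], vars_[j, 1] = self._backend.moments(n_ba, n_aa)
        w = self.weights
        mu = w @ mus
        var = w @ (vars_ + mus**2) - mu**2
        return {
            "mean_A_given_B": float(mu[0]),
            "var_A_given_B": float(var[0]),
            "mean_B_given_A": float(mu[1]),
            "var_B_given_A": float(var[1]),
        }

    def chunk_length_stats(self) -> tuple[float, float]:
        """Posterior mean and variance of the current chunk's length."""
        lengths = self.t - self._last_chunk_starts() + 1
        mean = float(self.weights @ lengths)
        var = float(self.weights @ (lengths - mean) ** 2)
        return mean, var


def enumerate_posterior(
    y: np.ndarray,
    p_jump: float,
    backend: Literal["beta", "grid"] = "beta",
    grid_k: Optional[int] = None,
) -> ExactPosterior:
    """Enumerate all 2^(t-1) jump configurations of the prefix ``y``."""
    y = np.asarray(y, dtype=np.int64)
    t = len(y)
    if t < 2:
        raise ValueError("need at least two stimuli to enumerate partitions")
    if t > 20:
        raise ValueError("enumeration is exponential; refusing t > 20")
    be = _GridBackend(grid_k) if backend == "grid" else None
    log_ml = be.log_ml if be is not None else _log_ml_beta

    configs = np.array(list(product((0, 1), repeat=t - 1)), dtype=np.int64)
    logw = np.empty(len(configs))
    lp, lq = np.log(p_jump) if p_jump > 0 else -np.inf, np.log1p(-p_jump)
    for j, cfg in enumerate(configs):
        starts = [1] + [k + 2 for k in np.flatnonzero(cfg)]
        ends = [s - 1 for s in starts[1:]] + [t]
        n_jumps = int(cfg.sum())
        lw = (n_jumps * lp if n_jumps else 0.0) + (t - 1 - n_jumps) * lq
        for s, e in zip(starts, ends):
            lw += log_ml(chunk_counts(y, s, e))
        logw[j] = lw
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    return ExactPosterior(w, configs.astype(float), y, be)
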