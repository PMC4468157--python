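"""Iterative form of the ideal observer: forward-backward on a theta grid.

The pair of transition probabilities (theta_A|B, theta_B|A) is discretized
onto a regular K x K grid of interval midpoints, turning the changepoint
model into a hidden Markov model over K^2 states whose transition matrix is
T = (1 - p_J) I + p_J (1 prior^T): with probability p_J the thetas are
redrawn from the (uniform) prior, otherwise they persist.  The forward pass
yields the filtered theta posterior at every position; forward and backward
passes combine into the posterior probability that a jump occurred at
position k given the stimuli observed up to any horizon t >= k.

All passes renormalize each step and exploit the rank-one-plus-diagonal
structure of T, so a forward sweep is O(N K^2) and the full jump-posterior
matrix (all horizons) is O(N^2 K^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "ThetaGrid",
    "PosteriorSummary",
    "observation_likelihood",
    "forward_step",
    "forward_pass",
    "filtered_theta_summary",
    "filtered_series",
    "jump_posterior_matrix",
    "windowed_jump_matrix",
]


@dataclass(frozen=True)
class ThetaGrid:
    """Midpoint grid over the unit square of transition probabilities."""

    k: int = 40

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("grid needs at least 2 nodes per dimension")

    @property
    def nodes(self) -> np.ndarray:
        return (np.arange(self.k) + 0.5) / self.k

    @property
    def n_states(self) -> int:
        return self.k * self.k

    @property
    def prior(self) -> np.ndarray:
        return np.full(self.n_states, 1.0 / self.n_states)

    def state_thetas(self) -> tuple[np.ndarray, np.ndarray]:
        """(theta_A|B, theta_B|A) node values of each flattened state.

        States are laid out with theta_A|B varying along the first axis.
        """
        x1 = np.repeat(self.nodes, self.k)
        x2 = np.tile(self.nodes, self.k)
        return x1, x2


@dataclass
class PosteriorSummary:
    """Per-position posterior mean/variance for both transitions.

    ``times`` holds 1-based stimulus positions; row i summarizes the
    posterior after observing y_1..y_times[i].  Confidence is the
    log-precision -log(variance).
    """

    times: np.ndarray
    mean_A_given_B: np.ndarray
    var_A_given_B: np.ndarray
    mean_B_given_A: np.ndarray
    var_B_given_A: np.ndarray

    @property
    def confidence_A_given_B(self) -> np.ndarray:
        return -np.log(self.var_A_given_B)

    @property
    def confidence_B_given_A(self) -> np.ndarray:
        return -np.log(self.var_B_given_A)

    def queried(self, y: np.ndarray) -> dict[str, np.ndarray]:
        """Summaries of the queried quantity p(next stimulus is A).

        The queried transition at a pause after position t depends on the
        identity of stimulus t: theta_A|B after a B, 1 - theta_B|A after
        an A.  Variance (hence confidence) is that of the queried theta.
        """
        y = np.asarray(y, dtype=np.int64)
        prev_is_b = y[self.times - 1] == 0
        p_a = np.where(
            prev_is_b, self.mean_A_given_B, 1.0 - self.mean_B_given_A
        )
        var = np.where(prev_is_b, self.var_A_given_B, self.var_B_given_A)
        theta_mean = np.where(
            prev_is_b, self.mean_A_given_B, self.mean_B_given_A
        )
        return {
            "prob_next_A": p_a,
            "queried_theta_mean": theta_mean,
            "variance": var,
            "confidence": -np.log(var),
        }


def observation_likelihood(
    y_prev: Optional[int], y_curr: int, grid: ThetaGrid
) -> np.ndarray:
    """Likelihood vector over grid states for one observed stimulus.

    At the first stimulus (``y_prev`` is None) the likelihood is constant:
    the first stimulus is treated as carrying no information about the
    transition probabilities.
    """
    if y_prev is None:
        return np.ones(grid.n_states)
    x1, x2 = grid.state_thetas()
    if y_prev == 0:  # from B
        return x1.copy() if y_curr == 1 else 1.0 - x1
    return x2.copy() if y_curr == 0 else 1.0 - x2


def forward_step(
    alpha_prev: np.ndarray, lik: np.ndarray, p_jump: float, prior: np.ndarray
) -> tuple[np.ndarray, float]:
    """One forward update; returns the normalized alpha and log-normalizer.

    The structured transition T = (1-p_J) I + p_J (1 prior^T) gives
    T^T alpha = (1-p_J) alpha + p_J prior for a normalized alpha.  The
    observation enters only the no-jump branch: the first stimulus after a
    changepoint is the first stimulus of a fresh chunk, whose likelihood is
    theta-independent (the same convention the chunk marginal likelihoods
    use), so the jump branch carries a constant likelihood of 1.
    """
    a = (1.0 - p_jump) * alpha_prev * lik + p_jump * prior
    norm = a.sum()
    if norm <= 0.0:
        raise FloatingPointError("forward pass underflowed to zero mass")
    return a / norm, float(np.log(norm))


def forward_pass(
    y: np.ndarray, p_jump: float, grid: ThetaGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized filtered joint posteriors alpha_t for t = 1..N.

    Returns (alphas, log_normalizers): alphas[t-1] is p(x | y_1:t) over the
    K^2 states; the summed log-normalizers give the sequence log-evidence.
    """
    y = np.asarray(y, dtype=np.int64)
    n = len(y)
    alphas = np.empty((n, grid.n_states))
    lognorm = np.zeros(n)
    prior = grid.prior
    alphas[0] = prior  # first-stimulus likelihood is state-independent
    for t in range(1, n):
        lik = observation_likelihood(int(y[t - 1]), int(y[t]), grid)
        alphas[t], lognorm[t] = forward_step(alphas[t - 1], lik, p_jump, prior)
    return alphas, lognorm


def _moments(weights_1d: np.ndarray, nodes: np.ndarray) -> tuple[float, float]:
    w = weights_1d / weights_1d.sum()
    mu = float(w @ nodes)
    return mu, float(w @ (nodes - mu) ** 2)


def filtered_theta_summary(alpha: np.ndarray, grid: ThetaGrid) -> dict[str, float]:
    """Marginal mean/variance/confidence of both thetas from one alpha."""
    joint = alpha.reshape(grid.k, grid.k)
    out: dict[str, float] = {}
    for name, marg in (
        ("A_given_B", joint.sum(axis=1)),
        ("B_given_A", joint.sum(axis=0)),
    ):
        mu, var = _moments(marg, grid.nodes)
        out[f"mean_{name}"] = mu
        out[f"var_{name}"] = var
        out[f"confidence_{name}"] = -float(np.log(var))
    return out


def filtered_series(
    y: np.ndarray, p_jump: float, grid: ThetaGrid
) -> PosteriorSummary:
    """Filtered posterior summaries at every position of the sequence."""
    y = np.asarray(y, dtype=np.int64)
    alphas, _ = forward_pass(y, p_jump, grid)
    joint = alphas.reshape(len(y), grid.k, grid.k)
    nodes = grid.nodes
    out = {}
    for name, axis in (("A_given_B", 2), ("B_given_A", 1)):
        marg = joint.sum(axis=axis)
        marg = marg / marg.sum(axis=1, keepdims=True)
        mu = marg @ nodes
        var = marg @ (nodes**2) - mu**2
        out[f"mean_{name}"] = mu
        out[f"var_{name}"] = var
    return PosteriorSummary(
        times=np.arange(1, len(y) + 1),
        mean_A_given_B=out["mean_A_given_B"],
        var_A_given_B=out["var_A_given_B"],
        mean_B_given_A=out["mean_B_given_A"],
        var_B_given_A=out["var_B_given_A"],
    )


def _likelihood_table(y: np.ndarray, grid: ThetaGrid) -> np.ndarray:
    """L[t-1] = likelihood vector of observation t (t >= 2); L[0] unused."""
    n = len(y)
    lik = np.ones((n, grid.n_states))
    for t in range(1, n):
        lik[t] = observation_likelihood(int(y[t - 1]), int(y[t]), grid)
    return lik


def jump_posterior_matrix(
    y: np.ndarray,
    p_jump: float,
    grid: ThetaGrid,
    horizons: Optional[np.ndarray] = None,
) -> np.ndarray:
    """gamma[k-1, t-1] = p(a jump occurred at position k | y_1:t), k <= t.

    A jump "at k" means the thetas changed between stimuli k-1 and k, so
    entries exist for 2 <= k <= t.  One backward pass is run per requested
    horizon; unrequested horizons are left at NaN.
    """
    y = np.asarray(y, dtype=np.int64)
    n = len(y)
    if horizons is None:
        horizons = np.arange(2, n + 1)
    horizons = np.asarray(horizons, dtype=np.int64)
    alphas, _ = forward_pass(y, p_jump, grid)
    lik = _likelihood_table(y, grid)
    prior = grid.prior
    # jump/no-jump split of the (unnormalized-consistent) forward messages:
    # alpha_k(x, J=1) ~ p_J prior(x) (the observation at a chunk start is
    # theta-independent); alpha_k(x, J=0) ~ (1-p_J) alpha_{k-1}(x) L_k(x);
    # both share the same normalizer at each k.
    gamma = np.full((n, n), np.nan)
    for t in horizons:
        beta = np.ones(grid.n_states)
        for k in range(int(t), 1, -1):
            a1 = p_jump * prior
            a0 = (1.0 - p_jump) * alphas[k - 2] * lik[k - 1]
            num1 = float((a1 * beta).sum())
            num0 = float((a0 * beta).sum())
            gamma[k - 1, t - 1] = num1 / (num0 + num1)
            # backward step: beta at k -> beta at k - 1; the jump branch's
            # pooled term likewise carries no observation likelihood
            pooled = float(prior @ beta)
            beta = (1.0 - p_jump) * lik[k - 1] * beta + p_jump * pooled
            m = beta.max()
            if m <= 0.0:
                raise FloatingPointError("backward pass underflowed")
            beta /= m
    return gamma


def windowed_jump_matrix(gamma: np.ndarray, window: int = 5) -> np.ndarray:
    """p(>= 1 jump within k +/- window | y_1:t) under a per-position
    independence approximation: 1 - prod(1 - gamma) over the window."""
    n = gamma.shape[0]
    out = np.full_like(gamma, np.nan)
    g = np.nan_to_num(gamma, nan=0.0)
    log1m = np.log1p(-np.clip(g, 0.0, 1.0 - 1e-12))
    for k in range(2, n + 1):
        lo, hi = max(2, k - window), min(n, k + window)
        s = log1m[lo - 1 : hi, :].sum(axis=0)
        out[k - 1, :] = 1.0 - np.exp(s)
    out[:, : 1] = np.nan
    valid = ~np.isnan(gamma)
    # restore NaN wherever the horizon was not computed or k > t
    col_has = valid.any(axis=0)
    out[:, ~col_has] = np.nan
    for k in range(2, n + 1):
        out[k - 1, : k - 1] = np.nan
    out[0, :] = np.nan
    return out
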