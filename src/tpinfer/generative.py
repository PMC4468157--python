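"""Generative process for volatile binary Markov sequences.

A session is a sequence of two symbols (A/B) produced by a first-order
Markov chain whose two transition probabilities, theta_A|B = p(A after B)
and theta_B|A = p(B after A), stay constant within "chunks" and change
abruptly at unsignalled "jumps".  Chunk lengths are geometric (mean 75,
draws above 300 rejected), thetas are uniform on [0.1, 0.9] with the
constraint that at least one of the two odds ratios p/(1-p) changes by a
factor >= 4 between consecutive chunks.  The sequence pauses every
15 +/- {1,2,3} stimuli for probability/confidence questions.

Also provides a noisy-readout agent: a simulated subject whose answers are
the ideal observer's outputs corrupted by Gaussian noise and lapses, used
for parameter-recovery validation of the analysis stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GenerativeParams",
    "Session",
    "AgentParams",
    "SubjectResponses",
    "sample_chunk_lengths",
    "sample_transition_probs",
    "sample_question_positions",
    "generate_session",
    "simulate_agent",
]

# symbols are encoded internally as integers: A = 1, B = 0
A, B = 1, 0

_MAX_REJECT = 100_000


@dataclass(frozen=True)
class GenerativeParams:
    """Constants of the generative process (defaults are the task's)."""

    session_length: int = 380
    mean_chunk_length: float = 75.0
    max_chunk_length: int = 300
    theta_low: float = 0.1
    theta_high: float = 0.9
    min_odds_ratio_change: float = 4.0
    question_period: int = 15
    question_jitter_magnitudes: tuple[int, ...] = (1, 2, 3)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_low < self.theta_high < 1.0):
            raise ValueError("need 0 < theta_low < theta_high < 1")
        if self.mean_chunk_length < 1:
            raise ValueError("mean_chunk_length must be >= 1")
        if self.max_chunk_length <= self.mean_chunk_length:
            raise ValueError("max_chunk_length must exceed mean_chunk_length")
        if self.min_odds_ratio_change < 1:
            raise ValueError("min_odds_ratio_change must be >= 1")
        if self.session_length < 1:
            raise ValueError("session_length must be >= 1")


@dataclass(frozen=True)
class Session:
    """One generated sequence plus its hidden structure.

    Stimulus positions are 1-based throughout the public interface.
    ``stimuli`` is an int array of 0 (B) / 1 (A) of length ``session_length``;
    ``jump_positions[j]`` is the 1-based position at which chunk ``j+1``
    begins (position 1 never counts as a jump); ``chunk_thetas`` has one
    ``(theta_A_given_B, theta_B_given_A)`` row per chunk.
    """

    stimuli: np.ndarray
    jump_positions: np.ndarray
    chunk_thetas: np.ndarray
    question_positions: np.ndarray

    @property
    def n_stimuli(self) -> int:
        return len(self.stimuli)

    @property
    def n_chunks(self) -> int:
        return len(self.chunk_thetas)

    def chunk_index(self) -> np.ndarray:
        """0-based chunk id of every stimulus position."""
        idx = np.zeros(self.n_stimuli, dtype=np.int64)
        for pos in self.jump_positions:
            idx[pos - 1 :] += 1
        return idx

    def theta_at(self, position: int) -> tuple[float, float]:
        """Generative (theta_A|B, theta_B|A) in force at a 1-based position."""
        k = int(np.searchsorted(self.jump_positions, position, side="right"))
        return tuple(self.chunk_thetas[k])

    def relabel(self) -> "Session":
        """Swap the A/B labels (and hence the two transition probabilities)."""
        return Session(
            stimuli=1 - self.stimuli,
            jump_positions=self.jump_positions.copy(),
            chunk_thetas=self.chunk_thetas[:, ::-1].copy(),
            question_positions=self.question_positions.copy(),
        )


def _odds(p: float) -> float:
    return p / (1.0 - p)


def sample_chunk_lengths(
    params: GenerativeParams, rng: np.random.Generator
) -> list[int]:
    """Draw chunk lengths covering exactly ``session_length`` stimuli.

    Lengths are geometric on {1, 2, ...} with success probability
    1/mean_chunk_length; draws above ``max_chunk_length`` are rejected and
    redrawn, and the final chunk is truncated at the session end.
    """
    p = 1.0 / params.mean_chunk_length
    lengths: list[int] = []
    remaining = params.session_length
    guard = 0
    while remaining > 0:
        draw = int(rng.geometric(p))
        if draw > params.max_chunk_length:
            guard += 1  # consecutive rejections signal a bad configuration
            if guard > _MAX_REJECT:
                raise RuntimeError(
                    "chunk-length rejection loop did not terminate"
                )
            continue
        guard = 0
        lengths.append(min(draw, remaining))
        remaining -= lengths[-1]
    return lengths


def sample_transition_probs(
    params: GenerativeParams,
    previous_thetas: Optional[Sequence[float]],
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Draw a (theta_A|B, theta_B|A) pair uniform on the allowed interval.

    When ``previous_thetas`` is given, candidates are rejected until the
    multiplicative change in odds ratio p/(1-p) relative to the previous
    chunk is at least ``min_odds_ratio_change`` for at least one of the two
    transitions.
    """
    lo, hi = params.theta_low, params.theta_high
    for _ in range(_MAX_REJECT):
        cand = (float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi)))
        if previous_thetas is None:
            return cand
        ok = False
        for new, old in zip(cand, previous_thetas):
            r = _odds(new) / _odds(old)
            if max(r, 1.0 / r) >= params.min_odds_ratio_change:
                ok = True
        if ok:
            return cand
    raise RuntimeError(
        "odds-ratio constraint unsatisfiable under the given theta bounds"
    )


def sample_question_positions(
    params: GenerativeParams, rng: np.random.Generator
) -> np.ndarray:
    """Question positions spaced question_period +/- a jitter magnitude.

    The jitter magnitude is uniform over ``question_jitter_magnitudes`` and
    its sign uniform, drawn independently per interval; jitter is never 0.
    """
    mags = np.asarray(params.question_jitter_magnitudes, dtype=np.int64)
    positions: list[int] = []
    pos = 0
    while True:
        step = params.question_period + int(rng.choice(mags)) * int(
            rng.choice((-1, 1))
        )
        pos += step
        if pos > params.session_length:
            break
        positions.append(pos)
    return np.asarray(positions, dtype=np.int64)


def generate_session(
    params: GenerativeParams, rng: Optional[np.random.Generator] = None
) -> Session:
    """Generate one full session from the generative process."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    lengths = sample_chunk_lengths(params, rng)
    thetas: list[tuple[float, float]] = []
    for _ in lengths:
        prev = thetas[-1] if thetas else None
        thetas.append(sample_transition_probs(params, prev, rng))
    chunk_thetas = np.asarray(thetas, dtype=float)
    jump_positions = np.cumsum(lengths[:-1]) + 1  # chunk k+1 starts here

    stimuli = np.empty(params.session_length, dtype=np.int64)
    # the first stimulus carries no transition information; draw it fair
    stimuli[0] = A if rng.random() < 0.5 else B
    chunk_of = np.zeros(params.session_length, dtype=np.int64)
    for pos in jump_positions:
        chunk_of[pos - 1 :] += 1
    u = rng.random(params.session_length)
    for t in range(1, params.session_length):
        th_ab, th_ba = chunk_thetas[chunk_of[t]]
        p_a = th_ab if stimuli[t - 1] == B else 1.0 - th_ba
        stimuli[t] = A if u[t] < p_a else B

    questions = sample_question_positions(params, rng)
    return Session(
        stimuli=stimuli,
        jump_positions=np.asarray(jump_positions, dtype=np.int64),
        chunk_thetas=chunk_thetas,
        question_positions=questions,
    )


# ---------------------------------------------------------------------------
# simulated subjects


@dataclass(frozen=True)
class AgentParams:
    """Noisy-readout agent of the ideal observer.

    The agent reports the observer's posterior mean plus Gaussian noise as
    its probability estimate, an affine-plus-noise readout of the observer's
    log-precision as its confidence rating, and jumps wherever the
    observer's jump posterior exceeds ``detection_threshold``.
    """

    estimate_noise_sd: float = 0.05
    confidence_offset: float = -0.6
    confidence_gain: float = 0.25
    confidence_noise_sd: float = 0.10
    detection_threshold: float = 0.25
    lapse_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.estimate_noise_sd < 0 or self.confidence_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not (0.0 <= self.lapse_rate <= 1.0):
            raise ValueError("lapse_rate must lie in [0, 1]")
        if not (0.0 < self.detection_threshold < 1.0):
            raise ValueError("detection_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class SubjectResponses:
    """Per-question estimates/ratings and on-line jump reports.

    ``report_times`` (W) and ``reported_positions`` (Z) are parallel arrays
    with Z <= W: at stimulus W the subject reported a jump located at Z.
    ``probability_estimates`` may be NaN in the confidence-only variant.
    """

    question_positions: np.ndarray
    probability_estimates: np.ndarray
    confidence_ratings: np.ndarray
    report_times: np.ndarray
    reported_positions: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.reported_positions > self.report_times):
            raise ValueError("every reported position Z must satisfy Z <= W")


def simulate_agent(
    session: Session,
    io_mean: np.ndarray,
    io_confidence: np.ndarray,
    reports: Sequence[tuple[int, int]],
    agent: AgentParams,
    rng: np.random.Generator,
) -> SubjectResponses:
    """Simulate one subject as a noisy readout of the ideal observer.

    ``io_mean`` and ``io_confidence`` are the observer's per-question
    posterior mean (for the queried transition) and log-precision, computed
    on-line on this session; ``reports`` are the observer's thresholded jump
    reports (W, Z pairs at the agent's detection threshold).
    """
    q = session.question_positions
    if len(io_mean) != len(q) or len(io_confidence) != len(q):
        raise ValueError("observer outputs do not match the question count")
    n = len(q)
    est = io_mean + rng.normal(0.0, agent.estimate_noise_sd, size=n)
    conf = (
        agent.confidence_offset
        + agent.confidence_gain * io_confidence
        + rng.normal(0.0, agent.confidence_noise_sd, size=n)
    )
    lapse = rng.random(n) < agent.lapse_rate
    est[lapse] = rng.random(int(lapse.sum()))
    lapse_c = rng.random(n) < agent.lapse_rate
    conf[lapse_c] = rng.random(int(lapse_c.sum()))
    W = np.asarray([w for w, _ in reports], dtype=np.int64)
    Z = np.asarray([z for _, z in reports], dtype=np.int64)
    return SubjectResponses(
        question_positions=q.copy(),
        probability_estimates=np.clip(est, 0.0, 1.0),
        confidence_ratings=np.clip(conf, 0.0, 1.0),
        report_times=W,
        reported_positions=Z,
    )
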