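"""Jump-report extraction and detection scoring.

The observer's jump posterior is a lower-triangular matrix gamma(k, t):
the probability that the thetas changed at position k given the stimuli
observed up to horizon t.  Thresholding this matrix produces connected
"patches"; each patch is read out as one discrete jump report (W, Z): at
report time W (the patch's earliest horizon) a jump is reported at
position Z.  Reports are scored against the generative jump positions with
a +/- w tolerance window, summarized by the informedness index
(hit rate - false-alarm rate), and tested against a surrogate null that
regenerates the hidden jump structure while holding reports fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, stats

from .generative import GenerativeParams, sample_chunk_lengths

__all__ = [
    "DetectionConfig",
    "TrialClassification",
    "discretize_jump_posterior",
    "classify_trials",
    "informedness",
    "pooled_informedness",
    "group_informedness_t",
    "surrogate_null",
    "sort_posterior_by_outcome",
    "select_threshold",
]

HIT, MISS, FALSE_ALARM, CORRECT_REJECTION = "hit", "miss", "FA", "CR"


@dataclass(frozen=True)
class DetectionConfig:
    window: int = 5
    threshold: float = 0.25
    n_surrogates: int = 10_000

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")


def discretize_jump_posterior(
    gamma: np.ndarray, threshold: float
) -> list[tuple[int, int]]:
    """Read discrete jump reports (W, Z) off a thresholded gamma matrix.

    Supra-threshold cells form 4-connected patches in the (position k,
    horizon t) plane; each patch yields one report with W = the patch's
    earliest horizon (the detection moment) and Z = the smallest position
    present at that horizon.  Reports are returned sorted by W.
    """
    mask = np.nan_to_num(gamma, nan=0.0) >= threshold
    if not mask.any():
        return []
    labels, n = ndimage.label(mask)  # default structure = 4-connectivity
    reports = []
    for lab in range(1, n + 1):
        ks, ts = np.nonzero(labels == lab)
        w = int(ts.min())
        z = int(ks[ts == w].min())
        reports.append((w + 1, z + 1))  # matrix indices are 0-based
    reports.sort()
    return reports


@dataclass
class TrialClassification:
    """Per-position outcome labels plus the report-level matching."""

    labels: np.ndarray  # '<U4' array over stimulus positions
    report_times: np.ndarray
    reported_positions: np.ndarray
    report_is_hit: np.ndarray
    jump_positions: np.ndarray
    jump_is_detected: np.ndarray

    @property
    def counts(self) -> dict[str, int]:
        return {
            lab: int(np.sum(self.labels == lab))
            for lab in (HIT, MISS, FALSE_ALARM, CORRECT_REJECTION)
        }


def classify_trials(
    reports: Sequence[tuple[int, int]],
    jump_positions: np.ndarray,
    n_stimuli: int,
    window: int = 5,
) -> TrialClassification:
    """Sort every stimulus position into hit/miss/false-alarm/rejection.

    Reports are matched one-to-one to generative jumps, greedily by
    |Z - jump| distance within the tolerance window.  A matched report's Z
    is a hit, an unmatched report's Z a false alarm; an unmatched jump's
    position is a miss and every remaining position a correct rejection.
    """
    jump_positions = np.asarray(jump_positions, dtype=np.int64)
    W = np.asarray([w for w, _ in reports], dtype=np.int64)
    Z = np.asarray([z for _, z in reports], dtype=np.int64)
    if np.any(Z < 1) or np.any(Z > n_stimuli):
        raise ValueError("reported positions fall outside the session")

    pairs = []
    for r, z in enumerate(Z):
        for j, g in enumerate(jump_positions):
            d = abs(int(z) - int(g))
            if d <= window:
                pairs.append((d, r, j))
    pairs.sort()
    report_matched = np.zeros(len(Z), dtype=bool)
    jump_matched = np.zeros(len(jump_positions), dtype=bool)
    for _, r, j in pairs:
        if not report_matched[r] and not jump_matched[j]:
            report_matched[r] = True
            jump_matched[j] = True

    labels = np.full(n_stimuli, CORRECT_REJECTION, dtype="<U4")
    for g in jump_positions[~jump_matched]:
        labels[g - 1] = MISS
    # report labels take precedence over misses; hits over false alarms
    # (two reports can share a position when patches flicker at threshold)
    for r, z in enumerate(Z):
        if not report_matched[r]:
            labels[z - 1] = FALSE_ALARM
    for r, z in enumerate(Z):
        if report_matched[r]:
            labels[z - 1] = HIT
    return TrialClassification(
        labels=labels,
        report_times=W,
        reported_positions=Z,
        report_is_hit=report_matched,
        jump_positions=jump_positions,
        jump_is_detected=jump_matched,
    )


def informedness(classification: TrialClassification) -> float:
    """Hit rate minus false-alarm rate, in [-1, 1]; 0 is chance level."""
    c = classification.counts
    n_pos = c[HIT] + c[MISS]
    n_neg = c[FALSE_ALARM] + c[CORRECT_REJECTION]
    if n_pos == 0 or n_neg == 0:
        raise ValueError("informedness undefined: empty outcome class")
    return c[HIT] / n_pos - c[FALSE_ALARM] / n_neg


def pooled_informedness(
    classifications: Sequence[TrialClassification],
) -> float:
    """Informedness from outcome counts pooled over a subject's blocks."""
    totals = {HIT: 0, MISS: 0, FALSE_ALARM: 0, CORRECT_REJECTION: 0}
    for tc in classifications:
        for lab, n in tc.counts.items():
            totals[lab] += n
    n_pos = totals[HIT] + totals[MISS]
    n_neg = totals[FALSE_ALARM] + totals[CORRECT_REJECTION]
    if n_pos == 0 or n_neg == 0:
        raise ValueError("informedness undefined: empty outcome class")
    return totals[HIT] / n_pos - totals[FALSE_ALARM] / n_neg


def group_informedness_t(values: np.ndarray) -> float:
    """One-sample t-value of per-subject informedness against zero."""
    values = np.asarray(values, dtype=float)
    return float(stats.ttest_1samp(values, 0.0).statistic)


def surrogate_null(
    reports_per_subject: Sequence[Sequence[Sequence[tuple[int, int]]]],
    params: GenerativeParams,
    n_surrogates: int,
    rng: np.random.Generator,
    window: int = 5,
) -> np.ndarray:
    """Null distribution of the group informedness t-value.

    ``reports_per_subject[s][b]`` holds the (W, Z) reports of subject s in
    block b.  Reports are held fixed while the hidden jump structure of
    every block is regenerated (new chunk lengths, hence new jump
    positions) for each surrogate, mimicking sequences the subjects never
    saw; informedness is pooled over blocks within subject.
    """
    null_t = np.empty(n_surrogates)
    for s in range(n_surrogates):
        vals = []
        for blocks in reports_per_subject:
            tcs = []
            for reports in blocks:
                lengths = sample_chunk_lengths(params, rng)
                jumps = np.cumsum(lengths[:-1]) + 1
                tcs.append(
                    classify_trials(
                        reports, np.asarray(jumps, dtype=np.int64),
                        params.session_length, window,
                    )
                )
            vals.append(pooled_informedness(tcs))
        null_t[s] = group_informedness_t(np.asarray(vals))
    return null_t


def permutation_p(null: np.ndarray, observed: float) -> float:
    """Upper-tail permutation p-value, never smaller than 1/(n+1)."""
    null = np.asarray(null, dtype=float)
    return float((1 + np.sum(null >= observed)) / (len(null) + 1))


def _nanmean_cols(arr: np.ndarray) -> np.ndarray:
    """Column nanmean that returns NaN (silently) for all-NaN columns."""
    arr = np.atleast_2d(arr)
    valid = np.isfinite(arr)
    n = valid.sum(axis=0)
    total = np.where(valid, arr, 0.0).sum(axis=0)
    return np.where(n > 0, total / np.maximum(n, 1), np.nan)


def sort_posterior_by_outcome(
    classification: TrialClassification,
    windowed_gamma: np.ndarray,
    latencies: Sequence[int],
    offsets: Sequence[int] = tuple(range(-10, 1)),
    fallback_latency: int = 10,
) -> dict[str, np.ndarray]:
    """Time-locked averages of the windowed jump posterior per outcome.

    Hits and false alarms are evaluated at the reported position given the
    stimuli observed at report time (horizon W); misses and correct
    rejections at the outcome position, averaging over the subject's
    typical report latencies (horizon = position + latency).  Returns one
    mean trace per category over the requested offsets (NaN where no trial
    contributes).
    """
    n = windowed_gamma.shape[0]
    lats = [int(l) for l in latencies]
    if not lats:
        logging.getLogger(__name__).info(
            "empty latency list: falling back to latency %d", fallback_latency
        )
        lats = [int(fallback_latency)]
    offsets = np.asarray(list(offsets), dtype=np.int64)
    traces: dict[str, list[np.ndarray]] = {
        HIT: [], MISS: [], FALSE_ALARM: [], CORRECT_REJECTION: []
    }

    def value(pos: int, horizon: int) -> float:
        horizon = min(horizon, n)
        if pos < 2 or pos > horizon:
            return np.nan
        return float(windowed_gamma[pos - 1, horizon - 1])

    for w, z, is_hit in zip(
        classification.report_times,
        classification.reported_positions,
        classification.report_is_hit,
    ):
        trace = np.array([value(int(z) + d, int(w)) for d in offsets])
        traces[HIT if is_hit else FALSE_ALARM].append(trace)
    for pos in np.flatnonzero(
        (classification.labels == MISS) | (classification.labels == CORRECT_REJECTION)
    ):
        k = int(pos) + 1
        cat = str(classification.labels[pos])
        per_lat = np.array(
            [[value(k + d, k + lat) for d in offsets] for lat in lats]
        )
        traces[cat].append(_nanmean_cols(per_lat))

    out: dict[str, np.ndarray] = {"offsets": offsets.astype(float)}
    for cat, rows in traces.items():
        if rows:
            out[cat] = _nanmean_cols(np.vstack(rows))
        else:
            out[cat] = np.full(len(offsets), np.nan)
    return out


def select_threshold(
    gammas: Sequence[np.ndarray],
    jump_positions: Sequence[np.ndarray],
    n_stimuli: int,
    window: int = 5,
    grid: Optional[np.ndarray] = None,
) -> float:
    """Grid-search the discretization threshold maximizing informedness.

    Mean informedness across sessions is evaluated on a threshold grid
    (default 0.01..0.99 step 0.01); ties break toward the larger threshold.
    """
    if grid is None:
        grid = np.round(np.arange(0.01, 1.0, 0.01), 2)
    best_thr, best_val = float(grid[-1]), -np.inf
    for thr in grid:
        vals = []
        for g, jp in zip(gammas, jump_positions):
            reports = discretize_jump_posterior(g, float(thr))
            try:
                vals.append(
                    informedness(
                        classify_trials(reports, jp, n_stimuli, window)
                    )
                )
            except ValueError:
                continue
        mean_val = float(np.mean(vals)) if vals else 0.0
        if mean_val >= best_val:  # >= implements the larger-threshold tie rule
            best_val, best_thr = mean_val, float(thr)
    return best_thr
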