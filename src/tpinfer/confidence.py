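"""Regression analyses linking responses to the ideal observer.

All group statistics follow the same two-level scheme: an ordinary least
squares fit per subject on a constant plus z-scored regressors, then a
two-tailed one-sample t-test of the per-subject coefficients against zero.
The module also builds the per-question regressor table (model revision,
log sample count, transition entropies, jump-location uncertainty), the
U-shape fit of confidence on (estimate - 0.5)^2, accuracy correlations
between subjects and the observer, and their permutation/shuffle and
reassignment nulls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

from .generative import Session
from .fb import PosteriorSummary

__all__ = [
    "GroupStat",
    "zscore",
    "subject_regression",
    "group_ttest",
    "ushape_fit",
    "binary_entropy",
    "build_regressors",
    "normalize_uncertainty",
    "confidence_factor_analysis",
    "affine_align",
    "accuracy_correlations",
    "shuffle_nulls",
    "error_confidence_controls",
]

FACTORS = ("model_revision", "log_sample_count", "entropy_relevant", "entropy_irrelevant")


@dataclass
class GroupStat:
    """Per-subject coefficients with their group-level t-test."""

    coefs: np.ndarray
    t: float
    p: float

    @property
    def df(self) -> int:
        return len(self.coefs) - 1


def zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant regressor")
    return (x - x.mean()) / sd


def subject_regression(
    response: np.ndarray, regressors: np.ndarray, names: Optional[Sequence[str]] = None
) -> np.ndarray:
    """OLS coefficients of response on a constant + z-scored regressors.

    Rows with any NaN (response or regressor) are dropped listwise.
    Returns the coefficient per regressor (the constant is not returned).
    """
    response = np.asarray(response, dtype=float)
    X = np.atleast_2d(np.asarray(regressors, dtype=float))
    if X.shape[0] != len(response):
        X = X.T
    keep = np.isfinite(response) & np.all(np.isfinite(X), axis=1)
    y, X = response[keep], X[keep]
    if len(y) < X.shape[1] + 2:
        raise ValueError("need at least 2 more trials than regressors")
    cols = []
    for j in range(X.shape[1]):
        try:
            cols.append(zscore(X[:, j]))
        except ValueError as err:
            name = names[j] if names else f"regressor {j}"
            raise ValueError(f"constant regressor: {name}") from err
    design = np.column_stack([np.ones(len(y))] + cols)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            "rank-deficient design (collinear regressors): "
            + ", ".join(names or [f"regressor {j}" for j in range(X.shape[1])])
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return beta[1:]


def group_ttest(coefs: np.ndarray) -> GroupStat:
    """Two-tailed one-sample t-test of per-subject coefficients vs zero."""
    coefs = np.asarray(coefs, dtype=float)
    res = stats.ttest_1samp(coefs, 0.0)
    return GroupStat(coefs=coefs, t=float(res.statistic), p=float(res.pvalue))


def ushape_fit(confidence: np.ndarray, estimates: np.ndarray) -> float:
    """Quadratic coefficient of confidence ~ (estimate - 0.5)^2."""
    estimates = np.asarray(estimates, dtype=float)
    if np.nanstd(estimates) == 0:
        raise ValueError("U-shape fit undefined: all estimates equal")
    quad = (estimates - 0.5) ** 2
    return float(subject_regression(confidence, quad[:, None], ["ushape"])[0])


def binary_entropy(p: np.ndarray) -> np.ndarray:
    """Shannon entropy of a Bernoulli(p), in nats."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -p * np.log(p) - (1 - p) * np.log(1 - p)
    return np.where((p <= 0) | (p >= 1), 0.0, h)


def build_regressors(
    session: Session,
    filtered: PosteriorSummary,
    reports: Sequence[tuple[int, int]],
    chunk_length_mean: Optional[np.ndarray] = None,
    chunk_length_var: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Per-question regressor table for the confidence analyses.

    ``filtered`` must cover every stimulus position (the observer's on-line
    series).  The queried transition at each question is the one departing
    from the last stimulus seen.  Per trial the table holds the observer's
    queried-probability mean and log-precision confidence, the generative
    probability, the model revision (|delta mu| between the two most recent
    observations of the queried transition type), the log count of queried
    transitions since the observer's last detected jump, the generative
    entropies of the relevant and irrelevant transitions, and (optionally)
    the posterior chunk-length variance used for jump-location uncertainty.
    """
    y = session.stimuli
    q = session.question_positions
    if len(filtered.times) != session.n_stimuli or filtered.times[0] != 1:
        raise ValueError("filtered series must cover every stimulus position")

    mean_ab = filtered.mean_A_given_B
    mean_ba = filtered.mean_B_given_A
    var_ab, var_ba = filtered.var_A_given_B, filtered.var_B_given_A

    rows = []
    detections = sorted(reports)  # (W, Z), sorted by report time
    for ordinal, t in enumerate(q):
        t = int(t)
        s = int(y[t - 1])  # symbol preceding the question
        # positions j (2..t) where a transition from s was observed
        obs = np.flatnonzero(y[: t - 1] == s) + 2
        mu_series = mean_ba if s == 1 else mean_ab
        var_series = var_ba if s == 1 else var_ab
        prob_next_a = (1.0 - mean_ba[t - 1]) if s == 1 else mean_ab[t - 1]
        if len(obs) >= 2:
            revision = abs(mu_series[obs[-1] - 1] - mu_series[obs[-2] - 1])
        else:
            revision = np.nan
        # last jump detected on-line by time t, located at Z
        z_last = 1
        for w, z in detections:
            if w <= t and z > z_last:
                z_last = z
        n_samples = int(np.sum(obs > z_last)) if z_last > 1 else len(obs)
        th_ab, th_ba = session.theta_at(t)
        th_relevant = th_ba if s == 1 else th_ab
        th_irrelevant = th_ab if s == 1 else th_ba
        gen_prob_next_a = (1.0 - th_ba) if s == 1 else th_ab
        rows.append(
            {
                "question_position": t,
                "ordinal": ordinal,
                "io_mean": prob_next_a,
                "io_confidence": -np.log(var_series[t - 1]),
                "generative_prob_next_A": gen_prob_next_a,
                "model_revision": revision,
                "sample_count": n_samples,
                "log_sample_count": np.log(n_samples) if n_samples >= 1 else np.nan,
                "entropy_relevant": float(binary_entropy(th_relevant)),
                "entropy_irrelevant": float(binary_entropy(th_irrelevant)),
            }
        )
    table = pd.DataFrame(rows)
    n_undefined = int(table["model_revision"].isna().sum()) + int(
        table["log_sample_count"].isna().sum()
    )
    if n_undefined:
        logger.info(
            "%d question trial(s) have undefined regressors and will be "
            "dropped listwise in regressions",
            n_undefined,
        )
    if chunk_length_var is not None:
        table["chunk_length_var"] = np.asarray(chunk_length_var, dtype=float)
        if chunk_length_mean is not None:
            table["chunk_length_mean"] = np.asarray(chunk_length_mean, dtype=float)
    return table


def normalize_uncertainty(tables: Sequence[pd.DataFrame]) -> None:
    """Add a jump_location_uncertainty column, in place, to every table.

    The per-trial measure is the posterior chunk-length variance relative
    to the posterior chunk-length mean (variance alone is confounded by
    chunk length: a long, confidently delimited chunk has a large raw
    variance simply because lengths are large).  The ratio is then
    normalized by its mean over matched question ordinals pooled across
    all given sessions, so values above 1 mark trials where the last
    jump's location was less clear than is typical at that point of a
    session.
    """
    for t in tables:
        t["_rel_var"] = t["chunk_length_var"] / t["chunk_length_mean"]
    pooled = pd.concat(
        [t[["ordinal", "_rel_var"]] for t in tables], ignore_index=True
    )
    mean_by_ordinal = pooled.groupby("ordinal")["_rel_var"].mean()
    for t in tables:
        denom = t["ordinal"].map(mean_by_ordinal)
        t["jump_location_uncertainty"] = t["_rel_var"] / denom
        t.drop(columns="_rel_var", inplace=True)


def confidence_factor_analysis(
    responses: Sequence[np.ndarray], tables: Sequence[pd.DataFrame]
) -> dict[str, GroupStat]:
    """Single-factor, four-factor and residual regressions of confidence.

    ``responses`` holds one confidence-rating vector per subject, aligned
    with that subject's regressor table.  Returns group statistics for each
    single-factor regression, for every factor in the four-factor multiple
    regression (keys ``multi_<factor>``), and for the regression of the
    four-factor residuals on the observer's log-precision (``residual_io``).
    """
    single = {f: [] for f in FACTORS + ("jump_location_uncertainty",)}
    multi = {f: [] for f in FACTORS}
    residual = []
    for conf, table in zip(responses, tables):
        conf = np.asarray(conf, dtype=float)
        for f in single:
            if f in table:
                single[f].append(
                    subject_regression(conf, table[f].to_numpy()[:, None], [f])[0]
                )
        X = table[list(FACTORS)].to_numpy()
        coefs = subject_regression(conf, X, list(FACTORS))
        for f, c in zip(FACTORS, coefs):
            multi[f].append(c)
        keep = np.isfinite(conf) & np.all(np.isfinite(X), axis=1)
        Xk = np.column_stack(
            [np.ones(keep.sum())] + [zscore(X[keep, j]) for j in range(X.shape[1])]
        )
        beta, *_ = np.linalg.lstsq(Xk, conf[keep], rcond=None)
        resid = conf[keep] - Xk @ beta
        io_conf = table["io_confidence"].to_numpy()[keep]
        residual.append(
            subject_regression(resid, io_conf[:, None], ["io_confidence"])[0]
        )
    out = {f: group_ttest(np.asarray(v)) for f, v in single.items() if v}
    out.update({f"multi_{f}": group_ttest(np.asarray(v)) for f, v in multi.items()})
    out["residual_io"] = group_ttest(np.asarray(residual))
    return out


def affine_align(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares affine map of ``x`` onto the scale of ``target``."""
    x = np.asarray(x, dtype=float)
    target = np.asarray(target, dtype=float)
    keep = np.isfinite(x) & np.isfinite(target)
    if x[keep].std() == 0:
        return np.full_like(x, target[keep].mean())
    b, a = np.polyfit(x[keep], target[keep], 1)
    return a + b * x


@dataclass
class AccuracyCorrelations:
    estimate_accuracy: np.ndarray  # per subject
    confidence_accuracy: np.ndarray
    between_r: float
    between_p: float
    within_r: np.ndarray  # per-subject trialwise error correlation
    within_group: GroupStat
    estimate_errors: list[np.ndarray]
    confidence_errors: list[np.ndarray]


def accuracy_correlations(
    subject_estimates: Sequence[np.ndarray],
    subject_confidence: Sequence[np.ndarray],
    io_estimates: Sequence[np.ndarray],
    io_confidence: Sequence[np.ndarray],
) -> AccuracyCorrelations:
    """Between- and within-subject links of estimation/confidence accuracy.

    Per subject, accuracy of estimates (resp. confidence) is the Pearson
    correlation across trials of the subject's and the observer's series;
    the two accuracies are then correlated across subjects.  At the trial
    level, accuracy is the unsigned error between the subject's and the
    observer's value (confidence compared after affine alignment of the
    subject's ratings onto the observer's log-precision scale); the two
    error series are correlated across trials within each subject.
    """
    est_acc, conf_acc, within, est_err, conf_err = [], [], [], [], []
    for se, sc, oe, oc in zip(
        subject_estimates, subject_confidence, io_estimates, io_confidence
    ):
        se, sc = np.asarray(se, float), np.asarray(sc, float)
        oe, oc = np.asarray(oe, float), np.asarray(oc, float)
        keep = np.isfinite(se) & np.isfinite(sc) & np.isfinite(oe) & np.isfinite(oc)
        if keep.sum() < 3:
            logger.info("subject excluded: fewer than 3 valid trials")
            continue
        se, sc, oe, oc = se[keep], sc[keep], oe[keep], oc[keep]
        est_acc.append(stats.pearsonr(se, oe).statistic)
        conf_acc.append(stats.pearsonr(sc, oc).statistic)
        ee = np.abs(se - oe)
        ce = np.abs(affine_align(sc, oc) - oc)
        est_err.append(ee)
        conf_err.append(ce)
        if ee.std() == 0 or ce.std() == 0:
            within.append(np.nan)
        else:
            within.append(stats.pearsonr(ee, ce).statistic)
    est_acc, conf_acc = np.asarray(est_acc), np.asarray(conf_acc)
    br = stats.pearsonr(est_acc, conf_acc)
    within = np.asarray(within)
    return AccuracyCorrelations(
        estimate_accuracy=est_acc,
        confidence_accuracy=conf_acc,
        between_r=float(br.statistic),
        between_p=float(br.pvalue),
        within_r=within,
        within_group=group_ttest(within[np.isfinite(within)]),
        estimate_errors=est_err,
        confidence_errors=conf_err,
    )


def _within_corr(se, sc, oe, oc) -> float:
    ee = np.abs(se - oe)
    ce = np.abs(sc - oc)
    if ee.std() == 0 or ce.std() == 0:
        return np.nan
    return float(stats.pearsonr(ee, ce).statistic)


def shuffle_nulls(
    subject_estimates: Sequence[np.ndarray],
    subject_confidence_aligned: Sequence[np.ndarray],
    io_estimates: Sequence[np.ndarray],
    io_confidence: Sequence[np.ndarray],
    n_perm: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, object]:
    """Two shuffle nulls for the within-subject accuracy correlation.

    Shuffle #1 keeps (estimate, confidence) pairs intact but permutes their
    trial order, separately for the subject's and the observer's series,
    destroying trial-specific information while preserving any
    estimate-to-confidence mapping.  Shuffle #2 additionally breaks the
    mapping by permuting the subject's estimates and confidence ratings
    independently.  Subject confidence must already be affine-aligned to
    the observer's scale.  Returns both null distributions of the group
    t-value, their permutation p-values for the observed statistic, and a
    classical one-tailed t-test of the observed correlations against zero
    (the parametric equivalent of shuffle #2).
    """
    if rng is None:
        rng = np.random.default_rng()
    series = [
        (np.asarray(a, float), np.asarray(b, float), np.asarray(c, float),
         np.asarray(d, float))
        for a, b, c, d in zip(
            subject_estimates, subject_confidence_aligned, io_estimates, io_confidence
        )
    ]
    observed = np.array([_within_corr(*s) for s in series])
    obs_t = group_ttest(observed[np.isfinite(observed)]).t
    null1 = np.empty(n_perm)
    null2 = np.empty(n_perm)
    for m in range(n_perm):
        v1, v2 = [], []
        for se, sc, oe, oc in series:
            n = len(se)
            ps, po = rng.permutation(n), rng.permutation(n)
            v1.append(_within_corr(se[ps], sc[ps], oe[po], oc[po]))
            p1, p2 = rng.permutation(n), rng.permutation(n)
            v2.append(_within_corr(se[p1], sc[p2], oe, oc))
        v1, v2 = np.asarray(v1), np.asarray(v2)
        null1[m] = group_ttest(v1[np.isfinite(v1)]).t
        null2[m] = group_ttest(v2[np.isfinite(v2)]).t
    p1 = float((1 + np.sum(null1 >= obs_t)) / (n_perm + 1))
    p2 = float((1 + np.sum(null2 >= obs_t)) / (n_perm + 1))
    finite = observed[np.isfinite(observed)]
    t_res = stats.ttest_1samp(finite, 0.0, alternative="greater")
    return {
        "observed_r": observed,
        "observed_t": obs_t,
        "null1_t": null1,
        "null2_t": null2,
        "p_vs_shuffle1": p1,
        "p_vs_shuffle2": p2,
        "classical_one_tailed_p": float(t_res.pvalue),
    }


def error_confidence_controls(
    estimates: Sequence[np.ndarray],
    confidence: Sequence[np.ndarray],
    generative: Sequence[np.ndarray],
    n_sim: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, object]:
    """Confidence-predicts-error statistic against three reassignment nulls.

    The observed statistic is the group t-value of the per-subject
    correlation between confidence and the unsigned error
    |estimate - generative probability| (expected negative).  Each control
    shuffles exactly one of the three variables across trials (within
    subject) and rebuilds the null distribution of the group t-value;
    one-sided p-values ask how often the null is at least as negative.
    """
    if rng is None:
        rng = np.random.default_rng()
    data = [
        (np.asarray(e, float), np.asarray(c, float), np.asarray(g, float))
        for e, c, g in zip(estimates, confidence, generative)
    ]

    def corr(e, c, g):
        err = np.abs(e - g)
        if err.std() == 0 or c.std() == 0:
            return np.nan
        return float(stats.pearsonr(c, err).statistic)

    observed = np.array([corr(*d) for d in data])
    obs_t = group_ttest(observed[np.isfinite(observed)]).t
    nulls = {}
    pvals = {}
    for which, name in ((0, "estimates"), (1, "confidence"), (2, "generative")):
        null = np.empty(n_sim)
        for m in range(n_sim):
            vals = []
            for d in data:
                parts = [x.copy() for x in d]
                parts[which] = parts[which][rng.permutation(len(parts[which]))]
                vals.append(corr(*parts))
            vals = np.asarray(vals)
            null[m] = group_ttest(vals[np.isfinite(vals)]).t
        nulls[name] = null
        pvals[name] = float((1 + np.sum(null <= obs_t)) / (n_sim + 1))
    return {
        "observed_r": observed,
        "observed_t": obs_t,
        "nulls": nulls,
        "p_values": pvals,
    }
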