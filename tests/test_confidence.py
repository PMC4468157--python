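"""Regression harness, regressor construction, and shuffle controls."""

import numpy as np
import pandas as pd
import pytest

from tpinfer.confidence import (
    accuracy_correlations,
    affine_align,
    binary_entropy,
    build_regressors,
    error_confidence_controls,
    group_ttest,
    normalize_uncertainty,
    shuffle_nulls,
    subject_regression,
    ushape_fit,
    zscore,
)
from tpinfer.fb import PosteriorSummary
from tpinfer.generative import Session


class TestSubjectRegression:
    def test_recovers_unit_coefficient(self, rng):
        x = rng.normal(size=100)
        y = zscore(x)
        coef = subject_regression(y, x[:, None], ["x"])
        assert coef[0] == pytest.approx(1.0)

    def test_constant_regressor_named_in_error(self, rng):
        y = rng.normal(size=50)
        X = np.column_stack([rng.normal(size=50), np.ones(50)])
        with pytest.raises(ValueError, match="badcol"):
            subject_regression(y, X, ["good", "badcol"])

    def test_collinear_design_rejected(self, rng):
        x = rng.normal(size=60)
        X = np.column_stack([x, 2 * x + 1])
        with pytest.raises(ValueError, match="collinear"):
            subject_regression(rng.normal(size=60), X, ["a", "b"])

    def test_nan_rows_dropped_listwise(self, rng):
        x = rng.normal(size=80)
        y = 2 * zscore(x)
        x2 = x.copy()
        x2[:5] = np.nan
        coef = subject_regression(y, x2[:, None], ["x"])
        assert coef[0] == pytest.approx(
            2 * np.std(x) / np.std(x[5:]) * np.corrcoef(y[5:], x[5:])[0, 1],
            rel=0.05,
        )

    def test_null_group_t_is_small(self, rng):
        coefs = [
            subject_regression(
                rng.normal(size=60), rng.normal(size=(60, 2)), ["a", "b"]
            )
            for _ in range(40)
        ]
        stat = group_ttest(np.array(coefs)[:, 0])
        assert abs(stat.t) < 3
        assert stat.df == 39


class TestUShape:
    def test_exact_quadratic_recovered(self, rng):
        est = rng.random(200)
        conf = (est - 0.5) ** 2
        assert ushape_fit(conf, est) > 0
        assert ushape_fit(conf, est) == pytest.approx(np.std(conf))

    def test_constant_confidence_zero_weight(self, rng):
        est = rng.random(100)
        assert ushape_fit(np.ones(100), est) == pytest.approx(0.0, abs=1e-10)

    def test_constant_estimates_signalled(self):
        with pytest.raises(ValueError):
            ushape_fit(np.arange(10.0), np.full(10, 0.5))


def _toy_session_and_series(y, questions, thetas=(0.7, 0.3)):
    y = np.asarray(y, dtype=np.int64)
    session = Session(
        stimuli=y,
        jump_positions=np.array([], dtype=np.int64),
        chunk_thetas=np.array([thetas]),
        question_positions=np.asarray(questions, dtype=np.int64),
    )
    n = len(y)
    series = PosteriorSummary(
        times=np.arange(1, n + 1),
        mean_A_given_B=np.linspace(0.5, 0.7, n),
        var_A_given_B=np.linspace(0.08, 0.02, n),
        mean_B_given_A=np.linspace(0.5, 0.3, n),
        var_B_given_A=np.linspace(0.08, 0.03, n),
    )
    return session, series


class TestBuildRegressors:
    def test_revision_uses_consecutive_same_transitions(self):
        # A B B B B A A: from-A transitions observed at positions 2 and 7
        session, series = _toy_session_and_series(
            [1, 0, 0, 0, 0, 1, 1], questions=[7]
        )
        table = build_regressors(session, series, reports=[])
        mu = series.mean_B_given_A
        assert table.loc[0, "model_revision"] == pytest.approx(
            abs(mu[7 - 1] - mu[2 - 1])
        )
        assert table.loc[0, "sample_count"] == 2

    def test_maximal_entropy_at_half(self):
        session, series = _toy_session_and_series(
            [0, 1, 0, 1], questions=[4], thetas=(0.5, 0.2)
        )
        table = build_regressors(session, series, reports=[])
        # question follows an A: relevant transition is from A (theta 0.2),
        # irrelevant is from B (theta 0.5, maximal entropy)
        assert table.loc[0, "entropy_irrelevant"] == pytest.approx(np.log(2))
        assert table.loc[0, "entropy_relevant"] == pytest.approx(
            float(binary_entropy(0.2))
        )

    def test_sample_counts_increase_without_detections(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 120)
        session, series = _toy_session_and_series(y, questions=[30, 60, 90, 120])
        table = build_regressors(session, series, reports=[])
        # pooled over both transition types the counts cannot decrease
        assert table["log_sample_count"].is_monotonic_increasing

    def test_detection_resets_sample_count(self):
        y = np.tile([0, 1], 30)
        session, series = _toy_session_and_series(y, questions=[40])
        no_reset = build_regressors(session, series, reports=[])
        with_reset = build_regressors(session, series, reports=[(35, 30)])
        assert with_reset.loc[0, "sample_count"] < no_reset.loc[0, "sample_count"]

    def test_queried_probability_follows_previous_stimulus(self):
        y = [0, 1, 1, 0, 0, 1]
        session, series = _toy_session_and_series(y, questions=[3, 4])
        table = build_regressors(session, series, reports=[])
        # question at 3 follows an A: p(next A) = 1 - mean_B_given_A
        assert table.loc[0, "io_mean"] == pytest.approx(
            1 - series.mean_B_given_A[2]
        )
        # question at 4 follows a B: p(next A) = mean_A_given_B
        assert table.loc[1, "io_mean"] == pytest.approx(
            series.mean_A_given_B[3]
        )


class TestNormalization:
    def test_uncertainty_normalized_to_unit_mean_per_ordinal(self, rng):
        tables = []
        for _ in range(6):
            tables.append(
                pd.DataFrame(
                    {
                        "ordinal": np.arange(10),
                        "chunk_length_var": rng.random(10) + 0.2,
                        "chunk_length_mean": rng.random(10) * 30 + 5,
                    }
                )
            )
        normalize_uncertainty(tables)
        pooled = pd.concat(tables)
        means = pooled.groupby("ordinal")["jump_location_uncertainty"].mean()
        assert np.allclose(means.to_numpy(), 1.0)
        assert (pooled["jump_location_uncertainty"] > 0).all()


class TestAccuracy:
    def test_affine_align_idempotent(self, rng):
        x = rng.normal(size=50)
        target = 3 * x - 1 + rng.normal(scale=0.1, size=50)
        once = affine_align(x, target)
        twice = affine_align(once, target)
        assert np.allclose(once, twice)

    def test_identical_responses_perfect_accuracy(self, rng):
        est = [rng.random(30) for _ in range(5)]
        conf = [rng.random(30) * 4 + 1 for _ in range(5)]
        out = accuracy_correlations(est, conf, est, conf)
        assert np.allclose(out.estimate_accuracy, 1.0)
        assert np.allclose(out.confidence_accuracy, 1.0)
        # zero errors: trialwise correlation undefined -> NaN signalled
        assert np.all(np.isnan(out.within_r))

    def test_shared_precision_couples_accuracies(self, rng):
        io_est = [rng.random(120) for _ in range(16)]
        io_conf = [rng.random(120) * 4 for _ in range(16)]
        noise = np.linspace(0.02, 0.6, 16)  # one shared precision per subject
        sub_est = [e + rng.normal(0, s, 120) for e, s in zip(io_est, noise)]
        sub_conf = [c + rng.normal(0, 8 * s, 120) for c, s in zip(io_conf, noise)]
        out = accuracy_correlations(sub_est, sub_conf, io_est, io_conf)
        assert out.between_r > 0.5
        assert out.between_p < 0.01

    def test_independent_noise_decouples_accuracies(self, rng):
        io_est = [rng.random(60) for _ in range(14)]
        io_conf = [rng.random(60) * 4 for _ in range(14)]
        sub_est = [e + rng.normal(0, 0.2, 60) for e in io_est]
        sub_conf = [c + rng.normal(0, 0.8, 60) for c in io_conf]
        out = accuracy_correlations(sub_est, sub_conf, io_est, io_conf)
        assert abs(out.between_r) < 0.75  # no systematic coupling


class TestShuffleNulls:
    def _data(self, rng, n_sub=8, n_tr=40):
        io_est = [rng.random(n_tr) for _ in range(n_sub)]
        io_conf = [rng.random(n_tr) * 3 for _ in range(n_sub)]
        sub_est = [e + rng.normal(0, 0.1, n_tr) for e in io_est]
        sub_conf = [c + rng.normal(0, 0.3, n_tr) for c in io_conf]
        return sub_est, sub_conf, io_est, io_conf

    def test_null_sizes_and_determinism(self, rng):
        data = self._data(rng)
        out1 = shuffle_nulls(*data, n_perm=50, rng=np.random.default_rng(0))
        out2 = shuffle_nulls(*data, n_perm=50, rng=np.random.default_rng(0))
        assert len(out1["null1_t"]) == 50 and len(out1["null2_t"]) == 50
        assert np.array_equal(out1["null1_t"], out2["null1_t"])
        for key in ("p_vs_shuffle1", "p_vs_shuffle2"):
            assert 1 / 51 <= out1[key] <= 1.0
            assert out1[key] == out2[key]


class TestReassignmentControls:
    def test_perfect_error_tracking_rejects_all_controls(self, rng):
        est = [rng.random(60) for _ in range(10)]
        gen = [rng.random(60) for _ in range(10)]
        conf = [-np.abs(e - g) for e, g in zip(est, gen)]
        out = error_confidence_controls(
            est, conf, gen, n_sim=99, rng=np.random.default_rng(1)
        )
        assert np.allclose(out["observed_r"], -1.0)
        assert all(p <= 0.05 for p in out["p_values"].values())

    def test_independent_variables_stay_inside_nulls(self, rng):
        est = [rng.random(60) for _ in range(10)]
        gen = [rng.random(60) for _ in range(10)]
        conf = [rng.random(60) for _ in range(10)]
        out = error_confidence_controls(
            est, conf, gen, n_sim=99, rng=np.random.default_rng(2)
        )
        assert all(p > 0.05 for p in out["p_values"].values())
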