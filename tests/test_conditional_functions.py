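"""Quantile binning, CAF/CIAF construction, rates, CIs, Bayes factors."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emgchrono import (
    ValidationError,
    bic_bayes_factor,
    caf,
    ciaf,
    correction_likelihood,
    model_ready_table,
    morey_ci,
    partial_error_rate,
    quantile_partition,
    summarize,
)


def make_trials(rts, correct, trial_class=None, partial_latencies=None,
                participant="p01", sat="neutral", lexicality="word"):
    n = len(rts)
    if trial_class is None:
        trial_class = ["pure_correct" if c else "overt_error" for c in correct]
    return pd.DataFrame({
        "participant": [participant] * n,
        "trial": np.arange(1, n + 1),
        "sat": [sat] * n,
        "lexicality": [lexicality] * n,
        "correct": list(correct),
        "rt_ms": list(rts),
        "trial_class": list(trial_class),
        "partial_latencies": partial_latencies or [""] * n,
    })


class TestQuantilePartition:
    def test_ten_latencies_five_bins(self):
        bins = quantile_partition(np.arange(1, 11), 5)
        np.testing.assert_array_equal(bins, [1, 1, 2, 2, 3, 3, 4, 4, 5, 5])

    def test_unsorted_input_binned_by_rank(self):
        bins = quantile_partition([30, 10, 20, 50, 40], 5)
        np.testing.assert_array_equal(bins, [3, 1, 2, 5, 4])

    def test_ties_stable_and_balanced(self):
        bins = quantile_partition(np.zeros(10), 5)
        np.testing.assert_array_equal(bins, [1, 1, 2, 2, 3, 3, 4, 4, 5, 5])

    def test_one_trial_per_bin(self):
        np.testing.assert_array_equal(quantile_partition([5, 1, 3, 2, 4], 5),
                                      [5, 1, 3, 2, 4])

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValidationError):
            quantile_partition([1, 2, 3], 5)

    def test_invariant_to_monotone_transform(self, rng):
        lat = rng.uniform(300, 900, 40)
        np.testing.assert_array_equal(quantile_partition(lat, 5),
                                      quantile_partition(np.log(lat), 5))


class TestCaf:
    def test_all_correct_cell_is_flat_one(self):
        df = caf(make_trials(np.arange(400, 410), [True] * 10), 5)
        np.testing.assert_array_equal(df["proportion"], np.ones(5))
        np.testing.assert_array_equal(df["n_trials"], np.full(5, 2))

    def test_errors_on_two_fastest_land_in_bin_one(self):
        correct = [False, False] + [True] * 8
        df = caf(make_trials(np.arange(400, 410), correct), 5)
        np.testing.assert_array_equal(df["proportion"], [0, 1, 1, 1, 1])

    def test_mean_latency_per_bin(self):
        df = caf(make_trials(np.arange(400, 410), [True] * 10), 5)
        np.testing.assert_allclose(df["mean_latency_ms"],
                                   [400.5, 402.5, 404.5, 406.5, 408.5])

    def test_small_cell_skipped(self):
        df = caf(make_trials([400, 410, 420], [True] * 3), 5)
        assert len(df) == 0

    def test_bin_counts_sum_to_cell_count(self, rng):
        df = caf(make_trials(rng.uniform(300, 900, 23), [True] * 23), 5)
        assert df["n_trials"].sum() == 23
        # pooled proportion equals the unbinned rate
        pooled = (df["proportion"] * df["n_trials"]).sum() / 23
        assert pooled == pytest.approx(1.0)


class TestCiaf:
    def test_no_incorrect_activations_flat_zero(self):
        df = ciaf(make_trials(np.arange(400, 410), [True] * 10), 5)
        np.testing.assert_array_equal(df["proportion"], np.zeros(5))

    def test_partials_with_smallest_latencies_fill_bin_one(self):
        """8 correct trials (RT 500..570) plus 2 partial errors whose covert
        latencies (200, 210 ms) are the two smallest pooled events: bin 1
        holds exactly those two flagged events."""
        trials = make_trials(
            np.arange(500, 580, 10), [True] * 8,
            trial_class=["partial_error_trial"] * 2 + ["pure_correct"] * 6,
            partial_latencies=["200.0", "210.0"] + [""] * 6)
        df = ciaf(trials, 5)
        np.testing.assert_array_equal(df["proportion"], [1, 0, 0, 0, 0])
        assert df["n_trials"].sum() == 10  # 8 presses + 2 partial events

    def test_ciaf_at_least_caf_error_rate(self, rng):
        n = 40
        correct = rng.random(n) > 0.2
        tc = np.where(correct, "pure_correct", "overt_error").astype(object)
        pl = [""] * n
        for i in range(0, 6):  # some corrected impulses on correct trials
            if correct[i]:
                tc[i] = "partial_error_trial"
                pl[i] = f"{rng.uniform(200, 400):.1f}"
        trials = make_trials(rng.uniform(400, 900, n), correct, list(tc), pl)
        caf_err = 1 - (caf(trials, 5)["proportion"] * caf(trials, 5)["n_trials"]
                       ).sum() / n
        cf = ciaf(trials, 5)
        ciaf_rate = (cf["proportion"] * cf["n_trials"]).sum() / cf["n_trials"].sum()
        assert ciaf_rate >= caf_err - 1e-12


class TestRates:
    def test_correction_likelihood_six_of_eight(self):
        tc = ["partial_error_trial"] * 6 + ["overt_error"] * 2
        trials = make_trials(np.arange(400, 480, 10),
                             [True] * 6 + [False] * 2, tc)
        assert correction_likelihood(trials) == pytest.approx(0.75)

    def test_correction_likelihood_all_corrected(self):
        trials = make_trials([400, 500], [True, True],
                             ["partial_error_trial", "pure_correct"])
        assert correction_likelihood(trials) == 1.0

    def test_correction_likelihood_undefined_without_incorrect_activity(self):
        trials = make_trials([400, 500], [True, True])
        assert np.isnan(correction_likelihood(trials))

    def test_partial_error_rate_five_percent(self):
        tc = ["partial_error_trial"] * 5 + ["pure_correct"] * 95
        trials = make_trials(np.linspace(400, 900, 100), [True] * 100, tc)
        assert partial_error_rate(trials) == pytest.approx(0.05)

    def test_partial_error_rate_zero(self):
        trials = make_trials([400, 500], [True, True])
        assert partial_error_rate(trials) == 0.0

    def test_rates_match_brute_force_recount(self, rng):
        classes = rng.choice(
            ["pure_correct", "partial_error_trial", "overt_error",
             "partial_correct_trial", "no_response"], size=50,
            p=[0.6, 0.1, 0.1, 0.05, 0.15])
        correct = [c in ("pure_correct", "partial_error_trial")
                   for c in classes]
        rts = [np.nan if c == "no_response" else r
               for c, r in zip(classes, rng.uniform(300, 900, 50))]
        trials = make_trials(rts, correct, list(classes))
        n_pe = sum(c == "partial_error_trial" for c in classes)
        n_pc = sum(c == "pure_correct" for c in classes)
        n_err = sum(c in ("overt_error", "partial_correct_trial")
                    for c in classes)
        assert partial_error_rate(trials) == pytest.approx(n_pe / (n_pe + n_pc))
        assert correction_likelihood(trials) == pytest.approx(
            n_pe / (n_pe + n_err))
        summary = summarize(trials)
        assert summary["n"].iloc[0] == 50


class TestMoreyCI:
    @staticmethod
    def brute_force(X, coverage=0.95):
        """Independent two-step implementation."""
        X = np.asarray(X, float)
        n, j = X.shape
        grand = X.mean()
        norm = np.empty_like(X)
        for i in range(n):
            for k in range(j):
                norm[i, k] = X[i, k] - X[i].mean() + grand
        half = []
        for k in range(j):
            se = norm[:, k].std(ddof=1) / np.sqrt(n)
            se *= np.sqrt(j / (j - 1))
            half.append(stats.t.ppf(0.5 + coverage / 2, n - 1) * se)
        return np.array(half)

    def test_identical_profiles_have_zero_width(self):
        base = np.array([500.0, 600.0, 700.0])
        X = pd.DataFrame([base, base + 50.0, base - 30.0],
                         columns=["neutral", "accuracy", "speed"])
        np.testing.assert_allclose(morey_ci(X), 0.0, atol=1e-9)

    def test_two_condition_correction_factor_sqrt2(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 2)), columns=["a", "b"])
        norm = X.to_numpy() - X.to_numpy().mean(axis=1, keepdims=True) \
            + X.to_numpy().mean()
        se = norm.std(axis=0, ddof=1) / np.sqrt(12)
        expected = stats.t.ppf(0.975, 11) * se * np.sqrt(2.0)
        np.testing.assert_allclose(morey_ci(X).to_numpy(), expected)

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(5):
            X = pd.DataFrame(rng.normal(600, 80, size=(10, 3)),
                             columns=["neutral", "accuracy", "speed"])
            np.testing.assert_allclose(morey_ci(X).to_numpy(),
                                       self.brute_force(X.to_numpy()))

    def test_single_condition_rejected(self, rng):
        with pytest.raises(ValidationError):
            morey_ci(pd.DataFrame(rng.normal(size=(5, 1)), columns=["a"]))

    def test_missing_cells_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 3)))
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValidationError):
            morey_ci(X)


class TestBayesFactor:
    def test_equal_bics_give_unity(self):
        assert bic_bayes_factor(100.0, 100.0) == 1.0

    def test_delta_two_gives_e(self):
        # model a worse by 2 BIC points -> BF e^{-1}... model b better
        assert bic_bayes_factor(102.0, 100.0) == pytest.approx(np.exp(-1.0))
        assert bic_bayes_factor(100.0, 102.0) == pytest.approx(np.e)

    def test_reported_interaction_test_value(self):
        """BIC(additive) lower by 15.28 points: evidence for the interaction
        model over the additive one is about 0.00048."""
        delta = 2.0 * np.log(0.00048)
        bf = bic_bayes_factor(100.0 - delta, 100.0)
        assert bf == pytest.approx(0.00048, rel=1e-9)
        assert bf < 1  # favours model b (additive)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            bic_bayes_factor(np.inf, 0.0)


class TestModelReadyTable:
    def test_orthogonal_polynomial_columns(self):
        df = caf(make_trials(np.arange(400, 420), [True] * 20), 5)
        out = model_ready_table(df)
        np.testing.assert_allclose(out["quantile_c"],
                                   out["quantile"] - 3.0)
        p1 = out["quantile_poly1"].to_numpy()
        p2 = out["quantile_poly2"].to_numpy()
        # orthonormal over the 5 distinct quantile levels
        assert np.dot(p1, p2) == pytest.approx(0.0, abs=1e-12)
        assert np.dot(p1, p1) == pytest.approx(1.0)
        assert np.sum(p1) == pytest.approx(0.0, abs=1e-12)
        # linear contrast increases with quantile
        assert np.all(np.diff(p1) > 0)
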