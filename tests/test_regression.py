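"""The three-parameter model: fitting, prediction, evaluation protocol and
difficulty classification."""

import numpy as np
import pandas as pd
import pytest

from chromablind import regression
from chromablind.exceptions import (
    DegenerateClassError,
    InsufficientDataError,
    SingularFitError,
)
from chromablind.regression import DetectionTimeModel, ModelParams


def feature_matrix(rng, n=200):
    return np.column_stack([
        rng.uniform(1.2, 22.0, n),     # f_cm
        rng.uniform(0.0, 0.1, n),      # f_si
        rng.uniform(1.0, 3721.0, n),   # f_ue
    ])


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------

def test_fit_recovers_exact_linear_targets(rng):
    X = feature_matrix(rng, 50)
    y = X @ np.array([2.0, 3.0, 0.01])
    res = DetectionTimeModel(X, y).fit()
    assert np.allclose(res.params.as_array(), [2.0, 3.0, 0.01], atol=1e-8)
    assert res.params.intercept is None


def test_fit_zero_targets_give_zero_coefficients(rng):
    X = feature_matrix(rng, 20)
    res = DetectionTimeModel(X, np.zeros(20)).fit()
    assert np.allclose(res.params.as_array(), 0.0, atol=1e-12)


def test_fit_noisy_recovery_within_three_standard_errors():
    rng = np.random.default_rng(11)
    X = feature_matrix(rng, 200)
    b = np.array([2.0, 30.0, 0.008])
    y = X @ b + rng.normal(0, 5, 200)
    res = DetectionTimeModel(X, y).fit()
    z = (res.params.as_array() - b) / res.bse
    assert np.all(np.abs(z) < 3)


def test_fit_names_collinear_columns(rng):
    X = feature_matrix(rng, 30)
    X[:, 2] = 2.5 * X[:, 0]  # f_ue degenerate with f_cm
    with pytest.raises(SingularFitError, match="collinear"):
        DetectionTimeModel(X, np.ones(30)).fit()


def test_fit_with_intercept(rng):
    X = feature_matrix(rng, 60)
    y = 7.0 + X @ np.array([1.0, 2.0, 0.001])
    res = DetectionTimeModel(X, y, intercept=True).fit()
    assert res.params.intercept == pytest.approx(7.0, abs=1e-8)
    assert "intercept" in res.summary()


def test_fit_rejects_tiny_samples(rng):
    with pytest.raises(InsufficientDataError):
        DetectionTimeModel(feature_matrix(rng, 3), np.ones(3))


# ---------------------------------------------------------------------------
# predict / evaluate
# ---------------------------------------------------------------------------

def test_predict_is_the_linear_combination():
    p = ModelParams(1.0, 1.0, 1.0)
    assert regression.predict(p, [0.0, 0.0, 0.0])[0] == 0.0
    assert regression.predict(ModelParams(2.0, 0.0, 0.0), [5.0, 9.0, 3.0])[0] == 10.0


def test_predict_reproduces_targets_in_column_space(rng):
    X = feature_matrix(rng, 40)
    y = X @ np.array([1.5, -2.0, 0.004])
    res = DetectionTimeModel(X, y).fit()
    assert np.allclose(res.predict(X), y, atol=1e-8)


def test_predict_optional_clipping():
    p = ModelParams(10.0, 0.0, 0.0)
    out = regression.predict(p, np.array([[22.0, 0, 0]]), clip=(0, 60))
    assert out[0] == 60.0


def test_evaluate_trivial_identities(rng):
    y = rng.uniform(1, 60, 30)
    ev = regression.evaluate(y, y)
    assert ev.plcc == pytest.approx(1.0) and ev.srocc == pytest.approx(1.0)
    assert ev.rmse_s == 0.0
    ev = regression.evaluate(-y, y)
    assert ev.plcc == pytest.approx(-1.0) and ev.srocc == pytest.approx(-1.0)
    ev = regression.evaluate(y + 10, y)
    assert ev.plcc == pytest.approx(1.0) and ev.rmse_s == pytest.approx(10.0)


def test_evaluate_rejects_constant_vectors():
    with pytest.raises(ValueError):
        regression.evaluate(np.ones(5), np.arange(5.0))


# ---------------------------------------------------------------------------
# Fisher z
# ---------------------------------------------------------------------------

def test_fisher_average_identities():
    assert regression.fisher_average([0.5, 0.5, 0.5]) == pytest.approx(0.5)
    assert regression.fisher_average([0.3, -0.3]) == pytest.approx(0.0)
    expected = np.tanh((np.arctanh(0.2) + np.arctanh(0.8)) / 2)
    assert regression.fisher_average([0.2, 0.8]) == pytest.approx(expected)
    with pytest.raises(ValueError):
        regression.fisher_average([1.0, 0.5])


def test_fisher_average_bounded_by_extremes(rng):
    r = rng.uniform(-0.9, 0.9, size=20)
    avg = regression.fisher_average(r)
    assert r.min() <= avg <= r.max()


def test_fisher_z_difference_is_zero_for_equal_correlations():
    z, p = regression.fisher_z_difference(0.6, 0.6, 50, 50)
    assert z == 0.0 and p == 1.0


# ---------------------------------------------------------------------------
# cross-validation protocol
# ---------------------------------------------------------------------------

def test_cross_validate_is_deterministic_given_seed(rng):
    X = feature_matrix(rng, 60)
    y = X @ np.array([1.0, 5.0, 0.005]) + rng.normal(0, 3, 60)
    ev1 = regression.cross_validate(X, y, n_splits=25, seed=9)
    ev2 = regression.cross_validate(X, y, n_splits=25, seed=9)
    assert (ev1.plcc, ev1.srocc, ev1.rmse_s) == (ev2.plcc, ev2.srocc, ev2.rmse_s)
    assert ev1.per_split.equals(ev2.per_split)


def test_cross_validate_noiseless_targets_are_perfect(rng):
    X = feature_matrix(rng, 40)
    y = X @ np.array([2.0, 1.0, 0.01])
    ev = regression.cross_validate(X, y, n_splits=10, seed=1)
    assert ev.plcc == pytest.approx(1.0, abs=1e-9)
    assert ev.rmse_s == pytest.approx(0.0, abs=1e-8)


def test_cross_validate_shuffled_pairing_has_no_correlation():
    rng = np.random.default_rng(5)
    X = feature_matrix(rng, 100)
    y = rng.uniform(1, 60, 100)  # independent of X
    ev = regression.cross_validate(X, y, n_splits=50, seed=2)
    assert abs(ev.plcc) < 0.3


def test_cross_validate_full_data_equals_in_sample(rng):
    X = feature_matrix(rng, 30)
    y = X @ np.array([1.0, 2.0, 0.003]) + rng.normal(0, 2, 30)
    ev = regression.cross_validate(X, y, train_frac=1.0)
    res = DetectionTimeModel(X, y).fit()
    ref = regression.evaluate(res.predict(X), y)
    assert ev.plcc == ref.plcc and ev.rmse_s == ref.rmse_s
    assert ev.n_splits == 1


def test_cross_validate_needs_enough_samples(rng):
    X = feature_matrix(rng, 8)
    with pytest.raises(InsufficientDataError):
        regression.cross_validate(X, np.ones(8), n_splits=5)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def separated_clusters(rng, n=120):
    half = n // 2
    easy = rng.normal([3, 0.01, 300], [1, 0.005, 100], size=(half, 3))
    hard = rng.normal([15, 0.05, 2500], [1, 0.005, 100], size=(half, 3))
    X = np.vstack([easy, hard])
    y = np.array(["C1"] * half + ["C2"] * half)
    return X, y


def test_qda_separates_clean_clusters(rng):
    X, y = separated_clusters(rng)
    out = regression.classify_difficulty(X, y, method="qda", seed=0)
    assert out["accuracy"] >= 0.95


def test_label_permutation_destroys_accuracy(rng):
    X, y = separated_clusters(rng)
    perm = np.random.default_rng(1).permutation(len(y))
    out = regression.classify_difficulty(X, y[perm], method="qda", seed=0)
    assert abs(out["accuracy"] - 0.5) < 0.15


def test_conflicting_duplicates_cannot_beat_the_prior(rng):
    X = np.tile([[5.0, 0.02, 900.0]], (40, 1))
    X += rng.normal(0, 1e-9, X.shape)  # break exact singularity only
    y = np.array(["C1"] * 25 + ["C2"] * 15)
    out = regression.classify_difficulty(X, y, method="qda", folds=5, seed=0)
    assert out["accuracy"] <= 25 / 40 + 1e-9


def test_tree_respects_node_budget_and_reports_rules(rng):
    X, y = separated_clusters(rng)
    out = regression.classify_difficulty(X, y, method="tree", seed=0)
    assert out["n_split_nodes"] <= 4
    assert "f_" in out["rules"]  # rules are stated in feature terms
    assert out["accuracy"] >= 0.9


def test_single_class_raises():
    X = np.random.default_rng(0).normal(size=(20, 3))
    with pytest.raises(DegenerateClassError):
        regression.classify_difficulty(X, np.array(["C1"] * 20))


# ---------------------------------------------------------------------------
# end-to-end parameter recovery (coverage over replicates)
# ---------------------------------------------------------------------------

def test_recovery_within_three_se_in_at_least_95_percent_of_replicates():
    """Simulated studies with known coefficients and 5 s trial noise recover
    the truth within 3 standard errors in >= 95% of 100 replicates."""
    from chromablind.synthetic import (
        SimulationSpec, generate_sequences, sample_change_targets,
        simulate_detections,
    )

    b_true = ModelParams(1.5, 4.0, 0.005)
    n_pairs, n_obs, ppo = 100, 20, 30
    hits = 0
    for rep in range(100):
        rng = np.random.default_rng(1000 + rep)
        feats = pd.DataFrame({
            "pair_id": range(n_pairs),
            "f_cm": sample_change_targets(n_pairs, rng),
            "f_si": rng.uniform(0.002, 0.07, n_pairs),
        })
        idx = generate_sequences(n_obs, n_pairs, ppo, seed=2000 + rep)
        sim = SimulationSpec(true_params=b_true, noise_sd=5.0, lapse_prob=0.0,
                             fp_prob=0.0, observer_offsets=np.ones(n_obs),
                             seed=3000 + rep)
        rec = simulate_detections(feats, idx, sim)
        valid = rec[rec["detected"]]
        fmap = feats.set_index("pair_id")
        X = np.column_stack([
            fmap.loc[valid["pair_id"], "f_cm"],
            fmap.loc[valid["pair_id"], "f_si"],
            valid["seq_index"] ** 2,
        ])
        res = DetectionTimeModel(X, valid["time_s"].to_numpy()).fit()
        z = (res.params.as_array() - b_true.as_array()) / res.bse
        hits += bool(np.all(np.abs(z) < 3))
    assert hits >= 95
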