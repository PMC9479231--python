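"""QC predictor: split, CART vs brute force, pruning, logistic IRLS,
F score and feature importance."""

import numpy as np
import pandas as pd
import pytest

from ffpeqc import simulate as sim
from ffpeqc.models import (
    DecisionModel,
    best_split,
    default_cp_grid,
    evaluate_split,
    f_score,
    feature_importance,
    fit_cart,
    fit_logistic,
    predict,
    prune,
    split_train_test,
)


def gini_bruteforce(x: np.ndarray, y: np.ndarray):
    """Enumerate every (feature, midpoint threshold) split, no shortcuts."""
    n = len(y)
    best = None
    for j in range(x.shape[1]):
        values = sorted(set(x[:, j]))
        for a, b in zip(values, values[1:]):
            thr = (a + b) / 2
            left = x[:, j] < thr
            out = 0.0
            for mask in (left, ~left):
                m = mask.sum()
                p = y[mask].mean() if m else 0.0
                out += m / n * 2 * p * (1 - p)
            cand = (out, j, thr)
            if best is None or cand[0] < best[0] - 1e-15:
                best = cand
    return best


class TestSplitTrainTest:
    def test_seven_three_with_both_classes(self):
        labels = pd.Series(["PASS"] * 5 + ["FAIL"] * 5, index=[f"s{i}" for i in range(10)])
        train, test = split_train_test(labels, ratio=0.7, seed=1)
        assert len(train) == 7 and len(test) == 3
        assert set(train) | set(test) == set(labels.index)
        assert not set(train) & set(test)
        for part in (train, test):
            assert set(labels.loc[part]) == {"PASS", "FAIL"}

    def test_deterministic_per_seed(self):
        labels = pd.Series(["PASS"] * 8 + ["FAIL"] * 6)
        assert split_train_test(labels, seed=3) == split_train_test(labels, seed=3)

    def test_degenerate_ratio_rejected(self):
        labels = pd.Series(["PASS"] * 6 + ["FAIL"] * 6)
        with pytest.raises(ValueError, match="ratio"):
            split_train_test(labels, ratio=1.0)


class TestBestSplit:
    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(10):
            x = rng.uniform(0, 10, size=(40, 2))
            y = (rng.random(40) < 0.5).astype(int)
            if len(np.unique(y)) < 2:
                continue
            ours = best_split(x, y)
            brute = gini_bruteforce(x, y)
            assert ours is not None
            j, thr, g = ours
            assert g == pytest.approx(brute[0], abs=1e-12)
            assert (j, thr) == (brute[1], pytest.approx(brute[2]))

    def test_no_split_on_constant_features(self):
        x = np.ones((10, 2))
        y = np.array([0, 1] * 5)
        assert best_split(x, y) is None


class TestFitCart:
    def test_separable_single_split(self):
        x = pd.DataFrame({"f": np.concatenate([np.linspace(0, 9, 20), np.linspace(11, 20, 20)])})
        y = pd.Series(["FAIL"] * 20 + ["PASS"] * 20, index=x.index)
        model = fit_cart(x, y, cv=(5, 1), seed=0)
        assert model.root.feature == "f"
        assert 9 < model.root.threshold < 11
        preds = predict(model, x)["status"]
        assert (preds == y).all()

    def test_planted_rule_depth_two(self):
        cohort = sim.planted_rule_cohort(200, seed=1, label_noise=0.05)
        model = fit_cart(
            cohort[["rna_qubit", "library_qubit"]], cohort["status"], seed=1
        )
        root = model.root
        assert root.feature == "rna_qubit"
        assert round(root.threshold) == 25
        assert root.right.feature == "library_qubit"
        assert round(root.right.threshold, 1) == pytest.approx(1.7, abs=0.1)

    def test_three_quality_categories(self):
        """Tree descent reproduces the three planted quality groups."""
        cohort = sim.planted_rule_cohort(300, seed=2, label_noise=0.0)
        model = fit_cart(cohort[["rna_qubit", "library_qubit"]], cohort["status"], seed=2)
        cases = pd.DataFrame(
            {
                "rna_qubit": [30.0, 10.0, 30.0],
                "library_qubit": [2.0, 5.0, 1.0],
            },
            index=["good", "low", "intermediate"],
        )
        preds = predict(model, cases)["status"]
        assert list(preds) == ["PASS", "FAIL", "FAIL"]

    def test_pruning_monotone_in_cp(self):
        cohort = sim.planted_rule_cohort(150, seed=3, label_noise=0.1)
        model = fit_cart(
            cohort[["rna_qubit", "library_qubit"]], cohort["status"], cp_grid=[1e-6], cv=(3, 1)
        )
        full = model.root
        sizes = [
            prune(full, cp, full.impurity).n_leaves() for cp in default_cp_grid()
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_single_class_warns_single_leaf(self):
        x = pd.DataFrame({"f": np.arange(12.0)})
        y = pd.Series(["PASS"] * 12, index=x.index)
        with pytest.warns(UserWarning, match="single-class"):
            model = fit_cart(x, y)
        assert model.root.is_leaf

    def test_missing_feature_at_predict_names_sample(self):
        cohort = sim.planted_rule_cohort(100, seed=4)
        model = fit_cart(cohort[["rna_qubit", "library_qubit"]], cohort["status"], cv=(3, 1))
        bad = pd.DataFrame({"rna_qubit": [30.0], "library_qubit": [np.nan]}, index=["sX"])
        with pytest.raises(ValueError, match="sX"):
            predict(model, bad)


class TestFScore:
    def test_perfect(self):
        assert f_score(["PASS", "FAIL"], ["PASS", "FAIL"]) == 1.0

    def test_hand_confusion_matrix(self):
        # TP=8, FP=2, FN=2 -> precision = recall = 0.8 -> F = 0.8
        pred = ["PASS"] * 10 + ["FAIL"] * 2
        truth = ["PASS"] * 8 + ["FAIL"] * 2 + ["PASS"] * 2
        assert f_score(pred, truth, positive_class="PASS") == pytest.approx(0.8)

    def test_no_positive_predictions(self):
        assert f_score(["FAIL", "FAIL"], ["PASS", "FAIL"]) == 0.0

    def test_length_mismatch_and_absent_class(self):
        with pytest.raises(ValueError):
            f_score(["PASS"], ["PASS", "FAIL"])
        with pytest.raises(ValueError, match="absent"):
            f_score(["FAIL", "FAIL"], ["FAIL", "FAIL"], positive_class="PASS")


def loglik(x, y, b0, b1):
    eta = b0 + b1 * x
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


class TestLogistic:
    def test_centered_symmetric_data_zero_intercept(self):
        x = pd.DataFrame({"f": [-2.0, -1.0, 1.0, 2.0] * 5})
        y = pd.Series((["FAIL", "FAIL", "PASS", "PASS"] * 5), index=x.index)
        model = fit_logistic(x, y)
        assert abs(model.beta0) < 1e-6

    def test_matches_grid_likelihood_maximization(self, rng):
        x = rng.normal(0, 1, 20)
        p = 1 / (1 + np.exp(-(0.5 + 1.2 * x)))
        y = (rng.random(20) < p).astype(int)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        feats = pd.DataFrame({"f": x})
        labels = pd.Series(np.where(y == 1, "PASS", "FAIL"), index=feats.index)
        model = fit_logistic(feats, labels)
        # coarse-to-fine grid search of the log-likelihood
        b0s = np.linspace(-5, 5, 101)
        b1s = np.linspace(-8, 8, 161)
        ll = np.array([[loglik(x, y, b0, b1) for b1 in b1s] for b0 in b0s])
        i, j = np.unravel_index(ll.argmax(), ll.shape)
        b0c, b1c = b0s[i], b1s[j]
        b0s = np.linspace(b0c - 0.2, b0c + 0.2, 81)
        b1s = np.linspace(b1c - 0.2, b1c + 0.2, 81)
        ll = np.array([[loglik(x, y, b0, b1) for b1 in b1s] for b0 in b0s])
        i, j = np.unravel_index(ll.argmax(), ll.shape)
        assert model.beta0 == pytest.approx(b0s[i], abs=1e-2)
        assert model.beta1["f"] == pytest.approx(b1s[j], abs=1e-2)

    def test_two_point_closed_form(self):
        """For one point per class the MLE diverges (complete
        separation) and is reported as such."""
        feats = pd.DataFrame({"f": [0.0, 1.0]})
        labels = pd.Series(["FAIL", "PASS"], index=feats.index)
        with pytest.warns(UserWarning, match="separation"):
            model = fit_logistic(feats, labels)
        assert model.separated
        preds = predict(model, feats)["status"]
        assert list(preds) == ["FAIL", "PASS"]

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        x = rng.normal(0, 1, size=(80, 2))
        p = 1 / (1 + np.exp(-(0.3 + x @ np.array([1.0, -0.7]))))
        y = (rng.random(80) < p).astype(int)
        feats = pd.DataFrame(x, columns=["a", "b"])
        labels = pd.Series(np.where(y == 1, "PASS", "FAIL"), index=feats.index)
        ours = fit_logistic(feats, labels)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert ours.beta0 == pytest.approx(ref.params[0], abs=1e-5)
        assert np.allclose(ours.beta1.to_numpy(), ref.params[1:], atol=1e-5)

    def test_similar_f_to_cart_on_quality_linked_cohort(self):
        """When both concentrations track latent sample quality (as in
        a real cohort), the linear model matches the tree's held-out F
        score closely; independent uniform features would instead
        handicap the linear boundary on the AND-shaped rule."""
        params = sim.SimulationParams(n_samples=180, n_batches=5, seed=5, label_noise=0.05)
        truth = sim.generate_cohort_truth(params)
        lab = sim.simulate_lab_metrics(truth, params, planted_rule=True)
        feats = lab[["rna_qubit", "library_qubit"]]
        labels = lab["true_status"]
        cart, _, _ = evaluate_split(feats, labels, model_kind="cart", seed=5)
        logit, _, _ = evaluate_split(feats, labels, model_kind="logistic", seed=5)
        assert abs(cart.f_score - logit.f_score) <= 0.05


class TestFeatureImportance:
    def test_sums_to_one_and_single_feature(self):
        x = pd.DataFrame(
            {"rna": np.linspace(0, 1, 40), "lib": np.r_[np.zeros(20), np.ones(20)]}
        )
        y = pd.Series(["FAIL"] * 20 + ["PASS"] * 20, index=x.index)
        model = fit_cart(x, y, cv=(5, 1))
        imp = feature_importance(model)
        assert imp.sum() == pytest.approx(1.0)

    def test_library_dominates_on_planted_rule(self):
        """When the cohort is concentrated above the RNA cutoff, the
        library threshold does the discriminative work."""
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            rna = rng.uniform(20.0, 60.0, 200)  # mostly above 25
            lib = rng.uniform(0.2, 8.0, 200)
            status = sim.apply_planted_rule(rna, lib, 0.05, rng)
            feats = pd.DataFrame({"rna_qubit": rna, "library_qubit": lib})
            model = fit_cart(feats, pd.Series(status, index=feats.index), seed=seed)
            imp = model.feature_importance
            if imp["library_qubit"] >= imp["rna_qubit"]:
                wins += 1
        assert wins >= 3

    def test_single_leaf_zero_importance(self):
        x = pd.DataFrame({"f": np.arange(12.0)})
        y = pd.Series(["PASS"] * 12, index=x.index)
        with pytest.warns(UserWarning):
            model = fit_cart(x, y)
        with pytest.warns(UserWarning, match="importance"):
            imp = feature_importance(model)
        assert (imp == 0).all()
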