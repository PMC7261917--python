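"""Gaussian NB prognosis model against closed forms, sklearn, and pair counting."""

import numpy as np
import pandas as pd
import pytest

from panprog import (
    CohortLabels,
    fit_alternative,
    fit_gaussian_nb,
    predict_proba,
    roc_auc,
)
from panprog.datatypes import HIGH_OS, LOW_OS
from panprog.pcpa import PCPAModel

from conftest import make_matrix


def two_class_labels(n_low, n_high):
    ids = [f"s{i}" for i in range(n_low + n_high)]
    return ids, CohortLabels(
        median_os=0.0,
        labels=pd.Series([LOW_OS] * n_low + [HIGH_OS] * n_high, index=ids),
    )


def nb_model(mean_low, mean_high, var=1.0, prior_high=0.5):
    return PCPAModel(
        family="NB",
        feature_ids=["f0"],
        class_priors={HIGH_OS: prior_high, LOW_OS: 1 - prior_high},
        means={HIGH_OS: [mean_high], LOW_OS: [mean_low]},
        variances={HIGH_OS: [var], LOW_OS: [var]},
        variance_floor=1e-12,
    )


class TestGaussianNbPosterior:
    def test_far_from_low_class_is_confident(self):
        model = nb_model(0.0, 10.0)
        p = predict_proba(model, make_matrix([[10.0]], features=["f0"]))
        assert p.iloc[0] > 0.99

    def test_midpoint_is_even_odds(self):
        model = nb_model(0.0, 2.0)
        p = predict_proba(model, make_matrix([[1.0]], features=["f0"]))
        assert p.iloc[0] == pytest.approx(0.5)

    def test_closed_form_posterior_at_high_mean(self):
        # equal unit variances, equal priors, x at the high-OS mean of 2:
        # log likelihood ratio = 2, posterior = e^2 / (1 + e^2)
        model = nb_model(0.0, 2.0)
        p = predict_proba(model, make_matrix([[2.0]], features=["f0"]))
        assert p.iloc[0] == pytest.approx(np.exp(2) / (1 + np.exp(2)), abs=1e-12)

    def test_probabilities_normalized_and_duplicates_equal(self, rng):
        ids, labels = two_class_labels(10, 10)
        train = make_matrix(rng.normal(size=(4, 20)), samples=ids)
        model = fit_gaussian_nb(train, labels)
        test = make_matrix(np.tile(rng.normal(size=(4, 1)), (1, 3)),
                           samples=["a", "b", "c"])
        p = predict_proba(model, test)
        assert (p <= 1).all() and (p >= 0).all()
        assert p.iloc[0] == p.iloc[1] == p.iloc[2]

    def test_log_space_matches_naive_product_on_small_model(self, rng):
        ids, labels = two_class_labels(15, 15)
        train = make_matrix(rng.normal(size=(5, 30)), samples=ids)
        model = fit_gaussian_nb(train, labels)
        x = rng.normal(size=(5, 1))
        p = predict_proba(model, make_matrix(x, samples=["t"])).iloc[0]

        def gauss(v, mu, var):
            return np.exp(-((v - mu) ** 2) / (2 * var)) / np.sqrt(2 * np.pi * var)

        num = {}
        for cls in (HIGH_OS, LOW_OS):
            num[cls] = model.class_priors[cls] * np.prod(
                [gauss(x[i, 0], model.means[cls][i], model.variances[cls][i]) for i in range(5)]
            )
        assert p == pytest.approx(num[HIGH_OS] / (num[HIGH_OS] + num[LOW_OS]), abs=1e-9)

    def test_matches_sklearn_gaussian_nb(self, rng):
        """Independent cross-check of the fit + posterior against sklearn."""
        from sklearn.naive_bayes import GaussianNB

        ids, labels = two_class_labels(40, 35)
        train = make_matrix(rng.normal(size=(8, 75)), samples=ids)
        test = make_matrix(rng.normal(size=(8, 20)),
                           samples=[f"t{i}" for i in range(20)])
        model = fit_gaussian_nb(train, labels)
        ours = predict_proba(model, test)

        y = (labels.for_samples(ids) == HIGH_OS).astype(int)
        clf = GaussianNB(var_smoothing=1e-9).fit(train.data.to_numpy().T, y)
        theirs = clf.predict_proba(test.data.to_numpy().T)[:, list(clf.classes_).index(1)]
        np.testing.assert_allclose(ours.to_numpy(), theirs, atol=1e-6)

    def test_feature_order_invariance_and_uninformative_feature(self, rng):
        ids, labels = two_class_labels(12, 12)
        train = make_matrix(rng.normal(size=(4, 24)), samples=ids)
        test = make_matrix(rng.normal(size=(4, 6)), samples=[f"t{i}" for i in range(6)])
        base = predict_proba(fit_gaussian_nb(train, labels), test)

        perm = ["f2", "f0", "f3", "f1"]
        shuffled = predict_proba(fit_gaussian_nb(train.subset_features(perm), labels),
                                 test.subset_features(perm))
        np.testing.assert_allclose(base.to_numpy(), shuffled.to_numpy(), atol=1e-12)

        # a feature with identical class-conditional parameters is a no-op
        model = fit_gaussian_nb(train, labels)
        model.feature_ids = model.feature_ids + ["extra"]
        for cls in (HIGH_OS, LOW_OS):
            model.means[cls] = list(model.means[cls]) + [1.0]
            model.variances[cls] = list(model.variances[cls]) + [2.0]
        test2 = make_matrix(np.vstack([test.data.to_numpy(), rng.normal(size=(1, 6))]),
                            features=["f0", "f1", "f2", "f3", "extra"],
                            samples=test.sample_ids)
        np.testing.assert_allclose(predict_proba(model, test2).to_numpy(),
                                   base.to_numpy(), atol=1e-12)

    def test_constant_feature_gets_floored_variance(self):
        ids, labels = two_class_labels(3, 3)
        vals = np.vstack([np.ones(6), [0, 1, 2, 3, 4, 5.0]])
        model = fit_gaussian_nb(make_matrix(vals, samples=ids), labels)
        assert min(model.variances[HIGH_OS]) >= model.variance_floor > 0

    def test_missing_feature_is_reported(self):
        model = nb_model(0.0, 1.0)
        with pytest.raises(ValueError, match="f0"):
            predict_proba(model, make_matrix([[1.0]], features=["other"]))

    def test_single_class_training_rejected(self):
        ids = ["a", "b"]
        labels = CohortLabels(0.0, pd.Series([LOW_OS, LOW_OS], index=ids))
        with pytest.raises(ValueError, match=HIGH_OS):
            fit_gaussian_nb(make_matrix([[1.0, 2.0]], samples=ids), labels)

    def test_json_round_trip_is_exact(self, rng):
        ids, labels = two_class_labels(8, 9)
        train = make_matrix(rng.normal(size=(3, 17)), samples=ids)
        model = fit_gaussian_nb(train, labels)
        back = PCPAModel.from_json(model.to_json())
        assert back == model


class TestRocAuc:
    def test_perfect_separation(self):
        rep = roc_auc([0.9, 0.8, 0.3, 0.2], [HIGH_OS, HIGH_OS, LOW_OS, LOW_OS])
        assert rep.auc == 1.0

    def test_three_of_four_concordant_pairs(self):
        rep = roc_auc([0.9, 0.2, 0.8, 0.3], [HIGH_OS, LOW_OS, LOW_OS, HIGH_OS])
        assert rep.auc == pytest.approx(0.75)

    def test_all_equal_probabilities_give_half(self):
        rep = roc_auc([0.5, 0.5, 0.5, 0.5], [HIGH_OS, LOW_OS, HIGH_OS, LOW_OS])
        assert rep.auc == pytest.approx(0.5)

    def test_roc_points_monotone(self, rng):
        probs = rng.uniform(size=30)
        truth = [HIGH_OS if rng.uniform() < 0.5 else LOW_OS for _ in range(30)]
        if len(set(truth)) < 2:
            truth[0], truth[1] = HIGH_OS, LOW_OS
        rep = roc_auc(probs, truth)
        fpr, tpr = zip(*rep.roc_points)
        assert all(a <= b for a, b in zip(fpr, fpr[1:]))
        assert all(a <= b for a, b in zip(tpr, tpr[1:]))

    def test_matches_pairwise_concordance_count(self, rng):
        """AUC equals the brute-force concordance probability with tie credit."""
        for _ in range(100):
            n = int(rng.integers(4, 50))
            probs = np.round(rng.uniform(size=n), 1)  # rounding forces ties
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            truth = [HIGH_OS if v else LOW_OS for v in y]
            rep = roc_auc(probs, truth)
            pos, neg = probs[y == 1], probs[y == 0]
            conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert rep.auc == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [HIGH_OS, HIGH_OS])


class TestAlternativeFamilies:
    def _separable(self, rng):
        ids, labels = two_class_labels(20, 20)
        low = rng.normal(-3, 0.3, size=(2, 20))
        high = rng.normal(3, 0.3, size=(2, 20))
        return make_matrix(np.hstack([low, high]), samples=ids), labels

    @pytest.mark.parametrize("family", ["LR", "SVM", "NN"])
    def test_separable_data_fits_perfectly(self, family, rng):
        train, labels = self._separable(rng)
        model = fit_alternative(train, labels, family)
        preds = model.predict_proba(train) > 0.5
        truth = (labels.for_samples(train.sample_ids) == HIGH_OS).to_numpy()
        assert (preds.to_numpy() == truth).all()
        assert model.family == family

    def test_same_seed_same_predictions(self, rng):
        train, labels = self._separable(rng)
        a = fit_alternative(train, labels, "NN", random_state=7).predict_proba(train)
        b = fit_alternative(train, labels, "NN", random_state=7).predict_proba(train)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_unknown_family_rejected(self, rng):
        train, labels = self._separable(rng)
        with pytest.raises(ValueError, match="unknown model family"):
            fit_alternative(train, labels, "XGB")
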