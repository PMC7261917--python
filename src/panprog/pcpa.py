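"""The pan-cancer prognosis (PCPA) classifier.

Gaussian naive Bayes is the reference model: class priors are the training
class frequencies and each feature gets a per-class mean and variance, with
variances floored at a small fraction of the largest feature variance so a
constant feature cannot produce a singular likelihood. Posteriors are
computed in log space (log-sum of per-feature Gaussian log-densities plus
the log prior, normalized with logsumexp), so thousands of features do not
underflow. The explicit parametric state is what the marker-oriented
counterfactual screen perturbs, and it serializes losslessly to JSON.

Logistic-regression, SVM and neural-network alternatives are exposed as
thin scikit-learn adapters with the same ``predict_proba`` surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .datatypes import HIGH_OS, LOW_OS, CohortLabels, ExpressionMatrix

CLASSES = (HIGH_OS, LOW_OS)


@dataclass
class PCPAModel:
    """Fitted Gaussian naive Bayes state for the two prognosis classes."""

    family: str
    feature_ids: list[str]
    class_priors: dict  # class -> probability
    means: dict  # class -> list of per-feature means
    variances: dict  # class -> list of per-feature variances (floored)
    variance_floor: float

    def __post_init__(self) -> None:
        total = sum(self.class_priors.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class priors must sum to 1, got {total}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "family": self.family,
                "feature_ids": self.feature_ids,
                "class_priors": self.class_priors,
                "means": {c: list(map(float, m)) for c, m in self.means.items()},
                "variances": {c: list(map(float, v)) for c, v in self.variances.items()},
                "variance_floor": self.variance_floor,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PCPAModel":
        return cls(**json.loads(text))


@dataclass
class EvalReport:
    """Held-out evaluation: per-sample probabilities, ROC points, AUC."""

    sample_ids: list[str]
    prob_high: np.ndarray
    predicted_label: list[str]
    roc_points: list  # (FPR, TPR) pairs
    auc: float

    def predictions(self) -> pd.Series:
        return pd.Series(self.predicted_label, index=self.sample_ids)


def fit_gaussian_nb(
    train: ExpressionMatrix,
    labels: CohortLabels,
    variance_floor: float | None = None,
) -> PCPAModel:
    """Fit the Gaussian NB prognosis model on a training matrix.

    ``variance_floor`` defaults to 1e-9 times the largest per-feature
    training variance (population variances, matching the per-class ML
    estimates).
    """
    lab = labels.for_samples(train.sample_ids)
    X = train.data.to_numpy(dtype=float)
    means, variances, priors = {}, {}, {}
    if variance_floor is None:
        overall_var = X.var(axis=1).max() if X.size else 0.0
        variance_floor = max(1e-9 * float(overall_var), 1e-12)
    for cls in CLASSES:
        cols = np.asarray(lab == cls)
        if cols.sum() == 0:
            raise ValueError(f"training set contains no {cls} samples")
        Xc = X[:, cols]
        means[cls] = Xc.mean(axis=1).tolist()
        variances[cls] = np.maximum(Xc.var(axis=1), variance_floor).tolist()
        priors[cls] = float(cols.sum() / len(lab))
    return PCPAModel(
        family="NB",
        feature_ids=train.feature_ids,
        class_priors=priors,
        means=means,
        variances=variances,
        variance_floor=float(variance_floor),
    )


def _log_likelihood(model: PCPAModel, X: np.ndarray) -> np.ndarray:
    """Per-class log posterior numerators; X is features x samples."""
    out = np.empty((len(CLASSES), X.shape[1]))
    for k, cls in enumerate(CLASSES):
        mu = np.asarray(model.means[cls])[:, None]
        var = np.asarray(model.variances[cls])[:, None]
        ll = -0.5 * (np.log(2 * np.pi * var) + (X - mu) ** 2 / var)
        out[k] = ll.sum(axis=0) + np.log(model.class_priors[cls])
    return out


def predict_proba(model: PCPAModel, matrix: ExpressionMatrix) -> pd.Series:
    """Posterior probability of high-OS for every sample in the matrix."""
    if model.family != "NB":
        raise ValueError("predict_proba on a PCPAModel requires the NB family")
    missing = [f for f in model.feature_ids if f not in set(matrix.feature_ids)]
    if missing:
        raise ValueError(f"matrix lacks model features: {missing[:5]}")
    X = matrix.data.loc[model.feature_ids].to_numpy(dtype=float)
    log_post = _log_likelihood(model, X)
    log_norm = logsumexp(log_post, axis=0)
    prob_high = np.exp(log_post[CLASSES.index(HIGH_OS)] - log_norm)
    return pd.Series(prob_high, index=matrix.sample_ids, name="prob_high")


def roc_auc(prob_high, truth, threshold: float = 0.5) -> EvalReport:
    """ROC sweep and AUC (concordance with half credit for ties).

    ``truth`` holds the class labels (high-OS positive); both classes must
    be present.
    """
    from sklearn.metrics import roc_auc_score, roc_curve

    probs = pd.Series(prob_high)
    y = np.asarray([1 if t == HIGH_OS else 0 for t in truth])
    if y.min() == y.max():
        raise ValueError("both classes must be present to compute ROC/AUC")
    fpr, tpr, _ = roc_curve(y, probs.to_numpy())
    auc = float(roc_auc_score(y, probs.to_numpy()))
    predicted = [HIGH_OS if p > threshold else LOW_OS for p in probs.to_numpy()]
    return EvalReport(
        sample_ids=list(probs.index),
        prob_high=probs.to_numpy(),
        predicted_label=predicted,
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        auc=auc,
    )


class AlternativeModel:
    """Thin scikit-learn adapter exposing the PCPA ``predict_proba`` surface."""

    def __init__(self, family: str, estimator, feature_ids: list[str]):
        self.family = family
        self.estimator = estimator
        self.feature_ids = feature_ids

    def predict_proba(self, matrix: ExpressionMatrix) -> pd.Series:
        X = matrix.data.loc[self.feature_ids].to_numpy(dtype=float).T
        idx = list(self.estimator.classes_).index(1)
        prob = self.estimator.predict_proba(X)[:, idx]
        return pd.Series(prob, index=matrix.sample_ids, name="prob_high")


def fit_alternative(
    train: ExpressionMatrix,
    labels: CohortLabels,
    family: str,
    random_state: int = 0,
    **config,
) -> AlternativeModel:
    """Fit an LR / SVM / NN alternative with library defaults.

    Not part of the reference analysis surface; hyperparameters pass
    through to scikit-learn.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC

    factories = {
        "LR": lambda: LogisticRegression(max_iter=1000, random_state=random_state, **config),
        "SVM": lambda: SVC(probability=True, random_state=random_state, **config),
        "NN": lambda: MLPClassifier(
            hidden_layer_sizes=config.pop("hidden_layer_sizes", (32,)),
            max_iter=config.pop("max_iter", 500),
            random_state=random_state,
            **config,
        ),
    }
    if family not in factories:
        raise ValueError(f"unknown model family {family!r}; choose from {sorted(factories)}")
    est = factories[family]()
    lab = labels.for_samples(train.sample_ids)
    y = np.asarray([1 if v == HIGH_OS else 0 for v in lab])
    est.fit(train.data.to_numpy(dtype=float).T, y)
    return AlternativeModel(family, est, train.feature_ids)
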