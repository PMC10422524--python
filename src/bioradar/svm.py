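"""Linear SVM scoring, training, bundled reference models, group-wise rates.

The decision score of a linear SVM on an observation x with training mean
mu, standard deviation sigma, weights beta, kernel scale s and bias b is

    f(x) = sum_i ((x_i - mu_i) / sigma_i) * beta_i / s + b

with the sign convention f(x) < 0 => "with person" (positive detection),
f(x) > 0 => "without person".  |f(x)| is the confidence of the prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import WITH_PERSON, WITHOUT_PERSON

#: the four-feature set selected by the ranking analysis, in model order
SELECTED_FEATURES = ["PR_ffft_db", "f_cwt_mean_hz", "TD_cwt_mode", "dF_fft_cwt_mean"]


@dataclass
class LinearSVMModel:
    """Linear SVM in standardized-feature parameterization."""

    feature_names: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    beta: np.ndarray
    s: float
    b: float
    positive_convention: str = "f(x) < 0 => with_person"

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        m = len(self.feature_names)
        if not (self.mu.size == self.sigma.size == self.beta.size == m):
            raise ValueError("mu, sigma, beta must match feature_names in length")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive elementwise")
        if self.s <= 0:
            raise ValueError("kernel scale s must be positive")

    @property
    def dim(self) -> int:
        return len(self.feature_names)


def _as_matrix(model: LinearSVMModel, x) -> np.ndarray:
    """Coerce a vector, mapping, or DataFrame to [n, dim] in model order."""
    if isinstance(x, pd.DataFrame):
        X = x[model.feature_names].to_numpy(dtype=float)
    elif isinstance(x, dict):
        X = np.array([[x[f] for f in model.feature_names]], dtype=float)
    else:
        X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[1] != model.dim:
        raise ValueError(f"expected {model.dim} features, got {X.shape[1]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    return X


def lsvm_score(model: LinearSVMModel, x):
    """Decision score f(x); scalar for a single observation, else an array."""
    X = _as_matrix(model, x)
    z = (X - model.mu) / model.sigma
    scores = z @ model.beta / model.s + model.b
    return float(scores[0]) if scores.size == 1 and np.ndim(x) in (0, 1) or isinstance(x, dict) else scores


def lsvm_predict(model: LinearSVMModel, x, return_confidence: bool = False):
    """Class labels under the sign rule; optionally with confidence |f(x)|.

    A score of exactly zero lies on the hyperplane and is classified
    "without person" with a boundary warning.
    """
    scores = np.atleast_1d(lsvm_score(model, x))
    if np.any(scores == 0.0):
        warnings.warn("observation exactly on the decision boundary")
    labels = np.where(scores < 0, WITH_PERSON, WITHOUT_PERSON)
    if return_confidence:
        return labels, np.abs(scores)
    return labels


def train_lsvm(features, labels, C: float = 1.0, seed: int = 0) -> LinearSVMModel:
    """Fit a soft-margin linear SVM with equal misclassification costs.

    Features are standardized with the training mean and standard
    deviation; the fitted hyperplane is exported in the
    (mu, sigma, beta, s, b) parameterization with s = 1.  Classes are coded
    so that negative scores mean "with person".  Deterministic for fixed
    inputs; exported parameters are rounded to 10 decimals.
    """
    from sklearn.svm import SVC

    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("training data must contain both classes")
    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=1)
    if np.any(sigma <= 0):
        raise ValueError("constant feature column; cannot standardize")
    Z = (X - mu) / sigma
    # decision_function is positive for class 1 = without_person
    y01 = (y == WITHOUT_PERSON).astype(int)
    if y01.sum() in (0, len(y01)):
        raise ValueError("labels must use the with_person / without_person convention")
    clf = SVC(kernel="linear", C=C, random_state=seed)
    clf.fit(Z, y01)
    beta = clf.coef_.ravel()
    b = float(clf.intercept_[0])
    return LinearSVMModel(
        feature_names=names,
        mu=np.round(mu, 10),
        sigma=np.round(sigma, 10),
        beta=np.round(beta, 10),
        s=1.0,
        b=round(b, 10),
    )


# Reference linear SVM models for the four selected features, trained on a
# 2165-observation laboratory rescue-bioradar dataset (433 measurements x 5
# range bins).  Shared standardization moments; per-dimension weights.
_REFERENCE_MU = (12.58, 0.40, 0.47, 0.67)
_REFERENCE_SIGMA = (4.60, 0.14, 0.30, 0.49)
_REFERENCE = {
    2: {"s": 0.11, "b": -0.17, "beta": (-0.09, 0.25)},
    3: {"s": 0.25, "b": -0.62, "beta": (-0.19, 0.50, -0.26)},
    4: {"s": 0.43, "b": -0.69, "beta": (-0.31, 0.79, -0.41, 0.18)},
}


def reference_model(dim: int = 4) -> LinearSVMModel:
    """Bundled pre-trained linear SVM over the selected feature set.

    ``dim`` selects the 2-, 3- or 4-feature variant; features enter in the
    order PR(f_fft) [dB], f_cwt_mean [Hz], TD_cwt_mode and
    Δf(fft, cwt_mean) [fractions].  All variants share the training
    standardization moments.
    """
    if dim not in _REFERENCE:
        raise ValueError("reference models exist for dim in {2, 3, 4}")
    p = _REFERENCE[dim]
    return LinearSVMModel(
        feature_names=SELECTED_FEATURES[:dim],
        mu=np.array(_REFERENCE_MU[:dim]),
        sigma=np.array(_REFERENCE_SIGMA[:dim]),
        beta=np.array(p["beta"]),
        s=p["s"],
        b=p["b"],
    )


@dataclass
class EvaluationReport:
    """Confusion counts and rates, optionally broken down by group."""

    TP: int
    FP: int
    TN: int
    FN: int
    ACC: float
    FNR: float
    FPR: float
    by_group: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def _rates(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float, float]:
    n = tp + fp + tn + fn
    acc = (tp + tn) / n if n else np.nan
    fnr = fn / (tp + fn) if (tp + fn) else np.nan
    fpr = fp / (fp + tn) if (fp + tn) else np.nan
    return acc, fnr, fpr


def pr_bin_labels(pr_values, width: float = 5.0) -> np.ndarray:
    """Bin prominence-ratio values into fixed-width dB groups ("[10, 15) dB")."""
    pr = np.asarray(pr_values, dtype=float)
    lo = np.floor(pr / width) * width
    return np.array([f"[{int(a)}, {int(a + width)}) dB" for a in lo])


def groupwise_false_rates(predictions, truth, grouping=None) -> EvaluationReport:
    """Overall and per-group confusion rates ("with person" positive).

    ``grouping`` maps each observation to a bin label (array-like aligned
    with the observations), e.g. prominence-ratio dB bins or body position.
    Rates of empty denominators are reported as NaN (undefined), never 0.
    """
    pred = np.asarray(predictions)
    true = np.asarray(truth)
    if pred.size != true.size:
        raise ValueError("predictions and truth must align")
    pred_pos = pred == WITH_PERSON
    true_pos = true == WITH_PERSON
    tp = int(np.sum(pred_pos & true_pos))
    fp = int(np.sum(pred_pos & ~true_pos))
    tn = int(np.sum(~pred_pos & ~true_pos))
    fn = int(np.sum(~pred_pos & true_pos))
    acc, fnr, fpr = _rates(tp, fp, tn, fn)
    by_group = None
    if grouping is not None:
        g = np.asarray(grouping)
        if g.size != pred.size:
            raise ValueError("grouping must cover all observations")
        rows = []
        for key in pd.unique(g):
            m = g == key
            gtp = int(np.sum(pred_pos[m] & true_pos[m]))
            gfp = int(np.sum(pred_pos[m] & ~true_pos[m]))
            gtn = int(np.sum(~pred_pos[m] & ~true_pos[m]))
            gfn = int(np.sum(~pred_pos[m] & true_pos[m]))
            gacc, gfnr, gfpr = _rates(gtp, gfp, gtn, gfn)
            rows.append({"group": key, "n": int(m.sum()), "TP": gtp, "FP": gfp,
                         "TN": gtn, "FN": gfn, "ACC": gacc, "FNR": gfnr, "FPR": gfpr})
        by_group = pd.DataFrame(rows).sort_values("group").reset_index(drop=True)
    return EvaluationReport(TP=tp, FP=fp, TN=tn, FN=fn, ACC=acc, FNR=fnr, FPR=fpr,
                            by_group=by_group)
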