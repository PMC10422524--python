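"""Feature ranking (one-way ANOVA, MRMR) and subset-augmentation curves.

ANOVA ranks each feature independently by the evidence against equal class
means, scored as -ln(p) of the upper-tail F probability.  MRMR ranks
features by the mutual information quotient MIQ = relevance / redundancy,
trading class-informativeness against duplication of other features.
Subset curves then measure how cross-validated SVM accuracy grows as
features are added in rank order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .simulate import WITH_PERSON

#: -ln(p) cap where p underflows the double range (reported as infinite score)
SCORE_CAP = 745.0


@dataclass
class AnovaResult:
    """One-way ANOVA decomposition for one feature against binary labels."""

    F: float
    p: float
    score: float  # -ln(p), capped at SCORE_CAP
    score_is_inf: bool
    SSG: float
    SSE: float
    SST: float
    MSG: float
    MSE: float
    dfG: int
    dfE: int
    v0bar: float
    v1bar: float
    vbar: float
    N0: int
    N1: int


def _binary_groups(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"expected exactly two classes, got {classes.size}")
    return values[labels == classes[0]], values[labels == classes[1]]


def anova_score(values, labels) -> AnovaResult:
    """One-way ANOVA F statistic and -ln(p) score for a binary grouping.

    F = MSG / MSE with dfG = 1, dfE = N0 + N1 - 2;
    SSG = N0 (v0bar - vbar)^2 + N1 (v1bar - vbar)^2, SSE = SST - SSG.
    The p-value is the upper tail of the F distribution, evaluated in log
    space so that huge F still yields a finite, sortable score.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if v.size != y.size:
        raise ValueError("values and labels must have equal length")
    if v.size < 3:
        raise ValueError("need at least three observations")
    g0, g1 = _binary_groups(v, y)
    N0, N1 = g0.size, g1.size
    if N0 == 0 or N1 == 0:
        raise ValueError("both classes must be non-empty")
    vbar = v.mean()
    v0bar, v1bar = g0.mean(), g1.mean()
    SST = float(np.sum((v - vbar) ** 2))
    SSG = float(N0 * (v0bar - vbar) ** 2 + N1 * (v1bar - vbar) ** 2)
    SSE = SST - SSG
    dfG, dfE = 1, N0 + N1 - 2
    MSG = SSG / dfG
    MSE = SSE / dfE
    if MSE <= 0:
        if MSG <= 0:
            raise ValueError("degenerate feature: zero variance within and between groups")
        # perfectly separated constants: infinite evidence against H0
        return AnovaResult(
            F=math.inf, p=0.0, score=SCORE_CAP, score_is_inf=True,
            SSG=SSG, SSE=SSE, SST=SST, MSG=MSG, MSE=MSE, dfG=dfG, dfE=dfE,
            v0bar=v0bar, v1bar=v1bar, vbar=vbar, N0=N0, N1=N1,
        )
    F = MSG / MSE
    logp = _stats.f.logsf(F, dfG, dfE)
    score = min(-logp, SCORE_CAP)
    p = float(np.exp(logp))
    return AnovaResult(
        F=float(F), p=p, score=float(score), score_is_inf=score >= SCORE_CAP,
        SSG=SSG, SSE=SSE, SST=SST, MSG=MSG, MSE=MSE, dfG=dfG, dfE=dfE,
        v0bar=v0bar, v1bar=v1bar, vbar=vbar, N0=N0, N1=N1,
    )


def anova_table(features: pd.DataFrame, labels, feature_cols=None) -> pd.DataFrame:
    """Rank all feature columns by ANOVA score (descending, stable order)."""
    cols = list(feature_cols) if feature_cols is not None else list(features.columns)
    rows = []
    for c in cols:
        r = anova_score(features[c].to_numpy(), labels)
        rows.append({"feature": c, "F": r.F, "p": r.p, "score": r.score,
                     "score_is_inf": r.score_is_inf})
    out = pd.DataFrame(rows)
    out = out.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def _discretize(x: np.ndarray, max_bins: int) -> np.ndarray:
    """Integer codes: native categories if few, else equal-frequency bins."""
    values = np.unique(x)
    if values.size <= max_bins:
        return np.searchsorted(values, x)
    qs = np.quantile(x, np.linspace(0, 1, max_bins + 1)[1:-1])
    return np.searchsorted(np.unique(qs), x, side="right")


def mutual_information(u, v, max_bins: int | None = None) -> float:
    """Plug-in mutual information I(u; v) in nats.

    Continuous inputs are discretized into ceil(sqrt(n)/2) equal-frequency
    bins (at most 16); inputs with few distinct values are used as-is, so
    discrete toy tables are computed exactly.  Symmetric, non-negative, and
    zero for any constant column.
    """
    u = np.asarray(u).ravel()
    v = np.asarray(v).ravel()
    if u.size != v.size:
        raise ValueError("columns must have equal length")
    n = u.size
    if n == 0:
        raise ValueError("empty columns")
    if max_bins is None:
        max_bins = min(16, max(2, math.ceil(math.sqrt(n) / 2)))
    cu = _discretize(u.astype(float) if u.dtype.kind in "fiub" else _codes(u), max_bins)
    cv = _discretize(v.astype(float) if v.dtype.kind in "fiub" else _codes(v), max_bins)
    joint = np.zeros((cu.max() + 1, cv.max() + 1))
    np.add.at(joint, (cu, cv), 1.0)
    joint /= n
    pu = joint.sum(axis=1)
    pv = joint.sum(axis=0)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / np.outer(pu, pv)[nz])))
    return max(mi, 0.0)


def _codes(x: np.ndarray) -> np.ndarray:
    _, codes = np.unique(x, return_inverse=True)
    return codes.astype(float)


@dataclass
class MrmrResult:
    """Relevance / redundancy decomposition of a feature set."""

    table: pd.DataFrame  # feature, V, W, MIQ, rank
    mi_matrix: pd.DataFrame  # symmetric pairwise feature MI

    @property
    def ranking(self) -> list[str]:
        return list(self.table["feature"])


def mrmr_rank(features: pd.DataFrame, labels, feature_cols=None) -> MrmrResult:
    """Rank features by the mutual information quotient MIQ = V / W.

    Relevance V(u) = I(u; y).  Redundancy W(u) is the average mutual
    information between u and each *other* feature of the set, with the
    1/M normalization of the full set size.  Ranking is by descending MIQ
    with stable tie-breaking in declaration order.
    """
    cols = list(feature_cols) if feature_cols is not None else list(features.columns)
    if len(cols) < 2:
        raise ValueError("need at least two features")
    y = np.asarray(labels)
    M = len(cols)
    data = {c: features[c].to_numpy() for c in cols}
    mi = pd.DataFrame(np.zeros((M, M)), index=cols, columns=cols)
    for a in range(M):
        for b in range(a, M):
            val = mutual_information(data[cols[a]], data[cols[b]])
            mi.iat[a, b] = mi.iat[b, a] = val
    rows = []
    for c in cols:
        V = mutual_information(data[c], y)
        W = float(mi.loc[c].drop(c).sum()) / M
        if W <= 0:
            warnings.warn(f"zero redundancy for feature {c!r}; MIQ capped")
            miq = SCORE_CAP if V > 0 else 0.0
        else:
            miq = V / W
        rows.append({"feature": c, "V": V, "W": W, "MIQ": miq})
    table = pd.DataFrame(rows)
    table = table.sort_values("MIQ", ascending=False, kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return MrmrResult(table=table, mi_matrix=mi)


def _cv_folds(n: int, k: int, labels: np.ndarray, rng: np.random.Generator,
              max_redraws: int = 20) -> list[np.ndarray]:
    """Random equal-size folds; redrawn if any training split is single-class."""
    for attempt in range(max_redraws):
        perm = rng.permutation(n)
        folds = [perm[i::k] for i in range(k)]
        ok = all(
            np.unique(labels[np.concatenate([f for j, f in enumerate(folds) if j != i])]).size == 2
            for i in range(k)
        )
        if ok:
            if attempt:
                warnings.warn("redrew cross-validation folds to cover both classes")
            return folds
    raise ValueError("could not draw folds containing both classes")


def _confusion(pred_pos: np.ndarray, true_pos: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum(pred_pos & true_pos))
    fp = int(np.sum(pred_pos & ~true_pos))
    tn = int(np.sum(~pred_pos & ~true_pos))
    fn = int(np.sum(~pred_pos & true_pos))
    return tp, fp, tn, fn


def evaluate_feature_subsets(
    features: pd.DataFrame,
    labels,
    rankings: dict[str, list[str]],
    k: int = 5,
    C: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated ACC/FNR/FPR of linear SVMs on growing feature subsets.

    For each named ranking and each subset size m = 1..M, trains a linear
    SVM (equal misclassification costs) on the top-m features, using k
    random equal-size folds shared across all subset sizes.  "with person"
    is the positive class.  Returns a tidy frame
    ``ranking, m, acc, fnr, fpr``.
    """
    from .svm import train_lsvm, lsvm_predict

    y = np.asarray(labels)
    true_pos = y == WITH_PERSON
    n = len(features)
    rng = np.random.default_rng(seed)
    folds = _cv_folds(n, k, y, rng)
    rows = []
    for name, order in rankings.items():
        missing = [f for f in order if f not in features.columns]
        if missing:
            raise ValueError(f"ranking {name!r} references unknown features {missing}")
        for m in range(1, len(order) + 1):
            cols = order[:m]
            pred_pos = np.zeros(n, dtype=bool)
            for i in range(k):
                test_idx = folds[i]
                train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
                model = train_lsvm(features.iloc[train_idx][cols], y[train_idx], C=C)
                pred = lsvm_predict(model, features.iloc[test_idx][cols])
                pred_pos[test_idx] = pred == WITH_PERSON
            tp, fp, tn, fn = _confusion(pred_pos, true_pos)
            rows.append(
                {
                    "ranking": name,
                    "m": m,
                    "acc": (tp + tn) / n,
                    "fnr": fn / (tp + fn) if (tp + fn) else np.nan,
                    "fpr": fp / (fp + tn) if (fp + tn) else np.nan,
                }
            )
    return pd.DataFrame(rows)
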