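"""Model / Results interface over feature ranking and SVM classification.

`LifeDetectionSVM` is constructed from a feature table and class labels;
`fit()` ranks the features (one-way ANOVA and MRMR), trains a linear SVM on
a chosen feature subset and returns a `LifeDetectionResults` carrying the
fitted hyperplane, the rankings, cross-validation curves and a text
summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS
from .selection import anova_table, mrmr_rank, evaluate_feature_subsets, MrmrResult
from .svm import (
    LinearSVMModel,
    SELECTED_FEATURES,
    groupwise_false_rates,
    lsvm_predict,
    lsvm_score,
    train_lsvm,
)


class LifeDetectionSVM:
    """Linear-SVM life-detection model over respiration features.

    Parameters
    ----------
    features : pandas.DataFrame
        One row per observation (measurement x range bin); must contain the
        candidate feature columns.
    labels : array-like
        Class of each observation: "with_person" or "without_person".
    feature_names : list of str, optional
        Candidate features; defaults to the nine standard columns present
        in ``features``.
    """

    def __init__(self, features: pd.DataFrame, labels, feature_names=None):
        if feature_names is None:
            feature_names = [c for c in FEATURE_COLUMNS if c in features.columns]
        missing = [c for c in feature_names if c not in features.columns]
        if missing:
            raise ValueError(f"feature columns missing from table: {missing}")
        self.features = features.reset_index(drop=True)
        self.labels = np.asarray(labels)
        if len(self.labels) != len(self.features):
            raise ValueError("labels must align with the feature table")
        self.feature_names = list(feature_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label", feature_names=None):
        """Build from a feature table that carries its labels in a column."""
        if label_col not in df.columns:
            raise ValueError(f"missing label column {label_col!r}")
        return cls(df, df[label_col].to_numpy(), feature_names=feature_names)

    def rank_features(self) -> tuple[pd.DataFrame, MrmrResult]:
        """One-way ANOVA table and MRMR result for the candidate features."""
        a = anova_table(self.features, self.labels, self.feature_names)
        m = mrmr_rank(self.features, self.labels, self.feature_names)
        return a, m

    def fit(self, subset=None, C: float = 1.0, seed: int = 0) -> "LifeDetectionResults":
        """Rank features and train the linear SVM on ``subset``.

        ``subset`` defaults to the four-feature selected set when its
        columns are available, else to all candidate features.
        """
        anova, mrmr = self.rank_features()
        if subset is None:
            subset = (
                SELECTED_FEATURES
                if all(c in self.features.columns for c in SELECTED_FEATURES)
                else self.feature_names
            )
        model = train_lsvm(self.features[list(subset)], self.labels, C=C, seed=seed)
        return LifeDetectionResults(self, model, anova, mrmr, C=C, seed=seed)


@dataclass
class LifeDetectionResults:
    """Fitted hyperplane plus the feature-selection diagnostics."""

    parent: LifeDetectionSVM
    model: LinearSVMModel
    anova: pd.DataFrame
    mrmr: MrmrResult
    C: float = 1.0
    seed: int = 0

    @property
    def params(self) -> pd.Series:
        """Hyperplane weights beta indexed by feature name."""
        return pd.Series(self.model.beta, index=self.model.feature_names, name="beta")

    def score(self, features=None):
        """Decision scores f(x); negative means "with person"."""
        X = self.parent.features if features is None else features
        return lsvm_score(self.model, X[self.model.feature_names] if isinstance(X, pd.DataFrame) else X)

    def predict(self, features=None, return_confidence: bool = False):
        X = self.parent.features if features is None else features
        return lsvm_predict(
            self.model,
            X[self.model.feature_names] if isinstance(X, pd.DataFrame) else X,
            return_confidence=return_confidence,
        )

    def evaluate(self, features=None, labels=None, grouping=None):
        """Confusion-rate report on given data (default: the training table)."""
        X = self.parent.features if features is None else features
        y = self.parent.labels if labels is None else np.asarray(labels)
        return groupwise_false_rates(self.predict(X), y, grouping)

    def cv_curves(self, k: int = 5, seed: int | None = None) -> pd.DataFrame:
        """Accuracy/FNR/FPR vs subset size for both rankings."""
        rankings = {
            "anova": list(self.anova["feature"]),
            "mrmr": self.mrmr.ranking,
        }
        return evaluate_feature_subsets(
            self.parent.features, self.parent.labels, rankings,
            k=k, C=self.C, seed=self.seed if seed is None else seed,
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        rep = self.evaluate()
        lines = [
            "Life-detection linear SVM",
            "=" * 60,
            f"observations: {len(self.parent.features)}   features (model): {self.model.dim}",
            f"C = {self.C}   kernel scale s = {self.model.s:.4g}   bias b = {self.model.b:.4g}",
            "",
            "hyperplane (standardized features):",
        ]
        for name, mu, sg, be in zip(
            self.model.feature_names, self.model.mu, self.model.sigma, self.model.beta
        ):
            lines.append(f"  {name:<18s} mu={mu:9.4f}  sigma={sg:8.4f}  beta={be:8.4f}")
        lines += [
            "",
            "feature rankings (1 = most significant):",
            f"  ANOVA: {', '.join(self.anova['feature'])}",
            f"  MRMR:  {', '.join(self.mrmr.ranking)}",
            "",
            f"training-set ACC={rep.ACC:.3f}  FNR={rep.FNR:.3f}  FPR={rep.FPR:.3f}"
            f"  (TP={rep.TP} FP={rep.FP} TN={rep.TN} FN={rep.FN})",
            'decision rule: f(x) < 0 => "with person"',
        ]
        return "\n".join(lines)
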