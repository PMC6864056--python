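"""Random-forest modelling of fibroglandular volume and diagnosis.

Two questions are asked of the 37-feature patient table:

1. *Regression*: which histologic features predict percent fibroglandular
   volume (global and localized)?  A random-forest regressor is fit on the
   training split, impurity (Gini) importances rank the features, and the
   held-out association is summarised as the Spearman rank correlation
   between predicted and actual FGV.
2. *Classification*: within high- and low-FGV strata (median cut-point from
   the training population), can the features distinguish invasive cancer
   from benign disease?  In-situ diagnoses are excluded from both training
   and testing; the benign class pools non-proliferative and proliferative
   disease with or without atypia.

Estimators follow scikit-learn conventions (``fit``, trailing-underscore
fitted attributes, ``get_params``/``set_params``) and compose with sklearn
tooling; the module-level functions are thin convenience wrappers that handle
the cohort-table bookkeeping (splits, strata, label mapping).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, TransformerMixin
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .errors import DegenerateStratumError
from .features import FEATURE_NAMES

DEFAULT_RF_PARAMS = {"n_estimators": 500}

BENIGN_DIAGNOSES = ("benign_nonproliferative", "proliferative", "atypia")
EXCLUDED_DIAGNOSES = ("insitu",)


def _ranking_from_importances(feature_names, importances) -> pd.DataFrame:
    """Rank features by importance, descending; ties keep canonical order."""
    order = np.argsort(-np.asarray(importances), kind="stable")
    return pd.DataFrame({
        "feature": np.asarray(feature_names)[order],
        "importance": np.asarray(importances)[order],
        "rank": np.arange(1, len(feature_names) + 1),
    })


def _as_frame(X, feature_names=None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X)
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=list(feature_names))


class CorrelationPruner(BaseEstimator, TransformerMixin):
    """Drop one feature from every highly rank-correlated pair.

    Feature pairs are visited in canonical column order; whenever both
    members of a pair with \\|Spearman rho\\| >= ``threshold`` are still
    retained, one of the two is removed by a seeded random choice.  The
    procedure is deterministic given ``random_state``.
    """

    def __init__(self, threshold: float = 0.85, random_state: int = 0):
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y=None):
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must lie in (0, 1]")
        X = _as_frame(X)
        cols = list(X.columns)
        if len(cols) < 2:
            raise ValueError("need at least 2 features to prune")
        rho = spearmanr(X.to_numpy()).statistic
        if np.ndim(rho) == 0:  # exactly two features
            rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        rng = np.random.default_rng(self.random_state)
        retained = dict.fromkeys(cols, True)
        dropped = []
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                if not (retained[cols[i]] and retained[cols[j]]):
                    continue
                if np.abs(rho[i, j]) >= self.threshold:
                    victim = cols[i] if rng.random() < 0.5 else cols[j]
                    retained[victim] = False
                    dropped.append(victim)
        self.feature_names_in_ = np.asarray(cols, dtype=object)
        self.retained_ = [c for c in cols if retained[c]]
        self.dropped_ = dropped
        return self

    def transform(self, X):
        X = _as_frame(X, getattr(self, "feature_names_in_", None))
        return X[self.retained_]


class FgvRegressor(BaseEstimator, RegressorMixin):
    """Random-forest regressor for percent fibroglandular volume.

    Wraps :class:`sklearn.ensemble.RandomForestRegressor` with library-default
    per-split feature sampling and unlimited depth, and exposes the Gini
    importance ranking (``importance_ranking_``) the analysis is built
    around.
    """

    def __init__(self, n_estimators: int = 500, max_depth=None,
                 max_features="sqrt", random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        X = _as_frame(X)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.model_ = RandomForestRegressor(
            n_estimators=self.n_estimators, max_depth=self.max_depth,
            max_features=self.max_features, random_state=self.random_state,
            n_jobs=1)
        self.model_.fit(X.to_numpy(), np.asarray(y, dtype=float))
        self.feature_importances_ = self.model_.feature_importances_
        self.importance_ranking_ = _ranking_from_importances(
            self.feature_names_in_, self.feature_importances_)
        return self

    def predict(self, X):
        X = _as_frame(X, self.feature_names_in_)
        return self.model_.predict(X[list(self.feature_names_in_)].to_numpy())

    def spearman_score(self, X, y) -> float:
        """Spearman rank correlation between predictions and actuals."""
        y = np.asarray(y, dtype=float)
        if len(y) < 3:
            raise ValueError("need at least 3 observations for Spearman r")
        return float(spearmanr(self.predict(X), y).statistic)


class CancerClassifier(BaseEstimator, ClassifierMixin):
    """Random-forest classifier for invasive vs benign diagnosis."""

    def __init__(self, n_estimators: int = 500, max_depth=None,
                 max_features="sqrt", random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        X = _as_frame(X)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise DegenerateStratumError("training data has a single class")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.model_ = RandomForestClassifier(
            n_estimators=self.n_estimators, max_depth=self.max_depth,
            max_features=self.max_features, random_state=self.random_state,
            n_jobs=1)
        self.model_.fit(X.to_numpy(), y)
        self.classes_ = self.model_.classes_
        self.feature_importances_ = self.model_.feature_importances_
        self.importance_ranking_ = _ranking_from_importances(
            self.feature_names_in_, self.feature_importances_)
        return self

    def predict(self, X):
        X = _as_frame(X, self.feature_names_in_)
        return self.model_.predict(X[list(self.feature_names_in_)].to_numpy())

    def predict_proba(self, X):
        X = _as_frame(X, self.feature_names_in_)
        return self.model_.predict_proba(
            X[list(self.feature_names_in_)].to_numpy())

    def invasive_probability(self, X) -> np.ndarray:
        """Predicted probability of the positive (invasive = 1) class."""
        proba = self.predict_proba(X)
        pos = int(np.where(self.classes_ == 1)[0][0])
        return proba[:, pos]


# ---------------------------------------------------------------------------
# cohort-table convenience wrappers


def _feature_columns(cohort: pd.DataFrame, covariates=()) -> list[str]:
    cols = [c for c in FEATURE_NAMES if c in cohort.columns]
    missing = set(FEATURE_NAMES) - set(cols)
    if missing:
        raise ValueError(f"cohort table is missing features: {sorted(missing)}")
    return cols + [c for c in covariates if c in cohort.columns]


def train_fgv_regressor(cohort: pd.DataFrame, target: str,
                        rf_params: dict | None = None, seed: int = 0,
                        covariates=()):
    """Fit the FGV regressor on the training split only.

    Returns ``(model, ranking)``; ``ranking`` is a DataFrame with columns
    feature/importance/rank over all input features.
    """
    if target not in cohort.columns:
        raise ValueError(f"target column {target!r} absent from cohort table")
    cols = _feature_columns(cohort, covariates)
    train = cohort[cohort["split"] == "train"]
    if len(train) == 0:
        raise ValueError("training split is empty")
    params = dict(DEFAULT_RF_PARAMS, **(rf_params or {}))
    model = FgvRegressor(random_state=seed, **params)
    model.fit(train[cols], train[target])
    return model, model.importance_ranking_


def predict_and_correlate(model: FgvRegressor, cohort: pd.DataFrame,
                          target: str) -> float:
    """Spearman r between predicted and actual target on the test split."""
    test = cohort[cohort["split"] == "test"]
    if len(test) < 3:
        raise ValueError("need at least 3 test patients")
    return model.spearman_score(test[list(model.feature_names_in_)],
                                test[target])


def prune_correlated(features: pd.DataFrame, threshold: float = 0.85,
                     seed: int = 0) -> list[str]:
    """Retained feature names after correlation pruning (see CorrelationPruner)."""
    pruner = CorrelationPruner(threshold=threshold, random_state=seed)
    pruner.fit(features)
    return pruner.retained_


def stratify_by_median(cohort: pd.DataFrame, target: str):
    """High/low stratification at the training-population median.

    Returns ``(cutpoint, strata)``: the cutpoint is the median of ``target``
    over training patients; ``strata`` is a Series aligned with ``cohort``
    holding ``"high"`` (> cutpoint) or ``"low"`` (<= cutpoint, ties to low).
    """
    train = cohort[cohort["split"] == "train"]
    if len(train) == 0:
        raise ValueError("training split is empty")
    cutpoint = float(np.median(train[target].to_numpy()))
    strata = pd.Series(
        np.where(cohort[target].to_numpy() > cutpoint, "high", "low"),
        index=cohort.index, name="stratum")
    return cutpoint, strata


def worst_diagnosis(diagnoses) -> str:
    """Patient-level diagnosis: the most severe across biopsies."""
    severity = {d: i for i, d in enumerate((
        "benign_nonproliferative", "proliferative", "atypia",
        "insitu", "invasive"))}
    return max(diagnoses, key=lambda d: severity[d])


def prepare_cancer_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Drop in-situ patients and add a binary ``invasive`` outcome column."""
    out = cohort[~cohort["diagnosis"].isin(EXCLUDED_DIAGNOSES)].copy()
    out["invasive"] = (out["diagnosis"] == "invasive").astype(int)
    return out


def train_cancer_classifier(stratum: pd.DataFrame,
                            rf_params: dict | None = None, seed: int = 0,
                            covariates=()):
    """Fit the invasive-vs-benign classifier on one FGV stratum.

    ``stratum`` must already be restricted to one stratum's patients (in-situ
    not yet excluded: they are dropped here).  Returns a dict with the fitted
    model, the importance ranking, and per-patient test scores
    (patient_id, score, truth).
    """
    data = prepare_cancer_cohort(stratum)
    cols = _feature_columns(data, covariates)
    train = data[data["split"] == "train"]
    test = data[data["split"] == "test"]
    for name, part in (("train", train), ("test", test)):
        if part["invasive"].nunique() < 2:
            raise DegenerateStratumError(
                f"{name} split of stratum has a single outcome class "
                f"(n={len(part)})")
    params = dict(DEFAULT_RF_PARAMS, **(rf_params or {}))
    model = CancerClassifier(random_state=seed, **params)
    model.fit(train[cols], train["invasive"])
    scores = pd.DataFrame({
        "patient_id": test["patient_id"].to_numpy(),
        "score": model.invasive_probability(test[cols]),
        "truth": test["invasive"].to_numpy(),
    })
    return {"model": model, "ranking": model.importance_ranking_,
            "scores": scores,
            "n_train": len(train), "n_test": len(test)}
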