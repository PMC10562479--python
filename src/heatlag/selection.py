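"""Boruta feature selection with SHAP importances on gradient-boosted trees.

Each trial appends a shuffled "shadow" copy of every feature, fits a
LightGBM regressor on the augmented matrix and scores each original feature
by its mean absolute SHAP value (computed with LightGBM's exact tree-SHAP).
A feature scores a hit when its importance exceeds the best shadow
importance.  Hit counts are compared against Binomial(n_active_trials, 1/2)
two-sided with a Bonferroni correction across the features still in play:
significantly many hits -> accepted, significantly few -> rejected,
otherwise tentative.  As in the original Boruta procedure the test is
applied periodically and rejected features (with their shadows) are removed
before further trials, so redundant informative features are no longer
drowned by a large shadow maximum.  Tentative features left at the trial
budget are treated as not selected downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = ["shadow_augment", "run_boruta_shap", "BorutaSHAPSelector", "SelectionResult"]

SHADOW_PREFIX = "shadow__"

DEFAULT_LEARNER_PARAMS: dict = {
    "n_estimators": 60,
    "num_leaves": 31,
    "learning_rate": 0.1,
    "min_child_samples": 10,
    "verbosity": -1,
    "deterministic": True,
    "force_row_wise": True,
    "n_jobs": 1,
}


class SelectionResult(pd.DataFrame):
    """Per-feature selection verdicts (a plain DataFrame with helpers).

    Columns: feature, status (accepted|rejected|tentative), hits, n_trials,
    mean_importance.
    """

    @property
    def _constructor(self):
        return SelectionResult

    @property
    def accepted(self) -> list[str]:
        return list(self.loc[self["status"] == "accepted", "feature"])

    @property
    def rejected(self) -> list[str]:
        return list(self.loc[self["status"] == "rejected", "feature"])

    @property
    def tentative(self) -> list[str]:
        return list(self.loc[self["status"] == "tentative", "feature"])

    def to_json(self, path) -> None:  # type: ignore[override]
        import json
        from pathlib import Path

        payload = {
            row.feature: {
                "status": row.status,
                "hits": int(row.hits),
                "n_trials": int(row.n_trials),
                "mean_importance": float(row.mean_importance),
            }
            for row in self.itertuples()
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def shadow_augment(X: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Append an independently row-permuted shadow copy of every column."""
    shadows = {}
    for col in X.columns:
        perm = rng.permutation(len(X))
        shadows[f"{SHADOW_PREFIX}{col}"] = X[col].to_numpy()[perm]
    shadow_df = pd.DataFrame(shadows, index=X.index)
    for col in X.columns:  # preserve categorical dtype in shadows
        if isinstance(X[col].dtype, pd.CategoricalDtype):
            shadow_df[f"{SHADOW_PREFIX}{col}"] = shadow_df[f"{SHADOW_PREFIX}{col}"].astype(
                X[col].dtype
            )
    return pd.concat([X, shadow_df], axis=1)


def _mean_abs_shap(model: LGBMRegressor, X: pd.DataFrame) -> np.ndarray:
    contrib = model.predict(X, pred_contrib=True)
    return np.abs(contrib[:, :-1]).mean(axis=0)  # last column is the base value


class BorutaSHAPSelector(BaseEstimator):
    """Boruta-SHAP feature selector (scikit-learn style).

    Fitted attributes: ``result_`` (:class:`SelectionResult`), ``support_``
    (boolean mask of accepted features), ``n_features_in_``.
    """

    def __init__(
        self,
        n_trials: int = 50,
        alpha: float = 0.05,
        learner_params: dict | None = None,
        test_every: int = 10,
        random_state: int = 0,
    ):
        self.n_trials = n_trials
        self.alpha = alpha
        self.learner_params = learner_params
        self.test_every = test_every
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y) -> "BorutaSHAPSelector":
        if self.n_trials < 10:
            raise ValueError("n_trials must be >= 10")
        X = pd.DataFrame(X).reset_index(drop=True)
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X and y must align")
        if np.std(y) == 0.0:
            raise ValueError("constant response: selection fit is degenerate")

        params = dict(DEFAULT_LEARNER_PARAMS)
        params.update(self.learner_params or {})
        features = list(X.columns)
        active = list(features)
        hits = {f: 0 for f in features}
        n_active = {f: 0 for f in features}
        importance_sum = {f: 0.0 for f in features}
        status = {f: "tentative" for f in features}

        root = np.random.default_rng([int(self.random_state) % (2**31), 7])
        for trial in range(self.n_trials):
            if not active:
                break
            rng = np.random.default_rng(root.integers(0, 2**31, size=2))
            X_aug = shadow_augment(X[active], rng)
            model = LGBMRegressor(random_state=int(rng.integers(0, 2**31)), **params)
            model.fit(X_aug, y)
            imp = _mean_abs_shap(model, X_aug)
            shadow_max = imp[len(active):].max()
            for f, v in zip(active, imp[: len(active)]):
                hits[f] += int(v > shadow_max)
                n_active[f] += 1
                importance_sum[f] += v
            if (trial + 1) % self.test_every == 0 or trial == self.n_trials - 1:
                alpha_adj = self.alpha / (2.0 * len(active))  # two-sided + Bonferroni
                for f in list(active):
                    if stats.binom.sf(hits[f] - 1, n_active[f], 0.5) < alpha_adj:
                        status[f] = "accepted"
                    elif stats.binom.cdf(hits[f], n_active[f], 0.5) < alpha_adj:
                        status[f] = "rejected"
                        active.remove(f)

        self.result_ = SelectionResult(
            {
                "feature": features,
                "status": [status[f] for f in features],
                "hits": [hits[f] for f in features],
                "n_trials": [n_active[f] for f in features],
                "mean_importance": [
                    importance_sum[f] / n_active[f] if n_active[f] else 0.0
                    for f in features
                ],
            }
        )
        self.support_ = np.array([status[f] == "accepted" for f in features])
        self.n_features_in_ = len(features)
        self.feature_names_in_ = np.array(features, dtype=object)
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X).loc[:, self.support_]

    def fit_transform(self, X, y) -> pd.DataFrame:
        return self.fit(X, y).transform(X)


def run_boruta_shap(
    X: pd.DataFrame,
    y,
    n_trials: int = 50,
    alpha: float = 0.05,
    learner_params: dict | None = None,
    seed: int = 0,
) -> SelectionResult:
    """Functional wrapper returning the per-feature :class:`SelectionResult`."""
    sel = BorutaSHAPSelector(
        n_trials=n_trials, alpha=alpha, learner_params=learner_params, random_state=seed
    )
    return sel.fit(X, y).result_
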