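"""Cross-validated gradient-boosted regression of the daily relative risk.

The only searched hyperparameter is LightGBM's ``num_leaves`` (grid 10..100
by default); the k-fold split is fixed before the search so every grid value
is scored on identical folds.  The fitted bundle keeps the k fold models,
the fold assignment, the concatenated out-of-fold "hindcast" and its
RMSE / MAE / ratio metrics.  SHAP dependence values come from LightGBM's
exact tree-SHAP (``pred_contrib``), evaluated per fold on that fold's
held-out rows so the attribution is out-of-sample like the hindcast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import GroupKFold, KFold

__all__ = ["evaluate", "DRRBoostRegressor", "tune_and_fit", "shap_dependence",
           "NoImportantFeaturesError"]


class NoImportantFeaturesError(ValueError):
    """Raised when model fitting is requested with an empty feature set."""


DEFAULT_LEARNER_PARAMS: dict = {
    "n_estimators": 200,
    "learning_rate": 0.05,
    "min_child_samples": 10,
    "verbosity": -1,
    "deterministic": True,
    "force_row_wise": True,
    "n_jobs": 1,
}


def evaluate(y_true, y_pred) -> tuple[float, float, float]:
    """Root-mean-square error, mean absolute error and their ratio."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    err = y_pred - y_true
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    ratio = rmse / mae if mae > 0 else float("nan")
    return rmse, mae, ratio


class DRRBoostRegressor(BaseEstimator, RegressorMixin):
    """num_leaves-tuned, k-fold cross-validated LightGBM DRR regressor.

    Fitted attributes
    -----------------
    best_num_leaves_ : chosen grid value (ties resolved to the smaller).
    boosters_ : the k fold models trained with the chosen value.
    fold_assignment_ : test-fold index of every training row.
    oof_prediction_ : out-of-fold prediction for every training row.
    metrics_ : dict with ``rmse``, ``mae``, ``ratio`` of the hindcast.
    cv_results_ : DataFrame of CV RMSE per grid value.
    """

    def __init__(
        self,
        leaves_grid: tuple[int, ...] = tuple(range(10, 101, 10)),
        k: int = 10,
        fold_scheme: str = "random",
        learner_params: dict | None = None,
        random_state: int = 0,
    ):
        self.leaves_grid = leaves_grid
        self.k = k
        self.fold_scheme = fold_scheme
        self.learner_params = learner_params
        self.random_state = random_state

    def _folds(self, X: pd.DataFrame, dates) -> list[tuple[np.ndarray, np.ndarray]]:
        if self.fold_scheme == "by_year":
            if dates is None:
                raise ValueError("fold_scheme='by_year' requires dates")
            groups = pd.to_datetime(pd.Series(dates)).dt.year.to_numpy()
            k = min(self.k, len(np.unique(groups)))
            return list(GroupKFold(n_splits=k).split(X, groups=groups))
        kf = KFold(n_splits=self.k, shuffle=True, random_state=int(self.random_state))
        return list(kf.split(X))

    def fit(self, X: pd.DataFrame, y, dates=None) -> "DRRBoostRegressor":
        X = pd.DataFrame(X).reset_index(drop=True)
        y = np.asarray(y, dtype=float)
        if X.shape[1] == 0:
            raise NoImportantFeaturesError(
                "no important features: the selection stage accepted nothing, "
                "so no model can be trained"
            )
        if len(X) < self.k:
            raise ValueError(f"need at least k={self.k} rows")
        params = dict(DEFAULT_LEARNER_PARAMS)
        params.update(self.learner_params or {})
        folds = self._folds(X, dates)

        grid = sorted(int(g) for g in self.leaves_grid)
        cv_rmse = []
        for leaves in grid:
            oof = np.empty(len(X))
            for fold_i, (tr, te) in enumerate(folds):
                m = LGBMRegressor(num_leaves=leaves,
                                  random_state=int(self.random_state) + fold_i, **params)
                m.fit(X.iloc[tr], y[tr])
                oof[te] = m.predict(X.iloc[te])
            cv_rmse.append(evaluate(y, oof)[0])
        best_idx = int(np.argmin(cv_rmse))  # first minimum -> smaller num_leaves
        self.best_num_leaves_ = grid[best_idx]
        self.cv_results_ = pd.DataFrame({"num_leaves": grid, "cv_rmse": cv_rmse})

        self.boosters_ = []
        self.fold_assignment_ = np.empty(len(X), dtype=int)
        self.oof_prediction_ = np.empty(len(X))
        self.fold_test_indices_ = []
        for fold_i, (tr, te) in enumerate(folds):
            m = LGBMRegressor(num_leaves=self.best_num_leaves_,
                              random_state=int(self.random_state) + fold_i, **params)
            m.fit(X.iloc[tr], y[tr])
            self.boosters_.append(m)
            self.fold_assignment_[te] = fold_i
            self.oof_prediction_[te] = m.predict(X.iloc[te])
            self.fold_test_indices_.append(te)
        rmse, mae, ratio = evaluate(y, self.oof_prediction_)
        self.metrics_ = {"rmse": rmse, "mae": mae, "ratio": ratio}
        self.feature_names_in_ = np.array(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self._train_X = X
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Fold-averaged prediction for new days."""
        X = pd.DataFrame(X)[list(self.feature_names_in_)]
        preds = np.stack([m.predict(X) for m in self.boosters_])
        return preds.mean(axis=0)

    def shap_values(self, X: pd.DataFrame | None = None) -> pd.DataFrame:
        """Per-row, per-feature SHAP values (plus base value).

        With ``X=None`` the training rows are attributed out-of-fold: each
        row is explained by the model that did not train on it.  Otherwise
        the fold models' SHAP values on ``X`` are averaged.
        """
        cols = list(self.feature_names_in_) + ["__base__"]
        if X is None:
            out = np.empty((len(self._train_X), len(cols)))
            for fold_i, te in enumerate(self.fold_test_indices_):
                contrib = self.boosters_[fold_i].predict(
                    self._train_X.iloc[te], pred_contrib=True
                )
                out[te] = contrib
            return pd.DataFrame(out, columns=cols)
        X = pd.DataFrame(X)[list(self.feature_names_in_)]
        contribs = np.stack([m.predict(X, pred_contrib=True) for m in self.boosters_])
        return pd.DataFrame(contribs.mean(axis=0), columns=cols, index=X.index)


def tune_and_fit(
    X: pd.DataFrame,
    y,
    k: int = 10,
    leaves_grid: tuple[int, ...] = tuple(range(10, 101, 10)),
    seed: int = 0,
    fold_scheme: str = "random",
    learner_params: dict | None = None,
    dates=None,
) -> DRRBoostRegressor:
    """Functional wrapper mirroring the estimator interface."""
    model = DRRBoostRegressor(
        leaves_grid=leaves_grid, k=k, fold_scheme=fold_scheme,
        learner_params=learner_params, random_state=seed,
    )
    return model.fit(X, y, dates=dates)


def shap_dependence(model: DRRBoostRegressor, X: pd.DataFrame | None = None) -> pd.DataFrame:
    """Out-of-fold (or new-data) SHAP values; see ``DRRBoostRegressor.shap_values``."""
    return model.shap_values(X)
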