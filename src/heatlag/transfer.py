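"""SMOGN rare-value over-sampling and feature-augmentation transfer learning.

SMOGN (SMOTE-for-regression with Gaussian noise) synthesises extra training
days around the upper tail of the response: rows with DRR at or above the
``rare_quantile`` (default: the upper 10%) seed new rows either by
interpolating toward a near rare neighbor or, when the chosen neighbor is
far, by Gaussian perturbation scaled to per-feature spread.  The rare-row
count is grown to ``ceil(target_multiplier x original)``.

Transfer learning uses homogeneous feature augmentation: a source-domain row
x maps to <x, x, 0> and a target-domain row to <x, 0, x>, tripling the
feature width so a single learner can share a common effect while
specialising per domain.  Here the hotter city is the source and the cooler
city (whose future is being projected) is the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .model import DRRBoostRegressor

__all__ = [
    "SMOGNResampler",
    "ResampledSet",
    "smogn_resample",
    "augment_features",
    "FeatureAugmenter",
    "TransferRegressor",
    "train_tl",
]


@dataclass
class ResampledSet:
    """Original plus synthetic rows; ``synthetic`` flags the generated ones."""

    X: pd.DataFrame
    y: np.ndarray
    synthetic: np.ndarray
    rare_threshold: float
    parents: list[tuple[int, int]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = self.X.copy()
        out["drr"] = self.y
        out["synthetic"] = self.synthetic.astype(int)
        return out


class SMOGNResampler(BaseEstimator):
    """SMOTE-for-regression over-sampler of rare high-response days.

    ``fixed_interp_weight`` pins the interpolation weight (normally uniform
    on [0, 1]) to a constant; with weight 0 and ``noise_scale`` 0 every
    synthetic row duplicates its seed row exactly, which is useful for
    auditing the resampling plumbing.
    """

    def __init__(
        self,
        rare_quantile: float = 0.90,
        k_neighbors: int = 5,
        noise_scale: float = 0.05,
        target_multiplier: float = 1.3,
        fixed_interp_weight: float | None = None,
        random_state: int = 0,
    ):
        self.rare_quantile = rare_quantile
        self.k_neighbors = k_neighbors
        self.noise_scale = noise_scale
        self.target_multiplier = target_multiplier
        self.fixed_interp_weight = fixed_interp_weight
        self.random_state = random_state

    def fit_resample(self, X: pd.DataFrame, y) -> ResampledSet:
        X = pd.DataFrame(X).reset_index(drop=True)
        num = X.select_dtypes(include=[np.number])
        if num.shape[1] != X.shape[1]:
            raise ValueError(
                "SMOGN requires numeric features; encode or drop categorical columns"
            )
        y = np.asarray(y, dtype=float)
        threshold = float(np.quantile(y, self.rare_quantile))
        rare_idx = np.flatnonzero(y >= threshold)
        if len(rare_idx) < self.k_neighbors + 1:
            raise ValueError(
                f"only {len(rare_idx)} rare rows at quantile {self.rare_quantile}; "
                f"need at least k_neighbors+1 = {self.k_neighbors + 1}"
            )
        n_rare = len(rare_idx)
        n_new = int(np.ceil(self.target_multiplier * n_rare)) - n_rare

        values = X.to_numpy(dtype=float)
        scale = values.std(axis=0, ddof=0)
        scale[scale == 0.0] = 1.0
        rare = values[rare_idx] / scale

        # pairwise distances among rare rows; the near/far cutoff is half the
        # median pairwise distance (SMOGN convention)
        diff = rare[:, None, :] - rare[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        iu = np.triu_indices(n_rare, k=1)
        cutoff = 0.5 * float(np.median(dist[iu])) if len(iu[0]) else 0.0

        rng = np.random.default_rng([int(self.random_state) % (2**31), 11])
        y_sd = float(np.std(y, ddof=0))
        new_rows, new_y, parents = [], [], []
        for _ in range(n_new):
            si = int(rng.integers(n_rare))
            order = np.argsort(dist[si])
            neighbors = [j for j in order if j != si][: self.k_neighbors]
            ni = int(neighbors[rng.integers(len(neighbors))])
            seed_row = values[rare_idx[si]]
            if dist[si, ni] <= cutoff:
                u = (self.fixed_interp_weight if self.fixed_interp_weight is not None
                     else float(rng.uniform()))
                row = seed_row + u * (values[rare_idx[ni]] - seed_row)
                yv = y[rare_idx[si]] + u * (y[rare_idx[ni]] - y[rare_idx[si]])
            else:
                row = seed_row + rng.normal(0.0, self.noise_scale * scale)
                yv = y[rare_idx[si]] + rng.normal(0.0, self.noise_scale * y_sd)
            new_rows.append(row)
            new_y.append(yv)
            parents.append((int(rare_idx[si]), int(rare_idx[ni])))

        if new_rows:
            X_out = pd.concat(
                [X, pd.DataFrame(np.vstack(new_rows), columns=X.columns)],
                ignore_index=True,
            )
            y_out = np.concatenate([y, np.asarray(new_y)])
        else:
            X_out, y_out = X.copy(), y.copy()
        synthetic = np.zeros(len(X_out), dtype=bool)
        synthetic[len(X):] = True
        return ResampledSet(X=X_out, y=y_out, synthetic=synthetic,
                            rare_threshold=threshold, parents=parents)


def smogn_resample(X, y, rare_quantile=0.90, k_neighbors=5, noise_scale=0.05,
                   target_multiplier=1.3, seed=0, **kwargs) -> ResampledSet:
    return SMOGNResampler(
        rare_quantile=rare_quantile, k_neighbors=k_neighbors, noise_scale=noise_scale,
        target_multiplier=target_multiplier, random_state=seed, **kwargs
    ).fit_resample(X, y)


def augment_features(
    X_source: pd.DataFrame | None, X_target: pd.DataFrame | None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Stack source and target rows into the 3F-wide augmented space.

    Returns the augmented matrix with blocks <common, source, target> and a
    per-row domain label array ('source' / 'target').
    """
    frames = [f for f in (X_source, X_target) if f is not None and len(f)]
    if not frames:
        raise ValueError("at least one non-empty domain is required")
    columns = list(frames[0].columns)
    for f in frames[1:]:
        if list(f.columns) != columns:
            raise ValueError("source and target must share feature names and order")

    aug = FeatureAugmenter(columns)
    parts, labels = [], []
    if X_source is not None and len(X_source):
        parts.append(aug.transform(X_source, domain="source"))
        labels.append(np.full(len(X_source), "source", dtype=object))
    if X_target is not None and len(X_target):
        parts.append(aug.transform(X_target, domain="target"))
        labels.append(np.full(len(X_target), "target", dtype=object))
    return pd.concat(parts, ignore_index=True), np.concatenate(labels)


class FeatureAugmenter(BaseEstimator):
    """Maps rows into <common, source-specific, target-specific> blocks."""

    def __init__(self, columns: list[str] | None = None):
        self.columns = columns

    def fit(self, X: pd.DataFrame, y=None) -> "FeatureAugmenter":
        self.columns = list(pd.DataFrame(X).columns)
        return self

    def augmented_columns(self) -> list[str]:
        c = list(self.columns)
        return c + [f"src__{v}" for v in c] + [f"tgt__{v}" for v in c]

    def transform(self, X: pd.DataFrame, domain: str = "target") -> pd.DataFrame:
        if domain not in ("source", "target"):
            raise ValueError("domain must be 'source' or 'target'")
        X = pd.DataFrame(X)[list(self.columns)].reset_index(drop=True)
        zeros = pd.DataFrame(0.0, index=X.index, columns=self.columns)
        src = X if domain == "source" else zeros
        tgt = X if domain == "target" else zeros
        out = pd.concat(
            [X, src.add_prefix("src__"), tgt.add_prefix("tgt__")], axis=1
        )
        return out


class TransferRegressor(BaseEstimator, RegressorMixin):
    """Feature-augmentation transfer learner over the boosted DRR model.

    The target set is optionally SMOGN-resampled before pooling; the pooled
    augmented rows train one :class:`DRRBoostRegressor`.  ``predict`` maps
    new target-domain days through the target block.
    """

    def __init__(
        self,
        use_smogn: bool = True,
        smogn_params: dict | None = None,
        leaves_grid: tuple[int, ...] = tuple(range(10, 101, 10)),
        k: int = 10,
        learner_params: dict | None = None,
        random_state: int = 0,
    ):
        self.use_smogn = use_smogn
        self.smogn_params = smogn_params
        self.leaves_grid = leaves_grid
        self.k = k
        self.learner_params = learner_params
        self.random_state = random_state

    def fit(self, X_source: pd.DataFrame, y_source, X_target: pd.DataFrame, y_target
            ) -> "TransferRegressor":
        X_source = pd.DataFrame(X_source).reset_index(drop=True)
        X_target = pd.DataFrame(X_target).reset_index(drop=True)
        y_source = np.asarray(y_source, dtype=float)
        y_target = np.asarray(y_target, dtype=float)

        if self.use_smogn:
            resampler = SMOGNResampler(
                random_state=self.random_state, **(self.smogn_params or {})
            )
            res = resampler.fit_resample(X_target, y_target)
            X_target_fit, y_target_fit = res.X, res.y
            self.resampled_target_ = res
        else:
            X_target_fit, y_target_fit = X_target, y_target
            self.resampled_target_ = None

        X_aug, domains = augment_features(X_source, X_target_fit)
        y_aug = np.concatenate([y_source, y_target_fit])
        self.augmenter_ = FeatureAugmenter(list(X_source.columns))
        self.domains_ = domains
        self.model_ = DRRBoostRegressor(
            leaves_grid=self.leaves_grid, k=self.k,
            learner_params=self.learner_params, random_state=self.random_state,
        ).fit(X_aug, y_aug)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        X_aug = self.augmenter_.transform(pd.DataFrame(X), domain="target")
        return self.model_.predict(X_aug)


def train_tl(
    X_source, y_source, X_target, y_target,
    use_smogn: bool = True, smogn_params: dict | None = None,
    leaves_grid=tuple(range(10, 101, 10)), k: int = 10,
    learner_params: dict | None = None, seed: int = 0,
) -> TransferRegressor:
    return TransferRegressor(
        use_smogn=use_smogn, smogn_params=smogn_params, leaves_grid=leaves_grid,
        k=k, learner_params=learner_params, random_state=seed,
    ).fit(X_source, y_source, X_target, y_target)
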