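"""SMOGN over-sampling and feature-augmentation transfer learning."""

import numpy as np
import pandas as pd
import pytest

from heatlag.transfer import (FeatureAugmenter, SMOGNResampler, TransferRegressor,
                              augment_features)

FAST = {"n_estimators": 40}


@pytest.fixture()
def drr_like():
    rng = np.random.default_rng(0)
    n = 400
    X = pd.DataFrame({"Tmax": rng.normal(31, 2.5, n), "AcTmax30": np.abs(rng.normal(60, 40, n))})
    y = 1.0 + 0.1 * np.clip(X["Tmax"] - 30, 0, None) + 0.15 * rng.normal(size=n)
    return X, y.to_numpy()


class TestSMOGN:
    def test_originals_preserved_and_count_multiplied(self, drr_like):
        X, y = drr_like
        res = SMOGNResampler(target_multiplier=1.3, random_state=0).fit_resample(X, y)
        pd.testing.assert_frame_equal(res.X.iloc[: len(X)], X)
        np.testing.assert_allclose(res.y[: len(y)], y)
        n_rare = int((y >= np.quantile(y, 0.9)).sum())
        expected_new = int(np.ceil(1.3 * n_rare)) - n_rare
        assert res.synthetic.sum() == expected_new
        assert not res.synthetic[: len(X)].any()

    def test_degenerate_parameters_duplicate_seed_rows(self, drr_like):
        X, y = drr_like
        res = SMOGNResampler(noise_scale=0.0, fixed_interp_weight=0.0,
                             random_state=1).fit_resample(X, y)
        originals = res.X.iloc[: len(X)].to_numpy()
        for row in res.X.iloc[len(X):].to_numpy():
            assert (np.abs(originals - row).max(axis=1) < 1e-12).any()

    def test_interpolated_rows_lie_between_parents(self, drr_like):
        X, y = drr_like
        res = SMOGNResampler(noise_scale=0.0, random_state=2).fit_resample(X, y)
        values = X.to_numpy()
        for k, (si, ni) in enumerate(res.parents):
            row = res.X.iloc[len(X) + k].to_numpy()
            lo = np.minimum(values[si], values[ni]) - 1e-9
            hi = np.maximum(values[si], values[ni]) + 1e-9
            assert ((row >= lo) & (row <= hi)).all()

    def test_synthetic_response_dominates_full_distribution(self, drr_like):
        X, y = drr_like
        res = SMOGNResampler(target_multiplier=2.0, random_state=3).fit_resample(X, y)
        syn_y = res.y[res.synthetic]
        for q in (0.1, 0.5, 0.9):
            assert np.quantile(syn_y, q) >= np.quantile(y, q)

    def test_too_few_rare_rows_is_an_error(self, drr_like):
        X, y = drr_like
        with pytest.raises(ValueError, match="rare rows"):
            SMOGNResampler(rare_quantile=0.999).fit_resample(X, y)

    def test_categorical_features_rejected(self, drr_like):
        X, y = drr_like
        X = X.assign(DOW=pd.Categorical(["Mon"] * len(X)))
        with pytest.raises(ValueError, match="numeric"):
            SMOGNResampler().fit_resample(X, y)

    def test_seeded_determinism(self, drr_like):
        X, y = drr_like
        a = SMOGNResampler(random_state=5).fit_resample(X, y)
        b = SMOGNResampler(random_state=5).fit_resample(X, y)
        pd.testing.assert_frame_equal(a.X, b.X)
        np.testing.assert_allclose(a.y, b.y)


class TestAugmentation:
    def test_worked_example(self):
        src = pd.DataFrame([[1.0, 2.0]], columns=["a", "b"])
        tgt = pd.DataFrame([[1.0, 2.0]], columns=["a", "b"])
        aug, domains = augment_features(src, tgt)
        np.testing.assert_allclose(aug.iloc[0], [1, 2, 1, 2, 0, 0])
        np.testing.assert_allclose(aug.iloc[1], [1, 2, 0, 0, 1, 2])
        assert list(domains) == ["source", "target"]

    def test_width_is_exactly_three_f(self, drr_like):
        X, _ = drr_like
        aug, _ = augment_features(X.iloc[:50], X.iloc[50:100])
        assert aug.shape[1] == 3 * X.shape[1]

    def test_zero_block_pattern_for_every_row(self, drr_like):
        X, _ = drr_like
        ns = 37
        aug, domains = augment_features(X.iloc[:ns], X.iloc[ns:100])
        f = X.shape[1]
        src_block = aug.iloc[:, f: 2 * f].to_numpy()
        tgt_block = aug.iloc[:, 2 * f:].to_numpy()
        common = aug.iloc[:, :f].to_numpy()
        is_src = domains == "source"
        assert np.all(tgt_block[is_src] == 0) and np.all(src_block[~is_src] == 0)
        np.testing.assert_allclose(src_block[is_src], common[is_src])
        np.testing.assert_allclose(tgt_block[~is_src], common[~is_src])

    def test_empty_source_still_three_f_wide(self, drr_like):
        X, _ = drr_like
        aug, domains = augment_features(None, X.iloc[:20])
        assert aug.shape == (20, 3 * X.shape[1])
        assert set(domains) == {"target"}

    def test_mismatched_columns_rejected(self, drr_like):
        X, _ = drr_like
        with pytest.raises(ValueError, match="share feature names"):
            augment_features(X, X.rename(columns={"Tmax": "T"}))

    def test_transformer_roundtrip(self, drr_like):
        X, _ = drr_like
        aug = FeatureAugmenter().fit(X)
        out = aug.transform(X.iloc[:5], domain="target")
        assert list(out.columns) == aug.augmented_columns()


class TestTransferRegressor:
    def test_fit_predict_deterministic(self, drr_like):
        X, y = drr_like
        kw = dict(leaves_grid=(20,), k=4, learner_params=FAST, random_state=0)
        a = TransferRegressor(**kw).fit(X.iloc[:200], y[:200], X.iloc[200:], y[200:])
        b = TransferRegressor(**kw).fit(X.iloc[:200], y[:200], X.iloc[200:], y[200:])
        np.testing.assert_allclose(a.predict(X.iloc[:30]), b.predict(X.iloc[:30]))

    def test_pooled_training_respects_block_structure(self, drr_like):
        X, y = drr_like
        model = TransferRegressor(leaves_grid=(20,), k=4, learner_params=FAST,
                                  random_state=0).fit(
            X.iloc[:200], y[:200], X.iloc[200:], y[200:]
        )
        f = X.shape[1]
        aug_cols = model.augmenter_.augmented_columns()
        assert len(aug_cols) == 3 * f
        assert (model.domains_ == "source").sum() == 200
        res = model.resampled_target_
        assert res is not None and res.synthetic.any()
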