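"""End-to-end orchestration of the analysis pipeline.

Stage order (enforced; no stage reads a later stage's output):

  simulate -> DLNM lag specification -> features -> selection
           -> training (hindcast, no-TL future, TL future) -> projection

Every stage writes its artifact under the output directory, and a
machine-readable manifest (config hash, seeds, package versions, artifact
digests) plus a human-readable log are emitted at the end.  With a fixed
configuration and seed the CSV/JSON artifacts are byte-identical across
runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .dlnm import DLNM
from .features import (ELEMENT_COLUMNS, LagSpec, build_feature_table,
                       compute_drr, write_feature_table)
from .model import DRRBoostRegressor
from .projection import percentile_change
from .selection import BorutaSHAPSelector
from .simulate import (generate_future_weather, generate_mortality,
                       generate_weather, write_mortality, write_weather)
from .transfer import TransferRegressor

__all__ = ["run_pipeline", "PipelineStageError"]

log = logging.getLogger("heatlag")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and a digest of its input."""

    def __init__(self, stage: str, input_digest: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed (input {input_digest}): {cause}")
        self.stage = stage
        self.input_digest = input_digest
        self.__cause__ = cause


def _digest(obj: Any) -> str:
    try:
        blob = json.dumps(obj, sort_keys=True, default=str).encode()
    except TypeError:
        blob = repr(obj).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _stage(name: str, fn, *args, digest_of=None, **kwargs):
    log.info("stage %s: start", name)
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        raise PipelineStageError(name, _digest(digest_of), exc) from exc
    log.info("stage %s: done", name)
    return out


def _encode_numeric(X: pd.DataFrame) -> pd.DataFrame:
    """Category columns (DOW) to integer codes so resampling stays numeric."""
    out = X.copy()
    for col in out.columns:
        if isinstance(out[col].dtype, pd.CategoricalDtype):
            out[col] = out[col].cat.codes.astype(float)
    return out


def _specify_lags(config: PipelineConfig, weather, deaths) -> tuple[LagSpec, dict]:
    if config.lagspec_override is not None:
        spec = LagSpec(**config.lagspec_override)
        return spec, {k: {"lag_days": v, "source": "override"}
                      for k, v in spec.to_dict().items()}
    decisions = {}
    lags = {}
    model = DLNM(max_lag=config.max_lag, var_df=config.var_df, lag_df=config.lag_df,
                 trend_df_per_year=config.trend_df_per_year)
    for prefix, column in ELEMENT_COLUMNS.items():
        res = model.fit(weather[column], deaths["count"], weather["date"])
        decision = res.specify_lag_days(exposure_percentile=config.lag_percentile)
        lags[column] = decision.lag_days
        decisions[column] = {
            "lag_days": decision.lag_days,
            "significant": bool(decision.significant),
            "significant_lags": list(decision.significant_lags),
            "source": "dlnm",
        }
        log.info("DLNM %s: lag_days=%d significant=%s",
                 prefix, decision.lag_days, decision.significant)
    return LagSpec(**lags), decisions


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, Any]:
    """Run the full pipeline; returns the in-memory artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> dict[str, Any]:
    sc = config.scenario
    tgt, src = config.target_city, config.source_city

    # -- simulate -------------------------------------------------------
    def simulate():
        data = {}
        for city in (tgt, src):
            w = generate_weather(sc, city)
            m, truth = generate_mortality(w, sc)
            data[city] = (w, m, truth)
        future = {
            name: generate_future_weather(
                data[tgt][0], sc, offset, seed=config.seed,
                year_shift=config.future_year_shift,
            )
            for name, offset in config.scenario_offsets.items()
        }
        return data, future

    data, future_weather = _stage("simulate", simulate, digest_of=sc.to_dict())
    for city in (tgt, src):
        w, m, truth = data[city]
        write_weather(w, out / f"weather_{city}.csv")
        write_mortality(m, out / f"deaths_{city}.csv")
        (out / f"ground_truth_{city}.json").write_text(
            json.dumps(truth.to_dict(), indent=2, sort_keys=True)
        )
    for name, fw in future_weather.items():
        write_weather(fw, out / f"future_weather_{name}.csv")

    # -- DLNM lag specification ----------------------------------------
    lagspec, lag_decisions = _stage(
        "dlnm", _specify_lags, config, data[tgt][0], data[tgt][1],
        digest_of={"city": tgt},
    )
    lagspec.to_yaml(out / "lagspec.yaml")
    (out / "lag_decisions.json").write_text(json.dumps(lag_decisions, indent=2, sort_keys=True))

    # -- features -------------------------------------------------------
    def make_features(city):
        w, m, _ = data[city]
        feats = build_feature_table(w, lagspec, diff_mode=config.diff_mode)
        drr = compute_drr(m)
        merged = feats.merge(drr, on="date", how="left")
        return feats, merged["drr"].to_numpy()

    features = {
        city: _stage(f"features[{city}]", make_features, city, digest_of=city)
        for city in (tgt, src)
    }
    for city, (feats, drr) in features.items():
        write_feature_table(feats, out / f"features_{city}.csv")
        pd.DataFrame({"date": pd.to_datetime(feats["date"]).dt.strftime("%Y-%m-%d"),
                      "drr": drr}).to_csv(out / f"drr_{city}.csv", index=False,
                                          float_format="%.6f")

    # -- selection ------------------------------------------------------
    X_tgt = features[tgt][0].drop(columns=["date"])
    y_tgt = features[tgt][1]
    selector = _stage(
        "select",
        lambda: BorutaSHAPSelector(
            n_trials=config.selection_trials, alpha=config.selection_alpha,
            learner_params=config.selection_learner_params, random_state=config.seed,
        ).fit(X_tgt, y_tgt),
        digest_of={"n": len(X_tgt)},
    )
    selector.result_.to_json(out / "selection.json")
    selected = selector.result_.accepted
    log.info("selected features: %s", selected)

    # -- training -------------------------------------------------------
    def train():
        Xs = _encode_numeric(features[src][0].drop(columns=["date"])[selected])
        ys = features[src][1]
        Xt = _encode_numeric(X_tgt[selected])
        smogn_params = {
            "rare_quantile": config.rare_quantile,
            "k_neighbors": config.k_neighbors,
            "noise_scale": config.noise_scale,
            "target_multiplier": config.target_multiplier,
        }
        hindcast = DRRBoostRegressor(
            leaves_grid=config.leaves_grid, k=config.k_folds,
            fold_scheme=config.fold_scheme, learner_params=config.learner_params,
            random_state=config.seed,
        ).fit(Xt, y_tgt, dates=features[tgt][0]["date"])
        # no-TL future model: same resampling as TL, no source domain
        if config.use_smogn:
            from .transfer import SMOGNResampler

            res = SMOGNResampler(random_state=config.seed, **smogn_params
                                 ).fit_resample(Xt, y_tgt)
            no_tl = DRRBoostRegressor(
                leaves_grid=config.leaves_grid, k=config.k_folds,
                learner_params=config.learner_params, random_state=config.seed,
            ).fit(res.X, res.y)
        else:
            no_tl = hindcast
        tl = TransferRegressor(
            use_smogn=config.use_smogn, smogn_params=smogn_params,
            leaves_grid=config.leaves_grid, k=config.k_folds,
            learner_params=config.learner_params, random_state=config.seed,
        ).fit(Xs, ys, Xt, y_tgt)
        return hindcast, no_tl, tl

    hindcast, no_tl, tl = _stage("train", train, digest_of=selected)
    (out / "metrics.json").write_text(json.dumps(
        {"hindcast": hindcast.metrics_, "num_leaves": hindcast.best_num_leaves_},
        indent=2, sort_keys=True))
    pd.DataFrame({
        "date": pd.to_datetime(features[tgt][0]["date"]).dt.strftime("%Y-%m-%d"),
        "fold": hindcast.fold_assignment_,
        "oof_prediction": hindcast.oof_prediction_,
        "actual_drr": y_tgt,
    }).to_csv(out / "oof_predictions.csv", index=False, float_format="%.6f")

    # -- projection -----------------------------------------------------
    def project():
        rows = []
        preds = {}
        Xt_sel = _encode_numeric(X_tgt[selected])
        # each variant's present-era baseline is its own simulation of the
        # present days, so the ratios isolate the climate signal and an
        # identity scenario yields ratios of exactly 1
        present_ml = {
            "no_tl": no_tl.predict(Xt_sel),
            "tl": tl.predict(Xt_sel),
        }
        for name in sorted(config.scenario_offsets):
            fw = future_weather[name]
            feats_f = build_feature_table(fw, lagspec, diff_mode=config.diff_mode)
            Xf = _encode_numeric(feats_f.drop(columns=["date"])[selected])
            for variant, model in (("no_tl", no_tl), ("tl", tl)):
                pred = model.predict(Xf)
                preds[(name, variant)] = pred
                result = percentile_change(
                    present_ml[variant], y_tgt, pred,
                    levels=config.percentile_levels, scenario=name, variant=variant,
                )
                t = result.table
                t.insert(0, "variant", variant)
                t.insert(0, "scenario", name)
                rows.append(t)
        return pd.concat(rows, ignore_index=True), preds

    projection, future_preds = _stage("project", project, digest_of=list(config.scenario_offsets))
    projection.to_csv(out / "projection.csv", index=False, float_format="%.6f")

    manifest = {
        "package": "heatlag",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "percentile_method": "linear interpolation between order statistics",
        "versions": _library_versions(),
        "artifacts": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.iterdir())
            if p.suffix in (".csv", ".json", ".yaml") and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("pipeline complete: %s", out)
    return {
        "lagspec": lagspec,
        "lag_decisions": lag_decisions,
        "selection": selector.result_,
        "hindcast": hindcast,
        "no_tl": no_tl,
        "tl": tl,
        "projection": projection,
        "future_predictions": future_preds,
        "features": features,
        "out_dir": out,
    }


def _library_versions() -> dict[str, str]:
    import lightgbm
    import sklearn

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "lightgbm": lightgbm.__version__,
    }
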