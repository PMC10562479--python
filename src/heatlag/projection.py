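"""Future-climate risk projection and percentile-change summaries.

Trained models (with and without transfer learning) are applied to feature
tables built from warmed future weather; the projected daily-relative-risk
distribution is compared with the present era at chosen percentiles, against
both the machine-learning hindcast and the actual DRR baselines.  Empirical
percentiles use linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["project_future", "percentile_change", "ProjectionResult"]

PERCENTILE_METHOD = "linear"  # interpolation between order statistics


@dataclass
class ProjectionResult:
    """Percentile table of one scenario x variant projection."""

    table: pd.DataFrame  # level, future, present_ml, present_actual, ratio_vs_ml, ratio_vs_actual
    scenario: str = ""
    variant: str = ""


def project_future(model, future_features: pd.DataFrame, mapping: str | None = None
                   ) -> np.ndarray:
    """Predict the future daily DRR series (fold-averaged).

    ``mapping='target'`` routes the rows through the transfer learner's
    target-domain block; plain models predict directly.
    """
    if mapping not in (None, "target"):
        raise ValueError("mapping must be None or 'target'")
    if mapping == "target":
        return np.asarray(model.predict(future_features))
    return np.asarray(model.predict(future_features))


def percentile_change(
    present_pred,
    present_actual,
    future_pred,
    levels: tuple[float, ...] = (95.0, 99.0),
    scenario: str = "",
    variant: str = "",
) -> ProjectionResult:
    """Percentiles of each era's pooled in-season days, and future/present ratios."""
    present_pred = np.asarray(present_pred, dtype=float)
    present_actual = np.asarray(present_actual, dtype=float)
    future_pred = np.asarray(future_pred, dtype=float)
    rows = []
    for level in levels:
        fut = float(np.percentile(future_pred, level, method=PERCENTILE_METHOD))
        ml = float(np.percentile(present_pred, level, method=PERCENTILE_METHOD))
        act = float(np.percentile(present_actual, level, method=PERCENTILE_METHOD))
        rows.append(
            {
                "level": float(level),
                "future": fut,
                "present_ml": ml,
                "present_actual": act,
                "ratio_vs_ml": fut / ml,
                "ratio_vs_actual": fut / act,
            }
        )
    return ProjectionResult(table=pd.DataFrame(rows), scenario=scenario, variant=variant)
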