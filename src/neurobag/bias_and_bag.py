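"""Regression-to-the-mean bias correction and brain-age-gap computation.

Brain-age predictors systematically over-estimate young and under-estimate
old subjects.  The correction fits ordinary least squares of predicted on
chronological age in the normative cohort (predicted = alpha + beta * age)
and applies, by default, the additive offset

    corrected = predicted + [age - (alpha + beta * age)]

so that the corrected prediction is unbiased in age on the cohort the bias
model was fitted on.  The rescaling variant (predicted - alpha) / beta is
available behind ``mode="rescale"`` for sensitivity analysis; it removes the
slope attenuation entirely but is unstable when beta is small.

BAG = corrected - chronological; positive values mean an older-appearing brain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["BiasModel", "fit_bias_model", "correct_and_bag",
           "fit_bias_models", "bag_table"]


@dataclass(frozen=True)
class BiasModel:
    intercept: float    # alpha, years
    slope: float        # beta, dimensionless
    n: int
    residual_sd: float

    def expected(self, chronological: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(chronological, float)


def fit_bias_model(predicted, chronological) -> BiasModel:
    """OLS of predicted brain age on chronological age (normative cohort)."""
    pred = np.asarray(predicted, float)
    age = np.asarray(chronological, float)
    if pred.shape != age.shape or pred.ndim != 1:
        raise ValueError("predicted and chronological must be equal-length vectors")
    if len(age) < 3:
        raise ValueError("need at least 3 subjects to fit the bias model")
    if np.ptp(age) == 0:
        raise ValueError("chronological age has zero variance")
    res = stats.linregress(age, pred)
    resid = pred - (res.intercept + res.slope * age)
    return BiasModel(float(res.intercept), float(res.slope), len(age),
                     float(resid.std(ddof=2)))


def correct_and_bag(bias: BiasModel, predicted, chronological,
                    mode: str = "offset") -> pd.DataFrame:
    """Apply the bias model and compute BAG per subject."""
    pred = np.asarray(predicted, float)
    age = np.asarray(chronological, float)
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(age))):
        raise ValueError("non-finite predictions or ages")
    if mode == "offset":
        corrected = pred + (age - bias.expected(age))
    elif mode == "rescale":
        if abs(bias.slope) < 1e-8:
            raise ValueError("bias slope too close to 0 for the rescale variant")
        corrected = (pred - bias.intercept) / bias.slope
    else:
        raise ValueError(f"unknown correction mode {mode!r}")
    return pd.DataFrame({
        "age": age,
        "predicted": pred,
        "corrected": corrected,
        "bag": corrected - age,
    })


def fit_bias_models(global_pred, regional_pred: dict[int, np.ndarray],
                    chronological) -> tuple[BiasModel, dict[int, BiasModel]]:
    """One bias model for the global predictor and one per regional model."""
    g = fit_bias_model(global_pred, chronological)
    regional = {lab: fit_bias_model(p, chronological)
                for lab, p in regional_pred.items()}
    return g, regional


def bag_table(global_bias: BiasModel, regional_bias: dict[int, BiasModel],
              global_pred, regional_pred: dict[int, np.ndarray],
              chronological, subject_ids=None,
              mode: str = "offset") -> pd.DataFrame:
    """Subject x [global + per-region] corrected BAG table.

    Columns: ``age``, ``bag_global`` and ``bag_region_<label>``; indexed by
    subject id when given.
    """
    out = correct_and_bag(global_bias, global_pred, chronological, mode=mode)
    cols = {"age": out["age"].to_numpy(), "bag_global": out["bag"].to_numpy()}
    for lab in sorted(regional_pred):
        if lab not in regional_bias:
            continue
        reg = correct_and_bag(regional_bias[lab], regional_pred[lab],
                              chronological, mode=mode)
        cols[f"bag_region_{lab}"] = reg["bag"].to_numpy()
    table = pd.DataFrame(cols)
    if subject_ids is not None:
        table.index = pd.Index(subject_ids, name="id")
    return table
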