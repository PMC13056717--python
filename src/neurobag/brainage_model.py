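"""Global and regional brain-age prediction with SVR-RBF and nested CV.

The global model regresses chronological age on the vector of region-mean
GMV values; each regional model uses that region's voxel-wise GMV signature.
Hyperparameters (C, gamma) are tuned on inner folds only; performance (MAE
and R^2) is measured on outer folds whose subjects never touch the model
selection, and folds are stratified by age quantile bins so every fold spans
the age range ("equipartitioned" stratification).

Features are standardized inside each training fold (RBF kernels are
scale-sensitive); the scaler is part of the persisted pipeline.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_predict
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = ["ModelSpec", "CvReport", "TrainedModelSet",
           "nested_cv_train", "fit_final_models", "predict_brain_age"]

_DEFAULT_GRID = tuple(10.0 ** k for k in range(-3, 4))   # 1e-3 .. 1e3


@dataclass(frozen=True)
class ModelSpec:
    c_grid: tuple[float, ...] = _DEFAULT_GRID
    gamma_grid: tuple[float, ...] | None = _DEFAULT_GRID  # None -> sklearn 'scale'
    outer_folds: int = 5
    inner_folds: int = 5
    n_age_bins: int = 5        # quantile bins used for stratification
    epsilon: float = 0.1       # SVR tube half-width, years
    seed: int = 0

    def validate(self) -> None:
        if not self.c_grid or (self.gamma_grid is not None and not self.gamma_grid):
            raise ValueError("hyperparameter grids must be non-empty")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")


@dataclass
class CvReport:
    fold_mae: np.ndarray
    fold_r2: np.ndarray
    mae: float                      # mean of per-fold MAE
    r2: float                       # mean of per-fold R^2 (headline metric)
    adjusted_r2: float              # n-adjusted variant, per fold then averaged
    oof_predictions: np.ndarray     # one out-of-fold prediction per subject
    fold_assignment: np.ndarray
    chosen_params: list[dict]


@dataclass
class TrainedModelSet:
    global_model: Pipeline
    regional_models: dict[int, Pipeline]
    spec: ModelSpec
    regional_spec: ModelSpec
    global_params: dict
    regional_params: dict[int, dict]
    cv_pred_global: np.ndarray | None = None    # 5-fold training predictions
    cv_pred_regional: dict[int, np.ndarray] = field(default_factory=dict)
    skipped_regions: list[int] = field(default_factory=list)

    @property
    def n_models(self) -> int:
        return 1 + len(self.regional_models)

    def save(self, directory: str | os.PathLike) -> None:
        directory = os.fspath(directory)
        os.makedirs(directory, exist_ok=True)
        joblib.dump(self.global_model, os.path.join(directory, "global.joblib"))
        for lab, model in self.regional_models.items():
            joblib.dump(model, os.path.join(directory, f"region-{lab}.joblib"))
        manifest = {
            "regions": sorted(self.regional_models),
            "spec": {"c_grid": list(self.spec.c_grid),
                     "gamma_grid": None if self.spec.gamma_grid is None
                     else list(self.spec.gamma_grid),
                     "outer_folds": self.spec.outer_folds,
                     "inner_folds": self.spec.inner_folds,
                     "n_age_bins": self.spec.n_age_bins,
                     "epsilon": self.spec.epsilon,
                     "seed": self.spec.seed},
            "global_params": self.global_params,
            "regional_params": {str(k): v for k, v in self.regional_params.items()},
            "skipped_regions": self.skipped_regions,
        }
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, directory: str | os.PathLike) -> "TrainedModelSet":
        directory = os.fspath(directory)
        with open(os.path.join(directory, "manifest.json")) as fh:
            manifest = json.load(fh)
        s = manifest["spec"]
        spec = ModelSpec(c_grid=tuple(s["c_grid"]),
                         gamma_grid=None if s["gamma_grid"] is None
                         else tuple(s["gamma_grid"]),
                         outer_folds=s["outer_folds"], inner_folds=s["inner_folds"],
                         n_age_bins=s["n_age_bins"], epsilon=s["epsilon"],
                         seed=s["seed"])
        global_model = joblib.load(os.path.join(directory, "global.joblib"))
        regional = {int(lab): joblib.load(os.path.join(directory, f"region-{lab}.joblib"))
                    for lab in manifest["regions"]}
        return cls(global_model, regional, spec, spec,
                   manifest["global_params"],
                   {int(k): v for k, v in manifest["regional_params"].items()},
                   skipped_regions=manifest.get("skipped_regions", []))


def _age_bins(ages: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile-bin labels for stratification; collapses ties gracefully."""
    qs = np.quantile(ages, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(np.unique(qs), ages, side="right")

def _check_features(x: np.ndarray) -> None:
    const = np.ptp(x, axis=0) == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant feature column(s); "
                      "model will still be fit")


def _pipeline(spec: ModelSpec) -> Pipeline:
    return Pipeline([("scale", StandardScaler()),
                     ("svr", SVR(kernel="rbf", epsilon=spec.epsilon))])


def _param_grid(spec: ModelSpec) -> dict:
    grid = {"svr__C": sorted(spec.c_grid)}
    if spec.gamma_grid is not None:
        grid["svr__gamma"] = sorted(spec.gamma_grid)
    return grid


def _grid_fit(x, ages, bins, spec: ModelSpec, n_folds: int, seed: int):
    """Grid-search SVR with age-stratified folds; ties resolve to smaller
    C then smaller gamma (first best in ascending grid order)."""
    grid = _param_grid(spec)
    n_combos = int(np.prod([len(v) for v in grid.values()]))
    if n_combos == 1:
        params = {k: v[0] for k, v in grid.items()}
        model = _pipeline(spec).set_params(**params).fit(x, ages)
        return model, params
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(cv.split(x, bins))
    search = GridSearchCV(_pipeline(spec), grid, cv=splits,
                          scoring="neg_mean_absolute_error", refit=True, n_jobs=1)
    search.fit(x, ages)
    return search.best_estimator_, dict(search.best_params_)


def nested_cv_train(features, ages, spec: ModelSpec = ModelSpec()) -> CvReport:
    """Nested stratified CV: inner grid search, outer performance estimate."""
    spec.validate()
    x = np.asarray(features, float)
    ages = np.asarray(ages, float)
    if x.shape[0] != ages.shape[0]:
        raise ValueError("features and ages disagree on subject count")
    if x.shape[0] < spec.outer_folds:
        raise ValueError("fewer subjects than outer folds")
    if not np.all(np.isfinite(ages)):
        raise ValueError("ages must be finite")
    _check_features(x)

    bins = _age_bins(ages, spec.n_age_bins)
    outer = StratifiedKFold(n_splits=spec.outer_folds, shuffle=True,
                            random_state=spec.seed)
    n = x.shape[0]
    oof = np.full(n, np.nan)
    assignment = np.full(n, -1)
    fold_mae, fold_r2, fold_adj, chosen = [], [], [], []
    for k, (tr, te) in enumerate(outer.split(x, bins)):
        model, params = _grid_fit(x[tr], ages[tr], bins[tr], spec,
                                  spec.inner_folds, spec.seed + k)
        pred = model.predict(x[te])
        oof[te] = pred
        assignment[te] = k
        chosen.append(params)
        fold_mae.append(mean_absolute_error(ages[te], pred))
        r2 = r2_score(ages[te], pred)
        m = len(te)
        fold_r2.append(r2)
        fold_adj.append(1.0 - (1.0 - r2) * (m - 1) / max(m - 2, 1))
    return CvReport(np.asarray(fold_mae), np.asarray(fold_r2),
                    float(np.mean(fold_mae)), float(np.mean(fold_r2)),
                    float(np.mean(fold_adj)), oof, assignment, chosen)


def fit_final_models(region_means, ages,
                     spec: ModelSpec = ModelSpec(),
                     voxel_features: Mapping[int, np.ndarray] | None = None,
                     regional_spec: ModelSpec | None = None,
                     cv_predictions: bool = True) -> TrainedModelSet:
    """Fit the application models on the complete training cohort.

    The global model is grid-searched with ``spec`` on the region means; one
    regional model per voxel-feature block is fit with ``regional_spec``
    (defaults to ``spec``).  When ``cv_predictions`` is true, K-fold
    out-of-fold predictions on the training cohort are stored for downstream
    bias-model fitting.  Regions with fewer than 2 voxels are skipped.
    """
    spec.validate()
    x = np.asarray(region_means, float)
    ages = np.asarray(ages, float)
    regional_spec = regional_spec or spec
    bins = _age_bins(ages, spec.n_age_bins)
    _check_features(x)

    global_model, global_params = _grid_fit(x, ages, bins, spec,
                                            spec.inner_folds, spec.seed)
    cv = StratifiedKFold(n_splits=spec.outer_folds, shuffle=True,
                         random_state=spec.seed)
    splits = list(cv.split(x, bins))
    cv_global = None
    if cv_predictions:
        cv_global = cross_val_predict(clone(global_model), x, ages, cv=splits)

    regional_models: dict[int, Pipeline] = {}
    regional_params: dict[int, dict] = {}
    cv_regional: dict[int, np.ndarray] = {}
    skipped: list[int] = []
    for lab, vox in (voxel_features or {}).items():
        vox = np.asarray(vox, float)
        if vox.shape[1] < 2:
            skipped.append(int(lab))
            warnings.warn(f"region {lab}: fewer than 2 voxels, regional model skipped")
            continue
        model, params = _grid_fit(vox, ages, bins, regional_spec,
                                  regional_spec.inner_folds, regional_spec.seed)
        regional_models[int(lab)] = model
        regional_params[int(lab)] = params
        if cv_predictions:
            cv_regional[int(lab)] = cross_val_predict(clone(model), vox, ages, cv=splits)
    return TrainedModelSet(global_model, regional_models, spec, regional_spec,
                           global_params, regional_params,
                           cv_global, cv_regional, skipped)


def predict_brain_age(models: TrainedModelSet, region_means,
                      voxel_features: Mapping[int, np.ndarray] | None = None):
    """Predict global and per-region brain age; deterministic.

    Returns ``(global_pred, regional_pred)`` where ``regional_pred`` is a
    dict keyed by region label (empty if no voxel features given).
    """
    x = np.asarray(region_means, float)
    n_expected = models.global_model.named_steps["scale"].n_features_in_
    if x.shape[1] != n_expected:
        raise ValueError(f"global model expects {n_expected} region means, "
                         f"got {x.shape[1]}")
    global_pred = models.global_model.predict(x)
    regional_pred: dict[int, np.ndarray] = {}
    for lab, vox in (voxel_features or {}).items():
        lab = int(lab)
        if lab not in models.regional_models:
            continue
        model = models.regional_models[lab]
        vox = np.asarray(vox, float)
        d = model.named_steps["scale"].n_features_in_
        if vox.shape[1] != d:
            raise ValueError(f"region {lab}: model expects {d} voxels, "
                             f"got {vox.shape[1]}")
        regional_pred[lab] = model.predict(vox)
    return global_pred, regional_pred
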