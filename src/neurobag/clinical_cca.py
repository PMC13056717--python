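"""Permutation-based canonical correlation analysis of regional BAG patterns
against clinical profiles.

Pipeline: residualize both variable sets on their confound designs
(clinical: age, sex; imaging: age, centred age^2, sex, TIV, protocol), reduce
the regional BAG set with PCA keeping components up to 50% explained
variance, then run CCA with non-parametric permutation inference.  Mode m is
tested step-down on data deflated of modes < m, with the Wilks-lambda-based
statistic -sum_{i>=m} log(1 - r_i^2); the p-value uses the +1 convention.
Nuisance handling is Freedman-Lane style: rows of the residualized clinical
set are permuted against the fixed residualized imaging set.

Loadings are reported as the correlation of each original variable with its
own set's canonical variate; their family-wise-error-corrected p-values come
from a max-statistic permutation distribution of the cross-correlation of
each variable with the *other* set's variate (the association with BAG that
the test is about — own-set loadings are not null under permutation).
Stability is assessed by bootstrap with the PCA basis held fixed.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PcaReduction", "CcaResult", "BootstrapResult",
           "residualize", "pca_reduce", "canonical_correlations",
           "permcca_test", "loading_inference", "bootstrap_stability",
           "region_contributions", "run_clinical_cca", "ClinicalCcaReport"]

_EPS = 1e-12


def _with_intercept(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, float)
    if z.ndim == 1:
        z = z[:, None]
    has_const = np.any(np.ptp(z, axis=0) == 0) if z.size else False
    if not has_const:
        z = np.column_stack([np.ones(len(z)), z])
    return z


def residualize(data, confounds=None) -> np.ndarray:
    """Replace each column by its OLS residual on the confounds (+ intercept)."""
    m = np.asarray(data, float)
    if m.ndim == 1:
        m = m[:, None]
    if confounds is None:
        return m - m.mean(axis=0)
    z = _with_intercept(np.asarray(pd.DataFrame(confounds), float))
    if np.linalg.matrix_rank(z) < z.shape[1]:
        raise ValueError("rank-deficient confound matrix")
    beta, *_ = np.linalg.lstsq(z, m, rcond=None)
    return m - z @ beta


@dataclass
class PcaReduction:
    scores: np.ndarray
    components: np.ndarray          # (k, n_features)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    k: int

    def transform(self, data: np.ndarray) -> np.ndarray:
        return (np.asarray(data, float) - self.mean) @ self.components.T


def pca_reduce(data, variance_target: float = 0.5) -> PcaReduction:
    """Smallest number of principal components reaching the variance target."""
    if not 0.0 < variance_target <= 1.0:
        raise ValueError("variance_target must be in (0, 1]")
    m = np.asarray(data, float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a matrix with at least 2 columns")
    mean = m.mean(axis=0)
    c = m - mean
    u, s, vt = np.linalg.svd(c, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total <= _EPS:
        raise ValueError("zero-variance matrix")
    ratio = var / total
    k = int(np.searchsorted(np.cumsum(ratio), variance_target - _EPS) + 1)
    return PcaReduction(c @ vt[:k].T, vt[:k], ratio[:k], mean, k)


def _center_qr(m: np.ndarray):
    c = m - m.mean(axis=0)
    q, r = np.linalg.qr(c)
    if np.abs(np.diag(r)).min() < _EPS * max(1.0, np.abs(np.diag(r)).max()):
        raise np.linalg.LinAlgError("rank-deficient variable set")
    return c, q


def canonical_correlations(y, x) -> np.ndarray:
    """Canonical correlations of two centred variable sets (descending)."""
    _, qy = _center_qr(np.asarray(y, float))
    _, qx = _center_qr(np.asarray(x, float))
    s = np.linalg.svd(qy.T @ qx, compute_uv=False)
    return np.clip(s, 0.0, 1.0)


def _cca(y, x):
    """Full CCA: correlations and unit-norm canonical variates per mode."""
    _, qy = _center_qr(np.asarray(y, float))
    _, qx = _center_qr(np.asarray(x, float))
    u, s, vt = np.linalg.svd(qy.T @ qx)
    k = min(qy.shape[1], qx.shape[1])
    return np.clip(s[:k], 0.0, 1.0), qy @ u[:, :k], qx @ vt.T[:, :k]


def _wilks_stat(r: np.ndarray) -> float:
    with np.errstate(divide="ignore"):
        return float(-np.sum(np.log(np.maximum(1.0 - r ** 2, _EPS))))


def _corr_cols(m: np.ndarray, v: np.ndarray) -> np.ndarray:
    mc = m - m.mean(axis=0)
    vc = v - v.mean()
    denom = np.sqrt((mc ** 2).sum(axis=0) * (vc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (mc.T @ vc) / denom


@dataclass
class CcaResult:
    r: np.ndarray                   # canonical correlations per mode
    p: np.ndarray                   # permutation p per mode
    variates_y: np.ndarray
    variates_x: np.ndarray
    loadings_y: np.ndarray          # own-set loadings, mode 1
    loadings_x: np.ndarray
    nperm: int
    n: int
    perm_max_cross_y: np.ndarray = field(default=None)  # type: ignore[assignment]
    perm_max_cross_x: np.ndarray = field(default=None)  # type: ignore[assignment]
    cross_y: np.ndarray = field(default=None)  # type: ignore[assignment]
    cross_x: np.ndarray = field(default=None)  # type: ignore[assignment]
    pca: PcaReduction | None = None


def permcca_test(Y, X, Z_Y=None, Z_X=None, nperm: int = 10000,
                 seed: int | None = None, exhaustive: bool = False,
                 compute_loadings: bool = True) -> CcaResult:
    """CCA with step-down permutation inference on residualized sets.

    With ``exhaustive=True`` every row order of the clinical set is
    enumerated (feasible for small n); the p-value is then the exact fraction
    of orders, identity included, whose statistic reaches the observed one.
    """
    yr = residualize(Y, Z_Y)
    xr = residualize(X, Z_X)
    n = yr.shape[0]
    if n != xr.shape[0]:
        raise ValueError("Y and X disagree on subject count")
    k = min(yr.shape[1], xr.shape[1])
    min_rank = yr.shape[1] + xr.shape[1] + 1
    if n <= min_rank:
        raise ValueError(f"n={n} too small for {k} canonical modes "
                         f"(need n > {min_rank})")
    if not (np.all(np.isfinite(yr)) and np.all(np.isfinite(xr))):
        raise ValueError("inputs contain non-finite values (complete cases only)")

    r_obs, uy, ux = _cca(yr, xr)

    if exhaustive:
        perms = np.array(list(itertools.permutations(range(n))))
        n_draws = len(perms)
    else:
        if nperm < 99:
            raise ValueError("nperm must be >= 99")
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(nperm)])
        n_draws = nperm

    p_out = np.ones(k)
    max_cross_y = max_cross_x = None
    cross_y = cross_x = None
    for mode in range(k):
        # deflate both sets of the modes already established
        if mode == 0:
            yd, xd = yr, xr
        else:
            py, px = uy[:, :mode], ux[:, :mode]
            yd = yr - py @ (py.T @ yr)
            xd = xr - px @ (px.T @ xr)
        try:
            _, qyd = _center_qr(yd)
            _, qxd = _center_qr(xd)
        except np.linalg.LinAlgError:
            # deflation exhausted a set's rank; remaining modes untestable
            break
        s_d = np.clip(np.linalg.svd(qyd.T @ qxd, compute_uv=False), 0.0, 1.0)
        obs = _wilks_stat(s_d)
        qyd_t = qyd.T
        exceed = 0
        if mode == 0 and compute_loadings:
            max_cross_y = np.empty(n_draws)
            max_cross_x = np.empty(n_draws)
        for i, perm in enumerate(perms):
            m = qyd_t[:, perm] @ qxd
            if mode == 0 and compute_loadings:
                u_p, s_p, vt_p = np.linalg.svd(m)
                s_p = np.clip(s_p, 0.0, 1.0)
                stat = _wilks_stat(s_p)
                # variates of the permuted problem, mode 1
                vy = qyd[perm] @ u_p[:, 0]
                vx = qxd @ vt_p[0]
                max_cross_y[i] = np.max(np.abs(_corr_cols(yr[perm], vx)))
                max_cross_x[i] = np.max(np.abs(_corr_cols(xr, vy)))
            else:
                s_p = np.clip(np.linalg.svd(m, compute_uv=False), 0.0, 1.0)
                stat = _wilks_stat(s_p)
            if stat >= obs - 1e-12:
                exceed += 1
        if exhaustive:
            p_raw = exceed / n_draws
        else:
            p_raw = (1 + exceed) / (1 + n_draws)
        # enforce step-down monotonicity of p-values
        p_out[mode] = max(p_raw, p_out[mode - 1]) if mode else p_raw

    loadings_y = _corr_cols(yr, uy[:, 0])
    loadings_x = _corr_cols(xr, ux[:, 0])
    # sign convention: largest |loading| on the clinical side is positive
    j = int(np.nanargmax(np.abs(loadings_y)))
    if loadings_y[j] < 0:
        loadings_y, loadings_x = -loadings_y, -loadings_x
        uy, ux = -uy, -ux
    if compute_loadings:
        cross_y = np.abs(_corr_cols(yr, ux[:, 0]))
        cross_x = np.abs(_corr_cols(xr, uy[:, 0]))
    return CcaResult(r_obs, p_out, uy, ux, loadings_y, loadings_x,
                     n_draws, n, max_cross_y, max_cross_x, cross_y, cross_x)


def loading_inference(result: CcaResult, Y=None, X=None) -> pd.DataFrame:
    """FWE-corrected p per variable from the max-statistic permutation null.

    Variables with zero variance have undefined loadings and are flagged.
    """
    if result.perm_max_cross_y is None:
        raise ValueError("permcca_test must be run with compute_loadings=True")
    rows = []
    for side, loadings, cross, null in (
            ("clinical", result.loadings_y, result.cross_y, result.perm_max_cross_y),
            ("imaging", result.loadings_x, result.cross_x, result.perm_max_cross_x)):
        for j, (ld, cr) in enumerate(zip(loadings, cross)):
            if not np.isfinite(ld):
                rows.append({"set": side, "variable": j, "loading": np.nan,
                             "p_fwe": np.nan, "flag": "zero-variance"})
                continue
            exceed = int(np.sum(null >= cr - 1e-12))
            rows.append({"set": side, "variable": j, "loading": float(ld),
                         "p_fwe": (1 + exceed) / (1 + len(null)), "flag": ""})
    return pd.DataFrame(rows)


@dataclass
class BootstrapResult:
    r_ci: tuple[float, float]
    loading_ci_y: np.ndarray        # (p, 2)
    loading_ci_x: np.ndarray        # (k, 2)
    r_samples: np.ndarray
    n_skipped: int


def bootstrap_stability(Y, bag_matrix, Z_Y=None, Z_X=None,
                        pca: PcaReduction | None = None,
                        nboot: int = 10000, seed: int | None = None,
                        ci: float = 0.95) -> BootstrapResult:
    """Percentile bootstrap CIs for the mode-1 canonical correlation and loadings.

    Subjects are resampled with replacement; residualization is redone per
    replicate; the PCA basis (when given) stays fixed at the original one so
    component-order instability does not dominate the loading CIs.  Replicate
    variate signs are aligned to the original solution before aggregation.
    """
    Y = np.asarray(pd.DataFrame(Y), float)
    bag = np.asarray(pd.DataFrame(bag_matrix), float)
    n = len(Y)
    if n < 20:
        raise ValueError("bootstrap needs n >= 20")
    zy = None if Z_Y is None else np.asarray(pd.DataFrame(Z_Y), float)
    zx = None if Z_X is None else np.asarray(pd.DataFrame(Z_X), float)

    yr0 = residualize(Y, zy)
    xr0_full = residualize(bag, zx)
    x0 = pca.transform(xr0_full) if pca is not None else xr0_full
    r0, uy0, ux0 = _cca(yr0, x0)
    l_y0 = _corr_cols(yr0, uy0[:, 0])
    l_x0 = _corr_cols(x0, ux0[:, 0])

    rng = np.random.default_rng(seed)
    r_s, ly_s, lx_s = [], [], []
    skipped = 0
    for _ in range(nboot):
        idx = rng.integers(n, size=n)
        try:
            yr = residualize(Y[idx], None if zy is None else zy[idx])
            xr = residualize(bag[idx], None if zx is None else zx[idx])
            xs = pca.transform(xr) if pca is not None else xr
            r, uy, ux = _cca(yr, xs)
            ly = _corr_cols(yr, uy[:, 0])
            lx = _corr_cols(xs, ux[:, 0])
        except (np.linalg.LinAlgError, ValueError):
            skipped += 1
            continue
        sign = np.sign(np.nansum(ly * l_y0)) or 1.0
        r_s.append(r[0])
        ly_s.append(sign * ly)
        lx_s.append(sign * lx)
    if skipped > 0.05 * nboot:
        warnings.warn(f"{skipped}/{nboot} bootstrap replicates degenerate")
    lo, hi = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    r_s = np.asarray(r_s)
    ly_s, lx_s = np.asarray(ly_s), np.asarray(lx_s)
    return BootstrapResult(
        (float(np.percentile(r_s, lo)), float(np.percentile(r_s, hi))),
        np.percentile(ly_s, [lo, hi], axis=0).T,
        np.percentile(lx_s, [lo, hi], axis=0).T,
        r_s, skipped)


def region_contributions(clinical_variate, bag_matrix) -> pd.DataFrame:
    """Pearson correlation of each region's BAG with the clinical variate."""
    v = np.asarray(clinical_variate, float)
    bag = pd.DataFrame(bag_matrix)
    if len(v) != len(bag):
        raise ValueError("variate and BAG matrix disagree on subject count")
    rows = []
    for col in bag.columns:
        x = bag[col].to_numpy(float)
        if np.ptp(x) == 0:
            rows.append({"region": col, "r": np.nan, "p": np.nan,
                         "flag": "constant"})
            continue
        r, p = stats.pearsonr(x, v)
        rows.append({"region": col, "r": float(r), "p": float(p), "flag": ""})
    return pd.DataFrame(rows).set_index("region")


@dataclass
class ClinicalCcaReport:
    cca: CcaResult
    loadings: pd.DataFrame
    bootstrap: BootstrapResult | None
    contributions: pd.DataFrame
    pca: PcaReduction
    n: int
    clinical_variables: list[str]


def run_clinical_cca(bag_regional: pd.DataFrame, clinical: pd.DataFrame,
                     confounds_y: pd.DataFrame, confounds_x: pd.DataFrame,
                     variance_target: float = 0.5, nperm: int = 10000,
                     nboot: int = 10000, seed: int | None = None,
                     pca_on: str = "residualized") -> ClinicalCcaReport:
    """End-to-end PermCCA of regional BAG patterns vs clinical profiles.

    Complete cases only; ``pca_on`` selects whether the 50%-variance PCA is
    computed on confound-residualized BAG (default) or on raw BAG.
    """
    clinical = pd.DataFrame(clinical)
    bag_regional = pd.DataFrame(bag_regional)
    complete = clinical.notna().all(axis=1) & bag_regional.notna().all(axis=1)
    clinical = clinical.loc[complete]
    bag = bag_regional.loc[complete]
    zy = pd.DataFrame(confounds_y).loc[complete].to_numpy(float)
    zx = pd.DataFrame(confounds_x).loc[complete].to_numpy(float)
    n = len(clinical)

    bag_arr = bag.to_numpy(float)
    if pca_on == "residualized":
        pca = pca_reduce(residualize(bag_arr, zx), variance_target)
        scores = pca.scores
    elif pca_on == "raw":
        pca = pca_reduce(bag_arr, variance_target)
        scores = pca.scores
    else:
        raise ValueError("pca_on must be 'residualized' or 'raw'")

    result = permcca_test(clinical.to_numpy(float), scores, zy, zx,
                          nperm=nperm, seed=seed)
    result.pca = pca
    loadings = loading_inference(result)
    boot = None
    if nboot > 0 and n >= 20:
        boot = bootstrap_stability(clinical, bag_arr, zy, zx, pca=pca,
                                   nboot=nboot, seed=seed)
    contrib = region_contributions(result.variates_y[:, 0], bag)
    return ClinicalCcaReport(result, loadings, boot, contrib, pca, n,
                             list(clinical.columns))
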