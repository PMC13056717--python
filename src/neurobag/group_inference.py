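"""Covariate-adjusted group comparison of BAG with parcel-wise FDR control,
ComBat harmonization and protocol-stratified validation.

The comparison is a linear model BAG ~ group + age + age^2 + sex + TIV +
protocol (age centred before squaring to limit collinearity).  The adjusted
difference is the group coefficient, its Wald t-interval gives the 95% CI,
and the effect size is partial eta squared, SS_group / (SS_group + SS_resid).
Across parcels, Benjamini-Hochberg step-up controls the FDR.

ComBat is the parametric empirical-Bayes location-scale harmonization of
batch (protocol) effects; biological covariates are preserved in the design.
A non-EB mode (plain per-batch standardization) is provided for auditing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["AncovaResult", "RegionalTestTable", "make_covariates",
           "ancova_compare", "ancova_omnibus", "regional_ancova", "fdr_select",
           "combat_harmonize", "stratified_compare"]


@dataclass
class AncovaResult:
    difference: float           # adjusted group difference, years
    ci: tuple[float, float]     # 95% Wald t-interval
    f_stat: float
    df1: int
    df2: int
    p_value: float
    eta_p2: float
    coefficients: pd.Series
    n: int


@dataclass
class RegionalTestTable:
    table: pd.DataFrame         # one row per region
    q: float

    @property
    def significant_regions(self) -> np.ndarray:
        return self.table.index[self.table["significant"]].to_numpy()


def make_covariates(subjects: pd.DataFrame,
                    include=("age", "age2", "sex", "tiv", "protocol")) -> pd.DataFrame:
    """Standard covariate frame from a subject table.

    ``age2`` is the square of centred age; ``sex`` and ``protocol`` are dummy
    coded (first level dropped).
    """
    cols = {}
    if "age" in include:
        cols["age"] = subjects["age"].to_numpy(float)
    if "age2" in include:
        a = subjects["age"].to_numpy(float)
        cols["age2"] = (a - a.mean()) ** 2
    out = pd.DataFrame(cols, index=subjects.index)
    if "sex" in include:
        dummies = pd.get_dummies(subjects["sex"], prefix="sex", drop_first=True)
        out = pd.concat([out, dummies.astype(float)], axis=1)
    if "tiv" in include:
        col = "tiv_ml" if "tiv_ml" in subjects else "tiv"
        out["tiv"] = subjects[col].to_numpy(float)
    if "protocol" in include and "protocol" in subjects:
        dummies = pd.get_dummies(subjects["protocol"], prefix="protocol",
                                 drop_first=True)
        out = pd.concat([out, dummies.astype(float)], axis=1)
    return out


def _design(group, covariates) -> tuple[np.ndarray, pd.DataFrame, str]:
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, found {len(levels)}")
    ref, other = sorted(map(str, levels))
    indicator = (group.astype(str) == other).astype(float)
    if covariates is None:
        covariates = pd.DataFrame(index=pd.RangeIndex(len(group)))
    covariates = pd.DataFrame(covariates).reset_index(drop=True)
    x = pd.DataFrame({"const": np.ones(len(group)), "group": indicator})
    x = pd.concat([x, covariates.astype(float)], axis=1)
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        # name the offending columns for the caller
        bad = []
        arr = x.to_numpy()
        for j in range(arr.shape[1]):
            sub = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(x.columns[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return indicator, x, other


def ancova_compare(bag, group, covariates: pd.DataFrame | None = None,
                   alpha: float = 0.05) -> AncovaResult:
    """Single-factor two-level ANCOVA for group differences in BAG."""
    y = np.asarray(bag, float)
    _, x, _ = _design(group, covariates)
    fit = sm.OLS(y, x.to_numpy()).fit()
    params = pd.Series(fit.params, index=x.columns)
    j = list(x.columns).index("group")
    diff = float(fit.params[j])
    se = float(fit.bse[j])
    df2 = int(fit.df_resid)
    tq = stats.t.ppf(1 - alpha / 2, df2)
    tval = diff / se
    f_stat = tval ** 2
    p = 2 * stats.t.sf(abs(tval), df2)
    ss_resid = float(fit.ssr)
    ss_group = f_stat * ss_resid / df2     # SS for a 1-df effect
    eta_p2 = ss_group / (ss_group + ss_resid)
    return AncovaResult(diff, (diff - tq * se, diff + tq * se),
                        float(f_stat), 1, df2, float(p), float(eta_p2),
                        params, len(y))


def ancova_omnibus(bag, group, covariates: pd.DataFrame | None = None):
    """k-group covariate-adjusted comparison: omnibus F plus pairwise contrasts.

    Returns ``(f_stat, p_value, pairwise)`` where ``pairwise`` maps
    ``"A_vs_B"`` to the two-level :func:`ancova_compare` result (no
    multiplicity adjustment on the contrasts, mirroring post hoc reporting).
    """
    y = np.asarray(bag, float)
    group = np.asarray(group)
    levels = sorted(map(str, pd.unique(group)))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    dummies = pd.get_dummies(pd.Categorical(group.astype(str), levels),
                             drop_first=True).astype(float)
    if covariates is None:
        covariates = pd.DataFrame(index=pd.RangeIndex(len(y)))
    cov = pd.DataFrame(covariates).reset_index(drop=True).astype(float)
    x_full = np.column_stack([np.ones(len(y)), dummies.to_numpy(),
                              cov.to_numpy()]) if cov.shape[1] else \
        np.column_stack([np.ones(len(y)), dummies.to_numpy()])
    x_red = np.column_stack([np.ones(len(y)), cov.to_numpy()]) \
        if cov.shape[1] else np.ones((len(y), 1))
    full = sm.OLS(y, x_full).fit()
    red = sm.OLS(y, x_red).fit()
    df1 = len(levels) - 1
    df2 = int(full.df_resid)
    f = ((red.ssr - full.ssr) / df1) / (full.ssr / df2)
    p = stats.f.sf(f, df1, df2)
    pairwise = {}
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            m = np.isin(group.astype(str), [a, b])
            cov_ab = cov.loc[m].reset_index(drop=True) if cov.shape[1] else None
            pairwise[f"{a}_vs_{b}"] = ancova_compare(y[m], group[m], cov_ab)
    return float(f), float(p), pairwise


def fdr_select(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up: adjusted p-values and the significant set."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def regional_ancova(bag_regional: pd.DataFrame, group,
                    covariates: pd.DataFrame | None = None,
                    q: float = 0.05) -> RegionalTestTable:
    """ANCOVA per region with BH-FDR across all parcels."""
    rows = {}
    for col in bag_regional.columns:
        res = ancova_compare(bag_regional[col].to_numpy(), group, covariates)
        rows[col] = {"difference": res.difference, "ci_low": res.ci[0],
                     "ci_high": res.ci[1], "f": res.f_stat, "p": res.p_value,
                     "eta_p2": res.eta_p2}
    table = pd.DataFrame(rows).T
    p_adj, reject = fdr_select(table["p"].to_numpy(), q)
    table["p_fdr"] = p_adj
    table["significant"] = reject
    return RegionalTestTable(table, q)


# ---------------------------------------------------------------------------
# ComBat (parametric empirical-Bayes location/scale batch harmonization)


def _aprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m ** 2) / s2

def _bprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m ** 3) / s2

def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)

def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)

def _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4):
    n = (~np.isnan(sdat)).sum(axis=0).astype(float)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((sdat - g_new[None, :]) ** 2).sum(axis=0)
        d_new = _postvar(sum2, n, a, b)
        change = max(np.abs(g_new - g_old).max() / np.abs(g_old).max()
                     if np.abs(g_old).max() > 0 else 0.0,
                     np.abs(d_new - d_old).max() / np.abs(d_old).max())
        g_old, d_old = g_new, d_new
    return g_old, d_old


def combat_harmonize(data, batch, covariates: pd.DataFrame | None = None,
                     eb: bool = True) -> np.ndarray:
    """Remove batch location/scale effects, preserving covariate structure.

    Parameters
    ----------
    data : (n_subjects, n_features) array of features or BAG values
    batch : per-subject batch (protocol) labels
    covariates : biological design to preserve (e.g. age, sex, group, TIV)
    eb : pool batch parameters across features with parametric empirical
        Bayes; requires >= 2 features (with a single feature there is nothing
        to pool and plain location/scale standardization is applied)
    """
    y = np.asarray(data, float)
    if y.ndim == 1:
        y = y[:, None]
    n, p = y.shape
    batch = np.asarray(batch)
    levels, batch_idx = np.unique(batch, return_inverse=True)
    n_batches = len(levels)
    counts = np.bincount(batch_idx)
    if (counts < 2).any():
        raise ValueError("every batch needs at least 2 subjects")
    if n_batches == 1:
        return y.copy()
    if eb and p < 2:
        warnings.warn("empirical Bayes pooling needs >= 2 features; "
                      "falling back to non-EB harmonization")
        eb = False

    batch_design = np.zeros((n, n_batches))
    batch_design[np.arange(n), batch_idx] = 1.0
    if covariates is not None:
        cov = pd.DataFrame(covariates).to_numpy(float)
        design = np.column_stack([batch_design, cov])
    else:
        cov = np.zeros((n, 0))
        design = batch_design

    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    grand_mean = (counts / n) @ beta[:n_batches]
    stand_mean = grand_mean[None, :] + cov @ beta[n_batches:]
    resid = y - design @ beta
    var_pooled = (resid ** 2).mean(axis=0)
    var_pooled[var_pooled == 0] = 1e-12
    s_data = (y - stand_mean) / np.sqrt(var_pooled)[None, :]

    gamma_hat = np.stack([s_data[batch_idx == i].mean(axis=0)
                          for i in range(n_batches)])
    delta_hat = np.stack([s_data[batch_idx == i].var(axis=0, ddof=1)
                          for i in range(n_batches)])
    if eb:
        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for i in range(n_batches):
            g_bar = gamma_hat[i].mean()
            t2 = gamma_hat[i].var(ddof=1)
            a, b = _aprior(delta_hat[i]), _bprior(delta_hat[i])
            gamma_star[i], delta_star[i] = _it_sol(
                s_data[batch_idx == i], gamma_hat[i], delta_hat[i],
                g_bar, t2, a, b)
    else:
        gamma_star, delta_star = gamma_hat, delta_hat
    delta_star = np.maximum(delta_star, 1e-12)

    adj = (s_data - gamma_star[batch_idx]) / np.sqrt(delta_star[batch_idx])
    out = adj * np.sqrt(var_pooled)[None, :] + stand_mean
    return out if np.asarray(data).ndim > 1 else out[:, 0]


def stratified_compare(bag, group, covariates: pd.DataFrame | None,
                       stratum) -> dict[str, AncovaResult]:
    """Run the ANCOVA independently inside each protocol stratum.

    The stratum variable is removed from the covariates (constant within a
    stratum); strata missing either group are skipped with a warning.
    """
    bag = np.asarray(bag, float)
    group = np.asarray(group)
    stratum = np.asarray(stratum)
    if covariates is not None:
        covariates = pd.DataFrame(covariates).reset_index(drop=True)
        keep = [c for c in covariates.columns
                if not str(c).startswith("protocol")]
        covariates = covariates[keep]
    out: dict[str, AncovaResult] = {}
    for s in pd.unique(stratum):
        m = stratum == s
        if len(pd.unique(group[m])) < 2:
            warnings.warn(f"stratum {s!r} lacks one of the groups; skipped")
            continue
        cov_s = covariates.loc[m].reset_index(drop=True) if covariates is not None else None
        out[str(s)] = ancova_compare(bag[m], group[m], cov_s)
    return out
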