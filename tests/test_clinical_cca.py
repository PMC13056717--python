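"""PermCCA building blocks: residualization projections, 50%-variance PCA
against an eigendecomposition oracle, exhaustive-permutation exactness,
loading inference and bootstrap stability."""

import itertools

import numpy as np
import pandas as pd
import pytest

from neurobag.clinical_cca import (bootstrap_stability, canonical_correlations,
                                   loading_inference, pca_reduce, permcca_test,
                                   region_contributions, residualize,
                                   run_clinical_cca)


# ---------------------------------------------------------------- residualize

def test_residualize_orthogonal_confound_demeans_only():
    rng = np.random.default_rng(0)
    n = 200
    c = np.tile([1.0, -1.0], n // 2)
    y = rng.normal(size=n)
    y -= (y @ c) / (c @ c) * c          # make y exactly orthogonal to c
    res = residualize(y, c)
    np.testing.assert_allclose(res[:, 0], y - y.mean(), atol=1e-10)


def test_residualize_removes_confound_and_is_idempotent():
    rng = np.random.default_rng(1)
    c = rng.normal(size=100)
    y = 2 * c + rng.normal(size=100)
    r1 = residualize(y, c)
    assert abs(np.corrcoef(r1[:, 0], c)[0, 1]) < 1e-10
    r2 = residualize(r1, c)
    np.testing.assert_allclose(r1, r2, atol=1e-12)


def test_residualize_rejects_rank_deficient_confounds():
    rng = np.random.default_rng(2)
    z = np.column_stack([np.arange(20.0), 2 * np.arange(20.0)])
    with pytest.raises(ValueError, match="rank"):
        residualize(rng.normal(size=20), z)


# ------------------------------------------------------------------- pca

def test_pca_two_equal_variance_columns_keeps_one():
    y = np.array([[1.0, 1], [1, -1], [-1, 1], [-1, -1]])
    red = pca_reduce(y, 0.5)
    assert red.k == 1
    assert red.explained_variance_ratio[0] == pytest.approx(0.5)


def test_pca_rank_one_matrix():
    u = np.arange(10.0)[:, None]
    red = pca_reduce(u @ np.array([[1.0, 2.0, -1.0]]), 0.5)
    assert red.k == 1
    assert red.explained_variance_ratio[0] == pytest.approx(1.0)


def test_pca_component_count_matches_eigen_oracle():
    rng = np.random.default_rng(3)
    m = rng.normal(size=(80, 66)) @ np.diag(np.linspace(0.2, 3, 66))
    red = pca_reduce(m, 0.5)
    evals = np.linalg.eigvalsh(np.cov(m.T))[::-1]
    ratios = np.cumsum(evals) / evals.sum()
    assert ratios[red.k - 1] >= 0.5
    assert red.k == 1 or ratios[red.k - 2] < 0.5
    # scores round-trip through the stored basis
    np.testing.assert_allclose(red.transform(m), red.scores, atol=1e-8)


def test_pca_degenerate_matrix_rejected():
    with pytest.raises(ValueError, match="zero-variance"):
        pca_reduce(np.ones((10, 3)), 0.5)


# ------------------------------------------------------------------- permcca

def test_perfect_association_maximal_r_minimal_p():
    rng = np.random.default_rng(4)
    y = rng.normal(size=(50, 3))
    res = permcca_test(y, y.copy(), nperm=199, seed=0)
    assert res.r[0] == pytest.approx(1.0)
    assert res.p[0] == pytest.approx(1 / 200)
    assert np.all(np.diff(res.r) <= 1e-12)          # descending modes
    assert np.all((res.p >= 1 / 200) & (res.p <= 1))


def test_exhaustive_permutation_matches_enumeration_oracle():
    """For n=6 and 1-column sets, the permutation p equals brute-force
    enumeration over all 720 row orders."""
    rng = np.random.default_rng(5)
    y = rng.normal(size=(6, 1))
    x = rng.normal(size=(6, 1))
    res = permcca_test(y, x, exhaustive=True, compute_loadings=False)
    yc, xc = y[:, 0] - y.mean(), x[:, 0] - x.mean()
    obs = abs(np.corrcoef(yc, xc)[0, 1])
    count = sum(abs(np.corrcoef(yc[list(p)], xc)[0, 1]) >= obs - 1e-12
                for p in itertools.permutations(range(6)))
    assert res.p[0] == pytest.approx(count / 720)


def test_cca_invariant_to_affine_column_transforms():
    rng = np.random.default_rng(6)
    y = rng.normal(size=(60, 4))
    x = rng.normal(size=(60, 3))
    r0 = canonical_correlations(y, x)
    a = rng.normal(size=(4, 4)) + 4 * np.eye(4)
    b = rng.normal(size=(3, 3)) + 4 * np.eye(3)
    r1 = canonical_correlations(y @ a + rng.normal(size=4), x @ b - 2.0)
    np.testing.assert_allclose(r0, r1, atol=1e-8)


def test_sign_convention_and_loading_magnitudes():
    rng = np.random.default_rng(7)
    latent = rng.normal(size=120)
    y = np.column_stack([latent + 0.1 * rng.normal(size=120),
                         rng.normal(size=120)])
    x = np.column_stack([latent + 0.1 * rng.normal(size=120),
                         rng.normal(size=120)])
    res = permcca_test(y, x, nperm=99, seed=0)
    assert res.loadings_y[0] > 0.9           # dominant loading forced positive
    assert abs(res.loadings_y[1]) < 0.5
    table = loading_inference(res)
    clin = table[table["set"] == "clinical"]
    assert clin.loc[clin["variable"] == 0, "p_fwe"].iloc[0] <= 0.05


def test_pure_noise_variable_rarely_fwe_significant():
    hits = 0
    for s in range(20):
        rng = np.random.default_rng(100 + s)
        latent = rng.normal(size=80)
        y = np.column_stack([latent + 0.3 * rng.normal(size=80),
                             rng.normal(size=80)])      # second column pure noise
        x = (latent + 0.3 * rng.normal(size=80))[:, None]
        res = permcca_test(y, x, nperm=199, seed=s)
        table = loading_inference(res)
        p_noise = table[(table["set"] == "clinical")
                        & (table["variable"] == 1)]["p_fwe"].iloc[0]
        hits += p_noise < 0.05
    assert hits <= 2        # noise variable significant in <= 10% of seeds


# ------------------------------------------------------------------ bootstrap

def test_bootstrap_point_collapse_and_planted_effect():
    rng = np.random.default_rng(8)
    n = 200
    latent = rng.normal(size=n)
    y = np.column_stack([latent + 0.3 * rng.normal(size=n),
                         rng.normal(size=n)])
    x = np.column_stack([latent + 0.3 * rng.normal(size=n),
                         rng.normal(size=n)])
    one = bootstrap_stability(y, x, nboot=1, seed=0)
    assert one.r_ci[0] == pytest.approx(one.r_ci[1])
    boot = bootstrap_stability(y, x, nboot=200, seed=0)
    assert boot.r_ci[0] > 0.5               # strong planted association
    null = bootstrap_stability(rng.normal(size=(n, 2)),
                               rng.normal(size=(n, 2)), nboot=200, seed=0)
    assert null.r_ci[0] < 0.25              # null: lower bound near zero
    lo, hi = null.loading_ci_y[0]
    assert lo < 0 < hi                      # loadings unstable under the null


def test_bootstrap_requires_enough_subjects():
    rng = np.random.default_rng(9)
    with pytest.raises(ValueError, match="n >= 20"):
        bootstrap_stability(rng.normal(size=(10, 2)),
                            rng.normal(size=(10, 2)), nboot=10)


# ------------------------------------------------------------- contributions

def test_region_contributions_oracle_and_flags():
    rng = np.random.default_rng(10)
    n = 80
    variate = rng.normal(size=n)
    bag = pd.DataFrame({
        "self": variate,
        "noise": rng.normal(size=n),
        "flat": np.ones(n),
    })
    out = region_contributions(variate, bag)
    assert out.loc["self", "r"] == pytest.approx(1.0)
    assert out.loc["flat", "flag"] == "constant"
    # brute-force column-by-column oracle
    for col in ("self", "noise"):
        assert out.loc[col, "r"] == pytest.approx(
            np.corrcoef(bag[col], variate)[0, 1])
    # pure-noise regions rarely exceed |r| = 0.3 at n = 80
    exceed = 0
    for s in range(40):
        r = np.random.default_rng(s)
        exceed += abs(np.corrcoef(r.normal(size=n), variate)[0, 1]) > 0.3
    assert exceed <= 2


# ---------------------------------------------------------------- end to end

def test_run_clinical_cca_complete_cases_and_report_shape():
    rng = np.random.default_rng(11)
    n = 90
    latent = rng.normal(size=n)
    clinical = pd.DataFrame({f"v{i}": latent + rng.normal(size=n)
                             for i in range(3)})
    clinical.iloc[:5, 0] = np.nan           # incomplete cases dropped
    bag = pd.DataFrame(latent[:, None] + rng.normal(size=(n, 12)))
    conf = pd.DataFrame({"age": rng.uniform(20, 60, n)})
    rep = run_clinical_cca(bag, clinical, conf, conf, nperm=99, nboot=49, seed=0)
    assert rep.n == n - 5
    assert rep.cca.variates_y.shape[0] == n - 5
    assert rep.pca.k >= 1
    assert len(rep.contributions) == 12
    assert rep.cca.p[0] <= 0.05             # planted shared latent factor
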