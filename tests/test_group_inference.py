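"""ANCOVA (hand-computed sums of squares and an independent pingouin
cross-check), BH-FDR selection, ComBat harmonization and stratified runs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neurobag.group_inference import (ancova_compare, combat_harmonize,
                                      fdr_select, make_covariates,
                                      regional_ancova, stratified_compare)


def test_eta_squared_hand_example():
    """Groups A={1,2,3}, B={3,4,5}: SS_between=6, SS_within=4, eta_p2=0.6."""
    bag = np.array([1.0, 2, 3, 3, 4, 5])
    group = ["A"] * 3 + ["B"] * 3
    res = ancova_compare(bag, group)
    assert res.difference == pytest.approx(2.0)
    assert res.eta_p2 == pytest.approx(0.6)
    assert res.f_stat == pytest.approx(6.0)       # (6/1)/(4/4)
    assert res.ci[0] < res.difference < res.ci[1]
    # eta identity eta = F*df1 / (F*df1 + df2)
    assert res.eta_p2 == pytest.approx(
        res.f_stat * res.df1 / (res.f_stat * res.df1 + res.df2), abs=1e-10)


def test_balanced_covariates_leave_difference_unadjusted():
    rng = np.random.default_rng(0)
    cov_half = rng.normal(size=20)
    cov = pd.DataFrame({"c": np.concatenate([cov_half, cov_half])})
    bag = rng.normal(size=40) + np.repeat([0.0, 1.3], 20)
    group = np.repeat(["ctrl", "pat"], 20)
    res = ancova_compare(bag, group, cov)
    raw = bag[20:].mean() - bag[:20].mean()
    assert res.difference == pytest.approx(raw, abs=1e-10)


def test_ancova_matches_pingouin():
    """Independent cross-check of p-value and effect size."""
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(1)
    n = 80
    df = pd.DataFrame({
        "bag": rng.normal(size=n) + np.repeat([0, 0.8], n // 2),
        "group": np.repeat([0, 1], n // 2),
        "age": rng.uniform(20, 60, n),
        "tiv": rng.normal(1430, 120, n),
    })
    res = ancova_compare(df["bag"], df["group"], df[["age", "tiv"]])
    pg = pingouin.ancova(data=df, dv="bag", between="group",
                         covar=["age", "tiv"])
    row = pg[pg["Source"] == "group"].iloc[0]
    assert res.p_value == pytest.approx(row["p_unc"], rel=1e-6)
    assert res.eta_p2 == pytest.approx(row["np2"], rel=1e-6)


def test_shuffled_labels_give_uniform_pvalues():
    rng = np.random.default_rng(2)
    base = rng.normal(size=60)
    ps = []
    for s in range(60):
        r = np.random.default_rng(s)
        group = r.permutation(np.repeat(["a", "b"], 30))
        ps.append(ancova_compare(base, group).p_value)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_errors_on_degenerate_designs():
    rng = np.random.default_rng(3)
    bag = rng.normal(size=20)
    with pytest.raises(ValueError, match="2 groups"):
        ancova_compare(bag, ["a"] * 20)
    cov = pd.DataFrame({"x": np.arange(20.0), "x2": 2 * np.arange(20.0)})
    with pytest.raises(ValueError, match="collinear"):
        ancova_compare(bag, np.repeat(["a", "b"], 10), cov)


def test_bh_fdr_worked_examples():
    p_adj, sig = fdr_select([0.001, 0.01, 0.02, 0.04, 0.9], q=0.05)
    assert sig.sum() == 4
    assert not sig[-1]
    assert np.all(p_adj >= [0.001, 0.01, 0.02, 0.04, 0.9])
    _, none = fdr_select(np.ones(10), q=0.05)
    assert none.sum() == 0
    p1, s1 = fdr_select([0.01], q=0.05)
    assert p1[0] == pytest.approx(0.01) and s1[0]
    with pytest.raises(ValueError):
        fdr_select([])
    with pytest.raises(ValueError):
        fdr_select([1.5])


def test_regional_table_flags_match_threshold():
    rng = np.random.default_rng(4)
    n = 120
    group = np.repeat(["hc", "pat"], n // 2)
    bag = pd.DataFrame(rng.normal(size=(n, 30)),
                       columns=[f"bag_region_{i}" for i in range(30)])
    bag.iloc[n // 2:, :5] += 1.2
    res = regional_ancova(bag, group)
    assert (res.table["p_fdr"] >= res.table["p"] - 1e-12).all()
    assert set(res.significant_regions) >= {f"bag_region_{i}" for i in range(3)}


def test_combat_single_batch_is_identity():
    rng = np.random.default_rng(5)
    x = rng.normal(size=(30, 4))
    out = combat_harmonize(x, ["a"] * 30)
    np.testing.assert_allclose(out, x, atol=1e-8)


def test_combat_removes_additive_shift_matching_direct_standardization():
    """Two batches differing by a pure location shift, EB off: batch means
    equalized, matching the hand-computed location-scale adjustment."""
    rng = np.random.default_rng(6)
    n = 60
    batch = np.repeat(["p1", "p2"], n // 2)
    x = rng.normal(size=(n, 5))
    x[n // 2:] += 3.0
    out = combat_harmonize(x, batch, eb=False)
    diff = out[:n // 2].mean(axis=0) - out[n // 2:].mean(axis=0)
    np.testing.assert_allclose(diff, 0.0, atol=1e-8)
    # direct oracle: standardize residuals per batch, restore pooled scale/mean
    grand = 0.5 * (x[:30].mean(0) + x[30:].mean(0))
    resid = x - np.where(np.arange(n)[:, None] < 30, x[:30].mean(0), x[30:].mean(0))
    var_pooled = ((x - np.repeat([x[:30].mean(0), x[30:].mean(0)], 30, axis=0)) ** 2).mean(0)
    sd_b = np.stack([resid[:30].std(0, ddof=1), resid[30:].std(0, ddof=1)])
    z = resid / np.repeat(sd_b, 30, axis=0)
    oracle = z * np.sqrt(var_pooled) + grand
    np.testing.assert_allclose(out, oracle, atol=1e-6)


def test_combat_preserves_covariate_effect():
    """A group effect orthogonal to batch changes by < 5% after harmonization."""
    rng = np.random.default_rng(7)
    n = 200
    batch = np.tile(["p1", "p2"], n // 2)
    group = np.repeat([0.0, 1.0], n // 2)       # orthogonal to batch
    x = rng.normal(size=(n, 10))
    x[group == 1] += 1.0
    x[batch == "p2"] += 2.5
    cov = pd.DataFrame({"group": group})
    out = combat_harmonize(x, batch, covariates=cov)
    before = x[group == 1].mean() - x[group == 0].mean() - 0.0
    eff_before = (x[group == 1] - x[group == 0]).mean()
    eff_after = (out[group == 1] - out[group == 0]).mean()
    assert abs(eff_after - eff_before) / abs(eff_before) < 0.05


def test_combat_errors_and_single_feature_fallback():
    x = np.arange(8.0)[:, None]
    with pytest.raises(ValueError, match="at least 2"):
        combat_harmonize(x, ["a"] * 7 + ["b"])
    with pytest.warns(UserWarning, match="empirical Bayes"):
        out = combat_harmonize(x[:, 0], ["a", "a", "a", "a", "b", "b", "b", "b"])
    assert out.shape == (8,)


def test_stratified_identical_copies_and_reduction():
    rng = np.random.default_rng(8)
    n = 40
    bag = rng.normal(size=n) + np.repeat([0.0, 1.0], n // 2)
    group = np.repeat(["hc", "pat"], n // 2)
    cov = pd.DataFrame({"age": rng.uniform(20, 60, n)})
    # two strata that are identical copies of one dataset
    res = stratified_compare(np.tile(bag, 2), np.tile(group, 2),
                             pd.concat([cov, cov], ignore_index=True),
                             np.repeat(["s1", "s2"], n))
    assert res["s1"].difference == pytest.approx(res["s2"].difference)
    # one-stratum input equals the unstratified ANCOVA without protocol
    single = stratified_compare(bag, group, cov, ["only"] * n)["only"]
    direct = ancova_compare(bag, group, cov)
    assert single.difference == pytest.approx(direct.difference)
    assert single.p_value == pytest.approx(direct.p_value)


def test_stratified_skips_stratum_missing_a_group():
    bag = np.arange(30.0)
    group = np.array(["pat"] * 10 + ["hc"] * 10 + ["pat"] * 10)
    stratum = np.array(["a"] * 20 + ["b"] * 10)
    with pytest.warns(UserWarning, match="lacks"):
        res = stratified_compare(bag, group, None, stratum)
    assert set(res) == {"a"}


def test_make_covariates_centres_age_before_squaring():
    subjects = pd.DataFrame({"age": [30.0, 40, 50], "sex": ["F", "M", "F"],
                             "tiv_ml": [1400.0, 1500, 1450],
                             "protocol": ["a", "b", "a"]})
    cov = make_covariates(subjects)
    np.testing.assert_allclose(cov["age2"], [100.0, 0.0, 100.0])
    assert any(c.startswith("sex_") for c in cov.columns)
    assert any(c.startswith("protocol_") for c in cov.columns)


def test_omnibus_three_group_consistency():
    """With 2 groups the omnibus F equals the two-level ANCOVA F; with a
    planted 3-group gradient the omnibus rejects and the extreme pairwise
    contrast has the largest difference."""
    rng = np.random.default_rng(9)
    from neurobag.group_inference import ancova_omnibus
    n = 90
    group = np.repeat(["HC", "EM", "CM"], n // 3)
    bag = rng.normal(size=n) + np.repeat([0.0, 1.0, 2.0], n // 3)
    cov = pd.DataFrame({"age": rng.uniform(20, 60, n)})
    f, p, pairs = ancova_omnibus(bag, group, cov)
    assert p < 1e-4
    assert abs(pairs["CM_vs_HC"].difference) > abs(pairs["CM_vs_EM"].difference)
    two = ancova_omnibus(bag[:60], group[:60], cov.iloc[:60])
    direct = ancova_compare(bag[:60], group[:60], cov.iloc[:60])
    assert two[0] == pytest.approx(direct.f_stat, rel=1e-9)


def test_stratified_directions_agree_with_pooled_effect():
    """With a real pooled effect, small per-stratum estimates keep its sign."""
    agree = 0
    for s in range(10):
        rng = np.random.default_rng(50 + s)
        n = 120
        group = np.repeat(["hc", "pat"], n // 2)
        stratum = np.tile(["p1", "p2"], n // 2)
        bag = rng.normal(0, 1.0, n) + (group == "pat") * 1.5
        pooled = ancova_compare(bag, group).difference
        per = stratified_compare(bag, group, None, stratum)
        agree += all(np.sign(r.difference) == np.sign(pooled)
                     for r in per.values())
    assert agree >= 8
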