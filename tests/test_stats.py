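"""Cohort statistics: GLM, McFadden R2, lifespan model, Wilcoxon, FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest

from plexseg.stats import (DegenerateDataError, fdr_adjust, glm_gaussian,
                           lifespan_model, mcfadden_r2, wilcoxon_paired)


# ---------------------------------------------------------------- oracles

def gaussian_loglik(y, yhat):
    """ML Gaussian log-likelihood with sigma^2 = SSE/n (the GLM ML estimate)."""
    n = len(y)
    s2 = np.sum((y - yhat) ** 2) / n
    return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)


def wilcoxon_exact_enumeration(d):
    """Two-tailed signed-rank p by enumerating all sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    n = len(d)
    stats_all = [np.sum([r for r, s in zip(ranks, signs) if s])
                 for signs in itertools.product([0, 1], repeat=n)]
    stats_all = np.asarray(stats_all, float)
    mean_w = ranks.sum() / 2.0
    extreme = np.abs(stats_all - mean_w) >= abs(w_obs - mean_w) - 1e-12
    return extreme.mean()


def bh_stepup(p):
    """Hand-rolled Benjamini-Hochberg step-up with monotonicity."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        val = min(prev, p[i] * m / (rank_idx + 1))
        adj[i] = val
        prev = val
    return adj


# -------------------------------------------------------------------- glm

def test_glm_recovers_exact_linear_relationship():
    x = np.linspace(0, 10, 30)
    y = 2.5 * x + 1.0
    res = glm_gaussian(y, pd.DataFrame({"x": x}))
    assert res.params["x"] == pytest.approx(2.5, abs=1e-9)
    assert res.pvalues["x"] < 1e-12


def test_glm_null_slope_rarely_significant():
    rng = np.random.default_rng(10)
    rejections = 0
    for _ in range(100):
        x = rng.normal(size=200)
        y = rng.normal(size=200)  # independent of x
        res = glm_gaussian(y, pd.DataFrame({"x": x}))
        rejections += res.pvalues["x"] < 0.05
    assert rejections <= 10


def test_glm_rank_deficiency_rejected():
    x = np.arange(10.0)
    with pytest.raises(ValueError, match="rank"):
        glm_gaussian(x, pd.DataFrame({"a": x, "b": 2 * x}))


def test_glm_coefficients_rescale_under_affine_covariate_transform():
    rng = np.random.default_rng(11)
    x = rng.normal(50, 10, 80)
    y = 0.3 * x + rng.normal(0, 1, 80)
    r1 = glm_gaussian(y, pd.DataFrame({"x": x}))
    r2 = glm_gaussian(y, pd.DataFrame({"x": (x - 50.0) / 10.0}))
    assert r2.params["x"] == pytest.approx(10.0 * r1.params["x"], rel=1e-9)
    assert r2.pvalues["x"] == pytest.approx(r1.pvalues["x"], rel=1e-6)


# --------------------------------------------------------------- mcfadden

def test_mcfadden_trivial_values():
    assert mcfadden_r2(-100.0, -100.0) == 0.0
    assert mcfadden_r2(-50.0, -100.0) == 0.5
    with pytest.raises(ZeroDivisionError):
        mcfadden_r2(-1.0, 0.0)
    with pytest.warns(RuntimeWarning):
        mcfadden_r2(-120.0, -100.0)


def test_mcfadden_matches_hand_computed_gaussian_logliks():
    rng = np.random.default_rng(12)
    x = rng.normal(size=10)
    y = 1.5 * x + rng.normal(0, 0.3, 10)
    res = glm_gaussian(y, pd.DataFrame({"x": x}))
    beta = np.polyfit(x, y, 1)
    ll_model = gaussian_loglik(y, np.polyval(beta, x))
    ll_null = gaussian_loglik(y, np.full(10, y.mean()))
    assert res.loglik == pytest.approx(ll_model, abs=1e-6)
    assert res.loglik_null == pytest.approx(ll_null, abs=1e-6)
    assert res.mcfadden_r2 == pytest.approx(1 - ll_model / ll_null, abs=1e-6)


# --------------------------------------------------------------- lifespan

def _synthetic_lifespan_table(n=98, growth=0.15, male_offset=0.4, noise=0.05,
                              seed=0):
    rng = np.random.default_rng(seed)
    ages = np.linspace(21, 89, n)
    sexes = np.array(["M", "F"])[np.arange(n) % 2]
    vol = 1.5 * (1 + growth) ** ((ages - 20) / 10.0)
    vol = vol + np.where(sexes == "M", male_offset, 0.0)
    vol = vol + rng.normal(0, noise, n)
    tiv = rng.normal(1400, 100, n)
    return pd.DataFrame({"age": ages, "sex": sexes, "tiv_cm3": tiv,
                         "cp_volume_cm3_t1like": vol})


def test_lifespan_recovers_planted_growth_and_sex_effect():
    tab = _synthetic_lifespan_table()
    res = lifespan_model(tab, sequence="t1like")
    assert res.regression.params["age"] > 0
    assert res.regression.pvalues["age"] < 1e-3
    assert abs(res.percent_per_decade - 15.0) <= 5.0
    assert res.regression.params["sex_male"] > 0


def test_lifespan_null_sex_effect_is_uniformish():
    pvals = []
    for rep in range(40):
        tab = _synthetic_lifespan_table(male_offset=0.0, noise=0.3, seed=100 + rep)
        res = lifespan_model(tab)
        pvals.append(res.regression.pvalues["sex_male"])
    # under the null, about 5% of sex p-values fall below 0.05
    assert np.mean(np.asarray(pvals) < 0.05) <= 0.15
    assert np.mean(pvals) == pytest.approx(0.5, abs=0.2)


def test_lifespan_single_sex_cohort_drops_covariate():
    tab = _synthetic_lifespan_table()
    tab["sex"] = "F"
    with pytest.warns(RuntimeWarning, match="single-sex"):
        res = lifespan_model(tab)
    assert "sex_male" not in res.regression.params.index


def test_lifespan_requires_minimum_cohort():
    tab = _synthetic_lifespan_table(n=10)
    with pytest.raises(ValueError):
        lifespan_model(tab)


# --------------------------------------------------------------- wilcoxon

def test_wilcoxon_large_shift_is_significant():
    rng = np.random.default_rng(13)
    x = rng.normal(size=20)
    assert wilcoxon_paired(x, x + 10.0) < 1e-3


def test_wilcoxon_exact_matches_enumeration_oracle():
    x = np.array([1.3, 0.2, -0.4, 0.9, 2.1, -0.7])
    y = np.zeros(6)
    assert wilcoxon_paired(x, y) == pytest.approx(
        wilcoxon_exact_enumeration(x), abs=1e-12)


def test_wilcoxon_type_one_error_calibrated():
    rng = np.random.default_rng(14)
    rejections = 0
    reps = 1000
    for _ in range(reps):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        rejections += wilcoxon_paired(x, y) < 0.05
    assert 0.03 <= rejections / reps <= 0.07


def test_wilcoxon_degenerate_and_short_input():
    x = np.arange(6.0)
    with pytest.raises(DegenerateDataError):
        wilcoxon_paired(x, x)
    with pytest.raises(ValueError):
        wilcoxon_paired(x[:3], x[:3] + 1)


# -------------------------------------------------------------------- fdr

def test_fdr_single_p_unchanged_and_all_ones():
    assert fdr_adjust([0.037])[0] == pytest.approx(0.037)
    np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)


def test_fdr_stepup_hand_example():
    np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])


def test_fdr_matches_hand_rolled_stepup_on_random_vectors():
    rng = np.random.default_rng(15)
    for _ in range(100):
        p = rng.random(int(rng.integers(1, 12)))
        np.testing.assert_allclose(fdr_adjust(p), bh_stepup(p), atol=1e-12)


def test_fdr_never_decreases_and_validates_range():
    rng = np.random.default_rng(16)
    p = rng.random(20)
    assert (fdr_adjust(p) >= p).all()
    with pytest.raises(ValueError):
        fdr_adjust([0.5, 1.2])


# ------------------------------------------------------- property checks

from hypothesis import given, settings, strategies as st


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=15))
def test_fdr_properties_hold_for_arbitrary_pvalues(pvals):
    adj = fdr_adjust(pvals)
    p = np.asarray(pvals)
    assert (adj >= p - 1e-12).all() and (adj <= 1.0 + 1e-12).all()
    # ordering by raw p is preserved in the adjusted values
    order = np.argsort(p, kind="stable")
    assert (np.diff(adj[order]) >= -1e-12).all()
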