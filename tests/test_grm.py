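"""Graded response model: probabilities, EM estimation, information,
threshold comparison, and the response-consistency check."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import avadjust as av
from avadjust.grm import (GrmFit, GrmItemParams, category_probs, fit_grm,
                          information_curves, item_information,
                          response_consistency_check, threshold_correlation)


def _make_fit(params: list[tuple[str, float, list[float]]],
              se: float | None = None) -> GrmFit:
    items = []
    for item_id, a, b in params:
        b = np.asarray(b, dtype=float)
        items.append(GrmItemParams(
            item_id=item_id, a=a, b=b,
            se_a=se, se_b=None if se is None else np.full(len(b), se),
            n_categories=len(b) + 1))
    nodes = np.linspace(-6, 6, 61)
    w = np.exp(-nodes**2 / 2); w /= w.sum()
    return GrmFit(items=items, log_likelihood=0.0, ll_path=[0.0], nodes=nodes,
                  weights=w, converged=True, n_iter=1, n_obs=0)


# ------------------------------------------------------------- probabilities

def test_cumulative_probability_closed_forms():
    # P(X >= k) = 1/2 at theta = b_k
    p = category_probs(1.7, np.array([0.0]), np.array([0.0]))
    assert p[1, 0] == pytest.approx(0.5)
    # a = 2, theta - b = 1 -> logistic(2) ~ 0.8808
    p = category_probs(2.0, np.array([0.0]), np.array([1.0]))
    assert p[1, 0] == pytest.approx(1 / (1 + np.exp(-2)), abs=1e-6)


def test_category_probabilities_sum_to_one_everywhere():
    theta = np.linspace(-6, 6, 61)
    p = category_probs(2.3, np.array([-1.5, -0.2, 0.9, 2.1]), theta)
    assert np.allclose(p.sum(axis=0), 1.0)
    assert np.all(p >= 0)


# ----------------------------------------------------------------- estimation

def test_parameter_recovery_and_monotone_likelihood(grm_sim):
    """Fixed-seed recovery of discriminations and thresholds (RMSE <= 0.15)
    with the EM marginal likelihood non-decreasing at every iteration."""
    fit = fit_grm(grm_sim["responses"], compute_se=False)
    assert fit.converged
    a_hat = np.array([it.a for it in fit.items])
    b_hat = np.vstack([it.b for it in fit.items])
    assert np.sqrt(np.mean((a_hat - grm_sim["a"]) ** 2)) <= 0.15
    assert np.sqrt(np.mean((b_hat - grm_sim["b"]) ** 2)) <= 0.15
    assert all(y >= x - 1e-8 for x, y in zip(fit.ll_path, fit.ll_path[1:]))


def test_thresholds_ordered_and_item_order_invariance(grm_sim):
    df = grm_sim["responses"].iloc[:400]
    fit = fit_grm(df, compute_se=False)
    for it in fit.items:
        assert np.all(np.diff(it.b) > 0)
        assert it.a > 0
    # permuting item columns leaves each item's estimate unchanged
    perm = df[list(df.columns[::-1])]
    fit_p = fit_grm(perm, compute_se=False)
    for it, it_p in zip(fit.items, reversed(fit_p.items)):
        assert it.item_id == it_p.item_id
        assert it.a == pytest.approx(it_p.a, abs=1e-4)
        assert np.allclose(it.b, it_p.b, atol=1e-4)


def test_single_category_item_excluded_and_missing_rows_dropped(grm_sim):
    df = grm_sim["responses"].iloc[:300].copy()
    df["flat"] = 3
    df.iloc[0, :] = np.nan
    fit = fit_grm(df, compute_se=False)
    assert fit.excluded_items == ["flat"]
    assert fit.n_obs == 299


def test_wald_cis_contain_point_estimates(grm_sim):
    fit = fit_grm(grm_sim["responses"].iloc[:500, :4], compute_se=True)
    for it in fit.items:
        (lo_a, hi_a), ci_b = it.ci()
        assert lo_a < it.a < hi_a
        assert np.all(ci_b[:, 0] < it.b) and np.all(it.b < ci_b[:, 1])
        assert it.se_a > 0


# ---------------------------------------------------------------- information

def test_information_additivity_and_se():
    fit = _make_fit([("i1", 1.8, [-1.0, 0.0, 1.0]),
                     ("i2", 1.8, [-1.0, 0.0, 1.0])])
    ic = information_curves(fit)
    one = ic.item_information.loc["i1"].to_numpy()
    assert np.allclose(ic.test_information, 2 * one)
    # I = 4 -> SE = 0.5
    assert 1.0 / np.sqrt(4.0) == 0.5
    assert np.allclose(ic.standard_error, 1 / np.sqrt(ic.test_information))
    with pytest.raises(ValueError):
        information_curves(fit, theta=[])


def test_information_matches_numerical_derivative():
    """Graded-response information formula vs finite-difference slopes."""
    a, b = 1.6, np.array([-0.8, 0.3, 1.4])
    theta = np.array([-1.0, 0.0, 0.7])
    h = 1e-5
    p0 = category_probs(a, b, theta)
    dp = (category_probs(a, b, theta + h) - category_probs(a, b, theta - h)) / (2 * h)
    expected = (dp**2 / p0).sum(axis=0)
    assert np.allclose(item_information(a, b, theta), expected, atol=1e-6)


def test_adjusted_scores_keep_information_above_zero(dif_cohort):
    """After adjustment the 7-category items keep test information in the
    high-trait band (2 < theta < 4) where the original scale collapses."""
    cb, table = dif_cohort["codebook"], dif_cohort["table"]
    cols = [it.item_id for it in cb.items_for("conscientiousness")]
    f_o = fit_grm(table.data[cols], compute_se=False)
    f_a = fit_grm(table.data[[c + "_adj" for c in cols]], compute_se=False)
    grid = np.linspace(2.0, 4.0, 21)
    info_o = information_curves(f_o, grid).test_information.mean()
    info_a = information_curves(f_a, grid).test_information.mean()
    assert info_a > info_o


# ------------------------------------------------------ threshold correlation

def test_threshold_correlation_limits():
    b1 = [-2.0, -0.5, 1.0]
    fits = _make_fit([("i1", 1, b1), ("i2", 1, [-1.0, 0.2, 1.5]),
                      ("i3", 1, [-0.3, 0.8, 2.0])])
    same = threshold_correlation(fits, fits)
    assert np.allclose(np.diag(same.to_numpy(dtype=float)), 1.0)
    flipped = _make_fit([(f"i{j+1}", 1, list(-np.array(b)[::-1]))
                         for j, b in enumerate([b1, [-1.0, 0.2, 1.5], [-0.3, 0.8, 2.0]])])
    r = threshold_correlation(fits, flipped)
    assert r.iloc[0, 2] == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        threshold_correlation(_make_fit([("i1", 1, b1), ("i2", 1, b1)]), fits)


def test_threshold_correlation_on_dif_simulation(dif_cohort):
    """Original and adjusted thresholds of the same items are strongly
    positively related at matched indices."""
    cb, table = dif_cohort["codebook"], dif_cohort["table"]
    cols = [it.item_id for it in cb.items_for("openness")]
    f_o = fit_grm(table.data[cols], compute_se=False)
    f_a = fit_grm(table.data[[c + "_adj" for c in cols]], compute_se=False)
    r = threshold_correlation(f_o, f_a)
    band = [float(r.loc[f"orig_b{k}", f"adj_b{k + 1}"]) for k in range(1, 5)]
    assert np.mean(band) > 0.5


# -------------------------------------------------------- response consistency

def test_consistency_identical_fits_met():
    params = [("i1", 1.5, [-1.0, 0.0, 1.0, 2.0]), ("i2", 1.8, [-1.2, -0.1, 0.9, 1.9])]
    f = _make_fit(params, se=0.1)
    rep = response_consistency_check(f, f)
    assert rep.fraction_overlapping == 1.0
    assert rep.verdict == "met"


def test_consistency_disjoint_thresholds_violated():
    f1 = _make_fit([("i1", 1.5, [-1.0, 0.0, 1.0, 2.0])], se=0.01)
    f2 = _make_fit([("i1", 1.5, [9.0, 10.0, 11.0, 12.0])], se=0.01)
    rep = response_consistency_check(f1, f2)
    assert rep.fraction_overlapping == 0.0
    assert rep.verdict == "violated"


def test_consistency_mismatched_scales_rejected():
    f5 = _make_fit([("i1", 1.5, [-1.0, 0.0, 1.0, 2.0])], se=0.1)
    f7 = _make_fit([("i1", 1.5, [-2.0, -1.0, 0.0, 1.0, 2.0, 3.0])], se=0.1)
    with pytest.raises(ValueError):
        response_consistency_check(f5, f7)


def test_plotting_utilities_write_files(tmp_path, grm_sim):
    from avadjust.plotting import plot_discriminations, plot_information
    fit = fit_grm(grm_sim["responses"].iloc[:200, :3], compute_se=False,
                  max_iter=30)
    plot_information({"original": information_curves(fit)}, tmp_path / "info.png")
    plot_discriminations({"original": fit}, tmp_path / "disc.png")
    assert (tmp_path / "info.png").stat().st_size > 0
    assert (tmp_path / "disc.png").stat().st_size > 0
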