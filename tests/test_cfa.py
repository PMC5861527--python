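"""Correlated-factors CFA: discrepancy and fit indices, recovery, pruning,
and multigroup configural fit."""

import numpy as np
import pandas as pd
import pytest

from avadjust.cfa import CfaModel, configural_fit, fit_cfa, prune_items

RNG = np.random.default_rng(12)


def _five_factor_population(per=6, loadings=None, phi_off=0.25, rng=RNG):
    q = 5
    factors = tuple(f"F{i}" for i in range(q))
    pattern = {f"x{f}_{j}": f"F{f}" for f in range(q) for j in range(per)}
    model = CfaModel(pattern, factors)
    p = q * per
    lam = rng.uniform(0.4, 0.8, p) if loadings is None else np.asarray(loadings)
    item_f = np.repeat(np.arange(q), per)
    big_l = np.zeros((p, q))
    big_l[np.arange(p), item_f] = lam
    phi = np.full((q, q), phi_off)
    np.fill_diagonal(phi, 1.0)
    sigma = big_l @ phi @ big_l.T + np.diag(1 - lam**2)
    return model, lam, big_l, phi, sigma


def _sample(big_l, phi, lam, n, rng):
    q = phi.shape[0]
    eta = rng.standard_normal((n, q)) @ np.linalg.cholesky(phi).T
    x = eta @ big_l.T + rng.standard_normal((n, big_l.shape[0])) * np.sqrt(1 - lam**2)
    return pd.DataFrame(x, columns=list(big_l_names))


# column names shared between helpers
big_l_names = [f"x{f}_{j}" for f in range(5) for j in range(6)]


def test_population_covariance_is_perfectly_fit():
    """Covariance generated exactly from the model: F ~ 0, CFI 1, RMSEA 0."""
    model, lam, big_l, phi, sigma = _five_factor_population()
    fit = fit_cfa(sigma, model, n=500)
    assert fit.discrepancy == pytest.approx(0.0, abs=1e-6)
    assert fit.cfi == pytest.approx(1.0, abs=1e-6)
    assert fit.rmsea == pytest.approx(0.0, abs=1e-4)
    assert np.allclose(np.abs(fit.loadings.to_numpy()), lam, atol=1e-3)


def test_chi_square_identity_and_df():
    model, lam, big_l, phi, sigma = _five_factor_population()
    rng = np.random.default_rng(13)
    df = _sample(big_l, phi, lam, 400, rng)
    fit = fit_cfa(df, model)
    assert fit.chi2 == pytest.approx((fit.n - 1) * fit.discrepancy, rel=1e-12)
    p = 30
    assert fit.df == p * (p + 1) // 2 - (2 * p + 10)


def test_loading_recovery_at_n500():
    model, lam, big_l, phi, sigma = _five_factor_population(rng=np.random.default_rng(2))
    rng = np.random.default_rng(14)
    df = _sample(big_l, phi, lam, 500, rng)
    fit = fit_cfa(df, model)
    assert fit.converged
    assert np.max(np.abs(np.abs(fit.loadings.to_numpy()) - lam)) <= 0.1


def test_fit_invariant_to_item_reordering():
    model, lam, big_l, phi, sigma = _five_factor_population()
    rng = np.random.default_rng(15)
    df = _sample(big_l, phi, lam, 300, rng)
    fit1 = fit_cfa(df, model)
    cols = list(df.columns)[::-1]
    model2 = CfaModel({c: model.pattern[c] for c in cols}, model.factors)
    fit2 = fit_cfa(df[cols], model2)
    assert fit1.chi2 == pytest.approx(fit2.chi2, abs=1e-3)
    assert fit1.cfi == pytest.approx(fit2.cfi, abs=1e-5)


def test_non_positive_definite_covariance_rejected():
    model, *_ = _five_factor_population()
    bad = np.zeros((30, 30))
    with pytest.raises(ValueError, match="positive definite"):
        fit_cfa(bad, model, n=100)


def test_pruning_no_candidates_leaves_model_unchanged():
    model, lam, big_l, phi, sigma = _five_factor_population()
    rng = np.random.default_rng(16)
    df = _sample(big_l, phi, lam, 400, rng)
    final, fit, audit = prune_items(df, model)
    assert final.pattern == model.pattern
    assert audit == []


def test_pruning_removes_the_most_negative_item_first():
    lam = RNG.uniform(0.5, 0.7, 30)
    lam[7] = -0.05
    model, lam, big_l, phi, sigma = _five_factor_population(loadings=lam)
    rng = np.random.default_rng(17)
    df = _sample(big_l, phi, lam, 600, rng)
    final, fit, audit = prune_items(df, model)
    assert audit and audit[0].item == big_l_names[7]
    assert audit[0].loading < 0


def test_pruning_44_item_battery_with_8_bad_items_reaches_36():
    """A 44-item five-factor battery with 8 deliberately dead/miskeyed items
    prunes to exactly the 36 good items."""
    counts = {"E": 8, "A": 9, "C": 9, "N": 8, "O": 10}
    rng = np.random.default_rng(18)
    pattern = {f"{f}{j}": f for f in counts for j in range(counts[f])}
    names = list(pattern)
    bad = ["E0", "E1", "A0", "A1", "C0", "C1", "N0", "N1"]
    lam = np.array([rng.uniform(-0.10, 0.05) if nm in bad
                    else rng.uniform(0.45, 0.75) for nm in names])
    fmap = {f: i for i, f in enumerate(counts)}
    item_f = np.array([fmap[pattern[nm]] for nm in names])
    big_l = np.zeros((44, 5))
    big_l[np.arange(44), item_f] = lam
    phi = np.full((5, 5), 0.25); np.fill_diagonal(phi, 1.0)
    eta = rng.standard_normal((600, 5)) @ np.linalg.cholesky(phi).T
    x = eta @ big_l.T + rng.standard_normal((600, 44)) * np.sqrt(1 - np.minimum(lam**2, 0.9))
    df = pd.DataFrame(x, columns=names)
    final, fit, audit = prune_items(df, CfaModel(pattern, tuple(counts)))
    assert len(final.items) == 36
    assert sorted(s.item for s in audit) == sorted(bad)


def test_configural_identical_groups_doubles_statistics():
    model, lam, big_l, phi, sigma = _five_factor_population()
    rng = np.random.default_rng(19)
    df = _sample(big_l, phi, lam, 300, rng)
    single = fit_cfa(df, model)
    combined, per_group = configural_fit({"g1": df, "g2": df}, model)
    assert combined.chi2 == pytest.approx(2 * single.chi2, rel=1e-6)
    assert combined.df == 2 * single.df
    assert combined.cfi == pytest.approx(single.cfi, abs=0.02)


def test_configural_same_generator_groups_close_to_single_group():
    model, lam, big_l, phi, sigma = _five_factor_population()
    rng = np.random.default_rng(20)
    g1 = _sample(big_l, phi, lam, 350, rng)
    g2 = _sample(big_l, phi, lam, 350, rng)
    pooled = fit_cfa(pd.concat([g1, g2], ignore_index=True), model)
    combined, _ = configural_fit({"g1": g1, "g2": g2}, model)
    assert abs(combined.cfi - pooled.cfi) < 0.05


def test_configural_fit_degrades_with_opposite_sign_loadings():
    """Injecting sign-flipped loadings in one group breaks configural fit
    below the CFI 0.90 criterion."""
    model, lam, big_l, phi, sigma = _five_factor_population(
        rng=np.random.default_rng(30))
    rng = np.random.default_rng(21)
    g1 = _sample(big_l, phi, lam, 350, rng)
    # group 2: half the items load with opposite sign on a *different* factor
    big_l2 = big_l.copy()
    for j in range(0, 30, 2):
        f = np.argmax(np.abs(big_l2[j]))
        big_l2[j, f] = 0.0
        big_l2[j, (f + 2) % 5] = -lam[j]
    g2 = _sample(big_l2, phi, lam, 350, rng)
    mixed = pd.concat([g1, g2], ignore_index=True)
    pooled = fit_cfa(mixed, model)
    assert pooled.cfi < 0.90


def test_adjusted_scores_fit_better_than_raw_on_dif_cohort(dif_cohort):
    cb, table = dif_cohort["codebook"], dif_cohort["table"]
    raw = fit_cfa(table.data, CfaModel.from_codebook(cb))
    adj = fit_cfa(table.data, CfaModel.from_codebook(cb, suffix="_adj"))
    assert adj.cfi > raw.cfi
    assert adj.rmsea <= 0.08 and adj.cfi >= 0.90
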