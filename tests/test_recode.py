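"""Vignette recoding engine: exhaustive oracle agreement, order
classification, chance baselines, entropy, and survey-level recoding."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import avadjust as av
from avadjust.recode import (chance_baselines, classify_order, recode_item,
                             recode_survey, vignette_entropy, order_statistics)

M, K = 5, 3


def oracle_interval(y: int, z: tuple[int, ...]) -> list[int]:
    """Brute-force category set from weak-order-extension semantics.

    Vignette-vignette ties may refine to either order; the self-rating keeps
    its strict observed relations and, when tied with vignettes, must stay
    weakly inside the tied block (equal to a member or between members).
    A category c (odd: gap, even: exact tie) is consistent if the tied
    vignettes can be split into below/equal/above positions accordingly.
    """
    k = len(z)
    below = sum(v < y for v in z)
    above = sum(v > y for v in z)
    tied = k - below - above
    cats = []
    for c in range(1, 2 * k + 2):
        n_below = (c - 1) // 2
        n_eq = 1 if c % 2 == 0 else 0
        n_above = k - n_below - n_eq
        t_below = n_below - below
        t_above = n_above - above
        if t_below < 0 or t_above < 0 or n_eq > tied:
            continue
        if t_below + t_above + n_eq != tied:
            continue
        if tied >= 1 and (t_below + n_eq == 0 or t_above + n_eq == 0):
            continue  # self strictly outside its tied block
        cats.append(c)
    return cats


# ---------------------------------------------------------------- recode_item

@pytest.mark.parametrize("y,z,expected", [
    (1, (2, 3, 4), 1),   # self below all vignettes
    (2, (2, 3, 4), 2),   # self equals the lowest vignette
    (3, (2, 4, 5), 3),   # self strictly between vignettes 1 and 2
    (3, (2, 3, 4), 4),   # self equals the middle vignette
    (4, (2, 3, 5), 5),   # self strictly between vignettes 2 and 3
    (4, (2, 3, 4), 6),   # self equals the highest vignette
    (5, (2, 3, 4), 7),   # self above all vignettes
])
def test_recode_rules_on_correctly_ordered_vignettes(y, z, expected):
    """The seven canonical recoding rules for strictly ordered vignettes."""
    score = recode_item(y, z)
    assert score.scalar == expected
    assert score.lo == score.hi == expected
    assert not score.violation


@pytest.mark.parametrize("y,z,lo,hi,scalar", [
    (3, (3, 3, 4), 2, 4, 2),   # double tie with self -> interval, lower bound
    (2, (4, 2, 3), 2, 2, 2),   # violation treated as tie via the multiset
    (3, (2, 2, 3), 6, 6, 6),
])
def test_tie_and_violation_intervals(y, z, lo, hi, scalar):
    s = recode_item(y, z)
    assert (s.lo, s.hi, s.scalar) == (lo, hi, scalar)


def test_exhaustive_agreement_with_weak_order_oracle():
    """All 625 (y, z) combinations match the brute-force enumeration of
    weak-order extensions, and every interval is a contiguous block."""
    for y in range(1, M + 1):
        for z in itertools.product(range(1, M + 1), repeat=K):
            cats = oracle_interval(y, z)
            assert cats == list(range(cats[0], cats[-1] + 1))
            s = recode_item(y, z)
            assert (s.lo, s.hi) == (cats[0], cats[-1]), (y, z)
            assert recode_item(y, z, scalarization="upper").scalar == cats[-1]
            mid = recode_item(y, z, scalarization="midpoint").scalar
            assert cats[0] <= mid <= cats[-1]


@given(y=st.integers(1, M), z=st.lists(st.integers(1, M), min_size=K, max_size=K))
@settings(max_examples=200, deadline=None)
def test_ties_mode_is_permutation_invariant(y, z):
    base = recode_item(y, z)
    for perm in itertools.permutations(z):
        s = recode_item(y, perm)
        assert (s.lo, s.hi, s.scalar) == (base.lo, base.hi, base.scalar)


@given(z=st.lists(st.integers(1, M), min_size=K, max_size=K))
@settings(max_examples=200, deadline=None)
def test_lower_bound_scalar_monotone_in_self_rating(z):
    scalars = [recode_item(y, z).scalar for y in range(1, M + 1)]
    assert scalars == sorted(scalars)


@given(y=st.integers(1, M), z=st.lists(st.integers(1, M), min_size=K, max_size=K))
@settings(max_examples=200, deadline=None)
def test_strict_interval_contains_ties_scalar_without_contradiction(y, z):
    if classify_order(z) == "violation":
        return
    ties = recode_item(y, z, mode="ties")
    strict = recode_item(y, z, mode="strict")
    assert strict.lo <= ties.scalar <= strict.hi


# ------------------------------------------------------------- classify_order

@pytest.mark.parametrize("z,label", [
    ((2, 3, 4), "correct"),
    ((1, 1, 3), "tie"),
    ((2, 1, 3), "violation"),
    ((2, 1, 1), "violation"),   # violation takes precedence over tie
])
def test_classify_order(z, label):
    assert classify_order(z) == label


# ----------------------------------------------------------- chance baselines

def test_chance_baselines_five_point_three_vignettes():
    """Exact enumeration of the 125 triples: 8% / 20% / 72%."""
    pc, pt, pv = chance_baselines(5, 3)
    assert pc == pytest.approx(10 / 125)
    assert pt == pytest.approx(25 / 125)
    assert pv == pytest.approx(90 / 125)
    assert pc + pt + pv == pytest.approx(1.0)


@pytest.mark.parametrize("m,k,pc", [(2, 2, 0.25), (1, 3, 0.0)])
def test_chance_baseline_edge_cases(m, k, pc):
    p_correct, p_tie, p_violation = chance_baselines(m, k)
    assert p_correct == pytest.approx(pc)
    if m == 1:
        assert p_tie == pytest.approx(1.0)


def test_chance_baselines_closed_form_matches_enumeration():
    for m, k in [(5, 3), (7, 3), (4, 2)]:
        pc, pt, pv = chance_baselines(m, k)
        assert pc == pytest.approx(math.comb(m, k) / m**k)
        assert pc + pt == pytest.approx(math.comb(m + k - 1, k) / m**k)


# ---------------------------------------------------------------- entropy

def test_entropy_known_distributions():
    assert vignette_entropy(list(range(1, 8)), 7) == pytest.approx(np.log(7))
    assert vignette_entropy([3] * 10, 7) == pytest.approx(0.0)
    assert vignette_entropy([1, 1, 5, 5], 7) == pytest.approx(np.log(2))
    with pytest.raises(ValueError):
        vignette_entropy([np.nan], 7)


# ------------------------------------------------------------- recode_survey

def test_recode_survey_range_missing_propagation(tiny_codebook, tiny_table):
    keyed = av.apply_keying(tiny_table, tiny_codebook)
    adjusted, means = recode_survey(keyed, tiny_codebook)
    adj_cols = [c for c in adjusted.data.columns if c.endswith("_adj")]
    vals = adjusted.data[adj_cols].stack().dropna()
    assert vals.between(1, 7).all()
    # r4's g2 is missing -> g2_adj missing, other items still recoded
    assert pd.isna(adjusted.data.loc["r4", "g2_adj"])
    assert not pd.isna(adjusted.data.loc["r4", "g1_adj"])
    assert {"mean_original", "mean_adjusted"} <= set(means.columns)


def test_identical_ratings_hit_full_tie_interval(tiny_codebook):
    """Self equal to all K vignettes: interval [2, 2K], lower bound 2."""
    df = pd.DataFrame({
        "group": ["a"], "g1": [3], "g2": [3], "g3": [3],
        "grit_v1": [3], "grit_v2": [3], "grit_v3": [3],
        "h1": [1], "h2": [1], "h3": [1],
    }, index=pd.Index(["r1"], name="respondent"))
    table = av.apply_keying(av.from_dataframe(df, tiny_codebook), tiny_codebook)
    adjusted, _ = recode_survey(table, tiny_codebook)
    # g2 is reverse keyed: 3 stays 3 on a 5-point scale, so all selfs tie all
    for col in ("g1_adj", "g2_adj", "g3_adj"):
        assert adjusted.data.loc["r1", col] == 2
    s = recode_item(3, (3, 3, 3))
    assert (s.lo, s.hi) == (2, 6)


# ------------------------------------------------------------ order statistics

def test_order_statistics_flags_and_percentages(tiny_codebook):
    n = 40
    rng = np.random.default_rng(1)
    base = {"g1": rng.integers(1, 6, n), "g2": rng.integers(1, 6, n),
            "g3": rng.integers(1, 6, n),
            "h1": rng.integers(1, 6, n), "h2": rng.integers(1, 6, n),
            "h3": rng.integers(1, 6, n)}
    # 34 correct orders, 6 violations -> 15% violations, flag on
    z1 = [2] * n; z2 = [3] * n; z3 = [4] * n
    for i in range(6):
        z1[i], z2[i] = 3, 2
    df = pd.DataFrame({"group": ["a"] * n, **base,
                       "grit_v1": z1, "grit_v2": z2, "grit_v3": z3},
                      index=pd.Index([f"r{i}" for i in range(n)], name="respondent"))
    table = av.from_dataframe(df, tiny_codebook)
    diag = order_statistics(table, tiny_codebook, by_group=False)
    row = diag.table.loc[("grit", "all")]
    assert row["pct_violation"] == pytest.approx(15.0)
    assert row[["pct_correct", "pct_tie", "pct_violation"]].sum() == pytest.approx(100.0)
    assert diag.problematic() == ["grit"]

    # all correctly ordered -> flag off
    df2 = df.copy()
    df2["grit_v1"], df2["grit_v2"], df2["grit_v3"] = 2, 3, 4
    diag2 = order_statistics(av.from_dataframe(df2, tiny_codebook),
                             tiny_codebook, by_group=False)
    assert diag2.table.loc[("grit", "all"), "pct_correct"] == pytest.approx(100.0)
    assert diag2.problematic() == []


def test_uniform_random_ratings_match_chance_baselines(tiny_codebook):
    """Monte-Carlo order statistics agree with the exact enumeration."""
    n = 4000
    rng = np.random.default_rng(7)
    df = pd.DataFrame({
        "group": ["a"] * n,
        "g1": rng.integers(1, 6, n), "g2": rng.integers(1, 6, n),
        "g3": rng.integers(1, 6, n),
        "grit_v1": rng.integers(1, 6, n), "grit_v2": rng.integers(1, 6, n),
        "grit_v3": rng.integers(1, 6, n),
        "h1": [1] * n, "h2": [1] * n, "h3": [1] * n,
    }, index=pd.Index(range(n), name="respondent"))
    diag = order_statistics(av.from_dataframe(df, tiny_codebook),
                            tiny_codebook, by_group=False)
    row = diag.table.loc[("grit", "all")]
    pc, pt, pv = diag.chance
    for obs, exp in [(row["pct_correct"], pc), (row["pct_tie"], pt),
                     (row["pct_violation"], pv)]:
        assert obs / 100 == pytest.approx(exp, abs=3 * np.sqrt(exp * (1 - exp) / n))
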