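"""Shared fixtures: a tiny hand-built survey and session-scope simulated
cohorts (generated once; several test modules read them)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import avadjust as av
from avadjust.datamodel import (ItemSpec, LikertScale, OutcomeScale,
                                SurveyCodebook, VignetteSet, from_dataframe)


@pytest.fixture()
def tiny_codebook() -> SurveyCodebook:
    """One construct, three 5-point items (one reverse keyed), K=3 vignettes,
    one 2-item outcome."""
    return SurveyCodebook(
        constructs=("grit",),
        items=(
            ItemSpec("g1", "grit", False, LikertScale(5)),
            ItemSpec("g2", "grit", True, LikertScale(5)),
            ItemSpec("g3", "grit", False, LikertScale(5)),
        ),
        vignette_sets={"grit": VignetteSet("grit", ("grit_v1", "grit_v2", "grit_v3"),
                                          LikertScale(5))},
        outcomes=(OutcomeScale("happy", ("h1", "h2", "h3"), LikertScale(5)),),
        group_column="group",
    )


@pytest.fixture()
def tiny_table(tiny_codebook) -> av.ResponseTable:
    df = pd.DataFrame({
        "group": ["a", "a", "b", "b"],
        "g1": [1, 3, 5, 2],
        "g2": [2, 3, 1, pd.NA],
        "g3": [4, 3, 5, 2],
        "grit_v1": [2, 2, 2, 2],
        "grit_v2": [3, 3, 3, 1],
        "grit_v3": [4, 4, 4, 3],
        "h1": [1, 2, 3, 4],
        "h2": [2, 2, 4, 4],
        "h3": [1, 3, 3, 5],
    }, index=pd.Index(["r1", "r2", "r3", "r4"], name="respondent"))
    return from_dataframe(df, tiny_codebook)


@pytest.fixture(scope="session")
def dif_cohort():
    """Default study conditions (two groups, threshold-shift DIF, response
    styles), keyed, cleaned, and recoded; with aligned truth records."""
    res = av.simulate(av.SimConfig(), seed=0)
    keyed = av.apply_keying(res.table, res.codebook)
    cleaned, report = av.apply_cleaning(keyed, res.codebook)
    adjusted, means = av.recode_survey(cleaned, res.codebook)
    truth = res.truth.loc[adjusted.data.index]
    return {"codebook": res.codebook, "table": adjusted, "truth": truth,
            "cleaning_report": report, "item_means": means}


@pytest.fixture(scope="session")
def grm_sim():
    """Fixed-seed graded-response data with known parameters
    (8 items, 5 categories, n=2000)."""
    rng = np.random.default_rng(2024)
    n, p, m = 2000, 8, 5
    a = rng.uniform(1.0, 2.5, p)
    b = np.sort(rng.uniform(-2.0, 2.0, (p, m - 1)), axis=1)
    for j in range(p):
        for k in range(1, m - 1):
            b[j, k] = max(b[j, k], b[j, k - 1] + 0.25)
    theta = rng.standard_normal(n)
    from scipy.special import expit
    x = np.empty((n, p))
    for j in range(p):
        cum = expit(a[j] * (theta[:, None] - b[j][None, :]))
        u = rng.random((n, 1))
        x[:, j] = 1 + (u < cum).sum(axis=1)
    return {"responses": pd.DataFrame(x, columns=[f"i{j}" for j in range(p)]),
            "a": a, "b": b, "theta": theta}
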