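"""Test-criterion validity: scale scoring, Spearman correlations with
outcomes, and Steiger's test for the change in a dependent correlation.

Scale scores are available-case item means (a score is missing when fewer
than half the items were answered).  Constructs flagged as score-reversed in
the codebook (e.g. neuroticism measured through emotional-stability
vignettes) are flipped at scoring time so reported signs follow the
construct's conventional direction.

The raw-vs-adjusted comparison uses Steiger's z for two dependent
correlations sharing one variable (the outcome), via Fisher's
transformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ResponseTable, SurveyCodebook

__all__ = ["scale_scores", "spearman_with_outcomes",
           "compare_dependent_correlations", "criterion_table"]


def scale_scores(
    table: ResponseTable,
    codebook: SurveyCodebook,
    adjusted: bool = False,
    suffix: str = "_adj",
    min_answered: float = 0.5,
    apply_score_reversal: bool = True,
) -> pd.DataFrame:
    """Construct and outcome scale scores (available-case item means).

    With ``adjusted=True`` construct scores use the ``<item>_adj`` columns
    (range ``1..2K+1``); outcomes always use their original columns.
    """
    out: dict[str, pd.Series] = {}
    for c in codebook.constructs:
        cols = [it.item_id + (suffix if adjusted else "") for it in codebook.items_for(c)]
        block = table.data[cols].astype("Float64").astype(float)
        enough = block.notna().mean(axis=1) >= min_answered
        score = block.mean(axis=1).where(enough)
        if apply_score_reversal and c in codebook.score_reversed_constructs:
            if adjusted:
                vs = codebook.vignette_sets[c]
                top = 2 * vs.k + 2            # scale 1..2K+1 flips as (2K+2) - x
            else:
                top = codebook.items_for(c)[0].scale.n_categories + 1
            score = top - score
        out[c] = score
    for o in codebook.outcomes:
        block = table.data[list(o.item_ids)].astype("Float64").astype(float)
        enough = block.notna().mean(axis=1) >= min_answered
        out[o.outcome_id] = block.mean(axis=1).where(enough)
    return pd.DataFrame(out, index=table.data.index)


def spearman_with_outcomes(
    scores: pd.DataFrame,
    constructs: list[str],
    outcomes: list[str],
    min_n: int = 10,
) -> pd.DataFrame:
    """Spearman rho (average-rank ties, two-sided t-approximation p) of each
    construct score with each outcome score.  Pairs with a constant vector
    or fewer than ``min_n`` complete observations are reported as missing."""
    rows = []
    for c in constructs:
        for o in outcomes:
            pair = scores[[c, o]].dropna()
            if len(pair) < min_n or pair[c].nunique() < 2 or pair[o].nunique() < 2:
                rows.append({"construct": c, "outcome": o, "rho": np.nan,
                             "n": len(pair), "p": np.nan})
                continue
            rho, p = stats.spearmanr(pair[c], pair[o])
            rows.append({"construct": c, "outcome": o, "rho": float(rho),
                         "n": len(pair), "p": float(p)})
    return pd.DataFrame(rows).set_index(["construct", "outcome"])


def compare_dependent_correlations(
    r13: float, r23: float, r12: float, n: int,
) -> tuple[float, float]:
    """Steiger's z for H0: rho(1,3) = rho(2,3) with variable 3 shared.

    Variables 1 and 2 are the two predictors (raw and adjusted score), 3 the
    common outcome; ``r12`` is their correlation.  Returns ``(z, p)`` with a
    two-sided p-value.
    """
    if n <= 10:
        raise ValueError(f"Steiger's test needs n > 10, got {n}")
    for r in (r13, r23, r12):
        if abs(r) >= 1.0:
            raise ValueError("correlations must be strictly inside (-1, 1)")
    z13, z23 = np.arctanh(r13), np.arctanh(r23)
    rm2 = (r13**2 + r23**2) / 2.0
    f = min((1.0 - r12) / (2.0 * (1.0 - rm2)), 1.0)
    h = (1.0 - f * rm2) / (1.0 - rm2)
    z = (z13 - z23) * np.sqrt((n - 3) / (2.0 * (1.0 - r12) * h))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class CriterionTable:
    """Construct x outcome comparison of raw vs adjusted Spearman rho."""

    table: pd.DataFrame

    def __str__(self) -> str:
        return self.table.round(3).to_string()


def criterion_table(
    raw_scores: pd.DataFrame,
    adj_scores: pd.DataFrame,
    constructs: list[str],
    outcomes: list[str],
) -> CriterionTable:
    """Raw and adjusted outcome correlations side by side, with Steiger's
    difference test on the shared respondents."""
    rows = []
    for c in constructs:
        for o in outcomes:
            trio = pd.concat({"raw": raw_scores[c], "adj": adj_scores[c],
                              "out": raw_scores[o]}, axis=1).dropna()
            n = len(trio)
            rec = {"construct": c, "outcome": o, "n": n,
                   "rho_raw": np.nan, "p_raw": np.nan,
                   "rho_adjusted": np.nan, "p_adjusted": np.nan,
                   "z_diff": np.nan, "p_diff": np.nan}
            if n >= 10 and trio.nunique().min() > 1:
                ranks = trio.rank()
                r_raw, p_raw = stats.spearmanr(trio["raw"], trio["out"])
                r_adj, p_adj = stats.spearmanr(trio["adj"], trio["out"])
                r12 = float(ranks["raw"].corr(ranks["adj"]))
                rec.update(rho_raw=float(r_raw), p_raw=float(p_raw),
                           rho_adjusted=float(r_adj), p_adjusted=float(p_adj))
                if n > 10 and max(abs(r_raw), abs(r_adj), abs(r12)) < 1.0:
                    z, p = compare_dependent_correlations(r_raw, r_adj, r12, n)
                    rec.update(z_diff=z, p_diff=p)
            rows.append(rec)
    return CriterionTable(pd.DataFrame(rows).set_index(["construct", "outcome"]))
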