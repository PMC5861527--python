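"""Non-parametric anchoring-vignette recoding and vignette diagnostics.

A respondent's self-rating ``y`` on an m-point scale is located relative to
their own ratings ``z_1..z_K`` of K vignettes of known intended ordering,
producing an adjusted category on a ``2K+1``-point scale: odd categories are
the gaps below/between/above the vignettes, even categories are exact ties
with a vignette.

With ties or order violations among the vignette ratings the adjusted answer
is an *interval* of categories rather than a single value.  Following
standard practice for the non-parametric approach, order violations are
treated as ties — operationally, the recoding depends only on the multiset
of vignette ratings — and the interval is collapsed to its lower bound by
default.

Let ``B = #{j : z_j < y}`` and ``E = #{j : z_j = y}``.  Then

* ``E = 0``  ->  the single category ``2B + 1``;
* ``E >= 1`` ->  the interval ``[2B + 2, 2B + 2E]``.

A ``strict`` mode is also provided that keeps the design order of the
vignettes: each comparison of ``y`` against ``z_j`` constrains the adjusted
category, the constraints are intersected, and a contradictory set of
constraints (an order violation) widens the result to the span of the
conflicting bounds.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .datamodel import ResponseTable, SchemaError, SurveyCodebook

__all__ = [
    "AdjustedScore",
    "recode_item",
    "recode_survey",
    "classify_order",
    "chance_baselines",
    "vignette_entropy",
    "order_statistics",
    "VignetteDiagnostics",
]

Mode = Literal["ties", "strict"]
Scalarization = Literal["lower", "upper", "midpoint"]


@dataclass(frozen=True)
class AdjustedScore:
    """An interval on the recoded ``1..2K+1`` scale plus its scalar value."""

    lo: int
    hi: int
    scalar: int
    tie: bool
    violation: bool

    def __post_init__(self) -> None:
        if not (1 <= self.lo <= self.hi):
            raise ValueError("invalid adjusted interval")
        if not (self.lo <= self.scalar <= self.hi):
            raise ValueError("scalar must lie inside the interval")


def _scalarize(lo: int, hi: int, rule: Scalarization) -> int:
    if rule == "lower":
        return lo
    if rule == "upper":
        return hi
    if rule == "midpoint":
        return (lo + hi) // 2
    raise ValueError(f"unknown scalarization {rule!r}")


def classify_order(z: Sequence[int]) -> str:
    """Classify one vignette rating vector (in design order).

    ``violation`` if any strict decrease between consecutive design ranks
    (violations take precedence over ties), else ``tie`` if any equality,
    else ``correct``.
    """
    z = list(z)
    if any(b < a for a, b in zip(z, z[1:])):
        return "violation"
    if any(b == a for a, b in zip(z, z[1:])):
        return "tie"
    return "correct"


def recode_item(
    y: int,
    z: Sequence[int],
    mode: Mode = "ties",
    scalarization: Scalarization = "lower",
) -> AdjustedScore:
    """Recode one self-rating against one respondent's K vignette ratings.

    Parameters
    ----------
    y : self-rating, ``1..m``.
    z : vignette ratings listed by design rank.
    mode : ``"ties"`` (default) treats order violations as ties and is
        invariant to permutations of ``z``; ``"strict"`` respects the design
        order and spans contradictions.
    scalarization : which point of the interval becomes the scalar value.
    """
    z = [int(v) for v in z]
    y = int(y)
    k = len(z)
    label = classify_order(z)
    tie, violation = label == "tie", label == "violation"

    if mode == "ties":
        b = sum(v < y for v in z)
        e = sum(v == y for v in z)
        if e == 0:
            lo = hi = 2 * b + 1
        else:
            lo, hi = 2 * b + 2, 2 * b + 2 * e
    elif mode == "strict":
        # Each design-rank comparison constrains the category; contradictions
        # (order violations) leave an empty intersection, which is widened to
        # the span between the clashing bounds.
        lo_b, hi_b = 1, 2 * k + 1
        eq: list[int] = []
        for j, v in enumerate(z, start=1):
            if y > v:
                lo_b = max(lo_b, 2 * j + 1)
            elif y < v:
                hi_b = min(hi_b, 2 * j - 1)
            else:
                eq.append(2 * j)
        if eq:
            lo_c, hi_c = max(lo_b, min(eq)), min(hi_b, max(eq))
        else:
            lo_c, hi_c = lo_b, hi_b
        if lo_c > hi_c:
            lo_c, hi_c = hi_c, lo_c
        lo, hi = lo_c, hi_c
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return AdjustedScore(lo=lo, hi=hi, scalar=_scalarize(lo, hi, scalarization),
                         tie=tie, violation=violation)


def recode_survey(
    table: ResponseTable,
    codebook: SurveyCodebook,
    mode: Mode = "ties",
    scalarization: Scalarization = "lower",
    suffix: str = "_adj",
) -> tuple[ResponseTable, pd.DataFrame]:
    """Recode every self-report item against its construct's vignette set.

    Returns the table with ``<item>_adj`` columns appended (original columns
    retained) and a per-item summary of means before and after adjustment.
    Respondents with any missing rating in a construct's vignette set get
    missing adjusted values for that construct's items only.
    """
    if not table.keyed:
        raise SchemaError("recode_survey expects a keyed table (apply_keying first)")
    out = table.copy()
    rows = []
    for construct in codebook.constructs:
        if construct not in codebook.vignette_sets:
            raise SchemaError(f"construct {construct!r} has no vignette set")
        vs = codebook.vignette_sets[construct]
        zmat = out.data[list(vs.item_ids)]
        complete = zmat.notna().all(axis=1)
        for it in codebook.items_for(construct):
            src = out.data[it.item_id]
            adj = pd.array([pd.NA] * len(src), dtype="Int64")
            mask = complete & src.notna()
            idx = np.flatnonzero(mask.to_numpy())
            vals = src.to_numpy(dtype=float)
            zvals = zmat.to_numpy(dtype=float)
            scal = [
                recode_item(int(vals[i]), [int(v) for v in zvals[i]], mode, scalarization).scalar
                for i in idx
            ]
            adj[idx] = scal
            out.data[it.item_id + suffix] = adj
            rows.append({
                "item": it.item_id,
                "construct": construct,
                "mean_original": float(src.astype("Float64").mean()),
                "mean_adjusted": float(out.data[it.item_id + suffix].astype("Float64").mean()),
            })
    return out, pd.DataFrame(rows).set_index("item")


def chance_baselines(m: int, k: int) -> tuple[float, float, float]:
    """Probabilities of correct order / ties / violations under random rating.

    All ``m**k`` rating tuples equiprobable.  Computed by exact enumeration
    when feasible and by closed-form combinatorics otherwise; the two agree:
    ``P(correct) = C(m,k)/m**k`` and
    ``P(correct or tie) = C(m+k-1,k)/m**k`` (non-decreasing tuples).
    """
    if m < 1 or k < 2:
        raise ValueError("need m >= 1 and K >= 2")
    total = m ** k
    p_correct_cf = math.comb(m, k) / total
    p_nondec_cf = math.comb(m + k - 1, k) / total
    if total <= 200_000:
        counts = {"correct": 0, "tie": 0, "violation": 0}
        for tup in itertools.product(range(1, m + 1), repeat=k):
            counts[classify_order(tup)] += 1
        p_correct = counts["correct"] / total
        p_tie = counts["tie"] / total
        p_violation = counts["violation"] / total
        assert math.isclose(p_correct, p_correct_cf) and math.isclose(p_correct + p_tie, p_nondec_cf)
        return p_correct, p_tie, p_violation
    return p_correct_cf, p_nondec_cf - p_correct_cf, 1.0 - p_nondec_cf


def vignette_entropy(scores: Sequence[int] | pd.Series, n_categories: int) -> float:
    """Shannon entropy (nats) of the scalarized adjusted-category distribution.

    An index of how informatively a vignette set partitions respondents:
    0 when everyone lands in one category, ``ln(n_categories)`` at uniform.
    """
    s = pd.Series(scores).dropna()
    if s.empty:
        raise ValueError("entropy undefined: no non-missing adjusted scores")
    p = s.value_counts(normalize=True).to_numpy(dtype=float)
    return float(-(p * np.log(p)).sum())


@dataclass
class VignetteDiagnostics:
    """Per-construct (x group) order-statistics table plus chance baselines."""

    table: pd.DataFrame              # construct x group rows
    chance: tuple[float, float, float]
    violation_threshold: float = 0.10

    def problematic(self) -> list[str]:
        flagged = self.table[self.table["pct_violation"] > 100 * self.violation_threshold]
        return sorted(set(flagged.index.get_level_values("construct")))


def order_statistics(
    table: ResponseTable,
    codebook: SurveyCodebook,
    by_group: bool = True,
    violation_threshold: float = 0.10,
) -> VignetteDiagnostics:
    """Percent correct / tie / violation orderings per construct (and group).

    Percentages are over complete vignette-set cases; constructs with zero
    complete cases are omitted.  A construct is flagged problematic when its
    violation percentage exceeds ``violation_threshold`` (default the 10 %
    measurement-error rule of thumb) in any group.
    """
    groups = table.group_labels()
    keys = sorted(groups.unique()) if by_group else ["all"]
    rows = []
    m = k = None
    for construct, vs in codebook.vignette_sets.items():
        m, k = vs.scale.n_categories, vs.k
        zmat = table.data[list(vs.item_ids)]
        complete = zmat.notna().all(axis=1)
        for g in keys:
            sel = complete if g == "all" else complete & (groups == g)
            sub = zmat[sel].to_numpy(dtype=float)
            if len(sub) == 0:
                continue
            labels = pd.Series([classify_order([int(v) for v in row]) for row in sub])
            pct = labels.value_counts(normalize=True) * 100
            rows.append({
                "construct": construct,
                "group": g,
                "n": len(sub),
                "pct_correct": float(pct.get("correct", 0.0)),
                "pct_tie": float(pct.get("tie", 0.0)),
                "pct_violation": float(pct.get("violation", 0.0)),
            })
    if not rows:
        raise ValueError("no construct had complete vignette ratings")
    df = pd.DataFrame(rows).set_index(["construct", "group"])
    return VignetteDiagnostics(table=df, chance=chance_baselines(m, k),
                               violation_threshold=violation_threshold)
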