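"""A-priori participant removal rules and removal accounting.

Four rules, evaluated on the original (pre-removal) keyed table; a
respondent is removed when *any* rule fires and is reported under the first
firing rule, in this fixed order:

1. ``missing`` — more than ``max_missing_fraction`` of the survey columns
   unanswered (default > 10 %).
2. ``low_variance`` — population variance of the respondent's own answered
   self-report + vignette responses strictly below ``min_response_variance``
   (default 0.5).
3. ``pattern`` — straightlining: the longest run of identical consecutive
   responses over the self-report + vignette columns, as a fraction of
   answered columns, at or above ``straightline_run_fraction``.
4. ``consistent_violations`` — vignette-order violations in at least
   ``consistent_violation_min_sets`` of the vignette sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import ResponseTable, SurveyCodebook
from .recode import classify_order

__all__ = ["CleaningConfig", "CleaningReport", "apply_cleaning"]

REASONS = ("missing", "low_variance", "pattern", "consistent_violations")


@dataclass(frozen=True)
class CleaningConfig:
    max_missing_fraction: float = 0.10
    min_response_variance: float = 0.5
    straightline_run_fraction: float = 0.9
    consistent_violation_min_sets: int = 3
    # which columns count toward the missing rule; all survey columns by default
    missing_over_all_columns: bool = True

    def __post_init__(self) -> None:
        for name in ("max_missing_fraction", "straightline_run_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_response_variance < 0:
            raise ValueError("min_response_variance must be >= 0")
        if self.consistent_violation_min_sets < 1:
            raise ValueError("consistent_violation_min_sets must be >= 1")


@dataclass
class CleaningReport:
    removed: dict[str, str]            # respondent id -> first firing reason
    n_initial: int
    counts: dict[str, int] = field(init=False)
    removal_percentage: float = field(init=False)

    def __post_init__(self) -> None:
        self.counts = {r: sum(1 for v in self.removed.values() if v == r) for r in REASONS}
        self.removal_percentage = 100.0 * len(self.removed) / self.n_initial

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "n_initial": self.n_initial,
            "n_removed": len(self.removed),
            "removal_percentage": self.removal_percentage,
            "counts": self.counts,
            "removed": self.removed,
        }, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def summary(self) -> str:
        lines = [f"cleaning: removed {len(self.removed)}/{self.n_initial} "
                 f"({self.removal_percentage:.1f}%)"]
        lines += [f"  {r}: {c}" for r, c in self.counts.items() if c]
        return "\n".join(lines)


def _longest_run_fraction(values: np.ndarray) -> float:
    """Longest identical-response run over answered cells / answered count."""
    answered = values[~pd.isna(values)]
    if len(answered) == 0:
        return 0.0
    best = run = 1
    for a, b in zip(answered, answered[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best / len(answered)


def apply_cleaning(
    table: ResponseTable,
    codebook: SurveyCodebook,
    config: CleaningConfig | None = None,
) -> tuple[ResponseTable, CleaningReport]:
    """Apply the four removal rules; returns cleaned table and report."""
    config = config or CleaningConfig()
    if table.n == 0:
        raise ValueError("cannot clean an empty table")

    all_cols = codebook.all_columns()
    sv_cols = codebook.item_columns() + codebook.vignette_columns()
    miss_cols = all_cols if config.missing_over_all_columns else sv_cols

    removed: dict[str, str] = {}
    data = table.data
    miss_frac = data[miss_cols].isna().mean(axis=1)
    for rid in data.index:
        reason = None
        if miss_frac.loc[rid] > config.max_missing_fraction:
            reason = "missing"
        else:
            row = data.loc[rid, sv_cols].to_numpy(dtype=object)
            answered = np.array([float(v) for v in row if not pd.isna(v)])
            if len(answered) and float(np.var(answered)) < config.min_response_variance:
                reason = "low_variance"
            elif _longest_run_fraction(row) >= config.straightline_run_fraction:
                reason = "pattern"
            else:
                n_viol = 0
                for vs in codebook.vignette_sets.values():
                    z = data.loc[rid, list(vs.item_ids)]
                    if z.notna().all() and classify_order([int(v) for v in z]) == "violation":
                        n_viol += 1
                if n_viol >= config.consistent_violation_min_sets:
                    reason = "consistent_violations"
        if reason is not None:
            removed[str(rid)] = reason

    report = CleaningReport(removed=removed, n_initial=table.n)
    keep = [rid for rid in data.index if str(rid) not in removed]
    cleaned = ResponseTable(data.loc[keep].copy(), keyed=table.keyed,
                            _group_col=table._group_col)
    return cleaned, report
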