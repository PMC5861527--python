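"""Domain types and I/O for ordinal survey data with anchoring vignettes.

The central objects are :class:`SurveyCodebook` — the measurement design
(constructs, items, reverse keying, vignette sets with their intended
ordering, outcome scales, group column) — and :class:`ResponseTable`, a thin
wrapper around a pandas DataFrame of 1-based integer Likert responses with a
group label per respondent.

Conventions
-----------
* Category codes are consecutive integers ``1..m`` (any source coding must be
  mapped before load).
* Missing responses are a single canonical missing state (pandas ``NA`` in
  nullable integer columns; empty cells in CSV).
* Reverse keying (``x -> m + 1 - x``) orients every item in its construct's
  *vignette* direction and is applied exactly once, before vignette recoding.
  Constructs whose reported scale scores run opposite to the vignette
  direction (e.g. neuroticism scored from emotional-stability vignettes) are
  listed in ``score_reversed_constructs`` and flipped only at scoring time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "LikertScale",
    "ItemSpec",
    "VignetteSet",
    "OutcomeScale",
    "SurveyCodebook",
    "ResponseTable",
    "SchemaError",
    "ValidationError",
    "StateError",
    "load_survey",
    "load_codebook",
    "from_dataframe",
    "apply_keying",
]


class SchemaError(ValueError):
    """Codebook/data structure mismatch (unknown column, wrong layout)."""


class ValidationError(ValueError):
    """A cell value violates its declared scale range."""


class StateError(RuntimeError):
    """An operation was applied in an invalid order (e.g. keying twice)."""


@dataclass(frozen=True)
class LikertScale:
    """An ordinal response scale with consecutive category codes ``1..m``."""

    n_categories: int

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ValueError(f"a Likert scale needs m >= 2 categories, got {self.n_categories}")

    @property
    def codes(self) -> range:
        return range(1, self.n_categories + 1)

    def reverse(self, x: int) -> int:
        """Reverse-key a single code: ``x -> m + 1 - x``."""
        return self.n_categories + 1 - x


@dataclass(frozen=True)
class ItemSpec:
    item_id: str
    construct: str
    reverse_keyed: bool = False
    scale: LikertScale = field(default_factory=lambda: LikertScale(5))


@dataclass(frozen=True)
class VignetteSet:
    """Vignette item ids ordered by design rank (low -> high trait level)."""

    construct: str
    item_ids: tuple[str, ...]
    scale: LikertScale = field(default_factory=lambda: LikertScale(5))

    def __post_init__(self) -> None:
        if len(self.item_ids) < 2:
            raise ValueError("a vignette set needs K >= 2 vignettes")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValueError("duplicate vignette item ids")

    @property
    def k(self) -> int:
        return len(self.item_ids)


@dataclass(frozen=True)
class OutcomeScale:
    outcome_id: str
    item_ids: tuple[str, ...]
    scale: LikertScale = field(default_factory=lambda: LikertScale(5))
    reverse_keyed_items: tuple[str, ...] = ()


@dataclass(frozen=True)
class SurveyCodebook:
    """The full measurement design of one survey administration."""

    constructs: tuple[str, ...]
    items: tuple[ItemSpec, ...]
    vignette_sets: Mapping[str, VignetteSet]
    outcomes: tuple[OutcomeScale, ...] = ()
    group_column: str = "group"
    score_reversed_constructs: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        known = set(self.constructs)
        for it in self.items:
            if it.construct not in known:
                raise SchemaError(f"item {it.item_id!r} references unknown construct {it.construct!r}")
        for c, vs in self.vignette_sets.items():
            if c not in known or vs.construct != c:
                raise SchemaError(f"vignette set for {c!r} does not match a declared construct")
        cols = list(self.all_columns())
        dupes = {c for c in cols if cols.count(c) > 1}
        if dupes:
            raise SchemaError(f"column ids used twice: {sorted(dupes)}")

    # -- lookups ---------------------------------------------------------
    def items_for(self, construct: str) -> tuple[ItemSpec, ...]:
        return tuple(it for it in self.items if it.construct == construct)

    def item_columns(self) -> list[str]:
        return [it.item_id for it in self.items]

    def vignette_columns(self) -> list[str]:
        return [v for c in self.constructs if c in self.vignette_sets for v in self.vignette_sets[c].item_ids]

    def outcome_columns(self) -> list[str]:
        return [i for o in self.outcomes for i in o.item_ids]

    def all_columns(self) -> list[str]:
        return self.item_columns() + self.vignette_columns() + self.outcome_columns()

    def scale_for(self, column: str) -> LikertScale:
        for it in self.items:
            if it.item_id == column:
                return it.scale
        for vs in self.vignette_sets.values():
            if column in vs.item_ids:
                return vs.scale
        for o in self.outcomes:
            if column in o.item_ids:
                return o.scale
        raise SchemaError(f"unknown column {column!r}")

    # -- (de)serialization ----------------------------------------------
    @classmethod
    def from_dict(cls, d: Mapping) -> "SurveyCodebook":
        items = tuple(
            ItemSpec(
                item_id=str(i["id"]),
                construct=str(i["construct"]),
                reverse_keyed=bool(i.get("reverse", False)),
                scale=LikertScale(int(i.get("scale", 5))),
            )
            for i in d["items"]
        )
        vsets = {
            str(c): VignetteSet(
                construct=str(c),
                item_ids=tuple(str(v) for v in spec["ids"]) if isinstance(spec, Mapping) else tuple(map(str, spec)),
                scale=LikertScale(int(spec.get("scale", 5))) if isinstance(spec, Mapping) else LikertScale(5),
            )
            for c, spec in d.get("vignettes", {}).items()
        }
        outcomes = tuple(
            OutcomeScale(
                outcome_id=str(o["id"]),
                item_ids=tuple(str(i) for i in o["ids"]),
                scale=LikertScale(int(o.get("scale", 5))),
                reverse_keyed_items=tuple(str(i) for i in o.get("reverse", [])),
            )
            for o in d.get("outcomes", [])
        )
        return cls(
            constructs=tuple(str(c) for c in d["constructs"]),
            items=items,
            vignette_sets=vsets,
            outcomes=outcomes,
            group_column=str(d.get("group_column", "group")),
            score_reversed_constructs=frozenset(d.get("score_reversed", [])),
        )

    def to_dict(self) -> dict:
        return {
            "constructs": list(self.constructs),
            "items": [
                {"id": it.item_id, "construct": it.construct, "reverse": it.reverse_keyed,
                 "scale": it.scale.n_categories}
                for it in self.items
            ],
            "vignettes": {
                c: {"ids": list(vs.item_ids), "scale": vs.scale.n_categories}
                for c, vs in self.vignette_sets.items()
            },
            "outcomes": [
                {"id": o.outcome_id, "ids": list(o.item_ids), "scale": o.scale.n_categories,
                 "reverse": list(o.reverse_keyed_items)}
                for o in self.outcomes
            ],
            "group_column": self.group_column,
            "score_reversed": sorted(self.score_reversed_constructs),
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class ResponseTable:
    """Respondents x ordinal responses, plus group labels.

    ``data`` holds one row per respondent (index = respondent id), one
    nullable-integer column per survey column, and the group column as
    strings. ``keyed`` records whether reverse keying has been applied.
    """

    data: pd.DataFrame
    keyed: bool = False

    _group_col: str = "group"

    @property
    def n(self) -> int:
        return len(self.data)

    def group_labels(self) -> pd.Series:
        return self.data[self._group_col]

    def copy(self) -> "ResponseTable":
        return ResponseTable(self.data.copy(), keyed=self.keyed, _group_col=self._group_col)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=True, index_label="respondent")


def _validate(df: pd.DataFrame, codebook: SurveyCodebook) -> None:
    cols = codebook.all_columns()
    missing_cols = [c for c in cols + [codebook.group_column] if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"data is missing declared columns: {missing_cols}")
    for c in cols:
        m = codebook.scale_for(c).n_categories
        col = df[c]
        bad = col.dropna()[(col.dropna() < 1) | (col.dropna() > m)]
        if len(bad):
            row = bad.index[0]
            raise ValidationError(
                f"value {bad.iloc[0]} out of range 1..{m} in column {c!r}, respondent {row!r}"
            )


def load_codebook(path: str | Path) -> SurveyCodebook:
    with open(path) as fh:
        return SurveyCodebook.from_dict(yaml.safe_load(fh))


def from_dataframe(df: pd.DataFrame, codebook: SurveyCodebook, keyed: bool = False) -> ResponseTable:
    """Validate and canonicalize a raw DataFrame into a ResponseTable."""
    df = df.copy()
    for c in codebook.all_columns():
        if c in df.columns:
            df[c] = pd.array(pd.to_numeric(df[c], errors="coerce"), dtype="Int64")
    _validate(df, codebook)
    df[codebook.group_column] = df[codebook.group_column].astype(str)
    ordered = [codebook.group_column] + codebook.all_columns()
    return ResponseTable(df[ordered], keyed=keyed, _group_col=codebook.group_column)


def load_survey(codebook_path: str | Path, data_path: str | Path) -> tuple[SurveyCodebook, ResponseTable]:
    """Load a YAML codebook and a wide-format CSV of responses.

    Round trip contract: writing the returned table with
    :meth:`ResponseTable.to_csv` and re-loading yields identical values,
    missingness and grouping.
    """
    codebook = load_codebook(codebook_path)
    df = pd.read_csv(data_path, index_col="respondent")
    return codebook, from_dataframe(df, codebook)


def apply_keying(table: ResponseTable, codebook: SurveyCodebook) -> ResponseTable:
    """Orient every reverse-keyed column in construct direction (``m+1-x``).

    Applies to reverse-keyed self-report items and reverse-keyed outcome
    items; vignette columns are never keyed (the design rank already encodes
    direction). Raises :class:`StateError` if the table is already keyed.
    """
    if table.keyed:
        raise StateError("keying has already been applied to this table")
    out = table.copy()
    rev: list[tuple[str, int]] = [
        (it.item_id, it.scale.n_categories) for it in codebook.items if it.reverse_keyed
    ]
    rev += [
        (i, o.scale.n_categories) for o in codebook.outcomes for i in o.reverse_keyed_items
    ]
    for col, m in rev:
        out.data[col] = (m + 1 - out.data[col]).astype("Int64")
    out.keyed = True
    return out
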