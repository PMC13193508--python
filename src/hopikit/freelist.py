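"""Free-list recall data: parsing, validation and standardization.

A free list is one respondent's ordered recall of the objects they remember
from the stimulus ("Write down a list of all objects in the picture you can
remember").  Order carries information: ranks are 1-based, rank 1 is the
first object mentioned, and the list length L together with an item's rank
R_j are the ingredients of the salience index computed downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from hopikit.lexicon import Lexicon, normalize_term

logger = logging.getLogger(__name__)


class FreeListError(ValueError):
    """Raised for structurally invalid free-list input."""


@dataclass(frozen=True)
class FreeList:
    """One respondent's ordered recall terms.

    ``items[k]`` is the raw term at rank ``k + 1``; ranks are therefore
    consecutive 1..L by construction.  Terms must be non-empty after
    trimming.
    """

    respondent_id: str
    group: str
    items: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.items:
            raise FreeListError(f"respondent {self.respondent_id!r}: empty list")
        for term in self.items:
            if not str(term).strip():
                raise FreeListError(f"respondent {self.respondent_id!r}: blank term in list")

    @property
    def L(self) -> int:
        """List length."""
        return len(self.items)

    def ranks(self) -> range:
        return range(1, self.L + 1)


@dataclass(frozen=True)
class StandardizedItem:
    raw: str
    canonical: str
    macro_category: str
    specificity: str | None
    rank: int
    flag: Literal["mapped", "collective", "unmapped", "duplicate-dropped"]


@dataclass(frozen=True)
class StandardizedList:
    """A free list after lexicon standardization.

    ``items`` hold the surviving entries with re-validated consecutive ranks
    1..L'; entries removed by the duplicate policy are kept in ``dropped``
    for provenance.
    """

    respondent_id: str
    group: str
    items: tuple[StandardizedItem, ...]
    dropped: tuple[StandardizedItem, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for expected, item in enumerate(self.items, start=1):
            if item.rank != expected:
                raise FreeListError(
                    f"respondent {self.respondent_id!r}: ranks not consecutive "
                    f"(found {item.rank} at position {expected})"
                )

    @property
    def L(self) -> int:
        return len(self.items)

    def canonicals(self) -> tuple[str, ...]:
        return tuple(item.canonical for item in self.items)


# ---------------------------------------------------------------------------
# parsing


def parse_freelists(
    table: pd.DataFrame,
    format: Literal["wide", "long"] = "wide",
) -> list[FreeList]:
    """Parse a tabular free-list export into :class:`FreeList` objects.

    Wide format: one row per respondent with columns ``id``, ``group`` and
    rank columns ``item_1`` .. ``item_k`` (trailing empties ignored; an
    internal gap is a rank error).  Long format: columns ``id``, ``group``,
    ``rank``, ``term`` with explicit 1-based ranks.

    Respondents whose list is empty after cleaning are excluded with a
    logged warning; duplicate respondent ids and non-consecutive ranks are
    errors.
    """
    if format == "wide":
        return _parse_wide(table)
    if format == "long":
        return _parse_long(table)
    raise ValueError(f"unknown format {format!r}")


def _clean(cell: object) -> str:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return ""
    return str(cell).strip()


def _check_unique_ids(ids: Sequence[str]) -> None:
    seen: set[str] = set()
    for rid in ids:
        if rid in seen:
            raise FreeListError(f"duplicate respondent id {rid!r}")
        seen.add(rid)


def _parse_wide(table: pd.DataFrame) -> list[FreeList]:
    item_cols = sorted(
        (c for c in table.columns if str(c).startswith("item_")),
        key=lambda c: int(str(c).split("_", 1)[1]),
    )
    if not item_cols:
        raise FreeListError("wide table has no item_<rank> columns")
    _check_unique_ids([str(r) for r in table["id"]])
    lists: list[FreeList] = []
    for _, row in table.iterrows():
        rid = str(row["id"])
        cells = [_clean(row[c]) for c in item_cols]
        while cells and not cells[-1]:
            cells.pop()
        if any(not c for c in cells):
            raise FreeListError(f"respondent {rid!r}: non-consecutive ranks (internal empty cell)")
        if not cells:
            logger.warning("respondent %r excluded: empty list after cleaning", rid)
            continue
        lists.append(FreeList(respondent_id=rid, group=str(row["group"]), items=tuple(cells)))
    return lists


def _parse_long(table: pd.DataFrame) -> list[FreeList]:
    lists: list[FreeList] = []
    ids_in_order = list(dict.fromkeys(str(v) for v in table["id"]))
    grouped = {str(k): g for k, g in table.groupby("id", sort=False)}
    for rid in ids_in_order:
        g = grouped[rid].assign(rank=grouped[rid]["rank"].astype(int)).sort_values("rank")
        ranks = [int(r) for r in g["rank"]]
        if ranks != list(range(1, len(ranks) + 1)):
            raise FreeListError(f"respondent {rid!r}: non-consecutive ranks {ranks}")
        terms = [_clean(t) for t in g["term"]]
        terms = [t for t in terms if t]
        if len(terms) != len(ranks):
            raise FreeListError(f"respondent {rid!r}: blank term at an explicit rank")
        if not terms:
            logger.warning("respondent %r excluded: empty list after cleaning", rid)
            continue
        group = str(g["group"].iloc[0])
        lists.append(FreeList(respondent_id=rid, group=group, items=tuple(terms)))
    return lists


def read_freelists(
    path: str | Path,
    format: Literal["wide", "long"] = "wide",
    dialect: Literal["standard", "eu"] = "standard",
) -> list[FreeList]:
    """Read a free-list CSV.  ``dialect='eu'`` accepts semicolon-separated,
    decimal-comma exports common in the study region."""
    kwargs = {"sep": ";", "decimal": ","} if dialect == "eu" else {}
    return parse_freelists(pd.read_csv(path, dtype=str, **kwargs), format=format)


# ---------------------------------------------------------------------------
# standardization


def standardize(
    freelist: FreeList,
    lexicon: Lexicon,
    duplicate_policy: Literal["first", "error"] = "first",
) -> FreeList | StandardizedList:
    """Map a raw free list onto canonical, categorized objects.

    Each term is normalized (case, accents, whitespace) and looked up in the
    lexicon.  Terms mapping to a collective canonical ("bird", "beetle") are
    flagged ``collective``; unmapped terms become their own canonical with
    macro-category ``unknown``.  When two raw terms resolve to the same
    canonical, ``duplicate_policy='first'`` keeps the earliest mention and
    closes the rank gap (so the earliest rank dominates salience);
    ``'error'`` raises instead.

    Standardization is idempotent at the canonical level: applying it to an
    already-standardized list of canonicals changes nothing.
    """
    seen: dict[str, int] = {}
    kept: list[StandardizedItem] = []
    dropped: list[StandardizedItem] = []
    raw_items = freelist.items if isinstance(freelist, FreeList) else freelist.canonicals()
    for original_rank, raw in enumerate(raw_items, start=1):
        canonical = lexicon.canonical_of(raw)
        if canonical is None:
            canonical = normalize_term(raw)
            flag = "unmapped"
        elif lexicon.is_collective(canonical):
            flag = "collective"
        else:
            flag = "mapped"
        macro = lexicon.macro_of(canonical)
        spec = lexicon.specificity_of(canonical)
        if canonical in seen:
            if duplicate_policy == "error":
                raise FreeListError(
                    f"respondent {freelist.respondent_id!r}: duplicate canonical {canonical!r}"
                )
            dropped.append(
                StandardizedItem(raw, canonical, macro, spec, original_rank, "duplicate-dropped")
            )
            continue
        new_rank = len(kept) + 1
        seen[canonical] = new_rank
        kept.append(StandardizedItem(raw, canonical, macro, spec, new_rank, flag))
    return StandardizedList(
        respondent_id=freelist.respondent_id,
        group=freelist.group,
        items=tuple(kept),
        dropped=tuple(dropped),
    )


def standardize_all(
    freelists: Iterable[FreeList],
    lexicon: Lexicon,
    duplicate_policy: Literal["first", "error"] = "first",
) -> list[StandardizedList]:
    return [standardize(fl, lexicon, duplicate_policy) for fl in freelists]
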