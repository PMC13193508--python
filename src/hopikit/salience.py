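"""Smith's salience index and per-respondent category salience.

For an object mentioned at rank :math:`R_j` in a list of length :math:`L`,
the positional kernel is :math:`(L - R_j + 1)/L`: 1 for the first mention,
:math:`1/L` for the last, and 0 for no mention at all.  Smith's salience of
an object over a sample of N lists is

.. math:: S = \\frac{1}{N} \\sum_{\\text{lists containing it}} \\frac{L - R_j + 1}{L},

so :math:`S \\in [0, 1]` with :math:`S = 1` iff the object opens every list.
The per-respondent *personal salience* of a macro-category c sums the same
kernel over that respondent's items in c and normalizes by the list length:

.. math:: S_p(c) = \\frac{1}{L} \\sum_{j \\in c} \\frac{L - R_j + 1}{L}.

Averaging :math:`S_p` over the respondents of a group (the 1/N step) yields
the group-level category salience.  When every item of a list belongs to
one of the three macro-categories the per-respondent values satisfy the
exact identity :math:`\\sum_c S_p(c) = (L+1)/(2L)`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from hopikit.freelist import StandardizedList
from hopikit.lexicon import MACRO_CATEGORIES

logger = logging.getLogger(__name__)


def positional_weight(L: int, rank: int) -> float:
    """Kernel (L - R + 1)/L for a 1-based rank in a list of length L."""
    if not 1 <= rank <= L:
        raise ValueError(f"rank {rank} outside 1..{L}")
    return (L - rank + 1) / L


# ---------------------------------------------------------------------------
# per-object salience


def item_salience(
    lists: Sequence[StandardizedList],
    roster: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Smith's salience for every object over a sample of standardized lists.

    Returns a DataFrame indexed by canonical object with columns
    ``macro_category``, ``salience``, ``mention_count``, ``mean_rank`` and
    ``N``.  Objects present in ``roster`` but absent from every list are
    included with salience 0 (the mention/non-mention distinction central to
    the index); without a roster only mentioned objects appear.
    """
    if not lists:
        raise ValueError("empty sample: need at least one list")
    N = len(lists)
    weight_sum: dict[str, float] = {}
    count: dict[str, int] = {}
    rank_sum: dict[str, int] = {}
    macro: dict[str, str] = {}
    for sl in lists:
        L = sl.L
        for item in sl.items:
            w = (L - item.rank + 1) / L
            weight_sum[item.canonical] = weight_sum.get(item.canonical, 0.0) + w
            count[item.canonical] = count.get(item.canonical, 0) + 1
            rank_sum[item.canonical] = rank_sum.get(item.canonical, 0) + item.rank
            macro.setdefault(item.canonical, item.macro_category)
    objects = set(weight_sum)
    if roster is not None:
        objects |= set(roster)
    rows = []
    for obj in sorted(objects):
        c = count.get(obj, 0)
        rows.append(
            {
                "object": obj,
                "macro_category": macro.get(obj, "unknown"),
                "salience": weight_sum.get(obj, 0.0) / N,
                "mention_count": c,
                "mean_rank": rank_sum[obj] / c if c else np.nan,
                "N": N,
            }
        )
    return pd.DataFrame(rows).set_index("object")


def top_k_salient(table: pd.DataFrame, category: str, k: int) -> pd.DataFrame:
    """The k most salient objects of one macro-category.

    Ties on salience are broken by higher mention count, then
    lexicographically by object name, so the selection is deterministic.
    Returns all available objects (with a warning) if the category has
    fewer than k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sub = table[table["macro_category"] == category].reset_index()
    ordered = sub.sort_values(
        by=["salience", "mention_count", "object"],
        ascending=[False, False, True],
    ).set_index("object")
    if len(ordered) < k:
        warnings.warn(
            f"category {category!r} has only {len(ordered)} objects (< k={k})",
            stacklevel=2,
        )
        return ordered
    return ordered.head(k)


# ---------------------------------------------------------------------------
# personal (per-respondent, per-category) salience


@dataclass(frozen=True)
class PersonalSalience:
    respondent_id: str
    group: str
    sp: dict[str, float]  # macro-category -> S_p

    def __getitem__(self, category: str) -> float:
        return self.sp[category]


def personal_category_salience(
    slist: StandardizedList,
    literal_formula: bool = False,
    N: int | None = None,
) -> PersonalSalience:
    """Per-respondent salience of each of the three macro-categories.

    ``S_p(c) = [sum over items in c of (L - R_j + 1)/L] / L``.  Items with
    macro-category ``unknown`` contribute to no category (they still count
    towards L).  ``literal_formula=True`` additionally divides by the sample
    size ``N`` — an audit mode reproducing the double-normalized variant of
    the printed formula; the default applies the 1/N step once, at group
    averaging, which is the only reading consistent with group means in the
    0.2-0.3 range.
    """
    L = slist.L
    if L == 0:
        raise ValueError(f"respondent {slist.respondent_id!r}: empty list")
    sp = {c: 0.0 for c in MACRO_CATEGORIES}
    for item in slist.items:
        if item.macro_category in sp:
            sp[item.macro_category] += (L - item.rank + 1) / L
    denom = L
    if literal_formula:
        if N is None:
            raise ValueError("literal_formula=True requires N")
        denom = L * N
    return PersonalSalience(
        respondent_id=slist.respondent_id,
        group=slist.group,
        sp={c: v / denom for c, v in sp.items()},
    )


def personal_salience_table(
    lists: Sequence[StandardizedList],
    literal_formula: bool = False,
) -> pd.DataFrame:
    """Long-form table of S_p: one row per respondent with group and the
    three category columns."""
    N = len(lists)
    rows = []
    for sl in lists:
        ps = personal_category_salience(sl, literal_formula=literal_formula, N=N)
        rows.append({"respondent_id": ps.respondent_id, "group": ps.group, **ps.sp})
    return pd.DataFrame(rows)


def mean_personal_salience(personals: Iterable[PersonalSalience] | pd.DataFrame) -> pd.DataFrame:
    """Mean and sample (n-1) standard deviation of S_p per category.

    Accepts either PersonalSalience objects or the table from
    :func:`personal_salience_table`; rows are the three macro-categories,
    columns ``mean``, ``sd``, ``n``.
    """
    if isinstance(personals, pd.DataFrame):
        df = personals
    else:
        rows = [{"respondent_id": p.respondent_id, "group": p.group, **p.sp} for p in personals]
        df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("empty group")
    out = pd.DataFrame(
        {
            "mean": [df[c].mean() for c in MACRO_CATEGORIES],
            "sd": [df[c].std(ddof=1) for c in MACRO_CATEGORIES],
            "n": len(df),
        },
        index=pd.Index(MACRO_CATEGORIES, name="category"),
    )
    return out


# ---------------------------------------------------------------------------
# general vs specific plant terms


def specificity_salience(lists: Sequence[StandardizedList]) -> pd.DataFrame:
    """Per-respondent summed positional weight of general- versus
    specific-plant terms (same kernel as S_p, normalized by L).

    Returns one row per respondent with columns ``group``, ``general`` and
    ``specific``; group means feed the paired general-vs-specific
    comparison and the between-group contrast on specific-term salience.
    Emits a warning (and all-zero columns) when no plant item occurs
    anywhere.
    """
    rows = []
    any_plant = False
    for sl in lists:
        L = sl.L
        acc = {"general": 0.0, "specific": 0.0}
        for item in sl.items:
            if item.macro_category == "plant" and item.specificity in acc:
                acc[item.specificity] += (L - item.rank + 1) / L
                any_plant = True
        rows.append(
            {
                "respondent_id": sl.respondent_id,
                "group": sl.group,
                "general": acc["general"] / L,
                "specific": acc["specific"] / L,
            }
        )
    if not any_plant:
        warnings.warn("no plant items in any list; specificity salience all zero", stacklevel=2)
    return pd.DataFrame(rows)


def specificity_group_means(per_respondent: pd.DataFrame) -> pd.DataFrame:
    """Group means of the per-respondent general/specific plant weights."""
    return per_respondent.groupby("group")[["general", "specific"]].mean()
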