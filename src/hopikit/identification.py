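"""Rubric scoring of species-identification answers.

Respondents see an image crop of each target species and name it.  Answers
are scored on a four-level rubric:

====  ==========================================================
3     correct at species level (e.g., "spruce" for the spruce)
2     a *different* species named, but within the correct order or
      higher group (e.g., "fir tree")
1     correct order-or-higher group only (e.g., "conifer")
0     blank or unrecognized
====  ==========================================================

Which strings count for which level is encoded in the answer key, not
inferred linguistically — deterministic scoring over cleverness.  Aggregates
are the per-taxon arithmetic mean and standard deviation over respondents,
and a per-kingdom (plant/animal) grand mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import yaml

from hopikit.lexicon import normalize_term

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KeyEntry:
    """Accepted answers for one target taxon."""

    taxon: str
    kingdom: Literal["plant", "animal"]
    species_answers: frozenset[str]  # level 3
    wrong_species_answers: frozenset[str]  # level 2: named species, right group
    higher_answers: frozenset[str]  # level 1: order-or-higher terms

    def __post_init__(self) -> None:
        if not self.species_answers:
            raise ValueError(f"taxon {self.taxon!r}: empty species-level answer set")
        for a, b, la, lb in (
            (self.species_answers, self.higher_answers, 3, 1),
            (self.species_answers, self.wrong_species_answers, 3, 2),
            (self.wrong_species_answers, self.higher_answers, 2, 1),
        ):
            overlap = a & b
            if overlap:
                raise ValueError(
                    f"taxon {self.taxon!r}: answers in both level {la} and {lb}: {sorted(overlap)}"
                )


@dataclass
class IdentificationKey:
    entries: dict[str, KeyEntry] = field(default_factory=dict)

    def __getitem__(self, taxon: str) -> KeyEntry:
        return self.entries[taxon]

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.entries

    def taxa(self, kingdom: str | None = None) -> list[str]:
        return [t for t, e in self.entries.items() if kingdom in (None, e.kingdom)]

    @classmethod
    def from_mapping(cls, doc: Mapping[str, Mapping[str, object]]) -> "IdentificationKey":
        entries = {}
        for taxon, e in doc.items():
            entries[taxon] = KeyEntry(
                taxon=taxon,
                kingdom=str(e["kingdom"]),
                species_answers=frozenset(normalize_term(a) for a in e.get("level3", [])),
                wrong_species_answers=frozenset(normalize_term(a) for a in e.get("level2", [])),
                higher_answers=frozenset(normalize_term(a) for a in e.get("level1", [])),
            )
        return cls(entries)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "IdentificationKey":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))


def score_response(entry: KeyEntry, answer: str) -> int:
    """Score one raw answer against a key entry on the 0-3 rubric.

    Case- and whitespace-insensitive.  Non-blank answers matching no set
    score 0; they are logged so the key can be curated.
    """
    norm = normalize_term(answer) if answer else ""
    if not norm:
        return 0
    if norm in entry.species_answers:
        return 3
    if norm in entry.wrong_species_answers:
        return 2
    if norm in entry.higher_answers:
        return 1
    logger.info("unscored term %r for taxon %r", answer, entry.taxon)
    return 0


def score_table(key: IdentificationKey, responses: pd.DataFrame) -> pd.DataFrame:
    """Score a long-form response table (columns ``respondent``, ``taxon``,
    ``answer``) into a respondent x taxon score matrix."""
    unknown = set(responses["taxon"]) - set(key.entries)
    if unknown:
        raise KeyError(f"taxa missing from key: {sorted(unknown)}")
    scored = responses.assign(
        score=[
            score_response(key[t], a if isinstance(a, str) else "")
            for t, a in zip(responses["taxon"], responses["answer"])
        ]
    )
    return scored.pivot(index="respondent", columns="taxon", values="score")


def aggregate_scores(
    scores: pd.DataFrame,
    key: IdentificationKey,
    kingdom_mean: Literal["taxon", "cell"] = "taxon",
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-taxon mean/sd and per-kingdom grand means.

    ``scores`` is the respondent x taxon matrix from :func:`score_table`
    (NaN = respondent not asked).  The kingdom grand mean is by default the
    unweighted mean of the per-taxon means; ``kingdom_mean='cell'`` averages
    over all respondent x taxon cells instead (identical for balanced
    data).  Taxa with zero responses are excluded with a warning.
    """
    per_taxon_rows = []
    for taxon in scores.columns:
        col = scores[taxon].dropna()
        if col.empty:
            logger.warning("taxon %r has no responses; excluded", taxon)
            continue
        per_taxon_rows.append(
            {
                "taxon": taxon,
                "kingdom": key[taxon].kingdom,
                "mean": col.mean(),
                "sd": col.std(ddof=1) if len(col) > 1 else 0.0,
                "n": len(col),
            }
        )
    per_taxon = pd.DataFrame(per_taxon_rows).set_index("taxon").sort_values(
        ["kingdom", "mean"], ascending=[True, False]
    )
    if kingdom_mean == "taxon":
        kingdom = per_taxon.groupby("kingdom")["mean"].mean()
    else:
        melted = scores.melt(value_name="score", ignore_index=False).dropna()
        melted["kingdom"] = [key[t].kingdom for t in melted["taxon"]]
        kingdom = melted.groupby("kingdom")["score"].mean()
    kingdom.name = "grand_mean"
    return per_taxon, kingdom


def proportion_correct(scores: pd.DataFrame, correct_level: int = 3) -> pd.Series:
    """Simple proportion of respondents scoring at (>=) ``correct_level``
    per taxon — the expert-validation style summary, no partial credit."""
    return (scores >= correct_level).sum() / scores.notna().sum()
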