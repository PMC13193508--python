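"""Standardization lexicon: raw recall terms -> canonical objects -> categories.

Free-list respondents name the same depicted object in many ways ("firs",
"conifer" and "spruce" all denote the single spruce in the scene).  A
:class:`Lexicon` makes that mapping explicit, reproducible data rather than
ad-hoc code: every raw term maps to exactly one canonical object, every
canonical object carries exactly one macro-category (``plant``, ``animal``,
``human_nonliving`` or ``unknown``), and plant canonicals additionally carry
a specificity flag (``general`` growth-form/habitat terms such as "tree" or
"field" versus ``specific`` terms such as "sunflower" or "spruce").

Insufficiently specific terms may resolve to a *collective* canonical
("bird", "beetle") that stands for several depicted species of that group.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

MACRO_CATEGORIES = ("plant", "animal", "human_nonliving")
UNKNOWN = "unknown"
_VALID_MACROS = frozenset(MACRO_CATEGORIES) | {UNKNOWN}
_VALID_SPECIFICITY = frozenset({"general", "specific"})


def normalize_term(term: str) -> str:
    """Fold case, strip accents and collapse internal whitespace.

    This is the only normalization applied before lexicon lookup; fuzzy
    matching is deliberately not performed so that results are deterministic.
    """
    folded = unicodedata.normalize("NFKD", term)
    folded = "".join(ch for ch in folded if not unicodedata.combining(ch))
    return " ".join(folded.casefold().split())


@dataclass
class Lexicon:
    """Standardization and categorization dictionary.

    Parameters
    ----------
    synonym_map
        raw term -> canonical object name.  Closed under canonical names:
        every canonical maps to itself (enforced in ``__post_init__``).
    macro_map
        canonical -> macro-category, one of ``plant``, ``animal``,
        ``human_nonliving``, ``unknown``.
    specificity_map
        canonical -> ``general`` | ``specific`` (meaningful for plants).
    collective_map
        canonical -> name of the collective group it belongs to ("bird",
        "beetle"), or absent.  A canonical that *is* a collective maps to
        itself.
    """

    synonym_map: dict[str, str] = field(default_factory=dict)
    macro_map: dict[str, str] = field(default_factory=dict)
    specificity_map: dict[str, str] = field(default_factory=dict)
    collective_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.synonym_map = {normalize_term(k): normalize_term(v) for k, v in self.synonym_map.items()}
        self.macro_map = {normalize_term(k): v for k, v in self.macro_map.items()}
        self.specificity_map = {normalize_term(k): v for k, v in self.specificity_map.items()}
        self.collective_map = {normalize_term(k): normalize_term(v) for k, v in self.collective_map.items()}
        # close synonym_map under canonical names
        for canonical in list(self.synonym_map.values()) + list(self.macro_map):
            self.synonym_map.setdefault(canonical, canonical)

    # -- lookups ---------------------------------------------------------

    @property
    def canonicals(self) -> set[str]:
        return set(self.synonym_map.values()) | set(self.macro_map)

    def canonical_of(self, raw: str) -> str | None:
        """Canonical object for a raw term, or None if unmapped."""
        return self.synonym_map.get(normalize_term(raw))

    def macro_of(self, canonical: str) -> str:
        return self.macro_map.get(normalize_term(canonical), UNKNOWN)

    def specificity_of(self, canonical: str) -> str | None:
        return self.specificity_map.get(normalize_term(canonical))

    def is_collective(self, canonical: str) -> bool:
        c = normalize_term(canonical)
        return self.collective_map.get(c) == c

    def objects_in(self, macro: str) -> list[str]:
        return sorted(c for c, m in self.macro_map.items() if m == macro)

    # -- construction ----------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[Mapping[str, object]]) -> "Lexicon":
        """Build from row records with keys raw_term, canonical,
        macro_category, specificity, collective (latter two optional)."""
        syn: dict[str, str] = {}
        macro: dict[str, str] = {}
        spec: dict[str, str] = {}
        coll: dict[str, str] = {}
        for row in records:
            raw = str(row["raw_term"])
            canonical = str(row["canonical"])
            syn[raw] = canonical
            mc = row.get("macro_category")
            if mc is not None and not pd.isna(mc):
                macro[canonical] = str(mc)
            sp = row.get("specificity")
            if sp is not None and not pd.isna(sp) and str(sp):
                spec[canonical] = str(sp)
            cg = row.get("collective")
            if cg is not None and not pd.isna(cg) and str(cg):
                coll[canonical] = str(cg)
        return cls(synonym_map=syn, macro_map=macro, specificity_map=spec, collective_map=coll)

    @classmethod
    def from_csv(cls, path: str | Path, **read_kwargs: object) -> "Lexicon":
        df = pd.read_csv(path, **read_kwargs)
        return cls.from_records(df.to_dict("records"))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Lexicon":
        """Load from a YAML file mapping canonical -> {macro_category,
        specificity, collective, synonyms: [raw terms]}."""
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls.from_mapping(doc)

    @classmethod
    def from_mapping(cls, doc: Mapping[str, Mapping[str, object]]) -> "Lexicon":
        syn: dict[str, str] = {}
        macro: dict[str, str] = {}
        spec: dict[str, str] = {}
        coll: dict[str, str] = {}
        for canonical, entry in doc.items():
            entry = entry or {}
            macro[canonical] = str(entry.get("macro_category", UNKNOWN))
            if entry.get("specificity"):
                spec[canonical] = str(entry["specificity"])
            if entry.get("collective"):
                coll[canonical] = str(entry["collective"])
            for raw in entry.get("synonyms", []) or []:
                syn[str(raw)] = canonical
            syn[canonical] = canonical
        return cls(synonym_map=syn, macro_map=macro, specificity_map=spec, collective_map=coll)


@dataclass
class LexiconReport:
    passed: bool
    issues: list[str]

    def __bool__(self) -> bool:
        return self.passed


def validate_lexicon(lexicon: Lexicon) -> LexiconReport:
    """Report-only validation of a lexicon.

    Checks that synonym targets are themselves canonical (no chains
    a -> b -> c), that every canonical has a valid macro-category, and that
    plant canonicals carry a specificity flag.
    """
    issues: list[str] = []
    canonical_names = set(lexicon.synonym_map.values())
    for raw, target in sorted(lexicon.synonym_map.items()):
        if lexicon.synonym_map.get(target) != target:
            issues.append(f"non-canonical target: {raw!r} -> {target!r} which maps onward")
    for canonical in sorted(canonical_names):
        macro = lexicon.macro_map.get(canonical)
        if macro is None:
            issues.append(f"canonical {canonical!r} has no macro-category")
        elif macro not in _VALID_MACROS:
            issues.append(f"canonical {canonical!r} has invalid macro-category {macro!r}")
        if macro == "plant" and canonical not in lexicon.specificity_map:
            issues.append(f"plant canonical {canonical!r} missing specificity flag")
    for canonical, sp in sorted(lexicon.specificity_map.items()):
        if sp not in _VALID_SPECIFICITY:
            issues.append(f"invalid specificity {sp!r} for {canonical!r}")
    return LexiconReport(passed=not issues, issues=issues)
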