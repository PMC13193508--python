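from __future__ import annotations

import pytest

from hopikit.freelist import StandardizedItem, StandardizedList
from hopikit.lexicon import Lexicon
from hopikit.synthetic import default_identification_key, default_lexicon, default_scenario


def make_std(rid: str, items, group: str = "g") -> StandardizedList:
    """Build a StandardizedList from (canonical, macro[, specificity]) tuples."""
    built = []
    for rank, entry in enumerate(items, start=1):
        canonical, macro = entry[0], entry[1]
        spec = entry[2] if len(entry) > 2 else None
        built.append(
            StandardizedItem(
                raw=canonical,
                canonical=canonical,
                macro_category=macro,
                specificity=spec,
                rank=rank,
                flag="mapped",
            )
        )
    return StandardizedList(respondent_id=rid, group=group, items=tuple(built))


@pytest.fixture(scope="session")
def toy_lexicon() -> Lexicon:
    return Lexicon.from_mapping(
        {
            "spruce": {"macro_category": "plant", "specificity": "specific",
                       "synonyms": ["firs", "fir", "conifer"]},
            "tree": {"macro_category": "plant", "specificity": "general", "synonyms": ["trees"]},
            "sunflower": {"macro_category": "plant", "specificity": "specific", "synonyms": []},
            "crow": {"macro_category": "animal", "collective": "bird", "synonyms": ["black bird"]},
            "bird": {"macro_category": "animal", "collective": "bird", "synonyms": ["birds"]},
            "domestic cat": {"macro_category": "animal", "synonyms": ["cat", "kitty"]},
            "house": {"macro_category": "human_nonliving", "synonyms": []},
            "stream": {"macro_category": "human_nonliving", "synonyms": ["creek"]},
        }
    )


@pytest.fixture(scope="session")
def scene_lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def scene_key():
    return default_identification_key()


@pytest.fixture(scope="session")
def scenario():
    return default_scenario(seed=20260926)
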