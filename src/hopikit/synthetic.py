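"""Synthetic study data with known ground truth.

Every analysis stage of the package can be exercised without any field
data: this module generates free lists, identification responses, fixation
tables and object masks whose latent parameters are known, so recovery can
be tested.

The generative story for recall is a Plackett-Luce-type ranking: each
group g has attention weights :math:`w_g(c) \\ge 0` over the three
macro-categories (summing to 1) and every roster object o has a positive
latent prominence :math:`p_o` (normalized within its category).  A
respondent's list of length L (truncated Poisson) is built by successive
sampling *without replacement* with selection weight
:math:`w_g(\\mathrm{cat}(o)) \\cdot p_o`, so high-weight objects tend to
appear early — which makes Smith's salience a consistent estimator of
prominence order within a category.  Raw term strings are emitted through
an invertible alias map drawn from the lexicon, so standardization is
genuinely exercised.

Identification responses draw a rubric level per respondent x taxon from
per-taxon level probabilities (by default a Binomial(3, m/3) family with
target mean m) and emit a representative answer string for that level from
the key.  Fixation tables allocate a Poisson number of fixations over
objects proportionally to the same attention weights, with lognormal
fixation durations and a per-respondent viewing-time cap.  Object masks
are filled rectangles/ellipses on black with exact ground-truth pixel
counts.

All randomness flows from a single integer seed through independent
``numpy`` generator streams, so a fixed seed gives identical output.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image, ImageDraw

from hopikit.freelist import FreeList
from hopikit.identification import IdentificationKey
from hopikit.lexicon import MACRO_CATEGORIES, Lexicon

_PROB_TOL = 1e-9


# ---------------------------------------------------------------------------
# configuration


@dataclass
class GroupSpec:
    """One respondent group's latent parameters."""

    name: str
    n_respondents: int
    weights: dict[str, float]  # macro-category -> attention weight, sums to 1
    mean_list_length: float  # lambda of the truncated Poisson
    specific_plant_boost: float = 1.0  # multiplies prominence of specific plants

    def validate(self, roster_size: int) -> None:
        if self.n_respondents < 1:
            raise ValueError(f"group {self.name!r}: n_respondents < 1")
        if set(self.weights) != set(MACRO_CATEGORIES):
            raise ValueError(f"group {self.name!r}: weights must cover {MACRO_CATEGORIES}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError(f"group {self.name!r}: negative weight")
        if abs(sum(self.weights.values()) - 1.0) > _PROB_TOL:
            raise ValueError(f"group {self.name!r}: weights sum to {sum(self.weights.values())}, not 1")
        if not 1 <= self.mean_list_length <= roster_size:
            raise ValueError(
                f"group {self.name!r}: mean list length {self.mean_list_length} "
                f"incompatible with roster size {roster_size}"
            )
        if self.specific_plant_boost <= 0:
            raise ValueError(f"group {self.name!r}: non-positive specific_plant_boost")


@dataclass
class FixationSpec:
    group: str
    exposure_s: float = 30.0
    fixations_per_second: float = 3.0
    duration_mean_s: float = 0.25
    duration_sigma: float = 0.6
    category_duration_scale: dict[str, float] = field(
        default_factory=lambda: {c: 1.0 for c in MACRO_CATEGORIES}
    )


@dataclass
class GeneratorConfig:
    seed: int
    lexicon: Lexicon
    prominence: dict[str, float]  # canonical object -> latent prominence > 0
    groups: dict[str, GroupSpec]
    fixation: FixationSpec | None = None
    identification_group: str | None = None
    identification_means: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def roster(self) -> list[str]:
        return sorted(self.prominence)

    def validate(self) -> None:
        if not self.prominence:
            raise ValueError("empty roster")
        for obj, p in self.prominence.items():
            if p <= 0:
                raise ValueError(f"non-positive prominence for {obj!r}")
            if self.lexicon.canonical_of(obj) != obj:
                raise ValueError(f"roster object {obj!r} is not a lexicon canonical")
        for g in self.groups.values():
            g.validate(len(self.prominence))
        if self.fixation is not None and self.fixation.group not in self.groups:
            raise ValueError(f"fixation group {self.fixation.group!r} not defined")
        if self.identification_group is not None and self.identification_group not in self.groups:
            raise ValueError(f"identification group {self.identification_group!r} not defined")
        for taxon, m in self.identification_means.items():
            if not 0.0 <= m <= 3.0:
                raise ValueError(f"target mean for {taxon!r} outside [0, 3]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream; distinct per generator stage."""
        return np.random.default_rng([self.seed, stream])


# ---------------------------------------------------------------------------
# selection weights


def selection_weights(config: GeneratorConfig, group: GroupSpec) -> tuple[list[str], np.ndarray]:
    """Per-object Plackett-Luce selection weights for one group.

    Prominence is normalized within each macro-category (after applying the
    group's specific-plant boost within the plant category), then scaled by
    the group's category weight, so the rank-1 category probabilities equal
    the configured w_g(c) exactly.
    """
    objects = config.roster
    lex = config.lexicon
    raw = np.empty(len(objects))
    cats = []
    for i, obj in enumerate(objects):
        p = config.prominence[obj]
        cat = lex.macro_of(obj)
        if cat == "plant" and lex.specificity_of(obj) == "specific":
            p *= group.specific_plant_boost
        raw[i] = p
        cats.append(cat)
    cats_arr = np.array(cats)
    weights = np.zeros_like(raw)
    for cat in MACRO_CATEGORIES:
        mask = cats_arr == cat
        if mask.any():
            weights[mask] = group.weights[cat] * raw[mask] / raw[mask].sum()
    return objects, weights


def _truncated_poisson(rng: np.random.Generator, lam: float, upper: int) -> int:
    """Poisson(lam) conditioned on 1 <= L <= upper, by rejection."""
    while True:
        L = int(rng.poisson(lam))
        if 1 <= L <= upper:
            return L


# ---------------------------------------------------------------------------
# free lists


def generate_freelists(
    config: GeneratorConfig,
    groups: Sequence[str] | None = None,
) -> tuple[list[FreeList], dict]:
    """Ranked recall lists for the requested groups (default: all).

    Returns the lists plus ground truth: per group, the object roster and
    the exact selection weights used.  Raw terms are aliases sampled from
    the lexicon's synonym sets, so ``standardize`` inverts them exactly.
    """
    rng = config.rng(stream=1)
    alias_sets = _alias_sets(config.lexicon, config.roster)
    truth: dict = {"groups": {}}
    lists: list[FreeList] = []
    for gname in groups if groups is not None else sorted(config.groups):
        group = config.groups[gname]
        objects, weights = selection_weights(config, group)
        truth["groups"][gname] = {"objects": objects, "selection_weights": weights.copy()}
        n_nonzero = int((weights > 0).sum())
        for r in range(group.n_respondents):
            L = _truncated_poisson(rng, group.mean_list_length, n_nonzero)
            idx = _plackett_luce_draw(rng, weights, L)
            terms = []
            for i in idx:
                aliases = alias_sets[objects[i]]
                terms.append(aliases[rng.integers(len(aliases))])
            lists.append(
                FreeList(respondent_id=f"{gname}_{r + 1:04d}", group=gname, items=tuple(terms))
            )
    return lists, truth


def _plackett_luce_draw(rng: np.random.Generator, weights: np.ndarray, L: int) -> list[int]:
    """Successive sampling without replacement, probability ∝ weight."""
    w = weights.astype(float).copy()
    chosen: list[int] = []
    for _ in range(L):
        total = w.sum()
        i = int(rng.choice(len(w), p=w / total))
        chosen.append(i)
        w[i] = 0.0
    return chosen


def _alias_sets(lexicon: Lexicon, roster: Sequence[str]) -> dict[str, list[str]]:
    aliases: dict[str, list[str]] = {obj: [] for obj in roster}
    for raw, canonical in sorted(lexicon.synonym_map.items()):
        if canonical in aliases:
            aliases[canonical].append(raw)
    return aliases


# ---------------------------------------------------------------------------
# identification responses


def rubric_probabilities(target_mean: float) -> np.ndarray:
    """Level probabilities (pi_0, pi_1, pi_2, pi_3) with the given mean.

    Binomial(3, m/3) family: a one-parameter distribution over {0..3} whose
    expectation is exactly the target mean.
    """
    p = target_mean / 3.0
    probs = np.array([math.comb(3, k) * p**k * (1 - p) ** (3 - k) for k in range(4)])
    assert abs(probs.sum() - 1.0) < _PROB_TOL
    return probs


def generate_identification_responses(
    config: GeneratorConfig, key: IdentificationKey
) -> pd.DataFrame:
    """Response table (respondent, taxon, answer, level) for the
    identification test group.

    Each respondent x taxon cell draws a rubric level from the taxon's
    level probabilities and emits a representative answer string of that
    level from the key (blank for level 0); re-scoring the emitted answers
    through the rubric recovers the drawn levels exactly.
    """
    if config.identification_group is None:
        raise ValueError("config has no identification group")
    missing = set(config.identification_means) - set(key.entries)
    if missing:
        raise KeyError(f"taxa missing from key: {sorted(missing)}")
    rng = config.rng(stream=2)
    group = config.groups[config.identification_group]
    rows = []
    for r in range(group.n_respondents):
        rid = f"{config.identification_group}_{r + 1:04d}"
        for taxon in sorted(config.identification_means):
            probs = rubric_probabilities(config.identification_means[taxon])
            level = int(rng.choice(4, p=probs))
            entry = key[taxon]
            pool = {
                3: sorted(entry.species_answers),
                2: sorted(entry.wrong_species_answers),
                1: sorted(entry.higher_answers),
                0: [""],
            }[level]
            answer = pool[rng.integers(len(pool))] if pool else ""
            rows.append({"respondent": rid, "taxon": taxon, "answer": answer, "level": level})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixation tables


def generate_fixation_table(config: GeneratorConfig) -> pd.DataFrame:
    """AOI fixation metrics for the eye-tracking group.

    Per respondent, a Poisson total number of fixations (exposure x rate)
    is allocated over objects proportionally to the group's selection
    weights; each fixation's duration is lognormal, scaled by the object's
    category; total viewing time is capped at the exposure by proportional
    rescaling.  Time to first fixation is the minimum of the object's
    fixation arrival times, uniform over the exposure window — missing when
    the object was never fixated.
    """
    if config.fixation is None:
        raise ValueError("config has no fixation spec")
    spec = config.fixation
    rng = config.rng(stream=3)
    group = config.groups[spec.group]
    objects, weights = selection_weights(config, group)
    w = weights / weights.sum()
    mu = math.log(spec.duration_mean_s) - spec.duration_sigma**2 / 2
    cats = [config.lexicon.macro_of(o) for o in objects]
    scales = np.array([spec.category_duration_scale.get(c, 1.0) for c in cats])
    rows = []
    for r in range(group.n_respondents):
        rid = f"{spec.group}_{r + 1:04d}"
        total_fix = int(rng.poisson(spec.exposure_s * spec.fixations_per_second))
        counts = rng.multinomial(total_fix, w)
        tfd = np.zeros(len(objects))
        ttff = np.full(len(objects), np.nan)
        for i, c in enumerate(counts):
            if c == 0:
                continue
            tfd[i] = rng.lognormal(mu, spec.duration_sigma, size=c).sum() * scales[i]
            # min of c uniform arrival times on [0, exposure]
            ttff[i] = spec.exposure_s * (1.0 - rng.uniform() ** (1.0 / c))
        total = tfd.sum()
        if total > spec.exposure_s:
            # slight under-scale so the cap holds despite rounding
            tfd *= spec.exposure_s * (1.0 - 1e-12) / total
        for i, obj in enumerate(objects):
            rows.append(
                {
                    "respondent": rid,
                    "object": obj,
                    "ttff_s": ttff[i],
                    "tfd_s": tfd[i],
                    "n_fix": int(counts[i]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# object masks


@dataclass(frozen=True)
class MaskSpec:
    object_id: str
    shape: str  # "rectangle" | "ellipse"
    bbox: tuple[int, int, int, int]  # inclusive pixel box (x0, y0, x1, y1)
    color: tuple[int, int, int] = (255, 255, 255)


def generate_object_masks(
    specs: Sequence[MaskSpec],
    canvas_size: tuple[int, int],
) -> tuple[Image.Image, list[tuple[str, Image.Image]], dict[str, int]]:
    """Scene + per-object masks on black, with exact ground-truth counts.

    Rectangles have the analytic count (x1-x0+1)(y1-y0+1); for ellipses the
    ground truth is the rasterized count of the isolated mask, which is the
    quantity the area calculator measures by definition.  A shape extending
    beyond the canvas is an error.
    """
    width, height = canvas_size
    scene = Image.new("RGB", canvas_size, (0, 0, 0))
    scene_draw = ImageDraw.Draw(scene)
    masks: list[tuple[str, Image.Image]] = []
    truth: dict[str, int] = {}
    for s in specs:
        x0, y0, x1, y1 = s.bbox
        if not (0 <= x0 <= x1 < width and 0 <= y0 <= y1 < height):
            raise ValueError(f"shape {s.object_id!r} exceeds canvas {canvas_size}")
        if s.color == (0, 0, 0):
            raise ValueError(f"shape {s.object_id!r}: background-black fill")
        mask = Image.new("RGB", canvas_size, (0, 0, 0))
        draw = ImageDraw.Draw(mask)
        if s.shape == "rectangle":
            draw.rectangle(s.bbox, fill=s.color)
            scene_draw.rectangle(s.bbox, fill=s.color)
            truth[s.object_id] = (x1 - x0 + 1) * (y1 - y0 + 1)
        elif s.shape == "ellipse":
            draw.ellipse(s.bbox, fill=s.color)
            scene_draw.ellipse(s.bbox, fill=s.color)
            truth[s.object_id] = int(np.any(np.asarray(mask) > 0, axis=2).sum())
        else:
            raise ValueError(f"unknown shape {s.shape!r}")
        masks.append((s.object_id, mask))
    return scene, masks, truth


# ---------------------------------------------------------------------------
# packaged default scenario


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("hopikit").joinpath("data", name)))


def default_lexicon() -> Lexicon:
    """The packaged synthetic lexicon for the 71-object scene."""
    return Lexicon.from_yaml(_data_path("lexicon_synthetic.yaml"))


def default_identification_key() -> IdentificationKey:
    """The packaged synthetic identification answer key (20 taxa)."""
    return IdentificationKey.from_yaml(_data_path("identification_key_synthetic.yaml"))


def load_scenario(path: str | Path, seed: int, lexicon: Lexicon | None = None) -> GeneratorConfig:
    """Build a GeneratorConfig from a scenario YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    lexicon = lexicon if lexicon is not None else default_lexicon()
    groups = {
        name: GroupSpec(
            name=name,
            n_respondents=int(g["n"]),
            weights=dict(g["weights"]),
            mean_list_length=float(g["mean_list_length"]),
            specific_plant_boost=float(g.get("specific_plant_boost", 1.0)),
        )
        for name, g in doc["groups"].items()
    }
    fixation = None
    if "fixation" in doc:
        f = doc["fixation"]
        fixation = FixationSpec(
            group=str(f["group"]),
            exposure_s=float(f.get("exposure_s", 30.0)),
            fixations_per_second=float(f.get("fixations_per_second", 3.0)),
            duration_mean_s=float(f.get("duration_mean_s", 0.25)),
            duration_sigma=float(f.get("duration_sigma", 0.6)),
            category_duration_scale=dict(
                f.get("category_duration_scale", {c: 1.0 for c in MACRO_CATEGORIES})
            ),
        )
    ident = doc.get("identification", {})
    return GeneratorConfig(
        seed=seed,
        lexicon=lexicon,
        prominence={str(k): float(v) for k, v in doc["prominence"].items()},
        groups=groups,
        fixation=fixation,
        identification_group=ident.get("group"),
        identification_means={str(k): float(v) for k, v in ident.get("target_means", {}).items()},
    )


def default_scenario(seed: int) -> GeneratorConfig:
    """The packaged synthetic scenario emulating the three study designs."""
    return load_scenario(_data_path("scenario_synthetic.yaml"), seed=seed)


def demo_mask_specs() -> tuple[list[MaskSpec], tuple[int, int]]:
    """A small deterministic mask layout (including one forced overlap)
    for demonstrations and smoke tests."""
    canvas = (200, 150)
    specs = [
        MaskSpec("house", "rectangle", (10, 40, 59, 99), (180, 40, 40)),
        MaskSpec("tree", "ellipse", (70, 20, 119, 99), (30, 160, 30)),
        MaskSpec("pond", "ellipse", (120, 90, 189, 139), (40, 60, 200)),
        # cat overlaps the house on purpose
        MaskSpec("domestic cat", "rectangle", (40, 80, 69, 99), (220, 220, 220)),
    ]
    return specs, canvas
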