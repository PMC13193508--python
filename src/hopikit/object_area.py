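"""Per-object pixel areas in the stimulus image.

Each depicted object is isolated on an exact-black background in its own
RGB PNG of the same dimensions as the full scene.  An object's area is the
number of pixels with any channel strictly greater than zero, reported also
as a percentage of the whole image.  A shared claim bitmap processed in
mask order records, for each object, how many of its pixels were already
claimed by earlier objects, so both the raw and the deduplicated count are
recoverable.  PNG is assumed precisely because lossless storage makes
"exact black" well-defined; images with an alpha channel or mismatched
dimensions are rejected rather than silently converted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image


class MaskError(ValueError):
    """Raised for masks with wrong dimensions or color mode."""


def _as_rgb_array(image: Image.Image | np.ndarray, label: str = "image") -> np.ndarray:
    """Validate and return an (H, W, 3) uint8 array."""
    if isinstance(image, Image.Image):
        if image.mode != "RGB":
            raise MaskError(f"{label}: mode {image.mode!r}, expected RGB")
        arr = np.asarray(image)
    else:
        arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise MaskError(f"{label}: expected 3-channel RGB, got shape {arr.shape}")
    return arr


def count_nonbackground_pixels(
    mask: Image.Image | np.ndarray,
    scene_size: tuple[int, int] | None = None,
) -> int:
    """Count pixels where any channel > 0 (background = exact black).

    ``scene_size`` is (width, height); a mask of different dimensions is an
    error, as is anything but 3-channel RGB.
    """
    arr = _as_rgb_array(mask, "mask")
    if scene_size is not None:
        h, w = arr.shape[:2]
        if (w, h) != tuple(scene_size):
            raise MaskError(f"mask is {w}x{h}, scene is {scene_size[0]}x{scene_size[1]}")
    return int(np.any(arr > 0, axis=2).sum())


@dataclass(frozen=True)
class ObjectAreaRecord:
    object_id: str
    pixel_count: int
    percent_of_image: float
    overlap_pixels: int


def compute_area_table(
    scene_size: tuple[int, int],
    masks: Sequence[tuple[str, Image.Image | np.ndarray]],
    category_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Areas and overlap bookkeeping for an ordered collection of masks.

    Masks are processed in the given order against a shared claim bitmap:
    for each object we count its non-background pixels (order-invariant),
    record how many were already claimed by earlier objects
    (``overlap_pixels``, order-dependent), and claim the remainder.
    ``percent_of_image`` uses the raw count over width x height.

    Returns the per-object table (indexed by object_id, columns
    ``pixel_count``, ``percent_of_image``, ``overlap_pixels``,
    ``claimed_pixels``) and a totals table: one ``total`` row plus one row
    per macro-category when ``category_map`` is given.  Totals use claimed
    (deduplicated) pixels so they never exceed the image.
    """
    width, height = scene_size
    claimed = np.zeros((height, width), dtype=bool)
    seen_ids: set[str] = set()
    rows = []
    for object_id, mask in masks:
        if object_id in seen_ids:
            raise ValueError(f"duplicate object_id {object_id!r}")
        seen_ids.add(object_id)
        arr = _as_rgb_array(mask, f"mask {object_id!r}")
        h, w = arr.shape[:2]
        if (w, h) != (width, height):
            raise MaskError(f"mask {object_id!r} is {w}x{h}, scene is {width}x{height}")
        on = np.any(arr > 0, axis=2)
        overlap = int((on & claimed).sum())
        pixel_count = int(on.sum())
        claimed |= on
        rows.append(
            {
                "object_id": object_id,
                "pixel_count": pixel_count,
                "percent_of_image": pixel_count / (width * height) * 100.0,
                "overlap_pixels": overlap,
                "claimed_pixels": pixel_count - overlap,
            }
        )
    table = pd.DataFrame(
        rows, columns=["object_id", "pixel_count", "percent_of_image", "overlap_pixels", "claimed_pixels"]
    ).set_index("object_id")

    total_claimed = int(claimed.sum())
    totals_rows = [
        {
            "scope": "total",
            "pixels": total_claimed,
            "percent_of_image": total_claimed / (width * height) * 100.0,
        }
    ]
    if category_map is not None and not table.empty:
        cats = table.assign(category=[category_map.get(o, "unknown") for o in table.index])
        for cat, sub in cats.groupby("category"):
            px = int(sub["claimed_pixels"].sum())
            totals_rows.append(
                {"scope": cat, "pixels": px, "percent_of_image": px / (width * height) * 100.0}
            )
    totals = pd.DataFrame(totals_rows).set_index("scope")
    return table, totals


def load_mask_directory(
    scene_path: str | Path, mask_dir: str | Path
) -> tuple[tuple[int, int], list[tuple[str, Image.Image]]]:
    """Load a scene PNG and all ``<object_id>.png`` masks in a directory,
    sorted by object id for a deterministic processing order."""
    scene = Image.open(scene_path)
    if scene.mode != "RGB":
        raise MaskError(f"scene: mode {scene.mode!r}, expected RGB")
    masks = []
    for path in sorted(Path(mask_dir).glob("*.png")):
        masks.append((path.stem, Image.open(path)))
    return scene.size, masks
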