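"""Binary sulcus masks and label-image I/O.

Raters draw coloured strokes on five fixed 2D views of an endocast
(anterior, superior, posterior, lateral-left, lateral-right).  Each stroke
colour encodes a (sulcus label, hemisphere) pair via a palette.  This module
isolates every coloured stroke of a view image into an independent
:class:`BinaryMask` that preserves the position and size of the drawing —
mask pixel coordinates equal coordinates in the source image, so masks from
the same view are directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = [
    "VIEWS",
    "HEMISPHERES",
    "BinaryMask",
    "Palette",
    "load_label_image",
    "write_mask",
    "write_view_image",
    "merge_same_label",
]

VIEWS = ("anterior", "superior", "posterior", "lateral_left", "lateral_right")
HEMISPHERES = ("left", "right", "unassigned")

#: Lateral views show a single hemisphere; the view fixes it.
LATERAL_HEMISPHERE = {"lateral_left": "left", "lateral_right": "right"}

Color = tuple[int, int, int]
Pixel = tuple[int, int]


@dataclass(frozen=True)
class BinaryMask:
    """One sulcus stroke (or reference sulcus) on a fixed-size 2D grid.

    Pixels are (row, col) integer coordinates, 0-based, origin top-left.
    """

    view: str
    hemisphere: str
    label: str
    rater: str
    shape: tuple[int, int]
    pixels: frozenset[Pixel]

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r}; expected one of {VIEWS}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        rows, cols = self.shape
        if rows <= 0 or cols <= 0:
            raise ValueError(f"invalid shape {self.shape}")
        for r, c in self.pixels:
            if not (0 <= r < rows and 0 <= c < cols):
                raise ValueError(f"pixel {(r, c)} outside shape {self.shape}")

    def __len__(self) -> int:
        return len(self.pixels)

    @property
    def is_empty(self) -> bool:
        return not self.pixels

    def to_array(self) -> np.ndarray:
        """Pixels as a sorted ``(n, 2)`` integer array of (row, col)."""
        if not self.pixels:
            return np.empty((0, 2), dtype=int)
        return np.array(sorted(self.pixels), dtype=int)

    def to_image(self) -> np.ndarray:
        """Boolean raster of the mask."""
        img = np.zeros(self.shape, dtype=bool)
        if self.pixels:
            arr = self.to_array()
            img[arr[:, 0], arr[:, 1]] = True
        return img

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(row_min, row_max, col_min, col_max), inclusive."""
        if not self.pixels:
            raise ValueError("empty mask has no bounding box")
        arr = self.to_array()
        return (
            int(arr[:, 0].min()),
            int(arr[:, 0].max()),
            int(arr[:, 1].min()),
            int(arr[:, 1].max()),
        )

    @classmethod
    def from_image(
        cls,
        image: np.ndarray,
        view: str,
        hemisphere: str,
        label: str,
        rater: str,
    ) -> "BinaryMask":
        image = np.asarray(image, dtype=bool)
        pix = frozenset((int(r), int(c)) for r, c in np.argwhere(image))
        return cls(view, hemisphere, label, rater, image.shape, pix)


@dataclass
class Palette:
    """Mapping from stroke colour to (sulcus label, hemisphere).

    Hemisphere is carried by the colour in views where both hemispheres
    appear; lateral views override it with their own hemisphere.
    """

    colors: dict[Color, tuple[str, str]] = field(default_factory=dict)
    background: Color = (255, 255, 255)

    def __post_init__(self) -> None:
        for color, (label, hemi) in self.colors.items():
            if len(color) != 3:
                raise ValueError(f"colors must be RGB triples, got {color}")
            if hemi not in HEMISPHERES:
                raise ValueError(f"unknown hemisphere {hemi!r} for color {color}")
            if not label:
                raise ValueError(f"empty label for color {color}")

    def match(self, color: Color, tolerance: float = 30.0) -> tuple[str, str] | None:
        """Resolve a colour, allowing anti-aliased edge colours within a
        Euclidean RGB *tolerance* of a palette colour; None = background."""
        if color in self.colors:
            return self.colors[color]
        if color == self.background:
            return None
        best, best_d = None, tolerance
        for cand, value in self.colors.items():
            d = float(np.linalg.norm(np.subtract(color, cand, dtype=float)))
            if d <= best_d:
                best, best_d = value, d
        return best

    @classmethod
    def from_csv(cls, path: str | Path, background: Color = (255, 255, 255)) -> "Palette":
        """Read a palette CSV with columns ``color`` (hex), ``label``,
        ``hemisphere``."""
        table = pd.read_csv(path)
        required = {"color", "label", "hemisphere"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"palette file missing columns: {sorted(missing)}")
        colors: dict[Color, tuple[str, str]] = {}
        for row in table.itertuples():
            color = _hex_to_rgb(str(row.color))
            if color in colors:
                raise ValueError(f"duplicate palette color {row.color}")
            colors[color] = (str(row.label), str(row.hemisphere))
        return cls(colors, background)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "color": [_rgb_to_hex(c) for c in self.colors],
                "label": [v[0] for v in self.colors.values()],
                "hemisphere": [v[1] for v in self.colors.values()],
            }
        ).to_csv(path, index=False)


def _hex_to_rgb(value: str) -> Color:
    value = value.lstrip("#")
    if len(value) != 6:
        raise ValueError(f"expected 6-digit hex color, got {value!r}")
    return tuple(int(value[i : i + 2], 16) for i in (0, 2, 4))  # type: ignore[return-value]


def _rgb_to_hex(color: Color) -> str:
    return "#{:02X}{:02X}{:02X}".format(*color)


def load_label_image(
    path: str | Path,
    palette: Palette,
    view: str,
    rater: str,
    *,
    strict: bool = True,
    tolerance: float = 30.0,
) -> list[BinaryMask]:
    """Isolate every palette colour of a label image into a binary mask.

    One mask is produced per (label, hemisphere) colour present; a label
    drawn as several disconnected strokes is one mask (pixel union).
    Background pixels are ignored.  In strict mode an unmapped colour is an
    error; otherwise it is dropped with a warning.  RGBA alpha is ignored.
    """
    img = np.asarray(Image.open(path).convert("RGB"))
    flat = img.reshape(-1, 3)
    coords = np.indices(img.shape[:2]).reshape(2, -1).T
    unique, inverse = np.unique(flat, axis=0, return_inverse=True)

    groups: dict[tuple[str, str], set[Pixel]] = {}
    for idx, color in enumerate(map(tuple, unique.tolist())):
        resolved = palette.match(color, tolerance=tolerance)
        if resolved is None:
            if color != palette.background and color not in palette.colors:
                count = int((inverse == idx).sum())
                msg = f"unmapped color {color} ({count} px) in {path}"
                if strict:
                    raise ValueError(msg)
                logger.warning(msg)
            continue
        label, hemi = resolved
        hemi = LATERAL_HEMISPHERE.get(view, hemi)
        pix = groups.setdefault((label, hemi), set())
        pix.update((int(r), int(c)) for r, c in coords[inverse == idx])

    return [
        BinaryMask(view, hemi, label, rater, img.shape[:2], frozenset(pix))
        for (label, hemi), pix in sorted(groups.items())
    ]


def write_mask(
    mask: BinaryMask,
    path: str | Path,
    color: Color = (0, 0, 0),
    background: Color = (255, 255, 255),
) -> None:
    """Write one mask as a PNG on its full view frame.

    Round-trip guarantee: loading the file with a palette mapping *color*
    back to the mask's (label, hemisphere) reproduces the pixel set exactly.
    """
    if mask.is_empty:
        raise ValueError("refusing to write an empty mask")
    img = np.empty((*mask.shape, 3), dtype=np.uint8)
    img[:] = background
    arr = mask.to_array()
    img[arr[:, 0], arr[:, 1]] = color
    Image.fromarray(img).save(path)


def write_view_image(
    masks: Iterable[BinaryMask],
    palette: Palette,
    path: str | Path,
    shape: tuple[int, int] | None = None,
) -> None:
    """Compose the masks of one view into a single colour-coded PNG."""
    masks = list(masks)
    if shape is None:
        if not masks:
            raise ValueError("cannot infer frame shape from zero masks")
        shape = masks[0].shape
    key_to_color: dict[tuple[str, str], Color] = {
        value: color for color, value in palette.colors.items()
    }
    img = np.empty((*shape, 3), dtype=np.uint8)
    img[:] = palette.background
    for mask in masks:
        if mask.shape != shape:
            raise ValueError(f"mask shape {mask.shape} != frame {shape}")
        key = (mask.label, mask.hemisphere)
        if key not in key_to_color:
            raise KeyError(f"palette has no color for {key}")
        if mask.pixels:
            arr = mask.to_array()
            img[arr[:, 0], arr[:, 1]] = key_to_color[key]
    Image.fromarray(img).save(path)


def merge_same_label(masks: Iterable[BinaryMask]) -> list[BinaryMask]:
    """Union masks sharing (rater, view, hemisphere, label).

    Needed after label merging/correction, where several strokes can end up
    under the same canonical sulcus.
    """
    merged: dict[tuple[str, str, str, str], BinaryMask] = {}
    for mask in masks:
        key = (mask.rater, mask.view, mask.hemisphere, mask.label)
        if key not in merged:
            merged[key] = mask
        else:
            prev = merged[key]
            if prev.shape != mask.shape:
                raise ValueError(
                    f"masks for {key} disagree on frame shape: {prev.shape} vs {mask.shape}"
                )
            merged[key] = BinaryMask(
                mask.view, mask.hemisphere, mask.label, mask.rater,
                mask.shape, prev.pixels | mask.pixels,
            )
    return [merged[k] for k in sorted(merged)]
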