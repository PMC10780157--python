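"""Scoring core: Dice overlap, centroid streamlines, MMED, and SISS.

Two complementary measures compare a hand-drawn sulcus with its reference:

* the Dice score, ``2|A∩B| / (|A|+|B|)``, a pixel-overlap index that is
  informative only where drawing and reference actually intersect;
* the mean minimum Euclidean distance (MMED), a directed chamfer-style
  measure: for every point of the drawing's single-pixel-wide centroid
  streamline, the distance to the nearest reference pixel, averaged.

The MMED is computed on a centroid rather than the raw stroke so that
drawings of different pen widths are compared fairly; the reference keeps
all of its pixels because reference sulci are more complex in shape than
hand strokes.  MMED is rescaled to [0, 1] with a saturation threshold
(default 100 px, beyond which there is no meaningful similarity), and the
SISS composite is the arithmetic mean of Dice and normalized MMED.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from sklearn.ensemble import AdaBoostRegressor
from sklearn.tree import DecisionTreeRegressor

from .masks import BinaryMask

__all__ = [
    "DEFAULT_MMED_THRESHOLD",
    "CentroidPath",
    "SimilarityScore",
    "dice",
    "extract_centroid",
    "mmed",
    "normalize_mmed",
    "siss",
    "score_pair",
]

#: MMED value (pixels) at and beyond which similarity saturates to zero.
DEFAULT_MMED_THRESHOLD = 100.0


@dataclass(frozen=True)
class CentroidPath:
    """Ordered single-pixel-wide streamline summarizing a drawn stroke.

    ``axis`` names the independent regression axis: ``"horizontal"`` means
    one point per occupied column, ``"vertical"`` one per occupied row.
    """

    points: tuple[tuple[int, int], ...]
    axis: str

    def __post_init__(self) -> None:
        if self.axis not in ("horizontal", "vertical"):
            raise ValueError(f"unknown axis {self.axis!r}")
        if not self.points:
            raise ValueError("centroid path must be non-empty")
        ind = [p[1] for p in self.points] if self.axis == "horizontal" else [p[0] for p in self.points]
        if len(set(ind)) != len(ind):
            raise ValueError("exactly one point per independent-axis coordinate required")
        if list(ind) != sorted(ind):
            raise ValueError("points must be sorted along the independent axis")

    def __len__(self) -> int:
        return len(self.points)

    def to_array(self) -> np.ndarray:
        return np.array(self.points, dtype=int)


@dataclass(frozen=True)
class SimilarityScore:
    """Similarity of one drawing/reference pair.

    Invariants: ``siss == (dice + mmedn) / 2``; ``mmedn == 0`` whenever
    ``saturated``; hence ``siss <= 0.5 + dice / 2``.
    """

    dice: float
    mmed: float
    mmedn: float
    siss: float
    saturated: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.dice <= 1.0):
            raise ValueError(f"dice out of range: {self.dice}")
        if self.mmed < 0.0:
            raise ValueError(f"mmed must be non-negative: {self.mmed}")
        if not (0.0 <= self.mmedn <= 1.0):
            raise ValueError(f"mmedn out of range: {self.mmedn}")
        if self.saturated and self.mmedn != 0.0:
            raise ValueError("saturated scores must have mmedn == 0")
        if abs(self.siss - (self.dice + self.mmedn) / 2.0) > 1e-12:
            raise ValueError("siss must equal (dice + mmedn) / 2")


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap ``2|A∩B| / (|A|+|B|)`` between two masks of one view frame.

    Symmetric, in [0, 1]; 1 iff the pixel sets are equal, 0 iff disjoint.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.is_empty or b.is_empty:
        raise ValueError("dice is undefined for empty masks")
    inter = len(a.pixels & b.pixels)
    return 2.0 * inter / (len(a.pixels) + len(b.pixels))


def _round_half_away(values: np.ndarray) -> np.ndarray:
    return np.sign(values) * np.floor(np.abs(values) + 0.5)


def extract_centroid(
    mask: BinaryMask,
    smoother: str = "adaboost",
    random_state: int = 0,
    min_unique: int = 4,
) -> CentroidPath:
    """Reduce an arbitrary-width stroke to its central streamline.

    The independent axis is the axis along which the stroke's bounding box
    is longer (ties favour horizontal).  A nonparametric regression of the
    transverse coordinate on the independent coordinate is fitted to the
    stroke's pixels and evaluated at every occupied independent-axis
    integer; predictions are rounded half-away-from-zero and clipped to the
    bounding box.

    ``smoother="adaboost"`` (default) fits a boosted ensemble of fully
    grown regression trees; with a single feature such a tree predicts the
    per-coordinate transverse mean, which keeps the streamline inside the
    stroke.  ``smoother="mean"`` uses the per-coordinate transverse mean
    directly, and is the automatic fallback for degenerate pixel clouds
    with fewer than *min_unique* distinct independent coordinates.
    """
    if mask.is_empty:
        raise ValueError("cannot extract a centroid from an empty mask")
    if smoother not in ("adaboost", "mean"):
        raise ValueError(f"unknown smoother {smoother!r}")
    pts = mask.to_array()
    rmin, rmax, cmin, cmax = mask.bounding_box()
    horizontal = (cmax - cmin) >= (rmax - rmin)
    if horizontal:
        ind, trans, lo, hi = pts[:, 1], pts[:, 0], rmin, rmax
    else:
        ind, trans, lo, hi = pts[:, 0], pts[:, 1], cmin, cmax
    xs = np.unique(ind)
    if smoother == "mean" or xs.size < min_unique:
        pred = np.array([trans[ind == x].mean() for x in xs])
    else:
        model = AdaBoostRegressor(
            DecisionTreeRegressor(),
            n_estimators=50,
            random_state=random_state,
        )
        model.fit(ind[:, None].astype(float), trans.astype(float))
        pred = model.predict(xs[:, None].astype(float))
    rounded = np.clip(_round_half_away(pred), lo, hi).astype(int)
    if horizontal:
        points = tuple((int(t), int(x)) for x, t in zip(xs, rounded))
    else:
        points = tuple((int(x), int(t)) for x, t in zip(xs, rounded))
    return CentroidPath(points=points, axis="horizontal" if horizontal else "vertical")


def mmed(centroid: CentroidPath, reference: BinaryMask) -> float:
    """Mean minimum Euclidean distance from a centroid streamline to a mask.

    For each streamline point the Euclidean distance to the nearest
    reference pixel is taken; the MMED is the mean of those minima.  The
    measure is directed (drawing centroid → reference), not symmetric.
    """
    if reference.is_empty:
        raise ValueError("mmed is undefined against an empty reference")
    tree = cKDTree(reference.to_array())
    dists, _ = tree.query(centroid.to_array())
    return float(np.mean(dists))


def normalize_mmed(value: float, threshold: float = DEFAULT_MMED_THRESHOLD) -> float:
    """Rescale an MMED to a [0, 1] similarity.

    ``1 - value/threshold`` below the threshold, 0 at and beyond it: an
    MMED at the threshold or above means there is no meaningful similarity
    or proximity left.  Non-increasing and continuous on [0, ∞).
    """
    if value < 0.0:
        raise ValueError(f"mmed must be non-negative: {value}")
    if threshold <= 0.0:
        raise ValueError(f"threshold must be positive: {threshold}")
    if value >= threshold:
        return 0.0
    return 1.0 - value / threshold


def siss(dice_score: float, mmedn: float) -> float:
    """SISS composite: arithmetic mean of Dice and normalized MMED."""
    for name, v in (("dice", dice_score), ("mmedn", mmedn)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} out of range: {v}")
    return (dice_score + mmedn) / 2.0


def score_pair(
    drawing: BinaryMask,
    reference: BinaryMask,
    threshold: float = DEFAULT_MMED_THRESHOLD,
    smoother: str = "adaboost",
    random_state: int = 0,
) -> SimilarityScore:
    """Full similarity of a drawing against its reference sulcus.

    Dice uses the raw full-width stroke; MMED uses the drawing's centroid
    streamline against *all* reference pixels (no reference centroid —
    reference sulci are too complex in shape for a single streamline).
    """
    if drawing.view != reference.view:
        raise ValueError(f"view mismatch: {drawing.view!r} vs {reference.view!r}")
    d = dice(drawing, reference)
    centroid = extract_centroid(drawing, smoother=smoother, random_state=random_state)
    m = mmed(centroid, reference)
    mn = normalize_mmed(m, threshold=threshold)
    return SimilarityScore(
        dice=d,
        mmed=m,
        mmedn=mn,
        siss=siss(d, mn),
        saturated=m >= threshold,
    )
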