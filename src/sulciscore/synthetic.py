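"""Synthetic reference sulci and simulated rater drawings.

The study data (expert drawings on endocast views) are not redistributable,
so this module generates cohorts with the statistical structure the
analysis assumes: per-view reference curves of moderate width, and rater
drawings that deviate from them through interpretable noise channels —

* a rigid offset of the whole stroke (position error),
* a smooth random deformation along the stroke (shape error),
* blending toward the straight chord (the "rectilinear drawing" habit of
  raters reproducing a textbook sulcus rather than the observed groove),
* truncation of part of the stroke, variable pen width,
* omission, and mislabelling between designated confusable neighbour
  sulci (e.g. central vs pre-central).

Every perturbation is logged, so a correction file mapping mislabelled
drawings back to their true sulcus can be derived mechanically — enabling
an end-to-end raw-vs-corrected comparison.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.interpolate import make_interp_spline
from scipy.ndimage import gaussian_filter1d
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from .labels import CorrectionEntry
from .masks import BinaryMask, Palette, write_view_image

__all__ = [
    "ReferenceSpec",
    "RaterSimConfig",
    "TruthRecord",
    "generate_references",
    "default_reference_specs",
    "default_confusions",
    "simulate_rater",
    "simulate_cohort",
    "corrections_from_truth",
    "build_palette",
    "make_rater_configs",
    "emit_cohort",
    "DEFAULT_FRAME",
]

DEFAULT_FRAME = (600, 600)

#: Label pairs treated as confusable neighbours when both occur in a view.
PREFERRED_CONFUSIONS = (
    ("S.C", "S.Pe.C"),
    ("S.F.inter", "S.F.sup"),
    ("F.P.O", "Occipital"),
)


@dataclass(frozen=True)
class ReferenceSpec:
    """Parametric description of one reference sulcus curve.

    The curve is a spline through ``control_points`` rasterized as a
    function graph along ``axis`` (one pixel per occupied independent
    coordinate before widening), then dilated to ``width_px``.
    """

    view: str
    label: str
    hemisphere: str
    control_points: tuple[tuple[int, int], ...]
    width_px: int = 3
    axis: str = "horizontal"

    def __post_init__(self) -> None:
        if len(self.control_points) < 2:
            raise ValueError("need at least two control points")
        if self.width_px < 1:
            raise ValueError("width_px must be >= 1")
        if self.axis not in ("horizontal", "vertical"):
            raise ValueError(f"unknown axis {self.axis!r}")


@dataclass(frozen=True)
class RaterSimConfig:
    """Noise model for one simulated rater.

    All lengths are in pixels of the view raster.  ``displacement_px`` is
    the magnitude of a rigid offset applied in a uniformly random
    direction, so the knob equals the realised positional error exactly.
    ``smooth_deform_amp``/``smooth_deform_scale`` control a correlated
    random warp along the stroke; ``rectilinear_bias`` in [0, 1] blends the
    stroke toward its straight chord; ``truncation_frac`` removes that
    fraction of points from a random end.  The seed fully determines the
    output.
    """

    displacement_px: float = 0.0
    smooth_deform_amp: float = 0.0
    smooth_deform_scale: float = 30.0
    truncation_frac: float = 0.0
    stroke_width_px: int = 3
    p_omit: float = 0.0
    p_mislabel: float = 0.0
    rectilinear_bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_omit", "p_mislabel", "rectilinear_bias", "truncation_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.displacement_px < 0 or self.smooth_deform_amp < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if self.smooth_deform_scale <= 0:
            raise ValueError("smooth_deform_scale must be positive")
        if self.stroke_width_px < 1:
            raise ValueError("stroke_width_px must be >= 1")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated drawing (or omission)."""

    rater: str
    view: str
    hemisphere: str
    true_label: str
    emitted_label: str | None
    omitted: bool
    displacement: tuple[float, float] = (0.0, 0.0)
    n_truncated: int = 0


def _rasterize_graph(spec: ReferenceSpec, frame: tuple[int, int]) -> frozenset[tuple[int, int]]:
    pts = np.array(spec.control_points, dtype=float)
    if spec.axis == "horizontal":
        ind, trans = pts[:, 1], pts[:, 0]
    else:
        ind, trans = pts[:, 0], pts[:, 1]
    order = np.argsort(ind)
    ind, trans = ind[order], trans[order]
    if np.any(np.diff(ind) <= 0):
        raise ValueError(
            f"control points of {spec.label} must be strictly increasing along {spec.axis}"
        )
    k = min(3, len(ind) - 1)
    spline = make_interp_spline(ind, trans, k=k)
    xs = np.arange(int(np.ceil(ind[0])), int(np.floor(ind[-1])) + 1)
    ys = np.floor(np.abs(spline(xs.astype(float))) + 0.5) * np.sign(spline(xs.astype(float)))
    ys = ys.astype(int)
    rows, cols = (ys, xs) if spec.axis == "horizontal" else (xs, ys)
    if (
        rows.min() < 0 or rows.max() >= frame[0]
        or cols.min() < 0 or cols.max() >= frame[1]
    ):
        raise ValueError(f"curve for {spec.label} ({spec.view}) leaves the frame {frame}")
    pixels = frozenset(zip(rows.tolist(), cols.tolist()))
    return _widen(pixels, frame, spec.width_px)


def _widen(
    pixels: frozenset[tuple[int, int]],
    frame: tuple[int, int],
    width_px: int,
) -> frozenset[tuple[int, int]]:
    if width_px <= 1:
        return pixels
    img = np.zeros(frame, dtype=bool)
    arr = np.array(sorted(pixels))
    img[arr[:, 0], arr[:, 1]] = True
    img = dilation(img, disk(width_px // 2))
    return frozenset((int(r), int(c)) for r, c in np.argwhere(img))


def generate_references(
    specs: Iterable[ReferenceSpec],
    frame: tuple[int, int] = DEFAULT_FRAME,
    seed: int = 0,
) -> list[BinaryMask]:
    """Rasterize reference specs into reference masks.

    Rasterization is deterministic; *seed* is accepted for interface
    uniformity with the stochastic generators and ignored.
    """
    masks = []
    for spec in specs:
        pixels = _rasterize_graph(spec, frame)
        masks.append(
            BinaryMask(spec.view, spec.hemisphere, spec.label, "reference", frame, pixels)
        )
    return masks


def _mirror(points: Sequence[tuple[int, int]], frame_cols: int) -> tuple[tuple[int, int], ...]:
    mirrored = [(r, frame_cols - 1 - c) for r, c in points]
    return tuple(sorted(mirrored, key=lambda p: p[1]))


def default_reference_specs(frame: tuple[int, int] = DEFAULT_FRAME) -> list[ReferenceSpec]:
    """Packaged reference layout: 12 sulci across all five views.

    The layout places confusable neighbours next to each other (central
    next to pre-central, intermediate next to superior frontal, the
    parieto-occipital fissure next to the occipital region) without stroke
    crossings, on a 600x600 frame scaled to the requested one.
    """
    rows, cols = frame
    sr, sc = rows / 600.0, cols / 600.0

    def pt(r: int, c: int) -> tuple[int, int]:
        return (int(round(r * sr)), int(round(c * sc)))

    lateral_left = [
        ReferenceSpec("lateral_left", "S.C", "left",
                      (pt(150, 320), pt(250, 300), pt(350, 290)), 3, "vertical"),
        ReferenceSpec("lateral_left", "S.Pe.C", "left",
                      (pt(150, 265), pt(250, 252), pt(350, 244)), 3, "vertical"),
        ReferenceSpec("lateral_left", "F.C.L", "left",
                      (pt(360, 150), pt(340, 300), pt(350, 450)), 4, "horizontal"),
        ReferenceSpec("lateral_left", "S.T.s", "left",
                      (pt(425, 150), pt(405, 300), pt(415, 440)), 3, "horizontal"),
        ReferenceSpec("lateral_left", "S.F.sup", "left",
                      (pt(140, 100), pt(112, 200), pt(132, 300)), 3, "horizontal"),
        ReferenceSpec("lateral_left", "S.F.inf.ant", "left",
                      (pt(260, 90), pt(242, 160), pt(256, 230)), 2, "horizontal"),
    ]
    lateral_right = [
        dataclasses.replace(
            spec,
            view="lateral_right",
            hemisphere="right",
            control_points=(
                _mirror(spec.control_points, cols)
                if spec.axis == "horizontal"
                else tuple((r, cols - 1 - c) for r, c in spec.control_points)
            ),
        )
        for spec in lateral_left
    ]

    def mirrored_pair(view: str, label: str, points: list[tuple[int, int]],
                      width: int = 3) -> list[ReferenceSpec]:
        left_pts = tuple(pt(r, c) for r, c in points)
        return [
            ReferenceSpec(view, label, "left", left_pts, width, "horizontal"),
            ReferenceSpec(view, label, "right", _mirror(left_pts, cols), width, "horizontal"),
        ]

    superior = (
        mirrored_pair("superior", "S.C", [(200, 60), (190, 150), (200, 250)])
        + mirrored_pair("superior", "S.Pe.C", [(150, 60), (141, 150), (150, 250)])
        + mirrored_pair("superior", "F.I.P", [(380, 80), (398, 170), (388, 260)])
    )
    anterior = (
        mirrored_pair("anterior", "S.F.sup", [(150, 80), (131, 170), (145, 260)])
        + mirrored_pair("anterior", "S.F.inter", [(230, 70), (216, 160), (226, 250)])
        + mirrored_pair("anterior", "S.Or", [(420, 90), (438, 180), (428, 260)])
    )
    posterior = (
        mirrored_pair("posterior", "Occipital", [(300, 70), (318, 160), (308, 250)])
        + mirrored_pair("posterior", "S.O.T.lat.post", [(450, 80), (433, 170), (444, 255)])
        + mirrored_pair("posterior", "F.P.O", [(150, 90), (142, 170), (150, 245)])
    )
    return lateral_left + lateral_right + superior + anterior + posterior


def _mass_center(mask: BinaryMask) -> np.ndarray:
    return mask.to_array().mean(axis=0)


def default_confusions(
    references: Sequence[BinaryMask],
) -> list[tuple[str, str, str, str]]:
    """Designated confusable pairs per (view, hemisphere).

    Preferred anatomical pairs are used when both members occur in a view;
    remaining labels are greedily matched to their nearest neighbour by
    stroke centre distance.  Each label joins at most one pair.  Returned
    as sorted tuples ``(view, hemisphere, label_a, label_b)``.
    """
    pairs: list[tuple[str, str, str, str]] = []
    by_side: dict[tuple[str, str], list[BinaryMask]] = {}
    for mask in references:
        by_side.setdefault((mask.view, mask.hemisphere), []).append(mask)
    for (view, hemi), masks in sorted(by_side.items()):
        labels = {m.label: m for m in masks}
        taken: set[str] = set()
        for a, b in PREFERRED_CONFUSIONS:
            if a in labels and b in labels and not {a, b} & taken:
                pairs.append((view, hemi, *sorted((a, b))))
                taken |= {a, b}
        free = sorted(set(labels) - taken)
        while len(free) >= 2:
            a = free.pop(0)
            ca = _mass_center(labels[a])
            dists = [(float(np.linalg.norm(ca - _mass_center(labels[b]))), b) for b in free]
            _, b = min(dists)
            free.remove(b)
            pairs.append((view, hemi, *sorted((a, b))))
    return sorted(pairs)


def _perturb_path(
    path: np.ndarray,
    config: RaterSimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, tuple[float, float], int]:
    pts = path.astype(float).copy()
    theta = rng.uniform(0.0, 2.0 * np.pi)
    disp = config.displacement_px * np.array([np.sin(theta), np.cos(theta)])
    pts += disp
    if config.smooth_deform_amp > 0:
        for axis in (0, 1):
            noise = rng.standard_normal(len(pts))
            noise = gaussian_filter1d(noise, sigma=config.smooth_deform_scale, mode="nearest")
            std = noise.std()
            if std > 0:
                noise = noise / std
            pts[:, axis] += config.smooth_deform_amp * noise
    if config.rectilinear_bias > 0 and len(pts) > 1:
        t = np.linspace(0.0, 1.0, len(pts))[:, None]
        chord = pts[0] + t * (pts[-1] - pts[0])
        pts = (1.0 - config.rectilinear_bias) * pts + config.rectilinear_bias * chord
    n_trunc = 0
    if config.truncation_frac > 0 and len(pts) > 1:
        n_trunc = min(int(round(config.truncation_frac * len(pts))), len(pts) - 1)
        if n_trunc > 0:
            if rng.random() < 0.5:
                pts = pts[n_trunc:]
            else:
                pts = pts[: len(pts) - n_trunc]
    return pts, (float(disp[0]), float(disp[1])), n_trunc


def _rasterize_polyline(
    pts: np.ndarray,
    frame: tuple[int, int],
    width_px: int,
) -> frozenset[tuple[int, int]]:
    ipts = (np.sign(pts) * np.floor(np.abs(pts) + 0.5)).astype(int)
    pixels: set[tuple[int, int]] = set()
    for (r0, c0), (r1, c1) in zip(ipts[:-1], ipts[1:]):
        rr, cc = draw_line(r0, c0, r1, c1)
        pixels.update(zip(rr.tolist(), cc.tolist()))
    if len(ipts) == 1:
        pixels.add((int(ipts[0, 0]), int(ipts[0, 1])))
    inside = frozenset(
        (r, c) for r, c in pixels if 0 <= r < frame[0] and 0 <= c < frame[1]
    )
    if not inside:
        return frozenset()
    return _widen(inside, frame, width_px)


def simulate_rater(
    references: Sequence[BinaryMask],
    config: RaterSimConfig,
    rater_id: str = "R1",
    confusions: Sequence[tuple[str, str, str, str]] | None = None,
) -> tuple[list[BinaryMask], list[TruthRecord]]:
    """Simulate one rater's drawings over all reference sulci.

    Per reference: with probability ``p_omit`` nothing is drawn; otherwise
    the reference centreline is perturbed (rigid offset, smooth warp, chord
    blending, truncation) and re-rasterized at the rater's pen width.
    Mislabelling then swaps the labels of designated confusable pairs with
    probability ``p_mislabel`` (a swap keeps labels unique within a view).
    The truth log records every applied perturbation and the true label.
    """
    from .similarity import extract_centroid  # deferred: avoid import cycle

    refs = sorted(references, key=lambda m: (m.view, m.hemisphere, m.label))
    rng = np.random.default_rng(config.seed)
    if confusions is None:
        confusions = default_confusions(refs)

    emitted: dict[tuple[str, str, str], frozenset] = {}
    records: dict[tuple[str, str, str], TruthRecord] = {}
    for ref in refs:
        key = (ref.view, ref.hemisphere, ref.label)
        if rng.random() < config.p_omit:
            records[key] = TruthRecord(
                rater_id, ref.view, ref.hemisphere, ref.label, None, True
            )
            continue
        path = extract_centroid(ref, smoother="mean").to_array()
        pts, disp, n_trunc = _perturb_path(path, config, rng)
        pixels = _rasterize_polyline(pts, ref.shape, config.stroke_width_px)
        if not pixels:  # perturbed entirely off the canvas
            records[key] = TruthRecord(
                rater_id, ref.view, ref.hemisphere, ref.label, None, True, disp, n_trunc
            )
            continue
        emitted[key] = pixels
        records[key] = TruthRecord(
            rater_id, ref.view, ref.hemisphere, ref.label, ref.label, False, disp, n_trunc
        )

    if config.p_mislabel > 0:
        for view, hemi, a, b in confusions:
            if rng.random() >= config.p_mislabel:
                continue
            ka, kb = (view, hemi, a), (view, hemi, b)
            if ka in emitted and kb in emitted:
                # swap the *labels*, keeping each drawing's own pixels
                records[ka] = dataclasses.replace(records[ka], emitted_label=b)
                records[kb] = dataclasses.replace(records[kb], emitted_label=a)
            elif ka in emitted:
                records[ka] = dataclasses.replace(records[ka], emitted_label=b)
            elif kb in emitted:
                records[kb] = dataclasses.replace(records[kb], emitted_label=a)

    frame = refs[0].shape if refs else DEFAULT_FRAME
    drawings = []
    for key, rec in sorted(records.items()):
        if rec.omitted:
            continue
        true_key = (rec.view, rec.hemisphere, rec.true_label)
        drawings.append(
            BinaryMask(
                rec.view, rec.hemisphere, rec.emitted_label, rater_id,
                frame, emitted[true_key],
            )
        )
    return drawings, [records[k] for k in sorted(records)]


def make_rater_configs(
    base: RaterSimConfig,
    n_raters: int,
    seed: int = 0,
) -> list[RaterSimConfig]:
    """Derive one deterministic per-rater config from a cohort seed."""
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    return [
        dataclasses.replace(base, seed=int((seed * 1000003 + 7919 * i + 1) % 2**31))
        for i in range(n_raters)
    ]


def simulate_cohort(
    references: Sequence[BinaryMask],
    base_config: RaterSimConfig,
    n_raters: int,
    seed: int = 0,
) -> tuple[list[BinaryMask], list[TruthRecord]]:
    """Simulate a whole cohort; rater ids are ``R1``..``Rn``."""
    confusions = default_confusions(sorted(
        references, key=lambda m: (m.view, m.hemisphere, m.label)
    ))
    drawings: list[BinaryMask] = []
    truth: list[TruthRecord] = []
    for i, config in enumerate(make_rater_configs(base_config, n_raters, seed), start=1):
        d, t = simulate_rater(references, config, rater_id=f"R{i}", confusions=confusions)
        drawings.extend(d)
        truth.extend(t)
    return drawings, truth


def corrections_from_truth(truth: Iterable[TruthRecord]) -> list[CorrectionEntry]:
    """Derive the correction file for every mislabelled drawing."""
    return [
        CorrectionEntry(
            rater_id=rec.rater,
            view_id=rec.view,
            hemisphere=rec.hemisphere,
            drawn_label=rec.emitted_label,
            corrected_labels=(rec.true_label,),
        )
        for rec in truth
        if not rec.omitted and rec.emitted_label != rec.true_label
    ]


def build_palette(
    keys: Iterable[tuple[str, str]],
    background: tuple[int, int, int] = (255, 255, 255),
) -> Palette:
    """Assign a distinct, well-separated RGB colour to every
    (label, hemisphere) pair; deterministic in the sorted key order."""
    levels = (0, 64, 128, 192, 255)
    candidates = []
    for r in levels:
        for g in levels:
            for b in levels:
                color = (r, g, b)
                d_bg = float(np.linalg.norm(np.subtract(color, background, dtype=float)))
                if d_bg < 64.0:
                    continue
                candidates.append(color)
    keys = sorted(set(keys))
    if len(keys) > len(candidates):
        raise ValueError(f"too many labels for the colour grid: {len(keys)}")
    return Palette(dict(zip(candidates, keys)), background=background)


def emit_cohort(
    references: Sequence[BinaryMask],
    configs: Sequence[RaterSimConfig],
    out_dir: str | Path,
    palette: Palette | None = None,
) -> dict[str, object]:
    """Write a complete, file-based cohort fixture.

    Produces per-rater per-view PNGs, the reference PNGs, the palette file
    and a correction file derived from the truth log, so the whole pipeline
    can be driven from disk exactly as with real rater exports.
    """
    from .labels import write_corrections  # local import keeps module load light
    import pandas as pd

    out = Path(out_dir)
    (out / "references").mkdir(parents=True, exist_ok=True)
    refs = sorted(references, key=lambda m: (m.view, m.hemisphere, m.label))
    if not refs:
        raise ValueError("need at least one reference mask")
    frame = refs[0].shape
    views = sorted({m.view for m in refs})
    if palette is None:
        palette = build_palette({(m.label, m.hemisphere) for m in refs})

    for view in views:
        write_view_image(
            [m for m in refs if m.view == view], palette,
            out / "references" / f"{view}.png", shape=frame,
        )

    confusions = default_confusions(refs)
    truth: list[TruthRecord] = []
    rater_files = []
    for i, config in enumerate(configs, start=1):
        rater = f"R{i}"
        rater_dir = out / "drawings" / rater
        rater_dir.mkdir(parents=True, exist_ok=True)
        drawings, log = simulate_rater(refs, config, rater_id=rater, confusions=confusions)
        truth.extend(log)
        for view in views:
            path = rater_dir / f"{view}.png"
            write_view_image(
                [m for m in drawings if m.view == view], palette, path, shape=frame
            )
            rater_files.append(path)

    palette_path = out / "palette.csv"
    palette.to_csv(palette_path)
    corrections_path = out / "corrections.csv"
    write_corrections(corrections_from_truth(truth), corrections_path)
    truth_path = out / "truth.csv"
    pd.DataFrame(
        {
            "rater": [t.rater for t in truth],
            "view": [t.view for t in truth],
            "hemisphere": [t.hemisphere for t in truth],
            "true_label": [t.true_label for t in truth],
            "emitted_label": [t.emitted_label or "" for t in truth],
            "omitted": [t.omitted for t in truth],
            "displacement_row": [t.displacement[0] for t in truth],
            "displacement_col": [t.displacement[1] for t in truth],
            "n_truncated": [t.n_truncated for t in truth],
        }
    ).to_csv(truth_path, index=False)
    return {
        "references": out / "references",
        "drawings": out / "drawings",
        "palette": palette_path,
        "corrections": corrections_path,
        "truth": truth_path,
        "rater_images": rater_files,
        "views": views,
    }
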