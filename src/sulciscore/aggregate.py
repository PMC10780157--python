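"""Cohort scoring, reliability tables, identification rates, zone maps.

Every rater drawing is scored against the reference sulcus of the same
(view, hemisphere, canonical label); scores are averaged per cell into a
per-sulcus × hemisphere × view table with per-hemisphere marginals, the
layout used to report inter-rater reliability.  Cells that nobody drew are
missing, never zero-filled.  A traffic-light zone classification summarizes
the corrected analysis: green sulci are reliably identified (mean SISS
above 0.5 with more than 20% of raters in at least one view), yellow are
intermediate (mean in (0.4, 0.5]), red are unreliable or rarely attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .labels import CorrectionEntry, LabelRegistry, apply_corrections
from .masks import VIEWS, BinaryMask, merge_same_label
from .similarity import DEFAULT_MMED_THRESHOLD, score_pair

__all__ = [
    "CohortScores",
    "AggregateTable",
    "score_cohort",
    "mean_table",
    "identification_rate",
    "classify_zones",
    "write_scores",
    "read_scores",
    "write_data_dictionary",
    "SCORE_COLUMNS",
]

SCORE_COLUMNS = [
    "rater", "view", "hemisphere", "label",
    "dice", "mmed", "mmedn", "siss", "saturated", "corrected",
]

DATA_DICTIONARY = """\
sulciscore output files — column dictionary

scores.csv (long format, one row per scored drawing/reference pair)
  rater        rater identifier, or "reference"
  view         one of anterior, superior, posterior, lateral_left, lateral_right
  hemisphere   left, right or unassigned
  label        canonical sulcus abbreviation after merging (and correction,
               when the corrected analysis was requested)
  dice         Dice overlap of the full-width stroke vs the reference, [0, 1]
  mmed         mean minimum Euclidean distance of the stroke centroid to the
               reference pixels, in pixels of the view raster
  mmedn        MMED rescaled to [0, 1]; 0 at/beyond the saturation threshold
  siss         (dice + mmedn) / 2, [0, 1]
  saturated    True when mmed reached the saturation threshold
  corrected    True when the row comes from a corrected-label analysis

table.csv (wide format, one row per canonical sulcus and hemisphere)
  label, hemisphere           cell identity
  <view> columns              mean SISS over the raters who drew that cell;
                              empty when nobody drew it
  average                     mean over the present view cells only
  n_raters_<view>             number of contributing raters per view

zones.csv (one row per canonical sulcus and hemisphere)
  zone             green | yellow | red
  best_view        qualifying view with the highest mean SISS (if any)
  best_mean_siss   mean SISS in that view
  best_rate        identification rate in that view
                   (fraction of the full cohort that drew the cell)

unmatched.csv
  drawings excluded from the tables because no reference sulcus exists for
  their (view, hemisphere, label); columns rater, view, hemisphere, label,
  n_pixels
"""


@dataclass
class CohortScores:
    """Long-format scores plus the report of unmatched drawings."""

    scores: pd.DataFrame
    unmatched: pd.DataFrame
    corrected: bool = False

    def mean_siss(self) -> float:
        if self.scores.empty:
            return float("nan")
        return float(self.scores["siss"].mean())


@dataclass
class AggregateTable:
    """Per-(label, hemisphere, view) mean SISS with per-hemisphere marginals.

    ``cells`` is indexed by (label, hemisphere, view) with columns
    ``mean_siss`` and ``n_raters``; ``marginals`` by (label, hemisphere)
    with columns ``mean_siss`` (unweighted mean over present view cells)
    and ``n_views``.  Absent cells are absent, never zero.
    """

    cells: pd.DataFrame
    marginals: pd.DataFrame

    def cell(self, label: str, hemisphere: str, view: str) -> tuple[float, int] | None:
        try:
            row = self.cells.loc[(label, hemisphere, view)]
        except KeyError:
            return None
        return float(row["mean_siss"]), int(row["n_raters"])

    def to_wide(self) -> pd.DataFrame:
        """Reliability-table layout: one row per (label, hemisphere), one
        mean-SISS column per view, plus the across-view average."""
        wide = self.cells["mean_siss"].unstack("view")
        counts = self.cells["n_raters"].unstack("view")
        for view in VIEWS:
            if view not in wide.columns:
                wide[view] = np.nan
                counts[view] = np.nan
        wide = wide[list(VIEWS)]
        wide["average"] = self.marginals["mean_siss"]
        for view in VIEWS:
            wide[f"n_raters_{view}"] = counts[view]
        return wide.sort_index()

    def to_csv(self, path: str | Path, decimals: int = 2) -> None:
        self.to_wide().round(decimals).to_csv(path)


def _reference_lookup(
    references: Iterable[BinaryMask],
    registry: LabelRegistry | None,
) -> dict[tuple[str, str, str], BinaryMask]:
    canon = [_canonical_mask(m, registry) for m in references]
    merged = merge_same_label(canon)
    return {(m.view, m.hemisphere, m.label): m for m in merged}


def _canonical_mask(mask: BinaryMask, registry: LabelRegistry | None) -> BinaryMask:
    if registry is None:
        return mask
    try:
        label = registry.canonicalize(mask.label)
    except KeyError:
        return mask  # unknown labels surface in the unmatched report
    if label == mask.label:
        return mask
    import dataclasses

    return dataclasses.replace(mask, label=label)


def score_cohort(
    drawings: Iterable[BinaryMask],
    references: Iterable[BinaryMask],
    registry: LabelRegistry | None = None,
    corrections: Sequence[CorrectionEntry] | None = None,
    threshold: float = DEFAULT_MMED_THRESHOLD,
    smoother: str = "adaboost",
) -> CohortScores:
    """Score every rater drawing against its reference sulcus.

    Without *corrections* this is the raw-label analysis; with them the
    corrected analysis (corrections are applied before label merging).
    Drawings whose (view, hemisphere, canonical label) has no reference are
    excluded from the scores but listed in the ``unmatched`` report — they
    correspond to marks with no underlying sulcus.
    """
    drawings = list(drawings)
    if corrections is not None:
        drawings = apply_corrections(drawings, corrections, registry)
    drawings = merge_same_label(_canonical_mask(m, registry) for m in drawings)
    refs = _reference_lookup(references, registry)

    rows, orphans = [], []
    for mask in drawings:
        if mask.is_empty:
            continue
        ref = refs.get((mask.view, mask.hemisphere, mask.label))
        if ref is None:
            orphans.append(
                {
                    "rater": mask.rater,
                    "view": mask.view,
                    "hemisphere": mask.hemisphere,
                    "label": mask.label,
                    "n_pixels": len(mask),
                }
            )
            continue
        score = score_pair(mask, ref, threshold=threshold, smoother=smoother)
        rows.append(
            {
                "rater": mask.rater,
                "view": mask.view,
                "hemisphere": mask.hemisphere,
                "label": mask.label,
                "dice": score.dice,
                "mmed": score.mmed,
                "mmedn": score.mmedn,
                "siss": score.siss,
                "saturated": score.saturated,
                "corrected": corrections is not None,
            }
        )
    scores = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    unmatched = pd.DataFrame(
        orphans, columns=["rater", "view", "hemisphere", "label", "n_pixels"]
    )
    return CohortScores(scores=scores, unmatched=unmatched, corrected=corrections is not None)


def mean_table(scores: pd.DataFrame | CohortScores) -> AggregateTable:
    """Average scores into the per-sulcus reliability table.

    Cell mean = unweighted mean over the raters who drew that (label,
    hemisphere, view); the marginal is the unweighted mean over the view
    cells that exist (missing cells are skipped, not zero-filled).
    """
    if isinstance(scores, CohortScores):
        scores = scores.scores
    if scores.empty:
        raise ValueError("cannot aggregate an empty score set")
    cells = (
        scores.groupby(["label", "hemisphere", "view"])
        .agg(mean_siss=("siss", "mean"), n_raters=("rater", "nunique"))
        .sort_index()
    )
    marginals = (
        cells.groupby(["label", "hemisphere"])
        .agg(mean_siss=("mean_siss", "mean"), n_views=("mean_siss", "size"))
        .sort_index()
    )
    return AggregateTable(cells=cells, marginals=marginals)


def identification_rate(
    scores: pd.DataFrame | CohortScores,
    n_total_raters: int,
) -> pd.DataFrame:
    """Fraction of the cohort that drew each (label, hemisphere, view).

    The denominator is the full cohort size, not the per-view participant
    count.
    """
    if isinstance(scores, CohortScores):
        scores = scores.scores
    if n_total_raters < 1:
        raise ValueError("n_total_raters must be >= 1")
    counts = scores.groupby(["label", "hemisphere", "view"])["rater"].nunique()
    return (counts / float(n_total_raters)).rename("rate").to_frame()


def classify_zones(
    table: AggregateTable,
    rates: pd.DataFrame,
    green_min: float = 0.5,
    yellow_min: float = 0.4,
    rate_min: float = 0.2,
) -> pd.DataFrame:
    """Traffic-light reliability classification per (label, hemisphere).

    A view *qualifies* when its identification rate strictly exceeds
    *rate_min* (default 20% of the cohort).  Among qualifying views the one
    with the highest mean SISS decides the zone: green above *green_min*
    (strict), yellow in (*yellow_min*, *green_min*], red otherwise — and
    red whenever no view qualifies, however well the few attempts scored.
    """
    rows = []
    cells = table.cells.join(rates, how="left")
    for (label, hemi), group in cells.groupby(["label", "hemisphere"]):
        qualifying = group[group["rate"] > rate_min]
        if qualifying.empty:
            rows.append(
                {
                    "label": label,
                    "hemisphere": hemi,
                    "zone": "red",
                    "best_view": None,
                    "best_mean_siss": float("nan"),
                    "best_rate": float("nan"),
                }
            )
            continue
        best = qualifying["mean_siss"].idxmax()
        mean_siss = float(qualifying.loc[best, "mean_siss"])
        if mean_siss > green_min:
            zone = "green"
        elif mean_siss > yellow_min:
            zone = "yellow"
        else:
            zone = "red"
        rows.append(
            {
                "label": label,
                "hemisphere": hemi,
                "zone": zone,
                "best_view": best[2],
                "best_mean_siss": mean_siss,
                "best_rate": float(qualifying.loc[best, "rate"]),
            }
        )
    return pd.DataFrame(rows).set_index(["label", "hemisphere"]).sort_index()


def write_scores(scores: CohortScores, path: str | Path) -> None:
    scores.scores.to_csv(path, index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(SCORE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"scores file missing columns: {sorted(missing)}")
    return table


def write_data_dictionary(path: str | Path) -> None:
    Path(path).write_text(DATA_DICTIONARY)
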