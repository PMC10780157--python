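"""Sulcus nomenclature, label merging, and a posteriori label correction.

The scoring pipeline works on a fixed nomenclature of 42 sulci that raters
may identify on an endocast.  A handful of fine-grained labels are merged
into broader canonical sulci before any aggregation (e.g. the five
pre-central branches are all scored as the single pre-central sulcus
``S.Pe.C``), because the level of anatomical detail visible on an endocast
does not support the finer distinction.

Two analysis perspectives are distinguished downstream:

* *raw* — drawings are scored under the label the rater assigned;
* *corrected* — misnamed but correctly perceived grooves are re-assigned to
  their true sulcus via a declarative correction table before scoring.

Corrections are input metadata, not an algorithm: deciding that a stroke
"really is" the pre-central sulcus is expert judgement, so this module only
applies a correction file, it never infers one.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .masks import BinaryMask

__all__ = [
    "SulcusLabel",
    "LabelRegistry",
    "CorrectionEntry",
    "DEFAULT_MERGES",
    "NO_SULCUS",
    "load_nomenclature",
    "read_corrections",
    "write_corrections",
    "apply_corrections",
]

#: Sentinel used in correction files for a drawing that corresponds to no
#: real sulcus; such drawings are dropped from the corrected analysis.
NO_SULCUS = "NONE"

GROUPS = ("main", "other", "occipital_extra")

#: Default merge rules: fine-grained variants folded into broader sulci.
DEFAULT_MERGES: dict[str, str] = {
    "S.C.sylvian": "S.C",
    "S.Pe.C.median": "S.Pe.C",
    "S.Pe.C.marginal": "S.Pe.C",
    "S.Pe.C.sup": "S.Pe.C",
    "S.Pe.C.inter": "S.Pe.C",
    "S.Pe.C.inf": "S.Pe.C",
    "F.C.L.r.retroC.tr": "F.I.P.Po.C.inf",
}

#: Canonical entries required as merge targets but absent from the numbered
#: nomenclature table (they only exist as a union of merged variants).
_DERIVED_CANONICALS = {"S.Pe.C": "Pre-central sulcus"}

#: Canonical label under which rater-supplied occipital variants are pooled.
OCCIPITAL_CANONICAL = "Occipital"


@dataclass(frozen=True)
class SulcusLabel:
    """One entry of the sulcus nomenclature.

    Parameters
    ----------
    abbreviation : str
        Short code, e.g. ``"S.C"`` — unique within a registry.
    full_name : str
        Human-readable sulcus name.
    group : str
        ``"main"`` for the primary list, ``"other"`` for additional sulci,
        ``"occipital_extra"`` for occipital variants raters added on their
        own initiative (those carry no table index).
    index : int or None
        Position in the nomenclature table (1..42), or None for derived or
        extra entries.
    """

    abbreviation: str
    full_name: str
    group: str = "main"
    index: int | None = None

    def __post_init__(self) -> None:
        if not self.abbreviation:
            raise ValueError("abbreviation must be non-empty")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.group == "occipital_extra" and self.index is not None:
            raise ValueError("occipital_extra labels carry no table index")


class LabelRegistry:
    """The sulcus nomenclature plus its merge rules.

    ``merge_map`` maps a source abbreviation to its canonical target; the
    targets are themselves registry members and never sources, so applying
    the map twice equals applying it once.
    """

    def __init__(
        self,
        entries: Iterable[SulcusLabel],
        merge_map: Mapping[str, str] | None = None,
    ) -> None:
        self.entries: dict[str, SulcusLabel] = {}
        for entry in entries:
            if entry.abbreviation in self.entries:
                raise ValueError(f"duplicate abbreviation {entry.abbreviation!r}")
            self.entries[entry.abbreviation] = entry
        indices = [e.index for e in self.entries.values() if e.index is not None]
        if len(indices) != len(set(indices)):
            raise ValueError("table indices must be unique")
        self.merge_map: dict[str, str] = dict(merge_map or {})
        for source, target in self.merge_map.items():
            if target not in self.entries:
                raise ValueError(f"unknown merge target {target!r} (for {source!r})")
            if target in self.merge_map:
                raise ValueError(
                    f"merge target {target!r} is itself a merge source; "
                    "merge_map must be idempotent"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, abbreviation: str) -> bool:
        return abbreviation in self.entries or abbreviation in self.merge_map

    @property
    def n_indexed(self) -> int:
        """Number of numbered nomenclature-table entries."""
        return sum(1 for e in self.entries.values() if e.index is not None)

    def canonicalize(self, label: str) -> str:
        """Resolve *label* to its canonical abbreviation.

        Returns the merge target if the label is a merge source, otherwise
        the label itself.  Idempotent.  Raises ``KeyError`` for labels the
        registry does not know.
        """
        if label in self.merge_map:
            return self.merge_map[label]
        if label in self.entries:
            return label
        raise KeyError(f"unknown sulcus label {label!r}")

    def canonical_labels(self) -> set[str]:
        """Set of distinct canonical abbreviations."""
        return {self.canonicalize(a) for a in self.entries}

    def register_extra(self, abbreviation: str, full_name: str = "") -> SulcusLabel:
        """Register a rater-supplied occipital variant.

        The variant is pooled under the canonical ``Occipital`` label, which
        is how the occipital region is reported: raters used heterogeneous
        occipital terms that cannot be told apart on an endocast.
        """
        if abbreviation in self:
            raise ValueError(f"label {abbreviation!r} already registered")
        entry = SulcusLabel(abbreviation, full_name or abbreviation, "occipital_extra")
        self.entries[abbreviation] = entry
        if abbreviation != OCCIPITAL_CANONICAL:
            self.merge_map[abbreviation] = OCCIPITAL_CANONICAL
        return entry


def load_nomenclature(
    source: str | Path | None = None,
    merge_map: Mapping[str, str] | None = None,
) -> LabelRegistry:
    """Load the sulcus nomenclature table into a :class:`LabelRegistry`.

    Parameters
    ----------
    source : path-like, optional
        CSV with columns ``abbreviation``, ``full_name``, ``group`` and
        optionally ``index``.  Defaults to the packaged 42-entry table.
    merge_map : mapping, optional
        Override for the default merge rules (:data:`DEFAULT_MERGES`).
    """
    if source is None:
        with resources.as_file(
            resources.files("sulciscore.data") / "nomenclature.csv"
        ) as path:
            table = pd.read_csv(path)
    else:
        table = pd.read_csv(source)
    required = {"abbreviation", "full_name", "group"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"nomenclature file missing columns: {sorted(missing)}")
    if table.empty:
        raise ValueError("nomenclature file contains no entries")
    entries = [
        SulcusLabel(
            abbreviation=str(row.abbreviation),
            full_name=str(row.full_name),
            group=str(row.group),
            index=int(row.index) if "index" in table.columns and pd.notna(row.index) else None,
        )
        for row in table.itertuples()
    ]
    merges = dict(DEFAULT_MERGES if merge_map is None else merge_map)
    known = {e.abbreviation for e in entries}
    for target, name in _DERIVED_CANONICALS.items():
        if target in merges.values() and target not in known:
            entries.append(SulcusLabel(target, name, "main"))
    return LabelRegistry(entries, merges)


@dataclass(frozen=True)
class CorrectionEntry:
    """Reassignment of one rater drawing to its true sulcus (or to none).

    ``corrected_labels`` may hold several abbreviations when one stroke
    plausibly matches two adjacent sulci — the drawing is then scored once
    per label.  The sentinel :data:`NO_SULCUS` marks a drawing that matches
    no real sulcus; it is dropped from the corrected analysis.
    """

    rater_id: str
    view_id: str
    hemisphere: str
    drawn_label: str
    corrected_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.corrected_labels:
            raise ValueError("corrected_labels must be non-empty (use NO_SULCUS to drop)")
        if NO_SULCUS in self.corrected_labels and len(self.corrected_labels) > 1:
            raise ValueError("NO_SULCUS cannot be combined with real labels")

    @property
    def drops_drawing(self) -> bool:
        return self.corrected_labels == (NO_SULCUS,)


def read_corrections(path: str | Path) -> list[CorrectionEntry]:
    """Read a correction file.

    Expected CSV columns: ``rater_id``, ``view``, ``hemisphere``,
    ``drawn_label``, ``corrected_labels`` (semicolon-separated list, or the
    sentinel ``NONE``).
    """
    table = pd.read_csv(path)
    required = {"rater_id", "view", "hemisphere", "drawn_label", "corrected_labels"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"correction file missing columns: {sorted(missing)}")
    entries = []
    for row in table.itertuples():
        corrected = tuple(s.strip() for s in str(row.corrected_labels).split(";") if s.strip())
        entries.append(
            CorrectionEntry(
                rater_id=str(row.rater_id),
                view_id=str(row.view),
                hemisphere=str(row.hemisphere),
                drawn_label=str(row.drawn_label),
                corrected_labels=corrected,
            )
        )
    return entries


def write_corrections(entries: Sequence[CorrectionEntry], path: str | Path) -> None:
    pd.DataFrame(
        {
            "rater_id": [e.rater_id for e in entries],
            "view": [e.view_id for e in entries],
            "hemisphere": [e.hemisphere for e in entries],
            "drawn_label": [e.drawn_label for e in entries],
            "corrected_labels": [";".join(e.corrected_labels) for e in entries],
        }
    ).to_csv(path, index=False)


def _resolve(label: str, registry: LabelRegistry | None) -> str:
    if registry is None:
        return label
    return registry.canonicalize(label)


def apply_corrections(
    drawings: Iterable[BinaryMask],
    corrections: Sequence[CorrectionEntry],
    registry: LabelRegistry | None = None,
) -> list[BinaryMask]:
    """Relabel drawings according to a correction table.

    Pixel content is never touched — only labels and multiplicity change:
    a corrected drawing reappears once per corrected label, sentinel-marked
    drawings are dropped, uncorrected drawings pass through unchanged.

    Raises ``ValueError`` if any correction references a drawing that does
    not exist in *drawings*.
    """
    lookup: dict[tuple[str, str, str, str], CorrectionEntry] = {}
    for entry in corrections:
        key = (
            entry.rater_id,
            entry.view_id,
            entry.hemisphere,
            _resolve(entry.drawn_label, registry),
        )
        if key in lookup:
            raise ValueError(f"duplicate correction for {key}")
        lookup[key] = entry

    used: set[tuple[str, str, str, str]] = set()
    out: list[BinaryMask] = []
    for mask in drawings:
        try:
            canon = _resolve(mask.label, registry)
        except KeyError:
            canon = mask.label
        key = (mask.rater, mask.view, mask.hemisphere, canon)
        entry = lookup.get(key)
        if entry is None:
            out.append(mask)
            continue
        used.add(key)
        if entry.drops_drawing:
            continue
        for corrected in entry.corrected_labels:
            out.append(dataclasses.replace(mask, label=_resolve(corrected, registry)))
    dangling = set(lookup) - used
    if dangling:
        raise ValueError(
            "corrections reference drawings that do not exist: "
            + ", ".join(map(str, sorted(dangling)))
        )
    return out
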