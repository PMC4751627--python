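"""Selecting units and navigating the scale hierarchy.

Three selection routes mirror how a user addresses structure: by unit index
within the displayed scale, by lineage (scale information) when the index is
unknown, and by genome sequence location.  A :class:`Selection` is an
immutable set of same-scale unit indices on one structure; it is the operand
of scale-up / scale-down navigation, measurement and sequence retrieval.

The genome level is accepted as a selection scale and denotes the
genome-scale view, whose displayed points are the chromosome units — there
the unit index *is* the chromosome number.  Sequence selection uses overlap
semantics: a unit sharing any base with the query interval is selected.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable

from .core import GenomeStructure, GenomicInterval, ScaleLevel, Unit
from .errors import ScaleError, SelectionError

__all__ = [
    "Selection",
    "select_by_index",
    "select_by_scale_info",
    "select_by_sequence",
    "scale_down",
    "scale_up",
]


def _view_scale(structure: GenomeStructure, scale: ScaleLevel) -> ScaleLevel:
    """Resolve the genome-view alias: genome-scale selections operate on
    the chromosome unit list (one point per chromosome)."""
    if scale is ScaleLevel.GENOME:
        return ScaleLevel.CHROMOSOME
    return scale


@dataclass(frozen=True)
class Selection:
    """An ordered, de-duplicated set of unit indices at one scale."""

    structure: GenomeStructure
    scale: ScaleLevel
    indices: tuple[int, ...]

    def __post_init__(self):
        if self.scale is ScaleLevel.GENOME:
            object.__setattr__(self, "scale", ScaleLevel.CHROMOSOME)
        dedup = tuple(sorted(set(self.indices)))
        object.__setattr__(self, "indices", dedup)
        n = len(self.structure.units_at(self.scale))
        for i in dedup:
            if not 1 <= i <= n:
                raise SelectionError(
                    f"index {i} out of range [1, {n}] at scale {self.scale}"
                )

    @property
    def units(self) -> list[Unit]:
        all_units = self.structure.units_at(self.scale)
        return [all_units[i - 1] for i in self.indices]

    def __len__(self) -> int:
        return len(self.indices)

    def __bool__(self) -> bool:
        return bool(self.indices)

    def union(self, other: "Selection") -> "Selection":
        self._check_compatible(other)
        return Selection(self.structure, self.scale, self.indices + other.indices)

    def intersection(self, other: "Selection") -> "Selection":
        self._check_compatible(other)
        common = set(self.indices) & set(other.indices)
        return Selection(self.structure, self.scale, tuple(common))

    def _check_compatible(self, other: "Selection") -> None:
        if other.structure is not self.structure or other.scale is not self.scale:
            raise SelectionError("selections combine only on the same structure and scale")


def select_by_index(
    structure: GenomeStructure, scale: ScaleLevel, indices: Iterable[int]
) -> Selection:
    """Select units by their 1-based index at `scale`.

    At the genome view the index is the chromosome number.  Duplicates are
    collapsed; an out-of-range index raises naming the offending value.
    """
    scale = _view_scale(structure, scale)
    n = len(structure.units_at(scale))
    idx = []
    for i in indices:
        i = int(i)
        if not 1 <= i <= n:
            raise SelectionError(
                f"index {i} out of range [1, {n}] for {scale} units"
            )
        idx.append(i)
    return Selection(structure, scale, tuple(idx))


def select_by_scale_info(
    structure: GenomeStructure,
    scale: ScaleLevel,
    chromosome: int,
    locus: int | None = None,
    fiber: int | None = None,
    nucleosome: int | None = None,
) -> Selection:
    """Select the units at `scale` inside a chromosome / locus / fiber / NCP.

    The lineage fields must form a prefix (a fiber index requires a locus
    index), and the deepest given field must be at `scale` or coarser.
    """
    scale = _view_scale(structure, scale)
    given = [("locus", locus), ("fiber", fiber), ("nucleosome", nucleosome)]
    prefix: list[int] = [chromosome]
    stopped = False
    for name, value in given:
        if value is None:
            stopped = True
        elif stopped:
            raise SelectionError(
                f"lineage fields must form a prefix: {name} given but a coarser field omitted"
            )
        else:
            prefix.append(value)
    if chromosome not in structure.chromosome_lengths:
        raise SelectionError(f"unknown chromosome {chromosome}")
    deepest = ScaleLevel(ScaleLevel.CHROMOSOME + len(prefix) - 1)
    if scale < deepest:
        raise SelectionError(
            f"selection scale {scale} is coarser than the given {deepest} lineage"
        )
    key = tuple(prefix)
    hits = [
        u.index
        for u in structure.units_at(scale)
        if u.lineage.as_tuple()[: len(key)] == key
    ]
    return Selection(structure, scale, tuple(hits))


def select_by_sequence(
    structure: GenomeStructure, scale: ScaleLevel, interval: GenomicInterval
) -> Selection:
    """Select every unit at `scale` whose interval overlaps the query.

    Overlap means at least one shared base (1-based inclusive on both
    sides); a unit partially covering the query is included.  Implemented
    by bisection over the per-chromosome start coordinates.
    """
    scale = _view_scale(structure, scale)
    if interval.chromosome not in structure.chromosome_lengths:
        raise SelectionError(f"chromosome {interval.chromosome} absent from structure")
    units = structure.units_at(scale)
    # units are in genome order; restrict to the chromosome's contiguous run
    chroms = [u.interval.chromosome for u in units]
    lo = bisect.bisect_left(chroms, interval.chromosome)
    hi = bisect.bisect_right(chroms, interval.chromosome)
    starts = [units[i].interval.start_bp for i in range(lo, hi)]
    # first unit that could overlap: last with start <= query end
    last = bisect.bisect_right(starts, interval.end_bp)
    hits = []
    for i in range(lo, lo + last):
        if units[i].interval.end_bp >= interval.start_bp:
            hits.append(units[i].index)
    return Selection(structure, scale, tuple(hits))


def scale_down(selection: Selection) -> Selection:
    """All children of the selected units at the next finer scale.

    Gives the detailed structure of the selection.  The finer scale must be
    populated (nucleotide units are generated per-NCP on demand by the
    synthetic generator).
    """
    finer = selection.scale.finer
    if finer is None:
        raise ScaleError("no finer scale below nucleotide resolution")
    try:
        children = selection.structure.units_at(finer)
    except ScaleError:
        hint = (
            "; generate nucleotides for the selected NCPs first"
            if finer is ScaleLevel.NUCLEOTIDE
            else ""
        )
        raise ScaleError(f"scale {finer} is not populated{hint}") from None
    if not selection:
        return Selection(selection.structure, finer, ())
    keys = {u.lineage.as_tuple() for u in selection.units}
    hits = tuple(c.index for c in children if c.parent_key in keys)
    return Selection(selection.structure, finer, hits)


def scale_up(selection: Selection) -> Selection:
    """The (de-duplicated) parents of the selected units at the next
    coarser scale — an overview of where the selection sits."""
    coarser = selection.scale.coarser
    if coarser is None or coarser is ScaleLevel.GENOME:
        raise ScaleError(
            "no coarser scale: chromosome units are already the genome-scale view"
        )
    parents = selection.structure.units_at(coarser)
    if not selection:
        return Selection(selection.structure, coarser, ())
    wanted = {u.parent_key for u in selection.units}
    hits = tuple(p.index for p in parents if p.lineage.as_tuple() in wanted)
    return Selection(selection.structure, coarser, hits)
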