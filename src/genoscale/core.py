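"""Core data model: the six-level scale hierarchy and multi-scale structures.

A genome structure is modelled as point clouds at up to five *unit* scales
(chromosome, loci, fiber, nucleosome, nucleotide).  A unit at scale *s* is a
single 3D point (in nanometers) standing for a contiguous stretch of genome
sequence whose length is the scale's span — 1 bp for a nucleotide, 100 bp for
a nucleosome core particle, ~1 kb for a chromatin fiber segment, ~1 Mb for a
locus, and a whole chromosome at chromosome scale.  The sixth, coarsest level
(genome) is the root of the hierarchy: its view is the set of chromosome
units, so it stores no units of its own.

A coarser unit's position is the centroid of its children's positions, and
its genomic interval is tiled exactly by its children's intervals.  Those two
invariants are what :func:`build_coarser_scale` constructs and
:func:`validate_hierarchy` checks.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import HierarchyError, ScaleError

__all__ = [
    "ScaleLevel",
    "ScaleConfig",
    "GenomicInterval",
    "Lineage",
    "Unit",
    "GenomeStructure",
    "Finding",
    "centroid",
    "build_coarser_scale",
    "validate_hierarchy",
    "CENTROID_TOL_NM",
]

#: tolerance (nm) within which a parent position must match its children's centroid
CENTROID_TOL_NM = 1e-6


class ScaleLevel(enum.IntEnum):
    """The ordered six-level resolution hierarchy, coarsest to finest.

    ``GENOME < CHROMOSOME < LOCI < FIBER < NUCLEOSOME < NUCLEOTIDE``;
    a larger enum value means higher resolution.
    """

    GENOME = 0
    CHROMOSOME = 1
    LOCI = 2
    FIBER = 3
    NUCLEOSOME = 4
    NUCLEOTIDE = 5

    @property
    def finer(self) -> "ScaleLevel | None":
        """The next higher-resolution level, or None at NUCLEOTIDE."""
        if self is ScaleLevel.NUCLEOTIDE:
            return None
        return ScaleLevel(self.value + 1)

    @property
    def coarser(self) -> "ScaleLevel | None":
        """The next lower-resolution level, or None at GENOME."""
        if self is ScaleLevel.GENOME:
            return None
        return ScaleLevel(self.value - 1)

    @classmethod
    def from_name(cls, name: str) -> "ScaleLevel":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ScaleError(f"unknown scale level {name!r}") from None

    def __str__(self) -> str:  # "fiber", not "ScaleLevel.FIBER"
        return self.name.lower()


@dataclass(frozen=True)
class ScaleConfig:
    """Base-pair spans of the fixed-width scales.

    The nucleotide span is always 1 bp.  Nucleosome, fiber and locus spans
    are configurable but each must divide the next coarser one exactly, so
    that finer units tile coarser ones.  Chromosome "span" is the actual
    chromosome length and is carried by the structure, not by this config.
    """

    nucleosome_bp: int = 100
    fiber_bp: int = 1_000
    locus_bp: int = 1_000_000

    def __post_init__(self):
        for name in ("nucleosome_bp", "fiber_bp", "locus_bp"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.fiber_bp % self.nucleosome_bp:
            raise ValueError(
                f"nucleosome span ({self.nucleosome_bp}) must divide fiber span ({self.fiber_bp})"
            )
        if self.locus_bp % self.fiber_bp:
            raise ValueError(
                f"fiber span ({self.fiber_bp}) must divide locus span ({self.locus_bp})"
            )

    def span_bp(self, scale: ScaleLevel) -> int:
        """Fixed span of `scale` in bp. Undefined for GENOME/CHROMOSOME."""
        if scale is ScaleLevel.NUCLEOTIDE:
            return 1
        if scale is ScaleLevel.NUCLEOSOME:
            return self.nucleosome_bp
        if scale is ScaleLevel.FIBER:
            return self.fiber_bp
        if scale is ScaleLevel.LOCI:
            return self.locus_bp
        raise ScaleError(f"{scale} has no fixed base-pair span")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive interval on one chromosome."""

    chromosome: int
    start_bp: int
    end_bp: int

    def __post_init__(self):
        if self.chromosome < 1:
            raise ValueError(f"chromosome must be positive, got {self.chromosome}")
        if self.start_bp < 1 or self.end_bp < self.start_bp:
            raise ValueError(
                f"invalid interval [{self.start_bp}, {self.end_bp}] (1-based inclusive)"
            )

    @property
    def length(self) -> int:
        return self.end_bp - self.start_bp + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the intervals share at least one base."""
        return (
            self.chromosome == other.chromosome
            and self.start_bp <= other.end_bp
            and other.start_bp <= self.end_bp
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start_bp <= other.start_bp
            and other.end_bp <= self.end_bp
        )

    def __str__(self) -> str:
        return f"chr{self.chromosome}:{self.start_bp}-{self.end_bp}"


@dataclass(frozen=True, order=True)
class Lineage:
    """Hierarchical address of a unit: chromosome number, then 1-based
    locus / fiber / nucleosome indices, each within its parent.

    Fields must form a prefix: a fiber index requires a locus index, etc.
    Nucleotide units carry the full lineage of their parent nucleosome core
    particle (the address scheme stops at nucleosome depth).
    """

    chromosome: int
    locus: int | None = None
    fiber: int | None = None
    nucleosome: int | None = None

    def __post_init__(self):
        fields = (self.chromosome, self.locus, self.fiber, self.nucleosome)
        seen_none = False
        for v in fields:
            if v is None:
                seen_none = True
            elif seen_none:
                raise ValueError(f"lineage fields must form a prefix, got {fields}")
            elif v < 1:
                raise ValueError(f"lineage indices are 1-based positive, got {fields}")

    def as_tuple(self) -> tuple[int, ...]:
        """Lineage as a tuple with trailing Nones dropped."""
        out = [self.chromosome]
        for v in (self.locus, self.fiber, self.nucleosome):
            if v is None:
                break
            out.append(v)
        return tuple(out)

    @property
    def depth_scale(self) -> ScaleLevel:
        """The scale addressed by the deepest present field."""
        return ScaleLevel(ScaleLevel.CHROMOSOME + len(self.as_tuple()) - 1)

    def parent(self) -> "Lineage | None":
        """Lineage with the deepest field removed; None for a chromosome."""
        t = self.as_tuple()
        if len(t) == 1:
            return None
        return Lineage.from_tuple(t[:-1])

    @classmethod
    def from_tuple(cls, t: tuple[int, ...]) -> "Lineage":
        if not 1 <= len(t) <= 4:
            raise ValueError(f"lineage tuple must have 1-4 fields, got {t!r}")
        return cls(*t)

    def matches_prefix(self, other: "Lineage") -> bool:
        """True if `other`'s present fields all equal this lineage's."""
        o = other.as_tuple()
        return self.as_tuple()[: len(o)] == o

    def __str__(self) -> str:
        names = ("chr", "locus", "fiber", "ncp")
        return "/".join(f"{n}{v}" for n, v in zip(names, self.as_tuple()))


def lineage_for_interval(
    interval: GenomicInterval, scale: ScaleLevel, config: ScaleConfig
) -> Lineage:
    """Derive a unit's lineage from its interval start and the scale spans.

    The k-th fixed-span compartment of its parent starts at
    ``(k-1) * span + 1`` relative to the parent's origin, so every index is
    recovered by integer division on the 0-based start coordinate.
    """
    if scale is ScaleLevel.GENOME:
        raise ScaleError("genome level carries no units")
    pos0 = interval.start_bp - 1
    chrom = interval.chromosome
    if scale is ScaleLevel.CHROMOSOME:
        return Lineage(chrom)
    locus = pos0 // config.locus_bp + 1
    if scale is ScaleLevel.LOCI:
        return Lineage(chrom, locus)
    fiber = pos0 % config.locus_bp // config.fiber_bp + 1
    if scale is ScaleLevel.FIBER:
        return Lineage(chrom, locus, fiber)
    nucleosome = pos0 % config.fiber_bp // config.nucleosome_bp + 1
    return Lineage(chrom, locus, fiber, nucleosome)


@dataclass(frozen=True)
class Unit:
    """One structural point: a genomic stretch at one scale with a 3D
    position in nanometers.

    `index` is the unit's 1-based rank among all units of its scale,
    ordered by genome sequence (chromosome, then start coordinate).
    """

    scale: ScaleLevel
    index: int
    lineage: Lineage
    interval: GenomicInterval
    position: tuple[float, float, float]

    def __post_init__(self):
        if self.scale is ScaleLevel.GENOME:
            raise ScaleError("genome level carries no units")
        if self.index < 1:
            raise ValueError(f"unit index is 1-based, got {self.index}")
        if len(self.position) != 3 or not all(math.isfinite(c) for c in self.position):
            raise ValueError(f"position must be 3 finite coordinates, got {self.position}")
        if self.lineage.chromosome != self.interval.chromosome:
            raise ValueError(
                f"lineage chromosome {self.lineage.chromosome} != "
                f"interval chromosome {self.interval.chromosome}"
            )
        want = self.scale if self.scale is not ScaleLevel.NUCLEOTIDE else ScaleLevel.NUCLEOSOME
        if self.lineage.depth_scale is not want:
            raise ValueError(
                f"{self.scale} unit needs lineage down to {want}, got {self.lineage}"
            )

    @property
    def parent_key(self) -> tuple[int, ...]:
        """Grouping key of this unit's parent at the next coarser scale."""
        if self.scale is ScaleLevel.NUCLEOTIDE:
            return self.lineage.as_tuple()
        t = self.lineage.as_tuple()
        return t[:-1]

    def moved_by(self, offset) -> "Unit":
        ox, oy, oz = (float(v) for v in offset)
        x, y, z = self.position
        return replace(self, position=(x + ox, y + oy, z + oz))

    def label(self) -> str:
        return f"{self.scale}[{self.index}]({self.lineage})"


def _genome_order_key(u: Unit) -> tuple[int, int]:
    return (u.interval.chromosome, u.interval.start_bp)


@dataclass
class GenomeStructure:
    """Per-scale unit collections plus the scale configuration.

    Any subset of the five unit-bearing scales may be populated.  Unit lists
    are kept in genome order (chromosome, start) with ``index == rank``.
    """

    name: str
    scale_config: ScaleConfig = field(default_factory=ScaleConfig)
    chromosome_lengths: dict[int, int] = field(default_factory=dict)
    chromosome_names: dict[int, str] = field(default_factory=dict)
    units: dict[ScaleLevel, list[Unit]] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, length in self.chromosome_lengths.items():
            if length < 1:
                raise ValueError(f"chromosome {chrom} length must be >= 1 bp, got {length}")
            self.chromosome_names.setdefault(chrom, f"chr{chrom}")

    # -- accessors ---------------------------------------------------------

    def populated_scales(self) -> list[ScaleLevel]:
        return sorted(s for s, us in self.units.items() if us)

    def units_at(self, scale: ScaleLevel) -> list[Unit]:
        if scale not in self.units or not self.units[scale]:
            raise ScaleError(f"scale {scale} is not populated in structure {self.name!r}")
        return self.units[scale]

    def unit(self, scale: ScaleLevel, index: int) -> Unit:
        units = self.units_at(scale)
        if not 1 <= index <= len(units):
            raise ScaleError(f"no unit {index} at {scale} (have {len(units)})")
        return units[index - 1]

    def set_units(self, scale: ScaleLevel, units: list[Unit]) -> None:
        """Install a unit list at `scale`, sorting to genome order and
        re-assigning indices so that index == rank."""
        if any(u.scale is not scale for u in units):
            raise ScaleError(f"all units must be at scale {scale}")
        ordered = sorted(units, key=_genome_order_key)
        self.units[scale] = [
            replace(u, index=i) if u.index != i else u
            for i, u in enumerate(ordered, start=1)
        ]

    def children_of(self, unit: Unit) -> list[Unit]:
        """Units at the next finer populated scale whose lineage extends
        `unit`'s (empty if the finer scale is unpopulated)."""
        finer = unit.scale.finer
        if finer is None or finer not in self.units:
            return []
        key = unit.lineage.as_tuple() if unit.scale is not ScaleLevel.NUCLEOTIDE else None
        return [c for c in self.units[finer] if c.parent_key == key]

    def chromosome_number(self, name: str) -> int:
        """Resolve a chromosome name ('chr2', '2', 'X' via the name table)
        to its number."""
        for num, nm in self.chromosome_names.items():
            if nm == name:
                return num
        stripped = name.removeprefix("chr")
        try:
            num = int(stripped)
        except ValueError:
            raise HierarchyError(f"unknown chromosome name {name!r}") from None
        if num in self.chromosome_lengths:
            return num
        raise HierarchyError(f"unknown chromosome name {name!r}")

    def copy(self) -> "GenomeStructure":
        return GenomeStructure(
            name=self.name,
            scale_config=self.scale_config,
            chromosome_lengths=dict(self.chromosome_lengths),
            chromosome_names=dict(self.chromosome_names),
            units={s: list(us) for s, us in self.units.items()},
        )


# -- operations ------------------------------------------------------------


def centroid(points) -> tuple[float, float, float]:
    """Unweighted arithmetic mean of a non-empty list of 3D points (nm)."""
    arr = np.asarray(points, dtype=float)
    if arr.size == 0:
        raise ValueError("centroid of zero compartments is undefined")
    if arr.ndim != 2 or arr.shape[1] != 3 or not np.all(np.isfinite(arr)):
        raise ValueError("points must be a non-empty list of finite (x, y, z) triples")
    return tuple(arr.mean(axis=0))


def build_coarser_scale(
    structure: GenomeStructure, target_scale: ScaleLevel
) -> GenomeStructure:
    """Populate `target_scale` by aggregating the scale immediately finer.

    Each distinct parent lineage among the finer units becomes one unit:
    position is the centroid of the group, interval the (min start, max end)
    union, and indices follow genome order.  Mutates and returns `structure`.
    """
    finer = target_scale.finer
    if target_scale is ScaleLevel.GENOME:
        raise ScaleError("genome level carries no units; chromosome units are its view")
    if finer is None or finer not in structure.units or not structure.units[finer]:
        raise ScaleError(
            f"cannot build {target_scale}: finer scale "
            f"{finer if finer is not None else '<none>'} is not populated"
        )
    groups: dict[tuple[int, ...], list[Unit]] = {}
    for u in structure.units[finer]:
        groups.setdefault(u.parent_key, []).append(u)
    parents = []
    for key, children in groups.items():
        interval = GenomicInterval(
            chromosome=key[0],
            start_bp=min(c.interval.start_bp for c in children),
            end_bp=max(c.interval.end_bp for c in children),
        )
        parents.append(
            Unit(
                scale=target_scale,
                index=1,  # reassigned by set_units
                lineage=Lineage.from_tuple(key),
                interval=interval,
                position=centroid([c.position for c in children]),
            )
        )
    structure.set_units(target_scale, parents)
    return structure


@dataclass(frozen=True)
class Finding:
    """One hierarchy-consistency violation."""

    kind: str  # centroid_mismatch | tiling_gap | tiling_overlap | containment | index_order | orphan_child
    scale: ScaleLevel
    lineage: Lineage | None
    detail: str

    def __str__(self) -> str:
        where = f" at {self.lineage}" if self.lineage else ""
        return f"[{self.kind}] {self.scale}{where}: {self.detail}"


def validate_hierarchy(
    structure: GenomeStructure, *, centroid_tol_nm: float = CENTROID_TOL_NM
) -> list[Finding]:
    """Check every structural invariant and report all violations.

    Returns an empty list iff the structure is consistent.  Checks, per
    scale: genome ordering (index == rank under (chromosome, start) order);
    per consecutive populated scale pair: child intervals tile the parent
    interval with no gaps or overlaps, parent position equals the child
    centroid within `centroid_tol_nm`, and every child has a parent.
    Nucleosome units without any nucleotide children are skipped at the
    nucleotide level (nucleotides are populated lazily per NCP).

    `centroid_tol_nm` defaults to the in-memory tolerance (1e-6 nm); for
    structures re-loaded from GSS files, whose coordinates are quantized to
    3 decimals, a tolerance of ~1e-3 nm is the appropriate yardstick.
    """
    findings: list[Finding] = []
    scales = structure.populated_scales()
    if len(scales) < 2:
        raise ScaleError("hierarchy validation needs at least two populated scales")

    for scale in scales:
        units = structure.units[scale]
        ordered = sorted(units, key=_genome_order_key)
        for rank, u in enumerate(ordered, start=1):
            if u.index != rank:
                findings.append(
                    Finding(
                        "index_order",
                        scale,
                        u.lineage,
                        f"unit has index {u.index} but genome-order rank {rank}",
                    )
                )

    for parent_scale, child_scale in zip(scales, scales[1:]):
        if child_scale is not parent_scale.finer:
            # non-adjacent populated scales: containment is still checkable
            # through lineage prefixes, but tiling/centroid relations are
            # defined only between consecutive levels.
            continue
        parents = {u.lineage.as_tuple(): u for u in structure.units[parent_scale]}
        by_parent: dict[tuple[int, ...], list[Unit]] = {}
        for c in structure.units[child_scale]:
            by_parent.setdefault(c.parent_key, []).append(c)

        for key, children in by_parent.items():
            if key not in parents:
                findings.append(
                    Finding(
                        "orphan_child",
                        child_scale,
                        children[0].lineage,
                        f"{len(children)} child unit(s) have no parent {key} at {parent_scale}",
                    )
                )
        for key, parent in parents.items():
            children = by_parent.get(key, [])
            if not children:
                if child_scale is ScaleLevel.NUCLEOTIDE:
                    continue  # lazily populated; absence is legal there
                findings.append(
                    Finding("tiling_gap", parent_scale, parent.lineage, "parent has no children")
                )
                continue
            children = sorted(children, key=_genome_order_key)
            pi = parent.interval
            for c in children:
                if not pi.contains(c.interval):
                    findings.append(
                        Finding(
                            "containment",
                            child_scale,
                            c.lineage,
                            f"child interval {c.interval} not within parent {pi}",
                        )
                    )
            cursor = pi.start_bp
            for c in children:
                if c.interval.start_bp > cursor:
                    findings.append(
                        Finding(
                            "tiling_gap",
                            parent_scale,
                            parent.lineage,
                            f"gap [{cursor}, {c.interval.start_bp - 1}] before child {c.lineage}",
                        )
                    )
                elif c.interval.start_bp < cursor:
                    findings.append(
                        Finding(
                            "tiling_overlap",
                            parent_scale,
                            parent.lineage,
                            f"child {c.lineage} starts at {c.interval.start_bp}, "
                            f"overlapping previous child ending at {cursor - 1}",
                        )
                    )
                cursor = max(cursor, c.interval.end_bp + 1)
            if cursor != pi.end_bp + 1:
                findings.append(
                    Finding(
                        "tiling_gap",
                        parent_scale,
                        parent.lineage,
                        f"children end at {cursor - 1}, parent at {pi.end_bp}",
                    )
                )
            cen = centroid([c.position for c in children])
            err = max(abs(a - b) for a, b in zip(cen, parent.position))
            if err > centroid_tol_nm:
                findings.append(
                    Finding(
                        "centroid_mismatch",
                        parent_scale,
                        parent.lineage,
                        f"parent position deviates from child centroid by {err:.3g} nm",
                    )
                )
    return findings
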