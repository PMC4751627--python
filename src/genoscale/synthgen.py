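"""Seeded generator of hierarchy-consistent multi-scale structures.

The generator emulates the gross spatial statistics of interphase
chromatin: each chromosome occupies its own territory (a sphere around a
territory center), within which consecutive nucleosome core particles
follow a confined random walk with a fixed step length of the order of the
internucleosomal spacing (~10 nm).  Coarser scales are obtained by
centroid aggregation, so every hierarchy invariant holds by construction.
It makes no claim to fractal-globule contact statistics — it exists so the
file formats, selection, measurement and retrieval machinery are testable
with fully known ground truth.

A matching FASTA "genome" of seeded uniform ACGT sequence is generated for
the sequence-retrieval path, and :func:`make_variant` rigidly displaces one
chromosome to emulate a structural difference between two individuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    GenomeStructure,
    GenomicInterval,
    Lineage,
    ScaleConfig,
    ScaleLevel,
    Unit,
    build_coarser_scale,
    lineage_for_interval,
)
from .errors import GenerationError

__all__ = [
    "GenParams",
    "generate_structure",
    "generate_nucleotides",
    "generate_fasta",
    "make_variant",
    "NUCLEOTIDE_RING_RADIUS_NM",
]

#: radius of the ring on which a NCP's nucleotides are placed (~DNA gyre radius)
NUCLEOTIDE_RING_RADIUS_NM = 5.0

_MAX_STEP_TRIES = 1_000


@dataclass(frozen=True)
class GenParams:
    """Generation parameters.

    Defaults describe a small three-chromosome synthetic genome (30, 20 and
    10 kb) at the default scale spans, walked at a 10 nm step — the order
    of internucleosomal distance — inside per-chromosome territories whose
    radius defaults to half the unconfined random-walk RMS extent (so the
    walk feels the confinement without pathological rejection rates).
    Territory centers sit on the x axis, spaced so territories stay
    disjoint.
    """

    seed: int = 0
    chromosome_lengths: tuple[int, ...] = (30_000, 20_000, 10_000)
    scale_config: ScaleConfig = field(default_factory=ScaleConfig)
    step_nm: float = 10.0
    confinement_radius_nm: float | None = None  # None: auto per chromosome
    territory_spacing_nm: float | None = None  # None: auto from radii

    def __post_init__(self):
        if not self.chromosome_lengths or any(l < 1 for l in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be >= 1 bp")
        if self.step_nm <= 0:
            raise ValueError("step length must be positive")
        if (
            self.confinement_radius_nm is not None
            and self.confinement_radius_nm <= self.step_nm
        ):
            raise ValueError("confinement radius must exceed the step length")

    def n_units(self, chromosome: int, scale: ScaleLevel) -> int:
        """ceil(length / span) unit count for one chromosome."""
        length = self.chromosome_lengths[chromosome - 1]
        if scale is ScaleLevel.CHROMOSOME:
            return 1
        return -(-length // self.scale_config.span_bp(scale))

    def radius_for(self, chromosome: int) -> float:
        if self.confinement_radius_nm is not None:
            return self.confinement_radius_nm
        n = self.n_units(chromosome, ScaleLevel.NUCLEOSOME)
        return self.step_nm * max(2.0, math.sqrt(n) / 2.0)

    def spacing(self) -> float:
        if self.territory_spacing_nm is not None:
            return self.territory_spacing_nm
        rmax = max(self.radius_for(c) for c in range(1, len(self.chromosome_lengths) + 1))
        return 2.2 * rmax


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    norm = np.linalg.norm(v)
    while norm < 1e-12:  # vanishing draws are astronomically rare but cheap to guard
        v = rng.normal(size=3)
        norm = np.linalg.norm(v)
    return v / norm


def _tile_intervals(chromosome: int, length: int, span: int) -> list[GenomicInterval]:
    out = []
    start = 1
    while start <= length:
        out.append(GenomicInterval(chromosome, start, min(start + span - 1, length)))
        start += span
    return out


def generate_structure(params: GenParams) -> GenomeStructure:
    """Generate a structure with the nucleosome scale placed by confined
    random walks and all coarser scales derived by centroid aggregation.

    Deterministic for a fixed seed: one RNG stream drives the whole call.
    Steps leaving the territory sphere are rejected and redrawn, with a
    bounded retry budget.
    """
    rng = np.random.default_rng(params.seed)
    cfg = params.scale_config
    span = cfg.span_bp(ScaleLevel.NUCLEOSOME)
    lengths = {i: l for i, l in enumerate(params.chromosome_lengths, start=1)}
    structure = GenomeStructure(
        name=f"synthetic-{params.seed}",
        scale_config=cfg,
        chromosome_lengths=lengths,
    )
    ncps: list[Unit] = []
    spacing = params.spacing()
    for chrom, length in lengths.items():
        center = np.array([(chrom - 1) * spacing, 0.0, 0.0])
        radius = params.radius_for(chrom)
        pos = center.copy()
        for interval in _tile_intervals(chrom, length, span):
            if interval.start_bp > 1:
                for attempt in range(_MAX_STEP_TRIES):
                    cand = pos + params.step_nm * _random_unit_vector(rng)
                    if np.linalg.norm(cand - center) <= radius:
                        pos = cand
                        break
                else:
                    raise GenerationError(
                        f"confinement radius {radius:.1f} nm too tight for "
                        f"{params.step_nm:.1f} nm steps on chromosome {chrom}"
                    )
            ncps.append(
                Unit(
                    scale=ScaleLevel.NUCLEOSOME,
                    index=1,  # reassigned by set_units
                    lineage=lineage_for_interval(interval, ScaleLevel.NUCLEOSOME, cfg),
                    interval=interval,
                    position=tuple(float(c) for c in pos),
                )
            )
    structure.set_units(ScaleLevel.NUCLEOSOME, ncps)
    build_coarser_scale(structure, ScaleLevel.FIBER)
    build_coarser_scale(structure, ScaleLevel.LOCI)
    build_coarser_scale(structure, ScaleLevel.CHROMOSOME)
    return structure


def generate_nucleotides(
    structure: GenomeStructure,
    ncp_lineage: Lineage,
    seed: int = 0,
    attach: bool = False,
) -> list[Unit]:
    """Nucleotide-scale units for one nucleosome core particle.

    One point per base, evenly spaced on a ring of radius
    ``NUCLEOTIDE_RING_RADIUS_NM`` in a seeded random plane centered on the
    NCP position, so the ring centroid coincides with the NCP by symmetry.
    Intervals are consecutive 1-bp intervals tiling the NCP's interval.
    With ``attach=True`` the units are merged into the structure's
    nucleotide scale (re-indexed to genome order).
    """
    key = ncp_lineage.as_tuple()
    ncp = next(
        (
            u
            for u in structure.units_at(ScaleLevel.NUCLEOSOME)
            if u.lineage.as_tuple() == key
        ),
        None,
    )
    if ncp is None:
        raise GenerationError(f"no nucleosome unit with lineage {ncp_lineage}")
    rng = np.random.default_rng([seed, *key])
    u = _random_unit_vector(rng)
    w = _random_unit_vector(rng)
    w = w - np.dot(w, u) * u
    while np.linalg.norm(w) < 1e-9:  # redraw if nearly parallel
        w = _random_unit_vector(rng)
        w = w - np.dot(w, u) * u
    w /= np.linalg.norm(w)
    n = ncp.interval.length
    center = np.asarray(ncp.position)
    units = []
    for k in range(n):
        theta = 2.0 * math.pi * k / n
        p = center + NUCLEOTIDE_RING_RADIUS_NM * (math.cos(theta) * u + math.sin(theta) * w)
        base = ncp.interval.start_bp + k
        units.append(
            Unit(
                scale=ScaleLevel.NUCLEOTIDE,
                index=k + 1,
                lineage=ncp.lineage,
                interval=GenomicInterval(ncp.interval.chromosome, base, base),
                position=tuple(float(c) for c in p),
            )
        )
    if attach:
        existing = structure.units.get(ScaleLevel.NUCLEOTIDE, [])
        structure.set_units(ScaleLevel.NUCLEOTIDE, existing + units)
    return units


def generate_fasta(params: GenParams) -> str:
    """FASTA text for the synthetic genome: seeded uniform ACGT per
    chromosome, record lengths exactly the chromosome lengths.

    Seeded on a sub-stream of the structure seed so sequence and geometry
    are independent draws from the same parameter set.
    """
    rng = np.random.default_rng([params.seed, 1])
    bases = np.frombuffer(b"ACGT", dtype="S1")
    records = []
    for chrom, length in enumerate(params.chromosome_lengths, start=1):
        seq = bases[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
        wrapped = "\n".join(seq[i : i + 60] for i in range(0, length, 60))
        records.append(f">chr{chrom}\n{wrapped}\n")
    return "".join(records)


def make_variant(
    structure: GenomeStructure, seed: int, chromosome: int, displacement_nm: float
) -> GenomeStructure:
    """Rigidly translate one chromosome (at every populated scale) by
    `displacement_nm` in a seeded random direction.

    Emulates a structural difference between two individuals' genomes: the
    structures are identical except for the location of the displaced
    chromosome.  All hierarchy invariants are preserved (a rigid motion
    commutes with centroid aggregation).
    """
    if chromosome not in structure.chromosome_lengths:
        raise GenerationError(f"unknown chromosome {chromosome}")
    rng = np.random.default_rng([seed, chromosome])
    offset = displacement_nm * _random_unit_vector(rng)
    variant = structure.copy()
    for scale, units in variant.units.items():
        variant.units[scale] = [
            u.moved_by(offset) if u.interval.chromosome == chromosome else u
            for u in units
        ]
    return variant
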