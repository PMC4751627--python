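"""GSS file family and PDB interconversion.

The GSS (Genome Scale System) family has one file kind per hierarchy level,
named by a two-letter tag before the ``.gss`` suffix.  A file named for a
level stores the centroids of the compartments one level finer — the
genome-scale file ``.gs.gss`` holds the central point of every chromosome,
``.cs.gss`` the central points of all loci, ``.ls.gss`` all fibers,
``.fs.gss`` all nucleosome core particles, and ``.ns.gss`` the nucleotides
within NCPs.

The on-disk layout is line-oriented UTF-8 text: ``#``-prefixed header lines
with ``key=value`` metadata (structure name, scale spans, chromosome name
table with lengths), followed by one ``UNIT`` record per point::

    UNIT <index> <chrom> <locus|-> <fiber|-> <nucleosome|-> <start_bp> <end_bp> <x> <y> <z>

Coordinates are nanometers at fixed 3-decimal precision; output is
byte-deterministic for identical input.

PDB conversion writes one pseudo-atom (``CA``) per unit in strict v3.3
fixed columns, one chain per chromosome with ``TER`` separators, with an
optional uniform coordinate rescale recorded in a ``REMARK`` so that
re-import can undo it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .core import (
    GenomeStructure,
    GenomicInterval,
    Lineage,
    ScaleConfig,
    ScaleLevel,
    Unit,
    lineage_for_interval,
)
from .errors import GssFormatError, PdbFormatError, ScaleError

log = logging.getLogger(__name__)

__all__ = [
    "GSS_KINDS",
    "kind_for_scale",
    "scale_for_path",
    "extension_for_scale",
    "GssHeader",
    "read_gss",
    "write_gss",
    "export_pdb",
    "import_pdb",
    "load_structure",
    "save_structure",
    "PDB_MAX_UNITS",
]

# file-kind tag -> scale of the units the file CONTAINS (one finer than the
# scale the tag names: the genome-scale file stores chromosome centroids).
GSS_KINDS: dict[str, ScaleLevel] = {
    "gs": ScaleLevel.CHROMOSOME,
    "cs": ScaleLevel.LOCI,
    "ls": ScaleLevel.FIBER,
    "fs": ScaleLevel.NUCLEOSOME,
    "ns": ScaleLevel.NUCLEOTIDE,
}
_SCALE_TO_KIND = {scale: kind for kind, scale in GSS_KINDS.items()}

#: PDB ATOM serial field is 5 columns wide
PDB_MAX_UNITS = 99_999
_PDB_RESSEQ_WIDTH = 9_999
_PDB_COORD_MAX = 999.999  # symmetric bound fitting %8.3f either sign
_CHAIN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789abcdefghijklmnopqrstuvwxyz"
_REMARK_SCALE_TAG = "REMARK 250 COORDINATES SCALED BY FACTOR"


def scale_for_path(path: str | Path) -> ScaleLevel:
    """Scale of the units a GSS path contains, from its final two
    dot-segments (case-insensitive)."""
    parts = Path(path).name.lower().rsplit(".", 2)
    if len(parts) == 3 and parts[2] == "gss" and parts[1] in GSS_KINDS:
        return GSS_KINDS[parts[1]]
    raise GssFormatError(
        f"{Path(path).name!r} is not a GSS file name "
        f"(expected one of {', '.join('.' + k + '.gss' for k in GSS_KINDS)})"
    )


def kind_for_scale(scale: ScaleLevel) -> str:
    """File-kind tag whose content rule names `scale`."""
    try:
        return _SCALE_TO_KIND[scale]
    except KeyError:
        raise ScaleError(f"no GSS file kind stores {scale} units") from None


def extension_for_scale(scale: ScaleLevel) -> str:
    return f".{kind_for_scale(scale)}.gss"


@dataclass
class GssHeader:
    """Structure-level metadata carried in every GSS file."""

    name: str = "structure"
    scale_config: ScaleConfig = field(default_factory=ScaleConfig)
    chromosome_lengths: dict[int, int] = field(default_factory=dict)
    chromosome_names: dict[int, str] = field(default_factory=dict)

    @classmethod
    def from_structure(cls, structure: GenomeStructure) -> "GssHeader":
        return cls(
            name=structure.name,
            scale_config=structure.scale_config,
            chromosome_lengths=dict(structure.chromosome_lengths),
            chromosome_names=dict(structure.chromosome_names),
        )


def _format_header(header: GssHeader, scale: ScaleLevel) -> list[str]:
    cfg = header.scale_config
    lines = [
        "# gss-version=1",
        f"# name={header.name}",
        f"# scale={scale}",
        f"# span.nucleosome={cfg.nucleosome_bp}",
        f"# span.fiber={cfg.fiber_bp}",
        f"# span.locus={cfg.locus_bp}",
    ]
    for chrom in sorted(header.chromosome_lengths):
        name = header.chromosome_names.get(chrom, f"chr{chrom}")
        lines.append(f"# chromosome={chrom}:{name}:{header.chromosome_lengths[chrom]}")
    return lines


def write_gss(units: list[Unit], header: GssHeader, path: str | Path) -> Path:
    """Write one scale's units to a GSS file.

    The path extension must be the file kind whose content rule names the
    units' scale (nucleosome units go to ``.fs.gss``, etc.).
    """
    path = Path(path)
    if not units:
        raise GssFormatError("refusing to write a GSS file with no units")
    scales = {u.scale for u in units}
    if len(scales) != 1:
        raise ScaleError(f"units span multiple scales: {sorted(map(str, scales))}")
    (scale,) = scales
    file_scale = scale_for_path(path)
    if file_scale is not scale:
        raise ScaleError(
            f"{path.name!r} stores {file_scale} units "
            f"(content is one level finer than the name), got {scale} units"
        )
    lines = _format_header(header, scale)
    for u in sorted(units, key=lambda u: u.index):
        lg = u.lineage
        fields = [
            "UNIT",
            str(u.index),
            str(lg.chromosome),
            str(lg.locus) if lg.locus is not None else "-",
            str(lg.fiber) if lg.fiber is not None else "-",
            str(lg.nucleosome) if lg.nucleosome is not None else "-",
            str(u.interval.start_bp),
            str(u.interval.end_bp),
            f"{u.position[0]:.3f}",
            f"{u.position[1]:.3f}",
            f"{u.position[2]:.3f}",
        ]
        lines.append(" ".join(fields))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    return path


def read_gss(path: str | Path) -> tuple[list[Unit], GssHeader]:
    """Parse a GSS file into its unit list (genome order, index == rank)
    and header metadata.  Malformed records raise with their line number."""
    path = Path(path)
    scale = scale_for_path(path)
    header = GssHeader(name=path.name)
    spans: dict[str, int] = {}
    units: list[Unit] = []
    seen: dict[tuple, int] = {}

    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" not in body:
                continue
            key, _, value = body.partition("=")
            key, value = key.strip(), value.strip()
            try:
                if key == "name":
                    header.name = value
                elif key.startswith("span."):
                    spans[key.removeprefix("span.")] = int(value)
                elif key == "chromosome":
                    num_s, name, length_s = value.split(":")
                    num = int(num_s)
                    header.chromosome_lengths[num] = int(length_s)
                    header.chromosome_names[num] = name
                elif key == "scale" and ScaleLevel.from_name(value) is not scale:
                    raise GssFormatError(
                        f"header scale {value!r} contradicts file kind "
                        f"({path.name!r} stores {scale} units)",
                        lineno,
                    )
            except (ValueError, ScaleError) as exc:
                raise GssFormatError(f"malformed header {line!r}: {exc}", lineno) from None
            continue
        fields = line.split()
        if fields[0] != "UNIT" or len(fields) != 11:
            raise GssFormatError(
                f"expected 'UNIT' record with 10 fields, got {line!r}", lineno
            )
        try:
            index = int(fields[1])
            chrom = int(fields[2])
            opt = [None if f == "-" else int(f) for f in fields[3:6]]
            start, end = int(fields[6]), int(fields[7])
            pos = tuple(float(f) for f in fields[8:11])
        except ValueError as exc:
            raise GssFormatError(f"malformed record field: {exc}", lineno) from None
        try:
            unit = Unit(
                scale=scale,
                index=index,
                lineage=Lineage(chrom, *opt),
                interval=GenomicInterval(chrom, start, end),
                position=pos,
            )
        except (ValueError, ScaleError) as exc:
            raise GssFormatError(str(exc), lineno) from None
        dup_key = (unit.lineage.as_tuple(), unit.interval.start_bp)
        if dup_key in seen:
            raise GssFormatError(
                f"duplicate unit lineage {unit.lineage} "
                f"(first seen on line {seen[dup_key]})",
                lineno,
            )
        seen[dup_key] = lineno
        units.append(unit)

    if not units:
        raise GssFormatError(f"{path.name!r} contains no UNIT records")
    if spans:
        try:
            header.scale_config = ScaleConfig(
                nucleosome_bp=spans.get("nucleosome", 100),
                fiber_bp=spans.get("fiber", 1_000),
                locus_bp=spans.get("locus", 1_000_000),
            )
        except ValueError as exc:
            raise GssFormatError(f"invalid scale spans in header: {exc}") from None
    units.sort(key=lambda u: (u.interval.chromosome, u.interval.start_bp))
    for rank, u in enumerate(units, start=1):
        if u.index != rank:
            raise GssFormatError(
                f"unit {u.lineage} has index {u.index} but genome-order rank {rank}"
            )
    return units, header


def save_structure(structure: GenomeStructure, prefix: str | Path) -> list[Path]:
    """Write every populated scale of `structure` to ``<prefix>.<kind>.gss``."""
    header = GssHeader.from_structure(structure)
    written = []
    for scale in structure.populated_scales():
        path = Path(str(prefix) + extension_for_scale(scale))
        write_gss(structure.units[scale], header, path)
        written.append(path)
    if not written:
        raise ScaleError(f"structure {structure.name!r} has no populated scales")
    return written


def load_structure(prefix: str | Path) -> GenomeStructure:
    """Assemble a structure from every ``<prefix>.<kind>.gss`` present."""
    found = [
        (scale, Path(str(prefix) + extension_for_scale(scale)))
        for scale in GSS_KINDS.values()
        if Path(str(prefix) + extension_for_scale(scale)).exists()
    ]
    if not found:
        raise GssFormatError(f"no GSS files found with prefix {prefix!r}")
    structure: GenomeStructure | None = None
    for scale, path in found:
        units, header = read_gss(path)
        if structure is None:
            structure = GenomeStructure(
                name=header.name,
                scale_config=header.scale_config,
                chromosome_lengths=header.chromosome_lengths,
                chromosome_names=header.chromosome_names,
            )
        structure.set_units(scale, units)
    assert structure is not None
    return structure


# -- PDB -------------------------------------------------------------------


def _chain_id(chrom_rank: int) -> str:
    return _CHAIN_ALPHABET[(chrom_rank - 1) % len(_CHAIN_ALPHABET)]


def export_pdb(units: list[Unit], path: str | Path, *, name: str = "genome model") -> Path:
    """Write units as pseudo-atom ATOM records, one chain per chromosome.

    Coordinates outside the 8.3 fixed-column range are uniformly rescaled
    and the factor recorded in a REMARK so import can invert it.
    """
    path = Path(path)
    if not units:
        raise PdbFormatError("no units to export")
    if len(units) > PDB_MAX_UNITS:
        raise PdbFormatError(
            f"{len(units)} units exceed the PDB serial-field capacity of {PDB_MAX_UNITS}"
        )
    ordered = sorted(units, key=lambda u: (u.interval.chromosome, u.interval.start_bp))
    max_abs = max(abs(c) for u in ordered for c in u.position)
    factor = 1.0
    if max_abs > _PDB_COORD_MAX:
        factor = _PDB_COORD_MAX / max_abs
    lines = [
        "REMARK 250 GENOME STRUCTURE PSEUDO-ATOM MODEL: " + name.upper()[:40],
        f"REMARK 250 SCALE LEVEL {str(ordered[0].scale).upper()}",
    ]
    if factor != 1.0:
        lines.append(f"{_REMARK_SCALE_TAG} {factor:.9e}")
    serial = 0
    chrom_rank = 0
    current_chrom: int | None = None
    within = 0
    last = None
    for u in ordered:
        if u.interval.chromosome != current_chrom:
            if last is not None:
                serial += 1
                lines.append(
                    f"TER   {serial:>5d}      GEN {_chain_id(chrom_rank)}"
                    f"{((within - 1) % _PDB_RESSEQ_WIDTH) + 1:>4d}"
                )
            current_chrom = u.interval.chromosome
            chrom_rank += 1
            within = 0
        serial += 1
        within += 1
        if serial > 99_999:
            raise PdbFormatError("serial numbers exhausted (unit + TER records exceed 99999)")
        x, y, z = (c * factor for c in u.position)
        for c in (x, y, z):
            if not -999.999 <= c <= 9999.999:
                raise PdbFormatError(f"coordinate {c:.3f} overflows PDB columns after rescale")
        resseq = ((within - 1) % _PDB_RESSEQ_WIDTH) + 1
        lines.append(
            f"ATOM  {serial:>5d}  CA  GEN {_chain_id(chrom_rank)}{resseq:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          " + " C"
        )
        last = u
    serial += 1
    lines.append(
        f"TER   {serial:>5d}      GEN {_chain_id(chrom_rank)}"
        f"{((within - 1) % _PDB_RESSEQ_WIDTH) + 1:>4d}"
    )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    return path


def import_pdb(
    path: str | Path,
    scale: ScaleLevel,
    scale_config: ScaleConfig | None = None,
) -> list[Unit]:
    """Read a point-cloud genome model from PDB ATOM/HETATM records.

    Chains map to chromosomes in order of first appearance; the k-th atom of
    a chain becomes unit k of that chromosome with interval
    ``[(k-1)*span+1, k*span]`` at the given scale.  Only MODEL 1 is read.
    A chain that reappears after another chain has begun is an error.
    """
    path = Path(path)
    cfg = scale_config or ScaleConfig()
    span = cfg.span_bp(scale)
    factor = 1.0
    chain_order: list[str] = []
    closed: set[str] = set()
    per_chain: dict[str, list[tuple[float, float, float]]] = {}
    model_no = 0
    for raw in path.read_text(encoding="utf-8").splitlines():
        rec = raw[:6].strip()
        if rec == "MODEL":
            model_no += 1
            if model_no > 1:
                log.warning("%s: multiple MODELs; only MODEL 1 imported", path.name)
                break
        elif raw.startswith(_REMARK_SCALE_TAG):
            factor = float(raw[len(_REMARK_SCALE_TAG):].strip())
        elif rec in ("ATOM", "HETATM"):
            chain = raw[21].strip() or "A"
            if chain in closed:
                raise PdbFormatError(
                    f"chain {chain!r} is non-contiguous (reappears after another chain)"
                )
            if not chain_order or chain_order[-1] != chain:
                if chain_order:
                    closed.add(chain_order[-1])
                chain_order.append(chain)
            try:
                xyz = (float(raw[30:38]), float(raw[38:46]), float(raw[46:54]))
            except ValueError as exc:
                raise PdbFormatError(f"malformed coordinates in {raw!r}: {exc}") from None
            per_chain.setdefault(chain, []).append(xyz)
    if not per_chain:
        raise PdbFormatError(f"{path.name!r} contains no ATOM records")
    units: list[Unit] = []
    index = 0
    for chrom, chain in enumerate(chain_order, start=1):
        for k, (x, y, z) in enumerate(per_chain[chain], start=1):
            index += 1
            interval = GenomicInterval(chrom, (k - 1) * span + 1, k * span)
            units.append(
                Unit(
                    scale=scale,
                    index=index,
                    lineage=lineage_for_interval(interval, scale, cfg),
                    interval=interval,
                    position=(x / factor, y / factor, z / factor),
                )
            )
    return units
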