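"""Sequence retrieval for selections, backed by a local FASTA database.

A selection's units carry 1-based inclusive genomic intervals; retrieval
slices the corresponding subsequence out of a per-chromosome sequence
store.  The local backend reads a FASTA file (one record per chromosome,
record names resolved through the structure's chromosome name table).  A
remote Ensembl backend is declared with the same contract but is not
configured in this package and raises on use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import Unit
from .selection import Selection
from .errors import NotConfiguredError, SequenceDbError

log = logging.getLogger(__name__)

__all__ = ["LocalSequenceDB", "RemoteEnsemblDB", "fetch_sequence", "write_fasta"]

_PLAIN_BASES = frozenset("ACGTN")


@dataclass
class LocalSequenceDB:
    """Chromosome-number → sequence mapping loaded from FASTA."""

    sequences: dict[int, str]

    @classmethod
    def from_fasta(
        cls, path: str | Path, name_table: dict[int, str] | None = None
    ) -> "LocalSequenceDB":
        """Load one record per chromosome.

        Record ids are matched against the structure's chromosome name
        table when given; otherwise ids of the form ``chrN`` or ``N`` are
        mapped to chromosome number N.
        """
        by_name = {v: k for k, v in (name_table or {}).items()}
        sequences: dict[int, str] = {}
        for record in SeqIO.parse(str(path), "fasta"):
            rid = record.id
            if rid in by_name:
                num = by_name[rid]
            else:
                try:
                    num = int(rid.removeprefix("chr"))
                except ValueError:
                    raise SequenceDbError(
                        f"cannot map FASTA record {rid!r} to a chromosome number "
                        f"(not in the name table and not of the form 'chrN')"
                    ) from None
            if num in sequences:
                raise SequenceDbError(f"duplicate FASTA record for chromosome {num}")
            seq = str(record.seq).upper()
            if not _PLAIN_BASES.issuperset(seq):
                odd = sorted(set(seq) - _PLAIN_BASES)
                log.warning(
                    "chromosome %d contains non-ACGTN characters %s; passed through",
                    num,
                    "".join(odd),
                )
            sequences[num] = seq
        if not sequences:
            raise SequenceDbError(f"no FASTA records in {path!r}")
        return cls(sequences)

    @property
    def lengths(self) -> dict[int, int]:
        return {num: len(seq) for num, seq in self.sequences.items()}

    def fetch(self, chromosome: int, start_bp: int, end_bp: int) -> str:
        """Subsequence at a 1-based inclusive interval."""
        if chromosome not in self.sequences:
            raise SequenceDbError(f"chromosome {chromosome} not in the sequence database")
        seq = self.sequences[chromosome]
        if start_bp < 1 or end_bp > len(seq):
            raise SequenceDbError(
                f"interval [{start_bp}, {end_bp}] outside chromosome {chromosome} "
                f"(length {len(seq)} bp)"
            )
        return seq[start_bp - 1 : end_bp]


class RemoteEnsemblDB:
    """Declared remote backend with the local contract; not configured."""

    def fetch(self, chromosome: int, start_bp: int, end_bp: int) -> str:
        raise NotConfiguredError(
            "remote Ensembl backend is not configured; use a local FASTA database"
        )


def fetch_sequence(
    selection: Selection, db: LocalSequenceDB
) -> list[tuple[Unit, str]]:
    """Retrieve each selected unit's genomic subsequence, in selection order.

    Raises naming the unit when its interval exceeds the database
    chromosome length (structure and database disagree)."""
    results = []
    for unit in selection.units:
        iv = unit.interval
        try:
            seq = db.fetch(iv.chromosome, iv.start_bp, iv.end_bp)
        except SequenceDbError as exc:
            raise SequenceDbError(f"unit {unit.label()}: {exc}") from None
        results.append((unit, seq))
    return results


def write_fasta(
    results: list[tuple[Unit, str]], path: str | Path, name: str = "structure"
) -> Path:
    """Write retrieved sequences as FASTA, one record per unit.

    Headers are ``name|scale|chrN:start-end``; lines wrap at 60 columns.
    """
    if not results:
        raise SequenceDbError("no retrieved sequences to write")
    records = [
        SeqRecord(Seq(seq), id=f"{name}|{unit.scale}|{unit.interval}", description="")
        for unit, seq in results
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        SeqIO.write(records, fh, "fasta")
    return Path(path)
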