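"""Shared fixtures: small seeded structures and a matching FASTA genome."""

import pytest

from genoscale import (
    GenParams,
    GenomicInterval,
    Lineage,
    ScaleLevel,
    Unit,
    generate_fasta,
    generate_structure,
)


@pytest.fixture(scope="session")
def small_params():
    return GenParams(seed=7, chromosome_lengths=(5_000, 8_000))


@pytest.fixture(scope="session")
def small_structure(small_params):
    return generate_structure(small_params)


@pytest.fixture()
def structure(small_structure):
    """A per-test mutable copy of the session structure."""
    return small_structure.copy()


@pytest.fixture(scope="session")
def fasta_path(small_params, tmp_path_factory):
    path = tmp_path_factory.mktemp("genome") / "genome.fa"
    path.write_text(generate_fasta(small_params), encoding="utf-8")
    return path


def make_unit(scale, index, chrom, start, end, pos, lineage=None):
    """Terse unit factory for hand-built fixtures."""
    interval = GenomicInterval(chrom, start, end)
    if lineage is None:
        if scale is ScaleLevel.CHROMOSOME:
            lineage = Lineage(chrom)
        else:
            raise ValueError("give a lineage for sub-chromosome units")
    return Unit(scale=scale, index=index, lineage=lineage, interval=interval, position=pos)


@pytest.fixture()
def chromosome_pair_units():
    """Two chromosome-scale units at (0,0,0) and (3,4,0) — a 3-4-5 fixture."""
    return [
        make_unit(ScaleLevel.CHROMOSOME, 1, 1, 1, 5_000, (0.0, 0.0, 0.0)),
        make_unit(ScaleLevel.CHROMOSOME, 2, 2, 1, 8_000, (3.0, 4.0, 0.0)),
    ]
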