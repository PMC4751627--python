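"""GSS file family and PDB interconversion."""

import dataclasses

import pytest
from Bio.PDB import PDBParser

from genoscale import (
    GenomicInterval,
    GssHeader,
    Lineage,
    ScaleLevel,
    Unit,
    export_pdb,
    import_pdb,
    load_structure,
    read_gss,
    save_structure,
    write_gss,
)
from genoscale.errors import GssFormatError, PdbFormatError, ScaleError
from genoscale.gss import GSS_KINDS, extension_for_scale, scale_for_path


def quantized(units):
    """Units with positions at the 3-decimal precision GSS files carry."""
    return [
        dataclasses.replace(u, position=tuple(float(f"{c:.3f}") for c in u.position))
        for u in units
    ]


class TestFileKinds:
    @pytest.mark.parametrize(
        "name,scale",
        [
            ("x.gs.gss", ScaleLevel.CHROMOSOME),
            ("x.CS.GSS", ScaleLevel.LOCI),
            ("deep/dir/y.ls.gss", ScaleLevel.FIBER),
            ("x.fs.gss", ScaleLevel.NUCLEOSOME),
            ("x.ns.gss", ScaleLevel.NUCLEOTIDE),
        ],
    )
    def test_content_rule_one_scale_finer_than_the_name(self, name, scale):
        assert scale_for_path(name) is scale

    def test_kind_scale_bijection(self):
        assert len(set(GSS_KINDS.values())) == len(GSS_KINDS) == 5

    @pytest.mark.parametrize("name", ["x.gss", "x.pdb", "x.xs.gss", "gs.gss.txt"])
    def test_unknown_extensions_rejected(self, name):
        with pytest.raises(GssFormatError):
            scale_for_path(name)


class TestGssRoundTrip:
    @pytest.mark.parametrize(
        "scale", [ScaleLevel.CHROMOSOME, ScaleLevel.LOCI, ScaleLevel.FIBER, ScaleLevel.NUCLEOSOME]
    )
    def test_read_of_write_is_identity(self, structure, tmp_path, scale):
        units = quantized(structure.units_at(scale))
        header = GssHeader.from_structure(structure)
        path = tmp_path / f"t{extension_for_scale(scale)}"
        write_gss(units, header, path)
        back, back_header = read_gss(path)
        assert back == units
        assert back_header.chromosome_lengths == structure.chromosome_lengths
        assert back_header.scale_config == structure.scale_config
        assert back_header.name == structure.name

    def test_writes_are_deterministic_bytes(self, structure, tmp_path):
        units = structure.units_at(ScaleLevel.FIBER)
        header = GssHeader.from_structure(structure)
        a, b = tmp_path / "a.ls.gss", tmp_path / "b.ls.gss"
        write_gss(units, header, a)
        write_gss(units, header, b)
        assert a.read_bytes() == b.read_bytes()

    def test_write_read_write_idempotent(self, structure, tmp_path):
        header = GssHeader.from_structure(structure)
        p1 = tmp_path / "a.fs.gss"
        write_gss(structure.units_at(ScaleLevel.NUCLEOSOME), header, p1)
        units, header2 = read_gss(p1)
        p2 = tmp_path / "b.fs.gss"
        write_gss(units, header2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_fiber_fixture_interval_enumeration(self, tmp_path):
        """2 chromosomes of 5,000 bp tile into 10 fiber units 1-1000 ... 4001-5000."""
        from genoscale import GenParams, generate_structure

        s = generate_structure(GenParams(seed=3, chromosome_lengths=(5_000, 5_000)))
        path = tmp_path / "f.ls.gss"
        write_gss(s.units_at(ScaleLevel.FIBER), GssHeader.from_structure(s), path)
        units, _ = read_gss(path)
        assert len(units) == 10
        spans = [(u.interval.chromosome, u.interval.start_bp, u.interval.end_bp) for u in units]
        assert spans == [
            (c, k * 1_000 + 1, (k + 1) * 1_000) for c in (1, 2) for k in range(5)
        ]


class TestGssErrors:
    def test_non_numeric_coordinate_names_line(self, structure, tmp_path):
        path = tmp_path / "bad.ls.gss"
        write_gss(structure.units_at(ScaleLevel.FIBER), GssHeader.from_structure(structure), path)
        lines = path.read_text().splitlines()
        first_unit = next(i for i, l in enumerate(lines) if l.startswith("UNIT"))
        fields = lines[first_unit].split()
        fields[8] = "not-a-number"
        lines[first_unit] = " ".join(fields)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(GssFormatError, match=rf"line {first_unit + 1}"):
            read_gss(path)

    def test_duplicate_lineage_rejected(self, tmp_path):
        path = tmp_path / "dup.gs.gss"
        path.write_text(
            "# name=d\n# chromosome=1:chr1:100\n"
            "UNIT 1 1 - - - 1 100 0.0 0.0 0.0\n"
            "UNIT 2 1 - - - 1 100 1.0 0.0 0.0\n"
        )
        with pytest.raises(GssFormatError, match="duplicate"):
            read_gss(path)

    def test_scale_extension_mismatch(self, structure, tmp_path):
        header = GssHeader.from_structure(structure)
        with pytest.raises(ScaleError, match="ns.gss"):
            write_gss(structure.units_at(ScaleLevel.FIBER), header, tmp_path / "x.ns.gss")

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "e.gs.gss"
        path.write_text("# name=e\n")
        with pytest.raises(GssFormatError, match="no UNIT"):
            read_gss(path)


class TestStructurePrefix:
    def test_save_load_round_trip_preserves_hierarchy(self, structure, tmp_path):
        from genoscale import validate_hierarchy

        save_structure(structure, tmp_path / "s")
        back = load_structure(tmp_path / "s")
        assert back.populated_scales() == structure.populated_scales()
        # quantized coordinates: validate at the file precision
        assert validate_hierarchy(back, centroid_tol_nm=2e-3) == []

    def test_missing_prefix_rejected(self, tmp_path):
        with pytest.raises(GssFormatError, match="no GSS files"):
            load_structure(tmp_path / "nothing")


def _grid_units(n_chrom, per_chrom, scale=ScaleLevel.NUCLEOSOME):
    units, idx = [], 0
    for c in range(1, n_chrom + 1):
        for k in range(per_chrom):
            idx += 1
            iv = GenomicInterval(c, k * 100 + 1, (k + 1) * 100)
            units.append(
                Unit(
                    scale=scale,
                    index=idx,
                    lineage=Lineage(c, 1, 1, k + 1),
                    interval=iv,
                    position=(float(c), float(k), 0.25),
                )
            )
    return units


class TestPdb:
    def test_atom_and_ter_record_counts(self, tmp_path):
        path = tmp_path / "m.pdb"
        export_pdb(_grid_units(2, 3), path)
        lines = path.read_text().splitlines()
        assert sum(l.startswith("ATOM") for l in lines) == 6
        assert sum(l.startswith("TER") for l in lines) == 2

    def test_round_trip_recovers_positions(self, structure, tmp_path):
        units = structure.units_at(ScaleLevel.NUCLEOSOME)
        path = tmp_path / "s.pdb"
        export_pdb(units, path)
        back = import_pdb(path, ScaleLevel.NUCLEOSOME, structure.scale_config)
        assert len(back) == len(units)
        for u, b in zip(units, back):
            assert b.position == pytest.approx(u.position, abs=1e-3)
            assert b.interval == u.interval
            assert b.lineage == u.lineage

    def test_rescale_remark_round_trip(self, tmp_path):
        units = [
            dataclasses.replace(u, position=(u.position[0] * 5_000, u.position[1], u.position[2]))
            for u in _grid_units(1, 4)
        ]
        path = tmp_path / "big.pdb"
        export_pdb(units, path)
        assert "SCALED BY FACTOR" in path.read_text()
        back = import_pdb(path, ScaleLevel.NUCLEOSOME)
        for u, b in zip(units, back):
            # written at 3 decimals in rescaled space; compare relatively
            assert b.position == pytest.approx(u.position, abs=1e-3 * 5_000 / 999.0)

    def test_unit_cap_enforced(self, tmp_path):
        units = _grid_units(1, 1)
        too_many = units * 100_000  # same object repeated; only the count matters
        with pytest.raises(PdbFormatError, match="99999"):
            export_pdb(too_many, tmp_path / "x.pdb")

    def test_biopython_reads_export(self, structure, tmp_path):
        """Independent parser oracle: Bio.PDB sees the same chains/coords."""
        units = structure.units_at(ScaleLevel.FIBER)
        path = tmp_path / "o.pdb"
        export_pdb(units, path)
        model = PDBParser(QUIET=True).get_structure("o", str(path))[0]
        chains = list(model)
        assert len(chains) == len(structure.chromosome_lengths)
        atoms = [a for c in chains for a in c.get_atoms()]
        assert len(atoms) == len(units)
        for atom, u in zip(atoms, units):
            assert tuple(atom.coord) == pytest.approx(u.position, abs=1e-3)
            assert atom.get_name() == "CA"

    def test_hand_written_pdb_imports_with_derived_intervals(self, tmp_path):
        text = (
            "ATOM      1  CA  GEN A   1       1.000   2.000   3.000  1.00  0.00           C\n"
            "ATOM      2  CA  GEN A   2       4.000   5.000   6.000  1.00  0.00           C\n"
            "ATOM      3  CA  GEN B   1       7.000   8.000   9.000  1.00  0.00           C\n"
            "ATOM      4  CA  GEN B   2      10.000  11.000  12.000  1.00  0.00           C\n"
            "END\n"
        )
        path = tmp_path / "h.pdb"
        path.write_text(text)
        units = import_pdb(path, ScaleLevel.NUCLEOSOME)
        assert [u.interval.chromosome for u in units] == [1, 1, 2, 2]
        assert [(u.interval.start_bp, u.interval.end_bp) for u in units] == [
            (1, 100), (101, 200), (1, 100), (101, 200),
        ]
        assert units[3].position == (10.0, 11.0, 12.0)

    def test_non_contiguous_chain_rejected(self, tmp_path):
        text = (
            "ATOM      1  CA  GEN A   1       1.000   2.000   3.000  1.00  0.00           C\n"
            "ATOM      2  CA  GEN B   1       4.000   5.000   6.000  1.00  0.00           C\n"
            "ATOM      3  CA  GEN A   2       7.000   8.000   9.000  1.00  0.00           C\n"
        )
        path = tmp_path / "bad.pdb"
        path.write_text(text)
        with pytest.raises(PdbFormatError, match="non-contiguous"):
            import_pdb(path, ScaleLevel.NUCLEOSOME)

    def test_no_atoms_rejected(self, tmp_path):
        path = tmp_path / "none.pdb"
        path.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(PdbFormatError, match="no ATOM"):
            import_pdb(path, ScaleLevel.NUCLEOSOME)

    def test_only_first_model_read(self, tmp_path, caplog):
        text = (
            "MODEL        1\n"
            "ATOM      1  CA  GEN A   1       1.000   2.000   3.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      2  CA  GEN A   2       9.000   9.000   9.000  1.00  0.00           C\n"
            "ENDMDL\n"
        )
        path = tmp_path / "two.pdb"
        path.write_text(text)
        with caplog.at_level("WARNING"):
            units = import_pdb(path, ScaleLevel.NUCLEOSOME)
        assert len(units) == 1
        assert "MODEL 1" in caplog.text
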