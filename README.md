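# genoscale

A toolkit for working with multi-scale 3D genome structure models — the
point-cloud models of whole genomes that are reconstructed from
chromosome-conformation-capture (Hi-C) data by separate modelling tools.
Protein-structure viewers and the PDB format do not scale to a genome:
a structure with one point per nucleosome of a mammalian genome has
tens of millions of points and needs a resolution hierarchy, not a flat
atom list.  genoscale gives researchers who analyze such models a library
and command-line tool for storing, navigating, measuring and annotating
them across resolutions.

The core is a six-level scale hierarchy, coarsest to finest:

```
genome  >  chromosome  >  loci (Mb)  >  fiber (kb)  >  nucleosome (100 bp)  >  nucleotide (1 bp)
```

A *unit* at a level is one 3D point (nanometers) standing for a contiguous
genomic interval of that level's span; a coarser unit's position is the
centroid of its children and its interval is tiled exactly by theirs.  On
top of this model the package provides:

- **GSS files** — one file kind per level (`.gs.gss`, `.cs.gss`,
  `.ls.gss`, `.fs.gss`, `.ns.gss`), each storing the central points of the
  compartments one level finer than its name, as deterministic plain text;
- **PDB interconversion** — strict fixed-column pseudo-atom export (with
  automatic uniform rescale recorded in a REMARK) and import of
  Hi-C-derived point-cloud models in PDB form;
- **selection** — by unit index, by lineage (chromosome/locus/fiber/NCP),
  or by genome sequence location (overlap semantics), with scale-up /
  scale-down navigation of the selection;
- **measurement** — Euclidean distances (nm) and three-unit angles
  (degrees) between selected units;
- **sequence retrieval** — FASTA-backed local database lookup of the
  sequence under each selected unit;
- **a seeded synthetic generator** — hierarchy-consistent structures
  (confined random walks within per-chromosome territories) plus a
  matching FASTA genome, so every feature is usable and testable offline;
- **static image export** — deterministic orthographic projections (PNG/SVG)
  in place of an interactive viewer.

## Worked example: comparing two individuals

Generate a three-chromosome synthetic structure (30, 20 and 10 kb) for
"person A", then create "person B" by rigidly displacing chromosome 1 by
40 nm — the kind of structural difference one looks for when comparing
genome models of two individuals:

```sh
$ genoscale generate --seed 11 --chroms 30000,20000,10000 --out person_a
$ genoscale variant person_a --chrom 1 --displacement 40 --seed 12 --out person_b

$ genoscale info person_a.gs.gss
name:	synthetic-11
scale:	chromosome
units:	3
chromosomes:	1:chr1:30000, 2:chr2:20000, 3:chr3:10000
bounding_box_nm:	x[37.628, 379.263] y[-13.611, 8.435] z[-28.628, 26.522]
```

The genome-scale file holds one central point per chromosome.  Measuring
the chromosome-1–to–chromosome-2 distance in both individuals shows the
displacement:

```sh
$ genoscale measure --distance --index 1,2 person_a.gs.gss
distance	chromosome[1](chr1);chromosome[2](chr2)	147.798	nm
$ genoscale measure --distance --index 1,2 person_b.gs.gss
distance	chromosome[1](chr1);chromosome[2](chr2)	139.679	nm
```

The two values differ because chromosome 1 moved; every unit of
chromosomes 2 and 3 is byte-identical between the two file sets.  Next,
select the nucleosome-scale units under a sequence region.  The query
`chr1:950-1050` straddles a 100-bp unit boundary, so it returns the two
overlapping nucleosome core particles:

```sh
$ genoscale select person_a.fs.gss --range chr1:950-1050
index	chrom	locus	fiber	nucleosome	start_bp	end_bp	x_nm	y_nm	z_nm
10	1	1	1	10	901	1000	-13.674	20.974	-13.224
11	1	1	2	1	1001	1100	-19.917	13.165	-13.032
```

Finally retrieve the sequence under the first nucleosome unit from the
matching FASTA genome:

```sh
$ genoscale extract-seq person_a.fs.gss --index 1 --db person_a.fa --out seq.fa
$ head -2 seq.fa
>synthetic-11|nucleosome|chr1:1-100
CAATTTCGTTTTCCTTTTACCTGTATCATAATGCGGTCGCCATGAGTGCTTGGACACTTA
```

All of the above can be placed in a plain text script (one command per
line, `#` comments) and replayed with `genoscale script walkthrough.gsc`.
The same operations are available as a library:

```python
from genoscale import (GenParams, ScaleLevel, generate_structure,
                       select_by_index, scale_down, measure_selection)

structure = generate_structure(GenParams(seed=11, chromosome_lengths=(30000, 20000, 10000)))
chrom1 = select_by_index(structure, ScaleLevel.GENOME, [1])   # genome view: index = chromosome
fibers = scale_down(scale_down(chrom1))                       # chromosome -> loci -> fiber
print(len(fibers))                                            # 30 (30 kb / 1 kb)
```

See `docs/methods.md` for the model, file formats, semantics and the
generator's assumptions.

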