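# Methods

## The multi-scale model

genoscale represents a 3D genome structure as point clouds at up to five
unit-bearing resolution levels of a six-level hierarchy:

| level       | unit span (default)     | what one point stands for            |
|-------------|-------------------------|--------------------------------------|
| genome      | — (root view)           | the whole genome; its view is the chromosome points |
| chromosome  | whole chromosome        | the central point of one chromosome  |
| loci        | 1 Mb (`locus_bp`)       | a megabase-order locus               |
| fiber       | 1 kb (`fiber_bp`)       | a kilobase chromatin-fiber segment   |
| nucleosome  | 100 bp (`nucleosome_bp`)| one nucleosome core particle (NCP)   |
| nucleotide  | 1 bp (fixed)            | a single base                        |

A unit is a 3D position in nanometers plus a 1-based inclusive genomic
interval and a lineage address (chromosome, locus, fiber, nucleosome
indices, each 1-based within its parent).  Two invariants tie the levels
together:

1. **Tiling** — a parent's children cover its interval exactly, with no
   gaps or overlaps.  The last unit of a chromosome may be shorter than the
   nominal span (the truncated remainder).
2. **Centroid** — a parent's position is the unweighted arithmetic mean of
   its children's positions, within 1e-6 nm in memory.

"Central point" is implemented as the unweighted mean: the data carry no
masses or weights that would justify anything else.  Fixed spans must
divide each other (nucleosome | fiber | locus) so the tiling invariant is
achievable; the 1 kb and 1 Mb defaults are representative choices within
the kilobase/megabase bands conventional for fiber- and locus-level
descriptions, and both are overridable per structure.

The genome level is the root of the hierarchy and carries no units of its
own: its "display" is the set of chromosome points, so selection at the
genome view indexes chromosomes by number, and scaling up from chromosome
units reports "no coarser scale".  A single whole-genome pseudo-unit was
considered and rejected: it would need a genomic interval spanning
chromosomes, which the interval model (one chromosome per interval)
deliberately rules out.

## GSS files

One file kind per level, each storing the centroids of the compartments one
level finer than its name: `.gs.gss` holds the chromosome points,
`.cs.gss` the loci, `.ls.gss` the fibers, `.fs.gss` the NCPs, and
`.ns.gss` nucleotide points within NCPs.  The record layout is
line-oriented text: `#` header lines (`key=value`: structure name, spans,
chromosome name table with lengths) followed by

```
UNIT <index> <chrom> <locus|-> <fiber|-> <nucleosome|-> <start_bp> <end_bp> <x> <y> <z>
```

Coordinates are nanometers at 3 decimals; output is byte-deterministic.
The 3-decimal quantization means a structure reloaded from disk satisfies
the centroid invariant only to ~1e-3 nm, so `validate_hierarchy` takes a
`centroid_tol_nm` argument (default 1e-6 for in-memory structures; use
~2e-3 for file round trips).  Non-numeric chromosome names (X, Y, MT) are
supported through the persisted name table; internally chromosomes are
positive integers.

Nucleotide units are stored in a single `.ns.gss` per structure with full
NCP lineage distinguishing the particles, and are generated lazily per NCP
(one hundred 1-bp points per full NCP).  Because of this laziness, the
validator skips nucleosome units with zero nucleotide children; any NCP
that has children is checked fully.  Sparse models at coarser levels are
rejected (gaps are findings); supporting them is future work.

## PDB interconversion

Export writes strict fixed-column v3.3 `ATOM` records — pseudo-atom `CA`,
residue `GEN`, one chain per chromosome (IDs cycling A–Z, 0–9, a–z),
residue numbers wrapping at 9999, `TER` between chromosomes — with a hard
cap of 99,999 units (the serial field width; hybrid-36 extensions are not
used).  Coordinates that would overflow the `%8.3f` columns are uniformly
rescaled and the factor recorded in a `REMARK 250` line; import reads the
remark and inverts the scaling, so export→import recovers positions to the
3-decimal precision of the written file (1e-3 nm unscaled).  Import maps
chains to chromosomes in order of first appearance, derives intervals from
the atom rank and the stated scale's span, reads only `MODEL 1` (warning
on more), and rejects non-contiguous chains.

## Selection semantics

Three routes: by unit index, by lineage ("scale information"), and by
genome sequence location.  Sequence selection uses **overlap** semantics —
any unit sharing at least one base with the query is selected, so a query
straddling a unit boundary returns both units.  Containment semantics were
the alternative; overlap was chosen because a user asking for the units
"corresponding to" a region expects partial coverage to count.  Lineage
selection requires a prefix (chromosome before locus before fiber before
nucleosome) and a target scale at least as fine as the deepest given
field.  Selections are immutable values carrying (structure, scale,
indices); union/intersection are provided as plumbing.  `scale_down` maps
a selection to all children, `scale_up` to the de-duplicated parents; for
any parent-closed selection the two compose to the identity.

## Measurement

Distances are Euclidean in nm; angles are taken at a vertex between two
arms and reported in degrees within [0°, 180°].  For a three-unit
selection the **middle unit in index order is the vertex**, matching the
common molecular-viewer convention.  The arccosine argument is clamped to
[-1, 1] so floating-point excursions on near-collinear triples cannot
produce NaN; a zero-length arm is reported as a degenerate-unit error
rather than silently returning 0°.  Values are carried at full precision
and printed at 3 decimals.

## Sequence retrieval

The local database is a FASTA file, one record per chromosome, resolved
through the structure's name table (falling back to `chrN`/`N` ids).
Retrieval slices the 1-based inclusive unit interval; sequences are
uppercased, and non-ACGTN characters pass through with a warning.  The
remote Ensembl backend is declared with the same `fetch` contract but is
not configured and raises, keeping the two-backend shape without any
network dependence.  Output FASTA wraps at 60 columns with
`name|scale|chrN:start-end` headers.

## Synthetic generator

`generate_structure` places one point per NCP by a confined random walk:
per chromosome, a territory sphere (centers on the x axis) whose radius
defaults to `step * max(2, sqrt(n)/2)` — half the unconfined random-walk
RMS extent, so the walk is genuinely confined but step rejection stays
cheap — with steps of fixed 10 nm length (the order of internucleosomal
spacing) in uniformly random directions, rejecting and redrawing steps
that leave the sphere (bounded retries, then an error).  Coarser scales
are then built by centroid aggregation, which makes the centroid invariant
hold by construction rather than by adjustment.  All randomness flows from
one `numpy` Generator seeded explicitly; equal seeds give byte-identical
GSS output.

What the generator does **not** emulate: fractal-globule contact
statistics, loop/TAD structure, chromosome arm geometry, sequence
composition biases (the FASTA genome is uniform ACGT), or inter-cell
variability.  Passing tests therefore demonstrate the correctness of the
*machinery* — formats, hierarchy arithmetic, selection, measurement,
retrieval — on structures with fully known ground truth, not biological
realism of any particular model.

Nucleotide placement is deliberately schematic: each NCP's bases sit
evenly on a 5 nm ring (the order of the DNA gyre radius around the histone
octamer) in a seeded random plane, so the ring centroid coincides with the
NCP position exactly.  `make_variant` translates one chromosome rigidly at
every populated scale by a seeded random direction times the requested
displacement; rigid motion commutes with averaging, so the hierarchy stays
valid and the displacement is recoverable at the genome view to numerical
precision.

## Command-line interface

`genoscale` exposes generate / convert / info / select / measure /
extract-seq / render / script (plus `variant` for the displacement demo).
`script` replays a plain text file of such command lines sequentially and
fail-fast — command scripting is deliberately *not* a new language.
Rendering is a minimal static export standing in for interactive viewing:
orthographic projection onto a chosen coordinate plane, genome-order
polylines and one color per chromosome, PNG or SVG; SVG output is
byte-deterministic (fixed hash salt, no timestamp, text kept as text).

## Problem sizes and numerical choices

The consistency suites run on seeded structures of 2–4 chromosomes at
5–50 kb (20 structures), 100 smaller fixtures for round trips, 1,000
random queries against the brute-force overlap oracle, and 1,000 random
rigid motions for measurement invariance — sizes chosen so the whole suite
exercises every code path in seconds while keeping per-chromosome unit
counts (50–500 NCPs) large enough for grouping edge cases (terminal
truncated units, multi-locus chromosomes) to occur.  Tolerances: 1e-6 nm
for in-memory centroid consistency, 1e-3 nm for coordinate round trips
through 3-decimal files, 1e-9 nm for rigid-motion displacement recovery.
Ties and degenerate inputs: empty centroid input is an error (not a zero
vector); empty selections propagate as empty; equal-position units give
distance 0 and are rejected as angle vertices.

## Known limitations

- No sparse hierarchies above the nucleotide level.
- PDB capacity is hard-capped at 99,999 units; chromosome-scale imports
  need a stated fixed span, so PDB import targets loci/fiber/nucleosome
  scales in practice.
- No mmCIF, no compressed GSS, no streaming parser; files are read whole.
- The remote Ensembl backend is an interface stub only.
- Byte compatibility with any other GSS-writing tool is not claimed.
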