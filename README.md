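# bacscreen

Tools for designing, budgeting, decoding and simulating **two-dimensional
pooled screens of BAC libraries** read out by multiplex-tandem PCR with
high-resolution melt (MT-PCR-HRM) analysis.

## The problem

Integrating genetic and physical maps requires *anchoring* sequence-tagged
site (STS) markers to the large-insert clones that carry them. A BAC
library for a genome of size *G* at coverage *c* with mean insert *L* holds
`n = c·G/L` clones — 480,000 clones for a 16 Gbp genome at 3× with 100 kb
inserts — stored in 384-well plates (16 rows A–P × 24 columns 1–24).
Testing clones individually is hopeless; *group testing* on structured
pools is the standard answer. Because MT-PCR pre-amplification plus HRM
readout detects a single-copy target diluted into the freezer stocks of 25
whole plates, a two-dimensional pooling scheme suffices:

1. **Superpools** — up to 25 plates each; `N/25` reactions find the
   positive superpool of an *N*-plate library.
2. **Matrix pools** — the 25 plates on a 5×5 grid, pooled by grid row
   (H1–H5) and grid column (V1–V5); 10 reactions, and the single positive
   H/V pair intersects at the positive plate.
3. **Single-plate pools** — 8 overlapping row pools (4 rows each; every
   row in exactly 2 pools, all 16 pool-pairs distinct) and 10 column pools
   (6 of 4 columns, 4 of 6; every column in exactly 2 pools, all 24 pairs
   distinct). 18 reactions; the two positive row pools and two positive
   column pools identify the well.

So one marker costs `N/25 + 10 + 18 = N/25 + 28` reactions, against
`N/10 + 50` for the conventional-PCR 3-D comparator — and because HRM
distinguishes amplicons by melting temperature, up to 3 markers share each
reaction (triplexing divides the total by 3, rounded up).

The package implements the pool constructors with validity checking, the
pattern decoder (including honest ambiguity semantics when more pools light
up than one target explains — overlap-pair designs are not 2-disjunct), the
reaction/cost calculus, a Monte-Carlo simulator of the full gated screen
under a pool-level false-positive/false-negative error model, synthetic
melt-curve generation and −dF/dT peak calling on the 65–90 °C / 0.3 °C
ramp, and primer QC against standard design heuristics.

## Worked example

Reaction budget for a wheat-scale library (16 Gbp → 480,000 clones → 1250
plates → 50 superpools), 3 markers:

```
$ bacscreen count --plates 1250 --markers 3
n_plates  n_superpools  superpool_stage  matrix_stage  single_stage  total_simplex  total_triplex  per_marker_2d  per_marker_conventional_3d
1250      50            50               30            54            134            45             78.0           175.0
```

134 simplex reactions (50 superpool + 3×10 matrix + 3×18 single-plate)
anchor all three markers; triplexed, 45 reactions — versus 175 conventional
PCRs *per marker* under the 3-D scheme.

Simulate a full screen of a 24-plate (single-superpool) library with a 5 %
false-negative call rate:

```
$ cat sim.yaml
genome_size: 307200000
coverage: 3.0
insert_mean: 100000
n_markers: 1
beta: 0.05
seed: 4
$ bacscreen simulate --config sim.yaml --outdir out/
sensitivity 1.000, 64 reactions; outputs in out
$ cat out/anchoring.tsv
marker_id  plate  row  column  status
M1         5      M    23      ambiguous
M1         22     N    8       ambiguous
```

The marker landed in two clones (as expected at 3× coverage), both
recovered despite the call noise; the `ambiguous` status records that the
decoded set has more than one address. `out/performance.tsv` reports
sensitivity, phantom-address rate, ambiguity rate and per-stage reaction
counts; `out/pool_results.tsv` is the same TSV dialect `bacscreen decode`
reads back.

Other subcommands: `size` (library sizing), `design` (pool manifest TSVs),
`decode` (pool calls → anchoring report), `melt-call` (derivative peak
calling against a no-template control), `primer-check` (QC of primer FASTA
or plain text). `bacscreen count --table2` prints the per-genome budget
table for six reference genomes and reports, on stderr, the two cells where
recomputation disagrees with the published reference values.

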