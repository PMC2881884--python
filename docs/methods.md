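# Methods

## Library model and rounding conventions

All arithmetic is in base pairs internally; parsers accept `kb`/`Mb`/`Gb`
suffixes. Library size is `round(coverage × genome_size / mean_insert)`
clones (defaults: 3× coverage, 100 kb inserts — the standard design point
for PCR-screenable BAC libraries), stored in 384-well plates.

Two rounding modes convert fractional plate and superpool counts to
integers. `strict_ceil` is the physically meaningful convention (a
fractional plate must exist as a whole plate). `paper_round`
(`floor(x + 0.5)`) reproduces published summary tables, which round
half-up; published tables of this kind are not always internally consistent
(the reference table we check against uses the ceiling for its smallest
genome and half-up elsewhere), so both modes are exposed and
`render_table2` reports every cell where recomputation disagrees with the
stored published values rather than silently matching them.

## Pooling designs

**Superpools** partition plates into consecutive blocks of at most 25 (the
empirical sensitivity limit for direct amplification from pooled freezer
stocks). **Matrix pools** place a superpool's plates row-major on a
near-square grid (`g_cols = ceil(√n)`, `g_rows = ceil(n/g_cols)`; 5×5 for a
full superpool) and pool each grid row (H) and grid column (V). The map
plate → (H, V) is injective for every n ≤ 25, which is the decodability
requirement. A one-plate superpool needs no matrix stage and is flagged
skippable.

**Single-plate pools** overlap: every row belongs to exactly 2 of 8 row
pools (each of 4 rows) and every column to exactly 2 of 10 column pools (6
pools of 4 columns, 4 of 6), so a positive well lights exactly two pools
per dimension, and the *pair* of positives identifies the row/column —
possible because C(8,2) = 28 ≥ 16 and C(10,2) = 45 ≥ 24. The concrete pair
assignment is not uniquely determined by those constraints; we fix the
**lexicographically first** feasible assignment (depth-first over pairs in
lexicographic order with exact pool-capacity pruning) so the design is
canonical and reproducible. A plain greedy scan deadlocks (it fills pools
1–5 and leaves only 3 distinct pairs among pools 6–8 for the remaining 6
rows), hence the backtracking. Formats without a feasible 2-regular pair
assignment under the canonical size profile raise an error explaining the
counting obstruction. `validate_design` re-checks every invariant
(partition, injectivity, double coverage, size profile, pair distinctness)
and returns a violation report rather than raising.

Pool manifests carry per-clone aliquot volumes (default 5 µL; a full
superpool is 5 × 25 × 384 µL = 48 mL). The spiked-superpool fixture —
one positive clone at 5 µL among 3200 = (25×384)/3 negatives at 15 µL —
models the dilution a single-copy target experiences in a large-genome
screen.

## Decoding semantics

With exactly one target, decoding is exact: one positive H and one positive
V pool intersect at the plate; two positive row pools and two positive
column pools map through the pair tables to the well. With more positives
the decoder returns *every* address consistent with the observed positives
(pairs ⊆ positive set), flagged `ambiguous`. This union-of-patterns
interpretation can include phantom combinations — the overlap-pair design
is not 2-disjunct — and we deliberately report rather than resolve them,
since the protocol includes no retest step. Positives in only one dimension
(or a positive set matching no pair) are `inconsistent`. An optional
tolerant mode salvages one false negative per dimension by expanding a lone
positive pool to its members, flagged `inconsistent-tolerated`; it is off
by default because it trades specificity for recall without any published
recovery protocol to calibrate against. Adding a spurious positive call
never shrinks the candidate set (monotonicity, property-tested).

## Reaction accounting

`budget_paper_mode(N, n_markers=3)` reproduces the published whole-library
convention: superpool count `round(N/25)`; the superpool stage contributes
one reaction per superpool but **zero** when there is a single superpool;
the matrix stage contributes 10 reactions per positive superpool under the
assumption that markers occupy distinct superpools when there are enough;
the single-plate stage is 18 reactions per marker. Triplex totals are
`ceil(simplex/3)`. `budget_strict_mode` is the self-consistent alternative
(every stage per marker, ceiling superpool count, stage never skipped).
Costs default to 0.17 £ per PCR-HRM reaction and 0.16 £ per conventional
PCR, the latter flagged as excluding gel electrophoresis.

## Screen simulator

The generator emulates the intended use case: clone start positions i.i.d.
uniform on a linear genome (inserts clipped at the right end — edge effects
are negligible at 3×), fixed 100 kb inserts by default (uniform or
truncated-normal length distributions available), point markers either
placed explicitly or drawn uniformly. Ground truth is interval containment:
clone *i* carries marker *m* iff `start_i ≤ pos_m < start_i + len_i`.

The error model is **pool-level**: a pool is truly positive iff it contains
a carrying clone, and the observed call flips true positives with
probability β and true negatives with probability α, independently per
(pool, marker). This matches how false positives/negatives of PCR pool
screens are discussed and keeps the recovery probability analytic;
clone-level dropout could be layered underneath later. Screening is gated
top-down: only children of positive parents are tested, and a marker whose
superpool call is falsely negative is lost (no retest). Reactions are
counted per multiplexed reaction: markers are grouped up to 3; superpool
and matrix stages are shared within a group; each candidate plate costs 18
reactions per marker group present on it. Under these conventions a
noiseless screen of 3 single-clone markers on distinct plates consumes
exactly the calculator's paper-mode total (verified cross-module).

For a single-superpool library the true path of a single-clone marker runs
through k = 6 pools (2 matrix + 2 row + 2 column), so the probability of a
clean unique decode is `(1−β)^6`; simulated sensitivity at β = 0.05 over
500 noise replicates is checked against this closed form within a binomial
confidence band. What passing these tests shows is that the *screening
logic* is correct under the stated error model; the generator does not
model chimeric clones, cloning bias, well-to-well contamination or template
kinetics, so simulator sensitivity is not a wet-lab sensitivity estimate.
α and β defaults are 0 (they are free parameters, not calibrated values —
no quantitative error rates are published for this protocol).

All randomness flows through `numpy.random.default_rng` seeded from
explicit config/argument seeds; a fixed seed gives bit-identical libraries
and screens.

## Melt synthesis and peak calling

Melt content is fixture-grade synthesis for exercising the calling logic,
not a thermodynamic model. The ramp is 65–90 °C in 0.3 °C steps (84 grid
points). A curve is a baseline plus one logistic transition per amplicon,
`A·σ((Tm−T)/w)` with default amplitude 1 and width 0.5 °C, plus optional
Gaussian noise; −dF/dT then peaks at each Tm. Amplicon Tm defaults to the
standard empirical form `81.5 + 0.41·GC% − 675/length` (constants
configurable); primers use the Wallace rule `2(A+T) + 4(G+C)`, which is the
appropriate scale for 19–21-mers (the empirical amplicon form overshoots
the 57–60 °C primer optimum by ~10 °C at those lengths).

Derivatives use central differences with one-sided differences at the grid
ends (series length equals grid length). Peak detection (scipy
`find_peaks`) applies (i) the caller's height threshold — by default 5× the
median absolute deviation of the no-template control derivative, so calls
are invariant to uniform rescaling of fluorescence — and (ii) a
scale-relative prominence floor (10⁻⁶ × fluorescence range / step) that
suppresses float-level ripple on flat regions without affecting genuine
transitions. Marker calling requires expected Tms separated by more than
twice the matching tolerance (default ±1 °C) — otherwise peaks are not
attributable and a multiplex-design error is raised, mirroring the
"distinguishable melting curves" requirement; unmatched peaks are reported
as off-target. Multiplexing is capped at 3 amplicons.

Primer QC evaluates length 19–21 nt, GC within ±10 % of 50 %, Wallace Tm
57–60 °C, two G/C bases at the 3′ end and one at the 5′ end — as separate
criteria that **warn** rather than reject, because these are published
optima, not hard requirements (indeed some of the reference STS primers
deviate from the 5′ rule).

## Problem sizes

The test suite runs everything exhaustively where the space is small (all
384 wells, all 25 matrix positions, all n ≤ 25 grid sizes) and uses
24-plate (9,216-clone) or 10-plate libraries for simulator round trips,
with 60–500 noise replicates for the stochastic checks. The acceptance
script simulates the 1250-plate / 480,000-clone wheat-scale library in
full.

## Known limitations

- Single-plate pool design is defined for the 16×24 format only; other
  formats raise rather than silently generalizing.
- The decoder performs no probabilistic inference and no retest
  scheduling; ambiguity is reported, not resolved.
- The melt module does not parse instrument run files and is not a
  genotyping/mutation-scanning HRM tool.
- The published budget convention (paper mode) is intentionally
  reproduced including its asymmetries; use strict mode for self-consistent
  per-marker planning.
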