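# Methods

## The measurement and the statistic

Strand-resolved nascent-chromatin sequencing labels newly replicated DNA
(EdU pulse), immunoprecipitates a histone mark from that nascent chromatin,
separates the two daughter strands, and sequences them strand-specifically.
A fragment mapping to the forward reference strand came from one nascent
daughter, a reverse-mapping fragment from the other. Around a replication
origin the two daughters correspond to the leading and lagging strands of
the two diverging forks: to the right of an initiation center the leading
nascent strand maps to the forward reference strand, to the left it maps to
the reverse strand. This sign convention is fixed package-wide (simulator,
fork map, density stratification) and is the reason the average partition
profile around origins is a sigmoid.

Per genomic bin the package computes

    Partition = (F − R) / (F + R),

with F and R the normalized, input-corrected forward/reverse signals. The
value lies in [−1, 1]; > 0 means the mark's histones ended up
preferentially on the forward-mapping nascent strand. Bins with F + R = 0
are *missing*, not zero: a zero would claim perfectly symmetric recycling
where there is simply no data, and would shrink origin-averaged profiles
toward 0. No pseudocount is added to the denominator; input-corrected
signal can legitimately be zero.

Some library chemistries (xGen UDI-UMI adapters) sequence the complementary
strand, which mirrors the observed statistic into (R − F)/(R + F). The
correction is an explicit, flag-controlled negation (`flip_orientation`,
`chemistry: mirrored-umi`), declared as a property of the library chemistry
rather than inferred from the data; applying it twice is the identity.

## Track processing chain

Per strand and per sample: bin fragment midpoints → CPM → uniform blur →
subtract input, clamping negatives at zero. Parameters and defaults:

| parameter | default | mESC preset | meaning |
|---|---|---|---|
| `bin_size` | 500 bp | 1000 bp | width of the counting windows |
| `half_window` | 5 bins | 30 bins | uniform-blur reach on each side |
| `min_origin_score` | 20 | 20 | strict (>) firing-efficiency filter |
| `flank` | 2500 bp | — | aggregation half-window around origins |

Choices that needed a decision:

* **Counting convention.** A fragment is reduced to its midpoint
  (template-span midpoint for paired-end data), so one fragment increments
  exactly one bin and totals are conserved. Upstream deduplication is a
  precondition, not re-implemented.
* **CPM denominator** is the sample's total fragment count over *both*
  strands. Per-strand normalization would erase the strand asymmetry the
  partition measures.
* **Order of operations.** Smoothing precedes input subtraction, and the
  input is taken through the identical bin/CPM/blur chain before being
  subtracted (switchable via `blur_input`, default on): subtracting a raw
  track from a blurred one would mix scales.
* **Edges.** The blur uses truncated-window means at contig edges rather
  than zero padding (zero padding biases edge bins downward on small
  contigs). Consequently the blur conserves the track sum only where every
  receiving bin has a full window — i.e. on tracks whose support keeps at
  least 2·half_window zero bins from the edge; the tests verify exactly
  that. The last partial bin of a contig is kept with the full-bin divisor;
  edge bins never enter origin aggregates because windows that would cross
  a contig end are dropped (and counted).

## Origin aggregation

Origins are initiation centers `floor((start+end)/2)` with a firing
efficiency score; records with score strictly greater than 20 are retained
(the boundary value is excluded). The heatmap matrix holds one row of raw
per-bin partition values per usable origin over [center − flank,
center + flank); the metaprofile is its column mean with missing bins
excluded per offset (divisor = count of non-missing values). Offsets are
bin-center distances from the origin center, symmetric about zero. The
displayed profile is the raw signed sigmoid; an optional
`orient="leading"` mode negates the left flank to produce a single
leading-strand plateau.

The density analysis divides ChIP by input read density (both CPM of the
full library) per offset bin within ±2.5 kb of the centers, stratified into
leading / lagging (from strand × side of origin) / unstranded. Whether the
stranded strata divide by the matching-strand input or by the total input
is not dictated by the statistic itself; both are implemented
(`density_input_stratification`), with matching-strand as the default since
it keeps the two strata on the same scale as the unstranded ratio up to a
factor ~2. Note that a CPM/CPM ratio is invariant to overall library depth
by construction — only changes in *concentration* (in-window share of the
library) move it.

## The simulator and what it does — and does not — emulate

The generator provides ground truth for validation. Defaults are one
synthetic "experiment": a three-contig genome of 2.8/2.3/1.2 Mb (half-scale
fission-yeast chromosome proportions), 4 origins per contig with scores
uniform on (5, 100), 200,000 ChIP fragments per sample, 50,000 input
fragments, 150 bp fragments, and a signal half-span (`flank`) of 5 kb
around each origin.

Mechanics: origin centers sit on a 500 bp grid (so they coincide with bin
boundaries of the finest analysis grid), keep ≥ flank + fragment length
from contig ends and ≥ 4·flank from each other, making adjacent signal
windows provably disjoint. ChIP fragment midpoints pick an origin with
probability proportional to its firing score (heterogeneous row depth, as
real origin efficiency produces) and fall uniformly within ±flank. A
parental-histone fragment maps to the leading strand of its midpoint with
probability `p_lead`; a new-histone fragment with probability `1 − p_lead`;
input fragments are strand-balanced and uniform genome-wide. All draws are
independent substreams of one seed; identical configs give byte-identical
read sets.

Two sizing decisions matter for interpretation:

* **Signal span vs blur reach.** With 500 bp bins and a 5-bin blur the
  smoother reaches 2.5 kb, so the partition profile only plateaus at
  offsets beyond 2.5 kb. The simulator therefore spreads signal to ±5 kb
  and recovery analyses estimate the plateau over offsets [2.5 kb, 5 kb);
  within the blur reach the profile is the expected linear ramp through
  zero, not an estimate of 2·p_lead − 1.
* **Genome size vs input subtraction.** The simulated input is uniform
  genome-wide while ChIP signal is origin-concentrated, so input
  subtraction removes a flat offset from both strands and inflates the
  partition by a factor ≈ 1/(1 − w), where w ≈ 0.02 is the fraction of the
  genome covered by origin windows. At the default genome size this bias is
  ≤ 0.02 at p_lead = 0.95 and zero at p_lead = 0.5; on a toy-sized genome
  it would clamp the minor strand to zero and push the partition to ±1,
  which is why the default genome is megabase-scale.

The simulator emulates none of: sequence content or sequencing error,
replication timing, termination zones (nearest-origin fork assignment is
exact by construction), Okazaki-fragment structure, nucleosome positioning,
or origin-calling uncertainty. Passing recovery tests therefore demonstrate
that the *pipeline arithmetic* is faithful — that a known strand bias
propagates through binning, normalization, smoothing, input correction and
aggregation undistorted — not that real chromatin obeys the model. In
particular real EdU inputs are themselves nascent-DNA-shaped rather than
uniform, and real fork directionality is graded, not binary.

## Numerical conventions

* Coordinates 0-based half-open everywhere; a midpoint exactly on a bin
  boundary belongs to the right bin.
* Nearest-origin ties (positions equidistant from two centers) go to the
  leftmost origin; a position exactly at a center counts as right of it.
  Both rules exist for determinism.
* Partition missingness is NaN internally; bedGraph output omits missing
  bins and a companion F + R coverage bedGraph supports downstream
  filtering.
* Floats are serialized with `%.17g` (exact round-trip), so re-running any
  stage from the files a previous stage wrote reproduces downstream tables
  byte-identically, and same-seed runs are byte-identical end to end.
* Degenerate inputs fail loudly: empty origin sets, zero usable origins,
  zero library sizes, grid mismatches, fragments beyond contig bounds,
  malformed records (reported with line numbers), contigs without origins.

## Validation strategy

Every operation is tested against an independent oracle where one exists:
the partition against scalar evaluation, the blur against a brute-force
windowed mean, the full chain against a naive per-base reimplementation on
a 50 kb toy genome (agreement to 1e−9), strand draws against direct
binomial counting, and plateau recovery across p_lead ∈ {0.5, 0.65, 0.8,
0.95} within ±0.05 at 200,000 fragments. The parental/new mirror check
compares the two metaprofiles at every offset against a 3σ envelope whose
σ comes from direct fragment counting (binomial term plus the propagated
Poisson noise of the shared input subtraction). Exact symmetries — flip
involution, strand-swap antisymmetry, scale invariance — are asserted to
machine precision, several of them as derandomized property tests.

## Known limitations

Single-end flag semantics assume one record per fragment; mate-rescue and
mapping-quality filtering are out of scope. The heatmap holds all rows in
memory (fine for origin counts in the thousands). bigWig output is not
implemented (bedGraph only). The density profile pools counts across
origins before ratioing, so very sparse inputs make per-bin ratios
heavy-tailed; interpret them over windows, not single bins.
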