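# Methods

## The model

The package implements a mutation–selection model of motif evolution in
which the mutation process is context-dependent and selection acts only on
the protein code.

**Rates.**  Mutation is described by a complete heptamer table: for each of
the 16384 heptamers `h` and each alternate allele `a` of its middle base, a
dimensionless relative rate `r(h, a) > 0`.  Only ratios of rates matter.
Derived quantities:

* site mutability `m(i) = (1/3) Σ_a r(h_i, a)` where `h_i` is the ±3 nt
  context of position `i`;
* hexamer mutability: the mean of `r` over all 18 single-nucleotide changes
  of the hexamer, each heptamer context completed by uniform averaging over
  the unknown flanking bases (each flank base ¼ per nucleotide, i.e.
  `NNN[XXXXXX]NNN`).  Averages are arithmetic throughout, matching the
  "mean rate" definition used for sites;
* mutational bias β: `r → r^β` (equivalently, log-rates are multiplied
  by β).  β = 0 collapses the spectrum to uniform; β = 1 leaves it
  unchanged; rank order of individual rates is preserved for all β > 0.
  Note that the *hexamer-level* ranking is only approximately preserved:
  powers do not commute with the arithmetic flank average, so the heavy
  tail is re-weighted (Spearman ≈ 0.96 between β = 1 and β = 2 rankings on
  the default synthetic table).

**Dynamics.**  A genome is a set of circular sequences (circularity removes
edge effects; every position has a full heptamer context).  One step:

1. draw a position with probability proportional to `m(i)`;
2. draw an allele with probability proportional to `r(h_i, a)`;
3. without constraint, apply the substitution; with protein constraint,
   reject it unless it leaves the frame-0 amino-acid translation unchanged
   and creates no stop codon, redrawing position and allele on rejection.

Only accepted substitutions advance time, measured as τ = accepted
substitutions per base.  This matches the interpretation of simulation time
as "mutations introduced"; the alternative proposal-clock convention (every
proposal advances time) is available behind
`SimConfig(count_rejected_in_tau=True)`.

Because the position weight is exactly one third of the summed allele
rates, the two-stage draw is equivalent to sampling the (position, allele)
substitution jointly in proportion to `r`.  The embedded jump chain
therefore has move probabilities `r(move)/Σ r(moves)`, restricted to
accepted moves under constraint, and `exact_stationary` solves π P = π for
this chain directly (sparse linear solve, renormalised; for constrained
chains the state space is the component of single-nucleotide synonymous
moves reachable from the start state — synonymous codon sets such as
serine's are not connected under single-nucleotide moves, so the component,
not the full synonymous set, is the ergodic class).

**Reading frame and stop codons.**  The frame is anchored at position 0 and
sequence lengths under constraint are multiples of 3, so no codon spans the
circular origin.  Random initial sequences generally contain in-frame stop
codons; the rejection rule (no translation change, no stop creation) then
freezes those codons in place.  The translation-identity invariant
consequently holds relative to the recorded start state.  FASTA-initialised
constrained runs reject sequences with internal stops outright.

**Recording.**  At τ ∈ {0, Δ, 2Δ, …} the simulator records the circular
overlapping hexamer counts (length-weighted across sequences), the mean
site rate, and the mean hexamer enhancer score when a score table is
supplied.  Constrained/unconstrained enrichment at each τ is the ratio of
hexamer frequencies with one pseudocount added to each count (the transform
keeps ratios finite; sign and ordering conclusions do not depend on it).

## Genomic analyses

Splice windows cover 300 nt of intron and 150 nt of exon on each side of
every annotated exon boundary, in transcript orientation, with 3 nt of
extra genomic context so boundary heptamers extend across the junction
(sites shared between isoforms are deduplicated by coordinate; windows
truncated by contig ends are flagged, kept by default, and each offset is
averaged per-site across whatever windows cover it, so short exons
contribute truncated windows rather than being dropped).  Exon/intron
hexamer enrichment is `log2((f_exon + π_e)/(f_intron + π_i))` with
pseudo-frequency `π = 1/(total windows)` of each collection, which makes
the statistic finite and antisymmetric under swapping the collections.
Correlations against score tables are Pearson on the hexamers present in
both tables; the CpG-excluded variant drops the 1185 hexamers containing
the CG dinucleotide (leaving 2911 — both counts verified by enumeration in
the tests).

## Protein-layer analyses

Coding hexamers are associated with the two codons of largest overlap in
the reading frame (overlap patterns 3+3, 2+3+1 and 1+3+2 make the top two
unique), ordered by position.  Pair-level mean enhancer scores are
occurrence-weighted means over all in-frame hexamer occurrences; pair
enrichment is observed adjacent-pair frequency over the product of residue
frequencies, counted within proteins only.  ΔEI of a mutation is the mean,
over the two hexamers in which the mutated base occupies the 3rd and 4th
position, of (mutant score − wild-type score), both hexamers weighted
equally.  Stop-gain fractions are either uniform enumerations over a
pair's codon-pair encodings (or an explicit hexamer subset such as the
GARGAR set, where the enumeration gives exactly 1/9) or rate-weighted over
supplied genomic contexts, normalising within each occurrence before
averaging occurrences equally.

## Variant and assay statistics

The mutant/wild-type splice ratio is `log2((mt_o/mt_i)/(wt_o/wt_i))` over
read counts summed across replicates; the default pseudocount is 0 with a
hard error on zero terms (summing replicates makes zeros rare), with 0.5
available.  Splice-region variants (first or final 3 exonic nt) are
flagged and excluded from the synonymous/missense/stop-gain comparison,
which reports medians, quartiles and pairwise two-sided Mann–Whitney
p-values.  Mutability-by-frequency binning removes variants with missing
frequency or DAF < 5×10⁻⁵ (below which recurrent mutation distorts the
frequency spectrum) and uses log10-spaced bin edges
{5×10⁻⁵, 10⁻⁴, 10⁻³, 10⁻², 10⁻¹, 1} by default (left-closed; the top edge
inclusive); the edges are configurable since no canonical choice exists.

## Synthetic data: what it emulates, and what it does not

The generators plant exactly the structure the analyses assume:

* **Rate table** — iid log-normal context noise (σ = 0.8 natural-log units)
  per (heptamer, alternate), a 4× transition boost, a 12× CpG-context
  deamination boost (C→T with G following, and the reverse-complement
  G→A pattern), and an 8× purine-context G>T hotspot, normalised to
  geometric mean 1.  The composite spectrum spans well over 400-fold, in
  line with empirical heptamer tables.  The multipliers are round values
  chosen once to give the canonical hotspot anatomy (CpG transitions
  hottest, the purine G>T hotspot between transitions and CpG).
* **Scores** — `score = ρ·z + √(1−ρ²)·e` with `z` the standardised log
  hexamer mutability and `e` noise orthogonalised against `z`, so the
  sample correlation equals ρ exactly (default 0.7).
* **Gene models** — exons drawn from a protein-constrained simulation,
  introns from an unconstrained one at matched τ, concatenated as
  intron–exon–intron on per-gene contigs with exact coordinates.
* **Variants** — alternates drawn in proportion to context rates; effects
  classified from the codon context; log10 allele frequencies uniform with
  a downward shift of (coupling × standardised log site rate) for missense
  and stop-gain variants, planting the rare-variants-at-hot-sites signal.
* **Assay counts** — class effects (synonymous 0, missense −0.5, stop-gain
  −2 in log2 units) plus Gaussian noise (σ = 0.5), realised as Poisson
  counts over 2 input and 4 output replicates per species at depth 1000.
  An `exact` count model writes rounded expected counts instead; since
  2^(−0.5) is irrational, "exact" recovery of planted effects is to
  rounding precision (about 10⁻⁶ relative at depth 10⁶), not bit-exact.

What the generators do **not** emulate: genome-scale compositional
heterogeneity (GC isochores, repeats), splice-site consensus sequences,
transcription-coupled or replication-timing rate variation, linked
selection, or sequencing error.  Passing tests therefore demonstrate that
the statistics recover planted structure of the assumed form — not that
real genomes contain no confounders; the CpG-exclusion re-analysis is the
one confounder check carried over from real-data practice.

## Numerical choices

* The simulator's hot loop is a compiled kernel
  (`premotif/_kernel.py`, numba) implementing the identical proposal scheme
  as the documented pure-Python `step()`; tests verify the incremental ±3 nt
  site-rate cache against full recomputation after kernel runs, and kernel
  occupancy against the exact stationary distribution.
* The stationary solve replaces one equation of `(P^T − I)π = 0` with the
  normalisation constraint and uses a sparse LU; occupancies are compared
  by total variation after 3×10⁶ (unconstrained) / 10⁶ (constrained)
  recorded steps with a 1–2×10⁵-step burn-in — sizes chosen so multinomial
  sampling error sits comfortably under the 0.02 tolerance at the default
  table's effective support (~2900 states).
* Hexamer ranking breaks ties lexicographically; quintiles split the 4096
  descending ranks as evenly as possible (820 + 4×819), quintile 5 most
  mutable.
* TSV floats are written with `repr` and parsed with round-trip precision,
  so writer/reader pairs are bit-exact.
* Reduced problem sizes used by the default test and acceptance runs:
  genomes of 200–300 sequences × 300 nt (τ up to 10 where equilibrium
  matters), 8–400 synthetic genes at τ = 2, 100 assay variants per class.
  These sizes give each directional statistic a comfortable signal-to-noise
  margin (checked by the variance of the statistic across seeds) while the
  whole suite runs in about half a minute; the paper-scale configuration
  (5000 × 999 nt, τ ≤ 10) is available via `SimConfig` defaults and
  `premotif run --paper-scale`.

## Known limitations

* Selection is all-or-none (any amino-acid change rejected); there is no
  fitness gradation, drift with finite population size, or fixation
  dynamics — the simulator models the strong-selection limit.
* Stop codons present in random initial sequences are frozen rather than
  purged, a consequence of the no-new-stop rule (see above).
* The exact oracle is limited to circular sequences of length ≤ 6 (state
  space 4^L), and under constraint to one synonymous component.
* Enrichment ratios for individual rare hexamers at small genome sizes are
  dominated by the pseudocount; aggregate (e.g. top/bottom-50) ratios are
  the stable desk-scale statistic.
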