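# Methods

## Problem and model

A sequencing read of length R mapped at target (mitochondrial) position p
can originate wholly from the background (nuclear) genome only if the
background shares, across p, a subsequence at least as long as the read —
exactly for a perfect-mapping pipeline, or within the mapper's mismatch
tolerance otherwise. `nimap` therefore computes, for every target
position, the maximum and average length of background-shared
subsequences covering it, at mismatch budgets 0 (exact; "LCS" track) and
1 ("LSS" track). Positions where `lss_max(p) ≤ R` are "safe" for reads of
length R; the safe condition is deliberately inclusive (`≤`, not `<`),
since a read as long as the longest shared subsequence cannot be strictly
contained in it while still covering p with target-specific flanks.

### Search semantics

* The background is conceptually decomposed into all overlapping windows
  of length W (default 450) on both strands, de-replicated with
  occurrence multiplicities. Only membership matters for the LCS/LSS
  tracks; multiplicities feed occurrence counting for primer reports.
* For every target start s (1-based), L0(s)/L1(s) is the longest prefix
  of the target sequence starting at s that matches some background
  substring with 0/≤1 mismatches, on either strand, capped at
  min(W, target length) and wrapping past the origin for circular
  targets. If any per-start value reaches W the pipeline rebuilds the
  index with W doubled and repeats (W must strictly exceed the longest
  match for the cap to be inactive); the final W is recorded in the map
  metadata.
* A start with L(s) ≥ 1 covers positions s … s+L(s)−1 (modulo the length
  when circular). Per position, the max track is the maximum covering
  L(s) and the avg track the unweighted mean over covering starts (each
  start counted once, not per background occurrence — occurrence
  multiplicity weighting would conflate copy number with length and is
  not what a mapper's containment criterion sees). Uncovered positions
  report 0 in both tracks rather than a missing value, so tracks are
  total functions; genuine data has minima well above 0, so the two are
  distinguishable.
* Mismatch models: `substitution` (default) is Hamming distance at equal
  length. The optional `unit_edit` model allows one Levenshtein edit,
  with match length measured on the query side. Note a consequence of
  that contract: any single query base is within distance 1 of the empty
  string, so unit-edit L1 is essentially min(L0+1, |q|) or more; the
  model is useful for mappers that tolerate an indel, not as a "one
  substitution" criterion.
* `N` never matches any base (in background or target query) but may be
  consumed by the mismatch budget — conservative and deterministic.
  Target `N` placeholders are removed before profiling and the four
  tracks are restored afterwards, each removed position copying the
  preceding original position's value (position 1 copies the last
  position on a circular target). N positions are detected from the
  sequence itself, not assumed at a fixed coordinate, so reference
  dialects that shift the placeholder still work.

### Implementation and oracle

Queries are answered from sentinel-separated encoded text arrays (both
strands of every record) by a column dynamic programme over all text
offsets — a vectorized Landau–Vishkin scheme with k ≤ 1: per query
column, each offset carries the exact and budget-1 extension lengths
beginning at that column, so one right-to-left pass yields every start's
L0/L1 simultaneously in O(|target| · |background|) bit-parallel numpy
work. Sentinels can never match nor be consumed, which confines matches
within a single record/strand. The same pass at column 0 gives the
occurrence counts (an offset's window is within budget iff its greedy
budget-1 extension spans the query).

Correctness is established against two independent oracles: a
hand-written full-scan that counts cumulative mismatches per offset
(substitution model), and edlib's infix alignment at k=1 (unit-edit
model). Oracle equivalence is asserted on hundreds of randomized
instances and on whole maps of random genome pairs.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `window` (W) | 450 bases | background window length and match cap; auto-doubled while capped |
| `mismatch_model` | `substitution` | Hamming vs one-edit Levenshtein |
| primer count budget | 1 mismatch | budget for "similar background occurrences"; overlapping hits and both strands counted |
| smoothing `mu` | 21 taps | Gaussian kernel width for length densities (odd) |
| smoothing `sigma` | 3 grid units | kernel standard deviation |
| mixture `k` | 2 | number of transformed-Poisson components (3k−1 free parameters) |
| `n_restarts` | 32 | seeded Nelder–Mead restarts |

The defaults are the analysis conditions for a mitochondrial-scale
target: W = 450 comfortably exceeds the longest shared subsequences seen
in such data (a few hundred bases), and the 21-tap/σ=3 kernel removes
grid-level noise from densities supported on a few hundred integer
lengths without erasing multimodality.

## Mixture model

The per-position average-length track (`lcs_avg` or `lss_avg`) is
histogrammed on the integer grid 1..⌈max⌉ (values rounded to nearest),
normalized, smoothed, and fit by

G(l) = Σᵢ αᵢ βᵢ P(λᵢ, βᵢ l),  P(λ, x) = λˣ e^(−λ) / Γ(x+1),

minimizing Σ (F(lᵢ) − G(lᵢ))² over the grid. Choices made where the
procedure was genuinely open:

* Non-integer βl is handled by the Γ-function continuous extension of
  the Poisson pmf (a nearest-integer `rounding` flag provides the
  alternative). The continuous extension integrates to 1 only
  asymptotically in λ (≈0.97 at λ=2.5, 1−3·10⁻⁶ at λ=11), so the model
  is an unnormalized least-squares density approximation, which is what
  the objective measures.
* The kernel parameter pair is read as (tap count, standard deviation);
  a "mean 21" reading is meaningless for a symmetric noise filter.
* Optimizer: derivative-free Nelder–Mead from 32 seeded random starts
  plus a quantile-anchored deterministic start, on an unconstrained
  parameterization (softmax for α, log for β and λ), followed by two
  polish rounds. For k > 1 the search also starts from the fitted
  (k−1)-component model with its heaviest component split in two, which
  makes the achieved error provably non-increasing in k. Components are
  reported sorted by λ ascending; fits are bit-reproducible for a fixed
  seed.

On noiseless synthetic two-component densities the fit recovers all five
parameters to ≪1% with objective ~10⁻²⁸; on real tracks the residual
reflects genuine model misfit, not optimizer failure.

## Synthetic data

`simulate_pair` emulates the one structural feature that creates
interference: segments of the circular target copied into the background
at some point in the past. Each implant class has a count, a length
range, and a per-base substitution rate (or an exact substitution
count); implants may wrap the target origin, land on either strand with
probability 1/2, and occupy non-overlapping background offsets; all
remaining sequence is uniform i.i.d. over {A,C,G,T}. Ground truth yields
pointwise lower bounds on the map: for each implant, every position gets
at least the length of the largest surrounding window with 0 mutated
bases (exact track) and with ≤1 mutated base (one-mismatch track).

What the generator does *not* model — and what passing tests therefore
do not demonstrate — includes GC/repeat structure, segmental
duplications, indel divergence of old insertions (unless the unit-edit
mode is exercised), personal variation, and realistic NUMT length/age
distributions. Tests validate the string algorithmics and the
aggregation semantics, not genomic realism. Full-scale runs against real
references are supported through the CLI with the same code paths.

## Problem sizes and numerics

The test suite and acceptance script run at deliberately modest sizes —
backgrounds of a few kilobases, targets of a few hundred bases, with the
brute-force oracle as referee — chosen so the oracle (quadratic work)
remains the bottleneck and the whole suite completes in minutes on one
CPU. Results at these sizes exercise every code path (wrapping, strand
placement, N handling, capping/re-run) identically to full-scale runs.

Degenerate inputs: empty queries, empty backgrounds, even kernel widths,
annotations outside the target, primers that do not bind at their stated
site, and infeasible implant packings all raise descriptive errors;
records shorter than W contribute their full length as a single window
per strand.

## Known limitations

* Only mismatch budgets 0 and 1 are computed; more permissive mappers
  would need larger budgets (the maps are lower bounds on interference).
* The interference map describes containment of a read in a shared
  subsequence; it does not model mapper-specific scoring, paired-end
  rescue, or base-quality weighting.
* Occurrence counts treat overlapping background hits as distinct; a
  tandem-repeat background inflates counts relative to distinct loci.
* The window multiset view is materialized in memory and is intended
  for desk-scale backgrounds; queries themselves stream over encoded
  arrays and scale to large backgrounds given time.
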