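# Methods

This note documents the models behind each phagekit component, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions.

## Collapsed terminal-repeat detection

A linear genome whose two ends carry an identical repeat of length `r`
assembles into a circle of length `U = G − r` in which the repeat appears
once with (asymptotically) twice the read depth of the rest. Detection
works on a per-position depth profile of the circular assembly:

1. circular moving-average smoothing (default window 201 bp; odd windows
   only);
2. threshold at `ratio_threshold` × global median of the smoothed profile
   (default 1.5 — the collapsed-duplication expectation is 2.0 and the
   background is 1.0, so the threshold sits midway; the single observable
   reported for real data lies between those levels);
3. the longest contiguous circular run above threshold is the candidate
   (the number of disjoint qualifying runs is reported; "no segment above
   threshold" is an explicit no-detection result, not an error);
4. boundary refinement by a least-squares **flat / linear-ramp / flat** fit
   on the raw depth within `refine_window` (default 4 × smoothing window)
   of each threshold crossing. The ramp model is the correct local model:
   a position within one read length of a repeat boundary is covered by a
   mixture of single- and double-copy reads, so depth climbs linearly from
   the background level to the plateau over one read length. The reported
   boundary is the *foot* of the fitted ramp (the last background-level
   position). A sharp step is the small-width limit of the model and is
   recovered to within half the smallest ramp width in the fit grid
   (±5 bp). A two-level step fit, by contrast, settles mid-ramp and biases
   the detected length low by about one read length.

`coverage_ratio` is the plateau-over-background estimate: the inside mean
is taken on the segment interior between the fitted ramp tops (the ramps
are mixtures, not evidence about copy number), the outside mean on all
positions beyond the call. On simulated 400 nt-read assemblies this sits at
2.0 ± 0.06; averaging over the entire repeat including its edge ramps would
give exactly `2 − read_length/r` instead, an edge artefact.

Properties that hold by construction and are asserted in tests: detection
is rotation-equivariant on the circle; segments may wrap the origin;
linearization (`rotate so the repeat leads; total = unique + r`) conserves
the base multiset and is idempotent. The length accounting of the
linearized genome is additive by definition: a 147 175 bp circular unique
sequence with a 2669 bp collapsed repeat is a 149 844 bp linear molecule.
(Published descriptions of such genomes occasionally disagree internally on
the total; the additive identity is the only self-consistent reading.)

Tandem repeats are found by an exact/near-exact self-periodicity scan: for
each unit length `u`, maximal stretches with `seq[i] == seq[i+u]` and
mismatch fraction ≤ `max_mismatch_frac`; runs are attributed to their
smallest generating unit (a homopolymer is unit 1, not 2 or 4). Repeats are
associated with a repeat-boundary flank within a 200 bp window, covering
the offsets at which such repeats are observed near physical genome ends.

## Consensus gene calling

Gene callers disagree on start choice far more than on stop position, so
candidate CDSs from all predictor tracks are grouped by
**(strand, stop anchor)** — the genomic coordinate of the stop codon's last
base on the coding strand. A group reported by at least `min_support`
distinct tools (default 3 of 4) becomes one consensus feature; its start is
the most frequent start among group members, ties broken in favour of the
longest CDS. Overlapping same-strand candidates with different stop anchors
are distinct (no merging). The operation is order-invariant in tracks and
idempotent.

Sequence statistics: GC% excludes ambiguity codes from the denominator;
CDS density is the interval union of spans over genome length (overlaps
counted once); start codons are classified as ATG/TTG/GTG/other and stop
codons as TAA/TAG/TGA by reading the literal boundary triplets with
reverse-complementation on the minus strand.

## Ungapped local alignment and significance

The engine is seed-and-extend without a gapped stage:

- **nucleotide mode**: exact word seeds (default 7), both query strands,
  +1/−2 match/mismatch;
- **translated mode**: all 6×6 reading-frame pairs, exact protein 3-mer
  seeds, BLOSUM62; stop codons translate to X and score −1 against
  everything (fragments are genomic, not ORF-guided, so frames are not
  truncated at stops).

Extension along a seeded diagonal is computed exactly as the maximum-sum
segment of the per-position score array (Kadane), i.e. the unbounded-X-drop
limit of two-directional extension. This makes the reported score the true
ungapped optimum of its diagonal, which a full dynamic-programming oracle
verifies in the tests; an X-drop cutoff would only ever lose that
guarantee, and at these sequence lengths buys nothing.

Significance uses Karlin–Altschul ungapped statistics,
`E = K · m · n · e^{−λS}` and `P = 1 − e^{−E}` (so `P ≤ E`, `P ≈ E` for
small E), with the standard published ungapped parameters λ=1.28, K=0.46
for +1/−2 and λ=0.3176, K=0.134 for BLOSUM62. `m·n` is the plain product of
sequence lengths (no edge-effect correction); for translated searches `n`
counts residues across all six target frames. Exact reproduction of NCBI
BLAST bit scores is a non-goal; the statistics are used for thresholds and
network weights, where only the scale matters.

## Fragmented translated similarity

Genome A is tiled into `fragment_size` = 50 bp fragments every `step` =
25 bp (a final short fragment is kept; fragments under 9 bp are skipped).
Each fragment's best translated HSP score against genome B, capped at the
fragment's self-score and zeroed when `E` exceeds the per-fragment ceiling,
is summed:

    sim[A][B] = 100 · Σᵢ min(bestᵢ(B), selfᵢ) / Σᵢ selfᵢ

The ratio-of-sums normalization (rather than a mean of per-fragment
ratios) weights fragments by their information content and caps
self-comparison at exactly 100. The matrix is asymmetric for genomes of
unequal variable content: if A is a verbatim half of B, `sim[A][B] ≈ 100`
while `sim[B][A] ≈ 50`. The default per-fragment E ceiling is 1e-3: with
~16-residue fragments this keeps the expected number of random hits per
genome comparison well below one, so unrelated genomes score ≈ 0 instead
of accumulating a noise floor. Distances for tree building are
`d(A,B) = 100 − (sim[A][B]+sim[B][A])/2` with a forced zero diagonal.

## Similarity network and clustering

For every genome pair the best nucleotide HSP P-value is computed (the
ungapped scoring is symmetric, so one comparison serves both directions);
pairs within the E ceiling (default 1e-5; 1e-2 is the appropriate looser
setting for family-scale collections) become edges with

    attraction = min(1, −log₁₀(p) / 200),  p floored at 1e-200

mapping P ∈ [1e-200, 1] onto (0, 1]. The floor exponent doubles as the
normalization constant; the reference clustering tool does not document its
internal scaling, so this mapping is implementation-defined here. Closely
related genomes saturate at attraction 1.0 by design; the weight
discriminates only below the floor.

Groups are extracted as connected components of the subgraph with edge
`p ≤ p_cutoff` (default 1e-5), size-1 components flagged singletons.
Components, not embedding proximity, are the reproducible formalization of
reading clusters off a force-directed layout; the layout (classical
Fruchterman–Reingold: attraction·d²/k along edges, k²/d repulsion between
all pairs, displacement capped by a linearly cooling temperature, 10 000
rounds by default, deterministic in the seed) is kept for visualization.
The FR forces are the negative gradient of the potential
Σ w·d³/3k − Σ k²·ln d, so the energy trace is non-increasing over the late
cooling phase — asserted as a sanity check.

## Trees, patristic distances, separation

Neighbor joining is the standard Saitou–Nei Q-criterion algorithm with two
determinism conventions: Q ties break on the lexicographically smallest
label pair, and negative branch lengths are clamped to zero with the
deficit moved to the sister branch (total additivity preserved). On an
additive matrix the output patristic distances reproduce the input to
machine precision; topology agreement with an independent NJ implementation
is covered in tests. Output trees are unrooted Newick.

Marker trees are NJ on Poisson-corrected p-distances
`d = −((k−1)/k)·ln(1 − kp/(k−1))` with k = 20 states — the correction that
is exactly additive under the uniform-replacement protein process the
marker simulator uses. Maximum-likelihood inference, model selection and
bootstrap are out of scope.

Group separation: for each pair of groups, the mean between-group patristic
distance is compared against the **larger** of the two within-group maxima
(the conservative reading of "exceeds the greatest in-group distance").
Singleton groups have within-max 0 and enter only through between-group
means. Flags are invariant to uniform branch-length scaling.

## MAST and the congruence index

MAST is computed by dynamic programming over pairs of *directed edges*:
directed edge (u→v) denotes the subtree on the v side. For binary nodes the
recurrence takes the best of dropping a child on either side or matching
the two child pairs in either orientation; small multifurcations are
handled by exhaustive child matching. The unrooted MAST is the maximum over
edge pairs of the two directions' sum — equivalent to maximizing rooted
MAST over all edge-rootings of both trees, at O(n²) table size. Brute-force
leaf-subset enumeration verifies the DP exhaustively for n ≤ 8.

`I_cong = observed MAST / mean null MAST`, where the null is the MAST of
independent uniform random binary labelled topologies (PDA; generated by
uniform random edge insertion) on the same leaf set. The referenced online
calculator fits an expectation curve from simulations and does not state
its null; a direct, seedable Monte-Carlo null is self-contained and makes
the p-value exact by the add-one permutation convention
`p = (1 + #{null ≥ obs}) / (reps + 1)` — never exactly zero, minimal value
1/(reps+1). The null distribution depends only on the leaf count, so
`icong` accepts a precomputed null for batch tables. Published I_cong
values for real marker sets are not reproduction targets here (they require
the real sequences); the calibration properties replacing them are:
identical trees reach the minimal p; a label-permuted tree is itself a null
draw, so its expected index is 1 (mean over 50 seeds within [0.9, 1.1]).

## Growth kinetics

**Adsorption.** Free phage decays as `dP/dt = −k·B·P` at host density B,
so each timed titre yields `k_t = (2.303 / (B·t)) · log₁₀(P₀/P_t)`. The
reported constant is the mean of `k_t` over the monotone-decay window
(points before the titre stops falling), per replicate, then averaged —
the per-period form of the classical calculation, rather than a regression
slope. A non-decaying series is an explicit error. The estimator is
invariant to titre rescaling and, at the reference design (samples every
minute for 10 min, 4 replicates, 10% lognormal CV), recovers the
generating constant within 10% (median over 100 seeded runs; the
mean-preserving lognormal noise cancels in the log-ratio, so the estimator
is unbiased to first order).

**One-step growth.** The simulator's curve is flat at the infective-centre
baseline until the latent period; because lysis times scatter around their
mean, a fraction (`onset_release` = 0.1) of the eventual rise appears at
the latent time itself, followed by a linear ramp over `rise_min` = 25 min
to the plateau `burst × baseline`. The chloroform-treated series has the
same shape starting at the eclipse period from a residual free-phage
baseline (10% of infective centres). The estimator reads: latent = first
sampling time with mean total titre > `rise_factor` (default 3) × pre-rise
baseline; eclipse = same rule on the treated series (clipped to ≤ latent);
plateau = mean of total titres from the first successive change below
`plateau_tol` (default 10%); burst = plateau / baseline. If the series
ends before stabilizing the last point serves as plateau and the result is
flagged censored. Noise-free on-grid inputs are recovered exactly; under
the reference noise regime burst is recovered within 15% and latent within
one 10-minute grid step.

## Synthetic community generator

One root genome is drawn with coding-like core modules (random sense
codons, no in-frame stops) in a fixed syntenic order
(packaging–head–tail–replication by default, 450 bp each) interleaved with
300 bp accessory genes. Each group's ancestor is the root mutated at
`between_rate` substitutions/site per lineage (so pairwise between-group
divergence exceeds the nominal rate); members are the group ancestor
mutated at `within_rate`. Substitution is i.i.d. per-site replacement by a
uniformly chosen different base; indels occur only as whole-accessory-gene
replacement (probability `accessory_turnover` per genome), which keeps
core synteny exact and the truth trackable. The optional outgroup is a
fresh random genome of equal length sharing no ancestry. Defaults
(3 groups × 4 genomes, within 0.05, between 0.45, turnover 0.5, ~2.6 kb
genomes) put within-group pairs well inside the translated-similarity
dynamic range and between-group pairs at background, the regime the
grouped-versus-singleton analysis assumes; genome lengths are desk-scale
so the full pipeline runs in seconds to minutes on one core.

Protein markers evolve along a supplied tree with Poisson(branch × rate ×
sites) substitutions per branch over a 20-letter alphabet, aligned by
construction (no indels): the tested objects are trees, not alignments.

What the generators deliberately do **not** emulate — and what passing
tests therefore do not show about real data: read-level sequencing error
and non-uniform library coverage (GC bias, hotspots); recombination and
mosaicism *within* core modules; genuine indel/alignment uncertainty in
markers; gene-caller biases that are correlated between tools (consensus
voting assumes independent false calls); biological scatter in burst size
between cells. Real 100–160 kb genomes differ from the ~2.6 kb synthetic
ones only in scale for these algorithms (all are length-linear per pair),
but empirical significance thresholds (e.g. the e-ceilings) were chosen on
the synthetic scale of the benchmark and should be revisited for
full-length genomes.

## Numerical conventions and degenerate inputs

- Coordinates are 1-based inclusive throughout (GFF3 convention); circular
  segments may wrap the origin.
- Fixed seed ⇒ bit-identical output for every generator and for the
  pipeline bundle (asserted byte-for-byte in tests).
- P-values are computed as `−expm1(−E)` to avoid cancellation; network
  P-values are floored at 1e-200 before taking logs.
- Sequences with more than 50% ambiguity codes are rejected by the
  alignment engine; ambiguous bases never match and translate to X.
- A similarity matrix of fewer than 3 genomes skips network clustering and
  tree building with a notice; pairwise similarity is still emitted.
- NJ rejects matrices containing NaN; distance matrices validate symmetry
  and zero diagonal on construction.
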