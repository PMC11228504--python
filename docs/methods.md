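# Methods

## The matching model

Two species-annotated alignments M(A) and M(B) of interacting protein
families are grouped by species. Species present in only one alignment are
discarded (no within-species matching is possible); species with exactly
one unmatched sequence on each side are paired trivially; every other
shared species k becomes a block with N_k(A) and N_k(B) unmatched
sequences. Unequal sides are equalized by appending all-gap *padding
sequences*, so each block is square of size N_k = max(N_k(A), N_k(B));
pairs assigned to a padding row are reported but flagged, and are excluded
from precision numerators and denominators. Known interacting pairs
("positive examples") are removed from the permutation problem entirely
and re-attached as fixed context rows whose tokens are never masked; the
confidence matrices never contain them. Species with more than 50
sequences on either side (configurable) are excluded from optimization
and reported, since dense scorers scale quadratically with block size.

The model assumes one-to-one interaction within a species (no cross-talk)
and treats blocks as independent: the only coupling between species is
that one loss is evaluated on the concatenated paired alignment.

## Loss and optimization

Candidate pairings are parameterized by one real N_k×N_k matrix X_k per
block; the hard pairing is the exact maximum-weight assignment M(X_k)
(Hungarian algorithm — the problem sizes here, N_k ≤ 50, never justify an
approximate solver). The objective is the masked-language-modeling loss of
the paired alignment: one side is chosen (the shorter family when no
padding exists; the family with over twice as many padding rows when
lengths are within a factor 1.25; otherwise at random), each of its tokens
is masked independently with probability p = 0.7 (padding tokens
included), and the loss is the unweighted mean surprisal of the scorer's
predictions at masked positions. High masking probability forces the
scorer to draw information from the partner family rather than from the
masked family itself.

Gradients reach X_k through a straight-through estimator: the forward pass
consumes the hard permutation while the backward pass differentiates the
Sinkhorn relaxation S(X_k/τ) — iterated row/column normalization of the
entrywise exponential, computed in the log domain. Defaults τ = 1.0 and 20
normalization sweeps give stable, well-scaled gradients at these matrix
sizes; both are configurable. Relaxed permutations act on one-hot row
encodings, producing convex row mixtures that any scorer backend must
accept — this is the cross-backend contract that lets gradients flow.

One gradient step: (1) add i.i.d. standard Gumbel noise to each X_k,
scaled by 0.1 × SD(X_k) × (current lr / initial lr) — when SD(X_k) = 0, as
at the zero initialization, a floor of 10⁻³ stands in for the SD so the
first hard matching is a uniformly random permutation (random
tie-breaking); (2) pair, mask, evaluate the loss on the hard permutations;
(3) backpropagate and update each X_k with AdaDelta (ρ = 0.9, ε = 10⁻⁶,
initial learning rate γ = 9, weight decay w = 0.1 added to the gradient in
the optimizer's conventional coupled form — the matching operator is
scale-invariant, so shrinking ‖X_k‖ only regularizes); (4) mean-center
each X_k (shift invariance makes the mean a flat direction). A
reduce-on-plateau schedule multiplies the learning rate by 0.8 when the
raw step loss has not improved on the running best (relative threshold
10⁻⁴) for more than 20 steps; the schedule also drives the Gumbel scale,
so exploration anneals with the step size. Noise is re-drawn at the start
of every step, after the previous update.

Initialization matters, so a run consists of 20 zero-initialized probe
runs of 20 steps whose final parameterizations are averaged to warm-start
a 400-step main run. Every main-run step is recorded in a ledger (step,
loss, hard permutations, learning rate). The confidence matrix C_k is the
average of the hard permutations at the q lowest-loss ledger entries
(default q = 400, the whole ledger — high-confidence precision benefits
from the maximal q); the consensus pairing is M(C_k). Confidence entries
in [0, 1] estimate per-pair reliability. The scheduler compares raw
(single-mask) step losses; each ledger entry records the one mask drawn
for that step.

## MRA and IPA

MRA runs N_runs independent optimizations and selects the q = 400
lowest-loss permutations from the pooled ledgers before averaging, which
smooths out unlucky runs.

IPA iterates: optimize with the current positives, average the new
confidence matrix into the moving average C̃(n) = mean(C(n), C̃(n−1), …,
C̃(1)), take the consensus M(n) = M(C̃(n)), and compare its average MLM
loss over 200 random masks with that of the previous consensus (restricted
to the surviving rows) using a one-sided Welch t-test at α = 0.05 — chosen
for robustness to unequal variances; the comparison passes when the new
mean is lower or not significantly higher. Up to three fresh optimization
attempts (each with fresh probe runs) are made before reverting to the
previous moving average; a separate termination check repeats the
comparison under the positives available at the start of the previous
iteration. On acceptance the top five confidence entries pooled across all
species — kept row-disjoint greedily, and never padding rows — are
promoted to positive examples and removed from the problem; fewer than
five remaining pairs are promoted all at once and the loop ends. Two
degenerate equal samples (e.g. a constant scorer) certify nothing and
fail the comparison, so the procedure terminates rather than promoting on
no evidence; samples are called degenerate when their pooled standard
deviation is below 10⁻⁹ relative, which absorbs float rounding in
otherwise identical losses. After promotions the moving-average history
simply drops the promoted rows and columns; no renormalization is applied.

The single-sequence baseline scores each candidate pair (A_i, B_j) by its
MLM loss averaged over 10 random masks drawn across the whole concatenated
pair at p = 0.5 (sweepable over 0.1–1.0), then solves each N_k×N_k cost
matrix exactly as a minimum-cost assignment. Padding rows participate with
all-gap sequences; assignments to them are flagged unpaired.

## The synthetic scorer and benchmark

The planted benchmark emulates the geometry of curated interacting-family
datasets: K = 10 species with 3–5 paralogs each (≈ 40 pairable rows),
alignments of 60 and 40 columns over the 20-letter amino-acid alphabet,
and 10 coevolving column pairs. For each planted pair and column pair
(c_A, c_B), the A residue is drawn from the background and mapped to the B
residue through a per-column-pair bijection table with leakage ε = 0.05
(probability ε of a uniformly random letter instead); all other columns
are i.i.d. background. Rows are shuffled within species so input order is
uninformative. The same tables define the synthetic scorer, which predicts
a masked B token by pushing the (possibly soft) partner A state through
the table, a masked A token through the Bayes-inverted table, and
everything else from the background; predictive distributions are smoothed
with 1% background mass (and a 2% gap frequency) so gap tokens on padding
rows and leaked states keep finite surprisal. A masked partner is never
used as context. An optional per-row drop probability on the B side
produces asymmetric species for exercising the padding path.

What the benchmark deliberately does not emulate: phylogenetic correlation
between rows (sequences are exchangeable within a species), alignment
errors, insertions, biased amino-acid composition, and — most importantly
— cross-row context. The synthetic scorer scores each paired row
independently, so positive-example context rows can help only by shrinking
the permutation problem, not by conditioning predictions; tests of the
positive-example benefit therefore check non-degradation rather than the
strong gains an attention-based scorer can show. Passing the planted-
recovery tests demonstrates that the optimization machinery finds pairings
that minimize the loss, not that any particular real scorer's loss ranks
real pairings well.

## Numerical choices and problem sizes

Assignment ties are broken by an infinitesimal random perturbation
(relative scale 10⁻⁹) when a generator is supplied; consensus extraction
omits it, making results a deterministic function of the ledger. The whole
pipeline draws randomness from a single `numpy.random.Generator`, so a
seed reproduces ledgers, confidences and pairings bitwise. The autodiff
core is a minimal reverse-mode tape over numpy arrays covering exactly the
operations the pipeline composes (Sinkhorn sweeps, row mixtures, gathers);
its gradients are validated against central finite differences at 10⁻⁶
step.

Tests and the acceptance script run the full 20×20-probe + 400-step
schedule where a criterion concerns the published operating point (single-
run recovery), and a shortened schedule (4 probes × 10 steps, 80 main
steps) with correspondingly smaller or fewer datasets for the multi-run,
positive-example and iterative variants, where the claim under test is a
comparison between configurations rather than an absolute level. Masking
and generator parameters are never changed between variants of a
comparison.

## Known limitations

- The external language-model adapter is a contract only; no weights are
  bundled and none are downloaded. It raises a clear unavailable-backend
  error rather than degrading silently.
- Sequences are restricted to the 20 canonical amino acids plus gap;
  ambiguity codes (X, B, Z, …) are rejected at read time rather than
  silently recoded.
- IPA's loss comparisons are Monte-Carlo estimates; with very few masked
  informative positions the Welch test has little power and IPA may accept
  or terminate conservatively.
- The expected precision of random matching, K/ΣN_k, applies to the
  optimizable blocks; trivial pairs (always correct when annotations are
  consistent) are excluded from that baseline.
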