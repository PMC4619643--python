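# Methods

## Problem and model

A DNA barcode is a short oligo of N bases prepended to reads so that pooled
samples can be demultiplexed. On platforms dominated by substitution errors
the channel is modelled as a quaternary symmetric channel (QSC): each base
independently mutates to any of the other three bases with probability
p_s/3 each (total p_s) and survives with probability 1 − p_s. The studied
mismatch range is p_s ∈ [0.010, 0.075], with p_s = 0.01 the reference
operating point.

Decoding is deliberately *incomplete*: the identification-error probability
p_e splits into undetected misassignments p_u (the decoder accepts a wrong
codeword) and detected failures p_d (the decoder declines; the read is
lost). `p_e = p_u + p_d` holds as an exact counting identity in every
simulation. For applications sensitive to false positives, p_u is the
critical quantity and read losses are an acceptable currency.

## Finite fields

Barcode symbols live in GF(4) = GF(2)[x]/(x²+x+1), encoded as the integers
0–3 whose 2-bit expansions are the coefficient vectors; addition is then
bitwise XOR, and the bit-pair ↔ base correspondence used by the BCH layer
is exact rather than approximate. BCH decoding uses GF(2^m), m ∈ {4,5,6},
built as log/antilog tables over the conventional primitive polynomials
x⁴+x+1, x⁵+x²+1, x⁶+x+1. Any primitive choice yields an equivalent code,
so code equivalence (not bit-identity of tables) is the tested contract.

## Quaternary LDPC barcodes

**Construction.** The support of the m×n parity-check matrix H (column
weight j = 3) is placed by Progressive Edge Growth: edges are added one
variable at a time, each new edge attaching to a check as far as possible
from the variable in the current subgraph (unreachable checks first, then
maximal BFS depth), ties broken by lowest check degree then lowest index —
the canonical greedy rule. The template is deterministic given (n, m, j);
randomness enters through the GF(4) fill, which draws each non-zero entry
uniformly from {1, 2, 3}. On the configurations used here (all Table-style
(n, k) pairs with n ∈ {19, 21, 23, 24, 25}) the greedy construction leaves
no 4-cycles; in tighter configurations (e.g. n = 16, m = 12) it may not,
which is a known property of greedy PEG rather than a defect.

**Selection.** Candidate fills are ranked by
D(H) = (μ_h,c − σ_h,c)(μ_d,r − σ_d,r). The column statistic uses all
n(n−1)/2 normalised pairwise Hamming distances between columns (entries
compared as GF(4) values, divided by m, so μ_h,c ∈ [0,1]); the row
statistic uses all m(m−1)/2 pairwise cosine dissimilarities of rows
treated as real integer vectors. Standard deviations are population
(ddof = 0) values. Design choices the score's verbal definition leaves
open, fixed here: rows enter the cosine as raw 0–3 integer vectors (this
preserves the value diversity the score is meant to capture; a binary
image would erase it); an all-zero row — impossible for a connected PEG
graph but guarded anyway — takes dissimilarity 1 against any row.
Rank-deficient fills (rank(H) < m over GF(4)) are discarded and
regenerated so k = n − m always holds. The pool re-fills a single template
per (n, m); the default pool size is 1000, and ties in D are broken by
generation order.

**Generator.** G is the null space of H computed by Gaussian elimination
over GF(4), systematic on the non-pivot columns; G·Hᵀ = 0 and
rank(G) + rank(H) = n are asserted for every constructed code.

**Decoding.** Sum-product belief propagation in the probability domain.
Check-node updates are GF(4) convolutions computed via the 4-point
transform of the additive group (Z/2)²: beliefs are permuted into the
x = h·c domain where each check reads Σx = 0, transformed, multiplied
leave-one-out (prefix/suffix products along each check), and transformed
back. Variable-node updates multiply channel priors with leave-one-out
check messages. All messages are renormalised every iteration and floored
at 1e-30; no damping or clipping is applied — the codes are short and
underflow is the only numeric hazard. After every iteration the
entrywise-argmax word (ties toward the smaller symbol, for determinism) is
tested against H; a zero syndrome stops early with success, and reaching
the iteration cap (default 50, counting the initial syndrome screen of the
received word as iteration 1) is a detected failure. Both non-convergence
and convergence to a non-codeword are folded into the failure status. The
decoder is vectorised over batches of received words, with converged words
retired from the batch each iteration; words whose received form is
already a codeword bypass message passing entirely, which at p_s = 0.01
removes ~83% of length-19 trials.

## Shortened BCH barcodes

The generator polynomial of BCH(n = 2^m − 1, t) is the LCM of the minimal
polynomials of α…α^{2t}; k = n − deg g. Shortening by s fixes the first s
information bits to zero and omits them, leaving redundancy unchanged:
k′ = k − s, and the barcode carries N = (n+1−s)/2 bases for even s or
(n−s)/2 for odd s. The (n+1) term for even s is implemented as an
extension: an overall even-parity bit is appended so 2N is an integer bit
count. All published configurations use odd s, so the extension path is a
convention; the parity bit is stripped before algebraic decoding and not
otherwise used.

Encoding is systematic (message, then parity of m(x)x^{n−k} mod g). Bits
are paired and mapped to bases by a fixed bijection 00→A, 01→C, 10→G,
11→T; any fixed bijection preserves the key combinatorial fact that a base
substitution flips one bit pair in 1 or 2 positions (2/3 vs 1/3 under the
QSC), hence b = ⌊t/2⌋ guaranteed correctable mismatches. Position-dependent
optimal mappings are deliberately not used — interleaving replaces them.

Decoding reinserts the s zeros, computes syndromes S₁…S₂ₜ over GF(2^m),
runs Berlekamp–Massey for the error locator and a Chien search for its
roots. Failure is declared when the locator degree exceeds t or disagrees
with the root count, and also when a located error falls in a shortened
coordinate: those positions are known-zero, so an "error" there proves
miscorrection. This makes the decoder bounded-distance with detection,
which underpins the exact tail identity below.

## Pipeline: interleaving and chemistry

S-random interleavers (default spread S = ⌊√(N/2)⌋, the standard
feasibility bound) permute barcode positions so that any two inputs within
distance S land more than S apart; construction is rejection sampling with
restart, falling back to S−1 with a warning if infeasible after the
attempt budget. Interleaving breaks homopolymer runs contributed by
systematic zero prefixes and helps the independence assumption between
symbol errors that both decoders make.

Chemistry screening keeps sequences whose longest homopolymer run is ≤ 2
and whose GC fraction lies in [0.40, 0.60] (defaults; both configurable).
These are conventional values — the published screening settings are not
disclosed, so capacity values M from this package are config-dependent and
reported rather than asserted against printed M values; the barcoding rate
B = log₄(M)/N is asserted from printed (M, N) pairs instead. Exhaustive
screening of all q^k messages is used up to q^k = 1e7; beyond that a
Monte Carlo sample of messages estimates M with a binomial standard error.

## Monte Carlo protocol

Error rates are estimated from T samples of C barcodes drawn with
replacement from the valid set, corrupted, deinterleaved, decoded and
classified. Per-sample proportions p_i with s_i² = p_i(1−p_i)/C are pooled:
mean p̄ = Σp_i/T, pooled SD s_p = √(Σs_i²/T), and standard error
se_p = s_p/√T — algebraically the Bernoulli standard error over the T·C
trials, the only convention whose magnitude is consistent with the
zero-event bound's effective sample size C·T. 95% intervals are p̄ ± 2se_p;
with zero events the one-sided bound 1 − exp(−2/CT) is used (2.00e-9 at
the reference budget T = 100, C = 1e7), and log-scale intervals are
log₁₀(p̄) ± 2·0.434·(se_p/p̄). A decode to a valid codeword different from
the transmitted one counts as undetected even if that codeword was
screened out by chemistry — it is still a wrong identification
(conservative for a false-positive-sensitive metric).

Default desk budget is T = 10, C = 1e5 (overridable up to the reference
budget); estimates of p_e ≥ 1e-4 remain meaningful at the reduced budget,
and the test suite sizes each run so the quantity under test is resolvable.

**BCH tail identity.** For bounded-distance BCH decoding under the QSC,
an identification error occurs *exactly* when the induced bit-error weight
exceeds t, and the weight is E + Binomial(E, 1/3) with E ~ Binomial(N, p_s).
This yields both a closed-form p_e (the package's principal oracle) and a
simulation shortcut that draws only the two binomials, bypassing bit-level
decoding. At (63, 24, t=7, s=13→15) configurations the closed form lands
within ~1σ of the published 1e9-trial estimates; the (63, 30, 6, 21)
configuration is the exception (exact tail ≈ 6.58e-6 vs printed 6.94e-6),
so references use the (63, 24, 7, 15) row.

## Validation of the D score

At full scale the reference experiment correlates D with empirical
log₁₀ p_e across 20 sets × 50 matrices at p_s = 0.01 (reported Spearman
−0.52, p < 0.05; the plain coefficient, not a squared quantity). The
package's reduced-scale replication uses 5 sets × 10 matrices of (24, 5)
codes at p_s = 0.05 with 1e5 trials per selected code, repeated 10 times,
asserting only the sign (median coefficient ≤ 0): at this scale the
magnitude is not stable, but the direction is. Codes with zero observed
errors are excluded with a warning; fewer than 3 usable points or a
constant D vector is an error.

## What the simulations do and do not show

The QSC is an idealisation: real substitution errors are position- and
context-dependent, quality-score-correlated, and accompanied by indels and
ambiguous calls, none of which are modelled (indel-tolerant design is a
different problem requiring edit-distance machinery). Interleaving makes
the iid assumption more defensible but cannot be verified here. Passing
tests therefore demonstrate correctness of the coding machinery and
faithfulness to the stated channel, not platform-level performance.

## Known limitations

* Greedy PEG does not guarantee girth > 4 for every (n, m, j).
* Printed capacity values M are not reproducible without the original
  screening settings; only B-from-printed-(M, N) is checked.
* The BCH weight-shortcut estimates p_e only; resolving p_u vs p_d needs
  the bit-level decode path.
* The demultiplexer assumes the barcode at a fixed offset, ignores quality
  scores (the channel is a scalar-p_s QSC by assumption), and on a
  malformed FASTQ record stops at that record rather than attempting to
  resynchronise the 4-line frame.
* Fields beyond GF(64) (e.g. GF(16) barcode symbols) are out of scope.
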