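# Methods

## Sequence model and preprocessing

Input is a set of n peak sequences of widths t_i over {A,C,G,T,N}. All
characters are upper-cased and anything outside ACGT becomes N; every
k-window containing an N is excluded from counting and from EM offsets
rather than imputed. Optional width standardization (`center_trim`)
symmetrically trims all sequences to the minimum width, dropping the
extra base of an odd trim from the right — appropriate for
summit-centered peaks. Low-complexity/repeat masking and peak calling
are upstream concerns and out of scope.

## Background (negative) model

An order-r Markov chain with pseudocount-smoothed transition
frequencies (default pseudocount 0.01 per (context, symbol) cell,
default r = 2 — a common ChIP-seq convention capturing dinucleotide
bias). The first r positions of a sequence, which lack a full context,
are scored from the marginal mononucleotide distribution. When no
control FASTA is given, a control set is generated by shuffling the
input — either by sampling from the fitted chain (Markov shuffle) or by
an exact k-let-preserving Eulerian-path shuffle (random last-edge
arborescence, then random edge orders) — and the background is fitted
to that control. A supplied control file takes precedence.

## The counting trie

The SMT is a trie over fixed-width k-mers stored as a growable ν×6
int64 matrix: columns 1–4 are child pointers (0 = absent), column 5 the
count and column 6 the numeric code (2 bits per base, leftmost base
most significant). The matrix over-allocates rows geometrically so node
creation is amortized O(1); ν is tracked separately. Address lists —
(sequence index, 0-based offset) pairs, windows half-open [u, u+k) —
live in an auxiliary dict keyed by terminal node id, because a single
integer cell cannot hold a list. Counting is forward-strand only. The
2-bit code bounds k at 31 in a 64-bit cell; a warning flags k outside
the practical motif range [5, 35].

`kdive` performs depth-first search with a mismatch budget d_max,
pruning a branch the moment accumulated mismatches exceed the budget;
matches are terminals at depth k with Hamming distance ≤ d_max.
Recursion depth equals k ≤ 31, so the stack is safe. Its average cost
per fragment follows a negative-binomial stopping process: with
per-position mismatch probability p the scan of one fragment ends at
the d-th mismatch after on average d/p comparisons;
`simulate_kdive_cost` estimates this by summing d geometric draws per
replicate.

Occupancy — non-empty child cells over 4ν — averages 0.5 for an
idealized tree with two children per node and falls below that in
practice because branching thins with depth; it is exposed as a
diagnostic.

## Enrichment and seeding

Each stored k-mer w with observed count x out of m scanned windows is
tested one-sided against Binomial(m, P(w|β)), with P(w|β) evaluated
under the background chain; q-values are Benjamini–Hochberg over all
stored k-mers. The choice of a binomial tail test is a design decision
— any calibrated one-sided count test would fit behind the same
operation. Ties sort by q-value, then observed count descending, then
k-mer. Grouping is greedy: the most significant unclaimed k-mer claims
its entire distance-d neighborhood (found via `kdive`), aggregating the
neighborhood's counts; claimed k-mers cannot be re-counted, so
neighborhoods are disjoint and counts are never duplicated. The exact
grouping rule is a documented choice; the trie only guarantees fast
neighborhood retrieval. If nothing is significant at the cutoff the
pipeline falls back to the most frequent k-mer with a warning.

## EM refinement

Each seed k-mer becomes a PWM putting weight 0.7 on the consensus base
per row (must exceed the 0.25 background and leave mass for mutations;
otherwise arbitrary, since EM moves it immediately). The E-step uses
the log-space decomposition described in the README; it is an exact
refactoring of the naive per-offset product, verified to 1e-9 in the
tests, and all arithmetic stays in log space so sequences up to 10^4
bases do not underflow.

Occurrence models: OOPS places exactly one occurrence uniformly over
the m = t − k + 1 offsets; ZOOPS adds an absence component with prior
1 − γ (γ initialized at 0.5 and re-estimated each M-step as the mean
per-sequence presence mass); ANR treats every window as an independent
Bernoulli(γ) occurrence, MEME-style, with γ re-estimated as the mean
window responsibility. The M-step adds a pseudocount (default 0.1) to
each PWM cell before normalizing, keeping all entries positive.

Convergence uses the observed-data log-likelihood: iteration stops when
the increment falls below the tolerance (default 0.001) or at the
iteration cap (default 1000). The likelihood is nondecreasing for
OOPS/ZOOPS (standard EM guarantee; property-tested); ANR's per-window
objective treats overlapping windows as independent, so it is an
approximation and is not covered by the monotonicity guarantee. One
index-range ambiguity was resolved deliberately: windows span exactly k
symbols, positions u..u+k−1.

Reverse-strand scanning is off by default; a discovered PWM can still
be matched to a reference on either strand by the alignment routine.

## Pipeline

read → normalize → background → trie → enrichment → grouping → EM per
seed → rank by final log-likelihood. Defaults: d = 2, ZOOPS, 10 seeds,
q-cutoff 0.001, seed 42; one motif reported. Multi-motif discovery
masks windows with occurrence posterior > 0.5 to N and re-runs — a
conventional extension, flagged experimental, since the core design is
single-motif. A single integer seed drives every stochastic step, so a
fixed configuration is bit-reproducible.

## PWM comparison

Metrics are computed per column and averaged unweighted over aligned
columns: euc = √Σ(a−b)², man = Σ|a−b|, bha = Σ√(aᵢbᵢ),
hell = √(1−bha), sw = 2 − Σ(a−b)², and the Pearson correlation of the
two 4-vectors (defined as 1 for equal constant columns, 0 for unequal
constant ones). Per column, hell² + bha = 1 and sw = 2 − euc² hold
identically. Unequal widths are handled by scanning all offsets of the
query (both strands) with at least `min_overlap` (default 4) columns
of overlap and keeping the placement with maximal mean Bhattacharyya
coefficient — a documented convention, as is the 0.8-per-column
pseudocount applied when normalizing JASPAR count matrices.

## Synthetic data

The planted-motif generator emulates peak-like datasets: background
from a given Markov model (uniform i.i.d. by default), one width-k
consensus implanted per occurrence model (OOPS always; ZOOPS with
probability γ; ANR with a truncated-Poisson count), at uniform
non-overlapping offsets. Each instance mutates exactly j positions,
j ~ Uniform{0..d}, so distance ≤ d is a hard invariant and the implied
column distributions are analytic: consensus mass 1 − d/(2k), the rest
split evenly. Test regimes (e.g. n = 500, t = 100, k = 10, d = 1,
γ = 0.9) are sized so that recovery is expected while the suite stays
fast. The generator does not emulate real peak-length distributions,
chromatin artifacts, repeat content, or composite/multi-motif
structure — passing recovery tests demonstrates correctness of the
machinery, not performance on real ChIP-seq data.

## Known limitations

- Forward-strand counting only; palindromic or strand-balanced motifs
  rely on the EM phase and reference alignment to compensate.
- The binomial enrichment test ignores overlap dependence between
  windows of the same sequence; p-values are approximate.
- ANR's independence approximation over overlapping windows.
- k must be supplied; no automatic width estimation.
- Multi-motif masking is a heuristic extension without joint modeling.
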