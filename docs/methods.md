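# Methods

## Model

SIMILE treats fragmentation as a network of fragmentation paths from
precursor to product ions and assumes that similar structures fragment
similarly. A chemical modification adds or removes fragmentation
reactions; where it does not remove them, original and modified
fragment ions substitute for one another, and the m/z differences
cross-linking such substitutable ions recur with a frequency
proportional to the similarity of their fragmentation paths. Because
the true fragmentation paths are unknown, the method scores fragment
ions by the *average commute time* of a random walk over all pairwise
m/z differences: ions connected by many paths of frequently recurring
differences are similar.

Concretely, for spectra X (m fragments) and Y (n fragments), both
sorted ascending:

- `D = mz ⊗ mz` (outer difference of the concatenated list, row minus
  column): antisymmetric, zero diagonal. The diagonal participates in
  counting like any other entry; the m zero differences of each block
  give the count matrix its heavy diagonal.
- `C`: for an entry in the top m rows, the number of entries of the top
  m×(m+n) block of D within ± tolerance (closed inequality) of its
  value; bottom n rows count within the bottom block. Differences are
  signed — the walk is directional — and every entry matches itself, so
  C ≥ 1 everywhere and the chain below is automatically irreducible and
  aperiodic.
- `T = C / rowsum(C)`: a Markov chain on fragment ions. `p` solves
  `pT = p` (principal left eigenvector, computed by dense
  eigendecomposition of Tᵀ with a power-iteration fallback; round-off
  negatives clipped before renormalizing). A uniformly teleported chain
  `(1−α)T + α/(m+n)`, α = 1e−8, is tried only if the plain solve fails
  to reach residual 1e−8; with C ≥ 1 this is a safeguard, not a normal
  path, and is logged when used.
- `L = P½ (I − T) P^{−½}` (P = diag p), the directed graph Laplacian;
  a vanishing stationary entry (≤ 1e−12) is a degeneracy error naming
  the fragment.
- `S = pinv((L + Lᵀ)/2)`, with singular values below
  `(m+n)·σ_max·1e−12` treated as zero, then explicitly symmetrized.
  S acts as the covariance matrix of the commute-time embedding;
  `S_ii + S_jj − 2 S_ij` is a squared commute distance and must be
  non-negative up to round-off.

## Alignment

The interspectral quadrant S^XY enters a Needleman–Wunsch recurrence
with gap penalty zero and zero boundary conditions. With free gaps the
terminal DP value equals the best total similarity over monotone
matchings (both indices strictly increasing), floored at zero.
Traceback ties prefer diagonal over up over left, which among
co-optimal paths returns the one with the most aligned pairs; only
diagonal moves that strictly increase the DP value are recorded, so
every reported pair has a positive contribution, and the matched-ion
count used by the cutoffs is the number of such pairs. No score
normalization is applied; scores are raw similarity sums.

The score-only fast path grows `E_t(i,j)`, the best chain of at most t
pairs ending at (i,j), by alternating element-wise maxima with rolling
(prefix) maxima of `E_{t−1}` over the strict upper-left rectangle; at
most min(m,n) rounds are needed and the loop exits early when E stops
changing. The same update runs unchanged on a k×m×n stack of permuted
quadrants, which is what makes the permutation test cheap.

## Significance

Null hypothesis: m/z values are exchangeable between the spectra
provided both hypothetical spectra X′ and Y′ remain m/z-ordered. A
draw picks a uniformly random size-m subset of the m+n values for X′
(block sizes are preserved: X′ always has m values, Y′ has n); the
induced index permutation is applied to rows and columns of S
symmetrically and the new top-right m×n quadrant re-scored. After k
draws, `p = max(#{null ≥ observed}/k, 1/k)`.

Ties count as exceedances (≥). This is the standard conservative Monte
Carlo convention and it is load-bearing here: for structureless
spectrum pairs the interspectral quadrant is entirely non-positive, the
observed score is exactly 0 and every permuted score ties it, so ≥
counting yields p = 1 where strict > would yield the floor 1/k — a
guaranteed false positive. The flip side of conservative tie handling
is that *identical* spectra never reach the p-value floor: when every
m/z value is duplicated across the blocks, the ~2^k duplicate-swapping
permutations reproduce the observed score exactly, leaving
p ≈ 2^k/C(2k,k) (about 0.02 for k = 8) rather than 1/k. Both behaviors
are properties of the test definition, not numerical artifacts.

Evaluation is staged, by default 10/100/1000 cumulative draws. After
each stage the next runs only if p at least halved or sits at its
resolution floor 1/k (a floor means the estimate is resolution-limited,
so refinement continues); otherwise evaluation stops early. Null pairs
therefore typically cost 100 draws while promising pairs run to 1000.

Because the test conditions on the data-dependent matrix S (built from
the observed block assignment) rather than re-deriving S per
permutation, null p-values are not exactly uniform; under structureless
nulls the test is maximally conservative (p ≡ 1 for ~96% of uniform
random pairs in our calibration runs, type-I error ≈ 0 at the 0.05
threshold). Real spectra carry recurring chemical m/z differences that
give the null distribution genuine spread.

## Parameters

| parameter | default | meaning |
|---|---|---|
| tolerance | 0.01 Th | half-width of the difference-counting window; suits high-resolution library spectra. 0.5 Da mirrors coarse cosine settings |
| schedule | 10, 100, 1000 | cumulative Monte Carlo stages |
| score_min / p_max / min_matched_ions | 0.7 / 0.05 / 10 | similar-spectra cutoffs, boundaries inclusive |
| networking score_min / p_max | 1.0 / 0.05 | stricter edge cutoffs for networks |
| top_k / max_component | 10 / 100 | mutual top-k edge rule and component cap |
| seed | 0 | global seed; per-pair streams are SHA-256-derived from the sorted id pair so all-vs-all results are traversal-order independent |

The tolerance-window inequality is closed (≤). Merging of near-duplicate
peaks at read time is opt-in (default merge tolerance 0): library
spectra are consumed as published, and no intensity information or
noise filtering enters the core algorithm — intensities are carried
only for interoperability.

Network topology follows the molecular-networking conventions: an edge
survives only if it ranks in the top-k by score at *both* endpoints
(mutual top-k), and oversized components are shrunk by repeatedly
deleting their lowest-scoring edge, ties broken by lexicographic edge
id for determinism. The MCS rubric bins the bond-overlap Jaccard
coefficient `s = N/(N_A + N_B − N)` as [0, 0.35) not similar,
[0.35, 0.45) low, [0.45, 0.7] medium, (0.7, 1] high; the boundary
conventions at 0.35/0.45/0.7 are fixed here since prose rubrics leave
them open.

## Synthetic ground truth

The generator emulates the one structural ingredient the similarity
matrix detects: systematically recurring interspectral m/z differences.
A block molecule is a linear chain of mass blocks; every non-empty
contiguous run yields one fragment (run mass + modifier deltas + adduct
mass), mimicking linear backbone fragmentation and keeping fragment
counts quadratic rather than exponential. Related pairs share a
skeleton and differ by one or two per-block modifier deltas; unrelated
pairs are uniform random m/z lists with a minimum spacing of twice the
counting tolerance so no accidental structure enters.

Defaults, fixed once: 6 blocks drawn uniformly from 60–180 Da (21
fragments per spectrum — fragment-rich enough to clear the 10
matched-ion cutoff, comparable to library spectra of mid-sized
metabolites), protonated adduct (+1.007276 Da), modifiers drawn from
common elemental-change masses (CH₂ 14.016, O 15.995, H₂ 2.016, C₂H₄
28.031, H₂O 18.011, CH₂O 30.011). Null spectra default to the same
fragment count over 100–900 Th so the two arms are size-matched.

What the generator does *not* model: intensities, chemically realistic
fragmentation (rearrangements, bond-energy preferences), shared
chemistry between "unrelated" molecules, instrument noise, or adducts
beyond protonation. Passing tests therefore demonstrate that the
implementation detects recurring-difference structure and controls the
false-positive rate under a structureless null — not that it matches
any particular performance level on real spectral libraries.

## Problem sizes and numerical choices

The test suite and acceptance script use 200 brute-force-checked random
pairs (fragment counts ≤ 6), 500 exhaustively enumerated alignment
instances (≤ 5×5), 50+50 related/unrelated pairs and 1000 null pairs
for calibration — sizes at which the exhaustive oracles are exact and
the full run completes in seconds. Stage-wise agreement between the
vectorized pipeline and nested-loop references is ~1e−15; tolerances in
tests are set an order of magnitude looser (1e−8 matrices, 1e−9
alignment scores, 1e−6 Moore–Penrose identities).

Known limitations: single-charge protonation/deprotonation only; no
precursor neutral-loss augmentation of the counting step (pairs whose
best correspondence is a precursor-shift path can score poorly); p-value
resolution is bounded by 1/1000 under the default schedule; compute
time grows as O(k·n·m) with permutations k and can be dominated by
well-aligned spectra that defeat early stopping.
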