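# Methods

## Model

For a fixed target secondary structure `s0` of length `n` (well-nested,
minimum hairpin size θ = 3), the dual partition function is

    Z*(s0) = Σ_{a compatible with s0} exp(−E(a, s0) / RT),

with `E(a, s0)` the additive Turner nearest-neighbor loop energy of sequence
`a` folded into `s0`. Because `s0` is fixed, `Z*` factors over the loop
decomposition of `s0`: for every base pair `(i, j)`, taken in the
enclosed-before-enclosing total order (sorted by closing position ascending,
opening position descending), the six values `Z*(i, j; X, Y)` are assembled
from the directly enclosed pairs, and the exterior loop assembles `Z*(s0)`.

Every loop is compiled into a *plan*: an explicit enumeration of the joint
nucleotide configurations whose identity affects the loop energy — inner
pair instantiations, mismatch and flank nucleotides, dangling nucleotides —
plus a block of energetically free positions that contribute only a counting
factor (the product of allowed-set sizes under IUPAC constraints). The same
plans drive the plain forward pass, the GC-resolved forward pass, stochastic
backtracking and, indirectly, the standalone per-sequence energy evaluator,
so the four views of the model cannot drift apart; the test suite verifies
`Σ_a exp(−E(a, s0)/RT) = Z*(s0)` by full enumeration on randomized
constrained targets to 1e−9 relative error in both dangle modes.

### Loop energy conventions

The packaged tables are the Turner-2004 free energies at 310.15 K
(kcal/mol, plain-text block format under `src/dualpf/data/`, with the 2×2
interior-loop table in a companion file). Conventions, each validated
against the published per-pair table for the 28-nt worked example in the
test suite:

- **Hairpins**: initiation by size (Jacobson–Stockmayer extrapolation
  `E(30) + 1.75 RT ln(size/30)` beyond 30) plus a terminal mismatch for
  sizes ≥ 4. Tabulated special tri-/tetra-/hexaloops *replace* the whole
  loop term (initiation + mismatch) with their tabulated total energy;
  non-special triloops carry the terminal AU/GU penalty instead of a
  mismatch. Special-size hairpin interiors (3, 4 and 6 nt) are enumerated
  exhaustively in the plan, so GC resolution and sampling treat special
  loops exactly.
- **Stacks**: `stack(X, Y, U, V)` for outer pair XY on inner pair UV.
- **Bulges**: initiation by size; size-1 bulges additionally stack the
  flanking pairs across the bulge and carry no terminal penalty (standard
  convention; a `literal_size1_bulge` switch restores the plain
  initiation-plus-penalty rule). Bulges of size ≥ 2 add the terminal
  penalty of the outer closing pair.
- **Interior loops**: dedicated 1×1 / 1×2 / 2×1 / 2×2 lookup tables by
  default (`special_internal=True`); all other sizes use initiation by
  total size, the asymmetry penalty `min(asym·|r1−r2|, maxAsym)`, and two
  terminal mismatches, with flank positions shared between the closing
  pairs when one side has a single nucleotide. The lookup-table default is
  what reproduces the worked example's 1×1 row; the generic rule remains
  available behind the switch.
- **Multiloops**: affine penalty `a + b(k+1) + cℓ` for `k` branches and `ℓ`
  unpaired positions, plus the terminal penalty of the closing pair.
- **Terminal AU/GU penalty placement**: every helix-end pair whose outside
  neighbor is a multiloop or the exterior loop carries one indicator-gated
  terminal penalty in its own row; the pair closing a multiloop carries the
  plain penalty as well (so a multiloop-closing pair that is also an
  exterior helix end pays 1.0 kcal/mol total for an AU-type
  instantiation, which the worked example's multiloop row exhibits).
- **Dangles**: d0 ignores dangling ends. d2 adds a 5' and a 3' dangle term
  to every helix of a multiloop or exterior loop (and the two inner flanks
  of a multiloop's closing pair, read on the reversed pair). Helices whose
  dangle positions overlap — gap ≤ 2 between consecutive helix ends, or a
  component starting/ending within two positions of the multiloop closing
  pair — are merged transitively into maximal adjacency groups and
  instantiated jointly; a dangle position coinciding with a paired position
  takes that position's nucleotide, and two coinciding dangles share one
  nucleotide. A group with `h` pairs stores at most `6^h · 4^(h+1)`
  configurations; a guard refuses groups above 10^7 configurations (d2 cost
  is exponential in the branching of the largest multiloop; d0 is linear).

### Scaling

Values are stored as `Z† = Z*/C^span` with a per-nucleotide scaling constant
`C` (default `exp(−⟨stack⟩/(2RT))` ≈ 5, overridable). Each loop multiplies
by `C^−owned` for the positions it contributes, making the recursion exact;
`ln Z* = ln Z† + n ln C` recovers the unscaled log, and `C` cancels from
every sampling ratio (verified: identical sample streams and log values
across `C ∈ {1, 2.5, 5}`).

## GC resolution

`Z*(i, j; X, Y; α)` restricts each table entry to sequences with exactly `α`
G/C nucleotides in `[i, j]` (α includes the closing pair). Pair codes shift
by γ(XY) ∈ {0, 1, 2}; fixed configuration nucleotides shift by their own GC
count; inner-pair arrays combine by convolution; free blocks contribute a
constrained counting array computed position-by-position (collapsing to
`binom(m, k)·2^m` when unconstrained). Tabulated special hairpin loops are
enumerated with their exact GC content — a subtlety that a closed-form
"subtract the number of special loops from the binomial" shortcut would get
wrong — which is what makes the marginalization identity
`Σ_k Z*(s0, k) = Z*(s0)` hold exactly (tested to 1e−9, and per-k against a
GC-filtered enumeration oracle).

## Sampling

Stochastic backtracking from the exterior loop inward, mirroring the forward
pass: each decision is a roulette wheel over stored conditional masses, so
every sequence is drawn with exactly `p*(a)`. Roulette wheels scan outcomes
in a fixed canonical order (pairs AU, CG, GC, UA, GU, UG; nucleotides
A, C, G, U; GC budgets ascending), making runs bit-reproducible from the
64-bit seed. With a GC target `k`, loop-level GC budgets are drawn first by
suffix-convolution roulette over the GC-resolved factor arrays, then
configurations and nucleotides inside the chosen budgets; free-position
blocks place G/C uniformly over the count-weighted arrangements
(sequentially, with DP-backed conditionals, which degenerates to the
binomial rule when unconstrained). Every returned sequence has exactly `k`
G/C nucleotides.

Exactness is verified by chi-square goodness of fit against the exact
enumerated distribution on fully enumerable targets (unconditioned, and
GC-conditioned against the GC-filtered distribution). On the 7-mer
benchmark with 6·4^5 = 6144 compatible sequences, 200 000 draws give a
chi-square p ≈ 0.97 and a half-L1 total-variation statistic of ≈ 0.052 —
numerically indistinguishable from the ≈ 0.053 a *perfect* multinomial
sampler measures at that sample size, which is the correct yardstick for a
TV statistic over thousands of cells. MFE filtering (resampling until the
sampled sequence's MFE structure equals the target) is a post-processing
convenience over a pluggable folding backend, not part of the distribution
contract.

## Dual thermodynamics

The table temperature `T0` fixes the energies; the formal temperature `T`
appears only in the Boltzmann exponent. `⟨E*⟩ = R T0² ∂/∂T ln Z*` is a
central finite difference in `T` (default step h = 0.01 K; one-sided
differences available as diagnostics; a guard rejects steps below 1e−7 K).
`G* = −RT ln Z*`, `S* = (⟨E*⟩ − G*)/T0` (definitional, holds to machine
precision), and the heat capacity is exposed as the central difference of
`⟨E*⟩` in `T` — its defining formula is this package's own documented
choice, as no reference formula exists for the dual ensemble. The
finite-difference `⟨E*⟩` matches the enumerated Boltzmann mean to 1e−3
relative (typically 1e−9) and decomposes exactly over GC classes.

## Metrics and folding backends

Ensemble metrics operate on base-pair probability matrices `p_ij`:
ensemble diversity `d0 = 2 Σ_{i<j} p_ij(1−p_ij)` (the expected base-pair
distance of two independent ensemble draws), plasticity `d0/(n/2)`,
ensemble distance `D_V = sqrt(Σ (p_ij(a) − p_ij(b))²)` (equal to the
expected cross distance minus the mean diversity; a true metric — symmetry
and the triangle inequality are property-tested), the asymmetric `d1`, and
mutational robustness `1 − ⟨D_V⟩/n` (default) or `1 − ⟨d1⟩/(n/2)` over all
`3n` single-point mutants. Neutrality compares mutant MFE structures to the
wild type. The design battery (ensemble defect, expected base-pair distance
to target, proportion of native contacts, positional entropy over the
pairing-state distribution with natural logarithms, length-normalized
diversity) is computed from `p_ij`, the unpaired probabilities
`q_i = 1 − Σ_j p_ij`, and the MFE structure.

Two backends satisfy the folding interface: an adapter to the ViennaRNA
Python bindings (used when importable), and a bundled exact enumeration
backend that enumerates every secondary structure of a short sequence
(θ = 3, canonical pairs), scores each with this package's energy evaluator,
and derives MFE and `p_ij` exactly — a deliberately simple, provably correct
oracle, practical to ~20 nt and used to validate the metric pipeline without
any external engine. MFE ties break toward the lexicographically smallest
dot-bracket string.

## Synthetic data

Test fixtures are generated programmatically: `generate_random_structure`
draws reproducible well-nested targets (rejection sampling of non-crossing
pairs with θ = 3), and the test campaigns attach random IUPAC constraints
biased toward two-letter codes so that the compatible-sequence space stays
exhaustively enumerable (≤ ~10^4 sequences per instance; 50 instances per
campaign, lengths 5–14 plus hand-picked multiloop/bulge/interior shapes that
random draws at such lengths rarely produce). These fixtures exercise every
recursion case, but they are small: passing them demonstrates correctness of
the algorithmics, not biological realism of designed sequences at natural
RNA lengths (70–400 nt), where only the scaling machinery and the group-size
guard are additionally stressed.

## Numerical choices and limitations

- Energies are kept as kcal/mol floats; Boltzmann factors of infinite
  (forbidden) entries are 0.
- Degenerate inputs: an open chain has `Z* = 4^n` times unity factors; fully
  constrained targets collapse to a single sequence with `ln p* = 0`;
  infeasible constraints (an empty allowed-pair set) yield `Z* = 0` with a
  diagnostic naming the first offending pair and `ln Z* = −∞`.
- Enthalpy tables and rescaling of free energies to arbitrary temperatures
  are out of scope; the CLI's temperature flag moves the formal temperature
  only. Coaxial stacking, pseudoknots, multi-strand complexes and d1/d3
  dangle models are not modeled.
- The brute-force oracles refuse enumerations beyond ~2·10^6 sequences; the
  enumeration folding backend refuses beyond 2·10^5 structures.
- Lonely base pairs are allowed in targets.
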