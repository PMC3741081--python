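# Methods

## The computational model

All problems in this package compute *inside* properties β<sub>i,j</sub>
indexed by the ||s|| = n+1 positions of a string (a position sits between
two characters; s[i:j] is the substring between positions i and j), and
optionally *outside* properties α<sub>i,j</sub> of the residual instance —
the prefix s[0:i] together with the suffix s[j:n].  Values live in a
matrix whose lower triangle (j < i, no valid substring) is fixed at the
algebra's zero φ.

A *multiplication variant* is a tuple (domain, ⊗, ⊕, φ) with ⊕ associative
and φ both neutral for ⊕ and absorbing for ⊗.  Nothing else is assumed:
distributivity is never used, and ⊕ commutativity is required only where a
kernel reorders its accumulation and in the multiple-string reduction (the
naive kernel folds the inner index strictly left to right, so the contract
supports non-commutative ⊕; all shipped variants — dot, min-plus,
max-plus, boolean — are commutative).

## The divide-and-conquer engines

The inside engine computes a block B<sub>I,J</sub> of the property
matrices under the invariant: every cell of the square spanned by
intervals I and J is finalized except the block itself, whose
accumulators hold exactly the split contributions of points strictly
between I and J (μ<sub>I,J</sub> = β<sub>I,(I,J)</sub> ⊗
β<sub>(I,J),J</sub>).  A block is halved along its longer side; after the
first half is finished, one *bridging* matrix multiplication against the
half-interval between the siblings re-establishes the invariant for the
second half.  The bridge interval is the first sibling half when
max(I) < min(J) and empty otherwise (diagonal blocks need no bridge).
Accumulation order follows the recursion as written — existing ⊕ new for
the vertical case, new ⊕ existing for the horizontal one — preserving the
left-to-right split order for non-commutative ⊕.

The outside engine mirrors this from the outside in: its invariant covers
the region of rows [0, max(I)] and columns [min(J), n], its recursion
computes the right/top halves first (outermost residuals first), and its
bridging products transpose the inside operand, because the split index
runs over rows of β there.  Unlike the inside case the bridge interval is
always exactly the sibling half: invalid sibling cells hold φ and are
absorbed.  Each outside property declares at most one split form — prefix
(over β<sup>kβ</sup> and α<sup>kα</sup>, split index below i) or suffix
(split index above j) — or none, in which case no bridging is performed
for it.

Blocks whose sides are at most the recursion cutoff (default 32, a pure
constant-factor knob; results are cutoff-invariant by test) are finished
by classical per-cell loops: columns ascending / rows descending inside,
columns descending / rows ascending outside, so that every readable value
is finalized before it is read.  The per-cell loop adds exactly the split
points the bridges did not cover — q ≤ max(I) or q ≥ min(J) within (i, j)
— which handles diagonal and off-diagonal blocks uniformly.

A problem spec contributes K property sets, a list of split-term property
pairs per set (a *list* rather than a single pair so that CKY's many rules
per nonterminal each get their own accumulator slot; the single-slot case
is the common one), and a finalize callback that may read strict
sub-ranges (inside), strict super-ranges (outside), same-cell values of
earlier property sets, and — outside only — any inside value.
Out-of-range reads return φ, which makes boundary recurrences total
without engine special-cases.  `verify=True` checks the full invariant at
every recursive call against a freshly computed classical result (N ≤ 128).

The classical orders double as independent oracles; they share the spec
plumbing but none of the recursion.  The enumeration and triple-loop
oracles in `valiantdp.oracles` share nothing at all with the engines and
carry hard size guards (enumeration ≤ 14 bases, oracle CKY ≤ 24 tokens,
lattice recursion ≤ 2500 positions) — an oracle that silently truncated
would invalidate every comparison built on it.

## Kernels

Defaults: vendor dense multiply for dot; 0/1 integer multiply plus
threshold for boolean; a blocked broadcast kernel (≤ ~32 MiB intermediate)
for max/min-plus, with φ = ±inf as genuine IEEE infinities so that
φ-absorption is native arithmetic.  A registered kernel declares whether
it reorders accumulation; reordering kernels are refused for
non-commutative ⊕.  The Strassen kernel recurses on halved blocks
(zero-padding odd dimensions by one per level) down to a leaf threshold of
8, counting scalar multiplications exactly at its leaves; in counting
mode the engine also counts the per-cell split work below the cutoff, so
the reported totals cover the whole inside phase.  At n = 128 → 256 the
Strassen/naive count ratio for the partition-function inside phase drops
from ≈0.92 to ≈0.83 — the count-level signature of the sub-cubic bound
that a theoretical fast tropical multiply would sharpen further (such
algorithms, and any claim about wall-clock speed, are out of scope).

## Problem instantiations

**Base-pair maximization** (max-plus, K = 1): β[i,j] = max(β[i+1,j−1] +
δ(i,j−1), μ[i,j]) with δ = 1 for a complementary pair (A-U, C-G, G-U) and
β = 0 for substrings of length ≤ 1.  Pairs between adjacent bases are
allowed — the recurrence is taken exactly as stated; real thermodynamic
folders impose a ≥3-base hairpin loop that this model does not.  The
traceback prefers pairing i with j−1 when that attains the optimum and
otherwise splits at the smallest optimal q, giving a deterministic
folding; a split achieving the optimum always exists when the pair case
does not, because β[i,j−1] ≥ β[i+1,j−1].

**Partition function** (dot, K = 2): weight e^|F| per folding.
`paired[i,j]` (foldings of s[i:j] containing the pair i·(j−1)) equals
δ·`all[i+1,j−1]` with δ ∈ {e, 0}; `all[i,j]` = μ + `all[i,j−1]` +
`paired[i,j]`, where μ splits on the partner of base j−1.  Z = `all[0,n]`
≥ 1 always (the empty folding), with equality iff no complementary pair
exists.  Z grows like e^(n/2), so float64 overflows near n ≈ 1400; the
intended regime (n ≤ a few hundred) is far below that.

**Pair probabilities** (outside, K = 4): `pair_left` (residual foldings
pairing j leftward across the excised gap to i−1), `pair_prefix`
(prefix-form split: j paired into the prefix), `pair_suffix` (suffix-form
split: j paired into the suffix), and `all_out` (residual partition
function, the sum of the three pairing terms plus `all_out[i,j+1]` for j
unpaired).  γ[i,j] = `paired[i,j]`·`all_out[i,j]` is the ensemble weight
of foldings containing i·(j−1), and P(a·b) = γ[a,b+1]/Z.  Boundary
analysis: at i = 0 every term is already total under φ-valued
out-of-range reads (empty sums, δ over a nonexistent character), and the
recurrence reproduces `all_out[0,j]` = `all[j,n]` as a theorem.  Only
j = n needs code: no character j exists, so all pairing terms vanish and
the residual is the bare prefix, `all_out[i,n]` = `all[0,i]` — one
explicit case in the finalize callback.

**CFG / WCFG parsing**: one property set per nonterminal; each binary rule
A → B C is one split slot (β<sup>B</sup>, β<sup>C</sup>); terminal rules
seed spans of one token.  Boolean recognition ORs the slots; the weighted
variant takes max over slots of μ + rule weight, with parse weight defined
as the sum over *all* rule applications, terminal rules included (the
standard weighted-CKY convention, fixed explicitly so the oracles match).
The empty sentence is never derivable (no ε-rules in CNF as used here).

**Simultaneous alignment and folding**: positions are per-string index
tuples; one alignment column spans a *local increment* (each index
advances by 0 or 1, at least one by 1).  The score sums a column score ρ
and a column-pair score τ over the folding of the alignment.  The
recurrence takes the best of: first and last columns paired (max over
local increments of X and local decrements of Y of the inner score plus
ρ + ρ + τ, O(2^{2m}) candidates evaluated in the finalize callback);
a split strictly between X and Y (the engine's μ); and — necessary for
completeness — the single-column alignment ρ(X..Y) when Y is a local
increment of X, since the paired case needs two columns and the split
case an interior position, so neither can produce the one-column optimum
that anchors the recursion just above the base case β[X,X] = 0.  Every
multi-column alignment decomposes into one of the first two cases (split
at the partner of the last column, or before an unpaired last column).

The lattice is linearized mixed-radix with string 0 least significant;
unequal string lengths are handled directly (per-string radices), and
empty strings degenerate to radix 1.  h is monotone, every position
strictly between X and Y lands strictly between h(X) and h(Y), and any
linear split index whose decoded position is incomparable with X or Y has
a masked φ factor — so the linear-order accumulation equals the lattice
sum, provided ⊕ is commutative (enforced).  Dense ||S||×||S|| matrices
cap the lattice at 4096 positions by default (override `size_cap`
knowingly; m = 3 blows up fast).

Default scoring for CLI runs (ρ per string pair: +1 match, −1 mismatch,
−2 residue-against-gap; τ per string: +2 complementary column pair, −3
gap or non-pairing; all six configurable): a deliberately simple,
documented scheme — Sankoff-style tools use richer models.  Tests use the
single-string reduction (ρ ≡ 0, τ = 1 for a complementary pair else −∞),
under which the score provably equals the maximum pair count.

## Synthetic data

Generators draw uniform random RNA bases, uniform random CNF rules (every
nonterminal gets at least one terminal rule so that derivations of any
span length can bottom out and nonempty languages are common), and random
string sets, all deterministic under their seeds.  The suites they feed
(lengths 0–64 for inside, 1–48 for outside, ≤ 12 for enumeration, 2×(≤6)
lattices for alignment-folding, ≤ 5 nonterminals / ≤ 10 rules / ≤ 20
tokens for grammars) exercise every code path of the engines — odd sizes,
empty strings, unparseable sentences — at sizes where the independent
oracles are exact.  What they do not emulate: base-composition bias,
thermodynamically realistic energies, natural-language rule distributions.
Passing these suites shows the evaluation orders are equivalent and the
recurrences match their definitions — statements about algorithmic
correctness, which is the claim under test, not about biological accuracy
of the simplified models.

## Numerical choices and limitations

* Comparisons between evaluation orders are exact for boolean and for
  max-plus on integer-valued scores; dot-product comparisons use 1e-9
  relative tolerance with an absolute floor scaled to the largest finite
  reference magnitude, since different summation orders legitimately
  differ in the last bits and can cancel near zero.
* Engine results are invariant to recursion cutoff (1, 2, 8, 32) and to
  kernel choice; this is tested rather than assumed.
* The per-cell finalize work is spot-checked to be constant-bounded for
  the shipped specs via the operation counter (an asymptotic sublinearity
  claim cannot be asserted from finite runs; this is the weaker,
  executable check).
* One multiplication variant per problem spec; per-property-set variants
  are a straightforward extension not needed by any shipped problem.
* No outside variant of the multiple-string engine (none of the shipped
  problems needs one), no traceback beyond base-pair maximization, no
  sparse matrices, no parallelism.
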