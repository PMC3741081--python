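"""RNA folding instantiations: pair maximization, partition function, pair
probabilities.

A *folding* (secondary structure) of an RNA string is a nested set of base
pairs; complementary pairs are A-U, C-G and the G-U wobble.  Three problems
over this model are wired into the generic engines:

* maximum number of complementary pairs over all foldings (tropical
  max-plus recurrence);
* a simplified Boltzmann ensemble in which a folding with ``|F|`` pairs has
  weight ``e^|F|``: the partition function ``Z`` sums these weights over all
  foldings (dot-product recurrence, two mutually recursive property sets);
* base-pair probabilities ``P(a . b)`` as weight fractions, via four outside
  property sets over the partition-function inside matrices.

The weight model is deliberately minimal — one multiplicative factor ``e``
per pair, no loop energies — so that every quantity is checkable against
exhaustive enumeration.  Pairs between adjacent bases are allowed, matching
the recurrences exactly; thermodynamic folders impose a minimum hairpin loop
that this model does not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np

from ..algebra import DOT, MAX_PLUS
from ..inside import InsideProblemSpec, run_inside, run_inside_classical
from ..outside import PREFIX, SUFFIX, OutsideMuSpec, OutsideProblemSpec, run_outside

__all__ = [
    "RNA_ALPHABET",
    "COMPLEMENTARY_PAIRS",
    "complementary",
    "normalize_rna",
    "Folding",
    "bp_max_spec",
    "fold_max_pairs",
    "traceback_max_pairs",
    "partition_spec",
    "partition_function",
    "bpp_outside_spec",
    "base_pair_probabilities",
]

RNA_ALPHABET = "ACGU"
COMPLEMENTARY_PAIRS = frozenset(
    {frozenset("AU"), frozenset("CG"), frozenset("GU")}
)


def complementary(x: str, y: str) -> bool:
    """True iff x and y can form a base pair (A-U, C-G, or G-U)."""
    for b in (x, y):
        if b not in RNA_ALPHABET:
            raise ValueError(f"not an RNA base: {b!r}")
    return frozenset((x, y)) in COMPLEMENTARY_PAIRS


def normalize_rna(s: str) -> str:
    """Uppercase, map T to U, reject anything outside {A, C, G, U}."""
    out = s.upper().replace("T", "U")
    for ch in out:
        if ch not in RNA_ALPHABET:
            raise ValueError(f"not an RNA residue: {ch!r}")
    return out


@dataclass(frozen=True)
class Folding:
    """A nested set of index pairs a < b over a string of length n."""

    pairs: FrozenSet[Tuple[int, int]]
    n: int

    def __init__(self, pairs, n: int):
        pairs = frozenset((int(a), int(b)) for a, b in pairs)
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "n", int(n))
        for a, b in pairs:
            if not 0 <= a < b < self.n:
                raise ValueError(f"pair {a}.{b} out of range for length {self.n}")
        ordered = sorted(pairs)
        for ai, (a, b) in enumerate(ordered):
            for c, d in ordered[ai + 1 :]:
                if c > b:
                    break
                # a <= c by ordering; nestedness forbids a <= c <= b <= d
                if c <= b <= d and (a, b) != (c, d):
                    raise ValueError(f"crossing pairs {a}.{b} and {c}.{d}")

    def __len__(self) -> int:
        return len(self.pairs)

    def count_complementary(self, s: str) -> int:
        return sum(1 for a, b in self.pairs if complementary(s[a], s[b]))


# ---------------------------------------------------------------------------
# base-pair maximization (max-plus, K = 1)


def bp_max_spec(s: str) -> InsideProblemSpec:
    """Inside spec for the maximum-pairs recurrence.

    beta[i, j] = max( beta[i+1, j-1] + delta(i, j-1),
                      max_{q in (i, j)} beta[i, q] + beta[q, j] )
    with beta = 0 on empty and single-character substrings; delta is 1 for a
    complementary pair and 0 otherwise.
    """
    s = normalize_rna(s)

    def finalize(i, j, mu, beta):
        if j - i < 2:
            return (0.0,)
        delta = 1.0 if complementary(s[i], s[j - 1]) else 0.0
        paired = beta(0, i + 1, j - 1) + delta
        return (max(paired, mu[0][0]),)

    return InsideProblemSpec(
        K=1,
        property_names=("max_pairs",),
        variant=MAX_PLUS,
        mu_specs=[[(0, 0)]],
        finalize=finalize,
    )


def fold_max_pairs(
    s: str, kernel=None, cutoff: int = 32, classical: bool = False, return_matrix: bool = False
):
    """Maximum number of complementary base pairs over all foldings of s."""
    s = normalize_rna(s)
    spec = bp_max_spec(s)
    N = len(s) + 1
    runner = run_inside_classical if classical else run_inside
    kwargs = {} if classical else {"kernel": kernel, "cutoff": cutoff}
    B = runner(N, spec, **kwargs)[0]
    best = int(B[0, N - 1])
    return (best, B) if return_matrix else best


def traceback_max_pairs(s: str, B: Optional[np.ndarray] = None) -> Folding:
    """Recover one optimal folding from the filled pair-maximization matrix.

    Deterministic tie-break: pair positions i and j-1 whenever that attains
    the optimum; otherwise split at the smallest optimal q.
    """
    s = normalize_rna(s)
    n = len(s)
    if B is None:
        _, B = fold_max_pairs(s, return_matrix=True)
    pairs = []
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < 2:
            continue
        if complementary(s[i], s[j - 1]) and B[i, j] == B[i + 1, j - 1] + 1:
            pairs.append((i, j - 1))
            stack.append((i + 1, j - 1))
            continue
        for q in range(i + 1, j):
            if B[i, q] + B[q, j] == B[i, j]:
                stack.append((i, q))
                stack.append((q, j))
                break
        else:
            raise ValueError(f"inconsistent matrix at cell ({i}, {j})")
    folding = Folding(pairs, n)
    if folding.count_complementary(s) != int(B[0, n]):
        raise ValueError("traceback failed to reproduce the optimal score")
    return folding


# ---------------------------------------------------------------------------
# partition function (dot product, K = 2)

# property indices in the inside spec
PAIRED, ALL = 0, 1


def partition_spec(s: str) -> InsideProblemSpec:
    """Inside spec for the simplified Boltzmann ensemble.

    Two mutually recursive property sets over the dot-product variant:

    * ``paired[i, j]``: sum of weights of foldings of s[i:j] containing the
      pair i.(j-1); equals delta * all[i+1, j-1] with delta = e for a
      complementary pair, else 0.
    * ``all[i, j]``: the partition function of s[i:j];
      all = mu + all[i, j-1] + paired[i, j], where
      mu[i, j] = sum_{q in (i, j)} all[i, q] * paired[q, j] covers foldings
      whose last base pairs inside the substring.

    Base cases: paired = 0 and all = 1 for substrings of length <= 1 (the
    empty folding has weight e^0 = 1).
    """
    s = normalize_rna(s)
    e = math.e

    def finalize(i, j, mu, beta):
        if j - i < 2:
            return (0.0, 1.0)
        delta = e if complementary(s[i], s[j - 1]) else 0.0
        paired = delta * beta(ALL, i + 1, j - 1)
        total = mu[ALL][0] + beta(ALL, i, j - 1) + paired
        return (paired, total)

    return InsideProblemSpec(
        K=2,
        property_names=("paired", "all"),
        variant=DOT,
        mu_specs=[[], [(ALL, PAIRED)]],
        finalize=finalize,
    )


def partition_function(
    s: str, kernel=None, cutoff: int = 32, classical: bool = False
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Inside matrices (paired, all) and the partition function Z of s.

    Z grows like e^(n/2) in the worst case, so float64 overflows around a
    few hundred bases; a warning-free exact range is all this simplified
    model aims for.
    """
    s = normalize_rna(s)
    spec = partition_spec(s)
    N = len(s) + 1
    runner = run_inside_classical if classical else run_inside
    kwargs = {} if classical else {"kernel": kernel, "cutoff": cutoff}
    B = runner(N, spec, **kwargs)
    return B[PAIRED], B[ALL], float(B[ALL][0, N - 1])


# outside property indices
A_PAIR_LEFT, A_PAIR_PREFIX, A_PAIR_SUFFIX, A_ALL = 0, 1, 2, 3


def bpp_outside_spec(s: str) -> OutsideProblemSpec:
    """Outside spec computing residual-ensemble weights for pair probabilities.

    Four property sets over the residual instance (prefix s[0:i] plus suffix
    s[j:n]), all sums of folding weights of that residual:

    * ``pair_left[i, j]``: foldings containing the pair (i-1).j;
      delta(i-1, j) * all_out[i-1, j+1].
    * ``pair_prefix[i, j]``: foldings pairing j to some q-1 with q < i;
      prefix-form split over (all, pair_left).
    * ``pair_suffix[i, j]``: foldings pairing j to some q-1 with q > j;
      suffix-form split over (all_out, paired).
    * ``all_out[i, j]``: the residual partition function;
      all_out[i, j+1] + the three pairing terms (j unpaired, or paired
      leftward across the gap, into the prefix, or into the suffix).

    At j = n no character j exists, so every pairing term vanishes and the
    residual is the bare prefix: all_out[i, n] = all[0, i], an inside value.
    All other boundary cells are covered by phi-valued out-of-range reads.
    """
    s = normalize_rna(s)
    n = len(s)
    e = math.e

    def delta(a, b):
        if 0 <= a < n and 0 <= b < n and complementary(s[a], s[b]):
            return e
        return 0.0

    def finalize(i, j, mu, alpha, beta):
        if j == n:
            return (0.0, 0.0, 0.0, beta(ALL, 0, i))
        a1 = delta(i - 1, j) * alpha(A_ALL, i - 1, j + 1)
        a2 = mu[A_PAIR_PREFIX]
        a3 = mu[A_PAIR_SUFFIX]
        a4 = alpha(A_ALL, i, j + 1) + a1 + a2 + a3
        return (a1, a2, a3, a4)

    return OutsideProblemSpec(
        K=4,
        property_names=("pair_left", "pair_prefix", "pair_suffix", "all_out"),
        variant=DOT,
        mu_specs=[
            None,
            OutsideMuSpec(PREFIX, k_beta=ALL, k_alpha=A_PAIR_LEFT),
            OutsideMuSpec(SUFFIX, k_beta=PAIRED, k_alpha=A_ALL),
            None,
        ],
        finalize=finalize,
    )


def base_pair_probabilities(
    s: str, kernel=None, cutoff: int = 32, classical: bool = False
) -> Dict[str, object]:
    """Probability of every base pair under the e^|F| ensemble.

    Returns a dict with the n x n probability matrix ``P`` (entry [a, b] is
    the probability that a spontaneous folding contains a.b, for a < b), the
    ``gamma`` matrix of pair-constrained ensemble weights, ``Z``, and the
    inside/outside matrices.
    """
    from ..outside import run_outside_classical

    s = normalize_rna(s)
    n = len(s)
    N = n + 1
    paired, allm, Z = partition_function(s, kernel=kernel, cutoff=cutoff, classical=classical)
    assert Z >= 1.0, "the empty folding always contributes weight 1"
    spec = bpp_outside_spec(s)
    if classical:
        A = run_outside_classical([paired, allm], spec)
    else:
        A = run_outside([paired, allm], spec, kernel=kernel, cutoff=cutoff)
    gamma = paired * A[A_ALL]
    P = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            P[a, b] = gamma[a, b + 1] / Z
    return {
        "P": P,
        "gamma": gamma,
        "Z": Z,
        "inside": (paired, allm),
        "outside": A,
    }
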