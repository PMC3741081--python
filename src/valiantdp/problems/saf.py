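"""Simultaneous alignment and folding of multiple RNA strings (Sankoff-style).

An alignment of m RNA strings is a set of equal-length gapped strings whose
gap-free projections recover the inputs; a folding of the alignment pairs
alignment columns non-crossingly.  The score of an alignment-with-folding is

    sum_r rho(column r)  +  sum_{a.b in folding} tau(column a, column b)

for a column score rho and a column-pair score tau, both pure functions of
the column contents.

On the position lattice, one alignment column spans a *local increment*:
each string index advances by 0 or 1 (gap or residue), at least one by 1.
The best score beta[X, Y] over sub-instances satisfies

    beta[X, Y] = max( first and last columns paired:
                          max_{X' in inc(X), Y' in dec(Y)}
                              beta[X', Y'] + rho(X..X') + rho(Y'..Y)
                                           + tau(X..X', Y'..Y),
                      split:  max_{Q in (X, Y)} beta[X, Q] + beta[Q, Y],
                      single column (Y in inc(X)):  rho(X..Y) )

with beta[X, X] = 0.  The single-column candidate is required for
completeness: the paired case needs at least two columns and the split case
a position strictly between X and Y, so neither can produce the one-column
alignment that is optimal on the smallest sub-instances; every alignment of
two or more columns decomposes into one of the first two cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

from ..algebra import MAX_PLUS
from ..inside import InsideProblemSpec
from ..multistring import (
    DEFAULT_SIZE_CAP,
    MultiStringInstance,
    PositionCodec,
    local_decrements,
    local_increments,
    run_multistring_inside,
)
from .rna import complementary

__all__ = [
    "SAFScoring",
    "default_saf_scoring",
    "max_pairs_saf_scoring",
    "alignment_column",
    "saf_spec",
    "saf_score",
]

GAP = "-"


@dataclass(frozen=True)
class SAFScoring:
    """Column scoring: rho over one column, tau over a column pair.

    Columns are tuples of characters with '-' for gaps; both callables must
    be pure functions of the column contents.
    """

    rho: Callable[[Tuple[str, ...]], float]
    tau: Callable[[Tuple[str, ...], Tuple[str, ...]], float]


def alignment_column(
    instance: MultiStringInstance, Q: Sequence[int], Qp: Sequence[int]
) -> Tuple[str, ...]:
    """The column spanned by the local increment Q -> Qp."""
    col = []
    for s, a, b in zip(instance.strings, Q, Qp):
        col.append(s[a] if b == a + 1 else GAP)
    return tuple(col)


def default_saf_scoring(
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
    pair_bonus: float = 2.0,
    pair_penalty: float = -3.0,
) -> SAFScoring:
    """A concrete, configurable scheme for command-line runs.

    rho sums over unordered string pairs within the column: ``match`` for
    identical residues, ``mismatch`` for differing residues, ``gap`` when
    exactly one of the two entries is a gap.  tau sums over strings:
    ``pair_bonus`` when the two column characters of that string are
    complementary bases, ``pair_penalty`` when either is a gap or the bases
    do not pair.
    """

    def rho(col):
        total = 0.0
        m = len(col)
        for p in range(m):
            for r in range(p + 1, m):
                x, y = col[p], col[r]
                if x == GAP and y == GAP:
                    continue
                if GAP in (x, y):
                    total += gap
                elif x == y:
                    total += match
                else:
                    total += mismatch
        return total

    def tau(col_a, col_b):
        total = 0.0
        for x, y in zip(col_a, col_b):
            if GAP in (x, y) or not complementary(x, y):
                total += pair_penalty
            else:
                total += pair_bonus
        return total

    return SAFScoring(rho=rho, tau=tau)


def max_pairs_saf_scoring() -> SAFScoring:
    """The m = 1 reduction: with rho = 0 and tau = +1 for a complementary
    column pair (else -inf), the best score equals the maximum number of
    complementary base pairs of the single string."""

    def rho(col):
        return 0.0

    def tau(col_a, col_b):
        if GAP in col_a or GAP in col_b:
            return float("-inf")
        if all(complementary(x, y) for x, y in zip(col_a, col_b)):
            return 1.0
        return float("-inf")

    return SAFScoring(rho=rho, tau=tau)


def saf_spec(instance: MultiStringInstance, scoring: SAFScoring) -> InsideProblemSpec:
    """Inside spec over the linearized position lattice (K = 1, max-plus)."""
    codec = instance.codec()
    decode = codec.decode
    encode = codec.encode

    def finalize(i, j, mu, beta):
        X = decode(i)
        Y = decode(j)
        if X == Y:
            return (0.0,)
        best = mu[0][0]
        for Xp in local_increments(X, codec):
            if not PositionCodec.leq(Xp, Y):
                continue
            col_first = alignment_column(instance, X, Xp)
            rho_first = scoring.rho(col_first)
            for Yp in local_decrements(Y, codec):
                if not PositionCodec.leq(X, Yp):
                    continue
                inner = beta(0, encode(Xp), encode(Yp))
                if inner == float("-inf"):
                    continue
                col_last = alignment_column(instance, Yp, Y)
                cand = (
                    inner
                    + rho_first
                    + scoring.rho(col_last)
                    + scoring.tau(col_first, col_last)
                )
                if cand > best:
                    best = cand
        # single-column alignment
        for Xp in local_increments(X, codec):
            if Xp == Y:
                cand = scoring.rho(alignment_column(instance, X, Y))
                if cand > best:
                    best = cand
        return (best,)

    return InsideProblemSpec(
        K=1,
        property_names=("saf_score",),
        variant=MAX_PLUS,
        mu_specs=[[(0, 0)]],
        finalize=finalize,
    )


def saf_score(
    instance: MultiStringInstance,
    scoring: Optional[SAFScoring] = None,
    kernel=None,
    cutoff: int = 32,
    size_cap: int = DEFAULT_SIZE_CAP,
    return_matrix: bool = False,
):
    """Maximum score of an alignment-with-folding of the instance."""
    if scoring is None:
        scoring = default_saf_scoring()
    spec = saf_spec(instance, scoring)
    B = run_multistring_inside(
        instance, spec, kernel=kernel, cutoff=cutoff, size_cap=size_cap
    )[0]
    score = float(B[0, instance.size - 1])
    return (score, B) if return_matrix else score
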