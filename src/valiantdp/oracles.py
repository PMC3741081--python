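"""Slow, structurally independent reference implementations.

Everything here is deliberately naive — exhaustive enumeration of foldings,
triple-loop CKY, plain memoized lattice recursion — and shares no recursion
code with the engines.  These are the ground truth the engine results are
measured against; the size guards are hard errors because an oracle that
silently truncates would invalidate every comparison built on it.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Dict, FrozenSet, Iterator, List, Sequence, Tuple

import numpy as np

from .multistring import (
    MultiStringInstance,
    PositionCodec,
    local_decrements,
    local_increments,
)
from .problems.rna import Folding, complementary, normalize_rna
from .problems.grammar import CNFGrammar
from .problems.saf import SAFScoring, alignment_column

__all__ = [
    "enumerate_foldings",
    "brute_max_pairs",
    "brute_partition",
    "brute_bpp",
    "brute_cfg",
    "brute_wcfg",
    "exhaustive_cfg",
    "brute_saf",
]

MAX_ENUM_LENGTH = 14
MAX_CKY_LENGTH = 24
MAX_SAF_SIZE = 2500


def enumerate_foldings(s: str) -> Iterator[FrozenSet[Tuple[int, int]]]:
    """Every nested set of complementary base pairs of s, exactly once.

    The count grows exponentially, hence the hard length guard.
    """
    s = normalize_rna(s)
    n = len(s)
    if n > MAX_ENUM_LENGTH:
        raise ValueError(
            f"enumeration is limited to length {MAX_ENUM_LENGTH}, got {n}"
        )

    @lru_cache(maxsize=None)
    def sub(i: int, j: int) -> Tuple[FrozenSet[Tuple[int, int]], ...]:
        # foldings of s[i:j]; split on the status of index j-1
        if j - i < 1:
            return (frozenset(),)
        out = list(sub(i, j - 1))  # j-1 unpaired
        for q in range(i, j - 1):
            if complementary(s[q], s[j - 1]):
                for left in sub(i, q):
                    for inner in sub(q + 1, j - 1):
                        out.append(left | inner | {(q, j - 1)})
        return tuple(out)

    seen = set()
    for f in sub(0, n):
        if f not in seen:  # distinct by construction; set is a cheap safety net
            seen.add(f)
            yield f


def brute_max_pairs(s: str) -> int:
    """Maximum complementary-pair count by direct enumeration."""
    return max(len(f) for f in enumerate_foldings(s))


def brute_partition(s: str) -> float:
    """Z = sum over foldings of e^|F| by direct enumeration."""
    return sum(math.exp(len(f)) for f in enumerate_foldings(s))


def brute_bpp(s: str) -> np.ndarray:
    """P[a, b] = (sum of e^|F| over foldings containing a.b) / Z."""
    s = normalize_rna(s)
    n = len(s)
    P = np.zeros((n, n))
    Z = 0.0
    for f in enumerate_foldings(s):
        w = math.exp(len(f))
        Z += w
        for a, b in f:
            P[a, b] += w
    return P / Z


def brute_cfg(g: CNFGrammar, tokens: Sequence[str]) -> bool:
    """Classical boolean CKY with explicit triple loops."""
    tokens = list(tokens)
    n = len(tokens)
    if n > MAX_CKY_LENGTH:
        raise ValueError(f"oracle CKY is limited to {MAX_CKY_LENGTH} tokens")
    if n == 0:
        return False
    table: Dict[Tuple[int, int, str], bool] = {}
    for i in range(n):
        for a, t, _ in g.terminal_rules:
            if t == tokens[i]:
                table[(i, i + 1, a)] = True
    for span in range(2, n + 1):
        for i in range(n - span + 1):
            j = i + span
            for q in range(i + 1, j):
                for a, b, c, _ in g.binary_rules:
                    if table.get((i, q, b)) and table.get((q, j, c)):
                        table[(i, j, a)] = True
    return bool(table.get((0, n, g.start), False))


def brute_wcfg(g: CNFGrammar, tokens: Sequence[str]) -> float:
    """Classical max-plus CKY; -inf for unparseable input."""
    tokens = list(tokens)
    n = len(tokens)
    if n > MAX_CKY_LENGTH:
        raise ValueError(f"oracle CKY is limited to {MAX_CKY_LENGTH} tokens")
    if n == 0:
        return -math.inf
    table: Dict[Tuple[int, int, str], float] = {}

    def get(i, j, a):
        return table.get((i, j, a), -math.inf)

    for i in range(n):
        for a, t, w in g.terminal_rules:
            if t == tokens[i]:
                table[(i, i + 1, a)] = max(get(i, i + 1, a), w)
    for span in range(2, n + 1):
        for i in range(n - span + 1):
            j = i + span
            for q in range(i + 1, j):
                for a, b, c, w in g.binary_rules:
                    cand = get(i, q, b) + get(q, j, c) + w
                    if cand > get(i, j, a):
                        table[(i, j, a)] = cand
    return get(0, n, g.start)


def exhaustive_cfg(g: CNFGrammar, tokens: Sequence[str], max_len: int = 6) -> bool:
    """Recognition by un-memoized top-down derivation search.

    Tries every rule and split recursively; exponential, so only for spans of
    a handful of tokens.  A CNF derivation of n tokens applies exactly 2n - 1
    rules, so termination is structural.
    """
    tokens = tuple(tokens)
    if len(tokens) > max_len:
        raise ValueError(f"exhaustive search is limited to {max_len} tokens")

    def derives(a: str, toks: Tuple[str, ...]) -> bool:
        if len(toks) == 0:
            return False
        if len(toks) == 1:
            return any(x == a and t == toks[0] for x, t, _ in g.terminal_rules)
        for lhs, b, c, _ in g.binary_rules:
            if lhs != a:
                continue
            for q in range(1, len(toks)):
                if derives(b, toks[:q]) and derives(c, toks[q:]):
                    return True
        return False

    return derives(g.start, tokens)


def brute_saf(instance: MultiStringInstance, scoring: SAFScoring) -> float:
    """Best alignment-with-folding score by memoized lattice recursion.

    Implements the same recurrence as the engine spec (paired end columns /
    split / single column) but evaluates it by plain recursion over position
    pairs, with no engine code involved.
    """
    if instance.size > MAX_SAF_SIZE:
        raise ValueError(
            f"oracle recursion is limited to lattices of {MAX_SAF_SIZE} "
            f"positions, got {instance.size}"
        )
    codec = instance.codec()
    leq = PositionCodec.leq

    @lru_cache(maxsize=None)
    def beta(X: Tuple[int, ...], Y: Tuple[int, ...]) -> float:
        if not leq(X, Y):
            return -math.inf
        if X == Y:
            return 0.0
        best = -math.inf
        # paired first and last columns
        for Xp in local_increments(X, codec):
            if not leq(Xp, Y):
                continue
            col_first = alignment_column(instance, X, Xp)
            for Yp in local_decrements(Y, codec):
                if not leq(X, Yp) or not leq(Xp, Yp):
                    continue
                inner = beta(Xp, Yp)
                if inner == -math.inf:
                    continue
                col_last = alignment_column(instance, Yp, Y)
                cand = (
                    inner
                    + scoring.rho(col_first)
                    + scoring.rho(col_last)
                    + scoring.tau(col_first, col_last)
                )
                best = max(best, cand)
        # split strictly between X and Y
        for q in range(codec.encode(X) + 1, codec.encode(Y)):
            Q = codec.decode(q)
            if leq(X, Q) and leq(Q, Y) and Q != X and Q != Y:
                left = beta(X, Q)
                right = beta(Q, Y)
                if left > -math.inf and right > -math.inf:
                    best = max(best, left + right)
        # single column
        if Y in local_increments(X, codec):
            best = max(best, scoring.rho(alignment_column(instance, X, Y)))
        return best

    return beta(tuple(0 for _ in instance.strings), tuple(instance.lengths))
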