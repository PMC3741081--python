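"""Multiple-string inside dynamic programming via position encoding.

Problems over a set of strings (simultaneous alignment and folding being the
canonical example) index their sub-instances by *positions*: one index per
string.  A position tuple X is componentwise comparable to Y (``X <= Y``),
and the sub-instance S[X, Y] is the tuple of substrings between them.

The mixed-radix codec ``h`` linearizes positions into a single index space
of size ``prod(n_p + 1)`` with string 0 as the least significant digit.  It
is monotone (X <= Y implies h(X) <= h(Y)) but not conversely, so cells whose
decoded endpoints are incomparable do not correspond to sub-instances; they
are masked and keep phi.  With that mask, the single-string inside engine
runs unchanged: for any split position Q strictly between X and Y, h(Q)
falls strictly between h(X) and h(Y), and any linear index whose decoded
position is not between X and Y contributes phi to the split accumulation
because one of its factors is a masked cell.  Correctness requires a
commutative ``oplus`` since the linear order visits lattice split points in
an arbitrary lattice order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .inside import InsideProblemSpec, run_inside

__all__ = [
    "MultiStringInstance",
    "PositionCodec",
    "local_increments",
    "local_decrements",
    "run_multistring_inside",
    "DEFAULT_SIZE_CAP",
]

DEFAULT_SIZE_CAP = 4096


@dataclass(frozen=True)
class MultiStringInstance:
    """An ordered set of strings; the index space is the position lattice."""

    strings: Tuple[str, ...]

    def __init__(self, strings: Sequence[str]):
        if len(strings) < 1:
            raise ValueError("at least one string is required")
        object.__setattr__(self, "strings", tuple(strings))

    @property
    def m(self) -> int:
        return len(self.strings)

    @property
    def lengths(self) -> Tuple[int, ...]:
        return tuple(len(s) for s in self.strings)

    @property
    def size(self) -> int:
        """Number of positions: prod(n_p + 1)."""
        out = 1
        for n in self.lengths:
            out *= n + 1
        return out

    def codec(self) -> "PositionCodec":
        return PositionCodec(self.lengths)

    def substrings(self, X: Sequence[int], Y: Sequence[int]) -> Tuple[str, ...]:
        return tuple(s[x:y] for s, x, y in zip(self.strings, X, Y))


class PositionCodec:
    """Mixed-radix bijection between position tuples and linear indices.

    String 0 is the least significant digit; radix for string p is
    ``n_p + 1`` (positions run from 0 to the string length inclusive).
    """

    def __init__(self, lengths: Sequence[int]):
        self.lengths = tuple(int(n) for n in lengths)
        if any(n < 0 for n in self.lengths):
            raise ValueError("string lengths must be non-negative")
        self.radices = tuple(n + 1 for n in self.lengths)
        self.size = int(np.prod(self.radices)) if self.radices else 1
        self._weights = []
        w = 1
        for r in self.radices:
            self._weights.append(w)
            w *= r

    def encode(self, X: Sequence[int]) -> int:
        if len(X) != len(self.radices):
            raise ValueError("position arity mismatch")
        idx = 0
        for x, n, w in zip(X, self.lengths, self._weights):
            if not 0 <= x <= n:
                raise IndexError(f"position component {x} outside [0, {n}]")
            idx += x * w
        return idx

    def decode(self, idx: int) -> Tuple[int, ...]:
        if not 0 <= idx < self.size:
            raise IndexError(f"index {idx} outside [0, {self.size})")
        out = []
        for r in self.radices:
            out.append(idx % r)
            idx //= r
        return tuple(out)

    @staticmethod
    def leq(X: Sequence[int], Y: Sequence[int]) -> bool:
        """Componentwise comparison; h-order does not imply this order."""
        if len(X) != len(Y):
            raise ValueError("position arity mismatch")
        return all(x <= y for x, y in zip(X, Y))


def _neighbors(P: Sequence[int], bounds, step: int) -> List[Tuple[int, ...]]:
    m = len(P)
    out = []
    for mask in range(1, 1 << m):
        Q = list(P)
        ok = True
        for p in range(m):
            if mask >> p & 1:
                Q[p] += step
                if not 0 <= Q[p] <= bounds[p]:
                    ok = False
                    break
        if ok:
            out.append(tuple(Q))
    return out


def local_increments(X: Sequence[int], codec: PositionCodec) -> List[Tuple[int, ...]]:
    """Positions reachable by adding 1 to a nonempty subset of components.

    One such step spans exactly one alignment column of the sub-instance.
    """
    return _neighbors(X, codec.lengths, +1)


def local_decrements(Y: Sequence[int], codec: PositionCodec) -> List[Tuple[int, ...]]:
    """Positions reachable by subtracting 1 from a nonempty subset."""
    return _neighbors(Y, codec.lengths, -1)


def run_multistring_inside(
    instance: MultiStringInstance,
    spec: InsideProblemSpec,
    kernel=None,
    cutoff: int = 32,
    size_cap: int = DEFAULT_SIZE_CAP,
) -> List[np.ndarray]:
    """Run the inside engine over the linearized position lattice.

    ``spec.cell_valid`` is replaced with the lattice mask; the spec's
    finalize callback is expected to decode indices itself (or work purely
    from mu values).  Refuses variants without a commutative ``oplus`` and
    lattices larger than ``size_cap`` (dense matrices of that order are
    allocated).
    """
    if not spec.variant.oplus_commutative:
        raise ValueError(
            "multiple-string reduction requires a commutative oplus: the "
            "linear index order visits lattice split points arbitrarily"
        )
    codec = instance.codec()
    if codec.size > size_cap:
        raise ValueError(
            f"position lattice has {codec.size} indices, above the cap of "
            f"{size_cap}; raise size_cap explicitly to proceed"
        )
    decoded = [codec.decode(i) for i in range(codec.size)]

    def valid(i, j):
        return PositionCodec.leq(decoded[i], decoded[j])

    masked = InsideProblemSpec(
        K=spec.K,
        property_names=spec.property_names,
        variant=spec.variant,
        mu_specs=spec.mu_specs,
        finalize=spec.finalize,
        cell_valid=valid,
    )
    return run_inside(codec.size, masked, kernel=kernel, cutoff=cutoff)
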