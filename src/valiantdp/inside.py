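"""Divide-and-conquer inside dynamic programming.

An *inside property* ``beta[k][i, j]`` is a value that depends only on the
substring between positions ``i`` and ``j`` of the input (best folding score,
partition function, derivability from a grammar symbol, ...).  Recurrences of
the supported shape combine, for every split point ``q`` strictly between
``i`` and ``j``, a property of the prefix with a property of the suffix:

    mu[k][i, j] = oplus_{q in (i, j)} beta[k1][i, q] otimes beta[k2][q, j]

plus a per-cell finalization step that may consult ``mu`` and already
finalized values of strict sub-ranges.  The classical bottom-up algorithm
evaluates each ``mu`` cell with an explicit split loop in Theta(N^3) total
time; the divide-and-conquer engine instead charges the split accumulation to
matrix multiplications between sibling recursive calls, so its running time
is governed by the multiplication kernel.

Both evaluation orders compute the same fixpoint; the classical order
(`run_inside_classical`) doubles as the independent oracle and as the
evaluator for recursion blocks below the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .algebra import (
    MultiplicationVariant,
    OpCounter,
    full_phi,
    get_kernel,
    matrices_close,
)

__all__ = ["InsideProblemSpec", "InsideWorkspace", "run_inside", "run_inside_classical"]


@dataclass
class InsideProblemSpec:
    """Plugin contract for an inside problem.

    Parameters
    ----------
    K:
        Number of mutually recursive property sets.
    property_names:
        Names of the K property sets, in finalization order: the finalize
        callback for property ``k`` may read same-cell values only of
        properties with smaller index.
    variant:
        The multiplication variant shared by all split accumulations.
    mu_specs:
        For each property ``k``, a list of ``(k1, k2)`` pairs (0-based
        property indices).  Each pair contributes its own accumulation slot
        ``mu[k][s][i, j] = oplus_q beta[k1][i, q] otimes beta[k2][q, j]``.
        A property with no split term has an empty list.
    finalize:
        ``finalize(i, j, mu, beta) -> sequence of K values``.  ``mu`` is a
        list (per property) of lists (per slot) of accumulated scalars;
        ``beta(k, i, j)`` reads finalized values, returning ``phi`` for
        out-of-range indices.  Only strict sub-ranges of ``[i, j]`` (or the
        same cell for smaller ``k``) may be read; the engine's evaluation
        orders guarantee those are available.
    cell_valid:
        Predicate masking the index space; masked cells keep ``phi``.
        Defaults to the upper triangle ``i <= j``.
    """

    K: int
    property_names: Sequence[str]
    variant: MultiplicationVariant
    mu_specs: Sequence[Sequence[Tuple[int, int]]]
    finalize: Callable
    cell_valid: Callable = field(default=None)

    def __post_init__(self):
        if len(self.property_names) != self.K or len(self.mu_specs) != self.K:
            raise ValueError("property_names and mu_specs must have length K")
        for specs in self.mu_specs:
            for k1, k2 in specs:
                if not (0 <= k1 < self.K and 0 <= k2 < self.K):
                    raise ValueError("mu spec indices out of range")
        if self.cell_valid is None:
            self.cell_valid = lambda i, j: i <= j


class InsideWorkspace:
    """Property matrices plus per-slot split accumulators for one run."""

    def __init__(self, N: int, spec: InsideProblemSpec):
        if N < 1:
            raise ValueError("index-space size must be at least 1")
        self.N = N
        self.spec = spec
        self.B = [full_phi(spec.variant, (N, N)) for _ in range(spec.K)]
        self.mu = [
            [full_phi(spec.variant, (N, N)) for _ in specs]
            for specs in spec.mu_specs
        ]

    def beta_reader(self):
        B, N, phi = self.B, self.N, self.spec.variant.phi

        def read(k, i, j):
            if 0 <= i < N and 0 <= j < N:
                return B[k][i, j]
            return phi

        return read


def _finalize_cell(ws: InsideWorkspace, i: int, j: int, reader) -> None:
    spec = ws.spec
    mu_vals = [
        [ws.mu[k][s][i, j] for s in range(len(spec.mu_specs[k]))]
        for k in range(spec.K)
    ]
    values = spec.finalize(i, j, mu_vals, reader)
    values = tuple(values)
    if len(values) != spec.K:
        raise ValueError(
            f"finalize returned {len(values)} values, expected {spec.K}"
        )
    for k, v in enumerate(values):
        ws.B[k][i, j] = v


def _complete_block_classically(
    ws: InsideWorkspace,
    I: Tuple[int, int],
    J: Tuple[int, int],
    counter: Optional[OpCounter] = None,
) -> None:
    """Finish all cells of block (I, J) with per-cell split loops.

    On entry the accumulators hold the contribution of split points strictly
    between the intervals (the recursion's bridging products); the loop adds
    the remaining split points, which lie inside I or J, in an order (columns
    ascending, rows descending) that finalizes every needed value first.
    """
    spec = ws.spec
    v = spec.variant
    ilo, ihi = I
    jlo, jhi = J
    reader = ws.beta_reader()
    for j in range(jlo, jhi + 1):
        for i in range(ihi, ilo - 1, -1):
            if not spec.cell_valid(i, j):
                continue
            # split points not covered by the bridging products: q in (i, j)
            # with q <= max(I) or q >= min(J)
            qs = [q for q in range(i + 1, j) if q <= ihi or q >= jlo]
            if qs:
                qs = np.asarray(qs)
                for k in range(spec.K):
                    for s, (k1, k2) in enumerate(spec.mu_specs[k]):
                        terms = v.combine(ws.B[k1][i, qs], ws.B[k2][qs, j])
                        extra = v.reduce_axis(terms, 0)
                        ws.mu[k][s][i, j] = v.oplus(ws.mu[k][s][i, j], extra)
                        if counter is not None:
                            counter.add(len(qs))
            _finalize_cell(ws, i, j, reader)


def _bridge_vertical(ws, I, J2, L, kernel, counter):
    """mu[I, J2] <- mu[I, J2] oplus (B[k1][I, L] otimes B[k2][L, J2])."""
    spec = ws.spec
    v = spec.variant
    ilo, ihi = I
    jlo, jhi = J2
    llo, lhi = L
    for k in range(spec.K):
        for s, (k1, k2) in enumerate(spec.mu_specs[k]):
            X = ws.B[k1][ilo : ihi + 1, llo : lhi + 1]
            Y = ws.B[k2][llo : lhi + 1, jlo : jhi + 1]
            P = np.asarray(kernel(X, Y), dtype=v.dtype)
            tgt = ws.mu[k][s][ilo : ihi + 1, jlo : jhi + 1]
            ws.mu[k][s][ilo : ihi + 1, jlo : jhi + 1] = v.oplus_arrays(tgt, P)
            if counter is not None and not hasattr(kernel, "counter"):
                counter.add(X.shape[0] * X.shape[1] * Y.shape[1])


def _bridge_horizontal(ws, I2, J, L, kernel, counter):
    """mu[I2, J] <- (B[k1][I2, L] otimes B[k2][L, J]) oplus mu[I2, J]."""
    spec = ws.spec
    v = spec.variant
    ilo, ihi = I2
    jlo, jhi = J
    llo, lhi = L
    for k in range(spec.K):
        for s, (k1, k2) in enumerate(spec.mu_specs[k]):
            X = ws.B[k1][ilo : ihi + 1, llo : lhi + 1]
            Y = ws.B[k2][llo : lhi + 1, jlo : jhi + 1]
            P = np.asarray(kernel(X, Y), dtype=v.dtype)
            tgt = ws.mu[k][s][ilo : ihi + 1, jlo : jhi + 1]
            # new split points precede the accumulated ones, so the product
            # is folded on the left (matters only for non-commutative oplus)
            ws.mu[k][s][ilo : ihi + 1, jlo : jhi + 1] = v.oplus_arrays(P, tgt)
            if counter is not None and not hasattr(kernel, "counter"):
                counter.add(X.shape[0] * X.shape[1] * Y.shape[1])


def compute_inside_submatrix(
    ws: InsideWorkspace,
    I: Tuple[int, int],
    J: Tuple[int, int],
    kernel,
    cutoff: int,
    counter: Optional[OpCounter] = None,
    verify_against=None,
) -> None:
    """Recursively finalize block (I, J) of the property matrices.

    Pre-condition: every cell of the square region spanned by I and J is
    finalized except the block itself, whose accumulators hold the split
    contributions of points strictly between I and J.
    """
    if verify_against is not None:
        _check_precondition(ws, I, J, verify_against)
    ilo, ihi = I
    jlo, jhi = J
    len_i = ihi - ilo + 1
    len_j = jhi - jlo + 1
    if max(len_i, len_j) <= cutoff:
        _complete_block_classically(ws, I, J, counter)
        return
    if len_i <= len_j:
        half = len_j // 2
        J1 = (jlo, jlo + half - 1)
        J2 = (jlo + half, jhi)
        compute_inside_submatrix(ws, I, J1, kernel, cutoff, counter, verify_against)
        if ihi < jlo:  # bridge L = J1; otherwise L is empty
            _bridge_vertical(ws, I, J2, J1, kernel, counter)
        compute_inside_submatrix(ws, I, J2, kernel, cutoff, counter, verify_against)
    else:
        half = len_i // 2
        I2 = (ilo, ilo + half - 1)
        I1 = (ilo + half, ihi)
        compute_inside_submatrix(ws, I1, J, kernel, cutoff, counter, verify_against)
        if ihi < jlo:  # bridge L = I1
            _bridge_horizontal(ws, I2, J, I1, kernel, counter)
        compute_inside_submatrix(ws, I2, J, kernel, cutoff, counter, verify_against)


def _check_precondition(ws, I, J, oracle):
    """Debug check: finalized region and accumulators match a fresh oracle."""
    spec = ws.spec
    v = spec.variant
    ilo, ihi = I
    jlo, jhi = J
    # the spanned square [min(I), max(J)] x [min(I), max(J)]; empty below
    # the diagonal
    lo, hi = ilo, jhi
    for k in range(spec.K):
        for i in range(lo, hi + 1):
            for j in range(lo, hi + 1):
                if ilo <= i <= ihi and jlo <= j <= jhi:
                    continue
                if spec.cell_valid(i, j):
                    a = np.asarray([ws.B[k][i, j]])
                    b = np.asarray([oracle[k][i, j]])
                    if not matrices_close(a, b, v):
                        raise AssertionError(
                            f"pre-condition violated at B[{k}][{i},{j}] "
                            f"for block {I}x{J}"
                        )
    # accumulators must equal the split sum over q strictly between I and J
    for k in range(spec.K):
        for s, (k1, k2) in enumerate(spec.mu_specs[k]):
            for i in range(ilo, ihi + 1):
                for j in range(jlo, jhi + 1):
                    qs = np.arange(ihi + 1, jlo)
                    if len(qs):
                        terms = v.combine(oracle[k1][i, qs], oracle[k2][qs, j])
                        want = v.reduce_axis(terms, 0)
                    else:
                        want = v.phi
                    have = ws.mu[k][s][i, j]
                    if not matrices_close(
                        np.asarray([have]), np.asarray([want]), v
                    ):
                        raise AssertionError(
                            f"accumulator mismatch at mu[{k}][{s}][{i},{j}] "
                            f"for block {I}x{J}"
                        )


def run_inside(
    N: int,
    spec: InsideProblemSpec,
    kernel=None,
    cutoff: int = 32,
    verify: bool = False,
    counter: Optional[OpCounter] = None,
) -> List[np.ndarray]:
    """Compute all K inside property matrices for an index space of size N.

    ``kernel`` is a registered kernel name or a callable ``(X, Y) -> Z``.
    ``verify`` re-derives the result with the classical order first and
    asserts the recursion's pre-condition at every call (small N only).
    """
    if cutoff < 1:
        raise ValueError("cutoff must be at least 1")
    ws = InsideWorkspace(N, spec)
    fn = kernel if callable(kernel) else get_kernel(spec.variant, kernel)
    oracle = None
    if verify:
        if N > 128:
            raise ValueError("verify mode is limited to N <= 128")
        oracle = run_inside_classical(N, spec)
    compute_inside_submatrix(ws, (0, N - 1), (0, N - 1), fn, cutoff, counter, oracle)
    return ws.B


def run_inside_classical(
    N: int, spec: InsideProblemSpec, counter: Optional[OpCounter] = None
) -> List[np.ndarray]:
    """Classical bottom-up evaluation: one explicit split loop per cell.

    Columns ascending, rows descending — every value a cell may consult is
    finalized before the cell itself.  Serves as the reference oracle for the
    divide-and-conquer engine.
    """
    if N < 1:
        raise ValueError("index-space size must be at least 1")
    ws = InsideWorkspace(N, spec)
    v = spec.variant
    reader = ws.beta_reader()
    for j in range(N):
        for i in range(j, -1, -1):
            if not spec.cell_valid(i, j):
                continue
            if j - i >= 2:
                qs = np.arange(i + 1, j)
                for k in range(spec.K):
                    for s, (k1, k2) in enumerate(spec.mu_specs[k]):
                        terms = v.combine(ws.B[k1][i, qs], ws.B[k2][qs, j])
                        ws.mu[k][s][i, j] = v.reduce_axis(terms, 0)
                        if counter is not None:
                            counter.add(len(qs))
            _finalize_cell(ws, i, j, reader)
    return ws.B
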