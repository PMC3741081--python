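"""Divide-and-conquer outside dynamic programming.

An *outside property* ``alpha[k][i, j]`` depends on the residual instance
left after excising the substring between positions ``i`` and ``j`` — the
prefix before ``i`` together with the suffix after ``j``.  Outside
recurrences consume a set of pre-computed inside matrices and admit two
split-accumulation shapes:

    prefix form:  mu[k][i, j] = oplus_{q in [0, i)} beta[kb][q, i] otimes alpha[ka][q, j]
    suffix form:  mu[k][i, j] = oplus_{q in (j, n]} alpha[ka][i, q] otimes beta[kb][j, q]

Cells are finalized from the outermost ranges inward: ``alpha[i, j]`` may
consult ``alpha`` of strict super-ranges, same-cell values of earlier
properties, and any inside value.  The divide-and-conquer engine again
charges the split accumulation to matrix products (with the inside operand
transposed, since the split index runs over rows there); the classical
order (`run_outside_classical`) is the independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .algebra import (
    MultiplicationVariant,
    full_phi,
    get_kernel,
    matrices_close,
)

__all__ = [
    "PREFIX",
    "SUFFIX",
    "OutsideMuSpec",
    "OutsideProblemSpec",
    "OutsideWorkspace",
    "run_outside",
    "run_outside_classical",
]

PREFIX = "prefix"
SUFFIX = "suffix"


@dataclass(frozen=True)
class OutsideMuSpec:
    """One split-accumulation term: its form and operand property indices.

    ``k_beta`` indexes the inside matrices, ``k_alpha`` the outside ones.
    """

    form: str
    k_beta: int
    k_alpha: int

    def __post_init__(self):
        if self.form not in (PREFIX, SUFFIX):
            raise ValueError("form must be 'prefix' or 'suffix'")


@dataclass
class OutsideProblemSpec:
    """Plugin contract for an outside problem.

    ``mu_specs[k]`` is either None (property ``k`` needs no split term) or an
    :class:`OutsideMuSpec`.  ``finalize(i, j, mu, alpha, beta)`` returns the K
    values for cell ``(i, j)``; ``alpha``/``beta`` are bounds-checked readers
    returning ``phi`` out of range.
    """

    K: int
    property_names: Sequence[str]
    variant: MultiplicationVariant
    mu_specs: Sequence[Optional[OutsideMuSpec]]
    finalize: Callable
    cell_valid: Callable = field(default=None)

    def __post_init__(self):
        if len(self.property_names) != self.K or len(self.mu_specs) != self.K:
            raise ValueError("property_names and mu_specs must have length K")
        for ms in self.mu_specs:
            if ms is not None and not (
                0 <= ms.k_alpha < self.K and ms.k_beta >= 0
            ):
                raise ValueError("mu spec indices out of range")
        if self.cell_valid is None:
            self.cell_valid = lambda i, j: i <= j


class OutsideWorkspace:
    def __init__(self, N: int, spec: OutsideProblemSpec, inside: Sequence[np.ndarray]):
        if N < 1:
            raise ValueError("index-space size must be at least 1")
        for M in inside:
            if M.shape != (N, N):
                raise ValueError("inside matrices must match the index-space size")
        self.N = N
        self.spec = spec
        self.inside = list(inside)
        self.A = [full_phi(spec.variant, (N, N)) for _ in range(spec.K)]
        self.mu = [
            full_phi(spec.variant, (N, N)) if ms is not None else None
            for ms in spec.mu_specs
        ]

    def alpha_reader(self):
        return _bounded_reader(self.A, self.N, self.spec.variant.phi)

    def beta_reader(self):
        return _bounded_reader(self.inside, self.N, self.spec.variant.phi)


def _bounded_reader(mats, N, phi):
    def read(k, i, j):
        if 0 <= i < N and 0 <= j < N:
            return mats[k][i, j]
        return phi

    return read


def _finalize_cell(ws: OutsideWorkspace, i: int, j: int, a_read, b_read) -> None:
    spec = ws.spec
    mu_vals = [
        ws.mu[k][i, j] if ws.mu[k] is not None else None for k in range(spec.K)
    ]
    values = tuple(spec.finalize(i, j, mu_vals, a_read, b_read))
    if len(values) != spec.K:
        raise ValueError(f"finalize returned {len(values)} values, expected {spec.K}")
    for k, v in enumerate(values):
        ws.A[k][i, j] = v


def _complete_block_classically(ws: OutsideWorkspace, I, J) -> None:
    """Finish block (I, J): add the split points the bridges did not cover.

    Cells run columns descending, rows ascending, so each cell is finalized
    after every strict super-range inside the block.  For the prefix form
    the accumulators cover q < min(I) on entry and the loop adds
    q in [min(I), i); for the suffix form they cover q > max(J) and the loop
    adds q in (j, max(J)].
    """
    spec = ws.spec
    v = spec.variant
    ilo, ihi = I
    jlo, jhi = J
    a_read = ws.alpha_reader()
    b_read = ws.beta_reader()
    for j in range(jhi, jlo - 1, -1):
        for i in range(ilo, ihi + 1):
            if not spec.cell_valid(i, j):
                continue
            for k in range(spec.K):
                ms = spec.mu_specs[k]
                if ms is None:
                    continue
                if ms.form == PREFIX:
                    qs = np.arange(ilo, i)
                    if len(qs):
                        terms = v.combine(
                            ws.inside[ms.k_beta][qs, i], ws.A[ms.k_alpha][qs, j]
                        )
                        extra = v.reduce_axis(terms, 0)
                        ws.mu[k][i, j] = v.oplus(ws.mu[k][i, j], extra)
                else:
                    qs = np.arange(j + 1, jhi + 1)
                    if len(qs):
                        terms = v.combine(
                            ws.A[ms.k_alpha][i, qs], ws.inside[ms.k_beta][j, qs]
                        )
                        extra = v.reduce_axis(terms, 0)
                        # suffix split points here precede the accumulated tail
                        ws.mu[k][i, j] = v.oplus(extra, ws.mu[k][i, j])
            _finalize_cell(ws, i, j, a_read, b_read)


def compute_outside_submatrix(ws: OutsideWorkspace, I, J, kernel, cutoff, verify_against=None):
    """Recursively finalize block (I, J) of the outside matrices.

    Pre-condition: the region of rows [0, max(I)] and columns [min(J), n] is
    finalized except the block itself; each accumulator holds its bridging
    partial (prefix: split points below I; suffix: split points beyond J).
    """
    if verify_against is not None:
        _check_precondition(ws, I, J, verify_against)
    ilo, ihi = I
    jlo, jhi = J
    len_i = ihi - ilo + 1
    len_j = jhi - jlo + 1
    v = ws.spec.variant
    if max(len_i, len_j) <= cutoff:
        _complete_block_classically(ws, I, J)
        return
    if len_i <= len_j:
        half = len_j // 2
        J2 = (jlo, jlo + half - 1)  # left half, computed second
        J1 = (jlo + half, jhi)
        compute_outside_submatrix(ws, I, J1, kernel, cutoff, verify_against)
        for k in range(ws.spec.K):
            ms = ws.spec.mu_specs[k]
            if ms is not None and ms.form == SUFFIX:
                # bridge L = J1:  mu[I, J2] <- (A[I, L] otimes beta[J2, L]^T) oplus mu[I, J2]
                X = ws.A[ms.k_alpha][ilo : ihi + 1, J1[0] : J1[1] + 1]
                Y = ws.inside[ms.k_beta][J2[0] : J2[1] + 1, J1[0] : J1[1] + 1].T
                P = np.asarray(kernel(X, Y), dtype=v.dtype)
                tgt = ws.mu[k][ilo : ihi + 1, J2[0] : J2[1] + 1]
                ws.mu[k][ilo : ihi + 1, J2[0] : J2[1] + 1] = v.oplus_arrays(P, tgt)
        compute_outside_submatrix(ws, I, J2, kernel, cutoff, verify_against)
    else:
        half = len_i // 2
        I1 = (ilo, ilo + half - 1)  # top half, computed first
        I2 = (ilo + half, ihi)
        compute_outside_submatrix(ws, I1, J, kernel, cutoff, verify_against)
        for k in range(ws.spec.K):
            ms = ws.spec.mu_specs[k]
            if ms is not None and ms.form == PREFIX:
                # bridge L = I1:  mu[I2, J] <- mu[I2, J] oplus (beta[L, I2]^T otimes A[L, J])
                X = ws.inside[ms.k_beta][I1[0] : I1[1] + 1, I2[0] : I2[1] + 1].T
                Y = ws.A[ms.k_alpha][I1[0] : I1[1] + 1, jlo : jhi + 1]
                P = np.asarray(kernel(X, Y), dtype=v.dtype)
                tgt = ws.mu[k][I2[0] : I2[1] + 1, jlo : jhi + 1]
                ws.mu[k][I2[0] : I2[1] + 1, jlo : jhi + 1] = v.oplus_arrays(tgt, P)
        compute_outside_submatrix(ws, I2, J, kernel, cutoff, verify_against)


def _check_precondition(ws, I, J, oracle):
    spec = ws.spec
    v = spec.variant
    ilo, ihi = I
    jlo, jhi = J
    N = ws.N
    for k in range(spec.K):
        for i in range(0, ihi + 1):
            for j in range(jlo, N):
                if ilo <= i <= ihi and jlo <= j <= jhi:
                    continue
                if spec.cell_valid(i, j):
                    if not matrices_close(
                        np.asarray([ws.A[k][i, j]]),
                        np.asarray([oracle[k][i, j]]),
                        v,
                    ):
                        raise AssertionError(
                            f"pre-condition violated at A[{k}][{i},{j}] for block {I}x{J}"
                        )
    for k in range(spec.K):
        ms = spec.mu_specs[k]
        if ms is None:
            continue
        for i in range(ilo, ihi + 1):
            for j in range(jlo, jhi + 1):
                if ms.form == PREFIX:
                    qs = np.arange(0, ilo)
                    terms = (
                        v.combine(ws.inside[ms.k_beta][qs, i], oracle[ms.k_alpha][qs, j])
                        if len(qs)
                        else None
                    )
                else:
                    qs = np.arange(jhi + 1, N)
                    terms = (
                        v.combine(oracle[ms.k_alpha][i, qs], ws.inside[ms.k_beta][j, qs])
                        if len(qs)
                        else None
                    )
                want = v.reduce_axis(terms, 0) if terms is not None else v.phi
                if not matrices_close(
                    np.asarray([ws.mu[k][i, j]]), np.asarray([want]), v
                ):
                    raise AssertionError(
                        f"accumulator mismatch at mu[{k}][{i},{j}] for block {I}x{J}"
                    )


def run_outside(
    inside: Sequence[np.ndarray],
    spec: OutsideProblemSpec,
    kernel=None,
    cutoff: int = 32,
    verify: bool = False,
) -> List[np.ndarray]:
    """Compute all K outside matrices from finalized inside matrices."""
    if not inside:
        raise ValueError("outside computation requires finalized inside matrices")
    if cutoff < 1:
        raise ValueError("cutoff must be at least 1")
    N = inside[0].shape[0]
    ws = OutsideWorkspace(N, spec, inside)
    fn = kernel if callable(kernel) else get_kernel(spec.variant, kernel)
    oracle = None
    if verify:
        if N > 128:
            raise ValueError("verify mode is limited to N <= 128")
        oracle = run_outside_classical(inside, spec)
    compute_outside_submatrix(ws, (0, N - 1), (0, N - 1), fn, cutoff, oracle)
    return ws.A


def run_outside_classical(
    inside: Sequence[np.ndarray], spec: OutsideProblemSpec
) -> List[np.ndarray]:
    """Classical outside evaluation, outermost ranges first.

    Rows ascending, columns descending: cell (i, j) follows every (i', j')
    with [i, j] strictly contained in [i', j'].  Independent oracle for the
    divide-and-conquer engine.
    """
    N = inside[0].shape[0]
    ws = OutsideWorkspace(N, spec, inside)
    v = spec.variant
    a_read = ws.alpha_reader()
    b_read = ws.beta_reader()
    for i in range(N):
        for j in range(N - 1, i - 1, -1):
            if not spec.cell_valid(i, j):
                continue
            for k in range(spec.K):
                ms = spec.mu_specs[k]
                if ms is None:
                    continue
                if ms.form == PREFIX:
                    qs = np.arange(0, i)
                    src = (
                        v.combine(ws.inside[ms.k_beta][qs, i], ws.A[ms.k_alpha][qs, j])
                        if len(qs)
                        else None
                    )
                else:
                    qs = np.arange(j + 1, N)
                    src = (
                        v.combine(ws.A[ms.k_alpha][i, qs], ws.inside[ms.k_beta][j, qs])
                        if len(qs)
                        else None
                    )
                ws.mu[k][i, j] = v.reduce_axis(src, 0) if src is not None else v.phi
            _finalize_cell(ws, i, j, a_read, b_read)
    return ws.A
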