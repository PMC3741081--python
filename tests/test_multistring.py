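"""Position codec, lattice masking, and the multiple-string reduction."""

import itertools

import numpy as np
import pytest

from valiantdp.algebra import MAX_PLUS, MultiplicationVariant
from valiantdp.generate import gen_random_multistring, gen_random_rna
from valiantdp.inside import InsideProblemSpec
from valiantdp.multistring import (
    MultiStringInstance,
    PositionCodec,
    local_decrements,
    local_increments,
    run_multistring_inside,
)
from valiantdp.oracles import brute_saf
from valiantdp.problems import fold_max_pairs, saf_score
from valiantdp.problems.saf import default_saf_scoring, max_pairs_saf_scoring, saf_spec


def test_codec_examples():
    c = PositionCodec([3, 3])
    assert c.encode((0, 0)) == 0
    assert c.encode((1, 2)) == 1 + 2 * 4
    assert c.encode((3, 3)) == c.size - 1
    with pytest.raises(IndexError):
        c.encode((4, 0))
    with pytest.raises(IndexError):
        c.decode(c.size)


@pytest.mark.parametrize("lengths", [(0,), (3,), (2, 3), (1, 2, 3), (4, 4, 4)])
def test_codec_round_trip_and_monotonicity(lengths):
    c = PositionCodec(lengths)
    positions = list(itertools.product(*[range(n + 1) for n in lengths]))
    assert c.size == len(positions)
    for i in range(c.size):
        assert c.encode(c.decode(i)) == i
    for X in positions:
        assert c.decode(c.encode(X)) == X
    for X in positions:
        for Y in positions:
            if PositionCodec.leq(X, Y):
                assert c.encode(X) <= c.encode(Y)


def test_linear_order_does_not_imply_lattice_order():
    c = PositionCodec([3, 3])
    assert c.decode(3) == (3, 0)
    assert c.decode(4) == (0, 1)
    assert not PositionCodec.leq((3, 0), (0, 1))
    assert PositionCodec.leq((1, 1), (2, 1))
    assert PositionCodec.leq((2, 1), (2, 1))


def test_local_increments_and_decrements():
    c = PositionCodec([3, 3])
    assert set(local_increments((0, 0), c)) == {(1, 0), (0, 1), (1, 1)}
    assert local_increments((3, 3), c) == []
    c1 = PositionCodec([3])
    assert local_increments((2,), c1) == [(3,)]
    assert set(local_decrements((1, 1), c)) == {(0, 1), (1, 0), (0, 0)}
    assert local_decrements((0, 0), c) == []


def test_empty_strings_allowed():
    c = PositionCodec([0, 2])
    assert c.size == 3
    assert [c.decode(i) for i in range(3)] == [(0, 0), (0, 1), (0, 2)]
    inst = MultiStringInstance(["", "AU"])
    score = saf_score(inst, default_saf_scoring())
    assert np.isfinite(score)


def test_single_string_reduction_equals_plain_folding():
    for trial in range(25):
        s = gen_random_rna(int(np.random.default_rng(trial).integers(0, 11)), 300 + trial)
        inst = MultiStringInstance([s])
        assert saf_score(inst, max_pairs_saf_scoring()) == float(fold_max_pairs(s))


def test_two_string_instances_match_lattice_oracle():
    sc = default_saf_scoring()
    rng = np.random.default_rng(30)
    for trial in range(10):
        inst = gen_random_multistring(
            2, [int(rng.integers(0, 7)), int(rng.integers(0, 7))], 400 + trial
        )
        assert saf_score(inst, sc) == pytest.approx(brute_saf(inst, sc), abs=1e-9)


def test_invalid_lattice_cells_hold_phi():
    inst = MultiStringInstance(["AU", "GC"])
    sc = default_saf_scoring()
    _, B = saf_score(inst, sc, return_matrix=True)
    c = inst.codec()
    for i in range(c.size):
        for j in range(c.size):
            if not PositionCodec.leq(c.decode(i), c.decode(j)):
                assert B[i, j] == -np.inf
            elif i <= j:
                assert np.isfinite(B[i, j])


def test_split_terms_outside_the_lattice_interval_are_absorbed():
    """For valid endpoints X <= Y, any linear split index between them whose
    decoded position is not between X and Y has a phi factor, so the linear
    accumulation equals the lattice accumulation."""
    inst = MultiStringInstance(["GCAU", "GAU"])
    sc = default_saf_scoring()
    _, B = saf_score(inst, sc, return_matrix=True)
    c = inst.codec()
    for i in range(c.size):
        for j in range(i + 1, c.size):
            X, Y = c.decode(i), c.decode(j)
            if not PositionCodec.leq(X, Y):
                continue
            for q in range(i + 1, j):
                Q = c.decode(q)
                if not (PositionCodec.leq(X, Q) and PositionCodec.leq(Q, Y)):
                    assert B[i, q] == -np.inf or B[q, j] == -np.inf


try:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 6), min_size=1, max_size=3))
    def test_codec_bijection_property(lengths):
        """encode and decode are mutually inverse on the whole lattice and
        encode is monotone for componentwise-comparable positions."""
        c = PositionCodec(lengths)
        for i in range(c.size):
            assert c.encode(c.decode(i)) == i
        lo, hi = c.decode(0), tuple(c.lengths)
        assert c.encode(lo) == 0 and c.encode(hi) == c.size - 1
        assert PositionCodec.leq(lo, hi)

except ImportError:  # hypothesis is an optional test dependency
    pass


def test_noncommutative_variant_rejected():
    keep_first = MultiplicationVariant(
        name="keep_first", domain="real",
        otimes=lambda a, b: a + b, oplus=lambda a, b: a,
        phi=-np.inf, dtype=np.dtype(float), oplus_commutative=False,
        combine=np.add, reduce_axis=lambda a, axis: a.take(0, axis=axis),
        oplus_arrays=lambda a, b: a,
    )
    inst = MultiStringInstance(["AU", "AU"])
    spec = InsideProblemSpec(
        K=1, property_names=("x",), variant=keep_first,
        mu_specs=[[(0, 0)]], finalize=lambda i, j, mu, beta: (0.0,),
    )
    with pytest.raises(ValueError, match="commutative"):
        run_multistring_inside(inst, spec)


def test_size_cap_enforced():
    inst = MultiStringInstance(["A" * 20, "A" * 20, "A" * 20])
    with pytest.raises(ValueError, match="cap"):
        saf_score(inst, default_saf_scoring(), size_cap=4096)
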