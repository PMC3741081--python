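"""Multiplication variants, kernels, and the block-concatenation identities."""

import numpy as np
import pytest

from valiantdp.algebra import (
    BOOLEAN,
    DOT,
    MAX_PLUS,
    MIN_PLUS,
    CountingDotKernel,
    MultiplicationVariant,
    check_block_identities,
    full_phi,
    get_kernel,
    mat_add,
    mat_mult,
    matrices_close,
    naive_mat_mult,
    register_kernel,
    standard_variants,
    strassen_mat_mult,
)

VARIANTS = [DOT, MIN_PLUS, MAX_PLUS, BOOLEAN]


def random_matrix(variant, shape, rng):
    if variant.domain == "boolean":
        return rng.random(shape) < 0.4
    return np.round(rng.uniform(-5, 5, shape), 2)


def test_standard_variants_present_and_lawful():
    vs = standard_variants()
    assert set(vs) == {"dot", "min_plus", "max_plus", "boolean"}
    assert vs["dot"].phi == 0.0
    assert vs["min_plus"].phi == np.inf
    assert vs["max_plus"].phi == -np.inf
    assert vs["boolean"].phi is False
    assert all(v.oplus_commutative for v in vs.values())
    # phi is absorbing for otimes and neutral for oplus on sampled elements
    rng = np.random.default_rng(0)
    for v in vs.values():
        for _ in range(20):
            a = random_matrix(v, (), rng)[()]
            assert v.otimes(a, v.phi) == v.phi
            assert v.otimes(v.phi, a) == v.phi
            assert v.oplus(a, v.phi) == a
            assert v.oplus(v.phi, a) == a


def test_oplus_associativity_sampled():
    rng = np.random.default_rng(1)
    for v in VARIANTS:
        for _ in range(50):
            a, b, c = (random_matrix(v, (), rng)[()] for _ in range(3))
            lhs = v.oplus(v.oplus(a, b), c)
            rhs = v.oplus(a, v.oplus(b, c))
            assert lhs == rhs or abs(lhs - rhs) < 1e-12


def test_non_associative_variant_rejected():
    with pytest.raises(ValueError):
        MultiplicationVariant(
            name="bad", domain="real", otimes=lambda a, b: a, oplus=lambda a, b: a,
            phi=0.0, dtype=np.dtype(float), oplus_associative=False,
        )


@pytest.mark.parametrize("variant", VARIANTS, ids=lambda v: v.name)
def test_mat_mult_matches_naive_on_random_pairs(variant):
    rng = np.random.default_rng(2)
    for trial in range(25):
        n1, n2, n3 = rng.integers(1, 13, size=3)
        X = random_matrix(variant, (n1, n2), rng)
        Y = random_matrix(variant, (n2, n3), rng)
        fast = mat_mult(X, Y, variant)
        slow = naive_mat_mult(X, Y, variant)
        assert matrices_close(fast, slow, variant)


def test_known_max_plus_product():
    X = np.array([[1.0, 2.0], [3.0, 4.0]])
    Y = np.array([[5.0, 6.0], [7.0, 8.0]])
    Z = mat_mult(X, Y, MAX_PLUS)
    assert np.array_equal(Z, [[9.0, 10.0], [11.0, 12.0]])


def test_identity_matrix_under_dot():
    rng = np.random.default_rng(3)
    Y = rng.normal(size=(2, 2))
    assert np.allclose(mat_mult(np.eye(2), Y, DOT), Y)


@pytest.mark.parametrize("variant", VARIANTS, ids=lambda v: v.name)
def test_empty_inner_dimension_yields_all_phi(variant):
    X = full_phi(variant, (2, 0))
    Y = full_phi(variant, (0, 3))
    Z = mat_mult(X, Y, variant)
    assert Z.shape == (2, 3)
    assert matrices_close(Z, full_phi(variant, (2, 3)), variant)


@pytest.mark.parametrize("variant", VARIANTS, ids=lambda v: v.name)
def test_all_phi_matrix_absorbs(variant):
    rng = np.random.default_rng(4)
    X = random_matrix(variant, (4, 5), rng)
    P = full_phi(variant, (5, 3))
    assert matrices_close(
        mat_mult(X, P, variant), full_phi(variant, (4, 3)), variant
    )


def test_mat_add_entrywise_and_shape_errors():
    assert np.array_equal(
        mat_add(np.array([[1.0, 2.0]]), np.array([[3.0, 4.0]]), DOT), [[4.0, 6.0]]
    )
    assert np.array_equal(
        mat_add(np.array([[1.0]]), np.array([[2.0]]), MAX_PLUS), [[2.0]]
    )
    with pytest.raises(ValueError):
        mat_add(np.zeros((2, 2)), np.zeros((3, 2)), DOT)
    with pytest.raises(ValueError):
        mat_mult(np.zeros((2, 3)), np.zeros((2, 3)), DOT)


@pytest.mark.parametrize("variant", VARIANTS, ids=lambda v: v.name)
def test_block_identities_hold_on_random_decompositions(variant):
    rng = np.random.default_rng(5)
    for trial in range(100):
        r = int(rng.integers(1, 7))
        X1 = random_matrix(variant, (r, r), rng)
        X2 = random_matrix(variant, (r, r), rng)
        Y = random_matrix(variant, (r, r), rng)
        Y1 = random_matrix(variant, (r, r), rng)
        Y2 = random_matrix(variant, (r, r), rng)
        assert check_block_identities(X1, X2, Y, Y1, Y2, variant)


def test_block_identities_on_all_phi_blocks():
    for variant in VARIANTS:
        P = full_phi(variant, (3, 3))
        assert check_block_identities(P, P, P, P, P, variant)


@pytest.mark.parametrize("variant", VARIANTS, ids=lambda v: v.name)
def test_registered_kernels_agree_with_naive(variant):
    rng = np.random.default_rng(6)
    from valiantdp.algebra import kernel_names

    for name in kernel_names(variant):
        for trial in range(10):
            n = int(rng.integers(1, 33))
            X = random_matrix(variant, (n, n), rng)
            Y = random_matrix(variant, (n, n), rng)
            assert matrices_close(
                mat_mult(X, Y, variant, name),
                naive_mat_mult(X, Y, variant),
                variant,
            ), f"kernel {name} disagrees with naive for {variant.name}"


def test_reordering_kernel_rejected_for_noncommutative_oplus():
    v = MultiplicationVariant(
        name="left_biased", domain="real",
        otimes=lambda a, b: a * b, oplus=lambda a, b: a,  # keep-first: not commutative
        phi=0.0, dtype=np.dtype(float), oplus_commutative=False,
    )
    with pytest.raises(ValueError):
        register_kernel(v, lambda X, Y: X @ Y, "fast", reorders=True)
    register_kernel(v, lambda X, Y: naive_mat_mult(X, Y, v), "ordered")
    assert get_kernel(v, "ordered") is not None


def test_strassen_matches_vendor_multiply():
    rng = np.random.default_rng(7)
    for shape in [(16, 16, 16), (37, 23, 41), (64, 64, 64), (9, 1, 5)]:
        X = rng.normal(size=shape[:2])
        Y = rng.normal(size=shape[1:])
        assert np.allclose(strassen_mat_mult(X, Y), X @ Y, rtol=1e-9)


try:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.sampled_from(VARIANTS),
        st.integers(1, 5),
        st.integers(0, 2**32 - 1),
    )
    def test_block_identities_property(variant, r, entropy):
        """For any variant and any random block decomposition, the stacked,
        split, and mixed concatenation identities of the semiring matrix
        product hold."""
        rng = np.random.default_rng(entropy)
        blocks = [random_matrix(variant, (r, r), rng) for _ in range(5)]
        assert check_block_identities(*blocks, variant)

except ImportError:  # hypothesis is an optional test dependency
    pass


def test_counting_kernel_subcubic_growth():
    """Strassen-mode multiplication counts grow strictly slower than n^3."""
    counts = {}
    for n in (64, 128):
        k = CountingDotKernel(mode="strassen", threshold=8)
        k(np.ones((n, n)), np.ones((n, n)))
        counts[n] = k.count
        naive = CountingDotKernel(mode="naive")
        naive(np.ones((n, n)), np.ones((n, n)))
        assert k.count < naive.count == n**3
    # doubling n multiplies the count by 7 (< 8) at exact powers of two
    assert counts[128] == 7 * counts[64]
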