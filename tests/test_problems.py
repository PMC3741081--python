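"""Problem instantiations against enumeration and classical oracles."""

import math

import numpy as np
import pytest

from valiantdp.generate import gen_random_cnf, gen_random_rna, gen_random_sentence
from valiantdp.oracles import (
    brute_bpp,
    brute_cfg,
    brute_max_pairs,
    brute_partition,
    brute_wcfg,
)
from valiantdp.problems import (
    CNFGrammar,
    Folding,
    base_pair_probabilities,
    cfg_recognize,
    complementary,
    fold_max_pairs,
    normalize_rna,
    partition_function,
    saf_score,
    traceback_max_pairs,
    wcfg_best_parse,
)
from valiantdp.multistring import MultiStringInstance
from valiantdp.problems.saf import default_saf_scoring


# --- base pairing ----------------------------------------------------------


@pytest.mark.parametrize(
    "x,y,expect",
    [("A", "U", True), ("U", "A", True), ("C", "G", True), ("G", "C", True),
     ("G", "U", True), ("U", "G", True), ("A", "C", False), ("A", "G", False),
     ("C", "U", False), ("A", "A", False)],
)
def test_complementary_pairs(x, y, expect):
    assert complementary(x, y) is expect


def test_complementary_rejects_non_rna():
    with pytest.raises(ValueError):
        complementary("A", "T")


def test_normalize_rna():
    assert normalize_rna("acgt") == "ACGU"
    assert normalize_rna("ACGT") == "ACGU"
    with pytest.raises(ValueError):
        normalize_rna("ACGX")


@pytest.mark.parametrize(
    "s,expect", [("", 0), ("A", 0), ("AA", 0), ("AU", 1), ("ACAGUGACU", 3)]
)
def test_fold_max_pairs_examples(s, expect):
    assert fold_max_pairs(s) == expect


def test_fold_max_pairs_matches_enumeration():
    rng = np.random.default_rng(40)
    for trial in range(30):
        s = gen_random_rna(int(rng.integers(0, 13)), 500 + trial)
        assert fold_max_pairs(s) == brute_max_pairs(s)


def test_folding_invariants():
    Folding({(0, 3), (1, 2)}, 4)  # properly nested
    with pytest.raises(ValueError):
        Folding({(0, 2), (1, 3)}, 4)  # crossing
    with pytest.raises(ValueError):
        Folding({(2, 2)}, 4)  # a < b required
    with pytest.raises(ValueError):
        Folding({(0, 4)}, 4)  # out of range


def test_traceback_recovers_an_optimal_nested_folding():
    assert traceback_max_pairs("AU").pairs == frozenset({(0, 1)})
    assert traceback_max_pairs("AA").pairs == frozenset()
    rng = np.random.default_rng(41)
    for trial in range(25):
        s = gen_random_rna(int(rng.integers(0, 25)), 600 + trial)
        folding = traceback_max_pairs(s)  # Folding() validates nestedness
        assert folding.count_complementary(s) == fold_max_pairs(s)
        # deterministic under identical input
        assert traceback_max_pairs(s).pairs == folding.pairs


# --- partition function ----------------------------------------------------


def test_partition_base_cases_and_worked_example():
    paired, allm, Z = partition_function("AU")
    assert allm[0, 0] == allm[1, 1] == allm[2, 2] == 1.0
    assert allm[0, 1] == 1.0
    assert Z == pytest.approx(1 + math.e, rel=1e-12)


def test_partition_matches_enumeration():
    rng = np.random.default_rng(42)
    for trial in range(25):
        s = gen_random_rna(int(rng.integers(0, 13)), 700 + trial)
        _, _, Z = partition_function(s)
        assert Z == pytest.approx(brute_partition(s), rel=1e-9)


def test_partition_ensemble_properties():
    rng = np.random.default_rng(43)
    for trial in range(15):
        s = gen_random_rna(int(rng.integers(1, 20)), 800 + trial)
        _, _, Z = partition_function(s)
        assert Z >= 1.0
        has_pair = any(
            complementary(s[a], s[b])
            for a in range(len(s))
            for b in range(a + 1, len(s))
        )
        if has_pair:
            assert Z > 1.0
        else:
            assert Z == pytest.approx(1.0)
        # appending a partner for the first base can only enrich the ensemble
        partner = {"A": "U", "U": "A", "C": "G", "G": "C"}[s[0]]
        _, _, Z2 = partition_function(s + partner)
        assert Z2 >= Z - 1e-12


# --- base-pair probabilities -----------------------------------------------


def test_bpp_worked_example():
    res = base_pair_probabilities("AU")
    assert res["P"][0, 1] == pytest.approx(math.e / (1 + math.e), rel=1e-12)


def test_bpp_matches_enumeration():
    rng = np.random.default_rng(44)
    for trial in range(15):
        s = gen_random_rna(int(rng.integers(1, 11)), 900 + trial)
        res = base_pair_probabilities(s)
        assert np.allclose(res["P"], brute_bpp(s), atol=1e-9)


def test_bpp_probability_axioms():
    rng = np.random.default_rng(45)
    for trial in range(10):
        s = gen_random_rna(int(rng.integers(2, 30)), 1000 + trial)
        res = base_pair_probabilities(s)
        P, gamma, Z = res["P"], res["gamma"], res["Z"]
        assert np.all(P >= -1e-12) and np.all(P <= 1 + 1e-12)
        assert np.all(gamma <= Z + 1e-9 * Z)
        full = P + P.T
        assert np.all(full.sum(axis=1) <= 1 + 1e-12)


# --- grammars ---------------------------------------------------------------


@pytest.fixture
def toy_grammar():
    return CNFGrammar(
        ["S", "A", "B"], "S",
        [("A", "a", 2.0), ("B", "b", 3.0)],
        [("S", "A", "B", 1.0)],
    )


def test_cfg_recognition_examples(toy_grammar):
    assert cfg_recognize(toy_grammar, ["a", "b"]) is True
    assert cfg_recognize(toy_grammar, ["b", "a"]) is False
    assert cfg_recognize(toy_grammar, ["a"]) is False
    assert cfg_recognize(toy_grammar, []) is False


def test_wcfg_examples(toy_grammar):
    assert wcfg_best_parse(toy_grammar, ["a", "b"]) == pytest.approx(6.0)
    assert wcfg_best_parse(toy_grammar, ["b", "b", "a"]) == -np.inf


def test_grammar_validation():
    with pytest.raises(ValueError):
        CNFGrammar(["S"], "X", [("S", "a", 0.0)], [])
    with pytest.raises(ValueError):
        CNFGrammar(["S"], "S", [("A", "a", 0.0)], [])
    with pytest.raises(ValueError):
        CNFGrammar(["S"], "S", [], [("S", "S", "T", 0.0)])


def test_grammars_match_cky_oracles():
    rng = np.random.default_rng(46)
    for trial in range(40):
        g = gen_random_cnf(int(rng.integers(1, 6)), int(rng.integers(0, 11)), 1100 + trial)
        toks = gen_random_sentence("abc", int(rng.integers(0, 21)), 1200 + trial)
        assert cfg_recognize(g, toks) == brute_cfg(g, toks)
        we = wcfg_best_parse(g, toks)
        wo = brute_wcfg(g, toks)
        assert we == wo or we == pytest.approx(wo, rel=1e-12)


# --- simultaneous alignment and folding -------------------------------------


def test_saf_score_symmetric_under_string_permutation():
    """The default scoring is symmetric in string order, so the score is
    invariant under permuting the inputs."""
    sc = default_saf_scoring()
    a = saf_score(MultiStringInstance(["GCAU", "GAU"]), sc)
    b = saf_score(MultiStringInstance(["GAU", "GCAU"]), sc)
    assert a == pytest.approx(b)


def test_saf_figure_folding_is_nested():
    f = Folding({(1, 4), (7, 15), (9, 12)}, 17)
    assert len(f) == 3
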