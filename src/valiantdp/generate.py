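"""Seeded generators for random RNA strings, CNF grammars, and string sets.

Everything is deterministic under its seed; the random suites used by the
oracle-equivalence tests are built from these.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

from .multistring import MultiStringInstance
from .problems.grammar import CNFGrammar
from .problems.rna import RNA_ALPHABET

__all__ = ["gen_random_rna", "gen_random_cnf", "gen_random_multistring", "gen_random_sentence"]


def gen_random_rna(length: int, seed: int) -> str:
    """Uniform random RNA string of the given length."""
    if length < 0:
        raise ValueError("length must be non-negative")
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(RNA_ALPHABET), size=length)) if length else ""


def gen_random_cnf(
    n_nonterminals: int,
    n_rules: int,
    seed: int,
    alphabet: Sequence[str] = ("a", "b", "c"),
    max_weight: float = 5.0,
) -> CNFGrammar:
    """Random CNF grammar with useful language density.

    Every nonterminal receives at least one terminal rule (so spans of any
    length can bottom out), then ``n_rules`` random binary rules are drawn
    over the nonterminals.  Weights are uniform on [0, max_weight].
    """
    if n_nonterminals < 1 or n_rules < 0:
        raise ValueError("need at least one nonterminal and n_rules >= 0")
    rng = np.random.default_rng(seed)
    names = [f"N{k}" if k else "S" for k in range(n_nonterminals)]
    terminal_rules = []
    for a in names:
        for t in rng.choice(alphabet, size=rng.integers(1, len(alphabet) + 1), replace=False):
            terminal_rules.append((a, str(t), float(rng.uniform(0, max_weight))))
    binary_rules = []
    for _ in range(n_rules):
        a, b, c = rng.choice(names, size=3)
        binary_rules.append((str(a), str(b), str(c), float(rng.uniform(0, max_weight))))
    return CNFGrammar(names, "S", terminal_rules, binary_rules)


def gen_random_sentence(alphabet: Sequence[str], length: int, seed: int) -> List[str]:
    rng = np.random.default_rng(seed)
    return [str(t) for t in rng.choice(list(alphabet), size=length)]


def gen_random_multistring(
    m: int, lengths: Sequence[int], seed: int
) -> MultiStringInstance:
    """Random RNA string set; ``lengths`` may list one length per string."""
    if m < 1:
        raise ValueError("need at least one string")
    lengths = list(lengths)
    if len(lengths) == 1:
        lengths = lengths * m
    if len(lengths) != m:
        raise ValueError("lengths must match the number of strings")
    return MultiStringInstance(
        [gen_random_rna(n, int(seed) * 1000003 + p) for p, n in enumerate(lengths)]
    )
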