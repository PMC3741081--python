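"""CFG recognition and weighted best-parse over Chomsky-normal-form grammars.

Recognition is the boolean-variant inside problem with one property set per
nonterminal: the cell (i, j) of nonterminal A records whether tokens i..j-1
derive from A.  Each binary rule A -> B C contributes its own split
accumulation slot (the generalization of the single-slot template that makes
CKY fit without one property per rule), and terminal rules seed length-one
spans.  The weighted variant replaces booleans with max-plus scores: the
weight of a parse tree is the sum of the weights of all rule applications,
terminal rules included, and unparseable spans carry -inf.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ..algebra import BOOLEAN, MAX_PLUS
from ..inside import InsideProblemSpec, run_inside, run_inside_classical

__all__ = ["CNFGrammar", "cfg_spec", "cfg_recognize", "wcfg_spec", "wcfg_best_parse"]

NEG_INF = -np.inf


@dataclass(frozen=True)
class CNFGrammar:
    """A CNF grammar: binary rules A -> B C and terminal rules A -> 'a'.

    Weights are optional (default 0) and only meaningful under max-plus.
    The start symbol defaults to the left-hand side of the first rule.
    """

    nonterminals: Tuple[str, ...]
    start: str
    terminal_rules: Tuple[Tuple[str, str, float], ...]
    binary_rules: Tuple[Tuple[str, str, str, float], ...]

    def __init__(self, nonterminals, start, terminal_rules, binary_rules):
        object.__setattr__(self, "nonterminals", tuple(nonterminals))
        object.__setattr__(self, "start", start)
        object.__setattr__(
            self,
            "terminal_rules",
            tuple((a, t, float(w)) for a, t, w in terminal_rules),
        )
        object.__setattr__(
            self,
            "binary_rules",
            tuple((a, b, c, float(w)) for a, b, c, w in binary_rules),
        )
        declared = set(self.nonterminals)
        if self.start not in declared:
            raise ValueError(f"start symbol {self.start!r} is not a nonterminal")
        for a, t, _ in self.terminal_rules:
            if a not in declared:
                raise ValueError(f"undeclared nonterminal {a!r} in terminal rule")
        for a, b, c, _ in self.binary_rules:
            for sym in (a, b, c):
                if sym not in declared:
                    raise ValueError(f"undeclared nonterminal {sym!r} in binary rule")

    def index(self) -> Dict[str, int]:
        return {a: k for k, a in enumerate(self.nonterminals)}


def _build_spec(g: CNFGrammar, tokens: Sequence[str], weighted: bool) -> InsideProblemSpec:
    idx = g.index()
    K = len(g.nonterminals)
    variant = MAX_PLUS if weighted else BOOLEAN
    # one split slot per binary rule, grouped by left-hand side
    mu_specs: List[List[Tuple[int, int]]] = [[] for _ in range(K)]
    rule_weights: List[List[float]] = [[] for _ in range(K)]
    for a, b, c, w in g.binary_rules:
        mu_specs[idx[a]].append((idx[b], idx[c]))
        rule_weights[idx[a]].append(w)
    term: Dict[Tuple[str, str], float] = {}
    for a, t, w in g.terminal_rules:
        key = (a, t)
        if key not in term or w > term[key]:
            term[key] = w

    if weighted:

        def finalize(i, j, mu, beta):
            out = []
            for k, a in enumerate(g.nonterminals):
                best = NEG_INF
                if j == i + 1:
                    w = term.get((a, tokens[i]))
                    if w is not None:
                        best = w
                for s, w in enumerate(rule_weights[k]):
                    best = max(best, mu[k][s] + w)
                out.append(best)
            return out

    else:

        def finalize(i, j, mu, beta):
            out = []
            for k, a in enumerate(g.nonterminals):
                val = False
                if j == i + 1:
                    val = (a, tokens[i]) in term
                val = val or any(mu[k])
                out.append(val)
            return out

    return InsideProblemSpec(
        K=K,
        property_names=g.nonterminals,
        variant=variant,
        mu_specs=mu_specs,
        finalize=finalize,
    )


def cfg_spec(g: CNFGrammar, tokens: Sequence[str]) -> InsideProblemSpec:
    return _build_spec(g, tokens, weighted=False)


def wcfg_spec(g: CNFGrammar, tokens: Sequence[str]) -> InsideProblemSpec:
    return _build_spec(g, tokens, weighted=True)


def _run(g, tokens, weighted, kernel, cutoff, classical):
    tokens = list(tokens)
    spec = _build_spec(g, tokens, weighted)
    N = len(tokens) + 1
    if classical:
        return run_inside_classical(N, spec)
    return run_inside(N, spec, kernel=kernel, cutoff=cutoff)


def cfg_recognize(
    g: CNFGrammar,
    tokens: Sequence[str],
    kernel=None,
    cutoff: int = 32,
    classical: bool = False,
    return_matrices: bool = False,
):
    """Whether the token sequence derives from the start symbol.

    The empty sentence is never recognized: CNF as used here has no
    epsilon-rules.
    """
    tokens = list(tokens)
    B = _run(g, tokens, False, kernel, cutoff, classical)
    k = g.index()[g.start]
    ok = bool(B[k][0, len(tokens)])
    if return_matrices:
        return ok, dict(zip(g.nonterminals, B))
    return ok


def wcfg_best_parse(
    g: CNFGrammar,
    tokens: Sequence[str],
    kernel=None,
    cutoff: int = 32,
    classical: bool = False,
) -> float:
    """Maximum parse-tree weight (sum over all rule applications); -inf if
    the sentence is not derivable."""
    tokens = list(tokens)
    B = _run(g, tokens, True, kernel, cutoff, classical)
    k = g.index()[g.start]
    return float(B[k][0, len(tokens)])
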