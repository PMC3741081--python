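"""File formats: FASTA input, grammar dialect, dot-bracket and TSV output.

Grammar files hold one CNF rule per line::

    LHS -> RHS1 RHS2 [weight]
    LHS -> 'terminal' [weight]

with ``#`` comments; terminals are quoted to distinguish them from
nonterminals, the first rule's left-hand side is the start symbol, and
weights default to 0.  Base-pair probabilities are written as TSV with
1-based inclusive base indices; dot-bracket strings use one character per
base with '(' and ')' for paired columns.
"""

from __future__ import annotations

import re
from typing import Iterable, List, Tuple

import numpy as np
from Bio import SeqIO

from .problems.grammar import CNFGrammar
from .problems.rna import Folding, normalize_rna

__all__ = [
    "read_fasta",
    "read_grammar",
    "parse_grammar",
    "write_grammar",
    "format_grammar",
    "write_bpp",
    "write_dotbracket",
    "parse_dotbracket",
]


def read_fasta(path) -> List[Tuple[str, str]]:
    """(id, normalized RNA sequence) for every record in a FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return [(r.id, normalize_rna(str(r.seq))) for r in records]


_TERMINAL = re.compile(r"^'([^']*)'$")


def parse_grammar(text: str) -> CNFGrammar:
    terminal_rules = []
    binary_rules = []
    order: List[str] = []
    start = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "->" not in line:
            raise ValueError(f"line {lineno}: missing '->' in rule {raw!r}")
        lhs, rhs = (part.strip() for part in line.split("->", 1))
        if not lhs or _TERMINAL.match(lhs):
            raise ValueError(f"line {lineno}: bad left-hand side {lhs!r}")
        fields = rhs.split()
        weight = 0.0
        if fields and _is_number(fields[-1]):
            weight = float(fields[-1])
            fields = fields[:-1]
        if lhs not in order:
            order.append(lhs)
        if start is None:
            start = lhs
        if len(fields) == 1 and (m := _TERMINAL.match(fields[0])):
            terminal_rules.append((lhs, m.group(1), weight))
        elif len(fields) == 2:
            for sym in fields:
                if _TERMINAL.match(sym):
                    raise ValueError(
                        f"line {lineno}: terminals may not appear in binary "
                        f"rules ({raw!r} is not Chomsky normal form)"
                    )
            binary_rules.append((lhs, fields[0], fields[1], weight))
        else:
            raise ValueError(
                f"line {lineno}: rule {raw!r} is not Chomsky normal form"
            )
    if start is None:
        raise ValueError("grammar file contains no rules")
    for _, b, c, _ in binary_rules:
        for sym in (b, c):
            if sym not in order:
                order.append(sym)
    return CNFGrammar(order, start, terminal_rules, binary_rules)


def read_grammar(path) -> CNFGrammar:
    with open(path) as fh:
        return parse_grammar(fh.read())


def format_grammar(g: CNFGrammar) -> str:
    lines = []
    for a, t, w in g.terminal_rules:
        lines.append(f"{a} -> '{t}' {_fmt_weight(w)}".rstrip())
    for a, b, c, w in g.binary_rules:
        lines.append(f"{a} -> {b} {c} {_fmt_weight(w)}".rstrip())
    # the start symbol must own the first line
    lines.sort(key=lambda ln: 0 if ln.split(" ", 1)[0] == g.start else 1)
    return "\n".join(lines) + "\n"


def write_grammar(path, g: CNFGrammar) -> None:
    with open(path, "w") as fh:
        fh.write(format_grammar(g))


def write_bpp(path, P: np.ndarray) -> None:
    """TSV of pair probabilities: columns i, j (1-based, inclusive), prob."""
    n = P.shape[0]
    with open(path, "w") as fh:
        fh.write("i\tj\tprob\n")
        for a in range(n):
            for b in range(a + 1, n):
                if P[a, b] > 0.0:
                    fh.write(f"{a + 1}\t{b + 1}\t{P[a, b]:.9g}\n")


def write_dotbracket(folding: Folding, n: int) -> str:
    """Dot-bracket rendering of a nested folding over n columns."""
    if folding.n != n:
        raise ValueError("folding length disagrees with requested width")
    out = ["."] * n
    for a, b in folding.pairs:
        out[a] = "("
        out[b] = ")"
    return "".join(out)


def parse_dotbracket(text: str) -> Folding:
    stack = []
    pairs = []
    for i, ch in enumerate(text):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at column {i}")
            pairs.append((stack.pop(), i))
        elif ch != ".":
            raise ValueError(f"unexpected character {ch!r} at column {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at column {stack[-1]}")
    return Folding(pairs, len(text))


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def _fmt_weight(w: float) -> str:
    if w == 0.0:
        return ""
    return f"{w:.9g}"
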