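# valiantdp

Valiant-style divide-and-conquer semiring dynamic programming for RNA
secondary structure and context-free-grammar problems.

A large family of sequence algorithms — Nussinov-style RNA base-pair
maximization, McCaskill-style partition functions and base-pair
probabilities, CKY parsing of (weighted) Chomsky-normal-form grammars, and
Sankoff-style simultaneous alignment and folding — fill a triangular table
of *inside* values β<sub>i,j</sub> over substrings with recurrences of the
shape

```
μ[i,j] = ⊕_{q ∈ (i,j)}  β[i,q] ⊗ β[q,j]          (split accumulation)
β[i,j] = finalize(i, j, μ[i,j], nearby finalized values)
```

over a semiring-like algebra (⊕ associative, with an absorbing zero φ):
max-plus for optimization, the dot product for ensemble sums, boolean for
recognition.  The classical bottom-up orders spend Θ(n³) time in the split
loops.  This package implements the alternative evaluation order due to
Valiant: a divide-and-conquer recursion over sub-matrices that charges all
split work to matrix multiplications between sibling recursive calls, so
the whole computation runs at the speed of the multiplication kernel — a
vendor BLAS multiply, a blocked tropical kernel, or a genuinely sub-cubic
Strassen multiply with a measurable ~n^2.81 scalar-multiplication count.

Three generic engines are provided, each parameterized by a pluggable
problem spec and multiplication kernel:

* **inside** (`valiantdp.inside`) — K mutually recursive inside property
  sets over one index space;
* **outside** (`valiantdp.outside`) — outside properties
  α<sub>i,j</sub> of the residual string after excising s[i:j], with
  prefix-form (`⊕_{q<i} β[q,i] ⊗ α[q,j]`) and suffix-form
  (`⊕_{q>j} α[i,q] ⊗ β[j,q]`) split accumulations over pre-computed inside
  matrices;
* **multistring** (`valiantdp.multistring`) — inside DP over a lattice of
  position tuples for several strings at once, linearized by a monotone
  mixed-radix codec with invalid cells masked to φ.

Every engine result is checkable against an independent classical-order DP
(`run_inside_classical`, `run_outside_classical`) and, at small sizes,
against exhaustive enumeration (`valiantdp.oracles`).

## Worked example

The 9-base string `ACAGUGACU` admits at most 3 complementary base pairs
(A-U, C-G, or the G-U wobble) in a nested folding:

```bash
$ printf '>example\nACAGUGACU\n' > ex.fa
$ valiantdp fold --traceback ex.fa
3
(..((.)))
```

The first line is the optimal pair count; the dot-bracket line shows one
optimal folding (pairs 0·8, 3·7, 4·6).  Under the simplified Boltzmann
ensemble in which a folding with k pairs has weight e^k, the partition
function and the most probable pairs are:

```bash
$ valiantdp partition ex.fa
673.990685876
$ valiantdp bpp ex.fa --out ex_bpp.tsv && head -4 ex_bpp.tsv
i	j	prob
1	5	0.137288421
1	9	0.359946462
2	4	0.289381496
```

Z = 673.99… is the sum of e^k over all nested foldings; the TSV lists, for
each 1-based base pair (i, j), the fraction of ensemble weight carried by
foldings containing it (base 1 pairs base 9 with probability 0.36).

Grammar problems use a plain rule file (first left-hand side is the start
symbol, terminals quoted, optional trailing weight):

```bash
$ printf "S -> A B 1\nA -> 'a' 2\nB -> 'b' 3\n" > g.cnf
$ valiantdp recognize --grammar g.cnf --sentence "a b"
true
$ valiantdp parse-weight --grammar g.cnf --sentence "a b"
6
```

The parse weight 6 sums the weights of all three rule applications in the
single derivation.  `valiantdp saf` scores a simultaneous alignment and
folding of a multi-record FASTA, and `valiantdp gen rna|grammar` produces
seeded random inputs.  Global flags `--kernel`, `--cutoff`, `--verify`,
`--seed`, `--log-level` (or a YAML `--config`) control the engines;
`--verify` re-checks the recursion's pre-condition against a freshly
computed classical oracle at every call.

See `docs/methods.md` for the algorithms, the engine contracts, and the
numerical choices.

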