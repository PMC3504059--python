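# threeitem

Convert conventional phylogenetic character matrices into **three-item
statement (3TS) matrices** for parsimony and likelihood analysis.

Three-taxon analysis re-expresses each character of a data matrix as a
set of minimal rooted hypotheses A(BC): *taxa B and C are more closely
related to each other than either is to A*. The resulting 3TS matrix is
itself a character matrix (each statement is one column) that standard
phylogenetics software can analyse. `threeitem` is for systematists who
want to build such matrices from binary, ordered-multistate,
unordered-multistate, DNA, RNA or amino-acid data without hand-coding
them.

## The method

For a character scored over *t* taxa:

* **binary** characters (states 0/1, 0 plesiomorphic *a priori*): one
  statement x(y z) for every taxon *x* with state 0 and every unordered
  pair {y, z} with state 1 — `m·n(n−1)/2` statements for *m* zeros and
  *n* ones.
* **G-representation** (unordered multistate, "exhaustion of the
  outgroup value"): every observed state *p* serves in turn as
  plesiomorphic against every other observed state *a*, giving
  `Σ_p Σ_{a≠p} n_p·n_a(n_a−1)/2` statements.
* **W-representation**: only the state carried by a designated outgroup
  taxon is treated as plesiomorphic (`WS` = W written in 0/1/? binary
  notation).
* **ordered multistate**: the character is first decomposed into
  additive (Farris) binary threshold columns (one per observed level
  above the minimum), each then treated as binary; the `-mus` option
  keeps only unique statements per input character.

**Fractional weighting** (Nelson–Ladiges) corrects for redundancy among
the statements of one character. In the binary case

```
s = n(n−1)(t−n)/2,   i = (n−1)(t−n),   weight = i/s = 2/n
```

(*s* total statements, *i* independent ones). For the G-representation
each (p, a) state pair is treated as a pseudo-binary character, giving
per-statement weight `2/n_a`; the sum of weights per character equals
*i* exactly (all weight arithmetic is in exact rationals). For the
W-representation an optional block-level fraction `Wt = i_w/s_w` (or
`1/s_w`) is provided. IUPAC ambiguity codes are treated as missing data
by default; an opt-in mode instead averages each statement's weight over
all resolutions of the ambiguous cells.

## Worked example

Input `five.csv` — five taxa, one unordered character with states
0, 1, 1, 2, 2:

```
A,0
B,1
C,1
D,2
E,2
```

```sh
$ threeitem five.csv -ium -ob -og -nex
INFO: input: 5 taxa, 1 characters (1 variable, 1 parsimony informative), type umc
INFO: 3TS matrix: 2 statement columns, binary notation, weighting uniform
INFO: wrote five.3ts.nex
INFO: wrote five.3ts.weights.tsv
```

`-og` without a name fixes the first taxon (A, state 0) as the outgroup,
so only A(BC) and A(DE) survive — 2 columns. Dropping the outgroup
(`threeitem five.csv -ium -oum -phy`) selects the G-representation and
yields all 6 statements: A(BC), A(DE), B(DE), C(DE), D(BC), E(BC); the
PHYLIP header reads `5 6`. The `.weights.tsv` sidecar lists each
column's source character, out-taxon, in-pair and exact rational weight.

Flags: `-ib/-idna/-irna/-iaa/-ium/-iom` declare the input type;
`-ob/-odna/-oum` the output notation; `-og [NAME]` fixes the outgroup;
`-uw/-fw/-wt` select weighting; `-nex/-phy/-csv` the output formats
(long options: `--input-type`, `--notation`, `--outgroup`,
`--weighting`, …). `threeitem demo-data` generates random example
matrices. Input matrices are limited to 5000 taxa and 100000 characters
by default (`--max-taxa`, `--max-chars`).

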