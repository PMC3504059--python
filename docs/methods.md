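# Methods

## Statement enumeration

A three-item statement (3TS) x(y z) is admitted from a character when
taxon *x* carries the plesiomorphic state and *y*, *z* share an
apomorphic state. The four representations differ only in which states
may act as plesiomorphic:

| representation | plesiomorphic state | statements per character |
|---|---|---|
| binary | state 0, a priori | m·C(n,2) |
| G | every observed state in turn | Σ_p Σ_{a≠p} n_p·C(n_a,2) |
| W / WS | the designated outgroup taxon's state | n_p·Σ_{a≠p} C(n_a,2) |
| ordered (omc) | level-wise, via additive binary coding | Σ_levels m_v·C(n_v,2) |

Taxa with missing data for a character are excluded from that
character's statements. Statements are emitted in a fixed order —
source character, then out-taxon index, then the sorted in-pair — so
identical inputs produce byte-identical outputs. Duplicate statements
across *different* characters are always kept; the unique-statements
option (`mus`) deduplicates only within one input character, which can
only matter for ordered characters (the same (out, pair) arises at
several threshold levels).

Additive decomposition uses the *observed* state levels rather than the
full 0..max range: a threshold at an unobserved level reproduces the
partition of the next observed level and so adds only duplicate
columns, which the per-character dedup would remove again.

For the W-representation, the outgroup is a *taxon*, fixed once for the
whole run (first taxon in the file unless named); each character's
plesiomorphic state is that taxon's state for that character. A
character for which the outgroup is unscored (missing or ambiguous) is
skipped with a warning. Whether an ingroup taxon sharing the outgroup's
state should itself emit statements is a genuinely open convention;
here it does (any taxon with the plesiomorphic state may be the
out-taxon), which keeps W a strict subset of G — the subset relation is
property-tested.

Constant and autapomorphic characters yield no statements. Statements
of the form (ABC) for such characters are deliberately out of scope.

## Weighting

All weight arithmetic uses exact rationals (`fractions.Fraction`);
decimals appear only at serialization (12 significant digits in the
NEXUS `wtset`; exact rationals in the TSV sidecar). The driving
invariant, checked in tests, is that per character the weights of a
fractionally weighted block sum exactly to *i*, the number of
independent statements.

* **binary (Nelson–Ladiges)**: s = n(n−1)(t−n)/2, i = (n−1)(t−n),
  per-statement weight i/s = 2/n, with t the scored taxa and n the
  apomorphic taxa.
* **G-representation**: each ordered state pair (p, a) is treated as a
  pseudo-binary character with t′ = n_p + n_a and n′ = n_a, so every
  statement with apomorphic state a weighs 2/n_a. This per-pair
  decomposition is a **reconstruction**: it degenerates to the binary
  closed forms when only one informative state exists, satisfies
  Σweights = i and s = enumeration count per pair, but other
  generalisations satisfying the same constraints exist. If a different
  published form is preferred, `weighting.fw_block_weights` is the
  single place to swap it; the conservation tests pin the invariants
  either way.
* **Wt (fixed outgroup)**: a block-level fraction applied uniformly to
  the character's statements. Default mode `independent` uses i_w/s_w
  (independent over total statements with the outgroup value fixed,
  computed per (p, a) pair as above but restricted to the fixed p);
  mode `reciprocal` uses 1/s_w. Both are provided because the defining
  fraction is only constrained, not determined, by its description;
  neither is asserted as the original tool's. Wt is distinct from
  Nelson–Ladiges fractional weighting and is the recommended option for
  clock-like multistate matrices.
* Fractional weighting of ordered-multistate statements is undefined
  here (the additive decomposition already multiplies statements, and
  the redundancy structure across levels is contested); requesting it
  is an error, uniform weights (optionally with `mus`) apply instead.

**Ambiguity.** The default — and recommended — policy maps gaps and
IUPAC ambiguity codes to missing data on input. The opt-in averaging
mode enumerates every resolution of a column's ambiguity codes
(refusing beyond 4096 resolutions per character) and assigns each
statement the mean of its per-resolution weights, counting zero where
it does not occur; with a uniform base this reduces to the statement's
occurrence fraction. When *every* character of the matrix contains an
ambiguity code, weighting is disabled outright and all weights are 1.
The `mus` option likewise forces uniform weights; combining it with
fractional weighting is an error rather than a silent override.

## Input and output conventions

Input is CSV: one row per taxon, first field the taxon name, no header
row by default (`--header`, `--delimiter` adjust). This dialect is a
documented choice, the simplest that spreadsheet tools emit. Size
limits default to 5000 taxa × 100000 characters and are configuration,
not constants.

Outputs: simplified NEXUS (DATA block; `DATATYPE=STANDARD` with an
explicit symbol list for binary notation, `DNA`/`RNA`/`PROTEIN` for
multistate sequence notation; an ASSUMPTIONS `wtset` when weights are
non-uniform), relaxed PHYLIP (whitespace-separated names; a strict
10-character mode is available and rejects names with whitespace), and
CSV mirroring the input dialect with an optional `#weights` comment
row. PHYLIP cannot carry weights, so a TSV sidecar records per-column
provenance (source character, out-taxon, in-pair) and exact weights.
Round-trips through independent readers (dendropy for NEXUS, Biopython
for PHYLIP, the package's own CSV parser) are part of the test suite.

## Synthetic data and what the tests show

The fixture generator draws i.i.d. cells per taxon and character from
the declared alphabet with configurable state frequencies, missing
fraction and (for sequence types) ambiguity fraction, seeded for
reproducibility. It deliberately does **not** simulate evolution on a
tree: the converter is a deterministic recoding, so correctness is a
combinatorial property of single columns and tree structure in the data
is irrelevant to it. Passing tests therefore certify the enumeration,
weighting and serialization logic — not anything about the phylogenetic
merit of 3TS analysis on real alignments, and not alignment-quality
effects, to which 3TS representations of molecular data are known to be
sensitive.

The brute-force oracle used in tests re-implements each admission rule
as a literal scan over all t·C(t−1, 2) taxon triples, sharing no code
with the enumeration engine; engine/oracle agreement is checked on 200
seeded random matrices (up to 12 taxa × 30 characters, all data types
and representations, with and without missing data) plus the
closed-form count identities. These sizes keep the whole default suite
in the tens of seconds while exercising every code path; counts grow
only polynomially, so larger matrices add cost, not coverage.

## Known limitations

* NEXUS/FASTA input, alignment and any tree inference are out of scope;
  the tool reads CSV and writes matrices for other software.
* The G-representation FW formulas and the Wt fraction are
  reconstructions constrained by their stated invariants (see above).
* Ambiguity averaging is exponential in the number of ambiguous cells
  per column and is capped; treat-as-missing is the default for a
  reason.
* Reproduction of published column counts requires third-party matrices
  that cannot be redistributed; `scripts/reproduce_published.py`
  automates the runs once they are downloaded. A mismatch there while
  the property suite passes would point at the open W-state or
  ambiguity conventions, not at the enumeration itself.
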