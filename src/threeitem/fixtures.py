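"""Random character matrices and brute-force oracles.

The generator produces reproducible matrices for any supported data type.
The oracles re-derive statement multisets and counts by a direct scan of
all (x, {y, z}) taxon triples with each representation's admission rule
written out literally -- deliberately sharing no code with
:mod:`threeitem.statement_engine` so they are a genuine cross-check.
Exposed on the command line as the ``demo-data`` subcommand.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np

from .matrix_io import AMBIGUITY_CODES, MISSING, CharacterMatrix, DataType
from .statement_engine import RepresentationConfig

__all__ = [
    "FixtureSpec",
    "generate_matrix",
    "oracle_enumerate",
    "oracle_counts",
    "DEFAULT_STATES",
]

DEFAULT_STATES: dict[DataType, tuple[str, ...]] = {
    DataType.BINARY: ("0", "1"),
    DataType.OMC: ("0", "1", "2", "3"),
    DataType.UMC: ("0", "1", "2"),
    DataType.DNA: ("A", "C", "G", "T"),
    DataType.RNA: ("A", "C", "G", "U"),
    DataType.AA: tuple("ACDEFGHIKLMNPQRSTVWY"),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one random matrix."""

    n_taxa: int = 8
    n_chars: int = 10
    data_type: DataType = DataType.BINARY
    state_frequencies: Optional[tuple[float, ...]] = None  # over DEFAULT_STATES
    missing_fraction: float = 0.0
    ambiguity_fraction: float = 0.0  # sequence types only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.state_frequencies is not None:
            if abs(sum(self.state_frequencies) - 1.0) > 1e-9:
                raise ValueError("state frequencies must sum to 1")
            if len(self.state_frequencies) != len(DEFAULT_STATES[self.data_type]):
                raise ValueError("one frequency per elementary state required")
        for frac in (self.missing_fraction, self.ambiguity_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


def generate_matrix(spec: FixtureSpec) -> CharacterMatrix:
    """Draw a random matrix; identical for identical specs (seed included)."""
    data_type = DataType(spec.data_type)
    rng = np.random.default_rng(spec.seed)
    states = DEFAULT_STATES[data_type]
    freqs = spec.state_frequencies
    ambiguity_codes = sorted(AMBIGUITY_CODES[data_type])

    names = tuple(f"t{i + 1:03d}" for i in range(spec.n_taxa))
    rows = []
    for _ in range(spec.n_taxa):
        row = []
        for _ in range(spec.n_chars):
            u = rng.random()
            if u < spec.missing_fraction:
                row.append(MISSING)
            elif ambiguity_codes and u < spec.missing_fraction + spec.ambiguity_fraction:
                row.append(ambiguity_codes[rng.integers(len(ambiguity_codes))])
            else:
                row.append(str(rng.choice(states, p=freqs)))
        rows.append(tuple(row))
    return CharacterMatrix(names, tuple(rows), data_type)


StatementKey = tuple[int, int, tuple[int, int], str, str]


def _oracle_states(matrix: CharacterMatrix, j: int) -> list[Optional[str]]:
    ambiguous = AMBIGUITY_CODES[matrix.data_type]
    return [
        None if (s == MISSING or s in ambiguous) else s for s in matrix.column(j)
    ]


def oracle_enumerate(
    matrix: CharacterMatrix, config: RepresentationConfig
) -> Counter:
    """Statement multiset by brute force over all taxon triples.

    Keys are ``(char, out, (in1, in2), p_state, a_state)``.  Ambiguity
    codes are treated as missing (the recommended policy); the oracle does
    not model resolution averaging.
    """
    out: Counter = Counter()
    taxa = range(matrix.n_taxa)
    og = (
        matrix.taxon_index(config.outgroup)
        if config.outgroup is not None
        else None
    )
    for j in range(matrix.n_chars):
        col = _oracle_states(matrix, j)
        if matrix.data_type is DataType.OMC:
            levels = sorted({int(s) for s in col if s is not None})
            seen_unique: set[tuple[int, tuple[int, int]]] = set()
            for v in levels[1:]:
                for x in taxa:
                    if col[x] is None or int(col[x]) >= v:
                        continue
                    for y, z in combinations(taxa, 2):
                        if x in (y, z) or col[y] is None or col[z] is None:
                            continue
                        if int(col[y]) >= v and int(col[z]) >= v:
                            if config.mus:
                                if (x, (y, z)) in seen_unique:
                                    continue
                                seen_unique.add((x, (y, z)))
                            out[(j, x, (y, z), "0", "1")] += 1
            continue

        if matrix.data_type is DataType.BINARY:
            for x in taxa:
                if col[x] != "0":
                    continue
                for y, z in combinations(taxa, 2):
                    if x not in (y, z) and col[y] == "1" and col[z] == "1":
                        out[(j, x, (y, z), "0", "1")] += 1
            continue

        if og is not None:  # W-representation
            og_state = col[og]
            if og_state is None:
                continue
            for x in taxa:
                if col[x] != og_state:
                    continue
                for y, z in combinations(taxa, 2):
                    if x in (y, z) or col[y] is None:
                        continue
                    if col[y] == col[z] and col[y] != og_state:
                        out[(j, x, (y, z), og_state, col[y])] += 1
        else:  # G-representation
            for x in taxa:
                if col[x] is None:
                    continue
                for y, z in combinations(taxa, 2):
                    if x in (y, z) or col[y] is None:
                        continue
                    if col[y] == col[z] and col[y] != col[x]:
                        out[(j, x, (y, z), col[x], col[y])] += 1
    return out


def oracle_counts(
    matrix: CharacterMatrix, config: RepresentationConfig
) -> list[int]:
    """Per-character statement counts from the closed forms.

    binary: m n(n-1)/2; G: sum over p != a of n_p C(n_a, 2); W with fixed
    outgroup state p: n_p * sum over a != p of C(n_a, 2); ordered
    multistate (without mus): the sum of the binary form over threshold
    levels.
    """
    counts: list[int] = []
    og = (
        matrix.taxon_index(config.outgroup)
        if config.outgroup is not None
        else None
    )
    for j in range(matrix.n_chars):
        col = _oracle_states(matrix, j)
        tallies: dict[str, int] = {}
        for s in col:
            if s is not None:
                tallies[s] = tallies.get(s, 0) + 1

        if matrix.data_type is DataType.BINARY:
            m, n = tallies.get("0", 0), tallies.get("1", 0)
            counts.append(m * comb(n, 2))
        elif matrix.data_type is DataType.OMC:
            if config.mus:
                raise ValueError("no closed form for unique-statement counts")
            levels = sorted({int(s) for s in col if s is not None})
            total = 0
            for v in levels[1:]:
                lo = sum(1 for s in col if s is not None and int(s) < v)
                hi = sum(1 for s in col if s is not None and int(s) >= v)
                total += lo * comb(hi, 2)
            counts.append(total)
        elif og is not None:
            p = col[og]
            if p is None:
                counts.append(0)
            else:
                counts.append(
                    tallies[p]
                    * sum(comb(n_a, 2) for a, n_a in tallies.items() if a != p)
                )
        else:
            counts.append(
                sum(
                    n_p * comb(n_a, 2)
                    for p, n_p in tallies.items()
                    for a, n_a in tallies.items()
                    if a != p
                )
            )
    return counts
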