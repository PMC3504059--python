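"""Enumeration of three-item statements from character columns.

A three-item statement (3TS) ``x(y z)`` asserts that taxa *y* and *z* are
more closely related to each other than either is to *x*.  Each statement
derives from one input character: *x* carries the plesiomorphic state and
*y*, *z* share an apomorphic state.

Representations
---------------
binary
    0/1 characters with state 0 plesiomorphic a priori: one statement per
    0-taxon and unordered pair of 1-taxa.
G (general)
    Unordered multistate characters by exhaustion of the outgroup value:
    every observed state serves in turn as plesiomorphic against every
    other observed state.
W (fixed outgroup)
    Only the state carried by a designated outgroup taxon is treated as
    plesiomorphic.  "WS" is W rendered in binary notation.
omc (ordered multistate)
    The character is first decomposed into additive (Farris) binary
    threshold columns; each derived column is then treated as binary.
    The ``mus`` option keeps only unique statements per input character.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Optional, Sequence

from .matrix_io import (
    AMBIGUITY_CODES,
    MISSING,
    CharacterMatrix,
    DataType,
    EmptyMatrixError,
    MatrixError,
    StatementProvenance,
    ThreeItemMatrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ThreeItemStatement",
    "StatementBlock",
    "RepresentationConfig",
    "effective_column",
    "enumerate_binary",
    "enumerate_umc_g",
    "enumerate_umc_w",
    "decompose_additive",
    "enumerate_omc",
    "render_column",
    "build_three_item_matrix",
]


@dataclass(frozen=True, order=True)
class ThreeItemStatement:
    """One hypothesis ``out(in1 in2)`` with its source character and the
    plesiomorphic/apomorphic states that produced it."""

    source_char: int
    out_taxon: int
    in_pair: tuple[int, int]  # sorted taxon indices
    p_state: str
    a_state: str

    def __post_init__(self) -> None:
        if self.out_taxon in self.in_pair:
            raise ValueError("out-taxon cannot be part of the in-pair")
        if self.in_pair[0] >= self.in_pair[1]:
            raise ValueError("in_pair must be two distinct sorted indices")
        if self.p_state == self.a_state:
            raise ValueError("plesiomorphic and apomorphic states must differ")


@dataclass
class StatementBlock:
    """All statements derived from one input character."""

    source_char: int
    representation: str  # "binary" | "G" | "W" | "omc"
    statements: list[ThreeItemStatement] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.statements)

    def dedup(self) -> "StatementBlock":
        """Collapse statements sharing (out_taxon, in_pair); keeps the
        lowest-level statement's states and sorts the result, so the output
        is independent of input order."""
        seen: dict[tuple[int, tuple[int, int]], ThreeItemStatement] = {}
        for s in self.statements:
            seen.setdefault((s.out_taxon, s.in_pair), s)
        return StatementBlock(
            self.source_char,
            self.representation,
            sorted(seen.values(), key=lambda s: (s.out_taxon, s.in_pair)),
        )


Column = Sequence[Optional[str]]  # state symbol per taxon, None = missing


def effective_column(
    matrix: CharacterMatrix, j: int, *, ambiguity: str = "missing"
) -> list[Optional[str]]:
    """Column *j* with missing cells as ``None``.

    Under the default ``ambiguity="missing"`` policy IUPAC ambiguity codes
    are treated as missing data; under ``"keep"`` they pass through (used
    by the resolution-averaging machinery in :mod:`threeitem.weighting`).
    """
    ambiguous = AMBIGUITY_CODES[matrix.data_type]
    out: list[Optional[str]] = []
    for sym in matrix.column(j):
        if sym == MISSING or (ambiguity == "missing" and sym in ambiguous):
            out.append(None)
        else:
            out.append(sym)
    return out


def _state_taxa(column: Column) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = {}
    for i, sym in enumerate(column):
        if sym is not None:
            groups.setdefault(sym, []).append(i)
    return groups


def _statements_for_pair(
    source_char: int, p_taxa: Sequence[int], a_taxa: Sequence[int], p: str, a: str
) -> list[ThreeItemStatement]:
    return [
        ThreeItemStatement(source_char, x, (y, z), p, a)
        for x in p_taxa
        for y, z in combinations(sorted(a_taxa), 2)
    ]


def enumerate_binary(column: Column, source_char: int = 0) -> StatementBlock:
    """Statements of a binary character with state 0 plesiomorphic a priori.

    Count is m*n*(n-1)/2 for m zeros and n ones; taxa with missing state
    are excluded; an uninformative column yields an empty block.
    """
    groups = _state_taxa(column)
    stmts = _statements_for_pair(
        source_char, groups.get("0", ()), groups.get("1", ()), "0", "1"
    )
    stmts.sort(key=lambda s: (s.out_taxon, s.in_pair))
    return StatementBlock(source_char, "binary", stmts)


def enumerate_umc_g(column: Column, source_char: int = 0) -> StatementBlock:
    """G-representation: exhaustion of the outgroup value.

    Every observed state p serves in turn as plesiomorphic against every
    other observed state a: one statement per p-taxon and unordered pair
    of a-taxa.  Total count is sum over p != a of n_p * n_a*(n_a-1)/2.
    """
    groups = _state_taxa(column)
    stmts: list[ThreeItemStatement] = []
    for p in groups:
        for a in groups:
            if a != p:
                stmts += _statements_for_pair(source_char, groups[p], groups[a], p, a)
    stmts.sort(key=lambda s: (s.out_taxon, s.in_pair))
    return StatementBlock(source_char, "G", stmts)


def enumerate_umc_w(
    column: Column, outgroup_state: str, source_char: int = 0
) -> StatementBlock:
    """W-representation: statements relative to a fixed outgroup state.

    Only ``p = outgroup_state`` is admitted; pairs come from every other
    single shared state.  Count is n_p * sum over a != p of n_a*(n_a-1)/2.
    """
    groups = _state_taxa(column)
    p_taxa = groups.get(outgroup_state, ())
    stmts: list[ThreeItemStatement] = []
    for a in groups:
        if a != outgroup_state:
            stmts += _statements_for_pair(
                source_char, p_taxa, groups[a], outgroup_state, a
            )
    stmts.sort(key=lambda s: (s.out_taxon, s.in_pair))
    return StatementBlock(source_char, "W", stmts)


def decompose_additive(column: Column) -> list[list[Optional[str]]]:
    """Additive (Farris) binary coding of an ordered multistate column.

    For each observed level v above the minimum, a derived binary column
    scores 1 where state >= v and 0 otherwise; missing propagates.  Using
    observed levels only: unobserved levels would duplicate an existing
    derived column or produce a constant one.
    """
    values: list[Optional[int]] = []
    for sym in column:
        if sym is None:
            values.append(None)
        else:
            try:
                values.append(int(sym))
            except (TypeError, ValueError):
                raise MatrixError(
                    f"ordered multistate symbol {sym!r} is not an integer"
                ) from None
    observed = sorted({v for v in values if v is not None})
    derived: list[list[Optional[str]]] = []
    for level in observed[1:]:
        derived.append(
            [None if v is None else ("1" if v >= level else "0") for v in values]
        )
    return derived


def enumerate_omc(
    column: Column, mus: bool = False, source_char: int = 0
) -> StatementBlock:
    """Statements of an ordered multistate character via additive coding.

    Concatenates the binary enumeration of every derived threshold column
    (lowest level first).  With *mus*, duplicate statements -- the same
    (out, pair) arising at several levels -- collapse to one.
    """
    stmts: list[ThreeItemStatement] = []
    for binary_col in decompose_additive(column):
        stmts += enumerate_binary(binary_col, source_char).statements
    block = StatementBlock(source_char, "omc", stmts)
    return block.dedup() if mus else block


def render_column(
    stmt: ThreeItemStatement, notation: str, taxon_count: int
) -> tuple[str, ...]:
    """Render one statement as a symbol column over all taxa.

    Binary notation writes 0 for the out-taxon and 1 for the in-pair;
    multistate notation writes the plesiomorphic and apomorphic symbols
    themselves.  Every other taxon is missing.
    """
    if notation == "binary":
        out_sym, in_sym = "0", "1"
    elif notation == "multistate":
        out_sym, in_sym = stmt.p_state, stmt.a_state
    else:
        raise ValueError(f"unknown notation {notation!r}")
    col = [MISSING] * taxon_count
    col[stmt.out_taxon] = out_sym
    for k in stmt.in_pair:
        col[k] = in_sym
    return tuple(col)


@dataclass
class RepresentationConfig:
    """How to turn a character matrix into a 3TS matrix.

    ``outgroup=None`` selects the G-representation for multistate data;
    naming a taxon selects W (its state per character fixes the
    plesiomorphic value).  ``weighting`` is one of ``uniform``, ``fw``
    (Nelson-Ladiges fractional weighting), ``wt`` (fixed-outgroup
    fraction); ``ambiguity`` is ``missing`` (recommended) or ``average``.
    """

    notation: str = "binary"
    outgroup: Optional[str] = None
    mus: bool = False
    weighting: str = "uniform"
    ambiguity: str = "missing"
    wt_mode: str = "independent"  # or "reciprocal" (1/s_w)

    def __post_init__(self) -> None:
        if self.notation not in ("binary", "multistate"):
            raise ValueError(f"unknown notation {self.notation!r}")
        if self.weighting not in ("uniform", "fw", "wt", "disabled"):
            raise ValueError(f"unknown weighting mode {self.weighting!r}")
        if self.ambiguity not in ("missing", "average"):
            raise ValueError(f"unknown ambiguity policy {self.ambiguity!r}")
        if self.wt_mode not in ("independent", "reciprocal"):
            raise ValueError(f"unknown wt mode {self.wt_mode!r}")


def enumerate_block(
    matrix: CharacterMatrix, j: int, config: RepresentationConfig
) -> Optional[StatementBlock]:
    """Enumerate character *j* under the configured representation.

    Returns ``None`` when a W-representation character must be skipped
    because the outgroup taxon's state is missing or ambiguous there.
    """
    column = effective_column(matrix, j)
    if matrix.data_type is DataType.BINARY:
        block = enumerate_binary(column, j)
    elif matrix.data_type is DataType.OMC:
        return enumerate_omc(column, mus=config.mus, source_char=j)
    elif config.outgroup is not None:
        og = matrix.taxon_index(config.outgroup)
        og_state = column[og]
        if og_state is None:
            logger.warning(
                "character %d: outgroup %r state missing/ambiguous; skipped",
                j + 1,
                config.outgroup,
            )
            return None
        block = enumerate_umc_w(column, og_state, j)
    else:
        block = enumerate_umc_g(column, j)
    return block.dedup() if config.mus else block


def build_three_item_matrix(
    matrix: CharacterMatrix, config: RepresentationConfig
) -> ThreeItemMatrix:
    """Assemble the full 3TS matrix: per-character blocks in character
    order, statements in (out-taxon, in-pair) order, with weights from
    :mod:`threeitem.weighting` and per-column provenance.

    Raises :class:`EmptyMatrixError` when no informative statements exist.
    """
    from . import weighting  # deferred: weighting re-enumerates under ambiguity averaging

    plan = weighting.weighting_policy(matrix, config)

    columns: list[tuple[str, ...]] = []
    weights: list[Fraction] = []
    provenance: list[StatementProvenance] = []
    for j in range(matrix.n_chars):
        stmts, wts = weighting.weighted_statements(matrix, j, config, plan)
        for s, w in zip(stmts, wts):
            columns.append(render_column(s, config.notation, matrix.n_taxa))
            weights.append(w)
            provenance.append(
                StatementProvenance(j, s.out_taxon, s.in_pair, s.p_state, s.a_state)
            )

    if not columns:
        raise EmptyMatrixError(
            "no informative statements could be derived from this matrix"
        )
    return ThreeItemMatrix(
        taxon_names=matrix.taxon_names,
        columns=columns,
        weights=weights,
        notation=config.notation,
        provenance=provenance,
        source_type=matrix.data_type,
    )
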