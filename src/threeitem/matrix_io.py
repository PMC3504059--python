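"""Character-matrix input/output.

Reads conventional character matrices from CSV (rows = taxa, first field =
taxon name) and writes three-item-statement (3TS) matrices in simplified
NEXUS, relaxed PHYLIP and CSV, with per-column weights carried in a NEXUS
``wtset``, a trailing CSV comment row, or a TSV sidecar.

Supported data types: binary (0/1), ordered multistate (``omc``, integer
levels 0..9), unordered multistate (``umc``, up to 25 symbols), and DNA /
RNA / amino-acid alphabets with IUPAC ambiguity codes.  Gaps (``-``) are
mapped to missing (``?``) on input.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Iterable, Optional, Sequence

from Bio.Data import IUPACData

__all__ = [
    "DataType",
    "CharacterMatrix",
    "ThreeItemMatrix",
    "MatrixStats",
    "MatrixError",
    "AlphabetError",
    "DuplicateTaxonError",
    "SizeLimitError",
    "EmptyMatrixError",
    "ALPHABETS",
    "AMBIGUITY_CODES",
    "parse_csv_matrix",
    "matrix_stats",
    "write_nexus",
    "write_phylip",
    "write_csv_out",
    "write_weights_sidecar",
]

MISSING = "?"
GAP = "-"

DEFAULT_MAX_TAXA = 5000
DEFAULT_MAX_CHARS = 100000


class DataType(str, Enum):
    """Declared type of a conventional character matrix."""

    BINARY = "binary"
    OMC = "omc"  # ordered (additive) multistate
    UMC = "umc"  # unordered (non-additive) multistate
    DNA = "dna"
    RNA = "rna"
    AA = "aa"

    @property
    def is_sequence(self) -> bool:
        return self in (DataType.DNA, DataType.RNA, DataType.AA)


def _ambiguity_map(values: dict, alphabet: str) -> dict:
    return {
        sym: frozenset(exp)
        for sym, exp in values.items()
        if sym in alphabet and len(exp) > 1
    }


#: Full symbol alphabets per data type (missing/gap excluded).
ALPHABETS: dict[DataType, frozenset[str]] = {
    DataType.BINARY: frozenset("01"),
    DataType.OMC: frozenset("0123456789"),
    DataType.DNA: frozenset(IUPACData.ambiguous_dna_letters),
    DataType.RNA: frozenset(IUPACData.ambiguous_rna_letters),
    DataType.AA: frozenset(IUPACData.extended_protein_letters),
}

#: Ambiguity code -> set of elementary states it may resolve to.
AMBIGUITY_CODES: dict[DataType, dict[str, frozenset[str]]] = {
    DataType.BINARY: {},
    DataType.OMC: {},
    DataType.UMC: {},
    DataType.DNA: _ambiguity_map(
        IUPACData.ambiguous_dna_values, IUPACData.ambiguous_dna_letters
    ),
    DataType.RNA: _ambiguity_map(
        IUPACData.ambiguous_rna_values, IUPACData.ambiguous_rna_letters
    ),
    DataType.AA: _ambiguity_map(
        IUPACData.extended_protein_values, IUPACData.extended_protein_letters
    ),
}

UMC_MAX_SYMBOLS = 25


class MatrixError(ValueError):
    """Base class for matrix validation failures."""


class AlphabetError(MatrixError):
    def __init__(self, symbol: str, taxon: str, row: int, col: int, data_type: DataType):
        self.symbol, self.row, self.col = symbol, row, col
        super().__init__(
            f"symbol {symbol!r} at row {row} (taxon {taxon!r}), character {col} "
            f"is not in the {data_type.value} alphabet"
        )


class DuplicateTaxonError(MatrixError):
    pass


class SizeLimitError(MatrixError):
    pass


class EmptyMatrixError(MatrixError):
    pass


@dataclass(frozen=True)
class CharacterMatrix:
    """A taxa x characters grid of state symbols with a declared data type."""

    taxon_names: tuple[str, ...]
    cells: tuple[tuple[str, ...], ...]  # rows follow taxon_names
    data_type: DataType

    def __post_init__(self) -> None:
        if len(self.taxon_names) != len(self.cells):
            raise MatrixError("taxon name count does not match row count")
        if len(set(self.taxon_names)) != len(self.taxon_names):
            raise DuplicateTaxonError("duplicate taxon names")
        widths = {len(r) for r in self.cells}
        if len(widths) > 1:
            raise MatrixError(f"ragged rows: distinct lengths {sorted(widths)}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)

    @property
    def n_chars(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    def column(self, j: int) -> tuple[str, ...]:
        return tuple(row[j] for row in self.cells)

    def columns(self) -> Iterable[tuple[str, ...]]:
        for j in range(self.n_chars):
            yield self.column(j)

    def taxon_index(self, name: str) -> int:
        try:
            return self.taxon_names.index(name)
        except ValueError:
            raise MatrixError(f"unknown taxon {name!r}") from None


@dataclass(frozen=True)
class StatementProvenance:
    """Where one rendered 3TS column came from."""

    source_char: int  # 0-based character index in the input matrix
    out_taxon: int
    in_pair: tuple[int, int]
    p_state: str
    a_state: str


@dataclass
class ThreeItemMatrix:
    """Rendered 3TS output: one column per statement plus parallel weights."""

    taxon_names: tuple[str, ...]
    columns: list[tuple[str, ...]]  # each length n_taxa
    weights: list[Fraction]
    notation: str  # "binary" | "multistate"
    provenance: list[StatementProvenance] = field(default_factory=list)
    source_type: Optional[DataType] = None

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def row(self, i: int) -> tuple[str, ...]:
        return tuple(col[i] for col in self.columns)


@dataclass(frozen=True)
class MatrixStats:
    n_taxa: int
    n_characters: int
    variable: int
    parsimony_informative: int


# ---------------------------------------------------------------------------
# parsing


def _normalise_symbol(sym: str, data_type: DataType) -> str:
    sym = sym.strip()
    if data_type.is_sequence:
        sym = sym.upper()
    if sym == GAP or sym == "":
        return MISSING
    return sym


def parse_csv_matrix(
    text: str,
    data_type: DataType | str,
    *,
    delimiter: str = ",",
    has_header: bool = False,
    max_taxa: int = DEFAULT_MAX_TAXA,
    max_chars: int = DEFAULT_MAX_CHARS,
) -> CharacterMatrix:
    """Parse a CSV character matrix (rows = taxa, first field = taxon name).

    Blank lines and lines starting with ``#`` are skipped.  Symbols are
    upper-cased for sequence types; gaps and empty cells become ``?``.

    Raises :class:`AlphabetError`, :class:`DuplicateTaxonError`,
    :class:`SizeLimitError` or :class:`MatrixError` on invalid input.
    """
    data_type = DataType(data_type)
    if not text.strip():
        raise EmptyMatrixError("input CSV is empty")
    reader = csv.reader(io.StringIO(text), delimiter=delimiter)
    rows = [r for r in reader if r and not (r[0] or "").startswith("#")]
    if has_header:
        rows = rows[1:]
    if not rows:
        raise EmptyMatrixError("no data rows in input CSV")

    names: list[str] = []
    grid: list[tuple[str, ...]] = []
    for i, row in enumerate(rows):
        if len(row) < 2:
            raise MatrixError(f"row {i}: need a taxon name plus at least one character")
        name = row[0].strip()
        if not name:
            raise MatrixError(f"row {i}: empty taxon name")
        if name in names:
            raise DuplicateTaxonError(f"duplicate taxon name {name!r} at row {i}")
        names.append(name)
        grid.append(tuple(_normalise_symbol(c, data_type) for c in row[1:]))

    n_taxa, n_chars = len(names), len(grid[0])
    if n_taxa > max_taxa:
        raise SizeLimitError(f"{n_taxa} taxa exceeds the limit of {max_taxa}")
    if n_chars > max_chars:
        raise SizeLimitError(f"{n_chars} characters exceeds the limit of {max_chars}")

    alphabet = ALPHABETS.get(data_type)
    if alphabet is not None:
        for i, row_syms in enumerate(grid):
            for j, sym in enumerate(row_syms):
                if sym != MISSING and sym not in alphabet:
                    raise AlphabetError(sym, names[i], i, j, data_type)
    else:  # umc: any symbols, but at most 25 distinct
        observed = {s for row_syms in grid for s in row_syms if s != MISSING}
        if len(observed) > UMC_MAX_SYMBOLS:
            raise AlphabetError(
                sorted(observed)[UMC_MAX_SYMBOLS], names[0], 0, 0, data_type
            )

    return CharacterMatrix(tuple(names), tuple(grid), data_type)


def matrix_stats(matrix: CharacterMatrix) -> MatrixStats:
    """Count variable and parsimony-informative characters.

    A character is parsimony informative when at least two states are each
    present in at least two taxa.  Missing cells and ambiguity codes are
    excluded from the state counts.
    """
    ambiguous = AMBIGUITY_CODES[matrix.data_type]
    variable = informative = 0
    for col in matrix.columns():
        counts: dict[str, int] = {}
        for sym in col:
            if sym == MISSING or sym in ambiguous:
                continue
            counts[sym] = counts.get(sym, 0) + 1
        if len(counts) >= 2:
            variable += 1
            if sum(1 for c in counts.values() if c >= 2) >= 2:
                informative += 1
    return MatrixStats(matrix.n_taxa, matrix.n_chars, variable, informative)


# ---------------------------------------------------------------------------
# writers


def _check_nonempty(tim: ThreeItemMatrix) -> None:
    if tim.n_columns == 0:
        raise EmptyMatrixError(
            "the 3TS matrix has no columns: no informative statements "
            "could be derived from the input"
        )


def _format_weight(w: Fraction) -> str:
    return f"{float(w):.12g}"


def _nexus_name(name: str) -> str:
    if any(ch.isspace() for ch in name) or "'" in name:
        return "'" + name.replace("'", "''") + "'"
    return name


def _weight_ranges(indices: list[int]) -> str:
    """Compress sorted 1-based column indices into NEXUS range syntax."""
    parts: list[str] = []
    start = prev = indices[0]
    for idx in indices[1:]:
        if idx == prev + 1:
            prev = idx
            continue
        parts.append(str(start) if start == prev else f"{start}-{prev}")
        start = prev = idx
    parts.append(str(start) if start == prev else f"{start}-{prev}")
    return " ".join(parts)


def write_nexus(tim: ThreeItemMatrix, include_weights: bool = False) -> str:
    """Render a simplified NEXUS file with a DATA block.

    Binary-notation matrices are written as ``datatype=standard`` with an
    explicit symbol list; multistate DNA/RNA output uses the corresponding
    sequence datatype so that downstream likelihood software accepts it.
    When *include_weights* is set an ASSUMPTIONS block carries a ``wtset``
    with the per-column weights (12 significant digits).
    """
    _check_nonempty(tim)
    if tim.notation == "multistate" and tim.source_type in (DataType.DNA, DataType.RNA):
        fmt = f"DATATYPE={tim.source_type.value.upper()} MISSING={MISSING}"
    elif tim.notation == "multistate" and tim.source_type == DataType.AA:
        fmt = f"DATATYPE=PROTEIN MISSING={MISSING}"
    else:
        symbols = sorted({s for col in tim.columns for s in col if s != MISSING})
        fmt = f'DATATYPE=STANDARD SYMBOLS="{"".join(symbols)}" MISSING={MISSING}'

    name_width = max(len(_nexus_name(n)) for n in tim.taxon_names) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={tim.n_taxa} NCHAR={tim.n_columns};",
        f"  FORMAT {fmt};",
        "  MATRIX",
    ]
    for i, name in enumerate(tim.taxon_names):
        lines.append(f"    {_nexus_name(name):<{name_width}}{''.join(tim.row(i))}")
    lines += ["  ;", "END;"]

    if include_weights:
        groups: dict[Fraction, list[int]] = {}
        for idx, w in enumerate(tim.weights, start=1):
            groups.setdefault(w, []).append(idx)
        assignments = ", ".join(
            f"{_format_weight(w)}: {_weight_ranges(idx)}"
            for w, idx in sorted(groups.items(), reverse=True)
        )
        lines += [
            "BEGIN ASSUMPTIONS;",
            f"  WTSET * statement_weights = {assignments};",
            "END;",
        ]
    return "\n".join(lines) + "\n"


def _phylip_name(name: str, strict: bool) -> str:
    if strict:
        if any(ch.isspace() for ch in name):
            raise MatrixError(
                f"taxon name {name!r} contains whitespace; not representable "
                "in strict PHYLIP"
            )
        return f"{name[:10]:<10}"
    return name.replace(" ", "_")


def write_phylip(tim: ThreeItemMatrix, strict: bool = False) -> str:
    """Render relaxed PHYLIP (name, whitespace, symbols); *strict* pads
    names to the classic 10 characters.  PHYLIP cannot carry weights --
    use :func:`write_weights_sidecar`."""
    _check_nonempty(tim)
    lines = [f"{tim.n_taxa} {tim.n_columns}"]
    names = [_phylip_name(n, strict) for n in tim.taxon_names]
    width = max(len(n) for n in names) + 2 if not strict else 10
    for name, i in zip(names, range(tim.n_taxa)):
        sep = "" if strict else " " * (width - len(name))
        lines.append(f"{name}{sep}{''.join(tim.row(i))}")
    return "\n".join(lines) + "\n"


def write_csv_out(
    tim: ThreeItemMatrix, *, delimiter: str = ",", include_weights: bool = False
) -> str:
    """Render the 3TS matrix as CSV in the input dialect (rows = taxa).

    With *include_weights* a trailing ``#weights`` row carries the decimal
    weights; the row is ignored by :func:`parse_csv_matrix` (comment
    prefix), so the symbol grid round-trips."""
    _check_nonempty(tim)
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter=delimiter, lineterminator="\n")
    for i, name in enumerate(tim.taxon_names):
        writer.writerow([name, *tim.row(i)])
    if include_weights:
        writer.writerow(["#weights", *(_format_weight(w) for w in tim.weights)])
    return buf.getvalue()


def write_weights_sidecar(tim: ThreeItemMatrix) -> str:
    """TSV sidecar with exact rational weights and per-column provenance."""
    _check_nonempty(tim)
    lines = ["index\tsource_char\tout_taxon\tin1\tin2\tweight"]
    for idx, (prov, w) in enumerate(zip(tim.provenance, tim.weights), start=1):
        out_name = tim.taxon_names[prov.out_taxon]
        in1, in2 = (tim.taxon_names[k] for k in prov.in_pair)
        lines.append(
            f"{idx}\t{prov.source_char + 1}\t{out_name}\t{in1}\t{in2}\t{w}"
        )
    return "\n".join(lines) + "\n"
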