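"""Per-statement weights for three-item matrices.

Fractional weighting (FW) down-weights each statement of a character by
``i/s`` -- the ratio of independent to total statements -- to compensate
for redundancy among the statements a single character generates.  For a
binary character with ``t`` scored taxa of which ``n`` carry the
apomorphic state, the Nelson-Ladiges closed forms are

    s = n (n - 1) (t - n) / 2        total statements
    i = (n - 1) (t - n)              independent statements
    i / s = 2 / n                    per-statement weight

For the G-representation of an unordered multistate character we apply
these forms to each ordered (plesiomorphic, apomorphic) state pair as a
pseudo-binary character with ``t' = n_p + n_a`` and ``n' = n_a``, giving
per-statement weight ``2 / n_a``.  This per-pair decomposition is a
documented reconstruction: it degenerates to Nelson-Ladiges exactly in
the binary case and conserves the independent-statement count
(sum of weights == i, in exact rational arithmetic).

For the W-representation an optional fixed-outgroup fraction (Wt) gives
every statement of a character the block-level ratio ``i_w / s_w``
(default) or ``1 / s_w`` (alternative mode), where ``s_w`` is the number
of statements with the outgroup value fixed.

Ambiguity policy: the recommended default treats IUPAC ambiguity codes as
missing data.  The opt-in averaging mode enumerates every resolution of
the ambiguous cells and assigns each statement the mean of its weights
over all resolutions (zero where absent).  When every character of the
matrix contains ambiguities, weighting is disabled outright.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import product
from typing import Optional, Sequence

from .matrix_io import AMBIGUITY_CODES, CharacterMatrix, DataType, MatrixError
from .statement_engine import (
    RepresentationConfig,
    StatementBlock,
    ThreeItemStatement,
    effective_column,
    enumerate_block,
    enumerate_umc_w,
)

__all__ = [
    "FWParams",
    "WeightRecord",
    "WeightingError",
    "WeightingPlan",
    "fw_binary",
    "fw_block_weights",
    "wt_block_weight",
    "ambiguity_average",
    "weighting_policy",
    "weighted_statements",
]

ONE = Fraction(1)

#: Refuse to expand more ambiguity resolutions than this per character.
MAX_RESOLUTIONS = 4096


class WeightingError(ValueError):
    """Raised for incompatible weighting configuration."""


@dataclass(frozen=True)
class FWParams:
    """Fractional-weighting bookkeeping for one character.

    t: taxa scored (non-missing) for the character; n: taxa carrying
    informative (apomorphic) states; k: number of informative states;
    s: total statements; i: independent statements.
    """

    t: int
    n: int
    k: int
    s: int
    i: int

    @property
    def weight(self) -> Optional[Fraction]:
        """Per-statement weight i/s, or None when no statements exist."""
        return Fraction(self.i, self.s) if self.s else None


@dataclass(frozen=True)
class WeightRecord:
    statement: ThreeItemStatement
    weight: Fraction
    mode: str  # uniform | fw | wt | disabled

    def __post_init__(self) -> None:
        if self.mode in ("uniform", "disabled") and self.weight != 1:
            raise WeightingError(f"{self.mode} weighting requires weight 1")
        if self.weight <= 0:
            raise WeightingError("weights must be positive")


def fw_binary(t: int, n: int) -> FWParams:
    """Nelson-Ladiges closed forms for a binary character.

    *t* scored taxa, *n* of them apomorphic.  With n < 2 or n == t there
    are no statements (s = 0) and no weight.
    """
    if n < 2 or t - n < 1:
        return FWParams(t=t, n=n, k=1 if n else 0, s=0, i=0)
    s = n * (n - 1) * (t - n) // 2
    i = (n - 1) * (t - n)
    return FWParams(t=t, n=n, k=1, s=s, i=i)


def _state_counts(column: Sequence[Optional[str]]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for sym in column:
        if sym is not None:
            counts[sym] = counts.get(sym, 0) + 1
    return counts


def fw_char_params(
    column: Sequence[Optional[str]], outgroup_state: Optional[str] = None
) -> FWParams:
    """Character-level FW parameters under the per-pair decomposition.

    With *outgroup_state* the sums run only over pairs with that fixed
    plesiomorphic state (W-representation); otherwise over all ordered
    state pairs (G).  ``s`` equals the enumeration count and ``i`` is the
    summed per-pair independent count.
    """
    counts = _state_counts(column)
    informative = {st: c for st, c in counts.items() if c >= 2}
    t = sum(counts.values())
    s = i = 0
    for p, n_p in counts.items():
        if outgroup_state is not None and p != outgroup_state:
            continue
        for a, n_a in counts.items():
            if a == p or n_a < 2:
                continue
            s += n_p * n_a * (n_a - 1) // 2
            i += n_p * (n_a - 1)
    return FWParams(
        t=t,
        n=sum(informative.values()),
        k=len(informative),
        s=s,
        i=i,
    )


def fw_block_weights(
    block: StatementBlock, column: Sequence[Optional[str]]
) -> list[Fraction]:
    """Per-statement FW weights 2 / n_a for a binary- or G-representation
    block, where n_a counts the taxa sharing the statement's apomorphic
    state.  Conserves sum(weights) == i exactly."""
    counts = _state_counts(column)
    return [Fraction(2, counts[s.a_state]) for s in block.statements]


def wt_block_weight(
    block: StatementBlock,
    column: Sequence[Optional[str]],
    mode: str = "independent",
) -> Fraction:
    """Fixed-outgroup fraction for one W-representation block.

    ``independent`` mode returns i_w / s_w (independent over total
    statements with the outgroup value fixed); ``reciprocal`` returns
    1 / s_w.  Empty blocks have no weight.
    """
    s_w = len(block)
    if s_w == 0:
        raise WeightingError("cannot weight an empty statement block")
    if mode == "reciprocal":
        return Fraction(1, s_w)
    p = block.statements[0].p_state
    params = fw_char_params(column, outgroup_state=p)
    if params.s != s_w:  # pragma: no cover - internal consistency guard
        raise WeightingError("block size disagrees with closed-form count")
    return Fraction(params.i, s_w)


@dataclass(frozen=True)
class WeightingPlan:
    """Resolved weighting mode per character after the global rules."""

    char_modes: tuple[str, ...]
    global_mode: str


def _has_ambiguity(matrix: CharacterMatrix, j: int) -> bool:
    ambiguous = AMBIGUITY_CODES[matrix.data_type]
    return any(sym in ambiguous for sym in matrix.column(j))


def weighting_policy(
    matrix: CharacterMatrix, config: RepresentationConfig
) -> WeightingPlan:
    """Select the effective weighting mode for every character.

    Enforces the configuration rules: ``mus`` keeps only unique statements
    and implies uniform weights; FW is undefined for ordered multistate
    characters (additive decomposition already multiplies statements) and
    for a fixed outgroup (use Wt there); Wt requires a fixed outgroup.
    When every character of the matrix contains ambiguity codes, weighting
    is disabled and all weights are 1.
    """
    mode = config.weighting
    if config.mus and mode in ("fw", "wt"):
        raise WeightingError(
            "the unique-statements option (mus) implies uniform weights; "
            f"it cannot be combined with {mode!r}"
        )
    if mode == "fw":
        if matrix.data_type is DataType.OMC:
            raise WeightingError(
                "fractional weighting is not defined for ordered multistate "
                "characters; use uniform weights (optionally with mus)"
            )
        if config.outgroup is not None and matrix.data_type is not DataType.BINARY:
            raise WeightingError(
                "fractional weighting applies to the G-representation; "
                "with a fixed outgroup use the wt fraction instead"
            )
    if mode == "wt":
        if config.outgroup is None or matrix.data_type in (
            DataType.BINARY,
            DataType.OMC,
        ):
            raise WeightingError(
                "the wt fraction requires the W-representation "
                "(multistate data with a fixed outgroup taxon)"
            )

    if (
        (mode in ("fw", "wt") or config.ambiguity == "average")
        and matrix.n_chars > 0
        and matrix.data_type.is_sequence
        and all(_has_ambiguity(matrix, j) for j in range(matrix.n_chars))
    ):
        mode = "disabled"
    return WeightingPlan(char_modes=(mode,) * matrix.n_chars, global_mode=mode)


def _base_weights(
    block: StatementBlock,
    column: Sequence[Optional[str]],
    mode: str,
    config: RepresentationConfig,
) -> list[Fraction]:
    if mode in ("uniform", "disabled") or not block.statements:
        return [ONE] * len(block)
    if mode == "fw":
        return fw_block_weights(block, column)
    if mode == "wt":
        w = wt_block_weight(block, column, config.wt_mode)
        return [w] * len(block)
    raise WeightingError(f"unknown weighting mode {mode!r}")


def ambiguity_average(
    matrix: CharacterMatrix,
    j: int,
    config: RepresentationConfig,
    mode: str,
) -> tuple[list[ThreeItemStatement], list[Fraction]]:
    """Statements and weights of character *j* averaged over every
    resolution of its ambiguity codes.

    Each ambiguous cell is expanded to its elementary states; statements
    are enumerated per resolution with the base weighting *mode*, and a
    statement's final weight is its summed weight over resolutions divided
    by the number of resolutions (statements absent everywhere are
    absent).  Refuses columns with more than ``MAX_RESOLUTIONS``
    resolutions.
    """
    ambiguous = AMBIGUITY_CODES[matrix.data_type]
    raw = effective_column(matrix, j, ambiguity="keep")
    choices: list[list[Optional[str]]] = [
        sorted(ambiguous[sym]) if (sym is not None and sym in ambiguous) else [sym]
        for sym in raw
    ]
    n_res = 1
    for c in choices:
        n_res *= len(c)
        if n_res > MAX_RESOLUTIONS:
            raise MatrixError(
                f"character {j + 1}: more than {MAX_RESOLUTIONS} ambiguity "
                "resolutions; treat ambiguities as missing instead"
            )

    og = matrix.taxon_index(config.outgroup) if config.outgroup is not None else None
    acc: dict[ThreeItemStatement, Fraction] = {}
    for res in product(*choices):
        column = list(res)
        if og is not None:
            og_state = column[og]
            if og_state is None:
                return [], []  # outgroup unscored: character skipped entirely
            block = enumerate_umc_w(column, og_state, j)
        else:
            from .statement_engine import enumerate_umc_g

            block = enumerate_umc_g(column, j)
        if config.mus:
            block = block.dedup()
        for stmt, w in zip(
            block.statements, _base_weights(block, column, mode, config)
        ):
            acc[stmt] = acc.get(stmt, Fraction(0)) + w

    stmts = sorted(acc)
    if mode == "disabled":
        return stmts, [ONE] * len(stmts)
    return stmts, [acc[s] / n_res for s in stmts]


def weighted_statements(
    matrix: CharacterMatrix,
    j: int,
    config: RepresentationConfig,
    plan: Optional[WeightingPlan] = None,
) -> tuple[list[ThreeItemStatement], list[Fraction]]:
    """Statements of character *j* with their weights, honouring the
    ambiguity policy and the resolved weighting plan."""
    if plan is None:
        plan = weighting_policy(matrix, config)
    mode = plan.char_modes[j]
    if (
        config.ambiguity == "average"
        and matrix.data_type.is_sequence
        and _has_ambiguity(matrix, j)
    ):
        return ambiguity_average(matrix, j, config, mode)
    block = enumerate_block(matrix, j, config)
    if block is None:
        return [], []
    column = effective_column(matrix, j)
    return block.statements, _base_weights(block, column, mode, config)
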