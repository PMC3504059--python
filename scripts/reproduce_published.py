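#!/usr/bin/env python
"""Reproduce published three-item-statement column counts.

Requires third-party matrices that are not redistributed here; download
them into data/external/ first:

* ``primate-mtDNA.nex`` -- the 12-taxon, 898-site primate mitochondrial
  NADH-4 alignment distributed as an example file with PAUP*.
* ``mmc4.nex`` -- the African papionin craniodental supplement (ordered
  multistate characters).
* the grass *PHYC* alignment supplement (NEXUS), saved as
  ``saarela_phyc.nex``.

Published values this script re-derives:

* primate WS (fixed outgroup *Lemur catta*, binary notation): 21418
  columns; G (multistate notation): 61043; 367 parsimony-informative
  input sites.
* papionin ordered-multistate subset, unique statements: 1707 columns.
* *PHYC* without *Oryza*: WS 264201 and G 956437 columns.

Usage::

    python scripts/reproduce_published.py data/external/primate-mtDNA.nex
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import dendropy

from threeitem.matrix_io import DataType, matrix_stats, parse_csv_matrix
from threeitem.statement_engine import RepresentationConfig, build_three_item_matrix


def nexus_to_csv(path: Path, datatype: str = "dna", exclude: tuple[str, ...] = ()) -> str:
    reader = (
        dendropy.DnaCharacterMatrix
        if datatype == "dna"
        else dendropy.StandardCharacterMatrix
    )
    dm = reader.get(path=str(path), schema="nexus")
    lines = []
    for taxon in dm:
        label = taxon.label
        if any(e.lower() in label.lower() for e in exclude):
            continue
        lines.append(",".join([label.replace(",", "_"), *str(dm[taxon])]))
    return "\n".join(lines) + "\n"


def find_taxon(names: tuple[str, ...], fragment: str) -> str:
    hits = [n for n in names if fragment.lower() in n.lower()]
    if len(hits) != 1:
        raise SystemExit(f"expected one taxon matching {fragment!r}, got {hits}")
    return hits[0]


def primate_mtdna(path: Path) -> dict[str, int]:
    matrix = parse_csv_matrix(nexus_to_csv(path), DataType.DNA)
    stats = matrix_stats(matrix)
    outgroup = find_taxon(matrix.taxon_names, "Lemur")
    ws = build_three_item_matrix(
        matrix, RepresentationConfig(notation="binary", outgroup=outgroup)
    )
    g = build_three_item_matrix(
        matrix, RepresentationConfig(notation="multistate")
    )
    return {
        "primate_informative_sites": stats.parsimony_informative,
        "primate_ws_columns": ws.n_columns,
        "primate_g_columns": g.n_columns,
    }


def phyc(path: Path) -> dict[str, int]:
    matrix = parse_csv_matrix(
        nexus_to_csv(path, exclude=("Oryza",)), DataType.DNA
    )
    outgroup = find_taxon(matrix.taxon_names, "Amborella")
    ws = build_three_item_matrix(
        matrix, RepresentationConfig(notation="binary", outgroup=outgroup)
    )
    g = build_three_item_matrix(
        matrix, RepresentationConfig(notation="multistate")
    )
    return {"phyc_ws_columns": ws.n_columns, "phyc_g_columns": g.n_columns}


# ordered-multistate character numbers used in the papionin analysis (1-based)
PAPIONIN_ORDERED = (
    list(range(1, 18)) + list(range(19, 45)) + list(range(46, 70))
    + list(range(71, 74)) + list(range(75, 137)) + list(range(138, 142))
    + [143]
)


def papionin(path: Path) -> dict[str, int]:
    matrix = parse_csv_matrix(
        nexus_to_csv(path, datatype="standard"), DataType.OMC
    )
    keep = [c - 1 for c in PAPIONIN_ORDERED if c <= matrix.n_chars]
    from threeitem.matrix_io import CharacterMatrix

    subset = CharacterMatrix(
        matrix.taxon_names,
        tuple(tuple(row[j] for j in keep) for row in matrix.cells),
        DataType.OMC,
    )
    tim = build_three_item_matrix(
        subset, RepresentationConfig(notation="binary", mus=True)
    )
    return {"papionin_unique_columns": tim.n_columns}


HANDLERS = {
    "primate-mtdna": primate_mtdna,
    "phyc": phyc,
    "papionin": papionin,
}


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__.split("\n\n")[0])
    parser.add_argument("nexus", type=Path)
    parser.add_argument(
        "--dataset", choices=sorted(HANDLERS), default="primate-mtdna"
    )
    args = parser.parse_args()
    if not args.nexus.exists():
        print(f"{args.nexus} not found; download it first (see --help)",
              file=sys.stderr)
        return 1
    for key, value in HANDLERS[args.dataset](args.nexus).items():
        print(f"{key}\t{value}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
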