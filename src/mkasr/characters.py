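"""Discrete character data and tip likelihood vectors.

A character column maps taxa to small integer state codes; "?" marks a
missing observation.  The module also implements the flower-size coding rule
(corolla tube length / corolla lobe length: ratio > 1 codes "large" = 0,
ratio < 1 codes "small" = 1) and converts columns to the 0/1 tip partial
vectors that seed the pruning likelihood (missing data become all-ones,
i.e. the tip is compatible with every state).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import dendropy

__all__ = [
    "MISSING",
    "CharacterColumn",
    "TipPartials",
    "CharacterError",
    "read_character_matrix",
    "read_nexus_characters",
    "write_character_matrix",
    "code_ratio_character",
    "to_partials",
]

#: Sentinel for a missing observation ("?" on disk).
MISSING = None


class CharacterError(ValueError):
    """Raised for malformed character data."""


@dataclass
class CharacterColumn:
    """One discrete character: a state space plus taxon → code assignments."""

    name: str
    state_space: tuple[int, ...]
    assignments: dict[str, int | None]

    def __post_init__(self) -> None:
        self.state_space = tuple(self.state_space)
        if len(self.state_space) < 2:
            raise CharacterError(
                f"character {self.name!r}: state space needs >= 2 states"
            )
        allowed = set(self.state_space)
        for taxon, code in self.assignments.items():
            if code is not MISSING and code not in allowed:
                raise CharacterError(
                    f"character {self.name!r}: taxon {taxon!r} has code "
                    f"{code!r} outside state space {sorted(allowed)}"
                )

    @property
    def k(self) -> int:
        return len(self.state_space)

    def observed_states(self) -> set[int]:
        return {c for c in self.assignments.values() if c is not MISSING}

    def is_informative(self) -> bool:
        """At least two distinct observed states (needed for rate inference)."""
        return len(self.observed_states()) >= 2

    def relabelled(self, mapping: Mapping[int, int]) -> "CharacterColumn":
        """Return a copy with state codes permuted (used for symmetry checks)."""
        return CharacterColumn(
            name=self.name,
            state_space=self.state_space,
            assignments={
                t: (MISSING if c is MISSING else mapping[c])
                for t, c in self.assignments.items()
            },
        )


#: taxon → 0/1 compatibility vector over the state space.
TipPartials = dict


def read_character_matrix(
    path,
    state_spaces: Mapping[str, Sequence[int]] | None = None,
    sep: str | None = None,
) -> list[CharacterColumn]:
    """Read a delimited character matrix (first column: taxon; one character
    per remaining column; "?" = missing).

    ``state_spaces`` optionally declares the state space per character name;
    undeclared characters get the sorted set of observed codes.  The
    delimiter is sniffed (comma vs tab) unless given.
    """
    with open(path, "r", encoding="utf-8") as fh:
        head = fh.readline()
    if sep is None:
        sep = "\t" if "\t" in head else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise CharacterError(f"{path}: need a taxon column plus >= 1 character")
    taxon_col = df.columns[0]
    dupes = df[taxon_col][df[taxon_col].duplicated()]
    if not dupes.empty:
        row = int(dupes.index[0]) + 2  # header is row 1
        raise CharacterError(f"{path}: duplicated taxon {dupes.iloc[0]!r} at row {row}")

    columns: list[CharacterColumn] = []
    for name in df.columns[1:]:
        assignments: dict[str, int | None] = {}
        for i, (taxon, cell) in enumerate(zip(df[taxon_col], df[name])):
            cell = cell.strip()
            if cell in ("?", ""):
                assignments[taxon] = MISSING
                continue
            try:
                assignments[taxon] = int(cell)
            except ValueError:
                raise CharacterError(
                    f"{path}: non-integer code {cell!r} for character "
                    f"{name!r} at row {i + 2}"
                ) from None
        if state_spaces and name in state_spaces:
            space = tuple(state_spaces[name])
        else:
            observed = sorted({c for c in assignments.values() if c is not MISSING})
            if len(observed) < 2:
                observed = [0, 1]  # degenerate column: assume binary
            space = tuple(observed)
        columns.append(CharacterColumn(name=name, state_space=space, assignments=assignments))
    return columns


def write_character_matrix(columns: Sequence[CharacterColumn], path, sep: str = ",") -> None:
    """Write columns back to a delimited matrix; MISSING becomes "?"."""
    taxa = sorted({t for col in columns for t in col.assignments})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(["taxon"] + [c.name for c in columns]) + "\n")
        for taxon in taxa:
            cells = [taxon]
            for col in columns:
                code = col.assignments.get(taxon, MISSING)
                cells.append("?" if code is MISSING else str(code))
            fh.write(sep.join(cells) + "\n")


def read_nexus_characters(path) -> list[CharacterColumn]:
    """Read a NEXUS characters/data block (standard datatype, symbols like
    "012", missing "?")."""
    try:
        mat = dendropy.StandardCharacterMatrix.get(
            path=str(path), schema="nexus", preserve_underscores=True
        )
    except Exception as exc:
        raise CharacterError(f"failed to read NEXUS characters from {path}: {exc}") from exc
    n_chars = mat.max_sequence_size
    names = [f"char{i + 1}" for i in range(n_chars)]
    assignments: list[dict[str, int | None]] = [dict() for _ in range(n_chars)]
    for taxon in mat.taxon_namespace:
        seq = mat[taxon]
        for i, cell in enumerate(seq):
            symbol = str(cell.symbol) if cell is not None else "?"
            if symbol in ("?", "-"):
                assignments[i][taxon.label] = MISSING
            else:
                try:
                    assignments[i][taxon.label] = int(symbol)
                except ValueError:
                    raise CharacterError(
                        f"{path}: non-integer state symbol {symbol!r} "
                        f"for taxon {taxon.label!r}"
                    ) from None
    columns = []
    for name, asg in zip(names, assignments):
        observed = sorted({c for c in asg.values() if c is not MISSING})
        if len(observed) < 2:
            observed = [0, 1]
        columns.append(CharacterColumn(name=name, state_space=tuple(observed), assignments=asg))
    return columns


def code_ratio_character(tube_length: float, lobe_length: float) -> int | None:
    """Code flower size from corolla measurements (mm).

    ratio > 1 → 0 (large); ratio < 1 → 1 (small); a ratio of exactly 1 is
    left undefined by the coding rule and returns MISSING with a warning.
    """
    if not (tube_length > 0 and lobe_length > 0):
        raise CharacterError(
            f"corolla lengths must be positive, got tube={tube_length}, "
            f"lobe={lobe_length}"
        )
    ratio = tube_length / lobe_length
    if ratio > 1:
        return 0
    if ratio < 1:
        return 1
    warnings.warn(
        "corolla tube/lobe ratio exactly 1: flower-size coding undefined, "
        "treating as missing",
        stacklevel=2,
    )
    return MISSING


def to_partials(column: CharacterColumn, taxa: Iterable[str]) -> TipPartials:
    """Build tip likelihood vectors over the column's state space.

    Observed code c → unit vector at c; MISSING → all-ones.  Taxa absent
    from the column entirely are treated as missing, with a warning.
    """
    k = column.k
    index = {code: i for i, code in enumerate(column.state_space)}
    partials: TipPartials = {}
    absent: list[str] = []
    for taxon in taxa:
        vec = np.ones(k)
        if taxon not in column.assignments:
            absent.append(taxon)
        else:
            code = column.assignments[taxon]
            if code is not MISSING:
                vec = np.zeros(k)
                vec[index[code]] = 1.0
        partials[taxon] = vec
    if absent:
        warnings.warn(
            f"character {column.name!r}: no data for taxa "
            f"{', '.join(sorted(absent))}; treated as missing",
            stacklevel=2,
        )
    return partials
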