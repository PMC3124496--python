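"""Discrete character matrices and taxon/area occurrence tables.

The substrate of every parsimony computation in this package is a
rectangular matrix of small-integer character states scored across taxa,
with ``?`` marking missing data and state *sets* marking polymorphic
codings (a taxon observed in more than one state).  Three text dialects
are supported: NEXUS ``DATA``/``CHARACTERS`` blocks (via dendropy), TNT
``xread`` files, and a plain CSV layout (first column taxon name, one
character per remaining column, header row of character indices).

Biogeographic occurrence data — which paleogeographic areas each taxon
is found in — is carried by :class:`AreaAssignment` and read from CSV
rows of the form ``taxon,area1;area2``.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy

__all__ = [
    "CharMeta",
    "CharacterMatrix",
    "AreaAssignment",
    "MatrixFormatError",
    "read_matrix",
    "write_matrix",
    "drop_taxon",
    "informative_characters",
    "read_area_assignment",
    "write_area_assignment",
]

#: Missing-data cell marker (full ambiguity during scoring).
MISSING = None

Cell = frozenset  # frozenset[int]; None = missing


class MatrixFormatError(ValueError):
    """Raised when a character-matrix file violates its dialect."""


@dataclass(frozen=True)
class CharMeta:
    """Per-character scoring metadata.

    ordered: Wagner (linear-scale) scoring if True, Fitch otherwise.
    active:  inactive characters are excluded from tree lengths.
    weight:  positive multiplier on the character's step count.
    """

    ordered: bool = False
    active: bool = True
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("character weight must be positive")


class CharacterMatrix:
    """Taxa × discrete-character matrix with missing and polymorphic cells.

    Cells are ``frozenset`` objects of integer states, or ``None`` for
    missing data.  Single observed states are singleton sets.  The matrix
    is validated on construction: rows must be rectangular, taxon names
    unique and non-empty, and states non-negative integers.
    """

    def __init__(
        self,
        taxon_names: Sequence[str],
        cells: Sequence[Sequence[object]],
        char_meta: Sequence[CharMeta] | None = None,
    ) -> None:
        names = [str(t) for t in taxon_names]
        if not names:
            raise ValueError("matrix must contain at least one taxon")
        if len(set(names)) != len(names):
            raise ValueError("taxon names must be unique")
        if any(not n for n in names):
            raise ValueError("taxon names must be non-empty")
        if len(cells) != len(names):
            raise ValueError("one cell row required per taxon")
        norm_rows: list[list[Cell | None]] = []
        n_chars = len(cells[0]) if cells else 0
        for name, row in zip(names, cells):
            if len(row) != n_chars:
                raise MatrixFormatError(
                    f"ragged matrix: taxon {name!r} has {len(row)} cells, "
                    f"expected {n_chars}"
                )
            norm_rows.append([_normalize_cell(c, name) for c in row])
        if char_meta is None:
            char_meta = [CharMeta() for _ in range(n_chars)]
        if len(char_meta) != n_chars:
            raise ValueError("char_meta length must equal number of characters")
        self.taxon_names: list[str] = names
        self.cells: list[list[Cell | None]] = norm_rows
        self.char_meta: list[CharMeta] = list(char_meta)
        self._index = {t: i for i, t in enumerate(names)}

    # -- basic introspection -------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)

    @property
    def n_chars(self) -> int:
        return len(self.char_meta)

    def row(self, taxon: str) -> list[Cell | None]:
        try:
            return self.cells[self._index[taxon]]
        except KeyError:
            raise KeyError(f"taxon {taxon!r} not in matrix") from None

    def column(self, j: int) -> list[Cell | None]:
        return [r[j] for r in self.cells]

    def max_state(self, j: int) -> int:
        """Largest state observed for character *j* (0 if all missing)."""
        mx = 0
        for r in self.cells:
            if r[j] is not None and r[j]:
                mx = max(mx, max(r[j]))
        return mx

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CharacterMatrix)
            and self.taxon_names == other.taxon_names
            and self.cells == other.cells
            and self.char_meta == other.char_meta
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<CharacterMatrix {self.n_taxa} taxa x {self.n_chars} chars>"

    # -- derived matrices ----------------------------------------------------

    def with_characters(self, indices: Sequence[int]) -> "CharacterMatrix":
        """Submatrix restricted to (or resampled over) the given characters."""
        return CharacterMatrix(
            self.taxon_names,
            [[r[j] for j in indices] for r in self.cells],
            [self.char_meta[j] for j in indices],
        )

    def with_taxa(self, names: Sequence[str]) -> "CharacterMatrix":
        return CharacterMatrix(
            list(names), [self.row(t) for t in names], self.char_meta
        )


def _normalize_cell(c: object, taxon: str) -> Cell | None:
    if c is None:
        return None
    if isinstance(c, (set, frozenset)):
        if not c:
            raise MatrixFormatError(f"empty state set for taxon {taxon!r}")
        states = frozenset(int(s) for s in c)
    elif isinstance(c, (int,)) and not isinstance(c, bool):
        states = frozenset({int(c)})
    else:
        raise MatrixFormatError(
            f"bad cell {c!r} for taxon {taxon!r}: expected int, set or None"
        )
    if any(s < 0 for s in states):
        raise MatrixFormatError(f"negative state in cell for taxon {taxon!r}")
    return states


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

_DIALECTS = ("nexus", "tnt", "csv")


def read_matrix(path: str | Path, dialect: str = "nexus") -> CharacterMatrix:
    """Read a character matrix from *path* in the named dialect.

    ``?`` cells become missing; bracketed multi-state entries (``{01}``,
    ``(01)`` or ``[01]`` depending on dialect, ``0/1`` in CSV) become
    polymorphic state sets.
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    text = path.read_text()
    if dialect == "nexus":
        return _read_nexus(text)
    if dialect == "tnt":
        return _read_tnt(text)
    return _read_csv(text)


def write_matrix(matrix: CharacterMatrix, path: str | Path, dialect: str = "nexus") -> None:
    """Write *matrix* to *path*; ``read_matrix`` round-trips all dialects."""
    path = Path(path)
    if dialect == "nexus":
        out = _format_nexus(matrix)
    elif dialect == "tnt":
        out = _format_tnt(matrix)
    elif dialect == "csv":
        out = _format_csv(matrix)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    path.write_text(out)


def _cell_token(cell: Cell | None, brackets: str = "{}") -> str:
    if cell is None:
        return "?"
    if len(cell) == 1:
        return str(next(iter(cell)))
    inner = "".join(str(s) for s in sorted(cell))
    return brackets[0] + inner + brackets[1]


def _parse_state_tokens(seq: str, taxon: str, open_close: Mapping[str, str]) -> list[Cell | None]:
    cells: list[Cell | None] = []
    i = 0
    while i < len(seq):
        ch = seq[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "?":
            cells.append(None)
            i += 1
        elif ch.isdigit():
            cells.append(frozenset({int(ch)}))
            i += 1
        elif ch in open_close:
            close = open_close[ch]
            j = seq.find(close, i + 1)
            if j < 0:
                raise MatrixFormatError(
                    f"unclosed {ch!r} in row for taxon {taxon!r} at position {i}"
                )
            states = frozenset(int(s) for s in seq[i + 1 : j] if s.isdigit())
            if not states:
                raise MatrixFormatError(
                    f"empty state group in row for taxon {taxon!r} at position {i}"
                )
            cells.append(states)
            i = j + 1
        else:
            raise MatrixFormatError(
                f"unknown symbol {ch!r} in row for taxon {taxon!r} at position {i}"
            )
    return cells


# -- NEXUS ------------------------------------------------------------------


def _read_nexus(text: str) -> CharacterMatrix:
    try:
        dm = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:  # dendropy raises several error classes
        raise MatrixFormatError(f"NEXUS parse failure: {exc}") from exc
    names: list[str] = []
    rows: list[list[Cell | None]] = []
    for taxon in dm.taxon_namespace:
        seq = dm[taxon]
        row: list[Cell | None] = []
        for state in seq:
            sym = state.symbol
            if sym == "?":
                row.append(None)
            elif sym is not None and sym.isdigit():
                row.append(frozenset({int(sym)}))
            else:  # multistate group, e.g. {01}
                members = frozenset(
                    int(m.symbol)
                    for m in (state.member_states or [])
                    if m.symbol and m.symbol.isdigit()
                )
                row.append(members if members else None)
        names.append(taxon.label.replace(" ", "_"))
        rows.append(row)
    lens = {len(r) for r in rows}
    if len(lens) > 1:
        raise MatrixFormatError("ragged NEXUS matrix")
    return CharacterMatrix(names, rows)


def _format_nexus(matrix: CharacterMatrix) -> str:
    max_state = max((matrix.max_state(j) for j in range(matrix.n_chars)), default=0)
    symbols = "".join(str(s) for s in range(max_state + 1))
    name_w = max(len(t) for t in matrix.taxon_names) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_chars};",
        f'FORMAT DATATYPE=STANDARD MISSING=? SYMBOLS="{symbols}";',
        "MATRIX",
    ]
    for name, row in zip(matrix.taxon_names, matrix.cells):
        seq = "".join(_cell_token(c, "{}") for c in row)
        lines.append(f"{name:<{name_w}}{seq}")
    lines += [";", "END;", ""]
    return "\n".join(lines)


# -- TNT xread --------------------------------------------------------------

_TNT_HEADER = re.compile(r"xread\s+(?:'[^']*'\s+)?(\d+)\s+(\d+)", re.IGNORECASE)


def _read_tnt(text: str) -> CharacterMatrix:
    m = _TNT_HEADER.search(text)
    if not m:
        raise MatrixFormatError("not a TNT xread file (missing 'xread nchar ntax')")
    n_chars, n_taxa = int(m.group(1)), int(m.group(2))
    body = text[m.end() :]
    end = body.find(";")
    if end >= 0:
        body = body[:end]
    names: list[str] = []
    rows: list[list[Cell | None]] = []
    for line in body.splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise MatrixFormatError(f"bad TNT row: {line!r}")
        name, seq = parts
        cells = _parse_state_tokens(seq, name, {"[": "]", "(": ")", "{": "}"})
        if len(cells) != n_chars:
            raise MatrixFormatError(
                f"taxon {name!r} has {len(cells)} characters, header says {n_chars}"
            )
        names.append(name)
        rows.append(cells)
    if len(names) != n_taxa:
        raise MatrixFormatError(f"found {len(names)} taxa, header says {n_taxa}")
    return CharacterMatrix(names, rows)


def _format_tnt(matrix: CharacterMatrix) -> str:
    name_w = max(len(t) for t in matrix.taxon_names) + 2
    lines = ["xread", f"{matrix.n_chars} {matrix.n_taxa}"]
    for name, row in zip(matrix.taxon_names, matrix.cells):
        seq = "".join(_cell_token(c, "[]") for c in row)
        lines.append(f"{name:<{name_w}}{seq}")
    lines += [";", ""]
    return "\n".join(lines)


# -- CSV --------------------------------------------------------------------


def _read_csv(text: str) -> CharacterMatrix:
    reader = csv.reader(text.splitlines())
    try:
        header = next(reader)
    except StopIteration:
        raise MatrixFormatError("empty CSV matrix") from None
    n_chars = len(header) - 1
    names: list[str] = []
    rows: list[list[Cell | None]] = []
    for rec in reader:
        if not rec or (len(rec) == 1 and not rec[0].strip()):
            continue
        name = rec[0].strip()
        if len(rec) - 1 != n_chars:
            raise MatrixFormatError(
                f"ragged CSV matrix: taxon {name!r} has {len(rec) - 1} cells, "
                f"expected {n_chars}"
            )
        row: list[Cell | None] = []
        for k, tok in enumerate(rec[1:]):
            tok = tok.strip()
            if tok == "?":
                row.append(None)
            elif "/" in tok:
                row.append(frozenset(int(s) for s in tok.split("/")))
            elif tok.isdigit():
                row.append(frozenset({int(tok)}))
            else:
                raise MatrixFormatError(
                    f"unknown symbol {tok!r} for taxon {name!r}, character {k}"
                )
        names.append(name)
        rows.append(row)
    return CharacterMatrix(names, rows)


def _format_csv(matrix: CharacterMatrix) -> str:
    lines = ["taxon," + ",".join(str(j) for j in range(matrix.n_chars))]
    for name, row in zip(matrix.taxon_names, matrix.cells):
        toks = []
        for c in row:
            if c is None:
                toks.append("?")
            elif len(c) == 1:
                toks.append(str(next(iter(c))))
            else:
                toks.append("/".join(str(s) for s in sorted(c)))
        lines.append(name + "," + ",".join(toks))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# matrix editing and summaries
# ---------------------------------------------------------------------------


def drop_taxon(matrix: CharacterMatrix, taxon: str) -> CharacterMatrix:
    """Return a copy of *matrix* without *taxon* (characters unchanged)."""
    if taxon not in matrix.taxon_names:
        raise KeyError(f"taxon {taxon!r} not in matrix")
    if matrix.n_taxa == 1:
        raise ValueError("cannot drop the only taxon in a matrix")
    keep = [t for t in matrix.taxon_names if t != taxon]
    return matrix.with_taxa(keep)


def informative_characters(matrix: CharacterMatrix) -> set[int]:
    """Indices of parsimony-informative characters.

    A character is informative iff at least two of its states each occur in
    at least two taxa (missing cells ignored; polymorphic cells count toward
    every state they contain).
    """
    out: set[int] = set()
    for j in range(matrix.n_chars):
        counts: dict[int, int] = {}
        for cell in matrix.column(j):
            if cell is None:
                continue
            for s in cell:
                counts[s] = counts.get(s, 0) + 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            out.add(j)
    return out


# ---------------------------------------------------------------------------
# area occurrences
# ---------------------------------------------------------------------------

#: Canonical paleogeographic areas for the Ordovician–Silurian study system,
#: keyed by their customary integer codes.
AREA_CODES: dict[int, str] = {
    1: "Avalonia",
    2: "Baltica",
    3: "Bohemia",
    4: "E_Laurentia",
    5: "NW_Laurentia",
    6: "Yangtze",
    7: "Australia",
}


@dataclass(frozen=True)
class AreaAssignment:
    """Taxon → occupied-area mapping over a fixed ordered area list."""

    area_names: tuple[str, ...]
    occurrences: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        if len(set(self.area_names)) != len(self.area_names):
            raise ValueError("area names must be unique")
        known = set(self.area_names)
        for taxon, areas in self.occurrences.items():
            if not areas:
                raise ValueError(f"taxon {taxon!r} maps to no areas")
            unknown = set(areas) - known
            if unknown:
                raise ValueError(
                    f"taxon {taxon!r} references unknown areas {sorted(unknown)}"
                )

    def areas_of(self, taxon: str) -> frozenset:
        try:
            return frozenset(self.occurrences[taxon])
        except KeyError:
            raise KeyError(f"taxon {taxon!r} has no area assignment") from None


def read_area_assignment(
    path: str | Path, area_names: Sequence[str] | None = None
) -> AreaAssignment:
    """Read ``taxon,area1;area2`` CSV rows (names or integer codes 1–7)."""
    occ: dict[str, frozenset] = {}
    seen: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.lower().startswith("taxon,"):
            continue
        taxon, _, areas_tok = line.partition(",")
        areas = []
        for tok in areas_tok.split(";"):
            tok = tok.strip()
            if not tok:
                continue
            if tok.isdigit():
                code = int(tok)
                if code not in AREA_CODES:
                    raise MatrixFormatError(f"unknown area code {code} for {taxon!r}")
                tok = AREA_CODES[code]
            areas.append(tok)
            if tok not in seen:
                seen.append(tok)
        occ[taxon.strip()] = frozenset(areas)
    names = tuple(area_names) if area_names is not None else tuple(seen)
    return AreaAssignment(names, occ)


def write_area_assignment(assignment: AreaAssignment, path: str | Path) -> None:
    lines = ["taxon,areas"]
    for taxon in assignment.occurrences:
        areas = ";".join(sorted(assignment.occurrences[taxon]))
        lines.append(f"{taxon},{areas}")
    Path(path).write_text("\n".join(lines) + "\n")
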