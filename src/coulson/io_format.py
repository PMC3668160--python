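"""Reading and writing the Coulson plot table dialect.

The input is a comma- or tab-delimited spreadsheet export.  The top three
rows carry taxonomy (supergroup, kingdom/secondary label, species name), an
optional fourth row carries free-text annotation, and the first two columns
label complexes and their subunits.  The complex name appears in column one
only on the row of its first subunit; every other cell of the data block is
a binary occupancy token ('+'/'-' or '1'/'0').

Parsing is split into a lenient tokenizer (:func:`parse_table`) and a strict
validator (:func:`build_dataset`) that accumulates every problem it finds
into a :class:`ValidationReport` with 1-based spreadsheet coordinates.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FormatError",
    "RawTable",
    "Taxon",
    "ComplexDef",
    "Dataset",
    "ColorSet",
    "Issue",
    "ValidationReport",
    "DEFAULT_COLOR_SET",
    "parse_table",
    "parse_occupancy_token",
    "build_dataset",
    "read_color_set",
    "write_dataset",
]


class FormatError(ValueError):
    """Raised for inputs that cannot even be tokenized (not cell-level issues)."""


# Closed token sets; comparison happens after whitespace strip.  The
# typographic minus U+2212 is accepted because spreadsheet exports produce it.
_PRESENT_TOKENS = frozenset({"+", "1"})
_ABSENT_TOKENS = frozenset({"-", "−", "0"})

_DELIMS = {"comma": ",", "tab": "\t"}


@dataclass(frozen=True)
class RawTable:
    """A rectangular grid of stripped cell strings plus the delimiter used."""

    cells: tuple[tuple[str, ...], ...]
    delimiter: str  # "comma" | "tab"

    @property
    def n_rows(self) -> int:
        return len(self.cells)

    @property
    def n_cols(self) -> int:
        return len(self.cells[0]) if self.cells else 0


@dataclass(frozen=True)
class Taxon:
    """One data column of the header block."""

    group_top: str
    group_mid: str
    species: str
    annotation: str | None = None
    column_index: int = 0


@dataclass(frozen=True)
class ComplexDef:
    """One pie template: a named complex and its ordered subunits."""

    name: str
    subunits: tuple[str, ...]

    @property
    def n_subunits(self) -> int:
        return len(self.subunits)


@dataclass(eq=False)
class Dataset:
    """A validated presence/absence table.

    ``occupancy`` is a boolean matrix indexed ``[global subunit row, taxon
    column]`` where global subunit rows run over complexes in input order.
    """

    taxa: tuple[Taxon, ...]
    complexes: tuple[ComplexDef, ...]
    occupancy: np.ndarray
    has_row4: bool = False

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=bool)
        object.__setattr__(self, "occupancy", occ)
        n_sub = sum(c.n_subunits for c in self.complexes)
        if occ.shape != (n_sub, len(self.taxa)):
            raise ValueError(
                f"occupancy shape {occ.shape} does not match "
                f"{n_sub} subunits x {len(self.taxa)} taxa"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_complexes(self) -> int:
        return len(self.complexes)

    @property
    def n_subunits(self) -> int:
        return int(self.occupancy.shape[0])

    @property
    def n_present(self) -> int:
        return int(self.occupancy.sum())

    def global_row(self, complex_index: int, subunit_index: int) -> int:
        """Row of ``occupancy`` holding (complex, subunit)."""
        before = sum(c.n_subunits for c in self.complexes[:complex_index])
        return before + subunit_index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.complexes == other.complexes
            and self.has_row4 == other.has_row4
            and np.array_equal(self.occupancy, other.occupancy)
        )


@dataclass(frozen=True)
class ColorSet:
    """Ordered (label, "#RRGGBB") pairs assigned to supergroups."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("a color set must contain at least one color")
        for label, color in self.entries:
            if not _is_hex_color(color):
                raise ValueError(f"invalid sRGB hex color {color!r} for {label!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def label_map(self) -> dict[str, str]:
        """First color per label (exact-match lookup for group names)."""
        out: dict[str, str] = {}
        for label, color in self.entries:
            out.setdefault(label, color)
        return out


def _is_hex_color(s: str) -> bool:
    return (
        len(s) == 7
        and s[0] == "#"
        and all(c in "0123456789abcdefABCDEF" for c in s[1:])
    )


# Hard-coded default palette (qualitative, color-blind-aware); the same set
# ships as a loadable text file via ``ColorSet`` round-tripping.
DEFAULT_COLOR_SET = ColorSet(
    entries=(
        ("1", "#E41A1C"),
        ("2", "#377EB8"),
        ("3", "#4DAF4A"),
        ("4", "#984EA3"),
        ("5", "#FF7F00"),
        ("6", "#A65628"),
        ("7", "#F781BF"),
        ("8", "#999999"),
        ("9", "#FFD92F"),
    )
)


@dataclass(frozen=True)
class Issue:
    severity: str  # "error" | "warning"
    row: int  # 1-based physical file row
    column: int  # 1-based physical file column
    message: str

    def __str__(self) -> str:
        return f"{self.severity}: row {self.row}, column {self.column}: {self.message}"


@dataclass
class ValidationReport:
    issues: list[Issue] = field(default_factory=list)

    def add(self, severity: str, row: int, column: int, message: str) -> None:
        self.issues.append(Issue(severity, row, column, message))

    @property
    def errors(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors


def parse_table(text: str | bytes, delimiter: str = "auto") -> RawTable:
    """Tokenize delimited text into a rectangular :class:`RawTable`.

    ``delimiter`` is ``"comma"``, ``"tab"`` or ``"auto"``; in auto mode a tab
    anywhere in the first line wins, else comma.  RFC-4180 quoting is honored,
    every cell is whitespace-stripped, trailing blank lines are dropped and
    short rows are padded with empty cells.
    """
    if isinstance(text, bytes):
        try:
            text = text.decode("utf-8")
        except UnicodeDecodeError as exc:
            raise FormatError(f"input is not valid UTF-8: {exc}") from exc
    if text.startswith("\ufeff"):
        text = text[1:]

    if delimiter == "auto":
        first_line = text.split("\n", 1)[0]
        delimiter = "tab" if "\t" in first_line else "comma"
    if delimiter not in _DELIMS:
        raise ValueError(f"unknown delimiter {delimiter!r}")

    reader = csv.reader(io.StringIO(text), delimiter=_DELIMS[delimiter])
    rows = [[cell.strip() for cell in row] for row in reader]
    while rows and all(cell == "" for cell in rows[-1]):
        rows.pop()
    if not rows:
        raise FormatError("input contains no data rows")

    width = max(len(r) for r in rows)
    cells = tuple(tuple(r + [""] * (width - len(r))) for r in rows)
    return RawTable(cells=cells, delimiter=delimiter)


def parse_occupancy_token(token: str) -> bool:
    """Map an occupancy token to presence.

    '+' / '1' mean present; '-' / '0' (and the typographic minus) mean
    absent.  Anything else, including the empty string, raises ``ValueError``
    (the caller attaches spreadsheet coordinates).
    """
    stripped = token.strip()
    if stripped in _PRESENT_TOKENS:
        return True
    if stripped in _ABSENT_TOKENS:
        return False
    raise ValueError(f"invalid occupancy token {token!r}")


def _is_valid_token(token: str) -> bool:
    s = token.strip()
    return s in _PRESENT_TOKENS or s in _ABSENT_TOKENS


def _inherit_left(row: tuple[str, ...], start: int) -> list[str]:
    # Blank header cells inherit the nearest non-empty label to their left,
    # matching how merged spreadsheet cells export.
    out: list[str] = []
    current = ""
    for cell in row[start:]:
        if cell:
            current = cell
        out.append(current)
    return out


def build_dataset(
    table: RawTable,
    strict_row4: bool = False,
    group_contiguity: str = "error",
) -> tuple[Dataset | None, ValidationReport]:
    """Validate a raw table and assemble a :class:`Dataset`.

    Rows 1-2 are group labels, row 3 species names (every data column must be
    occupied), row 4 annotation or the first data row.  Row 4 is classified
    as data when any of its data cells is a valid occupancy token; the
    ``strict_row4`` flag forces the annotation reading.  A new complex starts
    on any row with a non-empty first column; fully blank rows are separators
    and are skipped.

    Returns ``(dataset, report)``; the dataset is ``None`` iff the report
    contains at least one error.
    """
    if group_contiguity not in ("error", "warning"):
        raise ValueError("group_contiguity must be 'error' or 'warning'")
    report = ValidationReport()
    rows = table.cells
    n_rows, n_cols = table.n_rows, table.n_cols

    if n_rows < 4:
        report.add("error", n_rows, 1, "table needs at least 4 rows (3 header rows and 1 data row)")
        return None, report
    if n_cols < 3:
        report.add("error", 1, n_cols, "table needs at least 3 columns (2 label columns and 1 taxon)")
        return None, report

    n_taxa = n_cols - 2
    group_top = _inherit_left(rows[0], 2)
    group_mid = _inherit_left(rows[1], 2)
    species = list(rows[2][2:])

    for j, label in enumerate(group_top):
        if not label:
            report.add("error", 1, j + 3, "missing supergroup label (row 1 must start with a label)")
    for j, name in enumerate(species):
        if not name:
            report.add("error", 3, j + 3, "empty species name: no gaps are permitted in row 3")

    # Row-4 classification: annotation unless it carries occupancy tokens.
    row4 = rows[3]
    row4_data = row4[2:]
    row4_has_tokens = any(_is_valid_token(c) for c in row4_data if c != "")
    if strict_row4:
        has_row4 = True
        if row4_has_tokens:
            report.add(
                "warning", 4, 1,
                "row 4 contains occupancy-like tokens but strict-row4 forces it to be annotation",
            )
    else:
        has_row4 = not row4_has_tokens
        if row4_has_tokens:
            report.add(
                "warning", 4, 1,
                "row 4 classified as the first data row because its cells parse as occupancy tokens",
            )
    annotations: list[str | None]
    if has_row4:
        annotations = list(row4_data)
        first_data_row = 4
    else:
        annotations = [None] * n_taxa
        first_data_row = 3

    taxa = tuple(
        Taxon(
            group_top=group_top[j],
            group_mid=group_mid[j],
            species=species[j],
            annotation=annotations[j],
            column_index=j,
        )
        for j in range(n_taxa)
    )

    # Group contiguity: repeats of a supergroup after an intervening different
    # one usually mean the columns are out of order.
    seen: list[str] = []
    for j, label in enumerate(group_top):
        if label and label in seen and seen[-1] != label:
            report.add(
                group_contiguity, 1, j + 3,
                f"supergroup {label!r} reappears non-contiguously; reorder taxon columns",
            )
        if not seen or seen[-1] != label:
            seen.append(label)

    complexes: list[tuple[str, list[str]]] = []
    occ_rows: list[list[bool]] = []
    for r in range(first_data_row, n_rows):
        row = rows[r]
        if all(cell == "" for cell in row):
            continue  # blank separator row between systems
        name_cell, subunit_cell = row[0], row[1]
        if name_cell:
            complexes.append((name_cell, []))
        if not complexes:
            report.add(
                "error", r + 1, 1,
                "subunit row appears before any complex name in column 1",
            )
            complexes.append(("", []))
        if not subunit_cell:
            report.add("error", r + 1, 2, "missing subunit name in column 2")
        complexes[-1][1].append(subunit_cell)

        occ_row: list[bool] = []
        for j, cell in enumerate(row[2:]):
            try:
                occ_row.append(parse_occupancy_token(cell))
            except ValueError:
                if cell.strip() == "":
                    msg = "empty cells are not allowed in the data matrix"
                else:
                    msg = f"invalid occupancy token {cell!r} (use '+'/'-' or '1'/'0')"
                report.add("error", r + 1, j + 3, msg)
                occ_row.append(False)
        occ_rows.append(occ_row)

    if not occ_rows:
        report.add("error", n_rows, 1, "no subunit data rows found")

    if not report.ok:
        return None, report

    dataset = Dataset(
        taxa=taxa,
        complexes=tuple(ComplexDef(name, tuple(subs)) for name, subs in complexes),
        occupancy=np.array(occ_rows, dtype=bool),
        has_row4=has_row4,
    )
    return dataset, report


def read_color_set(text: str) -> ColorSet:
    """Parse a plain-text color set: one ``label<TAB>#RRGGBB`` (or bare
    ``#RRGGBB``) per non-blank line; bare colors get their 1-based ordinal as
    label."""
    entries: list[tuple[str, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if "\t" in line:
            label, _, color = line.partition("\t")
            label = label.strip()
            color = color.strip()
        else:
            label, color = "", line
        if not label:
            label = str(len(entries) + 1)
        if not _is_hex_color(color):
            raise FormatError(
                f"line {lineno}: {color!r} is not a valid #RRGGBB color"
            )
        entries.append((label, color))
    if not entries:
        raise FormatError("color set file contains no colors")
    return ColorSet(entries=tuple(entries))


def write_color_set(cs: ColorSet) -> str:
    return "".join(f"{label}\t{color}\n" for label, color in cs.entries)


def write_dataset(ds: Dataset, delimiter: str = "comma") -> str:
    """Serialize a dataset back to the table dialect (occupancy as '1'/'0').

    The output re-parses to an identical dataset: ``build_dataset(
    parse_table(write_dataset(ds)))`` equals ``ds``.
    """
    if delimiter not in _DELIMS:
        raise ValueError(f"unknown delimiter {delimiter!r}")
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter=_DELIMS[delimiter], lineterminator="\n")
    writer.writerow(["", ""] + [t.group_top for t in ds.taxa])
    writer.writerow(["", ""] + [t.group_mid for t in ds.taxa])
    writer.writerow(["", ""] + [t.species for t in ds.taxa])
    if ds.has_row4:
        writer.writerow(["", ""] + [t.annotation or "" for t in ds.taxa])
    row = 0
    for cx in ds.complexes:
        for s, subunit in enumerate(cx.subunits):
            tokens = ["1" if v else "0" for v in ds.occupancy[row]]
            writer.writerow([cx.name if s == 0 else "", subunit] + tokens)
            row += 1
    return buf.getvalue()
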