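"""Synthetic datasets at arbitrary scale, plus systematically broken inputs.

Valid fixtures use systematic names (``G1``, ``G1_sp2``, ``C3``, ``C3_s4``),
uniform subunit counts and i.i.d. Bernoulli occupancy — enough structure to
exercise parsing, layout and rendering without modelling real gene loss.
Malformed fixtures are single-edit mutations of a serialized valid dataset,
so each one isolates exactly one validation rule and comes paired with the
spreadsheet coordinates the validator must report.

All randomness flows through one ``numpy`` generator seeded from the spec.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_format import ComplexDef, Dataset, Taxon, parse_table, write_dataset

__all__ = ["FixtureSpec", "MalformedFixture", "DEFECTS", "generate_dataset", "make_malformed"]

DEFECTS = (
    "gap_in_species_row",
    "empty_data_cell",
    "bad_token",
    "subunit_before_complex",
    "ragged_rows",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic dataset.

    Defaults give a mid-sized plot (5 supergroups x 5 species, 10 complexes
    of 2-8 subunits) at 60% subunit presence.
    """

    n_groups: int = 5
    species_per_group: int = 5
    n_complexes: int = 10
    subunits_min: int = 2
    subunits_max: int = 8
    presence_prob: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.species_per_group < 1 or self.n_complexes < 1:
            raise ValueError("counts must be >= 1")
        if not 1 <= self.subunits_min <= self.subunits_max:
            raise ValueError("need 1 <= subunits_min <= subunits_max")
        if not 0.0 <= self.presence_prob <= 1.0:
            raise ValueError("presence_prob must be in [0, 1]")


def generate_dataset(spec: FixtureSpec) -> Dataset:
    """Deterministically generate a valid dataset from ``spec``."""
    rng = np.random.default_rng(spec.seed)
    taxa = []
    for g in range(1, spec.n_groups + 1):
        for s in range(1, spec.species_per_group + 1):
            taxa.append(
                Taxon(
                    group_top=f"G{g}",
                    group_mid=f"K{g}",
                    species=f"G{g}_sp{s}",
                    annotation=None,
                    column_index=len(taxa),
                )
            )
    counts = rng.integers(spec.subunits_min, spec.subunits_max + 1, size=spec.n_complexes)
    complexes = tuple(
        ComplexDef(
            name=f"C{c + 1}",
            subunits=tuple(f"C{c + 1}_s{s + 1}" for s in range(int(counts[c]))),
        )
        for c in range(spec.n_complexes)
    )
    n_rows = int(counts.sum())
    occupancy = rng.random((n_rows, len(taxa))) < spec.presence_prob
    return Dataset(taxa=tuple(taxa), complexes=complexes, occupancy=occupancy)


@dataclass(frozen=True)
class MalformedFixture:
    """A broken serialized table plus where the validator must complain."""

    text: str
    defect: str
    row: int  # 1-based expected error row
    column: int  # 1-based expected error column


def _split_rows(text: str) -> list[list[str]]:
    table = parse_table(text, delimiter="comma")
    return [list(r) for r in table.cells]


def _join_rows(rows: list[list[str]]) -> str:
    import csv
    import io

    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerows(rows)
    return buf.getvalue()


def make_malformed(ds: Dataset, defect: str, seed: int = 0) -> MalformedFixture:
    """Serialize ``ds`` and inject exactly one named defect at a seeded spot."""
    if defect not in DEFECTS:
        raise ValueError(f"unknown defect {defect!r}; choose from {DEFECTS}")
    rng = np.random.default_rng(seed)
    rows = _split_rows(write_dataset(ds, delimiter="comma"))
    header_rows = 3 + (1 if ds.has_row4 else 0)
    n_cols = len(rows[0])
    taxon_col = int(rng.integers(0, ds.n_taxa))  # 0-based among taxa
    data_row = header_rows + int(rng.integers(0, ds.n_subunits))  # 0-based file row

    if defect == "gap_in_species_row":
        rows[2][2 + taxon_col] = ""
        row, col = 3, 3 + taxon_col
    elif defect == "empty_data_cell":
        rows[data_row][2 + taxon_col] = ""
        row, col = data_row + 1, 3 + taxon_col
    elif defect == "bad_token":
        rows[data_row][2 + taxon_col] = "x"
        row, col = data_row + 1, 3 + taxon_col
    elif defect == "subunit_before_complex":
        rows[header_rows][0] = ""  # orphan the first complex's subunits
        row, col = header_rows + 1, 1
    else:  # ragged_rows: truncate one data row; padding turns the lost
        # trailing cell into an empty data cell
        rows[data_row] = rows[data_row][: n_cols - 1]
        row, col = data_row + 1, n_cols

    return MalformedFixture(text=_join_rows(rows), defect=defect, row=row, column=col)
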