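# coulson

Deterministic **Coulson plots** — publication-quality matrices of pie charts
for comparative genomics — from plain spreadsheet exports.

## The problem

Comparative genomics routinely produces presence/absence calls for the
subunits of many protein complexes or pathways across many genomes
(phylogenetic profiles). As a spreadsheet these patterns are nearly
unreadable; as a Coulson plot each (complex, taxon) pair becomes one pie
whose sectors map one-to-one onto the complex's subunits, a sector being
filled — in the taxon's supergroup color — exactly when that subunit's gene
is predicted present:

- taxa are rows, complexes are columns, both in input order;
- a gray *key pie* above each column labels which sector is which subunit;
- sector *i* of an *n*-subunit complex spans degrees
  `[i·360/n, (i+1)·360/n)`, clockwise from 12 o'clock;
- complexes with a single subunit render as filled/unfilled discs, i.e. the
  classic dot-plot as a degenerate case.

The package is for anyone who already has an occupancy table (from BLAST,
HMMER, OrthoFinder, hand curation, …) and wants the figure: it parses and
validates the table dialect, lays out the scene, and writes byte-reproducible
SVG (PDF via post-conversion) that remains fully editable in Inkscape or
Illustrator — every pie, sector and label is an addressable element.

## Input format

Comma- or tab-delimited text (auto-detected). Rows 1–2: supergroup /
secondary group labels; row 3: species (no gaps allowed); row 4: optional
annotation; column 1: complex name on its first subunit row; column 2:
subunit names; data cells `+`/`-` or `1`/`0`. See `docs/methods.md` for the
full grammar and the row-4 disambiguation rule.

## Worked example

```sh
$ coulson example -o demo.csv --seed 7 --groups 2 --species 2 --complexes 2 --subunits 2:3
wrote demo.csv: 4 taxa, 2 complexes, 6 subunits

$ coulson validate demo.csv
warning: row 4, column 1: row 4 classified as the first data row because its cells parse as occupancy tokens
OK: 4 taxa, 2 complexes, 6 subunits

$ coulson plot demo.csv -o demo.svg
wrote demo.svg: 10 pies, 30 sectors, canvas 170x222
```

The summary lines mean: the generated table has 2 supergroups × 2 species
(4 taxon columns) and 2 complexes totalling 6 subunit rows; the plot holds
one pie per (complex, taxon) pair plus one key pie per complex
(2 × 4 + 2 = 10 pies) and one sector per subunit in each of those pies
(6 × 4 + 6 = 30). The warning documents that the table has no annotation
row, so row 4 was read as data; `--strict-row4` forces the other reading.
Invalid inputs exit with status 1 and one report line per problem, each
carrying the 1-based spreadsheet coordinates of the offending cell.

Library use mirrors the CLI:

```python
from coulson import io_format, layout, render

ds, report = io_format.build_dataset(io_format.parse_table(open("demo.csv").read()))
colors = layout.assign_group_colors(ds, io_format.DEFAULT_COLOR_SET)
scene = layout.layout_plot(ds, layout.LayoutConfig(group_gap=6), colors)
render.render_svg(scene).save("demo.svg")
```

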