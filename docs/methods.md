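# Methods

## The plot

A Coulson plot displays a binary phylogenetic-profile matrix — the predicted
presence or absence of every subunit of a set of protein complexes (or
pathways, or any other functional grouping) across a panel of genomes — as a
grid of pie charts. Each pie stands for one (complex, taxon) pair; the pie is
divided into `n` equal sectors, one per subunit, and a sector is filled when
that subunit's gene is called present in that genome. Taxa form the rows and
complexes the columns; a gray "key" pie above each column labels which sector
is which subunit, and taxa are colored by their top-level taxonomic group
(supergroup) so blocks of related genomes read as blocks of color. The format
preserves all of the information in the underlying spreadsheet while making
retention-and-loss patterns visible at a glance; setting every complex to a
single subunit degenerates gracefully into a classic dot plot.

## Input dialect

The accepted table is the natural spreadsheet export of such data:

- rows 1–2: supergroup and secondary group labels (row 1 drives coloring;
  blank header cells inherit the nearest label to their left, matching how
  merged spreadsheet cells export);
- row 3: species names — every data column must be occupied;
- row 4: optional free-text annotation;
- column 1: complex name, present only on the first subunit row of each
  complex; column 2: subunit names;
- data cells: `+`/`-` or `1`/`0` (plus the typographic minus U+2212, which
  word processors and spreadsheets silently substitute). The token set is
  closed and case-sensitive so that parsing is bit-exact; empty data cells
  are always an error.

Two conventions for separating complexes circulate (a name in column 1
versus a fully blank spacer row); the parser accepts both — a non-empty
column-1 cell starts a new complex and blank rows are skipped.

Row 4 is genuinely ambiguous: it may be annotation, absent, or the first
data row. The validator classifies it as data when any of its data cells is
a valid occupancy token, records the decision as a warning, and offers a
`strict_row4` flag that forces the annotation reading. Silent
misclassification was judged the worst outcome, so the choice is always
visible and overridable.

Validation accumulates every issue (never stops at the first) and reports
1-based physical row/column coordinates, i.e. exactly the cell the user
would click in their spreadsheet. A dataset object is produced only when no
error-severity issue exists. Non-contiguous repeats of a supergroup label
are an error by default (they almost always indicate mis-ordered columns)
but can be demoted to a warning.

## Geometry

Sectors are indexed in subunit input order and swept clockwise from
12 o'clock; sector `i` of an `n`-sector pie spans `[i·360/n, (i+1)·360/n)`
degrees. A configurable `start_angle` rotates the whole convention. On an
SVG canvas (y grows downward) the point at clock angle θ on a circle of
radius r is `(cx + r·sin θ, cy − r·cos θ)`.

Layout is computed without font metrics: text width is estimated as
0.6 × font-size per character, which keeps the scene fully deterministic
across platforms at the cost of approximate label clearances. Long complex
names widen their column (the canvas grows; text never wraps), and key-pie
subunit labels are placed radially at each sector's mid-angle with no
collision resolution — the tool's philosophy, like FigTree's, is to emit an
editable vector file and leave fine typography to Inkscape or Illustrator.
Species labels are plain by default with an italics option, since italic
taxon names are usually applied during final figure editing. Supergroup
labels are vertically centered on their block of rows.

Defaults (SVG user units): pie radius 12, key-pie radius 0.75 × that, pie
gaps 8 (x) and 6 (y), extra gap between complex columns 10, extra gap
between supergroup blocks 0 (supported but off by default, as published
plots typically add it in post-editing), margin 20, label font 10 pt, key
font 7 pt, absent sectors white with a 0.5-unit gray outline.

## Rendering

SVG is the single geometry backend. The serializer writes attributes in a
fixed order, rounds every coordinate to exactly three decimals (normalizing
`-0.000`), embeds no timestamps or font files, and references fonts by the
generic `sans-serif` family — identical inputs therefore give byte-identical
files on any platform. Every pie is a `<g>` with a stable `id` and
`data-complex`/`data-taxon` attributes (`data-taxon="key"` for key pies) and
every sector a `<path>` wedge — or a `<circle>` for single-subunit pies —
with `class="sector"`, keeping each logical element addressable for
post-editing and for the element-count checks in the test suite. Arc wedges
use a clockwise sweep with the large-arc flag set only for spans over 180°,
so an exact half-disc (n = 2) takes flag 0 with the sweep bit set.

PDF output is a thin delegation of the finished SVG to an installed
converter (cairosvg, rsvg-convert or inkscape, tried in that order). When
none is available the command fails with an actionable message; there is
deliberately no silent raster fallback and no second vector backend.

## Synthetic data

The fixture generator emulates the *structure* of comparative-genomics
occupancy tables, not their biology: systematic names (`G1`, `G1_sp2`,
`C3`, `C3_s4`), subunit counts drawn uniformly from a configurable range,
and i.i.d. Bernoulli presence per cell. Defaults are a mid-sized study:
5 supergroups × 5 species, 10 complexes of 2–8 subunits, 60 % presence. All
randomness flows through a single seeded NumPy generator, so a spec is a
complete recipe for its dataset. Real datasets have phylogenetically
correlated loss, which i.i.d. sampling does not model — passing tests
demonstrate parsing/layout/rendering correctness at realistic scale, not
fidelity of any evolutionary process. Malformed fixtures are single-edit
mutations of a serialized valid table (blanked species cell, blanked or
corrupted data cell, orphaned subunit rows, truncated row), each paired
with the coordinates the validator must report, so each test isolates one
rule.

The capability checks in `scripts/acceptance.py` and the test suite use a
25-complex × 10-taxon table (5 supergroups of 2 species, 3–8 subunits,
60 % presence): 250 data pies and on the order of 1 500 sector elements,
rendered end-to-end in well under a second.

## Numerical choices and edge cases

- Sector spans are `360/n` in double precision; per-pie spans sum to 360°
  within 1 × 10⁻⁹.
- A single-sector pie is emitted as a circle primitive, avoiding the
  degenerate zero-length arc.
- Coordinates are compared and emitted at 3-decimal precision; this is also
  the tolerance used when tests read coordinates back out of the SVG.
- Datasets must have at least one complex, one subunit and one taxon;
  "empty plot" is unrepresentable by construction.
- Group colors cycle (with a warning) when there are more supergroups than
  colors; an exact label match in a color-set file overrides positional
  assignment so saved palettes follow their groups across datasets.

## Known limitations

- No text-metric-exact collision avoidance; dense key-pie labels can
  overlap and are expected to be nudged in a vector editor.
- No three-state (confidence-weighted) occupancy; the data model is binary.
- No automatic reordering or clustering of taxa or complexes; input order
  is authoritative.
- No spreadsheet-binary input; export to CSV/TSV first.
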