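"""Scene construction: from a validated dataset to positioned, colored geometry.

The Coulson plot is a grid with taxa as rows and complexes as columns.  Each
grid cell holds one pie whose sectors map one-to-one onto the complex's
subunits, clockwise from 12 o'clock in subunit input order; a sector is
filled with the taxon's supergroup color when the subunit is present.  Above
each column sits the complex name and a smaller gray key pie whose sectors
are labelled with the subunit names.

Everything here is pure in-memory computation; no output format leaks in.
Text widths are estimated from a fixed per-character advance so the layout
is deterministic without font metrics (long labels grow the canvas rather
than wrap).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

from .io_format import ColorSet, Dataset

__all__ = [
    "LayoutConfig",
    "SectorArc",
    "Pie",
    "Label",
    "PlotGeometry",
    "GroupColorMap",
    "CoulsonWarning",
    "assign_group_colors",
    "sector_geometry",
    "layout_plot",
    "count_elements",
]


class CoulsonWarning(UserWarning):
    """Non-fatal layout conditions (e.g. a color set shorter than the groups)."""


# Approximate glyph advance as a fraction of font size (generic sans-serif).
_CHAR_W = 0.6


@dataclass(frozen=True)
class LayoutConfig:
    """Tunable plot parameters, in SVG user units (points for font sizes).

    ``key_pie_radius`` defaults to 0.75 x ``pie_radius`` when left ``None``.
    ``group_gap`` defaults to 0; extra spacing between supergroup blocks is
    an opt-in refinement.  ``start_angle`` rotates every pie's first sector
    boundary clockwise away from 12 o'clock.
    """

    pie_radius: float = 12.0
    key_pie_radius: float | None = None
    pie_gap_x: float = 8.0
    pie_gap_y: float = 6.0
    system_gap: float = 10.0
    group_gap: float = 0.0
    font_size_labels: float = 10.0
    font_size_key: float = 7.0
    margin: float = 20.0
    absent_fill: str = "#FFFFFF"
    absent_stroke: str = "#808080"
    key_fill: str = "#B3B3B3"
    start_angle: float = 0.0
    italic_species: bool = False

    def __post_init__(self) -> None:
        for name in ("pie_radius", "pie_gap_x", "pie_gap_y", "font_size_labels",
                     "font_size_key", "margin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("system_gap", "group_gap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.key_pie_radius is not None:
            if not 0 < self.key_pie_radius <= self.pie_radius:
                raise ValueError("key_pie_radius must be in (0, pie_radius]")

    @property
    def key_radius(self) -> float:
        return self.key_pie_radius if self.key_pie_radius is not None else 0.75 * self.pie_radius


@dataclass(frozen=True)
class SectorArc:
    """One pie sector: angles in degrees, clockwise from 12 o'clock."""

    index: int
    n: int
    start_angle: float
    end_angle: float
    filled: bool
    color: str

    @property
    def span(self) -> float:
        return self.end_angle - self.start_angle

    @property
    def mid_angle(self) -> float:
        return (self.start_angle + self.end_angle) / 2.0


KEY = None  # taxon_index marker for key pies


@dataclass(frozen=True)
class Pie:
    cx: float
    cy: float
    radius: float
    complex_index: int
    taxon_index: int | None  # None marks a key pie
    sectors: tuple[SectorArc, ...]

    @property
    def is_key(self) -> bool:
        return self.taxon_index is None


@dataclass(frozen=True)
class Label:
    text: str
    x: float
    y: float
    font_size: float
    color: str = "#000000"
    style: str = "plain"  # "plain" | "italic"
    rotation: float = 0.0
    anchor: str = "start"  # "start" | "middle" | "end"
    role: str = "label"


@dataclass(frozen=True)
class PlotGeometry:
    canvas_width: float
    canvas_height: float
    pies: tuple[Pie, ...]
    labels: tuple[Label, ...]
    legend: tuple[Label, ...]  # key-pie subunit names, per complex
    config: LayoutConfig


@dataclass(frozen=True)
class GroupColorMap:
    """Supergroup -> color, in first-appearance order among the taxa."""

    mapping: tuple[tuple[str, str], ...]

    def color(self, group: str) -> str:
        for label, color in self.mapping:
            if label == group:
                return color
        raise KeyError(group)

    def __len__(self) -> int:
        return len(self.mapping)


class CountSummary(NamedTuple):
    pies: int
    sectors: int
    filled_sectors: int
    labels: int


def assign_group_colors(ds: Dataset, cs: ColorSet) -> GroupColorMap:
    """Assign one color per distinct supergroup.

    The i-th distinct supergroup (first-appearance order) receives the i-th
    color-set entry, cycling with a warning if there are more groups than
    colors.  A color-set entry whose label exactly matches a supergroup name
    overrides the positional assignment for that group.
    """
    groups: list[str] = []
    for taxon in ds.taxa:
        if taxon.group_top not in groups:
            groups.append(taxon.group_top)
    by_label = cs.label_map()
    if len(groups) > len(cs):
        warnings.warn(
            f"{len(groups)} supergroups but only {len(cs)} colors; colors will repeat",
            CoulsonWarning,
            stacklevel=2,
        )
    mapping = tuple(
        (g, by_label.get(g, cs.entries[i % len(cs)][1])) for i, g in enumerate(groups)
    )
    return GroupColorMap(mapping=mapping)


def sector_geometry(n: int, index: int, start_angle: float = 0.0) -> tuple[float, float]:
    """Angles (start, end) of sector ``index`` of an ``n``-sector pie.

    Degrees, clockwise from 12 o'clock; sector 0 starts at ``start_angle``.
    ``n == 1`` yields the full disc.  The span is exactly ``360 / n``.
    """
    if n < 1:
        raise ValueError("a pie needs at least one sector")
    if not 0 <= index < n:
        raise ValueError(f"sector index {index} out of range for n={n}")
    span = 360.0 / n
    start = (start_angle + index * span) % 360.0
    return start, start + span


def _polar(cx: float, cy: float, r: float, angle_deg: float) -> tuple[float, float]:
    # Clockwise-from-12-o'clock convention in a y-down coordinate system.
    theta = math.radians(angle_deg)
    return cx + r * math.sin(theta), cy - r * math.cos(theta)


def _text_w(text: str, font_size: float) -> float:
    return len(text) * font_size * _CHAR_W


def _pie_sectors(
    n: int, start_angle: float, filled_flags: list[bool], fill_color: str, absent_fill: str
) -> tuple[SectorArc, ...]:
    out = []
    for i in range(n):
        start, end = sector_geometry(n, i, start_angle)
        filled = filled_flags[i]
        out.append(
            SectorArc(
                index=i, n=n, start_angle=start, end_angle=end,
                filled=filled, color=fill_color if filled else absent_fill,
            )
        )
    return tuple(out)


def layout_plot(ds: Dataset, cfg: LayoutConfig, colors: GroupColorMap) -> PlotGeometry:
    """Position every pie and label of the plot.

    Taxa become rows (input order), complexes columns (input order).  The
    header band holds complex names and gray key pies with radially placed
    subunit labels; the left band holds supergroup labels (once per
    contiguous block, vertically centered on it) and species names, both in
    the supergroup color.
    """
    r = cfg.pie_radius
    key_r = cfg.key_radius
    pad = 4.0

    # --- left band: supergroup column + species column
    group_w = max(_text_w(t.group_top, cfg.font_size_labels) for t in ds.taxa)
    species_w = max(_text_w(t.species, cfg.font_size_labels) for t in ds.taxa)
    left_band = group_w + pad + species_w + pad

    # --- header band: complex name line + key pie with radial labels
    name_h = cfg.font_size_labels * 1.4
    key_label_extent = cfg.font_size_key + pad  # radial clearance for subunit names
    header_h = name_h + pad + 2 * (key_r + key_label_extent) + pad

    # --- column geometry; a long complex name widens its column beyond the
    # pie cell so the canvas grows instead of wrapping text
    cell_w = 2 * r + cfg.pie_gap_x
    col_widths = [
        cell_w + max(0.0, _text_w(cx.name, cfg.font_size_labels) - 2 * r)
        for cx in ds.complexes
    ]
    col_centers: list[float] = []
    x = cfg.margin + left_band
    for c, w in enumerate(col_widths):
        if c > 0:
            x += cfg.system_gap
        col_centers.append(x + w / 2.0)
        x += w
    canvas_width = x + cfg.margin

    # --- row geometry with group_gap between supergroup blocks
    cell_h = 2 * r + cfg.pie_gap_y
    row_centers: list[float] = []
    y = cfg.margin + header_h
    for t, taxon in enumerate(ds.taxa):
        if t > 0 and taxon.group_top != ds.taxa[t - 1].group_top:
            y += cfg.group_gap
        row_centers.append(y + cell_h / 2.0)
        y += cell_h
    canvas_height = y + cfg.margin

    pies: list[Pie] = []
    labels: list[Label] = []
    legend: list[Label] = []

    key_cy = cfg.margin + name_h + pad + key_label_extent + key_r
    for c, cx_def in enumerate(ds.complexes):
        ccx = col_centers[c]
        labels.append(
            Label(
                text=cx_def.name, x=ccx, y=cfg.margin + cfg.font_size_labels,
                font_size=cfg.font_size_labels, anchor="middle", role="complex",
            )
        )
        n = cx_def.n_subunits
        sectors = _pie_sectors(n, cfg.start_angle, [True] * n, cfg.key_fill, cfg.absent_fill)
        pies.append(Pie(ccx, key_cy, key_r, c, KEY, sectors))
        for arc, subunit in zip(sectors, cx_def.subunits):
            lx, ly = _polar(ccx, key_cy, key_r + pad, arc.mid_angle)
            anchor = "middle"
            if math.sin(math.radians(arc.mid_angle)) > 0.1:
                anchor = "start"
            elif math.sin(math.radians(arc.mid_angle)) < -0.1:
                anchor = "end"
            legend.append(
                Label(
                    text=subunit, x=lx, y=ly + cfg.font_size_key * 0.35,
                    font_size=cfg.font_size_key, color="#404040",
                    anchor=anchor, role="subunit",
                )
            )

    # --- left band labels
    species_x = cfg.margin + left_band - pad
    group_x = cfg.margin + group_w
    block_start = 0
    for t, taxon in enumerate(ds.taxa):
        color = colors.color(taxon.group_top)
        labels.append(
            Label(
                text=taxon.species, x=species_x,
                y=row_centers[t] + cfg.font_size_labels * 0.35,
                font_size=cfg.font_size_labels, color=color,
                style="italic" if cfg.italic_species else "plain",
                anchor="end", role="species",
            )
        )
        last_of_block = t == ds.n_taxa - 1 or ds.taxa[t + 1].group_top != taxon.group_top
        if last_of_block:
            mid_y = (row_centers[block_start] + row_centers[t]) / 2.0
            labels.append(
                Label(
                    text=taxon.group_top, x=group_x,
                    y=mid_y + cfg.font_size_labels * 0.35,
                    font_size=cfg.font_size_labels, color=color,
                    anchor="end", role="group",
                )
            )
            block_start = t + 1

    # --- data pies
    for c, cx_def in enumerate(ds.complexes):
        n = cx_def.n_subunits
        row0 = ds.global_row(c, 0)
        for t, taxon in enumerate(ds.taxa):
            filled = [bool(ds.occupancy[row0 + s, t]) for s in range(n)]
            sectors = _pie_sectors(
                n, cfg.start_angle, filled, colors.color(taxon.group_top), cfg.absent_fill
            )
            pies.append(Pie(col_centers[c], row_centers[t], r, c, t, sectors))

    return PlotGeometry(
        canvas_width=canvas_width,
        canvas_height=canvas_height,
        pies=tuple(pies),
        labels=tuple(labels),
        legend=tuple(legend),
        config=cfg,
    )


def count_elements(g: PlotGeometry) -> CountSummary:
    """Exact tallies over a scene: (pies, sectors, filled sectors, labels).

    Key-pie sectors count as filled (they carry the key fill); the filled
    count over data pies alone equals the dataset's present-cell count.
    """
    pies = len(g.pies)
    sectors = sum(len(p.sectors) for p in g.pies)
    filled = sum(1 for p in g.pies for s in p.sectors if s.filled and not p.is_key)
    labels = len(g.labels) + len(g.legend)
    return CountSummary(pies=pies, sectors=sectors, filled_sectors=filled, labels=labels)
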