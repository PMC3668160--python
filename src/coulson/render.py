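"""Deterministic SVG serialization of a plot scene, plus PDF post-conversion.

SVG is the canonical output.  The serializer writes attributes in a fixed
order and rounds every coordinate to three decimals, so identical geometry
yields byte-identical files on any platform.  Each pie is a ``<g>`` with
stable ``id`` and ``data-*`` role attributes and each sector a ``<path>``
(or ``<circle>`` for single-sector pies), keeping every logical element
addressable for post-editing in Inkscape or Illustrator.

PDF is produced by delegating the finished SVG to an external converter
(cairosvg, rsvg-convert or inkscape); there is no second geometry backend.
"""

from __future__ import annotations

import math
import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path
from xml.sax.saxutils import escape

from .layout import Label, Pie, PlotGeometry, SectorArc

__all__ = [
    "SvgDocument",
    "PdfConversionError",
    "sector_path_data",
    "render_svg",
    "convert_to_pdf",
]


class PdfConversionError(RuntimeError):
    """No usable SVG-to-PDF converter was found."""


def _fmt(x: float) -> str:
    s = f"{x:.3f}"
    return "0.000" if s == "-0.000" else s


def _polar(cx: float, cy: float, r: float, angle_deg: float) -> tuple[float, float]:
    theta = math.radians(angle_deg)
    return cx + r * math.sin(theta), cy - r * math.cos(theta)


def sector_path_data(
    arc: SectorArc, cx: float, cy: float, r: float
) -> tuple[str, dict[str, str]]:
    """Geometry of one sector as an SVG element: ``(tag, attributes)``.

    Multi-sector pies produce a ``path`` wedge — move to the center, line to
    the arc start, elliptical arc (clockwise sweep; large-arc flag set only
    for spans over 180°) to the arc end, close.  A single-sector pie is the
    full disc and produces a ``circle``.  Angles are degrees clockwise from
    12 o'clock with y growing downward: a point at angle θ sits at
    ``(cx + r·sin θ, cy − r·cos θ)``.
    """
    if arc.n == 1:
        return "circle", {"cx": _fmt(cx), "cy": _fmt(cy), "r": _fmt(r)}
    x1, y1 = _polar(cx, cy, r, arc.start_angle)
    x2, y2 = _polar(cx, cy, r, arc.end_angle)
    large = 1 if arc.span > 180.0 else 0
    d = (
        f"M {_fmt(cx)},{_fmt(cy)} "
        f"L {_fmt(x1)},{_fmt(y1)} "
        f"A {_fmt(r)},{_fmt(r)} 0 {large},1 {_fmt(x2)},{_fmt(y2)} "
        f"Z"
    )
    return "path", {"d": d}


def _attrs(pairs: list[tuple[str, str]]) -> str:
    return "".join(f' {k}="{escape(v)}"' for k, v in pairs)


def _pie_group(pie: Pie, absent_stroke: str) -> list[str]:
    taxon = "key" if pie.is_key else str(pie.taxon_index)
    lines = [
        f'<g id="pie-c{pie.complex_index}-{"key" if pie.is_key else f"t{pie.taxon_index}"}"'
        f' class="pie" data-complex="{pie.complex_index}" data-taxon="{taxon}">'
    ]
    for arc in pie.sectors:
        tag, geo = sector_path_data(arc, pie.cx, pie.cy, pie.radius)
        pairs = [("class", "sector"), ("data-index", str(arc.index))]
        pairs += list(geo.items())
        pairs += [
            ("fill", arc.color),
            ("stroke", absent_stroke),
            ("stroke-width", "0.5"),
        ]
        lines.append(f"  <{tag}{_attrs(pairs)}/>")
    lines.append("</g>")
    return lines


def _text_element(label: Label) -> str:
    pairs = [
        ("class", "label"),
        ("data-role", label.role),
        ("x", _fmt(label.x)),
        ("y", _fmt(label.y)),
        ("font-family", "sans-serif"),
        ("font-size", _fmt(label.font_size)),
        ("fill", label.color),
        ("text-anchor", label.anchor),
    ]
    if label.style == "italic":
        pairs.append(("font-style", "italic"))
    if label.rotation:
        pairs.append(
            ("transform", f"rotate({_fmt(label.rotation)} {_fmt(label.x)} {_fmt(label.y)})")
        )
    return f"<text{_attrs(pairs)}>{escape(label.text)}</text>"


@dataclass(frozen=True)
class SvgDocument:
    """A complete, standalone SVG 1.1 document."""

    text: str
    width: float
    height: float

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.text, encoding="utf-8")


def render_svg(g: PlotGeometry) -> SvgDocument:
    """Serialize a scene to SVG with fully deterministic byte output."""
    w, h = _fmt(g.canvas_width), _fmt(g.canvas_height)
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{w}" height="{h}" viewBox="0 0 {w} {h}">',
        f'<rect class="background" x="0" y="0" width="{w}" height="{h}" fill="#FFFFFF"/>',
    ]
    for pie in g.pies:
        lines.extend(_pie_group(pie, g.config.absent_stroke))
    for label in g.labels:
        lines.append(_text_element(label))
    for label in g.legend:
        lines.append(_text_element(label))
    lines.append("</svg>")
    return SvgDocument(text="\n".join(lines) + "\n", width=g.canvas_width, height=g.canvas_height)


def _find_converter() -> tuple[str, object] | None:
    try:
        import cairosvg  # type: ignore[import-not-found]

        return "cairosvg", cairosvg
    except ImportError:
        pass
    for exe in ("rsvg-convert", "inkscape"):
        path = shutil.which(exe)
        if path:
            return exe, path
    return None


def pdf_converter_available() -> bool:
    return _find_converter() is not None


def convert_to_pdf(doc: SvgDocument, path: str | Path) -> None:
    """Write ``doc`` as a vector PDF by delegating to an installed converter.

    Tries cairosvg, then the rsvg-convert and inkscape executables.  When
    none is available this raises :class:`PdfConversionError` rather than
    silently rasterizing or writing a bogus file.
    """
    found = _find_converter()
    if found is None:
        raise PdfConversionError(
            "no SVG-to-PDF converter available: install the 'cairosvg' Python "
            "package or put 'rsvg-convert' or 'inkscape' on PATH"
        )
    name, handle = found
    path = Path(path)
    if name == "cairosvg":
        handle.svg2pdf(bytestring=doc.text.encode("utf-8"), write_to=str(path))  # type: ignore[union-attr]
        return
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".svg", delete=False) as tmp:
        tmp.write(doc.text)
        svg_path = tmp.name
    try:
        if name == "rsvg-convert":
            cmd = [str(handle), "-f", "pdf", "-o", str(path), svg_path]
        else:
            cmd = [str(handle), svg_path, "--export-type=pdf", f"--export-filename={path}"]
        result = subprocess.run(cmd, capture_output=True, text=True)
        if result.returncode != 0 or not path.exists():
            raise PdfConversionError(
                f"{name} failed (exit {result.returncode}): {result.stderr.strip()}"
            )
    finally:
        Path(svg_path).unlink(missing_ok=True)
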