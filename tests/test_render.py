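"""SVG serialization: determinism, well-formedness, sector path geometry."""

import math
import re

import pytest
from lxml import etree

from coulson.fixtures import FixtureSpec, generate_dataset
from coulson.io_format import DEFAULT_COLOR_SET
from coulson.layout import (
    LayoutConfig,
    SectorArc,
    assign_group_colors,
    count_elements,
    layout_plot,
    sector_geometry,
)
from coulson.render import (
    PdfConversionError,
    SvgDocument,
    convert_to_pdf,
    pdf_converter_available,
    render_svg,
    sector_path_data,
)

SVG_NS = "{http://www.w3.org/2000/svg}"


def _arc(n, index, filled=True, color="#123456"):
    start, end = sector_geometry(n, index)
    return SectorArc(index=index, n=n, start_angle=start, end_angle=end,
                     filled=filled, color=color)


def _scene(seed=1, **spec_kw):
    spec = FixtureSpec(n_groups=2, species_per_group=2, n_complexes=3, seed=seed, **spec_kw)
    ds = generate_dataset(spec)
    return ds, layout_plot(ds, LayoutConfig(), assign_group_colors(ds, DEFAULT_COLOR_SET))


def _parse(doc: SvgDocument):
    return etree.fromstring(doc.text.encode("utf-8"))


def _eval_svg_arc(x1, y1, x2, y2, r, fa, fs, steps=180):
    """Sample an SVG circular arc (rx = ry = r) per its endpoint parameterization."""
    dx, dy = (x1 - x2) / 2.0, (y1 - y2) / 2.0
    num = r * r - dx * dx - dy * dy
    co = math.sqrt(max(num, 0.0) / (dx * dx + dy * dy))
    if fa == fs:
        co = -co
    cx, cy = co * dy + (x1 + x2) / 2.0, -co * dx + (y1 + y2) / 2.0
    th1 = math.atan2(y1 - cy, x1 - cx)
    th2 = math.atan2(y2 - cy, x2 - cx)
    dth = th2 - th1
    if fs == 1 and dth < 0:
        dth += 2 * math.pi
    elif fs == 0 and dth > 0:
        dth -= 2 * math.pi
    return [
        (cx + r * math.cos(th1 + dth * k / steps), cy + r * math.sin(th1 + dth * k / steps))
        for k in range(steps + 1)
    ]


class TestSectorPathData:
    def test_single_sector_is_a_circle(self):
        tag, attrs = sector_path_data(_arc(1, 0), 5.0, 6.0, 10.0)
        assert tag == "circle"
        assert attrs == {"cx": "5.000", "cy": "6.000", "r": "10.000"}

    def test_quadrant_endpoints(self):
        tag, attrs = sector_path_data(_arc(4, 0), 0.0, 0.0, 10.0)
        assert tag == "path"
        assert attrs["d"] == "M 0.000,0.000 L 0.000,-10.000 A 10.000,10.000 0 0,1 10.000,0.000 Z"

    def test_half_disc_uses_small_arc_flag_with_sweep(self):
        _, attrs = sector_path_data(_arc(2, 0), 0.0, 0.0, 8.0)
        m = re.search(r"A [\d.]+,[\d.]+ 0 (\d),(\d)", attrs["d"])
        assert m.group(1) == "0" and m.group(2) == "1"

    def test_large_arc_flag_for_majority_sector(self):
        # a 240-degree sector (n=3 pie missing one sector span) via a custom arc
        arc = SectorArc(index=0, n=2, start_angle=0.0, end_angle=240.0,
                        filled=True, color="#000000")
        _, attrs = sector_path_data(arc, 0.0, 0.0, 8.0)
        assert re.search(r"A [\d.]+,[\d.]+ 0 1,1", attrs["d"])

    @pytest.mark.parametrize("n", [2, 3, 4, 6, 12])
    def test_endpoints_match_trigonometric_oracle(self, n):
        # independent formulation: clock angle t -> standard polar angle 90 - t
        cx, cy, r = 3.0, -2.0, 7.0
        for index in range(n):
            arc = _arc(n, index)
            _, attrs = sector_path_data(arc, cx, cy, r)
            nums = re.findall(r"-?\d+\.\d+", attrs["d"])
            x1, y1, x2, y2 = float(nums[2]), float(nums[3]), float(nums[6]), float(nums[7])
            for angle, (x, y) in [(arc.start_angle, (x1, y1)), (arc.end_angle, (x2, y2))]:
                phi = math.radians(90.0 - angle)
                assert x == pytest.approx(cx + r * math.cos(phi), abs=1e-3)
                assert y == pytest.approx(cy - r * math.sin(phi), abs=1e-3)

    def test_half_disc_path_traces_half_the_disc(self):
        # evaluate the emitted path with an independent arc interpreter
        # (endpoint parameterization -> center, then sample the sweep);
        # the enclosed area must be half the disc within 2% and the arc's
        # midpoint must sit at 3 o'clock, proving the sweep goes clockwise
        r = 10.0
        _, attrs = sector_path_data(_arc(2, 0), 0.0, 0.0, r)
        m = re.match(
            r"M (\S+),(\S+) L (\S+),(\S+) A (\S+),(\S+) 0 (\d),(\d) (\S+),(\S+) Z",
            attrs["d"],
        )
        cx0, cy0, x1, y1, ar, _, fa, fs, x2, y2 = (float(v) for v in m.groups())
        pts = [(cx0, cy0), (x1, y1)] + _eval_svg_arc(x1, y1, x2, y2, ar, int(fa), int(fs))
        area = 0.5 * abs(sum(
            pts[i][0] * pts[(i + 1) % len(pts)][1] - pts[(i + 1) % len(pts)][0] * pts[i][1]
            for i in range(len(pts))
        ))
        assert area == pytest.approx(math.pi * r * r / 2, rel=0.02)
        mid = pts[2 + 90]  # halfway along the 180-sample sweep
        assert mid == pytest.approx((r, 0.0), abs=1e-6)  # 3 o'clock, y-down


class TestRenderSvg:
    def test_byte_identical_across_runs(self):
        _, g = _scene()
        assert render_svg(g).text == render_svg(g).text

    def test_well_formed_xml_single_root(self):
        _, g = _scene()
        root = _parse(render_svg(g))
        assert root.tag == f"{SVG_NS}svg"
        assert root.get("width") and root.get("height")

    def test_canvas_attributes_match_geometry(self):
        _, g = _scene()
        doc = render_svg(g)
        root = _parse(doc)
        assert float(root.get("width")) == pytest.approx(g.canvas_width, abs=1e-3)
        assert float(root.get("height")) == pytest.approx(g.canvas_height, abs=1e-3)

    def test_element_conservation(self):
        _, g = _scene(seed=7)
        counts = count_elements(g)
        root = _parse(render_svg(g))
        pies = root.findall(f"{SVG_NS}g[@class='pie']")
        assert len(pies) == counts.pies
        sectors = [el for p in pies for el in p if el.get("class") == "sector"]
        assert len(sectors) == counts.sectors
        labels = root.findall(f"{SVG_NS}text[@class='label']")
        assert len(labels) == counts.labels

    def test_pies_carry_stable_role_attributes(self):
        ds, g = _scene()
        root = _parse(render_svg(g))
        pies = root.findall(f"{SVG_NS}g[@class='pie']")
        key = [p for p in pies if p.get("data-taxon") == "key"]
        data = [p for p in pies if p.get("data-taxon") != "key"]
        assert len(key) == ds.n_complexes
        assert len(data) == ds.n_complexes * ds.n_taxa
        assert all(p.get("id") for p in pies)
        assert len({p.get("id") for p in pies}) == len(pies)

    def test_absent_sectors_stroked(self):
        ds, g = _scene(presence_prob=0.0)
        root = _parse(render_svg(g))
        for p in root.findall(f"{SVG_NS}g[@class='pie']"):
            if p.get("data-taxon") == "key":
                continue
            for el in p:
                assert el.get("fill") == g.config.absent_fill
                assert el.get("stroke") == g.config.absent_stroke
                assert el.get("stroke-width") == "0.5"

    def test_text_nodes_carry_font_and_fill(self):
        _, g = _scene()
        root = _parse(render_svg(g))
        for el in root.findall(f"{SVG_NS}text"):
            assert el.get("font-size") and el.get("fill")
            assert el.get("font-family") == "sans-serif"


class TestPdfConversion:
    def test_contract(self, tmp_path):
        _, g = _scene()
        doc = render_svg(g)
        out = tmp_path / "plot.pdf"
        if pdf_converter_available():
            convert_to_pdf(doc, out)
            data = out.read_bytes()
            assert data.startswith(b"%PDF") and len(data) > 0
        else:
            with pytest.raises(PdfConversionError, match="converter"):
                convert_to_pdf(doc, out)
            assert not out.exists()
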