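"""SVG serialization, ribbon/tick/feature primitive construction, PNG export.

Ribbon styles
-------------
Style 1 is a straight quadrilateral through the four anchors. Styles 2-5
replace the two cross-track sides with cubic Bezier curves whose control
points sit directly above/below the anchors, offset vertically by
``f · height_ratio · default_height``:

===== ==================== =========================================
style (f at A-end, B-end)  shape
===== ==================== =========================================
2     (0.5, 0.5)           symmetric S-curve (the classic ribbon)
3     (0.25, 0.25)         taut curve, close to the chord
4     (0.75, 0.75)         deep sag: offsets point *outward* from each
                           anchor's edge, giving the wrap-around look
                           for DownDown links between stacked genomes
5     (0.8, 0.2)           asymmetric curve, strongly bent at the A end
===== ==================== =========================================

For styles 2, 3 and 5 the offset at each anchor points vertically toward
the other track; for style 4 it points away from the anchor's chromosome
edge ("up" edge -> upward, "down" edge -> downward).

SVG output uses 3-decimal fixed precision so identical scenes serialize to
identical bytes.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from typing import TYPE_CHECKING

from .errors import RenderError
from .io_formats import FeatureRecord
from .scene import (GroupPrim, LinePrim, PathPrim, Primitive, RectPrim,
                    RibbonPath, SceneGraph, TextPrim)

if TYPE_CHECKING:  # layout imports render; type-only import avoids the cycle
    from .config import GenomeParams
    from .layout import ChromRect, RibbonAnchors

__all__ = [
    "FEATURE_COLOR_TABLE",
    "build_ribbon_path",
    "build_axis_ticks",
    "build_feature_glyph",
    "nice_tick_step",
    "render_svg",
    "rasterize_png",
    "SVG_ELEMENT_WHITELIST",
]

#: default fill per feature type; a record's own ``fill`` attr overrides
FEATURE_COLOR_TABLE: dict[str, str] = {
    "cds": "#e41a1c",
    "utr": "#377eb8",
    "te": "#4daf4a",
    "snp": "#984ea3",
    "gene": "#ff7f00",
}

# (f_a, f_b, outward?) per style; see module docstring
_STYLE_PROFILES: dict[int, tuple[float, float, bool]] = {
    2: (0.5, 0.5, False),
    3: (0.25, 0.25, False),
    4: (0.75, 0.75, True),
    5: (0.8, 0.2, False),
}


def build_ribbon_path(
    anchors: "RibbonAnchors", style: int, height_ratio: float,
    default_height: float,
) -> RibbonPath:
    """Build the closed ribbon a_start→a_end→b_end→b_start→close.

    Path endpoints coincide with the anchors exactly; doubling
    ``height_ratio`` doubles every control-point offset, and offsets vanish
    as ``height_ratio`` → 0 (the curve degenerates to the straight quad).
    """
    if style not in (1, 2, 3, 4, 5):
        raise RenderError(f"link style must be in 1..5, got {style}")
    a0, a1 = anchors.a_start, anchors.a_end
    b0, b1 = anchors.b_start, anchors.b_end

    cmds: list[tuple] = [("M", *a0), ("L", *a1)]
    if style == 1:
        cmds.append(("L", *b1))
        cmds.append(("L", *b0))
    else:
        f_a, f_b, outward = _STYLE_PROFILES[style]
        h = height_ratio * default_height

        def offset_dir(p_self, p_other, edge_self: str) -> float:
            if outward:
                return 1.0 if edge_self == "down" else -1.0
            dy = p_other[1] - p_self[1]
            return math.copysign(1.0, dy) if dy != 0 else 1.0

        # side a_end -> b_end
        d1 = offset_dir(a1, b1, anchors.edge_a)
        d2 = offset_dir(b1, a1, anchors.edge_b)
        c1 = (a1[0], a1[1] + f_a * h * d1)
        c2 = (b1[0], b1[1] + f_b * h * d2)
        cmds.append(("C", *c1, *c2, *b1))
        cmds.append(("L", *b0))
        # side b_start -> a_start (mirror factors so the band has parallel rails)
        d3 = offset_dir(b0, a0, anchors.edge_b)
        d4 = offset_dir(a0, b0, anchors.edge_a)
        c3 = (b0[0], b0[1] + f_b * h * d3)
        c4 = (a0[0], a0[1] + f_a * h * d4)
        cmds.append(("C", *c3, *c4, *a0))
    cmds.append(("Z",))
    return RibbonPath(commands=cmds, link_style=style)


def nice_tick_step(window: tuple[int, int], max_ticks: int = 8) -> int:
    """Smallest 1/2/5·10^k step whose multiples inside the window number <= max_ticks."""
    ws, we = window
    span = max(we - ws, 1)
    k = 0
    while True:
        for mant in (1, 2, 5):
            step = mant * 10 ** k
            count = we // step - (ws + step - 1) // step + 1
            if count <= max_ticks:
                return step
        k += 1
        if 10 ** k > span * 10:  # pragma: no cover - unreachable guard
            return span


def _tick_label(pos: int, step: int) -> str:
    if step >= 1_000_000:
        unit, div = "Mb", 1_000_000
    elif step >= 1_000:
        unit, div = "kb", 1_000
    else:
        unit, div = "bp", 1
    val = pos / div
    text = f"{val:g}"
    return f"{text} {unit}"


def build_axis_ticks(rect: "ChromRect", show_coordinates: bool) -> GroupPrim | None:
    """Major ticks at nice bp intervals below the chromosome rect.

    Returns ``None`` when coordinates are disabled or no tick fits.
    """
    if not show_coordinates:
        return None
    ws, we = rect.bp_window
    step = nice_tick_step((ws, we))
    first = ((ws + step - 1) // step) * step
    children: list[Primitive] = []
    y_base = rect.y0 + rect.height
    pos = first
    i = 0
    while pos <= we:
        x = rect.bp_to_x(pos)
        children.append(LinePrim(
            style={"stroke": "black", "stroke-width": "0.6"},
            x1=x, y1=y_base, x2=x, y2=y_base + 4.0))
        children.append(TextPrim(
            style={"fill": "black",
                   "font-family": "Helvetica, Arial, sans-serif"},
            x=x, y=y_base + 13.0, text=_tick_label(pos, step),
            anchor="middle", font_size=7.0))
        pos += step
        i += 1
    if not children:
        return None
    return GroupPrim(children=children)


def build_feature_glyph(
    feat: FeatureRecord, rect: "ChromRect", params: "GenomeParams"
) -> RectPrim:
    """Rectangle over the feature's bp span, vertically centered on the rect.

    Height is ``chr_height × spe_region_width_ratio``; feature-type default
    colors apply unless the record carries its own ``fill``.
    """
    ws, we = rect.bp_window
    s, e = max(feat.start, ws), min(feat.end, we)
    glyph_h = params.chr_height * params.spe_region_width_ratio
    y = rect.y0 + rect.height / 2.0 - glyph_h / 2.0
    ftype = (feat.feature_type or "").lower()
    fill = feat.attrs.get("fill") or FEATURE_COLOR_TABLE.get(ftype, "#7f7f7f")
    x0 = rect.bp_to_x(s)
    x1 = rect.bp_to_x(e)
    if x1 <= x0:  # single-bp features still get a visible sliver
        x1 = x0 + 0.5
    return RectPrim(style={"fill": fill,
                           "stroke": feat.attrs.get("stroke") or "none"},
                    x=x0, y=y, width=x1 - x0, height=glyph_h)


# ---------------------------------------------------------------------------
# SVG serialization

SVG_NS = "http://www.w3.org/2000/svg"
SVG_ELEMENT_WHITELIST = {"svg", "g", "rect", "path", "line", "text"}


def _fmt(x: float) -> str:
    if x == 0:
        x = 0.0  # normalize -0.0
    s = f"{x:.3f}".rstrip("0").rstrip(".")
    return s if s else "0"


def _transform_attr(prim: Primitive) -> str | None:
    t = prim.transform
    if t is None or t.is_identity():
        return None
    return "matrix(" + " ".join(_fmt(c) for c in t.coefficients()) + ")"


def _path_d(commands: list[tuple]) -> str:
    parts: list[str] = []
    for cmd in commands:
        op = cmd[0]
        if op == "Z":
            parts.append("Z")
        else:
            parts.append(op + " " + " ".join(_fmt(v) for v in cmd[1:]))
    return " ".join(parts)


def _emit(parent: ET.Element, prim: Primitive) -> None:
    common: dict[str, str] = {}
    if prim.id:
        common["id"] = prim.id
    tr = _transform_attr(prim)
    if tr:
        common["transform"] = tr

    if isinstance(prim, GroupPrim):
        el = ET.SubElement(parent, "g", {**common, **prim.style})
        for child in prim.children:
            _emit(el, child)
        return
    if isinstance(prim, RectPrim):
        attrs = {"x": _fmt(prim.x), "y": _fmt(prim.y),
                 "width": _fmt(prim.width), "height": _fmt(prim.height)}
        if prim.rx:
            attrs["rx"] = _fmt(prim.rx)
        ET.SubElement(parent, "rect", {**common, **attrs, **prim.style})
        return
    if isinstance(prim, LinePrim):
        attrs = {"x1": _fmt(prim.x1), "y1": _fmt(prim.y1),
                 "x2": _fmt(prim.x2), "y2": _fmt(prim.y2)}
        ET.SubElement(parent, "line", {**common, **attrs, **prim.style})
        return
    if isinstance(prim, TextPrim):
        attrs = {"x": _fmt(prim.x), "y": _fmt(prim.y),
                 "text-anchor": prim.anchor,
                 "font-size": _fmt(prim.font_size)}
        el = ET.SubElement(parent, "text", {**common, **attrs, **prim.style})
        el.text = prim.text
        return
    if isinstance(prim, PathPrim):
        ET.SubElement(parent, "path",
                      {**common, "d": _path_d(prim.commands), **prim.style})
        return
    raise RenderError(f"unknown primitive type {type(prim).__name__}")


def render_svg(scene: SceneGraph) -> str:
    """Serialize a scene to SVG 1.1 text (deterministic bytes)."""
    for x in (scene.width, scene.height, scene.view_min_x, scene.view_min_y):
        if not math.isfinite(x):
            raise RenderError("non-finite canvas geometry")
    root = ET.Element("svg", {
        "xmlns": SVG_NS,
        "version": "1.1",
        "width": _fmt(scene.width),
        "height": _fmt(scene.height),
        "viewBox": " ".join(_fmt(v) for v in
                            (scene.view_min_x, scene.view_min_y,
                             scene.width, scene.height)),
    })
    for layer_name in scene.layers:
        prims = scene.layers[layer_name]
        if not prims:
            continue
        g = ET.SubElement(root, "g", {"id": f"layer-{layer_name}"})
        for prim in prims:
            _emit(g, prim)
    body = ET.tostring(root, encoding="unicode")
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + body + "\n"


def rasterize_png(svg_text: str, dpi: float = 96.0) -> bytes:
    """Rasterize SVG text to PNG at ``canvas_size × dpi/96`` pixels.

    Requires the optional ``cairosvg`` backend; without it a
    :class:`RenderError` is raised (the SVG output is unaffected).
    """
    try:
        import cairosvg  # type: ignore[import-not-found]
    except ImportError as exc:
        raise RenderError(
            "PNG output requires the optional 'cairosvg' backend "
            "(pip install multisyn[png]); SVG output is unaffected") from exc
    try:
        return cairosvg.svg2png(bytestring=svg_text.encode("utf-8"),
                                scale=dpi / 96.0)
    except Exception as exc:
        raise RenderError(f"PNG rasterization failed: {exc}") from exc
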