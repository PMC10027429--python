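"""Renderable scene primitives shared by the layout and render stages.

All coordinates are canvas units (y grows downward, SVG convention). A
primitive either stores absolute coordinates (ribbons) or local coordinates
plus an affine ``transform`` (track-attached rects, ticks, labels).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

__all__ = [
    "Affine",
    "Primitive",
    "RectPrim",
    "LinePrim",
    "TextPrim",
    "PathPrim",
    "RibbonPath",
    "GroupPrim",
    "SceneGraph",
]


@dataclass(frozen=True)
class Affine:
    """2x3 affine transform mapping (x, y) -> (a·x + c·y + e, b·x + d·y + f).

    Coefficient order matches the SVG ``matrix(a b c d e f)`` convention.
    """

    a: float = 1.0
    b: float = 0.0
    c: float = 0.0
    d: float = 1.0
    e: float = 0.0
    f: float = 0.0

    @staticmethod
    def identity() -> "Affine":
        return Affine()

    @staticmethod
    def translation(tx: float, ty: float) -> "Affine":
        return Affine(1.0, 0.0, 0.0, 1.0, tx, ty)

    @staticmethod
    def rotation_deg(angle: float) -> "Affine":
        """Counter-clockwise rotation (in the y-down frame) about the origin."""
        rad = math.radians(angle)
        ca, sa = math.cos(rad), math.sin(rad)
        return Affine(ca, sa, -sa, ca, 0.0, 0.0)

    @staticmethod
    def scaling(s: float) -> "Affine":
        return Affine(s, 0.0, 0.0, s, 0.0, 0.0)

    def __matmul__(self, other: "Affine") -> "Affine":
        """Compose: (self @ other)(p) == self(other(p))."""
        return Affine(
            a=self.a * other.a + self.c * other.b,
            b=self.b * other.a + self.d * other.b,
            c=self.a * other.c + self.c * other.d,
            d=self.b * other.c + self.d * other.d,
            e=self.a * other.e + self.c * other.f + self.e,
            f=self.b * other.e + self.d * other.f + self.f,
        )

    def apply(self, x: float, y: float) -> tuple[float, float]:
        return (self.a * x + self.c * y + self.e,
                self.b * x + self.d * y + self.f)

    @property
    def det(self) -> float:
        return self.a * self.d - self.b * self.c

    def is_identity(self, tol: float = 0.0) -> bool:
        return (abs(self.a - 1) <= tol and abs(self.b) <= tol and
                abs(self.c) <= tol and abs(self.d - 1) <= tol and
                abs(self.e) <= tol and abs(self.f) <= tol)

    def coefficients(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.d, self.e, self.f)


@dataclass
class Primitive:
    id: str = ""
    style: dict[str, str] = field(default_factory=dict)
    transform: Affine | None = None

    def corners(self) -> list[tuple[float, float]]:
        """Representative points in *absolute* canvas coordinates (for bbox)."""
        t = self.transform or Affine.identity()
        return [t.apply(x, y) for x, y in self._local_points()]

    def _local_points(self) -> list[tuple[float, float]]:  # pragma: no cover
        return []


@dataclass
class RectPrim(Primitive):
    x: float = 0.0
    y: float = 0.0
    width: float = 0.0
    height: float = 0.0
    rx: float = 0.0

    def _local_points(self) -> list[tuple[float, float]]:
        return [(self.x, self.y), (self.x + self.width, self.y),
                (self.x, self.y + self.height),
                (self.x + self.width, self.y + self.height)]


@dataclass
class LinePrim(Primitive):
    x1: float = 0.0
    y1: float = 0.0
    x2: float = 0.0
    y2: float = 0.0

    def _local_points(self) -> list[tuple[float, float]]:
        return [(self.x1, self.y1), (self.x2, self.y2)]


@dataclass
class TextPrim(Primitive):
    x: float = 0.0
    y: float = 0.0
    text: str = ""
    anchor: str = "start"  # start | middle | end
    font_size: float = 10.0

    def _local_points(self) -> list[tuple[float, float]]:
        return [(self.x, self.y)]


@dataclass
class PathPrim(Primitive):
    """Generic path: commands are ("M"|"L", x, y), ("C", x1,y1,x2,y2,x,y), ("Z",)."""

    commands: list[tuple] = field(default_factory=list)

    def _local_points(self) -> list[tuple[float, float]]:
        pts: list[tuple[float, float]] = []
        for cmd in self.commands:
            op = cmd[0]
            if op in ("M", "L"):
                pts.append((cmd[1], cmd[2]))
            elif op == "C":
                pts.extend([(cmd[1], cmd[2]), (cmd[3], cmd[4]), (cmd[5], cmd[6])])
        return pts

    def endpoints(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """First moveto point and final on-curve point before close."""
        first = last = None
        for cmd in self.commands:
            if cmd[0] == "M":
                if first is None:
                    first = (cmd[1], cmd[2])
                last = (cmd[1], cmd[2])
            elif cmd[0] == "L":
                last = (cmd[1], cmd[2])
            elif cmd[0] == "C":
                last = (cmd[5], cmd[6])
        if first is None or last is None:
            raise ValueError("empty path")
        return first, last


@dataclass
class RibbonPath(PathPrim):
    """A closed link ribbon (style 1 = straight quad, 2-5 = Bezier sides)."""

    link_style: int = 1

    def control_points(self) -> list[tuple[float, float]]:
        pts = []
        for cmd in self.commands:
            if cmd[0] == "C":
                pts.extend([(cmd[1], cmd[2]), (cmd[3], cmd[4])])
        return pts


@dataclass
class GroupPrim(Primitive):
    children: list[Primitive] = field(default_factory=list)

    def corners(self) -> list[tuple[float, float]]:
        t = self.transform or Affine.identity()
        pts: list[tuple[float, float]] = []
        for child in self.children:
            ct = child.transform or Affine.identity()
            for x, y in child._local_points():
                pts.append(t.apply(*ct.apply(x, y)))
        return pts


LAYER_ORDER = ("ribbons", "rects", "features", "axes", "labels")


@dataclass
class SceneGraph:
    """Layered renderable scene with a fixed layer order."""

    width: float = 0.0
    height: float = 0.0
    view_min_x: float = 0.0
    view_min_y: float = 0.0
    layers: dict[str, list[Primitive]] = field(
        default_factory=lambda: {name: [] for name in LAYER_ORDER})

    def add(self, layer: str, prim: Primitive) -> None:
        self.layers[layer].append(prim)

    def iter_primitives(self) -> Iterator[tuple[str, Primitive]]:
        for name in LAYER_ORDER:
            for prim in self.layers[name]:
                yield name, prim

    def all_ids(self) -> list[str]:
        ids: list[str] = []

        def walk(p: Primitive) -> None:
            ids.append(p.id)
            if isinstance(p, GroupPrim):
                for ch in p.children:
                    walk(ch)

        for _, prim in self.iter_primitives():
            walk(prim)
        return ids

    def finalize(self, padding: float = 40.0) -> None:
        """Compute the canvas viewBox from primitive extents."""
        xs: list[float] = []
        ys: list[float] = []
        for _, prim in self.iter_primitives():
            for x, y in prim.corners():
                xs.append(x)
                ys.append(y)
        if not xs:
            self.view_min_x = self.view_min_y = 0.0
            self.width = self.height = 2 * padding
            return
        self.view_min_x = min(xs) - padding
        self.view_min_y = min(ys) - padding
        self.width = (max(xs) - min(xs)) + 2 * padding
        self.height = (max(ys) - min(ys)) + 2 * padding

    # -- JSON serialization (--dump-scene) ---------------------------------

    def to_json(self) -> str:
        def prim_dict(p: Primitive) -> dict:
            d: dict = {"kind": type(p).__name__, "id": p.id, "style": p.style}
            if p.transform is not None and not p.transform.is_identity():
                d["transform"] = list(p.transform.coefficients())
            if isinstance(p, RectPrim):
                d.update(x=p.x, y=p.y, width=p.width, height=p.height, rx=p.rx)
            elif isinstance(p, LinePrim):
                d.update(x1=p.x1, y1=p.y1, x2=p.x2, y2=p.y2)
            elif isinstance(p, TextPrim):
                d.update(x=p.x, y=p.y, text=p.text, anchor=p.anchor,
                         font_size=p.font_size)
            elif isinstance(p, PathPrim):
                d["commands"] = [list(c) for c in p.commands]
                if isinstance(p, RibbonPath):
                    d["link_style"] = p.link_style
            if isinstance(p, GroupPrim):
                d["children"] = [prim_dict(ch) for ch in p.children]
            return d

        doc = {
            "width": self.width,
            "height": self.height,
            "view_min_x": self.view_min_x,
            "view_min_y": self.view_min_y,
            "layers": {name: [prim_dict(p) for p in self.layers[name]]
                       for name in LAYER_ORDER},
        }
        return json.dumps(doc, indent=1, sort_keys=True)


def bounding_box(points: Sequence[tuple[float, float]]) -> tuple[float, float, float, float]:
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    return min(xs), min(ys), max(xs), max(ys)
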