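"""Canvas geometry: genome tracks, bp→canvas mapping, clipping, ribbon anchors.

A track is laid out in a local frame whose origin is the left end of its
first chromosome baseline (y = 0 is the top edge of the chromosome
rectangles). The track transform is

    translation(move_to_x, move_to_y) ∘ rotation(rotate_chr) ∘ scale(zoom_chr)

applied about that local origin, so rotation and zoom compose predictably
with explicit placement. When ``move_to_y`` is unset, genomes stack
top-to-bottom in declaration order at a uniform slot pitch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .config import (ConfigModel, GenomeParams, LinkParams,
                     effective_link_params, resolve_genome_params,
                     resolve_link_params)
from .errors import LayoutError
from .io_formats import (FeatureRecord, GenomeDef, LinkRecord, Orientation,
                         read_feature_file, read_genome_file, read_link_file)
from .render import build_axis_ticks, build_feature_glyph, build_ribbon_path
from .scene import Affine, RectPrim, SceneGraph, TextPrim

logger = logging.getLogger("multisyn")

__all__ = [
    "DEFAULT_TRACK_WIDTH",
    "DEFAULT_SLOT_PITCH",
    "ChromRect",
    "GenomeTrack",
    "RibbonAnchors",
    "PlotData",
    "build_track",
    "bp_to_canvas",
    "clip_links_to_windows",
    "compute_ribbon_anchors",
    "load_plot_data",
    "layout_scene",
]

#: local-frame baseline width every genome is scaled into by default
DEFAULT_TRACK_WIDTH = 1000.0
#: vertical distance between stacked genome slots (canvas units)
DEFAULT_SLOT_PITCH = 140.0
_TOP_MARGIN = 40.0


@dataclass(frozen=True)
class ChromRect:
    """One chromosome's rectangle on the track baseline (pre-transform)."""

    seq_id: str
    x0: float
    x1: float
    y0: float
    height: float
    bp_window: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.x0 < self.x1:
            raise LayoutError(f"{self.seq_id}: degenerate rect (x0 >= x1)")
        ws, we = self.bp_window
        if ws >= we:
            raise LayoutError(f"{self.seq_id}: degenerate bp window {ws}..{we}")

    def bp_to_x(self, pos: float) -> float:
        ws, we = self.bp_window
        return self.x0 + (pos - ws) / (we - ws) * (self.x1 - self.x0)


@dataclass
class GenomeTrack:
    """Resolved geometry of one genome: rects + transform + parameters."""

    genome_index: int
    genome: GenomeDef
    rects: list[ChromRect]
    transform: Affine
    params: GenomeParams
    slot_y: float

    def rect_for(self, seq_id: str) -> ChromRect:
        for r in self.rects:
            if r.seq_id == seq_id:
                return r
        raise LayoutError(
            f"sequence {seq_id!r} not present in genome {self.genome.name!r} track")

    def __contains__(self, seq_id: str) -> bool:
        return any(r.seq_id == seq_id for r in self.rects)

    @property
    def baseline_width(self) -> float:
        return self.rects[-1].x1 if self.rects else 0.0


def _track_transform(params: GenomeParams, default_slot_y: float) -> Affine:
    ty = params.move_to_y if params.move_to_y is not None else default_slot_y
    return (Affine.translation(params.move_to_x, ty)
            @ Affine.rotation_deg(params.rotate_chr % 360.0)
            @ Affine.scaling(params.zoom_chr))


def build_track(
    genome: GenomeDef,
    params: GenomeParams,
    default_slot_y: float,
    *,
    genome_index: int = 1,
    px_per_bp: float | None = None,
) -> GenomeTrack:
    """Place a genome's chromosomes on a local baseline and build its transform.

    Chromosomes keep file order, separated by ``chr_spacing`` gaps, with one
    uniform bp→x scale across the track. If ``zoom_region`` is set, only
    that chromosome's slice is placed. *px_per_bp* fixes the scale (used by
    :func:`layout_scene` to share one scale across genomes); by default the
    track is scaled into :data:`DEFAULT_TRACK_WIDTH`.
    """
    if not genome.chroms:
        raise LayoutError(f"genome {genome.name!r} is empty")

    windows: list[tuple[str, int, int]] = []
    if params.zoom_region is not None:
        zr = params.zoom_region
        if zr.seq_id not in genome:
            raise LayoutError(
                f"zoom_region sequence {zr.seq_id!r} absent from genome "
                f"{genome.name!r}")
        chrom = genome.chrom(zr.seq_id)
        ws = max(zr.start, chrom.start)
        we = min(zr.end, chrom.end)
        if ws >= we:
            raise LayoutError(
                f"zoom_region {zr.seq_id}:{zr.start}:{zr.end} does not overlap "
                f"chromosome extent {chrom.start}..{chrom.end}")
        windows.append((zr.seq_id, ws, we))
    else:
        for chrom in genome.chroms:
            if chrom.start >= chrom.end:
                raise LayoutError(
                    f"chromosome {chrom.seq_id!r} has zero bp extent")
            windows.append((chrom.seq_id, chrom.start, chrom.end))

    total_bp = sum(we - ws for _, ws, we in windows)
    if px_per_bp is None:
        gaps = params.chr_spacing * (len(windows) - 1)
        px_per_bp = max(DEFAULT_TRACK_WIDTH - gaps, 1.0) / total_bp

    rects: list[ChromRect] = []
    cursor = 0.0
    for seq_id, ws, we in windows:
        width = (we - ws) * px_per_bp
        rects.append(ChromRect(seq_id, cursor, cursor + width, 0.0,
                               params.chr_height, (ws, we)))
        cursor += width + params.chr_spacing

    return GenomeTrack(
        genome_index=genome_index,
        genome=genome,
        rects=rects,
        transform=_track_transform(params, default_slot_y),
        params=params,
        slot_y=default_slot_y,
    )


def bp_to_canvas(
    track: GenomeTrack, seq_id: str, pos: float, edge: str = "up"
) -> tuple[float, float]:
    """Map a base-pair position to canvas coordinates on a chromosome edge.

    ``edge`` is ``"up"`` (top, smaller local y), ``"down"`` (bottom) or
    ``"mid"``. The window start maps to the rect's left edge and the window
    end to its right edge; the result includes the track transform.
    """
    rect = track.rect_for(seq_id)
    ws, we = rect.bp_window
    if pos < ws or pos > we:
        raise LayoutError(
            f"position {seq_id}:{pos} outside rendered window {ws}..{we}")
    x = rect.bp_to_x(pos)
    if edge == "up":
        y = rect.y0
    elif edge == "down":
        y = rect.y0 + rect.height
    elif edge == "mid":
        y = rect.y0 + rect.height / 2.0
    else:
        raise ValueError(f"edge must be up/down/mid, got {edge!r}")
    return track.transform.apply(x, y)


# ---------------------------------------------------------------------------
# clipping

def _clip_side(
    s: int, e: int, window: tuple[int, int]
) -> tuple[int, int, float, float] | None:
    """Clip [s, e] to window; return (s', e', frac_lo, frac_hi) or None."""
    ws, we = window
    if e < ws or s > we:
        return None
    s2, e2 = max(s, ws), min(e, we)
    span = e - s
    if span == 0:
        return s2, e2, 0.0, 1.0
    return s2, e2, (s2 - s) / span, (e2 - s) / span


def _rescale_partner(
    s: int, e: int, frac_lo: float, frac_hi: float, inverted: bool
) -> tuple[int, int]:
    """Shrink the partner interval to the kept fraction, matching ends.

    For an inverted link the low end of one side corresponds to the high end
    of the other, so the fractions are mirrored.
    """
    span = e - s
    if inverted:
        lo, hi = 1.0 - frac_hi, 1.0 - frac_lo
    else:
        lo, hi = frac_lo, frac_hi
    s2 = s + int(round(lo * span))
    e2 = s + int(round(hi * span))
    if e2 < s2:  # guard rounding collapse on tiny intervals
        e2 = s2
    return s2, e2


def clip_links_to_windows(
    links: list[LinkRecord], track_a: GenomeTrack, track_b: GenomeTrack
) -> list[tuple[LinkRecord, bool]]:
    """Clip links to both tracks' rendered windows.

    Returns one ``(record, dropped)`` pair per input link, in order. Links
    whose sequence or interval falls wholly outside either window are
    dropped; partial overlaps are clipped with the partner interval rescaled
    proportionally on the matching ends. kept + dropped == len(links).
    """
    out: list[tuple[LinkRecord, bool]] = []
    kept = clipped = dropped = 0
    for lk in links:
        if lk.seq_a not in track_a or lk.seq_b not in track_b:
            out.append((lk, True))
            dropped += 1
            continue
        win_a = track_a.rect_for(lk.seq_a).bp_window
        win_b = track_b.rect_for(lk.seq_b).bp_window
        inv = lk.inverted

        ca = _clip_side(lk.start_a, lk.end_a, win_a)
        if ca is None:
            out.append((lk, True))
            dropped += 1
            continue
        sa, ea, lo_a, hi_a = ca
        sb, eb = _rescale_partner(lk.start_b, lk.end_b, lo_a, hi_a, inv)

        cb = _clip_side(sb, eb, win_b)
        if cb is None:
            out.append((lk, True))
            dropped += 1
            continue
        sb2, eb2, lo_b, hi_b = cb
        sa2, ea2 = _rescale_partner(sa, ea, lo_b, hi_b, inv)
        sa2, ea2 = max(sa2, win_a[0]), min(ea2, win_a[1])

        changed = (sa2, ea2, sb2, eb2) != (lk.start_a, lk.end_a, lk.start_b, lk.end_b)
        rec = lk if not changed else LinkRecord(
            lk.seq_a, sa2, ea2, lk.seq_b, sb2, eb2, lk.orientation, lk.attrs)
        out.append((rec, False))
        kept += 1
        clipped += int(changed)
    logger.info("links: %d kept (%d clipped), %d dropped of %d",
                kept, clipped, dropped, len(links))
    return out


# ---------------------------------------------------------------------------
# ribbon anchors

@dataclass(frozen=True)
class RibbonAnchors:
    """Four canvas points where a ribbon meets the two chromosome edges."""

    a_start: tuple[float, float]
    a_end: tuple[float, float]
    b_start: tuple[float, float]
    b_end: tuple[float, float]
    edge_a: str  # "up" | "down"
    edge_b: str


def _edges_from_style(style_up_down: str) -> tuple[str, str]:
    # first token -> genome A edge, second -> genome B edge
    mapping = {"UpUp": ("up", "up"), "UpDown": ("up", "down"),
               "DownUp": ("down", "up"), "DownDown": ("down", "down")}
    return mapping[style_up_down]


def compute_ribbon_anchors(
    link: LinkRecord,
    track_a: GenomeTrack,
    track_b: GenomeTrack,
    link_params: LinkParams,
) -> RibbonAnchors:
    """Anchor a (possibly inverted) link on the edges chosen by StyleUpDown.

    "Up" always means the top edge of that genome's rectangles regardless of
    relative genome position. Inverted links swap b_start/b_end so the
    ribbon self-crosses.
    """
    edge_a, edge_b = _edges_from_style(link_params.style_up_down)
    a_start = bp_to_canvas(track_a, link.seq_a, link.start_a, edge_a)
    a_end = bp_to_canvas(track_a, link.seq_a, link.end_a, edge_a)
    b_lo = bp_to_canvas(track_b, link.seq_b, link.start_b, edge_b)
    b_hi = bp_to_canvas(track_b, link.seq_b, link.end_b, edge_b)
    if link.orientation is Orientation.INVERTED:
        b_start, b_end = b_hi, b_lo
    else:
        b_start, b_end = b_lo, b_hi
    return RibbonAnchors(a_start, a_end, b_start, b_end, edge_a, edge_b)


# ---------------------------------------------------------------------------
# whole-scene assembly

@dataclass
class PlotData:
    """Parsed inputs referenced by a configuration."""

    genomes: list[GenomeDef]
    features: list[list[FeatureRecord]]  # parallel to genomes
    links: list[list[LinkRecord]]  # parallel to model.link_entries


def load_plot_data(model: ConfigModel) -> PlotData:
    """Read every file referenced by the configuration, aggregating errors."""
    errors: list[str] = []
    genomes: list[GenomeDef] = []
    features: list[list[FeatureRecord]] = []
    links: list[list[LinkRecord]] = []
    for path, feat_paths in model.genome_entries:
        try:
            genomes.append(read_genome_file(model.resolve_path(path)))
        except Exception as exc:
            errors.append(str(exc))
            genomes.append(GenomeDef("?", []))
        feats: list[FeatureRecord] = []
        for fp in feat_paths:
            try:
                feats.extend(read_feature_file(model.resolve_path(fp)))
            except Exception as exc:
                errors.append(str(exc))
        features.append(feats)
    for path, _pair in model.link_entries:
        try:
            links.append(read_link_file(model.resolve_path(path)))
        except Exception as exc:
            errors.append(str(exc))
            links.append([])
    if errors:
        raise LayoutError("input errors:\n  " + "\n  ".join(errors))
    return PlotData(genomes, features, links)


def layout_scene(model: ConfigModel, data: PlotData) -> SceneGraph:
    """Assemble the full scene: ribbons, rects, features, axes, labels.

    Layer order and within-layer ordering (declaration order, then file
    order) are deterministic.
    """
    if len(data.genomes) != model.n_genomes or len(data.links) != model.n_links:
        raise LayoutError("PlotData does not match the configuration")

    params = [resolve_genome_params(model, i + 1) for i in range(model.n_genomes)]

    # shared bp scale: widest genome window (in bp) spans DEFAULT_TRACK_WIDTH
    def window_bp(genome: GenomeDef, gp: GenomeParams) -> int:
        if gp.zoom_region is not None and gp.zoom_region.seq_id in genome:
            c = genome.chrom(gp.zoom_region.seq_id)
            return max(min(gp.zoom_region.end, c.end)
                       - max(gp.zoom_region.start, c.start), 1)
        return sum(max(c.end - c.start, 1) for c in genome.chroms)

    max_bp = max(window_bp(g, gp) for g, gp in zip(data.genomes, params))
    px_per_bp = DEFAULT_TRACK_WIDTH / max_bp

    tracks: list[GenomeTrack] = []
    for i, (genome, gp) in enumerate(zip(data.genomes, params)):
        slot_y = _TOP_MARGIN + i * DEFAULT_SLOT_PITCH
        tracks.append(build_track(genome, gp, slot_y,
                                  genome_index=i + 1, px_per_bp=px_per_bp))

    scene = SceneGraph()

    # (1) ribbons
    for j, (entry, link_records) in enumerate(zip(model.link_entries, data.links)):
        _path, (ga, gb) = entry
        lp = resolve_link_params(model, j + 1)
        track_a, track_b = tracks[ga - 1], tracks[gb - 1]
        default_height = abs(track_b.slot_y - track_a.slot_y) or DEFAULT_SLOT_PITCH
        for k, (rec, drop) in enumerate(
                clip_links_to_windows(link_records, track_a, track_b)):
            if drop:
                continue
            rp = effective_link_params(lp, rec.attrs)
            anchors = compute_ribbon_anchors(rec, track_a, track_b, rp)
            ribbon = build_ribbon_path(anchors, rp.style, rp.height_ratio,
                                       default_height)
            ribbon.id = f"link{j + 1}.{k + 1}"
            ribbon.style = {"fill": rp.fill, "stroke": rp.stroke,
                            "fill-opacity": f"{rp.opacity:g}"}
            scene.add("ribbons", ribbon)

    # (2) chromosome rects
    for t in tracks:
        gp = t.params
        for r in t.rects:
            rect = RectPrim(
                id=f"g{t.genome_index}.{r.seq_id}",
                style={"fill": t.genome.chrom(r.seq_id).attrs.get("fill", gp.fill),
                       "stroke": t.genome.chrom(r.seq_id).attrs.get("stroke",
                                                                    gp.stroke)},
                transform=t.transform,
                x=r.x0, y=r.y0, width=r.x1 - r.x0, height=r.height,
                rx=(r.height / 2.0 if gp.rounded_ends else 0.0),
            )
            scene.add("rects", rect)

    # (3) features
    for t, feats in zip(tracks, data.features):
        skipped = 0
        for n, feat in enumerate(feats):
            if feat.seq_id not in t:
                skipped += 1
                continue
            rect = t.rect_for(feat.seq_id)
            ws, we = rect.bp_window
            if feat.end < ws or feat.start > we:
                skipped += 1
                continue
            glyph = build_feature_glyph(feat, rect, t.params)
            glyph.id = f"g{t.genome_index}.feat{n + 1}"
            glyph.transform = t.transform
            scene.add("features", glyph)
        if skipped:
            logger.info("genome %d: %d feature(s) outside rendered windows",
                        t.genome_index, skipped)

    # (4) axes/ticks
    for t in tracks:
        if not t.params.show_coordinates:
            continue
        for r in t.rects:
            group = build_axis_ticks(r, True)
            if group is None:
                continue
            group.id = f"g{t.genome_index}.{r.seq_id}.axis"
            group.transform = t.transform
            scene.add("axes", group)

    # (5) labels
    for t in tracks:
        gp = t.params
        if not gp.show_label:
            continue
        text = gp.label_text or t.genome.name
        w = t.baseline_width
        h = gp.chr_height
        pos = {
            "left": (-8.0, h / 2.0 + 3.0, "end"),
            "right": (w + 8.0, h / 2.0 + 3.0, "start"),
            "top": (w / 2.0, -8.0, "middle"),
            "bottom": (w / 2.0, h + 14.0, "middle"),
        }[gp.label_position]
        scene.add("labels", TextPrim(
            id=f"g{t.genome_index}.label",
            style={"fill": gp.label_color,
                   "font-family": "Helvetica, Arial, sans-serif"},
            transform=t.transform,
            x=pos[0], y=pos[1], text=text, anchor=pos[2], font_size=12.0))

    scene.finalize()
    _check_unique_ids(scene)
    return scene


def _check_unique_ids(scene: SceneGraph) -> None:
    ids = [i for i in scene.all_ids() if i]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise LayoutError(f"duplicate primitive ids: {dupes}")
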