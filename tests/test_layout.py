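import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multisyn.config import GenomeParams, LinkParams, RegionSpec, parse_config
from multisyn.errors import LayoutError
from multisyn.fixtures import FixtureSpec, make_fixture
from multisyn.io_formats import (AttrMap, ChromRecord, GenomeDef, LinkRecord,
                                 Orientation)
from multisyn.layout import (ChromRect, bp_to_canvas, build_track,
                             clip_links_to_windows, compute_ribbon_anchors,
                             layout_scene, load_plot_data)
from multisyn.scene import Affine


def _genome(*lengths, prefix="c"):
    return GenomeDef("g", [ChromRecord(f"{prefix}{i+1}", 1, n)
                           for i, n in enumerate(lengths)])


# ---------------------------------------------------------------------------
# transforms


def test_identity_params_transform_is_slot_translation():
    track = build_track(_genome(1000), GenomeParams(), default_slot_y=50.0)
    assert track.transform.apply(0.0, 0.0) == (0.0, 50.0)
    assert track.transform.apply(10.0, 5.0) == (10.0, 55.0)


def test_rotation_maps_baseline_to_vertical():
    gp = GenomeParams(rotate_chr=90.0)
    track = build_track(_genome(1000), gp, default_slot_y=0.0)
    x, y = track.transform.apply(1.0, 0.0)
    # CCW in the y-down SVG frame: (1,0) -> (0,1) up to sign convention
    assert abs(x) < 1e-12 and abs(abs(y) - 1.0) < 1e-12


@given(st.floats(0, 360), st.floats(-500, 500), st.floats(-500, 500))
def test_isometry_at_unit_zoom(angle, mx, my):
    """rotation + translation preserves pairwise distances (zoom_chr = 1)."""
    gp = GenomeParams(rotate_chr=angle, move_to_x=mx, move_to_y=my)
    t = build_track(_genome(1000), gp, 0.0).transform
    rng = random.Random(17)
    for _ in range(5):
        p = (rng.uniform(-1e3, 1e3), rng.uniform(-1e3, 1e3))
        q = (rng.uniform(-1e3, 1e3), rng.uniform(-1e3, 1e3))
        d0 = math.dist(p, q)
        d1 = math.dist(t.apply(*p), t.apply(*q))
        assert d1 == pytest.approx(d0, rel=1e-9, abs=1e-9)


def test_transform_invertible_nonzero_det():
    gp = GenomeParams(rotate_chr=33.0, zoom_chr=0.25, move_to_x=7, move_to_y=8)
    t = build_track(_genome(1000), gp, 0.0).transform
    assert abs(t.det) > 1e-12


def test_affine_composition_convention():
    t = Affine.translation(10, 20) @ Affine.scaling(2)
    assert t.apply(3, 4) == (16, 28)  # scale first, then translate


# ---------------------------------------------------------------------------
# track construction


def test_track_chromosome_positions_oracle():
    # arithmetic oracle recomputed by hand: widths proportional to (end-start)
    spacing = 7.0
    px = 0.1
    gp = GenomeParams(chr_spacing=spacing)
    track = build_track(_genome(1000, 500), gp, 0.0, px_per_bp=px)
    r1, r2 = track.rects
    assert r1.x0 == 0.0
    assert r1.x1 == pytest.approx(999 * px)
    assert r2.x0 == pytest.approx(999 * px + spacing)
    assert r2.x1 == pytest.approx(999 * px + spacing + 499 * px)
    assert track.baseline_width == pytest.approx(r2.x1)


def test_track_rects_non_overlapping_in_order():
    track = build_track(_genome(100, 200, 300), GenomeParams(), 0.0)
    for a, b in zip(track.rects, track.rects[1:]):
        assert a.x1 < b.x0


def test_track_zoom_region_slices_single_chromosome():
    gp = GenomeParams(zoom_region=RegionSpec("c2", 100, 400))
    track = build_track(_genome(1000, 500), gp, 0.0)
    assert [r.seq_id for r in track.rects] == ["c2"]
    assert track.rects[0].bp_window == (100, 400)


def test_track_zoom_region_unknown_chromosome():
    gp = GenomeParams(zoom_region=RegionSpec("nope", 1, 10))
    with pytest.raises(LayoutError, match="nope"):
        build_track(_genome(1000), gp, 0.0)


def test_track_empty_genome_rejected():
    with pytest.raises(LayoutError, match="empty"):
        build_track(GenomeDef("g", []), GenomeParams(), 0.0)


# ---------------------------------------------------------------------------
# bp -> canvas


def test_bp_to_canvas_boundaries():
    track = build_track(_genome(1001), GenomeParams(), 0.0, px_per_bp=1.0)
    assert bp_to_canvas(track, "c1", 1) == (0.0, 0.0)
    assert bp_to_canvas(track, "c1", 1001) == (1000.0, 0.0)
    assert bp_to_canvas(track, "c1", 501) == (500.0, 0.0)  # midpoint


def test_bp_to_canvas_edges():
    gp = GenomeParams(chr_height=12.0)
    track = build_track(_genome(1001), gp, 0.0, px_per_bp=1.0)
    assert bp_to_canvas(track, "c1", 1, "down") == (0.0, 12.0)
    assert bp_to_canvas(track, "c1", 1, "mid") == (0.0, 6.0)


def test_bp_to_canvas_outside_window_errors():
    gp = GenomeParams(zoom_region=RegionSpec("c1", 100, 200))
    track = build_track(_genome(1000), gp, 0.0)
    with pytest.raises(LayoutError, match="outside"):
        bp_to_canvas(track, "c1", 99)
    with pytest.raises(LayoutError):
        bp_to_canvas(track, "c2", 1)


def test_zoom_chr_doubles_canvas_distance():
    # numeric comparison of both mappings
    def span(zoom):
        gp = GenomeParams(zoom_chr=zoom)
        t = build_track(_genome(1000), gp, 0.0, px_per_bp=1.0)
        (x1, _), (x2, _) = (bp_to_canvas(t, "c1", 100),
                            bp_to_canvas(t, "c1", 600))
        return x2 - x1
    assert span(2.0) == pytest.approx(2.0 * span(1.0), rel=1e-12)


@settings(max_examples=60)
@given(st.integers(1, 10**6), st.integers(2, 10**6),
       st.floats(0, 360), st.floats(-100, 100), st.floats(0.1, 4))
def test_bp_to_canvas_affinity_and_monotonicity(start, span, angle, mv, zoom):
    """Images of (s, midpoint, e) are collinear & evenly spaced; bp order
    equals x order in the pre-rotation frame."""
    end = start + span
    genome = GenomeDef("g", [ChromRecord("c1", start, end)])
    gp = GenomeParams(rotate_chr=angle, move_to_x=mv, zoom_chr=zoom)
    track = build_track(genome, gp, 10.0)
    s, m, e = start, (start + end) / 2, end
    ps, pm, pe = (bp_to_canvas(track, "c1", p) for p in (s, m, e))
    # collinear with equidistant midpoint
    assert pm[0] == pytest.approx((ps[0] + pe[0]) / 2, rel=1e-9, abs=1e-6)
    assert pm[1] == pytest.approx((ps[1] + pe[1]) / 2, rel=1e-9, abs=1e-6)
    # monotone pre-rotation: local x increases with bp
    rect = track.rect_for("c1")
    xs = [rect.bp_to_x(p) for p in (s, m, e)]
    assert xs[0] <= xs[1] <= xs[2]


# ---------------------------------------------------------------------------
# clipping


def _tracks_for_windows(win_a, win_b):
    ga = GenomeDef("a", [ChromRecord("a1", 1, 10_000)])
    gb = GenomeDef("b", [ChromRecord("b1", 1, 10_000)])
    ta = build_track(ga, GenomeParams(zoom_region=RegionSpec("a1", *win_a)), 0.0)
    tb = build_track(gb, GenomeParams(zoom_region=RegionSpec("b1", *win_b)), 100.0)
    return ta, tb


def test_clip_link_fully_inside_unchanged():
    ta, tb = _tracks_for_windows((1, 10_000), (1, 10_000))
    lk = LinkRecord("a1", 100, 200, "b1", 300, 400)
    ((rec, dropped),) = clip_links_to_windows([lk], ta, tb)
    assert not dropped and rec == lk


def test_clip_link_fully_outside_dropped():
    ta, tb = _tracks_for_windows((5000, 6000), (1, 10_000))
    lk = LinkRecord("a1", 100, 200, "b1", 300, 400)
    ((rec, dropped),) = clip_links_to_windows([lk], ta, tb)
    assert dropped


def test_clip_half_overlap_rescales_partner():
    # A interval 1000..1999 (span 999); window starts at 1500 -> keep the
    # upper fraction; B must shrink to the matching fraction on its low end
    # being cut (same orientation -> same ends)
    ta, tb = _tracks_for_windows((1500, 10_000), (1, 10_000))
    lk = LinkRecord("a1", 1000, 1999, "b1", 2000, 2999)
    ((rec, dropped),) = clip_links_to_windows([lk], ta, tb)
    assert not dropped
    assert (rec.start_a, rec.end_a) == (1500, 1999)
    frac = (1500 - 1000) / 999
    assert rec.start_b == 2000 + round(frac * 999)
    assert rec.end_b == 2999


def test_clip_inverted_link_mirrors_fractions():
    ta, tb = _tracks_for_windows((1500, 10_000), (1, 10_000))
    lk = LinkRecord("a1", 1000, 1999, "b1", 2000, 2999,
                    Orientation.INVERTED)
    ((rec, dropped),) = clip_links_to_windows([lk], ta, tb)
    assert not dropped
    # cutting A's low end removes B's *high* end for an inverted link
    assert rec.start_b == 2000
    assert rec.end_b == 2999 - round(((1500 - 1000) / 999) * 999)


def _random_link(rng):
    sa = rng.randint(1, 9_000)
    sb = rng.randint(1, 9_000)
    return LinkRecord("a1", sa, sa + rng.randint(0, 900),
                      "b1", sb, sb + rng.randint(0, 900),
                      rng.choice(list(Orientation)))


@pytest.mark.parametrize("seed", range(5))
def test_clip_conservation_and_window_bounds(seed):
    """brute-force oracle: kept+dropped == total; clipped intervals inside
    windows; drop decision matches interval-overlap arithmetic."""
    rng = random.Random(seed)
    wa = sorted(rng.sample(range(1, 10_000), 2))
    wb = sorted(rng.sample(range(1, 10_000), 2))
    ta, tb = _tracks_for_windows(tuple(wa), tuple(wb))
    links = [_random_link(rng) for _ in range(50)]
    out = clip_links_to_windows(links, ta, tb)
    assert len(out) == len(links)
    kept = [r for r, d in out if not d]
    dropped = [r for r, d in out if d]
    assert len(kept) + len(dropped) == len(links)
    for rec in kept:
        assert wa[0] <= rec.start_a <= rec.end_a <= wa[1]
        assert wb[0] <= rec.start_b <= rec.end_b <= wb[1]
    # independent overlap oracle: a link overlapping A's window on A's side
    # can only be dropped if its rescaled B part misses B's window
    for (rec, d), orig in zip(out, links):
        a_overlaps = not (orig.end_a < wa[0] or orig.start_a > wa[1])
        if not a_overlaps:
            assert d


# ---------------------------------------------------------------------------
# ribbon anchors


def _two_stacked_tracks():
    ga = GenomeDef("a", [ChromRecord("a1", 1, 1001)])
    gb = GenomeDef("b", [ChromRecord("b1", 1, 1001)])
    gp = GenomeParams(chr_height=10.0)
    ta = build_track(ga, gp, 0.0, px_per_bp=1.0)
    tb = build_track(gb, gp, 100.0, px_per_bp=1.0)
    return ta, tb


def test_anchor_edges_follow_style_up_down():
    ta, tb = _two_stacked_tracks()
    lk = LinkRecord("a1", 1, 101, "b1", 1, 101)
    an = compute_ribbon_anchors(lk, ta, tb, LinkParams(style_up_down="UpDown"))
    assert an.a_start[1] == 0.0  # top edge of A
    assert an.b_start[1] == 110.0  # bottom edge of B
    an2 = compute_ribbon_anchors(lk, ta, tb,
                                 LinkParams(style_up_down="DownDown"))
    assert an2.a_start[1] == 10.0 and an2.b_start[1] == 110.0


def test_anchor_inversion_crosses_b_side():
    ta, tb = _two_stacked_tracks()
    same = LinkRecord("a1", 1, 101, "b1", 201, 301)
    inv = LinkRecord("a1", 1, 101, "b1", 201, 301, Orientation.INVERTED)
    lp = LinkParams()
    an_same = compute_ribbon_anchors(same, ta, tb, lp)
    an_inv = compute_ribbon_anchors(inv, ta, tb, lp)
    assert an_inv.b_start == an_same.b_end
    assert an_inv.b_end == an_same.b_start


def test_anchors_lie_on_transformed_edges():
    ga = GenomeDef("a", [ChromRecord("a1", 1, 1001)])
    gp = GenomeParams(rotate_chr=30.0, move_to_x=50.0, move_to_y=60.0)
    ta = build_track(ga, gp, 0.0, px_per_bp=1.0)
    tb = build_track(ga, GenomeParams(), 100.0, px_per_bp=1.0)
    lk = LinkRecord("a1", 101, 201, "a1", 101, 201)
    an = compute_ribbon_anchors(lk, ta, tb, LinkParams(style_up_down="UpUp"))
    assert an.a_start == ta.transform.apply(100.0, 0.0)
    assert an.a_end == ta.transform.apply(200.0, 0.0)


# ---------------------------------------------------------------------------
# whole-scene


def test_layout_scene_structure(demo_fixture):
    spec, paths = demo_fixture
    model = parse_config(paths["config"])
    data = load_plot_data(model)
    scene = layout_scene(model, data)
    assert len(scene.layers["rects"]) == sum(1 for g in data.genomes
                                             for _ in g.chroms)
    assert 0 < len(scene.layers["ribbons"]) <= sum(len(l) for l in data.links)
    assert scene.width > 0 and scene.height > 0


def test_layout_scene_triangle_rotations(demo_fixture):
    """3-genome fixture config uses three distinct nonzero rotations."""
    spec, paths = demo_fixture
    model = parse_config(paths["config"])
    from multisyn.config import resolve_genome_params
    rots = {resolve_genome_params(model, i).rotate_chr % 360 for i in (1, 2, 3)}
    assert len(rots) == 3 and 0 not in rots


def test_layout_scene_empty_links(tmp_path):
    (tmp_path / "g1.len").write_text("c1 1 1000\n")
    (tmp_path / "g2.len").write_text("c2 1 1000\n")
    (tmp_path / "l.link").write_text("# none\n")
    conf = tmp_path / "conf.txt"
    conf.write_text("Genome = g1.len\nGenome = g2.len\nLink = l.link 1 2\n")
    model = parse_config(conf)
    scene = layout_scene(model, load_plot_data(model))
    assert scene.layers["ribbons"] == []
    assert len(scene.layers["rects"]) == 2


def test_scene_determinism(demo_fixture):
    spec, paths = demo_fixture
    model = parse_config(paths["config"])
    data = load_plot_data(model)
    s1 = layout_scene(model, data).to_json()
    s2 = layout_scene(model, data).to_json()
    assert s1 == s2
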