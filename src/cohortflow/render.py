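"""Deterministic static rendering of the block view and timeline view.

Rendering happens in two stages: layout state is first turned into a
:class:`Scene` — a flat display list of primitive shapes in pixel
coordinates — and the scene is then serialized.  The native output is
SVG 1.1 text produced by a small built-in writer (byte-identical for
identical inputs); PNG and PDF are produced by re-drawing the same
scene through matplotlib's Agg/PDF backends.

Conventions: time flows top to bottom, patients left to right.  Gap
cells (no sample at this timepoint) are hatched light rectangles;
missing measurements are neutral grey — different glyphs for different
kinds of absence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

from .layout import FlowSet, GroupedBlock, MISSING_GROUP
from .model import GAP, Block, Feature, PatientTrack

__all__ = [
    "RenderSpec",
    "Scene",
    "render_block_view",
    "render_timeline_view",
    "export_figure",
    "color_for",
]

QUALITATIVE = [
    "#4e79a7", "#f28e2b", "#e15759", "#76b7b2", "#59a14f",
    "#edc948", "#b07aa1", "#ff9da7", "#9c755f", "#bab0ac",
]
SEQ_LO, SEQ_HI = "#deebf7", "#08519c"  # sequential blue ramp endpoints


@dataclass
class RenderSpec:
    """Visual parameters; every dimension is in pixels."""

    cell_width: float = 14.0
    cell_height: float = 14.0
    row_gap: float = 1.0
    block_gap: float = 56.0
    margin: float = 36.0
    band_opacity: float = 0.5
    highlight_color: str = "#f6c100"
    gap_fill: str = "#f4f4f4"
    missing_fill: str = "#bdbdbd"
    line_color: str = "#8a8a8a"
    font_size: float = 9.0
    day_px: float = 0.12  # timeline vertical scale
    track_gap: float = 34.0
    point_event_size: float = 5.0

    def __post_init__(self) -> None:
        for name in ("cell_width", "cell_height", "block_gap", "day_px", "track_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"RenderSpec.{name} must be > 0")


# -- primitives -------------------------------------------------------------


@dataclass
class Rect:
    x: float
    y: float
    w: float
    h: float
    fill: str
    opacity: float = 1.0
    hatch: bool = False
    css_class: str = ""


@dataclass
class StraightLine:
    x1: float
    y1: float
    x2: float
    y2: float
    stroke: str
    width: float = 1.0
    css_class: str = ""


@dataclass
class Curve:
    """Cubic Bezier from (x1,y1) to (x2,y2) with vertical control offsets."""

    x1: float
    y1: float
    x2: float
    y2: float
    stroke: str
    width: float = 1.0
    css_class: str = ""


@dataclass
class Band:
    """Filled ribbon between segment [sx0,sx1]@y1 and [tx0,tx1]@y2."""

    sx0: float
    sx1: float
    y1: float
    tx0: float
    tx1: float
    y2: float
    fill: str
    opacity: float = 0.5
    css_class: str = ""


@dataclass
class Dot:
    x: float
    y: float
    r: float
    fill: str
    css_class: str = ""


@dataclass
class Label:
    x: float
    y: float
    text: str
    size: float = 9.0
    anchor: str = "start"


@dataclass
class Scene:
    width: float
    height: float
    items: list = field(default_factory=list)

    def add(self, item) -> None:
        self.items.append(item)

    def count(self, css_class: str) -> int:
        return sum(1 for it in self.items if getattr(it, "css_class", "") == css_class)

    def to_svg(self) -> str:
        return scene_to_svg(self)


# -- colors -----------------------------------------------------------------


def _hex_to_rgb(h: str) -> tuple[int, int, int]:
    h = h.lstrip("#")
    return tuple(int(h[i:i + 2], 16) for i in (0, 2, 4))


def _lerp_hex(a: str, b: str, t: float) -> str:
    ra, rb = _hex_to_rgb(a), _hex_to_rgb(b)
    return "#" + "".join(f"{round(x + (y - x) * t):02x}" for x, y in zip(ra, rb))


def color_for(feature: Feature | None, value, spec: RenderSpec) -> str:
    """Deterministic value -> color assignment (domain order = palette order)."""
    if value is None or value is GAP:
        return spec.missing_fill
    if value == MISSING_GROUP:
        return spec.missing_fill
    if feature is None:
        return spec.line_color
    if isinstance(feature.color_scale, Mapping) and value in feature.color_scale:
        return feature.color_scale[value]
    if feature.datatype == "binary":
        return SEQ_HI if value else SEQ_LO
    if feature.datatype in ("categorical", "ordinal"):
        dom = list(feature.domain or [])
        try:
            i = dom.index(value)
        except ValueError:
            return spec.missing_fill
        if feature.datatype == "ordinal":
            t = i / max(len(dom) - 1, 1)
            return _lerp_hex(SEQ_LO, SEQ_HI, t)
        return QUALITATIVE[i % len(QUALITATIVE)]
    rng = feature.observed_range()
    if rng is None or rng[1] == rng[0]:
        return SEQ_LO
    t = (float(value) - rng[0]) / (rng[1] - rng[0])
    return _lerp_hex(SEQ_LO, SEQ_HI, min(max(t, 0.0), 1.0))


# -- block view -------------------------------------------------------------


def _block_height(state: Block | GroupedBlock, spec: RenderSpec) -> float:
    if isinstance(state, GroupedBlock):
        n_rows = 1 + len(next(iter(state.nested_summaries.values()), {}))
    else:
        n_rows = max(len(state.rows), 1)
    return n_rows * (spec.cell_height + spec.row_gap)


def _group_spans(state: GroupedBlock, x0: float, total_w: float) -> dict[Any, tuple[float, float]]:
    n = max(sum(len(p) for _, p in state.groups), 1)
    spans = {}
    x = x0
    for g, pids in state.groups:
        w = total_w * len(pids) / n
        spans[g] = (x, x + w)
        x += w
    return spans


def _draw_heatmap(scene: Scene, block: Block, features, x0: float, y0: float,
                  spec: RenderSpec, selection: set) -> None:
    for ri, fid in enumerate(block.rows):
        feat = features[fid]
        y = y0 + ri * (spec.cell_height + spec.row_gap)
        for ci, pid in enumerate(block.order):
            x = x0 + ci * spec.cell_width
            v = block.value(fid, pid)
            if v is GAP:
                scene.add(Rect(x, y, spec.cell_width - 0.5, spec.cell_height,
                               spec.gap_fill, hatch=True, css_class="gapcell"))
            else:
                scene.add(Rect(x, y, spec.cell_width - 0.5, spec.cell_height,
                               color_for(feat, v, spec), css_class="cell"))
            if pid in selection:
                scene.add(Rect(x, y, spec.cell_width - 0.5, 2.0,
                               spec.highlight_color, css_class="selmark"))


def _draw_grouped(scene: Scene, state: GroupedBlock, features, x0: float, y0: float,
                  total_w: float, spec: RenderSpec) -> None:
    primary = features.get(state.primary_feature)
    spans = _group_spans(state, x0, total_w)
    for g, pids in state.groups:
        gx0, gx1 = spans[g]
        scene.add(Rect(gx0, y0, gx1 - gx0 - 0.5, spec.cell_height,
                       color_for(primary, g, spec), css_class="groupbar"))
        sel = state.selected_counts.get(g, 0)
        if sel:
            frac = sel / max(len(pids), 1)
            scene.add(Rect(gx0, y0, (gx1 - gx0 - 0.5) * frac, 2.0,
                           spec.highlight_color, css_class="selmark"))
        # nested summaries of the other displayed features
        row_fids = sorted(state.nested_summaries.get(g, {}))
        for ri, fid in enumerate(row_fids):
            y = y0 + (ri + 1) * (spec.cell_height + spec.row_gap)
            summ = state.nested_summaries[g][fid]
            feat = features.get(fid)
            if isinstance(summ, dict) and "five_number" in summ:
                _draw_box_glyph(scene, summ["five_number"], feat, gx0, gx1, y, spec)
            else:
                total = max(sum(summ.values()), 1)
                x = gx0
                dom = list((feat.domain or [])) if feat is not None else sorted(summ)
                if feat is not None and feat.datatype == "binary":
                    dom = [0, 1]
                for val in [v for v in dom if v in summ]:
                    w = (gx1 - gx0 - 0.5) * summ[val] / total
                    scene.add(Rect(x, y, w, spec.cell_height,
                                   color_for(feat, val, spec), css_class="nested"))
                    x += w


def _draw_box_glyph(scene, five, feat, gx0, gx1, y, spec) -> None:
    if five is None:
        return
    rng = feat.observed_range() if feat is not None else None
    lo, hi = rng if rng and rng[1] > rng[0] else (five[0], max(five[4], five[0] + 1))
    span = (hi - lo) or 1.0
    gx1 = gx1 - 0.5

    def sx(v):
        return gx0 + (gx1 - gx0) * (v - lo) / span

    mid = y + spec.cell_height / 2
    scene.add(StraightLine(sx(five[0]), mid, sx(five[4]), mid, "#555555",
                           css_class="boxwhisker"))
    scene.add(Rect(sx(five[1]), y + 2, max(sx(five[3]) - sx(five[1]), 1.0),
                   spec.cell_height - 4, "#9ecae1", css_class="boxglyph"))
    scene.add(StraightLine(sx(five[2]), y + 1, sx(five[2]), y + spec.cell_height - 1,
                           "#08519c", width=1.5, css_class="boxmedian"))


def _anchor_x(state: Block | GroupedBlock, anchor: tuple, x0: float, total_w: float,
              spec: RenderSpec) -> float:
    if anchor[0] == "pos":
        return x0 + (anchor[1] + 0.5) * spec.cell_width
    spans = _group_spans(state, x0, total_w)
    gx0, gx1 = spans.get(anchor[1], (x0, x0 + total_w))
    return (gx0 + gx1) / 2


def _draw_flows(scene: Scene, fs: FlowSet, state_a, state_b, features,
                x0: float, y_a: float, y_b: float, total_w: float,
                spec: RenderSpec) -> None:
    if fs.mode == "flows":
        spans_a = _group_spans(state_a, x0, total_w)
        spans_b = _group_spans(state_b, x0, total_w)
        counts_a = state_a.group_sizes()
        counts_b = state_b.group_sizes()
        off_a = {g: spans_a[g][0] for g, _ in state_a.groups}
        off_b = {g: spans_b[g][0] for g, _ in state_b.groups}
        prim_a = features.get(fs.source_primary) if fs.source_primary else None
        prim_b = features.get(fs.target_primary) if fs.target_primary else None
        order_b = {g: i for i, (g, _) in enumerate(state_b.groups)}
        order_a = {g: i for i, (g, _) in enumerate(state_a.groups)}
        # band order at each end follows the opposite end's group order:
        # target-side offsets advance in (target, source) order, source-side
        # offsets in (source, target) order
        tx_of: dict[tuple, float] = {}
        for (ga, gb), pids in sorted(
            fs.flows.items(), key=lambda kv: (order_b.get(kv[0][1], 0), order_a.get(kv[0][0], 0))
        ):
            wb = (spans_b[gb][1] - spans_b[gb][0]) * len(pids) / max(counts_b[gb], 1)
            tx_of[(ga, gb)] = off_b[gb]
            off_b[gb] += wb
        for (ga, gb), pids in sorted(
            fs.flows.items(), key=lambda kv: (order_a.get(kv[0][0], 0), order_b.get(kv[0][1], 0))
        ):
            wa = (spans_a[ga][1] - spans_a[ga][0]) * len(pids) / max(counts_a[ga], 1)
            wb = (spans_b[gb][1] - spans_b[gb][0]) * len(pids) / max(counts_b[gb], 1)
            tx0 = tx_of[(ga, gb)]
            sx0 = off_a[ga]
            off_a[ga] += wa
            n_sel = len(set(pids) & fs.highlight)
            fill = color_for(prim_a, ga if ga != MISSING_GROUP else None, spec)
            scene.add(Band(sx0, sx0 + wa, y_a, tx0, tx0 + wb, y_b, fill,
                           opacity=spec.band_opacity, css_class="band"))
            if n_sel:
                frac = n_sel / len(pids)
                scene.add(Band(sx0, sx0 + wa * frac, y_a, tx0, tx0 + wb * frac, y_b,
                               spec.highlight_color, opacity=0.85, css_class="bandsel"))
            # proxy colors of each end's primary feature repeated at band ends
            scene.add(Rect(sx0, y_a, wa, 3.0, color_for(prim_a, ga, spec), css_class="proxy"))
            scene.add(Rect(tx0, y_b - 3.0, wb, 3.0, color_for(prim_b, gb, spec),
                           css_class="proxy"))
    else:
        for pid, anc_a, anc_b in fs.lines:
            xa = _anchor_x(state_a, anc_a, x0, total_w, spec)
            xb = _anchor_x(state_b, anc_b, x0, total_w, spec)
            selected = pid in fs.highlight
            scene.add(Curve(
                xa, y_a, xb, y_b,
                spec.highlight_color if selected else spec.line_color,
                width=1.6 if selected else 1.0,
                css_class="selline" if selected else "line",
            ))


def render_block_view(
    blocks: Sequence[Block],
    grouped_blocks: Mapping[int, GroupedBlock] | Sequence[GroupedBlock],
    flowsets: Sequence[FlowSet],
    features: Mapping[str, Feature],
    spec: RenderSpec | None = None,
    selection: Sequence[str] = (),
) -> Scene:
    """Render blocks (heatmaps or grouped proportion bars) stacked top to
    bottom with patient lines / Sankey bands in the gaps between them."""
    spec = spec or RenderSpec()
    if not isinstance(grouped_blocks, Mapping):
        grouped_blocks = {g.index: g for g in grouped_blocks}
    sel = set(selection)
    states: list[Block | GroupedBlock] = [
        grouped_blocks.get(b.index, b) for b in blocks
    ]
    by_index = {s.index: s for s in states}
    for fs in flowsets:
        for idx in fs.between:
            if idx not in by_index:
                raise ValueError(f"flowset references absent block {idx}")

    n_cols = max((len(b.columns) for b in blocks), default=1)
    total_w = n_cols * spec.cell_width
    width = 2 * spec.margin + total_w
    y = spec.margin
    tops: dict[int, float] = {}
    bottoms: dict[int, float] = {}
    heights = {}
    for state in states:
        tops[state.index] = y
        h = _block_height(state, spec)
        heights[state.index] = h
        bottoms[state.index] = y + h
        y += h + spec.block_gap
    height = y - spec.block_gap + spec.margin

    scene = Scene(width=width, height=height)
    x0 = spec.margin
    for state in states:
        label = f"{'timepoint' if state.kind == 'timepoint' else 'events'} {state.slot}"
        scene.add(Label(x0, tops[state.index] - 4, label, size=spec.font_size))
        if isinstance(state, GroupedBlock):
            _draw_grouped(scene, state, features, x0, tops[state.index], total_w, spec)
        else:
            _draw_heatmap(scene, state, features, x0, tops[state.index], spec, sel)
    for fs in flowsets:
        ia, ib = fs.between
        _draw_flows(scene, fs, by_index[ia], by_index[ib], features,
                    x0, bottoms[ia], tops[ib], total_w, spec)
    return scene


# -- timeline view ----------------------------------------------------------


def render_timeline_view(
    tracks: Sequence[PatientTrack],
    feature: Feature,
    spec: RenderSpec | None = None,
    selection: Sequence[str] = (),
) -> Scene:
    """One vertical date-proportional timeline per patient: sample
    markers colored by the display feature, event bars with length
    proportional to duration, zero-duration events as point markers."""
    spec = spec or RenderSpec()
    sel = set(selection)
    max_date = max(
        [d for t in tracks for d, _, _ in t.markers]
        + [b[1] for t in tracks for b in t.bars] + [1],
    )
    width = 2 * spec.margin + max(len(tracks), 1) * spec.track_gap
    height = 2 * spec.margin + max_date * spec.day_px
    scene = Scene(width=width, height=height)
    event_types = sorted({b[2] for t in tracks for b in t.bars})
    ev_color = {e: QUALITATIVE[i % len(QUALITATIVE)] for i, e in enumerate(event_types)}

    for i, track in enumerate(tracks):
        x = spec.margin + (i + 0.5) * spec.track_gap
        y0, y1 = spec.margin, spec.margin + max_date * spec.day_px
        selected = track.patient_id in sel
        scene.add(StraightLine(x, y0, x, y1,
                               spec.highlight_color if selected else "#d0d0d0",
                               width=2.0 if selected else 1.0, css_class="track"))
        scene.add(Label(x, y0 - 5, track.patient_id, size=spec.font_size, anchor="middle"))
        for start, stop, ev_type, _attrs in track.bars:
            by = spec.margin + start * spec.day_px
            bh = (stop - start) * spec.day_px
            if bh <= 0:
                s = spec.point_event_size
                scene.add(Rect(x - s / 2 + 4, by - s / 2, s, s, ev_color[ev_type],
                               css_class="pointevent"))
            else:
                scene.add(Rect(x + 2, by, 5.0, bh, ev_color[ev_type], css_class="eventbar"))
        for date, _sid, value in track.markers:
            my = spec.margin + date * spec.day_px
            scene.add(Dot(x, my, 4.0, color_for(feature, value, spec), css_class="marker"))
    return scene


# -- serialization ----------------------------------------------------------


def _f(v: float) -> str:
    return f"{v:.2f}".rstrip("0").rstrip(".")


def scene_to_svg(scene: Scene) -> str:
    """SVG 1.1 text; identical scenes serialize to identical bytes."""
    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_f(scene.width)}" '
        f'height="{_f(scene.height)}" viewBox="0 0 {_f(scene.width)} {_f(scene.height)}">',
        "<defs>"
        '<pattern id="hatch" width="4" height="4" patternUnits="userSpaceOnUse" '
        'patternTransform="rotate(45)">'
        '<line x1="0" y1="0" x2="0" y2="4" stroke="#cccccc" stroke-width="1"/>'
        "</pattern></defs>",
    ]
    for it in scene.items:
        cls = f' class="{it.css_class}"' if getattr(it, "css_class", "") else ""
        if isinstance(it, Rect):
            fill = "url(#hatch)" if it.hatch else it.fill
            op = f' fill-opacity="{_f(it.opacity)}"' if it.opacity != 1.0 else ""
            out.append(
                f'<rect{cls} x="{_f(it.x)}" y="{_f(it.y)}" width="{_f(max(it.w, 0))}" '
                f'height="{_f(max(it.h, 0))}" fill="{fill}"{op}/>'
            )
        elif isinstance(it, StraightLine):
            out.append(
                f'<line{cls} x1="{_f(it.x1)}" y1="{_f(it.y1)}" x2="{_f(it.x2)}" '
                f'y2="{_f(it.y2)}" stroke="{it.stroke}" stroke-width="{_f(it.width)}"/>'
            )
        elif isinstance(it, Curve):
            my = (it.y1 + it.y2) / 2
            d = (f"M {_f(it.x1)} {_f(it.y1)} C {_f(it.x1)} {_f(my)}, "
                 f"{_f(it.x2)} {_f(my)}, {_f(it.x2)} {_f(it.y2)}")
            out.append(
                f'<path{cls} d="{d}" fill="none" stroke="{it.stroke}" '
                f'stroke-width="{_f(it.width)}"/>'
            )
        elif isinstance(it, Band):
            my = (it.y1 + it.y2) / 2
            d = (f"M {_f(it.sx0)} {_f(it.y1)} "
                 f"C {_f(it.sx0)} {_f(my)}, {_f(it.tx0)} {_f(my)}, {_f(it.tx0)} {_f(it.y2)} "
                 f"L {_f(it.tx1)} {_f(it.y2)} "
                 f"C {_f(it.tx1)} {_f(my)}, {_f(it.sx1)} {_f(my)}, {_f(it.sx1)} {_f(it.y1)} Z")
            out.append(
                f'<path{cls} d="{d}" fill="{it.fill}" fill-opacity="{_f(it.opacity)}"/>'
            )
        elif isinstance(it, Dot):
            out.append(
                f'<circle{cls} cx="{_f(it.x)}" cy="{_f(it.y)}" r="{_f(it.r)}" '
                f'fill="{it.fill}"/>'
            )
        elif isinstance(it, Label):
            out.append(
                f'<text x="{_f(it.x)}" y="{_f(it.y)}" font-size="{_f(it.size)}" '
                f'font-family="sans-serif" text-anchor="{it.anchor}" fill="#333333">'
                f"{it.text}</text>"
            )
    out.append("</svg>")
    return "\n".join(out) + "\n"


def _scene_to_matplotlib(scene: Scene):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle as MplCircle, PathPatch, Rectangle as MplRect
    from matplotlib.path import Path as MplPath

    dpi = 96.0
    fig = plt.figure(figsize=(scene.width / dpi, scene.height / dpi), dpi=dpi)
    ax = fig.add_axes([0, 0, 1, 1])
    ax.set_xlim(0, scene.width)
    ax.set_ylim(scene.height, 0)  # y grows downward, matching SVG
    ax.axis("off")
    for it in scene.items:
        if isinstance(it, Rect):
            ax.add_patch(MplRect(
                (it.x, it.y), it.w, it.h,
                facecolor="#ffffff" if it.hatch else it.fill,
                hatch="///" if it.hatch else None,
                edgecolor="#cccccc" if it.hatch else "none",
                alpha=it.opacity,
            ))
        elif isinstance(it, StraightLine):
            ax.plot([it.x1, it.x2], [it.y1, it.y2], color=it.stroke, linewidth=it.width)
        elif isinstance(it, Curve):
            my = (it.y1 + it.y2) / 2
            path = MplPath(
                [(it.x1, it.y1), (it.x1, my), (it.x2, my), (it.x2, it.y2)],
                [MplPath.MOVETO, MplPath.CURVE4, MplPath.CURVE4, MplPath.CURVE4],
            )
            ax.add_patch(PathPatch(path, facecolor="none", edgecolor=it.stroke,
                                   linewidth=it.width))
        elif isinstance(it, Band):
            my = (it.y1 + it.y2) / 2
            verts = [
                (it.sx0, it.y1), (it.sx0, my), (it.tx0, my), (it.tx0, it.y2),
                (it.tx1, it.y2), (it.tx1, my), (it.sx1, my), (it.sx1, it.y1),
                (it.sx0, it.y1),
            ]
            codes = [MplPath.MOVETO] + [MplPath.CURVE4] * 3 + [MplPath.LINETO] + \
                    [MplPath.CURVE4] * 3 + [MplPath.CLOSEPOLY]
            ax.add_patch(PathPatch(MplPath(verts, codes), facecolor=it.fill,
                                   alpha=it.opacity, edgecolor="none"))
        elif isinstance(it, Dot):
            ax.add_patch(MplCircle((it.x, it.y), it.r, facecolor=it.fill, edgecolor="none"))
        elif isinstance(it, Label):
            ha = {"start": "left", "middle": "center", "end": "right"}[it.anchor]
            ax.text(it.x, it.y, it.text, fontsize=it.size, ha=ha, va="baseline",
                    color="#333333")
    return fig


def export_figure(scene: Scene, path, format: str, metadata: dict | None = None) -> list[Path]:
    """Write the scene as svg/png/pdf; an optional metadata dict is
    written alongside as ``<path>.meta.json``.  Returns written paths."""
    if format not in ("svg", "png", "pdf"):
        raise ValueError(f"unsupported format {format!r}; choose svg, png or pdf")
    path = Path(path)
    written = [path]
    if format == "svg":
        path.write_text(scene.to_svg())
    else:
        fig = _scene_to_matplotlib(scene)
        save_meta = {"CreationDate": None} if format == "pdf" else {"Software": None}
        fig.savefig(path, format=format, dpi=96.0, metadata=save_meta)
        import matplotlib.pyplot as plt
        plt.close(fig)
    if metadata is not None:
        import json
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(metadata, indent=2, sort_keys=True))
        written.append(sidecar)
    return written
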