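"""Uncertainty-visualization encodings: wave plot, V-plot, transparency map.

Three complementary encodings communicate the uncertainty of smoothed
area-level estimates:

* **Wave plot** — the empirical density of an area's posterior, computed
  on the *logarithm* of the ratio-scale measure (so equal areas under the
  curve mean equal probability) but with the axis relabelled in
  exponentiated ratio units, overlaid with the posterior median and the
  60%/80% credible-interval glyph.
* **V-plot** — a scatter of each area's point estimate (x, log axis)
  against the folded confidence max(PPD, 1-PPD) (y).  Areas most likely
  different from the national average, in either direction, sit at the
  top of the V; the fold treats both directions symmetrically.
* **Transparency choropleth** — fills from a reversed diverging
  blue-yellow-red ramp (pale yellow = national average), with opacity
  driven by the PPD so areas whose difference from the average is
  uncertain fade toward the neutral average colour.  Enabled by default,
  switchable off.

Group-level overviews bin each group's estimates into the colour
classes (percentage or count mode) or give five-number summaries
(boxplot mode) on a shared axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .graph import ValidationError
from .summaries import AreaSummary

__all__ = [
    "WavePlotSpec",
    "VPlotPoint",
    "StyleSpec",
    "OverviewSpec",
    "wave_plot_spec",
    "v_plot_spec",
    "estimate_color",
    "color_class_edges",
    "apply_transparency",
    "overview_spec",
    "render",
    "NEUTRAL_YELLOW",
]

# Reversed ColorBrewer-style diverging blue-yellow-red anchors with a
# lightened ("paler yellow") midpoint marking the national average.
RAMP_ANCHORS: tuple[tuple[float, str], ...] = (
    (0.00, "#2C7BB6"),   # strong blue: well below average
    (0.25, "#ABD9E9"),
    (0.50, "#FFFFE0"),   # pale yellow: the national-average colour
    (0.75, "#FDAE61"),
    (1.00, "#D7191C"),   # strong red: well above average
)
NEUTRAL_YELLOW = "#FFFFE0"
DEFAULT_TICKS = (0.5, 0.75, 1.0, 1.33, 2.0)


@dataclass(frozen=True)
class WavePlotSpec:
    area_id: str
    log_grid: np.ndarray
    density: np.ndarray
    ticks: tuple[tuple[float, str], ...]   # (log position, ratio-scale label)
    point: float
    ci60: tuple[float, float]
    ci80: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "area_id": self.area_id,
            "log_grid": self.log_grid.tolist(),
            "density": self.density.tolist(),
            "ticks": [[p, lab] for p, lab in self.ticks],
            "point": self.point,
            "ci60": list(self.ci60),
            "ci80": list(self.ci80),
        }


@dataclass(frozen=True)
class VPlotPoint:
    area_id: str
    x: float      # point estimate, ratio scale (plotted on a log axis)
    y: float      # folded confidence in [0.5, 1]
    style: "StyleSpec | None" = None

    def to_dict(self) -> dict:
        d = {"area_id": self.area_id, "x": self.x, "y": self.y}
        if self.style is not None:
            d["style"] = self.style.to_dict()
        return d


@dataclass(frozen=True)
class StyleSpec:
    area_id: str
    fill: str     # RGB hex
    alpha: float  # opacity in [0, 1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha outside [0, 1]")

    def composited_fill(self, base: str = NEUTRAL_YELLOW) -> str:
        """Fill composited over the neutral base at this opacity."""
        f = _hex_to_rgb(self.fill)
        b = _hex_to_rgb(base)
        mixed = tuple(self.alpha * fc + (1.0 - self.alpha) * bc
                      for fc, bc in zip(f, b))
        return _rgb_to_hex(mixed)

    def to_dict(self) -> dict:
        return {"area_id": self.area_id, "fill": self.fill, "alpha": self.alpha}


@dataclass(frozen=True)
class OverviewSpec:
    groups: tuple[str, ...]
    mode: str                       # percentage | count | boxplot
    values: dict[str, np.ndarray]   # per group: bin values or 5-number summary
    class_edges: tuple[float, ...]  # ratio-scale bin edges (percentage/count)
    class_colors: tuple[str, ...]
    axis_bounds: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "mode": self.mode,
            "values": {g: v.tolist() for g, v in self.values.items()},
            "class_edges": list(self.class_edges),
            "class_colors": list(self.class_colors),
            "axis_bounds": list(self.axis_bounds),
        }


def _hex_to_rgb(h: str) -> tuple[float, float, float]:
    h = h.lstrip("#")
    return tuple(int(h[k:k + 2], 16) / 255.0 for k in (0, 2, 4))


def _rgb_to_hex(rgb) -> str:
    return "#" + "".join(f"{int(round(c * 255)):02X}" for c in rgb)


def _format_ratio(v: float) -> str:
    s = f"{v:g}"
    return s


def wave_plot_spec(draws, summary: AreaSummary, grid_size: int = 256,
                   ticks=DEFAULT_TICKS) -> WavePlotSpec:
    """Gaussian-KDE density of log(draws) with ratio-scale axis ticks.

    The grid spans the range of the log draws plus three bandwidths on
    each side; tick positions are placed at log(ratio) for ratio values
    that fall inside the grid.
    """
    x = np.asarray(draws, dtype=float)
    if x.size < 50:
        raise ValidationError(f"need >= 50 draws for a density, got {x.size}")
    if np.any(x <= 0):
        raise ValidationError("ratio-scale draws must be positive")
    logx = np.log(x)
    kde = gaussian_kde(logx, bw_method="silverman")
    bw = float(np.sqrt(kde.covariance[0, 0]))
    lo = logx.min() - 3.0 * bw
    hi = logx.max() + 3.0 * bw
    grid = np.linspace(lo, hi, grid_size)
    dens = kde(grid)
    tick_list = tuple(
        (float(np.log(t)), _format_ratio(t))
        for t in ticks if lo <= np.log(t) <= hi
    )
    return WavePlotSpec(
        area_id=summary.area_id,
        log_grid=grid,
        density=dens,
        ticks=tick_list,
        point=summary.point,
        ci60=summary.ci60,
        ci80=summary.ci80,
    )


def v_plot_spec(summaries: list[AreaSummary],
                styles: list[StyleSpec] | None = None) -> list[VPlotPoint]:
    """One V-plot point per area: x = point estimate, y = folded confidence."""
    if styles is not None:
        if [s.area_id for s in styles] != [s.area_id for s in summaries]:
            raise ValidationError("summaries and styles are not aligned by area_id")
    out = []
    for k, s in enumerate(summaries):
        out.append(VPlotPoint(
            area_id=s.area_id,
            x=s.point,
            y=max(s.ppd, 1.0 - s.ppd),
            style=styles[k] if styles is not None else None,
        ))
    return out


def estimate_color(estimate: float,
                   breakpoints: tuple[float, float] = (0.5, 2.0)) -> str:
    """Diverging blue-yellow-red fill for a ratio-scale estimate.

    The estimate is mapped to t = clamp((log e - log lo)/(log hi - log
    lo), 0, 1) and linearly interpolated through the ramp anchors; t =
    0.5 (estimate at the geometric midpoint, which is 1 for symmetric
    breakpoints) is the pale national-average yellow.
    """
    if not estimate > 0:
        raise ValueError(f"estimate must be positive, got {estimate}")
    lo, hi = breakpoints
    if not (0 < lo < 1 < hi):
        raise ValueError(f"breakpoints must straddle 1, got {breakpoints}")
    t = (np.log(estimate) - np.log(lo)) / (np.log(hi) - np.log(lo))
    t = float(np.clip(t, 0.0, 1.0))
    return _ramp_color(t)


def _ramp_color(t: float) -> str:
    pos = [p for p, _ in RAMP_ANCHORS]
    cols = [_hex_to_rgb(c) for _, c in RAMP_ANCHORS]
    for k in range(len(pos) - 1):
        if pos[k] <= t <= pos[k + 1]:
            f = (t - pos[k]) / (pos[k + 1] - pos[k])
            rgb = tuple((1 - f) * a + f * b for a, b in zip(cols[k], cols[k + 1]))
            return _rgb_to_hex(rgb)
    return _rgb_to_hex(cols[-1])


def color_class_edges(breakpoints: tuple[float, float] = (0.5, 2.0),
                      n_classes: int = 5) -> tuple[tuple[float, ...], tuple[str, ...]]:
    """Ratio-scale bin edges and representative colours for the ramp classes.

    Classes are equal-width in t (log-ratio) between the breakpoints,
    with open-ended first and last bins absorbing clamped estimates.
    """
    lo, hi = breakpoints
    ts = np.linspace(0.0, 1.0, n_classes + 1)
    edges = np.exp(np.log(lo) + ts * (np.log(hi) - np.log(lo)))
    edges[0] = 0.0
    edges[-1] = np.inf
    mids = (ts[:-1] + ts[1:]) / 2.0
    colors = tuple(_ramp_color(float(t)) for t in mids)
    return tuple(float(e) for e in edges), colors


def apply_transparency(fill: str, ppd_value: float,
                       mapping: tuple[float, float, float] = (0.2, 0.6, 0.1),
                       enabled: bool = True,
                       area_id: str = "") -> StyleSpec:
    """Opacity from the PPD: uncertain areas fade toward the average yellow.

    The confidence of a difference is c = 2|ppd - 0.5|.  Opacity is
    ``alpha_min`` for c <= c_lo, 1 for c >= c_hi, and linear in between.
    With the encoding disabled every area is fully opaque.
    """
    c_lo, c_hi, alpha_min = mapping
    if not 0.0 <= ppd_value <= 1.0:
        raise ValueError(f"ppd must be in [0, 1], got {ppd_value}")
    if not (0.0 <= c_lo < c_hi <= 1.0) or not (0.0 < alpha_min < 1.0):
        raise ValueError(f"invalid transparency mapping {mapping}")
    if not enabled:
        return StyleSpec(area_id=area_id, fill=fill, alpha=1.0)
    c = 2.0 * abs(ppd_value - 0.5)
    if c <= c_lo:
        alpha = alpha_min
    elif c >= c_hi:
        alpha = 1.0
    else:
        alpha = alpha_min + (1.0 - alpha_min) * (c - c_lo) / (c_hi - c_lo)
    return StyleSpec(area_id=area_id, fill=fill, alpha=alpha)


def styles_for_summaries(summaries: list[AreaSummary],
                         breakpoints: tuple[float, float] = (0.5, 2.0),
                         mapping: tuple[float, float, float] = (0.2, 0.6, 0.1),
                         enabled: bool = True) -> list[StyleSpec]:
    """Per-area colour + opacity for the full summary list."""
    return [
        apply_transparency(
            estimate_color(s.point, breakpoints), s.ppd, mapping,
            enabled=enabled, area_id=s.area_id,
        )
        for s in summaries
    ]


def overview_spec(summaries: list[AreaSummary], group_assignment: dict[str, str],
                  mode: str = "percentage",
                  breakpoints: tuple[float, float] = (0.5, 2.0),
                  n_classes: int = 5) -> OverviewSpec:
    """Group-level overview: colour-class bins or boxplot five-number summary."""
    if mode not in ("percentage", "count", "boxplot"):
        raise ValueError(f"unknown mode {mode!r}")
    missing = [s.area_id for s in summaries if s.area_id not in group_assignment]
    if missing:
        raise ValidationError(f"areas without a group assignment: {missing[:5]}")
    groups = tuple(dict.fromkeys(group_assignment.values()))
    edges, colors = color_class_edges(breakpoints, n_classes)
    by_group: dict[str, list[float]] = {g: [] for g in groups}
    for s in summaries:
        by_group[group_assignment[s.area_id]].append(s.point)

    values: dict[str, np.ndarray] = {}
    all_points = [s.point for s in summaries]
    for g in groups:
        pts = np.asarray(by_group[g], dtype=float)
        if mode == "boxplot":
            if pts.size:
                values[g] = np.asarray([
                    pts.min(),
                    np.quantile(pts, 0.25),
                    np.median(pts),
                    np.quantile(pts, 0.75),
                    pts.max(),
                ])
            else:
                values[g] = np.full(5, np.nan)
        else:
            counts, _ = np.histogram(pts, bins=np.asarray(edges))
            if mode == "count":
                values[g] = counts.astype(float)
            else:
                total = counts.sum()
                values[g] = (100.0 * counts / total if total
                             else np.zeros(len(counts)))
    if mode == "boxplot":
        bounds = (float(min(all_points)), float(max(all_points))) if all_points else (0.0, 1.0)
    elif mode == "count":
        bounds = (0.0, float(max((v.max() for v in values.values()), default=1.0)))
    else:
        bounds = (0.0, 100.0)
    return OverviewSpec(
        groups=groups, mode=mode, values=values,
        class_edges=edges, class_colors=colors, axis_bounds=bounds,
    )


# ---------------------------------------------------------------------------
# reference renderers (presentation only; every number comes from the spec)
# ---------------------------------------------------------------------------

def render(spec, path, polygons: dict | None = None) -> str:
    """Render a spec object to a PNG/SVG file and return the path."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(spec, WavePlotSpec):
        fig = _render_wave(spec, plt)
    elif isinstance(spec, OverviewSpec):
        fig = _render_overview(spec, plt)
    elif isinstance(spec, (list, tuple)) and spec and isinstance(spec[0], VPlotPoint):
        fig = _render_vplot(spec, plt)
    elif isinstance(spec, (list, tuple)) and spec and isinstance(spec[0], StyleSpec):
        if polygons is None:
            raise ValidationError("choropleth rendering requires polygons")
        fig = _render_choropleth(spec, polygons, plt)
    else:
        raise ValidationError(f"cannot render object of type {type(spec).__name__}")
    fig.savefig(path)
    plt.close(fig)
    return str(path)


def _render_wave(spec: WavePlotSpec, plt):
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.fill_between(spec.log_grid, spec.density, color="#7FB3D5", alpha=0.8)
    ax.hlines(0, np.log(spec.ci80[0]), np.log(spec.ci80[1]), lw=3, color="k")
    ax.hlines(0, np.log(spec.ci60[0]), np.log(spec.ci60[1]), lw=7, color="k")
    ax.plot(np.log(spec.point), 0, "o", ms=9, color="w", mec="k", zorder=5)
    ax.set_xticks([p for p, _ in spec.ticks])
    ax.set_xticklabels([lab for _, lab in spec.ticks])
    ax.set_xlabel("ratio vs national average")
    ax.set_ylabel("density (log scale)")
    ax.set_title(spec.area_id)
    return fig


def _render_vplot(points, plt):
    fig, ax = plt.subplots(figsize=(5, 4))
    xs = [np.log(p.x) for p in points]
    ys = [p.y for p in points]
    cols = [(p.style.fill if p.style else "#444444") for p in points]
    alphas = [(p.style.alpha if p.style else 1.0) for p in points]
    for x, y, c, a in zip(xs, ys, cols, alphas):
        ax.plot(x, y, "o", color=c, alpha=a, ms=4)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_ylim(0.48, 1.02)
    ax.set_xlabel("estimate vs national average (log axis)")
    ax.set_ylabel("confidence of difference")
    return fig


def _render_overview(spec: OverviewSpec, plt):
    fig, ax = plt.subplots(figsize=(6, 1 + 0.6 * len(spec.groups)))
    ypos = np.arange(len(spec.groups))[::-1]
    if spec.mode == "boxplot":
        for y, g in zip(ypos, spec.groups):
            mn, q1, med, q3, mx = spec.values[g]
            ax.plot([mn, mx], [y, y], color="k", lw=1)
            ax.add_patch(plt.Rectangle((q1, y - 0.2), q3 - q1, 0.4,
                                       fc="#FDAE61", ec="k"))
            ax.plot([med, med], [y - 0.2, y + 0.2], color="k", lw=2)
    else:
        for y, g in zip(ypos, spec.groups):
            left = 0.0
            for v, c in zip(spec.values[g], spec.class_colors):
                ax.barh(y, v, left=left, color=c, edgecolor="k", height=0.6)
                left += v
    ax.set_yticks(ypos)
    ax.set_yticklabels(spec.groups)
    ax.set_xlim(spec.axis_bounds)
    ax.set_xlabel({"percentage": "% of areas", "count": "areas",
                   "boxplot": "estimate"}[spec.mode])
    return fig


def _render_choropleth(styles, polygons, plt):
    from matplotlib.patches import Polygon as MplPolygon

    missing = [s.area_id for s in styles if s.area_id not in polygons]
    if missing:
        raise ValidationError(f"no polygon for styled areas: {missing[:5]}")
    fig, ax = plt.subplots(figsize=(6, 6))
    for s in styles:
        geom = polygons[s.area_id]
        polys = getattr(geom, "geoms", [geom])
        for poly in polys:
            xy = np.asarray(poly.exterior.coords)
            ax.add_patch(MplPolygon(xy, closed=True,
                                    facecolor=s.composited_fill(),
                                    edgecolor="#666666", lw=0.4))
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_axis_off()
    return fig
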