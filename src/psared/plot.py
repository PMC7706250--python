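"""Figure composition and the end-to-end PSA-ReD pipeline.

A PSA-ReD figure layers a color-graded relative-density image (cool hues at
low density, warm at high) under cumulative-probability contour lines, with
optional willingness-to-pay threshold lines, a base-case marker and the PSA
mean marker.  ``run_pipeline`` chains the whole computation — read, select
bandwidths, grid, KDE, normalize, cumulative map, contours, render — and
returns a machine-readable summary alongside the figure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LinearSegmentedColormap

from .density import (
    GridSpec,
    evaluate_kde,
    make_grid,
    normalize_density,
    select_bandwidths,
    NormalizedGrid,
)
from .hdr import (
    ContourSet,
    contours_to_csv,
    cumulative_map,
    empirical_coverage,
    extract_contours,
)
from .io import PsaSample, RunConfig, read_psa_table

__all__ = [
    "PlotSpec",
    "PipelineError",
    "wtp_polyline",
    "psa_mean",
    "apply_zoom",
    "render_red_plot",
    "run_pipeline",
    "DEFAULT_COLOR_ANCHORS",
]

#: Blue -> green -> yellow -> red over normalized density 0 -> 1.
DEFAULT_COLOR_ANCHORS = (
    (0.0, "#2166ac"),
    (1 / 3, "#1b9e50"),
    (2 / 3, "#ffe04d"),
    (1.0, "#b2182b"),
)


class PipelineError(RuntimeError):
    """Pipeline failure carrying the stage at which it occurred."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class PlotSpec:
    """Rendering configuration for the PSA-ReD figure."""

    color_anchors: tuple = DEFAULT_COLOR_ANCHORS
    contour_color: str = "black"
    contour_width: float = 0.8
    wtp_thresholds: tuple[float, ...] = ()
    base_case: Optional[tuple[float, float]] = None
    show_psa_mean: bool = False
    title: str = ""
    xlabel: str = "Incremental QALYs"
    ylabel: str = "Incremental costs"
    legend_title: str = "Relative density"
    font_family: Optional[str] = None
    font_size: Optional[float] = None
    out_path: str = "psared.png"
    dpi: int = 150

    def __post_init__(self) -> None:
        for lam in self.wtp_thresholds:
            if lam < 0:
                raise ValueError(f"WTP threshold must be >= 0, got {lam}")

    def colormap(self) -> LinearSegmentedColormap:
        return LinearSegmentedColormap.from_list(
            "psared", list(self.color_anchors)
        )


def wtp_polyline(
    lam: float, grid: GridSpec
) -> Optional[tuple[tuple[float, float], tuple[float, float]]]:
    """Segment of the willingness-to-pay line cost = lam * effect.

    The line passes through the origin (standard CE-plane convention) and is
    clipped against the grid extents; returns None when it misses the window.
    """
    if lam < 0:
        raise ValueError(f"WTP slope must be >= 0, got {lam}")
    x0, x1 = grid.x_min, grid.x_max
    y0, y1 = grid.y_min, grid.y_max
    if lam == 0:
        if y0 <= 0 <= y1:
            return ((x0, 0.0), (x1, 0.0))
        return None
    # Parametrize by effect; intersect y = lam*x with the window.
    lo, hi = x0, x1
    lo = max(lo, min(y0, y1) / lam)
    hi = min(hi, max(y0, y1) / lam)
    if lo >= hi:
        return None
    return ((lo, lam * lo), (hi, lam * hi))


def psa_mean(sample: PsaSample) -> tuple[float, float]:
    """Arithmetic mean of incremental effects and costs."""
    return float(sample.effects.mean()), float(sample.costs.mean())


def apply_zoom(
    sample: PsaSample, window: tuple[float, float, float, float]
) -> PsaSample:
    """Subsample inside an (x0, x1, y0, y1) window, boundaries included.

    Downstream KDE, cumulative map and contours are recomputed from scratch
    on the subsample, producing a new plot of that area rather than a crop.
    """
    x0, x1, y0, y1 = (float(v) for v in window)
    keep = (
        (sample.effects >= x0) & (sample.effects <= x1)
        & (sample.costs >= y0) & (sample.costs <= y1)
    )
    n = int(keep.sum())
    if n < 2:
        raise ValueError(
            f"zoom window contains {n} point(s); at least 2 are required"
        )
    return PsaSample(effects=sample.effects[keep], costs=sample.costs[keep])


def render_red_plot(
    ng: NormalizedGrid,
    cs: ContourSet,
    spec: PlotSpec,
    sample: Optional[PsaSample] = None,
) -> Path:
    """Write the PSA-ReD figure (density layer + contours + decorations).

    The axes span exactly the grid extents.  Returns the output path.
    """
    gs = ng.grid
    rc: dict = {}
    if spec.font_family:
        rc["font.family"] = spec.font_family
    if spec.font_size:
        rc["font.size"] = spec.font_size

    with plt.rc_context(rc):
        fig, ax = plt.subplots(figsize=(7, 5.6))
        im = ax.imshow(
            ng.values,
            origin="lower",
            extent=(gs.x_min, gs.x_max, gs.y_min, gs.y_max),
            aspect="auto",
            cmap=spec.colormap(),
            vmin=0.0,
            vmax=1.0,
            interpolation="nearest",
        )
        cbar = fig.colorbar(im, ax=ax)
        cbar.set_label(spec.legend_title)

        for level in cs.levels:
            for poly in cs.lines[level]:
                ax.plot(
                    poly.vertices[:, 0], poly.vertices[:, 1],
                    color=spec.contour_color, linewidth=spec.contour_width,
                )
            if cs.lines[level]:
                # Label at the topmost vertex of the level's first polyline.
                poly = max(
                    cs.lines[level], key=lambda p: p.vertices[:, 1].max()
                )
                top = poly.vertices[np.argmax(poly.vertices[:, 1])]
                ax.annotate(
                    f"{level:g}", xy=(top[0], top[1]),
                    ha="center", va="bottom", fontsize=8,
                    color=spec.contour_color,
                )

        for lam in spec.wtp_thresholds:
            seg = wtp_polyline(lam, gs)
            if seg is not None:
                (ax0, ay0), (ax1, ay1) = seg
                ax.plot(
                    [ax0, ax1], [ay0, ay1],
                    linestyle="--", color="dimgray", linewidth=1.0,
                )
                ax.annotate(
                    f"λ={lam:g}", xy=(ax1, ay1),
                    ha="right", va="bottom", fontsize=8, color="dimgray",
                )

        if spec.base_case is not None:
            ax.plot(
                *spec.base_case, marker="D", markersize=7,
                markerfacecolor="white", markeredgecolor="black",
                linestyle="none", label="Base case",
            )
        if spec.show_psa_mean and sample is not None:
            ax.plot(
                *psa_mean(sample), marker="X", markersize=8,
                markerfacecolor="black", markeredgecolor="white",
                linestyle="none", label="PSA mean",
            )
        if spec.base_case is not None or (spec.show_psa_mean and sample):
            ax.legend(loc="upper left", fontsize=8)

        ax.set_xlim(gs.x_min, gs.x_max)
        ax.set_ylim(gs.y_min, gs.y_max)
        ax.set_xlabel(spec.xlabel)
        ax.set_ylabel(spec.ylabel)
        if spec.title:
            ax.set_title(spec.title)

        out = Path(spec.out_path)
        fmt = out.suffix.lstrip(".").lower() or "png"
        save_kwargs = {"dpi": spec.dpi, "format": fmt}
        if fmt == "png":
            save_kwargs["metadata"] = {"Software": "psared"}
        elif fmt == "svg":
            save_kwargs["metadata"] = {"Date": None}
        try:
            fig.savefig(out, **save_kwargs)
        finally:
            plt.close(fig)
    return out


def run_pipeline(
    input_path: str | Path,
    config: Optional[RunConfig] = None,
    plot_spec: Optional[PlotSpec] = None,
    contour_csv: Optional[str | Path] = None,
    summary_path: Optional[str | Path] = None,
) -> dict:
    """Run the full PSA-ReD computation and render the figure.

    Stages: read -> (zoom) -> bandwidths -> grid -> KDE -> normalize ->
    cumulative map -> contours -> render.  Returns a summary dict (also
    written as JSON if ``summary_path`` is given) with n, bandwidths, grid
    extents, per-level empirical coverage, PSA mean and the base case.
    Errors carry the stage at which they occurred.
    """
    config = config or RunConfig()
    plot_spec = plot_spec or PlotSpec(
        wtp_thresholds=config.wtp_thresholds,
        base_case=config.base_case,
        title=config.title,
        xlabel=config.xlabel,
        ylabel=config.ylabel,
        legend_title=config.legend_title,
        font_family=config.font_family,
        font_size=config.font_size,
    )

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - re-tagged with stage
            raise PipelineError(name, str(exc)) from exc

    sample = stage("read", read_psa_table, input_path)
    if config.zoom_window is not None:
        sample = stage("zoom", apply_zoom, sample, config.zoom_window)

    bw = stage("bandwidth", select_bandwidths, sample)
    grid = stage("grid", make_grid, sample, config.n_bins, config.zoom_window)
    dg = stage("kde", evaluate_kde, sample, grid, bw)
    ng = stage("normalize", normalize_density, dg)
    cg = stage("cumulative", cumulative_map, dg)
    cs = stage("contours", extract_contours, cg, config.contour_levels)

    coverage = {
        str(lv): empirical_coverage(sample, cg, lv)
        for lv in config.contour_levels
    }
    summary = {
        "n_iterations": sample.n_iterations,
        "bandwidth_x": bw.h_x,
        "bandwidth_y": bw.h_y,
        "grid_extents": {
            "x_min": grid.x_min, "x_max": grid.x_max,
            "y_min": grid.y_min, "y_max": grid.y_max,
        },
        "n_bins": config.n_bins,
        "contour_levels": list(config.contour_levels),
        "empirical_coverage": coverage,
        "psa_mean": list(psa_mean(sample)),
        "base_case": list(config.base_case) if config.base_case else None,
    }

    image = stage("render", render_red_plot, ng, cs, plot_spec, sample)
    summary["image"] = str(image)

    if contour_csv is not None:
        summary["contour_csv"] = str(stage("export", contours_to_csv, cs, contour_csv))
    if summary_path is not None:
        Path(summary_path).write_text(json.dumps(summary, indent=2))
        summary["summary_json"] = str(summary_path)
    return summary
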