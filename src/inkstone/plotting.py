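"""Penscript image export and per-stroke diagnostic panels.

``render_penscript`` draws one trial's ink as connected polylines and saves
it under the ``<participant>_<item>_<char>.png`` naming convention (an
``ascii_names`` fallback substitutes the item number for filesystems that
reject non-ASCII characters).  ``render_stroke_panels`` produces one panel
per stroke, in production order, highlighting the current stroke over the
prior ink and hover trace and annotating its metrics:

* ``Abs RT`` — stroke onset relative to the audio offset of the prompt,
* ``Avg Pressure`` — mean pen pressure of the stroke,
* ``S length`` — the stroke's trajectory length,
* ``Prev Dist`` — straight-line gap from the previous stroke's end point,
* ``Start, RT`` — the inter-stroke writing latency,
* ``End, Dur`` — the stroke's writing duration.

The y axis is flipped so ink appears as written (device y grows downward).
Rendering is a pure output stage: it never mutates metric tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .segmentation import SegmentTree

__all__ = ["RenderSpec", "penscript_filename", "render_penscript",
           "render_stroke_panels"]

_PNG_METADATA = {"Software": "inkstone"}  # fixed so repeat renders are byte-identical


@dataclass(frozen=True)
class RenderSpec:
    out_dir: str | Path = "."
    fmt: str = "png"  # "png" or "svg"
    image_size: float = 3.0  # inches, square per panel
    dpi: int = 100
    ink_color: str = "black"
    current_color: str = "purple"
    hover_color: str = "0.6"
    distance_color: str = "green"
    line_width: float = 1.5
    show_hover: bool = True
    annotate: bool = True
    ascii_names: bool = False

    def __post_init__(self):
        if self.image_size <= 0:
            raise ValueError("image_size must be > 0")


def penscript_filename(
    participant_id: int, item_number: int, target_char: str, spec: RenderSpec
) -> str:
    name = str(item_number) if spec.ascii_names else target_char
    return f"{participant_id}_{item_number}_{name}.{spec.fmt}"


def _draw_strokes(ax, strokes, color, lw):
    for s in strokes:
        ax.plot(s.x, s.y, color=color, linewidth=lw, solid_capstyle="round")


def _save(fig, path: Path, spec: RenderSpec) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    kwargs = {"dpi": spec.dpi}
    if spec.fmt == "png":
        kwargs["metadata"] = _PNG_METADATA
    elif spec.fmt == "svg":
        kwargs["metadata"] = {"Date": None}
    fig.savefig(path, **kwargs)
    plt.close(fig)
    return path


def render_penscript(
    tree: SegmentTree,
    participant_id: int,
    item_number: int,
    target_char: str,
    spec: RenderSpec = RenderSpec(),
) -> Path:
    """Export one trial's penscript image; returns the written path.

    A trial without ink produces a blank image annotated ``no ink``.
    """
    out = Path(spec.out_dir) / penscript_filename(
        participant_id, item_number, target_char, spec
    )
    fig, ax = plt.subplots(figsize=(spec.image_size, spec.image_size))
    if tree.strokes:
        _draw_strokes(ax, tree.strokes, spec.ink_color, spec.line_width)
    else:
        ax.text(0.5, 0.5, "no ink", ha="center", va="center",
                transform=ax.transAxes)
    ax.set_aspect("equal", adjustable="datalim")
    ax.invert_yaxis()
    ax.set_axis_off()
    return _save(fig, out, spec)


def render_stroke_panels(
    tree: SegmentTree,
    stroke_table,
    audio_offset_ms: float,
    participant_id: int,
    item_number: int,
    target_char: str,
    spec: RenderSpec = RenderSpec(),
) -> Path:
    """One panel per stroke, each annotated with that stroke's metrics.

    ``stroke_table`` is the stroke-level slice of the trial's metric table
    (``unit_index`` 1..S with ``latency_ms``, ``duration_ms``, ``length``,
    ``pressure``, ``distance``); it must have exactly one row per detected
    stroke.  The annotated numbers come straight from the table so the panels
    always agree with the analysis output.
    """
    n = tree.n_strokes
    if n == 0:
        raise ValueError("cannot render stroke panels for a trial without ink")
    table = stroke_table.sort_values("unit_index").reset_index(drop=True)
    if len(table) != n:
        raise ValueError(
            f"stroke table has {len(table)} rows but the trial has {n} strokes"
        )
    ncols = min(4, n)
    nrows = math.ceil(n / ncols)
    fig, axes = plt.subplots(
        nrows, ncols,
        figsize=(spec.image_size * ncols, spec.image_size * nrows),
        squeeze=False,
    )
    for k in range(nrows * ncols):
        ax = axes[k // ncols][k % ncols]
        if k >= n:
            ax.set_axis_off()
            continue
        stroke = tree.strokes[k]
        row = table.iloc[k]
        if spec.show_hover and tree.hover is not None and len(tree.hover):
            ax.plot(tree.hover["x"], tree.hover["y"], ".",
                    color=spec.hover_color, markersize=2)
        _draw_strokes(ax, tree.strokes[:k], spec.ink_color, spec.line_width)
        _draw_strokes(ax, [stroke], spec.current_color, spec.line_width * 1.5)
        if k > 0:
            prev = tree.strokes[k - 1]
            ax.plot(
                [prev.end_xy[0], stroke.start_xy[0]],
                [prev.end_xy[1], stroke.start_xy[1]],
                color=spec.distance_color, linestyle="--", linewidth=1.0,
            )
        if spec.annotate:
            abs_rt = stroke.onset_t - audio_offset_ms
            lines = [
                f"Abs RT: {abs_rt:.0f} ms",
                f"Avg Pressure: {row['pressure']:.0f}",
                f"S length: {row['length']:.2f}",
            ]
            if k > 0:
                lines.append(f"Prev Dist: {row['distance']:.2f}")
                lines.append(f"Start, RT: {row['latency_ms']:.0f} ms")
            lines.append(f"End, Dur: {row['duration_ms']:.0f} ms")
            ax.text(
                0.02, 0.98, "\n".join(lines), transform=ax.transAxes,
                va="top", ha="left", fontsize=7,
            )
        ax.set_title(f"stroke {k + 1}", fontsize=8)
        ax.set_aspect("equal", adjustable="datalim")
        ax.invert_yaxis()
        ax.set_xticks([])
        ax.set_yticks([])
    name = penscript_filename(participant_id, item_number, target_char, spec)
    out = Path(spec.out_dir) / f"panels_{name}"
    fig.tight_layout()
    return _save(fig, out, spec)
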