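"""Deterministic static rendering of the region view and breakpoint panels.

Replaces an interactive multi-track viewer with reproducible images: a
region figure stacking depth, logR, BAF, alignment and annotation tracks
between the called segment boundaries, and a pair of breakpoint panels
showing the +/-100 bp read pileup around each boundary with reads colored
by their signature (split reads gray with the soft-clipped part in yellow;
discordant pairs purple/red/blue/orange by category).  Rendering is pure:
identical inputs give byte-identical files, and no session state is
touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import matplotlib
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.backends.backend_svg import FigureCanvasSVG
from matplotlib.figure import Figure
from matplotlib.patches import Rectangle
import numpy as np

from . import evidence as ev
from .evidence import Breakpoint, InsertModel, classify_read, clip_boundaries
from .segio import GAIN, LOSS, NEUTRAL, Segment, SegmentIndex
from .tracks import BafPoints, DepthTrack, LogRTrack

matplotlib.rcParams["svg.hashsalt"] = "cnvcurate"

# Display conventions: loss blue, gain red, neutral black; tumor depth red,
# normal depth green; BAF red dots; transcripts blue; split-read clip yellow
# on a gray body; pair categories purple/red/blue/orange.
DEFAULT_COLORS = {
    GAIN: "red",
    LOSS: "blue",
    NEUTRAL: "black",
    "tumor_depth": "red",
    "normal_depth": "green",
    "logr_pos": "red",
    "logr_neg": "blue",
    "baf": "red",
    "annotation": "blue",
    "read_body": "0.6",
    "clip": "gold",
    ev.MATE_UNMAPPED: "purple",
    ev.MATE_DIFF_CHROM: "red",
    ev.MATE_DIFF_STRAND: "blue",
    ev.MATE_DISCORDANT_DISTANCE: "orange",
    ev.CONCORDANT: "0.6",
}


@dataclass
class RenderSpec:
    """What to draw and where to write it."""

    chrom: str
    start: int
    end: int
    path: str
    show_depth: bool = True
    show_logr: bool = True
    show_baf: bool = True
    show_alignments: bool = True
    show_annotation: bool = True
    colors: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))
    width: float = 10.0
    track_height: float = 1.6
    dpi: int = 100
    max_read_rows: int = 60

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("render window must be non-empty")


def _save(fig: Figure, path, dpi: int) -> None:
    path = Path(path)
    if path.suffix.lower() == ".svg":
        FigureCanvasSVG(fig)
        fig.savefig(path, format="svg", metadata={"Date": None})
    else:
        FigureCanvasAgg(fig)
        fig.savefig(path, format="png", dpi=dpi)


def _stack_reads(records: Sequence) -> list[int]:
    """Greedy first-free-row layout over stable input ordering."""
    row_ends: list[int] = []
    rows = []
    for rec in records:
        for i, end in enumerate(row_ends):
            if rec.reference_start > end + 2:
                row_ends[i] = rec.reference_end
                rows.append(i)
                break
        else:
            row_ends.append(rec.reference_end)
            rows.append(len(row_ends) - 1)
    return rows


def _draw_reads(ax, records, insert_model: InsertModel, colors: dict,
                max_rows: int, min_clip: int = ev.DEFAULT_MIN_CLIP) -> None:
    records = sorted(records, key=lambda r: (r.reference_start, r.query_name))
    # wide windows can hold tens of thousands of reads; the stacked rows are
    # capped anyway, so drawing stops after a deterministic prefix
    records = records[:20 * max_rows]
    rows = _stack_reads(records)
    for rec, row in zip(records, rows):
        if row >= max_rows:
            continue
        sig = classify_read(rec, insert_model, min_clip=min_clip)
        if sig.clip_status == ev.SPLIT_READ:
            body = colors["read_body"]
        else:
            body = colors[sig.pair_status]
        y = -row
        ax.add_patch(Rectangle((rec.reference_start, y - 0.35),
                               rec.reference_end - rec.reference_start, 0.7,
                               facecolor=body, edgecolor="none"))
        if sig.clip_status == ev.SPLIT_READ:
            cig = rec.cigartuples or []
            if cig and cig[0][0] == 4 and cig[0][1] >= min_clip:
                ax.add_patch(Rectangle((rec.reference_start - cig[0][1], y - 0.35),
                                       cig[0][1], 0.7,
                                       facecolor=colors["clip"], edgecolor="none"))
            if cig and cig[-1][0] == 4 and cig[-1][1] >= min_clip:
                ax.add_patch(Rectangle((rec.reference_end, y - 0.35),
                                       cig[-1][1], 0.7,
                                       facecolor=colors["clip"], edgecolor="none"))
    ax.set_ylim(-min(max(rows, default=0), max_rows) - 1, 1)
    ax.set_yticks([])


def read_annotation(path) -> list[tuple[int, int, str]]:
    """Load transcript intervals from BED or GFF3, dispatched by extension.

    Returns 0-based half-open (start, end, name) tuples.
    """
    import pyranges as pr

    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        df = pr.read_gff3(str(path)).df
        names = df.get("ID", df.get("Name"))
        if names is None:
            names = df["Feature"]
        return [(int(s), int(e), str(n))
                for s, e, n in zip(df["Start"], df["End"], names)]
    df = pr.read_bed(str(path)).df
    names = df["Name"] if "Name" in df else df.index.astype(str)
    return [(int(s), int(e), str(n))
            for s, e, n in zip(df["Start"], df["End"], names)]


def render_region(spec: RenderSpec, index: Optional[SegmentIndex] = None,
                  tumor_depth: Optional[DepthTrack] = None,
                  normal_depth: Optional[DepthTrack] = None,
                  logr: Optional[LogRTrack] = None,
                  baf: Optional[BafPoints] = None,
                  tumor_bam=None, normal_bam=None,
                  annotation: Optional[Sequence[tuple[int, int, str]]] = None,
                  insert_model: Optional[InsertModel] = None) -> Path:
    """Render the multi-track region view to ``spec.path``.

    Tracks that are toggled off or not provided are omitted.  Called
    segment boundaries inside the window are drawn as vertical guide lines
    colored by the segment state.
    """
    colors = spec.colors
    panels: list[str] = []
    if spec.show_depth and (tumor_depth is not None or normal_depth is not None):
        panels.append("depth")
    if spec.show_logr and logr is not None:
        panels.append("logr")
    if spec.show_baf and baf is not None:
        panels.append("baf")
    if spec.show_alignments and tumor_bam is not None:
        panels.append("tumor_reads")
    if spec.show_alignments and normal_bam is not None:
        panels.append("normal_reads")
    if spec.show_annotation and annotation:
        panels.append("annotation")
    n = max(len(panels), 1)
    fig = Figure(figsize=(spec.width, spec.track_height * n + 0.8))
    axes = fig.subplots(n, 1, sharex=True, squeeze=False)[:, 0]
    if not panels:
        axes[0].set_yticks([])

    if insert_model is None and (tumor_bam is not None or normal_bam is not None):
        insert_model = InsertModel.estimate(tumor_bam or normal_bam)

    for ax, panel in zip(axes, panels):
        if panel == "depth":
            for track, key in ((tumor_depth, "tumor_depth"),
                               (normal_depth, "normal_depth")):
                if track is not None:
                    ax.plot(track.bin_starts + track.bin_size / 2, track.values,
                            color=colors[key], linewidth=0.8, label=key)
            ax.set_ylabel("depth", fontsize=8)
            ax.legend(fontsize=6, loc="upper right")
        elif panel == "logr":
            mid = logr.bin_starts + logr.bin_size / 2
            vals = logr.values
            pos = np.where(vals >= 0, vals, np.nan)
            neg = np.where(vals < 0, vals, np.nan)
            ax.plot(mid, pos, ".", color=colors["logr_pos"], markersize=1.5)
            ax.plot(mid, neg, ".", color=colors["logr_neg"], markersize=1.5)
            ax.axhline(0.0, color="0.7", linewidth=0.5)
            ax.set_ylabel("logR", fontsize=8)
        elif panel == "baf":
            ax.plot(baf.positions, baf.values, ".", color=colors["baf"],
                    markersize=2)
            ax.set_ylim(-0.05, 1.05)
            ax.set_ylabel("BAF", fontsize=8)
        elif panel in ("tumor_reads", "normal_reads"):
            bam_path = tumor_bam if panel == "tumor_reads" else normal_bam
            center = (spec.start + spec.end) // 2
            half = (spec.end - spec.start) // 2
            records = ev.extract_window(
                bam_path, Breakpoint(spec.chrom, center), half_width=half)
            _draw_reads(ax, records, insert_model, colors, spec.max_read_rows)
            frame = "red" if panel == "tumor_reads" else "green"
            for side in ax.spines.values():
                side.set_color(frame)
            ax.set_ylabel(panel.split("_")[0], fontsize=8)
        elif panel == "annotation":
            for i, (a_start, a_end, name) in enumerate(annotation):
                if a_end <= spec.start or a_start >= spec.end:
                    continue
                ax.add_patch(Rectangle((a_start, -0.3 - (i % 3)), a_end - a_start,
                                       0.6, facecolor=colors["annotation"]))
            ax.set_ylim(-3.5, 1)
            ax.set_yticks([])
            ax.set_ylabel("genes", fontsize=8)

    if index is not None:
        for seg in index.segments(spec.chrom):
            for ax in axes:
                for bound in (seg.start, seg.end):
                    if spec.start <= bound < spec.end:
                        ax.axvline(bound, color=colors[seg.state],
                                   linewidth=0.9, alpha=0.7)

    axes[-1].set_xlim(spec.start, spec.end)
    axes[-1].set_xlabel(f"{spec.chrom} position (bp)", fontsize=8)
    fig.suptitle(f"{spec.chrom}:{spec.start}-{spec.end}", fontsize=9)
    _save(fig, spec.path, spec.dpi)
    return Path(spec.path)


def render_breakpoint_panels(segment: Segment, tumor_bam, normal_bam,
                             out_prefix, half_width: int = ev.DEFAULT_HALF_WIDTH,
                             insert_model: Optional[InsertModel] = None,
                             colors: Optional[dict] = None,
                             fmt: str = "png", dpi: int = 100,
                             max_read_rows: int = 60) -> tuple[Path, Path]:
    """Render the two +/-``half_width`` bp breakpoint pileup panels.

    Each panel stacks the tumor pileup (red frame) over the normal pileup
    (green frame), with a vertical black line at the exact breakpoint.
    """
    colors = colors or DEFAULT_COLORS
    if insert_model is None:
        insert_model = InsertModel.estimate(tumor_bam)
    outputs = []
    for side, pos in (("left", segment.start), ("right", segment.end)):
        bp = Breakpoint(segment.chrom, pos, side=side)
        fig = Figure(figsize=(6.0, 5.0))
        axes = fig.subplots(2, 1, sharex=True)
        for ax, bam_path, frame in ((axes[0], tumor_bam, "red"),
                                    (axes[1], normal_bam, "green")):
            records = ev.extract_window(bam_path, bp, half_width=half_width)
            _draw_reads(ax, records, insert_model, colors, max_read_rows)
            ax.axvline(pos, color="black", linewidth=1.2)
            for spine in ax.spines.values():
                spine.set_color(frame)
        axes[0].set_title(
            f"{segment.chrom}:{pos} ({side} breakpoint, +/-{half_width} bp)",
            fontsize=9)
        axes[1].set_xlim(pos - half_width, pos + half_width + 1)
        axes[1].set_xlabel("position (bp)", fontsize=8)
        out = Path(f"{out_prefix}_{side}.{fmt}")
        _save(fig, out, dpi)
        outputs.append(out)
    return outputs[0], outputs[1]
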