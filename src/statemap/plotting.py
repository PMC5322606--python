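"""Painted-phylogram rendering of target summaries.

Each branch of the target tree is drawn as contiguous horizontal segments
whose length shares equal the posterior bin masses (plus a gray share for the
posterior mass of trees lacking the branch).  SVG output is written directly
(every segment carries its clade and bin as attributes, so the figure is
machine-checkable); PNG and PDF are rendered from the same segment geometry
with matplotlib.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
from matplotlib.colors import LinearSegmentedColormap, to_hex

from .summarize import N_BINS, TargetSummary
from .trees import Tree

__all__ = ["PaintSpec", "branch_segments", "paint_tree", "dwelling_colors",
           "transition_colors"]


def dwelling_colors() -> list[str]:
    """21 tones for dwelling fractions: blue (0%) -> green (50%) -> red (100%)."""
    cmap = LinearSegmentedColormap.from_list("dwell", ["#2040d0", "#20a020", "#e01010"])
    return [to_hex(cmap(k / (N_BINS - 1))) for k in range(N_BINS)]


def transition_colors() -> list[str]:
    """Sequential 21-step ramp for the adaptive 0-to-max transition scale."""
    cmap = LinearSegmentedColormap.from_list("trans", ["#f2e7c9", "#1b7837", "#00441b"])
    return [to_hex(cmap(k / (N_BINS - 1))) for k in range(N_BINS)]


@dataclass
class PaintSpec:
    """Colors and layout options for the painted phylogram."""

    colors: list[str] = field(default_factory=dwelling_colors)
    gray: str = "#9a9a9a"
    line_width: float = 3.0
    connector_color: str = "#404040"
    width: float = 800.0
    height: float | None = None
    show_tip_labels: bool = True
    legend: bool = True

    def __post_init__(self) -> None:
        if len(self.colors) != N_BINS:
            raise ValueError(f"need exactly {N_BINS} colors")

    @classmethod
    def for_quantity(cls, quantity: str, **kw) -> "PaintSpec":
        colors = dwelling_colors() if quantity == "dwelling_fraction" else transition_colors()
        return cls(colors=colors, **kw)


def _layout(tree: Tree) -> tuple[np.ndarray, np.ndarray]:
    """Rectangular phylogram coordinates: x = root distance, y = tip rank."""
    x = tree.node_depths()
    y = np.zeros(tree.n_nodes)
    rank = 0
    for v in tree.postorder:
        if not tree.children[v]:
            y[v] = rank
            rank += 1
        else:
            y[v] = np.mean([y[c] for c in tree.children[v]])
    return x, y


def branch_segments(
    target: Tree, summary: TargetSummary, spec: PaintSpec
) -> dict[int, list[tuple[float, float, str, int]]]:
    """Per branch (keyed by child node): list of (share_start, share_end,
    color, bin) tuples along the branch, root side first.

    The gray share (1 - matched_fraction, when not renormalized) comes first,
    then colored segments in order of decreasing bin mass (ties broken by bin
    index), so output is deterministic.  Shares sum to 1 for every branch.
    """
    out: dict[int, list[tuple[float, float, str, int]]] = {}
    for i, c in enumerate(summary.branch_children):
        masses = summary.distributions[i]
        total = masses.sum()
        gray_share = max(0.0, 1.0 - total)
        segs: list[tuple[float, float, str, int]] = []
        pos = 0.0
        if gray_share > 1e-12:
            segs.append((0.0, gray_share, spec.gray, -1))
            pos = gray_share
        order = sorted(range(N_BINS), key=lambda k: (-masses[k], k))
        for k in order:
            if masses[k] <= 1e-12:
                continue
            segs.append((pos, pos + masses[k], spec.colors[k], k))
            pos += masses[k]
        if segs:
            s0, _, col, b = segs[-1]
            segs[-1] = (s0, 1.0, col, b)  # absorb float dust at the tip end
        else:
            segs = [(0.0, 1.0, spec.gray, -1)]
        out[int(c)] = segs
    return out


def _figure_geometry(target: Tree, spec: PaintSpec):
    x, y = _layout(target)
    n = target.n_tips
    height = spec.height if spec.height is not None else max(200.0, 16.0 * n + 80.0)
    margin = 40.0
    label_space = 120.0 if spec.show_tip_labels else 10.0
    xmax = float(x.max()) or 1.0
    sx = (spec.width - margin - label_space) / xmax
    sy = (height - 2 * margin - (60.0 if spec.legend else 0.0)) / max(n - 1, 1)
    def X(val: float) -> float:
        return margin + val * sx
    def Y(val: float) -> float:
        return margin + val * sy
    return x, y, X, Y, height


def paint_tree(
    target: Tree,
    summary: TargetSummary,
    spec: PaintSpec | None = None,
    out: str | Path = "tree.svg",
    format: str | None = None,
) -> Path:
    """Render the painted phylogram to SVG, PNG or PDF.

    Writes a sidecar ``<out>.legend.json`` recording the exact bin-to-color
    mapping, the quantity, the state and the adaptive scale maximum.
    """
    out = Path(out)
    if format is None:
        format = out.suffix.lstrip(".").lower() or "svg"
    if format not in ("svg", "png", "pdf"):
        raise ValueError(f"unknown figure format {format!r}")
    if spec is None:
        spec = PaintSpec.for_quantity(summary.quantity)
    segs = branch_segments(target, summary, spec)
    if format == "svg":
        _write_svg(target, summary, spec, segs, out)
    else:
        _write_matplotlib(target, summary, spec, segs, out, format)
    legend = {
        "quantity": summary.quantity,
        "state": summary.state,
        "scale_max": summary.scale_max,
        "n_trees": summary.n_trees,
        "renormalized": summary.renormalized,
        "gray_color": spec.gray,
        "bins": [
            {
                "bin": k,
                "color": spec.colors[k],
                "label": (
                    f"{5 * k}%" if summary.quantity == "dwelling_fraction"
                    else f"{summary.scale_max * k / (N_BINS - 1):.3g}"
                ),
            }
            for k in range(N_BINS)
        ],
    }
    out.with_suffix(out.suffix + ".legend.json").write_text(
        json.dumps(legend, indent=1)
    )
    return out


def _write_svg(target, summary, spec, segs, out: Path) -> None:
    x, y, X, Y, height = _figure_geometry(target, spec)
    lines: list[str] = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{spec.width:.0f}" '
        f'height="{height:.0f}" viewBox="0 0 {spec.width:.0f} {height:.0f}">',
        '<rect width="100%" height="100%" fill="white"/>',
    ]
    for v in target.postorder:
        if v == target.root:
            continue
        p = target.parent[v]
        x0, x1 = X(x[p]), X(x[v])
        yy = Y(y[v])
        # vertical connector from the parent's y to this branch
        lines.append(
            f'<line class="connector" x1="{x0:.3f}" y1="{Y(y[p]):.3f}" '
            f'x2="{x0:.3f}" y2="{yy:.3f}" stroke="{spec.connector_color}" '
            f'stroke-width="1.0"/>'
        )
        clade = "|".join(sorted(summary.clades.get(int(v), frozenset())))
        for s0, s1, color, b in segs.get(int(v), [(0.0, 1.0, spec.gray, -1)]):
            xa = x0 + (x1 - x0) * s0
            xb = x0 + (x1 - x0) * s1
            lines.append(
                f'<line class="branchseg" data-clade="{escape(clade)}" '
                f'data-bin="{b}" data-share="{s1 - s0:.6f}" '
                f'x1="{xa:.3f}" y1="{yy:.3f}" x2="{xb:.3f}" y2="{yy:.3f}" '
                f'stroke="{color}" stroke-width="{spec.line_width:.1f}"/>'
            )
    if spec.show_tip_labels:
        for v in target.tip_ids:
            lines.append(
                f'<text x="{X(x[v]) + 5:.3f}" y="{Y(y[v]) + 4:.3f}" '
                f'font-size="10" font-family="sans-serif">'
                f"{escape(target.labels[v])}</text>"
            )
    if spec.legend:
        ly = height - 45.0
        step = (spec.width - 80.0) / N_BINS
        for k in range(N_BINS):
            lx = 40.0 + k * step
            lines.append(
                f'<rect class="legend" x="{lx:.1f}" y="{ly:.1f}" '
                f'width="{step:.1f}" height="12" fill="{spec.colors[k]}"/>'
            )
            if k % 4 == 0:
                label = (
                    f"{5 * k}%" if summary.quantity == "dwelling_fraction"
                    else f"{summary.scale_max * k / (N_BINS - 1):.3g}"
                )
                lines.append(
                    f'<text x="{lx:.1f}" y="{ly + 26:.1f}" font-size="9" '
                    f'font-family="sans-serif">{label}</text>'
                )
    lines.append("</svg>")
    out.write_text("\n".join(lines))


def _write_matplotlib(target, summary, spec, segs, out: Path, format: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x, y, _, _, _ = _figure_geometry(target, spec)
    fig, ax = plt.subplots(figsize=(spec.width / 100.0, max(3.0, target.n_tips * 0.18)))
    for v in target.postorder:
        if v == target.root:
            continue
        p = target.parent[v]
        ax.plot([x[p], x[p]], [y[p], y[v]], color=spec.connector_color, lw=0.8)
        for s0, s1, color, _b in segs.get(int(v), []):
            xa = x[p] + (x[v] - x[p]) * s0
            xb = x[p] + (x[v] - x[p]) * s1
            ax.plot([xa, xb], [y[v], y[v]], color=color, lw=spec.line_width,
                    solid_capstyle="butt")
    if spec.show_tip_labels:
        for v in target.tip_ids:
            ax.text(x[v] * 1.01, y[v], target.labels[v], va="center", fontsize=7)
    ax.set_ylim(-1, target.n_tips)
    ax.invert_yaxis()
    ax.axis("off")
    if spec.legend:
        from matplotlib.patches import Patch
        handles = [
            Patch(color=spec.colors[k], label=f"{5 * k}%")
            for k in range(0, N_BINS, 5)
        ] + [Patch(color=spec.gray, label="unmatched")]
        ax.legend(handles=handles, loc="lower left", fontsize=6, ncol=6,
                  frameon=False)
    fig.savefig(out, format=format, dpi=150, bbox_inches="tight")
    plt.close(fig)
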