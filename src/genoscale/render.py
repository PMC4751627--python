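"""Static image export: orthographic projections of a structure or selection.

A deliberately minimal stand-in for interactive 3D viewing: units are
projected orthographically onto a coordinate plane, drawn as points (one
color per chromosome) connected in genome order within each chromosome,
and written as PNG or SVG.  SVG output is byte-deterministic for identical
input and parameters.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .core import Unit

__all__ = ["render_static", "PROJECTIONS"]

PROJECTIONS = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}

_CMAP = matplotlib.colormaps["tab20"]


def render_static(
    units: list[Unit],
    path: str | Path,
    *,
    projection: str = "xy",
    connect: bool = True,
    point_size: float = 12.0,
    figsize: tuple[float, float] = (6.0, 6.0),
    title: str | None = None,
    legend: bool = True,
) -> Path:
    """Project units onto a plane and write a PNG/SVG scatter/polyline.

    `projection` picks the retained axes ("xy", "xz" or "yz"); format
    follows the path suffix.  Raises on an empty unit list.
    """
    if not units:
        raise ValueError("nothing to render: empty unit list")
    if projection not in PROJECTIONS:
        raise ValueError(f"unknown projection {projection!r} (choose from {sorted(PROJECTIONS)})")
    ai, aj = PROJECTIONS[projection]
    path = Path(path)

    by_chrom: dict[int, list[Unit]] = {}
    for u in sorted(units, key=lambda u: (u.interval.chromosome, u.interval.start_bp)):
        by_chrom.setdefault(u.interval.chromosome, []).append(u)

    # fonttype "none" keeps SVG text as <text>, so marker <use> elements
    # are countable and output stays deterministic and diff-able
    with plt.rc_context({"svg.hashsalt": "genoscale", "svg.fonttype": "none"}):
        fig, ax = plt.subplots(figsize=figsize)
        for chrom, chrom_units in sorted(by_chrom.items()):
            xs = [u.position[ai] for u in chrom_units]
            ys = [u.position[aj] for u in chrom_units]
            color = _CMAP((chrom - 1) % 20)
            if connect and len(xs) > 1:
                ax.plot(xs, ys, "-", color=color, linewidth=0.7, alpha=0.6, zorder=1)
            ax.scatter(xs, ys, s=point_size, color=color, label=f"chr{chrom}", zorder=2)
        ax.set_xlabel(f"{projection[0]} (nm)")
        ax.set_ylabel(f"{projection[1]} (nm)")
        ax.set_aspect("equal", adjustable="datalim")
        if title:
            ax.set_title(title)
        if legend and len(by_chrom) <= 12:
            ax.legend(loc="best", fontsize="small")
        fig.tight_layout()
        fig.savefig(path, metadata={"Date": None} if path.suffix == ".svg" else None)
        plt.close(fig)
    return path
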