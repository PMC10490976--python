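"""Confidence ellipses and double-angle plots for astigmatism (C0, C45) clouds.

A point cloud of astigmatism vectors is summarised by its centroid and a
confidence ellipse from the eigendecomposition of the sample covariance:
half-axes are sqrt(eigenvalue * q) along the eigenvectors, with q the
chi-square quantile at the requested level with 2 degrees of freedom
(q = -2 ln(1 - level); 4.60517 at the default 90%).  An F-based
small-sample factor q = 2 (n-1)/(n-2) F_{2,n-2}(level) is available for
sensitivity analysis.

The double-angle plot is the field's standard display: astigmatism plotted
at twice its axis so that vectors add geometrically, with-the-rule cases on
the positive C0 axis and against-the-rule on the negative, and reference
rings marking clinically relevant magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "EllipseParams",
    "DegenerateEllipseError",
    "confidence_ellipse",
    "points_in_ellipse",
    "double_angle_plot",
]


class DegenerateEllipseError(ValueError):
    """Fewer than three points or a singular covariance matrix."""


@dataclass(frozen=True)
class EllipseParams:
    """Centroid, half-axes (dpt), major-axis orientation in [0, 180)°, area (dpt²)."""

    centroid: tuple[float, float]
    half_major: float
    half_minor: float
    orientation: float
    area: float
    level: float
    n: int


def _quantile_factor(level: float, n: int, small_sample: bool) -> float:
    if not 0.0 <= level < 1.0:
        raise ValueError(f"level must be in [0, 1), got {level}")
    if small_sample:
        if n <= 2:
            raise DegenerateEllipseError("small-sample factor needs n > 2")
        return 2.0 * (n - 1) / (n - 2) * float(stats.f.ppf(level, 2, n - 2))
    return float(stats.chi2.ppf(level, 2))


def confidence_ellipse(
    points: Sequence[Sequence[float]] | np.ndarray,
    level: float = 0.90,
    small_sample: bool = False,
) -> EllipseParams:
    """Confidence ellipse of a 2-D point cloud via eigendecomposition.

    Centroid is the componentwise mean; the sample covariance (n-1) is
    eigendecomposed and the half-axes scaled by the square root of the
    level's quantile factor.  Orientation is the major eigenvector's angle
    in the (C0, C45) plane, reported in [0, 180).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) point array, got shape {pts.shape}")
    n = pts.shape[0]
    if n < 3:
        raise DegenerateEllipseError(f"need at least 3 points, got {n}")
    centroid = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[0] <= 0 or eigvals[0] / eigvals[1] < 1e-12:
        raise DegenerateEllipseError("singular covariance: points are collinear")
    q = _quantile_factor(level, n, small_sample)
    half_minor, half_major = np.sqrt(eigvals * q)
    major_vec = eigvecs[:, 1]
    orientation = math.degrees(math.atan2(major_vec[1], major_vec[0])) % 180.0
    return EllipseParams(
        centroid=(float(centroid[0]), float(centroid[1])),
        half_major=float(half_major),
        half_minor=float(half_minor),
        orientation=float(orientation),
        area=float(math.pi * half_major * half_minor),
        level=level,
        n=n,
    )


def points_in_ellipse(
    points: np.ndarray, ellipse: EllipseParams
) -> np.ndarray:
    """Boolean mask of points lying inside (or on) the ellipse."""
    pts = np.asarray(points, dtype=float) - np.asarray(ellipse.centroid)
    ang = math.radians(ellipse.orientation)
    rot = np.array([[math.cos(ang), math.sin(ang)], [-math.sin(ang), math.cos(ang)]])
    uv = pts @ rot.T
    return (uv[:, 0] / ellipse.half_major) ** 2 + (uv[:, 1] / ellipse.half_minor) ** 2 <= 1.0


def _ellipse_outline(e: EllipseParams, num: int = 200) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * math.pi, num)
    ang = math.radians(e.orientation)
    rot = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
    xy = np.stack([e.half_major * np.cos(t), e.half_minor * np.sin(t)], axis=1) @ rot.T
    return xy + np.asarray(e.centroid)


def double_angle_plot(
    panels: Mapping[str, np.ndarray],
    out_path: str | Path,
    ellipses: Mapping[str, EllipseParams] | None = None,
    level: float = 0.90,
    rings: Sequence[float] = (0.25, 0.5, 1.0),
    title: str | None = None,
) -> Path:
    """Render a double-angle plot of one or more (C0, C45) clouds to a file.

    Each panel is scattered with its centroid; its confidence ellipse (given,
    or computed at ``level`` when the panel has >= 3 points) is outlined with
    major/minor half-axis segments, and the legend carries the ellipse area.
    Yellow reference rings mark the ``rings`` astigmatism magnitudes and the
    C0 axis is annotated with the with-the-rule / against-the-rule ends.
    An empty panel mapping still produces a rings-only figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6.0, 6.0))
    theta = np.linspace(0, 2 * math.pi, 200)
    for r in rings:
        ax.plot(r * np.cos(theta), r * np.sin(theta), color="gold", lw=1.0, zorder=1)
        ax.annotate(f"{r:g}", (r, 0), fontsize=7, color="goldenrod")

    max_extent = max(rings, default=1.0)
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for i, (label, pts) in enumerate(panels.items()):
        pts = np.asarray(pts, dtype=float)
        color = colors[i % len(colors)]
        ell = None
        if ellipses and label in ellipses:
            ell = ellipses[label]
        elif pts.shape[0] >= 3:
            try:
                ell = confidence_ellipse(pts, level=level)
            except DegenerateEllipseError:
                ell = None
        if pts.size:
            ax.scatter(pts[:, 0], pts[:, 1], s=12, alpha=0.6, color=color, zorder=2)
            max_extent = max(max_extent, float(np.abs(pts).max()))
        if ell is not None:
            outline = _ellipse_outline(ell)
            ax.plot(outline[:, 0], outline[:, 1], color=color, lw=1.5, zorder=3,
                    label=f"{label} (area {ell.area:.4f} dpt$^2$)")
            cx, cy = ell.centroid
            ax.plot([cx], [cy], marker="o", ms=6, color=color, zorder=4)
            ang = math.radians(ell.orientation)
            for half, style in ((ell.half_major, "-"), (ell.half_minor, "--")):
                dx, dy = half * math.cos(ang), half * math.sin(ang)
                ax.plot([cx, cx + dx], [cy, cy + dy], style, color=color, lw=1.0, zorder=4)
                ang += math.pi / 2.0
        else:
            ax.plot([], [], marker="o", color=color, label=label)

    lim = 1.2 * max_extent
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.annotate("wtr", (lim * 0.92, 0), fontsize=9, ha="right")
    ax.annotate("atr", (-lim * 0.92, 0), fontsize=9, ha="left")
    ax.set_xlabel("C0 (dpt)")
    ax.set_ylabel("C45 (dpt)")
    ax.set_aspect("equal")
    if title:
        ax.set_title(title)
    if panels:
        ax.legend(fontsize=7, loc="upper right")
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
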