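"""Mean lesion-depth quantification on curved and on surface-aligned frames.

Two equivalent readings of the same zone limits are provided.  On the
original (slightly curved) surface the mean depth of a zone is

    D = (1/n) * sum_i Delta_i * ps_axial * cos(alpha)

where ``Delta_i`` is the per-A-line pixel count from the surface to the
deepest pixel of the zone, ``ps_axial`` the axial pixel size (um) and
``alpha`` the median tangent angle of the surface — the cosine projects the
axial pixel run onto the surface normal.  After aligning every A-line to
the highest surface level the same average is taken without the angle
term.  For a flat surface the two are identical.

The module also provides the surface-averaged A-line profile (linear-domain
averaging of dB values), integrated reflectivity, and an independent
spreadsheet-style "manual" depth computation used as a verification oracle.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io import BScan, ColorMap
from .segmentation import (
    ABSENT,
    ContractError,
    SurfaceProfile,
    ZoneLimits,
)

log = logging.getLogger(__name__)


class GeometryError(ValueError):
    """Raised when the surface is too short for geometry estimation."""


class UndefinedDepthError(ValueError):
    """Raised when no A-line carries a surface (n = 0)."""


@dataclass
class SurfaceGeometry:
    """Local tangent angles and global curvature of a detected surface.

    ``tangent_angle`` holds, per lateral column, the signed angle (radians)
    between the surface normal and the axial axis, estimated from a local
    least-squares line in physical coordinates; NaN where the column has no
    surface.  ``alpha_median`` is the median of the absolute angles (the
    median is used because it is insensitive to the few grossly wrong
    per-pixel normals a discrete surface produces).  ``curvature_index`` is
    the surface polyline arc length divided by the lateral span, 1.0 for a
    flat surface.
    """

    tangent_angle: np.ndarray
    alpha_median: float
    curvature_index: float


@dataclass
class DepthResult:
    """Mean zone depths in um: curved-surface (d_*) and aligned (dl_*)."""

    d_ia: float
    d_ie: float
    dl_ia: float
    dl_ie: float
    n: int


def surface_geometry(
    surface: SurfaceProfile,
    ps_axial: float,
    ps_lateral: float,
    window: int = 7,
) -> SurfaceGeometry:
    """Estimate tangent angles, their median, and the curvature index.

    The slope at each surface pixel is fitted by least squares over a
    centered ``window`` of neighbouring surface pixels in physical (um)
    coordinates; windows are shifted inward at the surface ends.
    """
    valid_idx = np.flatnonzero(surface.valid)
    if valid_idx.size < window:
        raise GeometryError(
            f"need at least {window} surface pixels, got {valid_idx.size}"
        )
    x = valid_idx * ps_lateral
    z = surface.surface_row[valid_idx] * ps_axial
    half = window // 2
    angles = np.full(surface.width, np.nan)
    for k in range(valid_idx.size):
        lo = min(max(k - half, 0), valid_idx.size - window)
        xs = x[lo:lo + window]
        zs = z[lo:lo + window]
        xm = xs - xs.mean()
        slope = float(xm @ (zs - zs.mean()) / (xm @ xm))
        angles[valid_idx[k]] = math.atan(slope)
    alpha_median = float(np.median(np.abs(angles[valid_idx])))
    seg = np.hypot(np.diff(x), np.diff(z)).sum()
    span = x[-1] - x[0]
    curvature_index = float(seg / span) if span > 0 else 1.0
    return SurfaceGeometry(angles, alpha_median, curvature_index)


def mean_depth_curved(
    limits: ZoneLimits, geom: SurfaceGeometry, ps_axial: float
) -> tuple[float, float]:
    """Mean Ia and Ie depths on the original curved surface (um).

    ``D = mean(Delta) * ps_axial * cos(alpha_median)`` over the A-lines
    that carry a surface.
    """
    if limits.n_valid == 0:
        raise UndefinedDepthError("no A-line carries a surface")
    c = math.cos(geom.alpha_median)
    d_ia = float(limits.delta_ia[limits.valid].mean() * ps_axial * c)
    d_ie = float(limits.delta_ie[limits.valid].mean() * ps_axial * c)
    return d_ia, d_ie


def align_to_surface(
    frame: BScan, surface: SurfaceProfile
) -> tuple[BScan, SurfaceProfile]:
    """Shift every A-line up so all surfaces sit at the highest surface row.

    Vacated bottom rows are filled with the background marker 0.  Columns
    without a surface are left untouched and logged.  Returns the aligned
    frame and the (constant) aligned surface profile.
    """
    if surface.width != frame.shape[1]:
        raise ContractError(
            f"surface width {surface.width} != frame width {frame.shape[1]}"
        )
    if surface.n_valid == 0:
        raise UndefinedDepthError("no A-line carries a surface")
    top = int(surface.surface_row[surface.valid].min())
    values = frame.intensity_db.copy()
    n_rows = values.shape[0]
    for j in np.flatnonzero(surface.valid):
        shift = int(surface.surface_row[j]) - top
        if shift > 0:
            values[: n_rows - shift, j] = values[shift:, j]
            values[n_rows - shift:, j] = 0.0
    n_absent = surface.width - surface.n_valid
    if n_absent:
        log.warning("%d columns without surface left unaligned", n_absent)
    aligned_rows = np.where(surface.valid, top, ABSENT)
    return frame.with_values(values), SurfaceProfile(aligned_rows)


def mean_depth_aligned(limits: ZoneLimits, ps_axial: float) -> tuple[float, float]:
    """Mean Ia and Ie depths on the surface-aligned frame (um)."""
    if limits.n_valid == 0:
        raise UndefinedDepthError("no A-line carries a surface")
    dl_ia = float(limits.delta_ia[limits.valid].mean() * ps_axial)
    dl_ie = float(limits.delta_ie[limits.valid].mean() * ps_axial)
    return dl_ia, dl_ie


def average_aline(aligned: BScan) -> np.ndarray:
    """Per-row average A-line profile of an aligned frame, in dB.

    dB values are converted to linear intensity (power convention,
    ``10**(dB/10)``), averaged per axial row over non-background pixels,
    and converted back with ``10*log10``.  Rows with no valid pixel are
    NaN.
    """
    db = aligned.intensity_db
    tissue = db != 0
    linear = np.where(tissue, 10.0 ** (db / 10.0), 0.0)
    counts = tissue.sum(axis=1)
    profile = np.full(db.shape[0], np.nan)
    rows = counts > 0
    profile[rows] = 10.0 * np.log10(linear[rows].sum(axis=1) / counts[rows])
    return profile


def integrated_reflectivity(
    frame: BScan,
    surface: SurfaceProfile,
    depth_limit_um: float,
) -> float:
    """Mean per-A-line sum of linear intensities from the surface down to a
    chosen depth (um); a lesion-severity summary.

    The depth limit is converted to whole axial pixels (at least one, the
    surface pixel itself); sums are truncated at the frame bottom.
    Background-marker pixels contribute zero.
    """
    if depth_limit_um <= 0:
        raise ValueError("depth limit must be positive")
    if depth_limit_um > frame.shape[0] * frame.ps_axial:
        raise ValueError("depth limit exceeds the axial extent of the frame")
    if surface.n_valid == 0:
        raise UndefinedDepthError("no A-line carries a surface")
    n_px = max(1, round(depth_limit_um / frame.ps_axial))
    db = frame.intensity_db
    linear = np.where(db != 0, 10.0 ** (db / 10.0), 0.0)
    sums = []
    for j in np.flatnonzero(surface.valid):
        s = int(surface.surface_row[j])
        sums.append(linear[s: s + n_px, j].sum())
    return float(np.mean(sums))


def manual_oracle_depths(aligned: BScan, cmap: ColorMap) -> DepthResult:
    """Spreadsheet-style manual depth computation on an aligned frame.

    Independent re-implementation of the aligned-depth measurement the way
    it would be done by hand in a spreadsheet: walk each column of cells,
    classify every cell by the colormap thresholds, note the last cell of
    each zone, count cells from the surface, average the counts and multiply
    by the axial pixel size.  Shares no code with
    :func:`mean_depth_aligned`; used to cross-check the algorithm.

    The manual path is alignment-based only, so the curved and aligned
    fields of the returned :class:`DepthResult` coincide.
    """
    cells = aligned.intensity_db.tolist()
    n_rows = len(cells)
    n_cols = len(cells[0])
    ia_floor = cmap.ia_range[0]
    ie_floor, ie_ceil = cmap.ie_range
    counts_ia: list[int] = []
    counts_ie: list[int] = []
    for j in range(n_cols):
        surface_row = None
        for i in range(n_rows):
            if cells[i][j] > cmap.background_db:
                surface_row = i
                break
        if surface_row is None:
            continue
        last_ia = None
        last_ie = None
        for i in range(surface_row, n_rows):
            v = cells[i][j]
            if v >= ia_floor:
                last_ia = i
            elif ie_floor <= v < ie_ceil:
                last_ie = i
        counts_ia.append(0 if last_ia is None else last_ia - surface_row + 1)
        counts_ie.append(0 if last_ie is None else last_ie - surface_row + 1)
    if not counts_ia:
        raise UndefinedDepthError("no A-line carries a surface")
    d_ia = sum(counts_ia) / len(counts_ia) * aligned.ps_axial
    d_ie = sum(counts_ie) / len(counts_ie) * aligned.ps_axial
    return DepthResult(d_ia=d_ia, d_ie=d_ie, dl_ia=d_ia, dl_ie=d_ie,
                       n=len(counts_ia))


def quantify_frame(
    frame: BScan,
    cmap: ColorMap,
    background_db: float | None = None,
    tangent_window: int = 7,
) -> tuple[DepthResult, SurfaceGeometry]:
    """Segment one raw frame and compute curved and aligned mean depths."""
    from .segmentation import segment_frame, zone_limits, label_zones

    clean, surface, labels, limits = segment_frame(frame, cmap, background_db)
    geom = surface_geometry(surface, frame.ps_axial, frame.ps_lateral,
                            window=tangent_window)
    d_ia, d_ie = mean_depth_curved(limits, geom, frame.ps_axial)
    aligned, aligned_surface = align_to_surface(clean, surface)
    aligned_labels = label_zones(aligned, aligned_surface, cmap)
    aligned_limits = zone_limits(aligned_labels, aligned_surface)
    dl_ia, dl_ie = mean_depth_aligned(aligned_limits, frame.ps_axial)
    return (
        DepthResult(d_ia=d_ia, d_ie=d_ie, dl_ia=dl_ia, dl_ie=dl_ie,
                    n=limits.n_valid),
        geom,
    )
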