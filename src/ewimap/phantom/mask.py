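"""Myocardial masks on a Cartesian raster.

The phantom wall is an annular arc between an endocardial and an epicardial
contour. Every mask pixel carries a normalized transmural coordinate
``wall_depth`` (0 = endocardium, 1 = epicardium) and a segment label from the
24-segment model, assigned by dividing the wall arc into contiguous equal
sub-arcs, one per segment listed for the view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ewimap.geometry import ViewGeometry
from ewimap.segments import COHORT_SEGMENT_ORDER, SegmentModel24, build_segment_model

#: segment_id value for pixels outside any segment allocation
UNASSIGNED = -1


@dataclass
class MyocardialMask:
    """Boolean wall mask with transmural depth and segment labels.

    Attributes
    ----------
    inside : (ny, nx) bool
        True on myocardial pixels.
    wall_depth : (ny, nx) float
        Normalized transmural coordinate in [0, 1]; NaN outside the mask.
    segment_id : (ny, nx) int
        24-segment label per pixel; ``UNASSIGNED`` outside the mask or where
        no segment was allocated.
    spacing_mm : float
        Isotropic pixel spacing.
    origin_mm : (x0, y0)
        Cartesian position of pixel (row 0, col 0), millimetres.
    """

    inside: np.ndarray
    wall_depth: np.ndarray
    segment_id: np.ndarray
    spacing_mm: float
    origin_mm: tuple[float, float]
    geometry: ViewGeometry | None = None
    view_name: str = "custom"
    segment_names: tuple[str, ...] = ()
    model: SegmentModel24 = field(default_factory=build_segment_model)

    @property
    def n_pixels(self) -> int:
        return int(self.inside.sum())

    @property
    def flat_indices(self) -> np.ndarray:
        """Flat (row-major) indices of mask pixels."""
        return np.flatnonzero(self.inside)

    @property
    def pixel_rowcol(self) -> np.ndarray:
        """(P, 2) array of (row, col) for mask pixels."""
        rows, cols = np.nonzero(self.inside)
        return np.column_stack([rows, cols])

    @property
    def pixel_xy_mm(self) -> np.ndarray:
        """(P, 2) Cartesian mm coordinates of mask pixel centers."""
        rc = self.pixel_rowcol
        x0, y0 = self.origin_mm
        return np.column_stack(
            [x0 + rc[:, 1] * self.spacing_mm, y0 + rc[:, 0] * self.spacing_mm]
        )

    def xy_of_flat(self, flat: np.ndarray) -> np.ndarray:
        rows, cols = np.unravel_index(np.asarray(flat), self.inside.shape)
        x0, y0 = self.origin_mm
        return np.column_stack([x0 + cols * self.spacing_mm, y0 + rows * self.spacing_mm])


def _annulus(
    center_mm: tuple[float, float],
    r_endo_mm: float,
    r_epi_mm: float,
    arc_deg: tuple[float, float],
    spacing_mm: float,
    geometry: ViewGeometry | None,
):
    cx, cy = center_mm
    x = np.arange(cx - r_epi_mm - spacing_mm, cx + r_epi_mm + spacing_mm, spacing_mm)
    y = np.arange(cy - r_epi_mm - spacing_mm, cy + r_epi_mm + spacing_mm, spacing_mm)
    xx, yy = np.meshgrid(x, y)
    rho = np.hypot(xx - cx, yy - cy)
    # arc angle measured from the +y axis of the annulus center, degrees
    phi = np.rad2deg(np.arctan2(xx - cx, yy - cy))
    a0, a1 = arc_deg
    full_ring = (a1 - a0) >= 360.0
    in_arc = np.ones_like(rho, bool) if full_ring else (phi >= a0) & (phi <= a1)
    inside = (rho >= r_endo_mm) & (rho <= r_epi_mm) & in_arc
    if geometry is not None:
        inside &= np.asarray(geometry.contains(xx, yy))
    return x, y, inside, rho, phi


def build_mask(
    geometry: ViewGeometry,
    r_endo_mm: float,
    r_epi_mm: float,
    *,
    center_mm: tuple[float, float] | None = None,
    spacing_mm: float = 0.5,
    arc_deg: tuple[float, float] = (-90.0, 90.0),
    segments: tuple[str, ...] | None = None,
    model: SegmentModel24 | None = None,
) -> MyocardialMask:
    """Build a half-annulus wall mask inside a sector view.

    The wall lies between concentric endo/epi contours centred at
    ``center_mm`` (default: on the beam axis at half the imaging depth), with
    the arc opening towards the transducer. ``wall_depth`` is the normalized
    radial distance between the two contours.

    Raises
    ------
    ValueError
        If the epicardial contour does not enclose the endocardial one, or if
        the contours extend outside the imaging sector.
    """
    if r_epi_mm <= r_endo_mm:
        raise ValueError("epicardial contour must enclose the endocardial contour")
    if center_mm is None:
        ax, ay = geometry.apex_position_mm
        center_mm = (ax, ay + 0.5 * geometry.depth_max_mm)
    # precondition: sampled contours lie inside the sector
    phis = np.deg2rad(np.linspace(arc_deg[0], arc_deg[1], 181))
    for r in (r_endo_mm, r_epi_mm):
        px = center_mm[0] + r * np.sin(phis)
        py = center_mm[1] + r * np.cos(phis)
        if not np.all(geometry.contains(px, py)):
            raise ValueError("wall contours extend outside the imaging sector")

    x, y, inside, rho, phi = _annulus(center_mm, r_endo_mm, r_epi_mm, arc_deg, spacing_mm, geometry)
    depth = np.where(inside, (rho - r_endo_mm) / (r_epi_mm - r_endo_mm), np.nan)

    model = model or build_segment_model()
    seg_id = np.full(inside.shape, UNASSIGNED, dtype=int)
    segments = tuple(segments or ())
    if segments:
        ids = np.array([model.by_name(s).segment_id for s in segments])
        frac = np.clip((phi - arc_deg[0]) / (arc_deg[1] - arc_deg[0]), 0.0, 1.0 - 1e-12)
        bins = (frac * len(segments)).astype(int)
        seg_id[inside] = ids[bins[inside]]

    return MyocardialMask(
        inside=inside,
        wall_depth=depth,
        segment_id=seg_id,
        spacing_mm=spacing_mm,
        origin_mm=(float(x[0]), float(y[0])),
        geometry=geometry,
        view_name=geometry.view_name,
        segment_names=segments,
        model=model,
    )


def build_ring_mask(
    r_endo_mm: float = 25.0,
    r_epi_mm: float = 35.0,
    *,
    spacing_mm: float = 1.0,
    segment_order: tuple[str, ...] = COHORT_SEGMENT_ORDER,
    model: SegmentModel24 | None = None,
) -> MyocardialMask:
    """Idealized full-ring biventricular annulus used by the cohort phantom.

    The 360 degree annulus is divided into ``len(segment_order)`` equal
    angular sectors, one per segment, so the whole 24-segment model is
    represented in a single plane with known ground truth.
    """
    if r_epi_mm <= r_endo_mm:
        raise ValueError("epicardial contour must enclose the endocardial contour")
    model = model or build_segment_model()
    x, y, inside, rho, phi = _annulus((0.0, 0.0), r_endo_mm, r_epi_mm, (-180.0, 180.0), spacing_mm, None)
    depth = np.where(inside, (rho - r_endo_mm) / (r_epi_mm - r_endo_mm), np.nan)
    ids = np.array([model.by_name(s).segment_id for s in segment_order])
    frac = np.clip((phi + 180.0) / 360.0, 0.0, 1.0 - 1e-12)
    bins = (frac * len(segment_order)).astype(int)
    seg_id = np.full(inside.shape, UNASSIGNED, dtype=int)
    seg_id[inside] = ids[bins[inside]]
    return MyocardialMask(
        inside=inside,
        wall_depth=depth,
        segment_id=seg_id,
        spacing_mm=spacing_mm,
        origin_mm=(float(x[0]), float(y[0])),
        geometry=None,
        view_name="ring",
        segment_names=tuple(segment_order),
        model=model,
    )
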