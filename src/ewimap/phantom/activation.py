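"""Ground-truth electrical activation by geodesic wavefront propagation.

The wavefront spreads isotropically from a focal source on the pixel
adjacency graph of the myocardial mask (8-connected); the activation time of
a pixel is the origin time plus the geodesic distance from the source, with
edge lengths scaled by the local inverse conduction velocity. Scar regions
slow conduction by a multiplicative velocity factor in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from ewimap.phantom.mask import MyocardialMask
from ewimap.segments import LAYERS

#: target wall_depth for a source placed in each transmural layer
LAYER_DEPTH_TARGET = {"endo": 1.0 / 6.0, "mid": 0.5, "epi": 5.0 / 6.0}
#: [lo, hi) wall_depth band per layer (terciles)
LAYER_BANDS = {"endo": (0.0, 1 / 3), "mid": (1 / 3, 2 / 3), "epi": (2 / 3, 1.0 + 1e-9)}


@dataclass(frozen=True)
class SourceSpec:
    """Focal source: segment, transmural layer, timing and conduction."""

    segment: str
    layer: str = "endo"
    origin_time_ms: float = 0.0
    conduction_velocity_mm_ms: float = 0.5
    scar_regions: tuple[tuple[np.ndarray, float], ...] = ()

    def __post_init__(self):
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}")
        if self.conduction_velocity_mm_ms <= 0:
            raise ValueError("conduction velocity must be positive")
        for _, mult in self.scar_regions:
            if not 0.0 < mult <= 1.0:
                raise ValueError("scar velocity multipliers must be in (0, 1]")


@dataclass
class ActivationField:
    """Electrical activation time per mask pixel, ms relative to the ECG reference."""

    at_ms: np.ndarray  # (ny, nx), NaN outside mask / unreachable
    truth: SourceSpec
    mask: MyocardialMask
    source_flat: int  # flat index of the source pixel
    unreached: np.ndarray = field(default=None)  # bool image of unreachable mask pixels

    @property
    def at_flat(self) -> np.ndarray:
        """Activation times at ``mask.flat_indices`` order."""
        return self.at_ms.ravel()[self.mask.flat_indices]

    def epicardial_flat(self, min_depth: float = 2.0 / 3.0) -> np.ndarray:
        """Flat indices of epicardial-band pixels (wall_depth >= min_depth)."""
        flat = self.mask.flat_indices
        depth = self.mask.wall_depth.ravel()[flat]
        return flat[depth >= min_depth]


def velocity_map(mask: MyocardialMask, source: SourceSpec) -> np.ndarray:
    """Per-pixel conduction velocity (mm/ms), scar multipliers applied."""
    v = np.full(mask.inside.shape, np.nan)
    v[mask.inside] = source.conduction_velocity_mm_ms
    if source.scar_regions:
        xy = mask.pixel_xy_mm
        rows, cols = np.nonzero(mask.inside)
        for poly, mult in source.scar_regions:
            hit = Path(np.asarray(poly, dtype=float)).contains_points(xy)
            v[rows[hit], cols[hit]] *= mult
    return v


def _pixel_graph(mask: MyocardialMask, v: np.ndarray):
    """8-connected sparse graph over mask pixels; edge weight in ms."""
    flat = mask.flat_indices
    n = flat.size
    node_of = np.full(mask.inside.size, -1, dtype=np.int64)
    node_of[flat] = np.arange(n)
    ny, nx = mask.inside.shape
    rows, cols = np.unravel_index(flat, (ny, nx))
    slow = 1.0 / v.ravel()[flat]  # ms/mm at each node

    src, dst, w = [], [], []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        ok = (rows + dr >= 0) & (rows + dr < ny) & (cols + dc >= 0) & (cols + dc < nx)
        nb_flat = (rows[ok] + dr) * nx + (cols[ok] + dc)
        nb = node_of[nb_flat]
        keep = nb >= 0
        a = np.arange(n)[ok][keep]
        b = nb[keep]
        dist = mask.spacing_mm * float(np.hypot(dr, dc))
        w_ab = dist * 0.5 * (slow[a] + slow[b])
        src.append(a)
        dst.append(b)
        w.append(w_ab)
    src = np.concatenate(src)
    dst = np.concatenate(dst)
    w = np.concatenate(w)
    graph = coo_matrix((w, (src, dst)), shape=(n, n)).tocsr()
    return graph, node_of


def source_pixel(mask: MyocardialMask, source: SourceSpec) -> int:
    """Flat index of the source pixel: in the source segment, at the layer's
    target wall depth, nearest the angular centre of the segment region."""
    seg = mask.model.by_name(source.segment)
    flat = mask.flat_indices
    in_seg = mask.segment_id.ravel()[flat] == seg.segment_id
    if not in_seg.any():
        raise ValueError(f"source segment {source.segment!r} does not intersect the mask")
    lo, hi = LAYER_BANDS[source.layer]
    depth = mask.wall_depth.ravel()[flat]
    band = in_seg & (depth >= lo) & (depth < hi)
    cand = band if band.any() else in_seg
    xy = mask.xy_of_flat(flat[cand])
    centroid = xy.mean(axis=0)
    target = LAYER_DEPTH_TARGET[source.layer]
    # prefer the target depth, then proximity to the region centre
    score = ((depth[cand] - target) * 20.0) ** 2 + ((xy - centroid) ** 2).sum(axis=1)
    return int(flat[cand][np.argmin(score)])


def simulate_activation(mask: MyocardialMask, source: SourceSpec) -> ActivationField:
    """Propagate a geodesic wavefront from the focal source over the mask.

    Returns per-pixel activation times ``origin_time + geodesic distance``
    (ms). Mask pixels in components unreachable from the source are flagged
    and carry NaN activation times.
    """
    v = velocity_map(mask, source)
    graph, node_of = _pixel_graph(mask, v)
    src_flat = source_pixel(mask, source)
    dist = dijkstra(graph, directed=False, indices=node_of[src_flat])
    at = np.full(mask.inside.shape, np.nan)
    flat = mask.flat_indices
    at.ravel()[flat] = source.origin_time_ms + dist
    unreached = np.zeros_like(mask.inside)
    unreached.ravel()[flat] = ~np.isfinite(dist)
    at[unreached] = np.nan
    return ActivationField(at_ms=at, truth=source, mask=mask, source_flat=src_flat, unreached=unreached)
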