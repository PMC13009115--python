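"""Electromechanical activation mapping from strain traces.

The local electromechanical activation time is the first downward zero
crossing (ZC) of the incremental axial strain trace: the moment the
myocardium switches from diastolic lengthening (positive strain) to systolic
shortening (negative strain). The mapping chain is

    strain traces -> ZC detection -> scattered activation times
                  -> Delaunay cubic isochrone interpolation on the mask
                  -> ECG-based multi-view co-registration
                  -> transmural site-of-origin (SoO) localization.

The ZC rule is fully automated and deterministic: after moving-average
smoothing, the first downward crossing inside the analysis window that is
followed by sustained negativity qualifies. A manual-override table (pixel ->
forced time) can replace individual annotations, mirroring the manual review
step of semi-automated workflows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CloughTocher2DInterpolator, NearestNDInterpolator
from scipy.ndimage import uniform_filter1d
from scipy.spatial import QhullError

from ewimap.phantom.mask import UNASSIGNED, MyocardialMask
from ewimap.phantom.strain import ECGTrace, StrainMovie
from ewimap.segments import SegmentModel24

DEFAULT_SMOOTHING_MS = 5.0
DEFAULT_MIN_NEGATIVE_MS = 20.0
DEFAULT_WINDOW_MS = (0.0, 350.0)


def smooth_trace(trace: np.ndarray, smoothing_ms: float, dt_ms: float) -> np.ndarray:
    """Moving-average smoothing with an odd window (nearest-edge padding)."""
    if smoothing_ms <= 0:
        return np.asarray(trace, dtype=float)
    n = max(1, int(round(smoothing_ms / dt_ms)))
    if n % 2 == 0:
        n += 1
    return uniform_filter1d(np.asarray(trace, dtype=float), size=n, mode="nearest")


@dataclass(frozen=True)
class ZCAnnotation:
    """One pixel's zero-crossing annotation."""

    activation_time_ms: float  # NaN unless accepted/ambiguous
    quality: str  # accepted | no_crossing | ambiguous
    n_candidate_crossings: int


def detect_zero_crossing(
    trace: np.ndarray,
    times_ms: np.ndarray,
    reference_ms: float = 0.0,
    *,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    smoothing_ms: float = DEFAULT_SMOOTHING_MS,
    min_negative_ms: float = DEFAULT_MIN_NEGATIVE_MS,
) -> ZCAnnotation:
    """First sustained downward zero crossing of a strain trace.

    The trace is smoothed, then scanned inside ``reference + window`` for
    sample pairs with s[i] >= 0 > s[i+1]. A crossing qualifies when the
    smoothed trace stays strictly negative for at least ``min_negative_ms``
    after it (crossings too close to the end of the trace cannot qualify).
    The reported time interpolates linearly between the bracketing frames and
    is expressed relative to ``reference_ms``. The count of candidate
    downward sign changes in the window is recorded; more than one
    *qualifying* crossing marks the annotation ambiguous (the first is still
    returned). A trace without a qualifying crossing yields quality
    ``no_crossing`` and NaN, never a silent zero.
    """
    if min_negative_ms < 0:
        raise ValueError("min_negative_ms must be >= 0")
    t = np.asarray(times_ms, dtype=float)
    if not (t[0] <= reference_ms + window_ms[0] and reference_ms + window_ms[1] <= t[-1] + 1e-9):
        raise ValueError("analysis window outside the trace duration")
    dt = t[1] - t[0]
    s = smooth_trace(trace, smoothing_ms, dt)
    lo, hi = reference_ms + window_ms[0], reference_ms + window_ms[1]

    down = np.flatnonzero((s[:-1] >= 0.0) & (s[1:] < 0.0))
    cross_t = t[down] + dt * s[down] / (s[down] - s[down + 1])
    in_win = (cross_t >= lo) & (cross_t <= hi)
    down, cross_t = down[in_win], cross_t[in_win]
    n_candidates = int(down.size)

    n_neg = int(np.ceil(min_negative_ms / dt))
    qualifying: list[float] = []
    for i, tc in zip(down, cross_t):
        j0, j1 = i + 1, i + 1 + n_neg
        if j1 > len(s):
            continue  # cannot certify sustained negativity
        if np.all(s[j0:j1] < 0.0):
            qualifying.append(float(tc))
    if not qualifying:
        return ZCAnnotation(float("nan"), "no_crossing", n_candidates)
    quality = "accepted" if len(qualifying) == 1 else "ambiguous"
    return ZCAnnotation(qualifying[0] - reference_ms, quality, n_candidates)


@dataclass
class ScatterAT:
    """Scattered activation-time samples for one view."""

    xy_mm: np.ndarray  # (P, 2)
    at_ms: np.ndarray  # (P,)
    view_name: str = "custom"
    reference_type: str = "QRS onset"  # or "pacing spike"
    quality: np.ndarray | None = None

    def accepted(self) -> "ScatterAT":
        ok = np.isfinite(self.at_ms)
        return ScatterAT(self.xy_mm[ok], self.at_ms[ok], self.view_name, self.reference_type)


def annotate_movie(
    movie: StrainMovie,
    *,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    smoothing_ms: float = DEFAULT_SMOOTHING_MS,
    min_negative_ms: float = DEFAULT_MIN_NEGATIVE_MS,
    overrides: dict[int, float] | None = None,
) -> ScatterAT:
    """Run ZC detection on every trace of a movie.

    ``overrides`` maps flat pixel indices to forced activation times (ms
    relative to the reference), replacing the detector output at those
    pixels.
    """
    ref = movie.ecg.reference_ms
    if ref is None:
        raise ValueError("movie ECG has no QRS onset or pacing spike reference")
    t = movie.times_ms
    ats = np.empty(movie.frames.shape[1])
    quality = np.empty(movie.frames.shape[1], dtype=object)
    for p in range(movie.frames.shape[1]):
        ann = detect_zero_crossing(
            movie.frames[:, p], t, ref,
            window_ms=window_ms, smoothing_ms=smoothing_ms, min_negative_ms=min_negative_ms,
        )
        ats[p] = ann.activation_time_ms
        quality[p] = ann.quality
    if overrides:
        for flat, forced in overrides.items():
            hit = np.flatnonzero(movie.pixel_flat == flat)
            ats[hit] = forced
            quality[hit] = "accepted"
    ref_type = "pacing spike" if movie.ecg.pacing_spike_ms is not None else "QRS onset"
    return ScatterAT(movie.pixel_xy_mm, ats, movie.mask.view_name, ref_type, quality)


def sample_points(
    mask: MyocardialMask,
    n: int,
    strategy: str = "uniform",
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Sample ``n`` distinct mask pixels (flat indices), seeded.

    ``stratified`` allocates points to segments proportionally to segment
    area (largest-remainder rounding), emulating reviewer coverage of the
    whole mask. At least 3 points are required (isochrone interpolation needs
    a non-degenerate triangulation).
    """
    if n < 3:
        raise ValueError("need at least 3 points")
    if n > mask.n_pixels:
        raise ValueError("cannot sample more points than mask pixels")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    flat = mask.flat_indices
    if strategy == "uniform":
        return np.sort(rng.choice(flat, size=n, replace=False))
    if strategy != "stratified":
        raise ValueError("strategy must be 'uniform' or 'stratified'")
    seg = mask.segment_id.ravel()[flat]
    ids = np.unique(seg[seg != UNASSIGNED])
    counts = np.array([(seg == i).sum() for i in ids], dtype=float)
    exact = n * counts / counts.sum()
    alloc = np.floor(exact).astype(int)
    remainder = exact - alloc
    for i in np.argsort(-remainder)[: n - alloc.sum()]:
        alloc[i] += 1
    chosen = []
    for i, k in zip(ids, alloc):
        pool = flat[seg == i]
        k = min(int(k), pool.size)
        if k:
            chosen.append(rng.choice(pool, size=k, replace=False))
    return np.sort(np.concatenate(chosen))


@dataclass
class IsochroneMap:
    """Continuous activation-time image on the mask."""

    at_ms: np.ndarray  # (ny, nx), NaN outside mask
    extrapolated: np.ndarray  # bool image: filled by nearest-sample value
    mask: MyocardialMask
    method: str = "delaunay-cubic"
    view_name: str = "custom"

    @property
    def at_flat(self) -> np.ndarray:
        return self.at_ms.ravel()[self.mask.flat_indices]


def interpolate_isochrones(points: ScatterAT, mask: MyocardialMask) -> IsochroneMap:
    """Delaunay-based cubic interpolation of scattered activation times.

    Clough-Tocher cubic interpolation on the Delaunay triangulation of the
    sample points, evaluated at every mask pixel; exact at the samples and
    exact for linear fields. Mask pixels outside the convex hull are filled
    with the nearest sample's value and flagged as extrapolated.
    """
    pts = points.accepted()
    if pts.at_ms.size < 3:
        raise ValueError("need at least 3 finite activation-time samples")
    try:
        cubic = CloughTocher2DInterpolator(pts.xy_mm, pts.at_ms)
    except QhullError as e:
        raise ValueError("sample points are collinear or degenerate") from e
    xy = mask.pixel_xy_mm
    vals = cubic(xy)
    outside = ~np.isfinite(vals)
    if outside.any():
        nearest = NearestNDInterpolator(pts.xy_mm, pts.at_ms)
        vals[outside] = nearest(xy[outside])
    at = np.full(mask.inside.shape, np.nan)
    at.ravel()[mask.flat_indices] = vals
    extrap = np.zeros_like(mask.inside)
    extrap.ravel()[mask.flat_indices] = outside
    return IsochroneMap(at_ms=at, extrapolated=extrap, mask=mask, view_name=points.view_name)


def register_views(
    views: list[tuple[IsochroneMap, ECGTrace]],
) -> tuple[list[IsochroneMap], list[float]]:
    """Co-register views on a common clock via the surface-ECG reference.

    Activation times are assumed to be expressed relative to each view's own
    reference event (QRS onset for spontaneous beats, pacing spike for paced
    beats) at its local offset; every view is re-expressed relative to the
    first view's reference. Returns the shifted maps and the per-view offsets
    that were removed.
    """
    if not views:
        raise ValueError("register_views requires at least one view")
    refs = []
    for _, ecg in views:
        if ecg.reference_ms is None:
            raise ValueError("view without a QRS onset or pacing spike reference")
        refs.append(ecg.reference_ms)
    base = refs[0]
    out, offsets = [], []
    for (iso, _), ref in zip(views, refs):
        off = ref - base
        shifted = IsochroneMap(
            at_ms=iso.at_ms - off,
            extrapolated=iso.extrapolated,
            mask=iso.mask,
            method=iso.method,
            view_name=iso.view_name,
        )
        out.append(shifted)
        offsets.append(float(off))
    return out, offsets


@dataclass(frozen=True)
class SoOEstimate:
    """Anatomical + transmural site-of-origin call."""

    segment: str
    layer: str  # endo | mid | epi | diffuse
    earliest_ms: float
    diffuse: bool
    view_name: str


def _region_boundary(region: np.ndarray, inside: np.ndarray) -> np.ndarray:
    """Region pixels adjacent (8-conn) to non-region mask pixels, outside-mask
    pixels, or the image edge."""
    padded = np.pad(region, 1)
    interior = np.ones_like(region, dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            interior &= padded[1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc]
    return region & ~interior


def localize_soo(
    views: list[IsochroneMap],
    model: SegmentModel24 | None = None,
    *,
    early_window_ms: float = 5.0,
    diffuse_max_segments: int = 2,
    diffuse_max_fraction: float = 0.25,
    diffuse_margin_ms: float = 5.0,
) -> SoOEstimate:
    """Localize the site of earliest activation across co-registered views.

    The earliest region collects pixels within ``early_window_ms`` of the
    global minimum over all views. The SoO segment is the one containing the
    region's earliness-weighted centroid (in the view attaining the global
    minimum); the transmural layer follows the wall-depth terciles of that
    location. The call is flagged diffuse when the earliest region spans more
    than ``diffuse_max_segments`` segments or more than
    ``diffuse_max_fraction`` of any view's mask while lacking a clearly
    separated local minimum (region-boundary times not rising at least half
    of ``diffuse_margin_ms`` above the minimum); diffuse calls report layer
    ``"diffuse"``.
    """
    if not views:
        raise ValueError("localize_soo requires at least one view")
    model = model or views[0].mask.model
    mins = [np.nanmin(v.at_flat) for v in views]
    gmin = float(np.nanmin(mins))
    best = int(np.argmin(mins))
    thr = gmin + early_window_ms

    seg_ids: set[int] = set()
    frac_exceeded = False
    for v in views:
        region_flat = np.isfinite(v.at_flat) & (v.at_flat <= thr)
        segs = v.mask.segment_id.ravel()[v.mask.flat_indices][region_flat]
        seg_ids.update(int(s) for s in np.unique(segs) if s != UNASSIGNED)
        if region_flat.sum() > diffuse_max_fraction * v.mask.n_pixels:
            frac_exceeded = True
    size_criterion = (len(seg_ids) > diffuse_max_segments) or frac_exceeded

    bv = views[best]
    region_img = np.zeros_like(bv.mask.inside)
    at_img = bv.at_ms
    with np.errstate(invalid="ignore"):
        region_img[(at_img <= thr) & np.isfinite(at_img)] = True
    boundary = _region_boundary(region_img, bv.mask.inside)
    bnd_vals = at_img[boundary]
    focal = bnd_vals.size > 0 and float(np.nanmin(bnd_vals)) - gmin >= 0.5 * diffuse_margin_ms
    diffuse = bool(size_criterion and not focal)

    rows, cols = np.nonzero(region_img)
    weights = thr - at_img[rows, cols] + 1e-9
    x0, y0 = bv.mask.origin_mm
    cx = np.average(x0 + cols * bv.mask.spacing_mm, weights=weights)
    cy = np.average(y0 + rows * bv.mask.spacing_mm, weights=weights)
    d2 = (x0 + cols * bv.mask.spacing_mm - cx) ** 2 + (y0 + rows * bv.mask.spacing_mm - cy) ** 2
    k = int(np.argmin(d2))
    seg_id = int(bv.mask.segment_id[rows[k], cols[k]])
    depth = float(bv.mask.wall_depth[rows[k], cols[k]])
    if diffuse:
        layer = "diffuse"
    elif depth < 1.0 / 3.0:
        layer = "endo"
    elif depth < 2.0 / 3.0:
        layer = "mid"
    else:
        layer = "epi"
    segment = model.by_id(seg_id).name if seg_id != UNASSIGNED else "unassigned"
    return SoOEstimate(
        segment=segment,
        layer=layer,
        earliest_ms=gmin,
        diffuse=diffuse,
        view_name=bv.view_name,
    )
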