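"""Interframe displacement and incremental axial strain from RF frames.

The physics path that feeds the mapping stage when strain is not supplied
directly: per-window 1-D normalized cross-correlation between consecutive
RF frames gives the interframe axial displacement (with parabolic sub-sample
refinement of the correlation peak), and the incremental strain is the
least-squares slope of displacement versus depth over a sliding kernel.
Only incremental (frame-to-frame) strain is computed: the zero-crossing
definition of electromechanical activation operates on incremental strain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ewimap.phantom.mask import MyocardialMask
from ewimap.phantom.rf import RFFrames
from ewimap.phantom.strain import ECGTrace, StrainMovie


@dataclass
class DisplacementField:
    """Axial displacement per (frame pair, line, window center)."""

    disp_samples: np.ndarray  # (n_pairs, n_lines, n_windows)
    disp_mm: np.ndarray
    correlation: np.ndarray  # NCC peak value per estimate
    valid: np.ndarray  # False where the window had zero variance
    centers_sample: np.ndarray  # (n_windows,) window-center sample indices
    centers_mm: np.ndarray
    sample_spacing_mm: float
    frame_rate_hz: float
    search_samples: int


def _parabolic_refine(y_m1: float, y_0: float, y_p1: float) -> float:
    denom = y_m1 - 2.0 * y_0 + y_p1
    if denom >= 0.0 or abs(denom) < 1e-30:
        return 0.0
    return float(np.clip(0.5 * (y_m1 - y_p1) / denom, -0.5, 0.5))


def estimate_displacement(
    frames: RFFrames,
    window_len: int = 64,
    overlap: float = 0.8,
    search: int = 8,
) -> DisplacementField:
    """Per-window interframe axial displacement by normalized cross-correlation.

    For each consecutive frame pair, line and axial window, the displacement
    is the argmax over integer lags of the normalized cross-correlation
    between the reference window and the shifted comparison frame, refined by
    parabolic interpolation around the integer peak. Flat (zero-variance)
    windows are flagged invalid (NaN displacement).
    """
    if window_len < 8:
        raise ValueError("window_len must be >= 8 samples")
    if search < 1:
        raise ValueError("search must be >= 1 sample")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    data = frames.data
    n_frames, n_lines, n_samples = data.shape
    step = max(1, int(round(window_len * (1.0 - overlap))))
    starts = np.arange(search, n_samples - window_len - search + 1, step)
    if starts.size == 0:
        raise ValueError("frames too short for the window and search settings")
    lags = np.arange(-search, search + 1)

    shape = (n_frames - 1, n_lines, starts.size)
    disp = np.full(shape, np.nan)
    corr = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    idx_win = starts[:, None] + np.arange(window_len)[None, :]  # (W, L)
    for k in range(n_frames - 1):
        for line in range(n_lines):
            a = data[k, line]
            b = data[k + 1, line]
            aw = a[idx_win]  # (W, L)
            aw = aw - aw.mean(axis=1, keepdims=True)
            a_norm = np.sqrt((aw**2).sum(axis=1))
            ncc = np.empty((starts.size, lags.size))
            for j, lag in enumerate(lags):
                bw = b[idx_win + lag]
                bw = bw - bw.mean(axis=1, keepdims=True)
                b_norm = np.sqrt((bw**2).sum(axis=1))
                denom = a_norm * b_norm
                with np.errstate(invalid="ignore", divide="ignore"):
                    ncc[:, j] = np.where(denom > 0, (aw * bw).sum(axis=1) / denom, -np.inf)
            ok = a_norm > 0
            peak = np.argmax(ncc, axis=1)
            for w in np.flatnonzero(ok):
                j = peak[w]
                if not np.isfinite(ncc[w, j]):
                    continue
                frac = 0.0
                # a perfect match is an exact integer shift; do not perturb it
                if (ncc[w, j] < 1.0 - 1e-12 and 0 < j < lags.size - 1
                        and np.isfinite(ncc[w, j - 1]) and np.isfinite(ncc[w, j + 1])):
                    frac = _parabolic_refine(ncc[w, j - 1], ncc[w, j], ncc[w, j + 1])
                disp[k, line, w] = lags[j] + frac
                corr[k, line, w] = ncc[w, j]
                valid[k, line, w] = True
    spacing = frames.sample_spacing_mm
    centers = starts + (window_len - 1) / 2.0
    return DisplacementField(
        disp_samples=disp,
        disp_mm=disp * spacing,
        correlation=corr,
        valid=valid,
        centers_sample=centers,
        centers_mm=centers * spacing,
        sample_spacing_mm=spacing,
        frame_rate_hz=frames.frame_rate_hz,
        search_samples=search,
    )


@dataclass
class StrainField:
    """Incremental axial strain per (frame pair, line, kernel center)."""

    strain: np.ndarray  # (n_pairs, n_lines, n_centers)
    centers_mm: np.ndarray
    kernel_mm: float
    frame_rate_hz: float


def estimate_incremental_strain(disp: DisplacementField, kernel_mm: float = 5.0) -> StrainField:
    """Incremental strain: least-squares slope of displacement vs depth.

    A sliding kernel of ``kernel_mm`` (at least 2 displacement estimates)
    runs along each line; the strain at the kernel center is the slope of the
    least-squares line fit of displacement (mm) against depth (mm) for that
    frame pair. NaN estimates inside a kernel propagate to its output.
    """
    spacing = float(np.mean(np.diff(disp.centers_mm)))
    k = int(round(kernel_mm / spacing)) + 1
    if k < 2:
        raise ValueError("kernel shorter than 2 displacement-estimate spacings")
    n_pairs, n_lines, n_w = disp.disp_mm.shape
    if n_w < k:
        raise ValueError("fewer displacement estimates than the kernel length")
    x = disp.centers_mm
    n_c = n_w - k + 1
    strain = np.empty((n_pairs, n_lines, n_c))
    xw = np.lib.stride_tricks.sliding_window_view(x, k)  # (n_c, k)
    xc = xw - xw.mean(axis=1, keepdims=True)
    sxx = (xc**2).sum(axis=1)
    for p in range(n_pairs):
        for line in range(n_lines):
            yw = np.lib.stride_tricks.sliding_window_view(disp.disp_mm[p, line], k)
            yc = yw - yw.mean(axis=1, keepdims=True)
            strain[p, line] = (xc * yc).sum(axis=1) / sxx
    centers = np.convolve(x, np.ones(k) / k, mode="valid")
    return StrainField(
        strain=strain,
        centers_mm=centers,
        kernel_mm=kernel_mm,
        frame_rate_hz=disp.frame_rate_hz,
    )


def strain_to_traces(
    strain: StrainField,
    mask: MyocardialMask,
    ecg: ECGTrace | None = None,
    max_distance_mm: float | None = None,
) -> StrainMovie:
    """Resample estimator-grid strain onto mask pixels (nearest estimate).

    The estimator grid is mapped through the view geometry: each mask pixel
    is assigned the strain trace of the nearest (line, kernel center)
    estimate. Pixels farther than ``max_distance_mm`` (default: two kernel
    centers) from any estimate raise an empty-overlap error if none remain.
    """
    geometry = mask.geometry
    if geometry is None:
        raise ValueError("mask has no view geometry to place the estimator grid")
    n_pairs, n_lines, n_c = strain.strain.shape
    angles = np.linspace(
        -np.deg2rad(geometry.sector_angle_deg) / 2,
        np.deg2rad(geometry.sector_angle_deg) / 2,
        n_lines,
    )
    xy = mask.pixel_xy_mm
    r, theta = geometry.polar(xy[:, 0], xy[:, 1])
    line_idx = np.clip(np.searchsorted(angles, theta), 1, n_lines - 1)
    line_idx = np.where(
        np.abs(theta - angles[line_idx - 1]) <= np.abs(theta - angles[line_idx]),
        line_idx - 1,
        line_idx,
    ) if n_lines > 1 else np.zeros(len(xy), dtype=int)
    c = strain.centers_mm
    c_idx = np.clip(np.searchsorted(c, r), 1, n_c - 1)
    c_idx = np.where(np.abs(r - c[c_idx - 1]) <= np.abs(r - c[c_idx]), c_idx - 1, c_idx)
    if max_distance_mm is None:
        max_distance_mm = 2.0 * float(np.mean(np.diff(c))) if n_c > 1 else strain.kernel_mm
    dist_r = np.abs(r - c[c_idx])
    covered = dist_r <= max_distance_mm
    if not covered.any():
        raise ValueError("estimator grid does not overlap the mask")
    frames = np.full((n_pairs, len(xy)), np.nan)
    frames[:, covered] = strain.strain[:, line_idx[covered], c_idx[covered]]
    if ecg is None:
        ecg = ECGTrace(np.zeros(max(50, n_pairs)), fs_hz=strain.frame_rate_hz, qrs_onset_ms=0.0)
    return StrainMovie(
        frames=frames,
        frame_rate_hz=strain.frame_rate_hz,
        pixel_flat=mask.flat_indices,
        mask=mask,
        ecg=ecg,
        geometry=geometry,
    )
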