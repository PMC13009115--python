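"""Synthetic post-beamformed RF frames for the physics path.

Each scan line is a random scatterer train convolved with a Gaussian-
modulated pulse (2.5 MHz centre frequency by default). Successive frames
shift the scatterers by the cumulative axial displacement implied by a
prescribed incremental strain schedule, so the displacement/strain
estimators in :mod:`ewimap.rf_strain` can be validated against known ground
truth. Axial sample spacing is c/(2 fs): 0.0385 mm at c = 1540 m/s and
fs = 20 MHz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import gausspulse

log = logging.getLogger(__name__)

SPEED_OF_SOUND_M_S = 1540.0


def axial_sample_spacing_mm(fs_hz: float, c_m_s: float = SPEED_OF_SOUND_M_S) -> float:
    """Axial sample spacing c/(2 fs), in millimetres."""
    return 1000.0 * c_m_s / (2.0 * fs_hz)


@dataclass
class RFFrames:
    """Post-beamformed RF data: (n_frames, n_lines, n_samples)."""

    data: np.ndarray
    fs_hz: float
    frame_rate_hz: float
    c_m_s: float = SPEED_OF_SOUND_M_S

    def __post_init__(self):
        if self.data.ndim != 3 or self.data.shape[0] < 2:
            raise ValueError("RF data must be (n_frames >= 2, n_lines, n_samples)")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def sample_spacing_mm(self) -> float:
        return axial_sample_spacing_mm(self.fs_hz, self.c_m_s)

    @property
    def depths_mm(self) -> np.ndarray:
        return np.arange(self.data.shape[2]) * self.sample_spacing_mm


def cumulative_displacement_mm(
    strain_schedule: np.ndarray, depths_mm: np.ndarray
) -> np.ndarray:
    """Cumulative axial displacement before each frame.

    ``strain_schedule`` is (n_pairs, n_lines, n_samples) incremental axial
    strain between consecutive frames; the interframe displacement at depth z
    is the depth integral of the strain, and frame k's cumulative field is the
    sum of the first k interframe fields. Returns (n_pairs + 1, n_lines,
    n_samples), zero for frame 0.
    """
    dz = np.gradient(depths_mm)
    inc = np.cumsum(strain_schedule * dz[None, None, :], axis=2)
    inc -= inc[:, :, :1]  # displacement integral is zero at the first sample
    cum = np.concatenate([np.zeros_like(inc[:1]), np.cumsum(inc, axis=0)], axis=0)
    return cum


def synthesize_rf(
    strain_schedule,
    *,
    n_frames: int = 2,
    n_lines: int = 4,
    n_samples: int = 2048,
    fs_hz: float = 20e6,
    frame_rate_hz: float = 2000.0,
    f0_hz: float = 2.5e6,
    bandwidth: float = 0.6,
    c_m_s: float = SPEED_OF_SOUND_M_S,
    scatterers_per_mm: float = 8.0,
    noise_sd: float = 0.0,
    declared_search_samples: float | None = None,
    rng: np.random.Generator | None = None,
) -> RFFrames:
    """Synthesize RF frames whose interframe motion realizes a strain schedule.

    ``strain_schedule`` may be a scalar (uniform incremental strain for every
    frame pair) or an array of shape (n_frames - 1, n_lines, n_samples).

    Raises
    ------
    ValueError
        If ``fs_hz`` < 4 x the pulse centre frequency.
    """
    if fs_hz < 4.0 * f0_hz:
        raise ValueError("fs_hz must be at least 4x the pulse centre frequency")
    rng = rng or np.random.default_rng()
    spacing = axial_sample_spacing_mm(fs_hz, c_m_s)
    depths = np.arange(n_samples) * spacing
    if np.isscalar(strain_schedule) or np.ndim(strain_schedule) == 0:
        schedule = np.full((n_frames - 1, n_lines, n_samples), float(strain_schedule))
    else:
        schedule = np.asarray(strain_schedule, dtype=float)
        if schedule.shape != (n_frames - 1, n_lines, n_samples):
            raise ValueError("strain_schedule shape must be (n_frames-1, n_lines, n_samples)")
    u = cumulative_displacement_mm(schedule, depths)  # (n_frames, n_lines, n_samples)

    if declared_search_samples is not None:
        inc_max = np.abs(np.diff(u, axis=0)).max() / spacing
        if inc_max > declared_search_samples:
            log.warning(
                "interframe displacement %.2f samples exceeds declared search range %.2f",
                inc_max,
                declared_search_samples,
            )

    depth_max = depths[-1]
    n_scat = max(8, int(round(scatterers_per_mm * depth_max)))
    data = np.empty((n_frames, n_lines, n_samples))
    t_axis = 2.0 * depths * 1e-3 / c_m_s  # echo arrival time per sample, s
    for line in range(n_lines):
        z0 = rng.uniform(0.0, depth_max, n_scat)
        amp = rng.normal(0.0, 1.0, n_scat)
        order = np.argsort(z0)
        z0, amp = z0[order], amp[order]
        for k in range(n_frames):
            uz = np.interp(z0, depths, u[k, line])
            tau = 2.0 * (z0 + uz) * 1e-3 / c_m_s
            data[k, line] = (gausspulse(t_axis[:, None] - tau[None, :], fc=f0_hz, bw=bandwidth) * amp).sum(axis=1)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd * np.std(data), data.shape)
    return RFFrames(data=data, fs_hz=fs_hz, frame_rate_hz=frame_rate_hz, c_m_s=c_m_s)
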