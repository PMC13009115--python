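"""Synthetic incremental axial strain movies and reference ECG traces.

Each pixel's incremental strain trace follows a smooth sigmoid template: a
positive (diastolic) plateau that crosses zero downward exactly at the local
mechanical activation time ``t_m = electrical AT + electromechanical delay``
and stays negative (systolic) for a configurable duration before recovering.
Gaussian noise and an optional linear baseline drift are added afterwards.
The zero crossing of the noiseless template is exact by construction, so a
detector sampling at the movie frame rate recovers ``t_m`` to within half a
frame period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ewimap.geometry import ViewGeometry
from ewimap.phantom.activation import ActivationField
from ewimap.phantom.mask import MyocardialMask


@dataclass
class ECGTrace:
    """Surface ECG reference co-acquired with a strain movie."""

    samples_mv: np.ndarray
    fs_hz: float
    qrs_onset_ms: float | None = None
    pacing_spike_ms: float | None = None
    beat_type: str = "VE"  # VE | VT | paced | sinus

    def __post_init__(self):
        dur = 1000.0 * len(self.samples_mv) / self.fs_hz
        ref = self.reference_ms
        if ref is not None and not 0.0 <= ref <= dur:
            raise ValueError("ECG reference event outside the trace duration")

    @property
    def reference_ms(self) -> float | None:
        """Common-clock reference: pacing spike for paced beats, else QRS onset."""
        if self.pacing_spike_ms is not None:
            return self.pacing_spike_ms
        return self.qrs_onset_ms


def synthesize_ecg(
    duration_ms: float,
    fs_hz: float = 2000.0,
    *,
    qrs_onset_ms: float | None = 100.0,
    pacing_spike_ms: float | None = None,
    beat_type: str = "VE",
    noise_sd_mv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ECGTrace:
    """Simple single-beat ECG: optional pacing spike, R wave and T wave."""
    t = np.arange(int(round(duration_ms * fs_hz / 1000.0))) * 1000.0 / fs_hz
    v = np.zeros_like(t)
    ref = pacing_spike_ms if pacing_spike_ms is not None else qrs_onset_ms
    if ref is None:
        raise ValueError("either qrs_onset_ms or pacing_spike_ms is required")
    if pacing_spike_ms is not None:
        v += 2.0 * np.exp(-0.5 * ((t - pacing_spike_ms) / 1.0) ** 2)
    if qrs_onset_ms is not None:
        v += 1.2 * np.exp(-0.5 * ((t - (qrs_onset_ms + 40.0)) / 12.0) ** 2)
        v += 0.3 * np.exp(-0.5 * ((t - (qrs_onset_ms + 300.0)) / 40.0) ** 2)
    if noise_sd_mv > 0:
        rng = rng or np.random.default_rng()
        v = v + rng.normal(0.0, noise_sd_mv, v.shape)
    return ECGTrace(v, fs_hz, qrs_onset_ms=qrs_onset_ms, pacing_spike_ms=pacing_spike_ms, beat_type=beat_type)


@dataclass
class StrainMovie:
    """Per-pixel incremental axial strain time series for one view.

    ``frames`` has shape (n_frames, n_pixels) where columns correspond to
    ``pixel_flat`` (flat indices into the mask grid).
    """

    frames: np.ndarray
    frame_rate_hz: float
    pixel_flat: np.ndarray
    mask: MyocardialMask
    ecg: ECGTrace
    geometry: ViewGeometry | None = None

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * 1000.0 / self.frame_rate_hz

    @property
    def duration_ms(self) -> float:
        return self.n_frames * 1000.0 / self.frame_rate_hz

    @property
    def pixel_xy_mm(self) -> np.ndarray:
        return self.mask.xy_of_flat(self.pixel_flat)


def strain_template(
    t_ms: np.ndarray,
    t_m_ms: np.ndarray,
    *,
    amplitude: float = 5e-4,
    transition_ms: float = 4.0,
    systolic_ms: float = 150.0,
    recovery_ms: float = 30.0,
) -> np.ndarray:
    """Noiseless strain trace(s): zero crossing exactly at ``t_m_ms``.

    ``t_ms`` is a (T,) time axis, ``t_m_ms`` scalar or (P,); output is (T,)
    or (T, P). Positive plateau before t_m, downward tanh transition with the
    zero crossing at t_m, negative plateau of ``systolic_ms``, then recovery.
    """
    t = np.asarray(t_ms, dtype=float)
    tm = np.atleast_1d(np.asarray(t_m_ms, dtype=float))
    dt = t[:, None] - tm[None, :]
    s = amplitude * np.tanh(-dt / transition_ms)
    s += amplitude * (1.0 + np.tanh((dt - systolic_ms) / recovery_ms))
    if np.isscalar(t_m_ms) or np.ndim(t_m_ms) == 0:
        return s[:, 0]
    return s


def synthesize_strain(
    field: ActivationField,
    delay_ms,
    *,
    duration_ms: float = 500.0,
    frame_rate_hz: float = 2000.0,
    amplitude: float = 5e-4,
    transition_ms: float = 4.0,
    systolic_ms: float = 150.0,
    recovery_ms: float = 30.0,
    noise_sd: float = 0.0,
    drift_per_s: float = 0.0,
    ecg: ECGTrace | None = None,
    qrs_onset_ms: float = 100.0,
    pixels: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> StrainMovie:
    """Synthesize an incremental-strain movie from an activation field.

    Parameters
    ----------
    field : ActivationField
        Electrical activation times (ms relative to the ECG reference).
    delay_ms : scalar or (ny, nx) array
        Electromechanical delay per pixel; mechanical activation is
        ``t_m = reference + at + delay`` in absolute movie time.
    pixels : optional array of flat mask indices
        Restrict the movie to these pixels (default: all mask pixels).
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    if ecg is None:
        ecg = synthesize_ecg(duration_ms, fs_hz=frame_rate_hz, qrs_onset_ms=qrs_onset_ms)
    ref = ecg.reference_ms
    mask = field.mask
    pixels = mask.flat_indices if pixels is None else np.asarray(pixels)
    at = field.at_ms.ravel()[pixels]
    if np.isscalar(delay_ms) or np.ndim(delay_ms) == 0:
        delay = np.full(pixels.shape, float(delay_ms))
    else:
        delay = np.asarray(delay_ms, dtype=float).ravel()[pixels]
    t_m = ref + at + delay
    finite = np.isfinite(t_m)
    if finite.any() and (np.nanmin(t_m) < 0.0 or np.nanmax(t_m) > duration_ms):
        raise ValueError("mechanical activation time outside the movie duration")

    n_frames = int(round(duration_ms * frame_rate_hz / 1000.0))
    t = np.arange(n_frames) * 1000.0 / frame_rate_hz
    frames = np.zeros((n_frames, pixels.size))
    frames[:, finite] = strain_template(
        t,
        t_m[finite],
        amplitude=amplitude,
        transition_ms=transition_ms,
        systolic_ms=systolic_ms,
        recovery_ms=recovery_ms,
    )
    frames[:, ~finite] = np.nan
    if noise_sd > 0 or drift_per_s != 0:
        rng = rng or np.random.default_rng()
        if noise_sd > 0:
            frames = frames + rng.normal(0.0, noise_sd, frames.shape)
        if drift_per_s != 0:
            slope = rng.normal(0.0, drift_per_s, pixels.size)  # strain units per second
            frames = frames + slope[None, :] * (t[:, None] / 1000.0)
    return StrainMovie(
        frames=frames,
        frame_rate_hz=frame_rate_hz,
        pixel_flat=pixels,
        mask=mask,
        ecg=ecg,
        geometry=mask.geometry,
    )
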