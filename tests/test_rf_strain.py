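"""Displacement and incremental-strain estimators on synthetic RF."""

import numpy as np
import pytest
from scipy.signal import butter, sosfiltfilt

from ewimap.phantom import axial_sample_spacing_mm, synthesize_rf
from ewimap.phantom.rf import RFFrames
from ewimap.rf_strain import (
    DisplacementField,
    estimate_displacement,
    estimate_incremental_strain,
    strain_to_traces,
)


def _bandlimited_line(n, rng):
    sos = butter(4, [0.05, 0.35], btype="band", output="sos")
    return sosfiltfilt(sos, rng.normal(size=n))


def _fourier_shift(x, d):
    X = np.fft.rfft(x)
    k = np.arange(len(X))
    return np.fft.irfft(X * np.exp(-2j * np.pi * k * d / len(x)), n=len(x))


def _frames(line_pairs):
    data = np.stack(line_pairs)[:, None, :]
    return RFFrames(data, fs_hz=20e6, frame_rate_hz=2000.0)


def test_identical_frames_zero_displacement_unit_correlation(rng):
    line = _bandlimited_line(1500, rng)
    d = estimate_displacement(_frames([line, line]))
    assert np.allclose(d.disp_samples[d.valid], 0.0)
    assert np.allclose(d.correlation[d.valid], 1.0)


def test_integer_shift_recovered_exactly(rng):
    line = _bandlimited_line(1500, rng)
    d = estimate_displacement(_frames([line, np.roll(line, 3)]))
    assert np.allclose(d.disp_samples[d.valid], 3.0)


def test_subsample_bias_below_half_twentieth_sample(rng):
    """|E[d_hat - d]| < 0.05 samples for sub-sample shifts on noiseless lines."""
    line = _bandlimited_line(2000, rng)
    for d_true in np.arange(-0.5, 0.51, 0.1):
        shifted = _fourier_shift(line, d_true)
        d = estimate_displacement(_frames([line, shifted]), window_len=64, overlap=0.8)
        bias = np.nanmean(d.disp_samples) - d_true
        assert abs(bias) < 0.05


def test_flat_window_flagged_invalid():
    a = np.zeros(600)
    a[300:350] = np.sin(np.arange(50))
    d = estimate_displacement(_frames([a, a]), window_len=32, overlap=0.5)
    assert (~d.valid).any()
    assert np.all(np.isnan(d.disp_samples[~d.valid]))


def test_parameter_validation(rng):
    f = _frames([_bandlimited_line(600, rng)] * 2)
    with pytest.raises(ValueError):
        estimate_displacement(f, window_len=4)
    with pytest.raises(ValueError):
        estimate_displacement(f, search=0)
    with pytest.raises(ValueError):
        estimate_displacement(f, overlap=1.0)


def _disp_field(disp_mm, centers_mm):
    disp_mm = disp_mm[None, None, :]
    return DisplacementField(
        disp_samples=disp_mm / 0.0385,
        disp_mm=disp_mm,
        correlation=np.ones_like(disp_mm),
        valid=np.ones_like(disp_mm, bool),
        centers_sample=centers_mm / 0.0385,
        centers_mm=centers_mm,
        sample_spacing_mm=0.0385,
        frame_rate_hz=2000.0,
        search_samples=8,
    )


def test_linear_displacement_gives_exact_slope():
    centers = np.linspace(0.0, 40.0, 81)
    d = _disp_field(0.01 * centers, centers)
    s = estimate_incremental_strain(d, kernel_mm=5.0)
    assert np.allclose(s.strain, 0.01)


def test_constant_displacement_gives_zero_strain():
    centers = np.linspace(0.0, 40.0, 81)
    d = _disp_field(np.full(81, 0.3), centers)
    s = estimate_incremental_strain(d, kernel_mm=5.0)
    assert np.allclose(s.strain, 0.0)


def test_piecewise_linear_slopes_recovered_away_from_breakpoint():
    centers = np.linspace(0.0, 40.0, 161)
    y = np.where(centers < 20.0, 0.02 * centers, 0.4 - 0.01 * (centers - 20.0))
    s = estimate_incremental_strain(_disp_field(y, centers), kernel_mm=5.0)
    c = s.centers_mm
    assert np.allclose(s.strain[0, 0][c < 17.0], 0.02, atol=1e-9)
    assert np.allclose(s.strain[0, 0][c > 23.0], -0.01, atol=1e-9)


def test_kernel_too_short_rejected():
    centers = np.linspace(0.0, 40.0, 11)  # 4 mm spacing
    with pytest.raises(ValueError, match="kernel"):
        estimate_incremental_strain(_disp_field(centers * 0.0, centers), kernel_mm=1.0)


def test_end_to_end_strain_recovery_at_20db_snr(rng):
    """Physics round trip: synthesize RF with a known schedule, estimate
    displacement then strain; RMS error < 10% of peak strain."""
    n, n_pairs, n_lines = 3000, 2, 4
    spacing = axial_sample_spacing_mm(20e6)
    z = np.arange(n) * spacing
    peak = 2e-3  # localized contraction band, well inside the search range
    profile = peak * np.exp(-0.5 * ((z - 40.0) / 15.0) ** 2)
    sched = np.tile(profile, (n_pairs, n_lines, 1))
    f = synthesize_rf(sched, n_frames=n_pairs + 1, n_lines=n_lines, n_samples=n,
                      noise_sd=0.1, rng=rng)  # 20 dB SNR
    d = estimate_displacement(f, window_len=128, overlap=0.8, search=8)
    s = estimate_incremental_strain(d, kernel_mm=5.0)
    # the schedule is common to all pairs and lines; recover it per depth
    recovered = np.nanmean(s.strain, axis=(0, 1))
    truth = np.interp(s.centers_mm, z, profile)
    rms = np.sqrt(np.nanmean((recovered - truth) ** 2))
    assert rms < 0.1 * peak


def test_strain_to_traces_identity_and_disjoint(sector_mask):
    geom = sector_mask.geometry
    n_lines, n_c = geom.n_lines, 120
    centers = np.linspace(20.0, 90.0, n_c)
    strain = np.zeros((4, n_lines, n_c))
    strain[:, :, :] = centers[None, None, :]  # value = radial center, traceable
    from ewimap.rf_strain import StrainField

    sf = StrainField(strain=strain, centers_mm=centers, kernel_mm=5.0, frame_rate_hz=2000.0)
    movie = strain_to_traces(sf, sector_mask)
    r, _ = geom.polar(*sector_mask.pixel_xy_mm.T)
    got = movie.frames[0]
    ok = np.isfinite(got)
    assert ok.all()  # estimator grid covers the whole mask
    # each pixel carries the value of its nearest kernel center
    assert np.all(np.abs(got - r) <= (centers[1] - centers[0]) / 2 + 1e-9)

    far = StrainField(strain=strain[:, :, :3], centers_mm=np.array([200.0, 205.0, 210.0]),
                      kernel_mm=5.0, frame_rate_hz=2000.0)
    with pytest.raises(ValueError, match="overlap"):
        strain_to_traces(far, sector_mask)
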