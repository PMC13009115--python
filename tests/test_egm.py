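"""Unipolar-electrogram operators: averaging, LAT, morphology, slew rate."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ewimap.egm import (
    UnipolarEGM,
    average_beats,
    classify_morphology,
    compute_lat,
    lowpass_filter,
    slew_rate,
    surrogate_stats,
)
from ewimap.phantom.ecgi import synthesize_uegm


def _uegm(v, filtered=True, t0=0.0, fs=1000.0):
    return UnipolarEGM(np.asarray(v, float), fs_hz=fs, filtered=filtered, t0_ms=t0)


# ------------------------------------------------------------------- LAT
def test_lat_at_steepest_descent_of_synthetic_qs_beat():
    u = synthesize_uegm(80.0)
    lat = compute_lat(u)
    assert lat.defined
    assert lat.lat_ms == pytest.approx(80.0, abs=1.0)  # 1000 Hz quantization


def test_lat_tie_breaks_to_earliest_on_linear_ramp():
    v = -0.1 * np.arange(100.0)
    lat = compute_lat(_uegm(v))
    assert lat.lat_ms == pytest.approx(1.0)  # first interior sample


def test_lat_undefined_for_non_decreasing_signal():
    lat = compute_lat(_uegm(np.zeros(100)))
    assert not lat.defined and np.isnan(lat.lat_ms)


def test_lat_requires_filtered_flag():
    with pytest.raises(ValueError, match="filtered"):
        compute_lat(_uegm(np.zeros(100), filtered=False))


# ------------------------------------------------------------- slew rate
def test_slew_rate_of_linear_ramp_is_exact():
    v = -0.3 * np.arange(200.0)  # -0.3 mV per 1 ms sample
    assert slew_rate(_uegm(v)) == pytest.approx(0.3)


def test_slew_rate_zero_for_constant_signal():
    assert slew_rate(_uegm(np.full(100, 2.0))) == 0.0


def test_configured_slew_round_trips_through_synthesis():
    # 0.32 mV/ms echoes the endocardial mean of the surrogate table
    u = synthesize_uegm(80.0, slew_mv_ms=0.32)
    assert slew_rate(u) == pytest.approx(0.32, abs=0.02)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.floats(-5, 5), st.floats(0.1, 10))
def test_slew_invariant_to_offset_and_linear_in_scale(offset, scale):
    rng = np.random.default_rng(7)
    v = lowpass_filter(rng.normal(0, 1, 300))
    base = slew_rate(_uegm(v))
    assert slew_rate(_uegm(v + offset)) == pytest.approx(base, rel=1e-9)
    assert slew_rate(_uegm(v * scale)) == pytest.approx(base * scale, rel=1e-9)


# ------------------------------------------------------------ morphology
def test_pure_negative_deflection_is_qs():
    t = np.arange(300.0)
    v = -1.0 / (1.0 + np.exp(-(t - 150.0) / 5.0))
    assert classify_morphology(_uegm(v)) == "QS"


def test_r_wave_above_threshold_is_rs():
    t = np.arange(300.0)
    v = -1.0 / (1.0 + np.exp(-(t - 150.0) / 5.0))
    v += 0.2 * np.exp(-0.5 * ((t - 130.0) / 5.0) ** 2)  # 0.2 relative r wave
    assert classify_morphology(_uegm(v), r_threshold=0.1) == "rS"


def test_flat_trace_is_other_and_all_zero_rejected():
    assert classify_morphology(_uegm(np.full(100, 1.0))) == "other"
    with pytest.raises(ValueError, match="zero"):
        classify_morphology(_uegm(np.zeros(100)))


def test_phantom_morphology_labels_recovered_at_zero_noise():
    for morph in ("QS", "rS"):
        u = synthesize_uegm(60.0, morphology=morph)
        assert classify_morphology(u) == morph


# ---------------------------------------------------------- beat averaging
def test_averaging_reduces_noise_variance_tenfold(rng):
    t = np.arange(400.0)
    clean = -np.tanh((t - 200.0) / 10.0)
    beats = clean[None, :] + rng.normal(0.0, 0.05, (10, 400))
    avg = average_beats(beats, clean, threshold=0.93)
    assert avg.n_accepted == 10
    resid = avg.samples_mv - clean
    var_ratio = resid.var() / 0.05**2
    assert var_ratio == pytest.approx(0.1, rel=0.3)  # variance of the mean


def test_inverted_beat_rejected(rng):
    t = np.arange(400.0)
    clean = -np.tanh((t - 200.0) / 10.0)
    beats = np.vstack([np.tile(clean, (9, 1)), -clean[None, :]])
    beats = beats + rng.normal(0, 0.01, beats.shape)
    avg = average_beats(beats, clean)
    assert avg.n_accepted == 9
    assert not avg.accepted[-1]
    assert avg.correlations[-1] < -0.9


def test_alignment_recovers_known_lag(rng):
    t = np.arange(300.0)
    template = -np.tanh((t - 150.0) / 8.0)
    beat = np.zeros(340)
    beat[25:325] = template
    avg = average_beats(beat[None, :], template)
    assert avg.lags[0] == 25


def test_impossible_threshold_raises(rng):
    t = np.arange(200.0)
    clean = -np.tanh((t - 100.0) / 10.0)
    beats = clean[None, :] + rng.normal(0.0, 0.5, (5, 200))
    with pytest.raises(ValueError, match="no beats"):
        average_beats(beats, clean, threshold=1.0)


def test_template_longer_than_beats_rejected():
    with pytest.raises(ValueError, match="template"):
        average_beats(np.zeros((2, 100)), np.zeros(200))


# ------------------------------------------------------- surrogate stats
def _records(rng, means=(0.32, 0.37, 0.29), n=(12, 11, 13)):
    rows = []
    for layer, m, k in zip(("endo", "mid", "epi"), means, n):
        for i in range(k):
            rows.append(
                {"map_id": f"{layer}{i}", "layer": layer,
                 "morphology": "QS" if rng.uniform() < 0.78 else "rS",
                 "slew_rate": abs(rng.normal(m, 0.18))}
            )
    return pd.DataFrame(rows)


def test_surrogate_table_shape_and_values(rng):
    summary = surrogate_stats(_records(rng))
    assert list(summary.table.index) == ["endo", "mid", "epi"]
    assert {"n", "slew_mean", "slew_sd", "qs_fraction"} <= set(summary.table.columns)
    assert summary.table["n"].sum() == 36
    assert 0.0 <= summary.anova_p <= 1.0


def test_separated_groups_give_tiny_p(rng):
    df = _records(rng)
    df.loc[df["layer"] == "epi", "slew_rate"] = rng.normal(10.0, 0.1, (df["layer"] == "epi").sum())
    assert surrogate_stats(df).anova_p < 1e-6


def test_single_layer_rejected(rng):
    df = _records(rng)
    with pytest.raises(ValueError, match="2 layers"):
        surrogate_stats(df[df["layer"] == "endo"])


def test_small_layer_excluded_with_warning(rng):
    df = _records(rng, n=(12, 1, 13))
    with pytest.warns(UserWarning, match="excluded"):
        summary = surrogate_stats(df)
    assert summary.excluded_layers == ("mid",)
    assert np.isfinite(summary.anova_p)
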