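"""Point sampling, isochrone interpolation, co-registration, SoO localization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ewimap.mapping import (
    IsochroneMap,
    ScatterAT,
    interpolate_isochrones,
    localize_soo,
    register_views,
    sample_points,
)
from ewimap.phantom import SourceSpec, simulate_activation, synthesize_ecg
from ewimap.phantom.mask import UNASSIGNED
from ewimap.phantom.strain import ECGTrace


# ---------------------------------------------------------------- sampling
def test_uniform_sampling_draws_distinct_in_mask_points(sector_mask):
    pts = sample_points(sector_mask, 200, "uniform", 0)
    assert len(pts) == 200 and len(np.unique(pts)) == 200
    assert np.all(sector_mask.inside.ravel()[pts])


def test_stratified_sampling_is_proportional_to_segment_area(ring_mask):
    pts = sample_points(ring_mask, 240, "stratified", 0)
    seg = ring_mask.segment_id.ravel()[pts]
    counts = np.bincount(seg, minlength=24)
    areas = np.bincount(ring_mask.segment_id[ring_mask.inside], minlength=24)
    expect = 240 * areas / areas.sum()
    assert np.all(np.abs(counts - expect) <= 1.0)  # largest-remainder rounding


def test_sampling_bounds_rejected(sector_mask):
    with pytest.raises(ValueError):
        sample_points(sector_mask, 2)
    with pytest.raises(ValueError):
        sample_points(sector_mask, sector_mask.n_pixels + 1)


def test_sampling_is_seeded(sector_mask):
    assert np.array_equal(sample_points(sector_mask, 50, "uniform", 3),
                          sample_points(sector_mask, 50, "uniform", 3))


# ----------------------------------------------------------- interpolation
def test_interpolation_exact_at_sample_points(sector_mask, rng):
    pts = sample_points(sector_mask, 80, "uniform", rng)
    xy = sector_mask.xy_of_flat(pts)
    vals = rng.normal(50.0, 20.0, len(pts))
    iso = interpolate_isochrones(ScatterAT(xy, vals), sector_mask)
    got = iso.at_ms.ravel()[pts]
    assert np.allclose(got, vals, atol=1e-8)


def test_interpolation_reproduces_linear_fields(sector_mask, rng):
    """Cubic schemes reproduce linear fields: interior error < 1e-6 x range."""
    pts = sample_points(sector_mask, 50, "uniform", rng)
    xy = sector_mask.xy_of_flat(pts)
    f = lambda p: 3.0 + 0.8 * p[:, 0] - 0.5 * p[:, 1]
    iso = interpolate_isochrones(ScatterAT(xy, f(xy)), sector_mask)
    interior = ~iso.extrapolated.ravel()[sector_mask.flat_indices]
    truth = f(sector_mask.pixel_xy_mm)
    err = np.abs(iso.at_flat - truth)[interior]
    assert err.max() < 1e-6 * (truth.max() - truth.min())


def test_outside_hull_filled_by_nearest_and_flagged(sector_mask):
    # three non-collinear points: most of the mask is outside their hull
    flat = sector_mask.flat_indices[[0, 5, 120]]
    xy = sector_mask.xy_of_flat(flat)
    vals = np.array([10.0, 20.0, 30.0])
    iso = interpolate_isochrones(ScatterAT(xy, vals), sector_mask)
    ext = iso.extrapolated.ravel()[sector_mask.flat_indices]
    assert ext.any()
    out_vals = iso.at_flat[ext]
    assert np.all(np.isin(np.round(out_vals, 6), np.round(vals, 6)))
    assert np.all(np.isfinite(iso.at_flat))


def test_collinear_points_rejected(sector_mask):
    xy = np.column_stack([np.linspace(0, 10, 8), np.linspace(40, 60, 8)])
    with pytest.raises(ValueError, match="collinear|degenerate"):
        interpolate_isochrones(ScatterAT(xy, np.arange(8.0)), sector_mask)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_interpolation_is_permutation_invariant(seed):
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0, 30, (25, 2))
    vals = rng.normal(0, 10, 25)
    perm = rng.permutation(25)
    from scipy.interpolate import CloughTocher2DInterpolator

    q = rng.uniform(5, 25, (40, 2))
    a = CloughTocher2DInterpolator(xy, vals)(q)
    b = CloughTocher2DInterpolator(xy[perm], vals[perm])(q)
    both = np.isfinite(a) & np.isfinite(b)
    # gradient estimation is iterative; identical to numerical tolerance only
    assert np.allclose(a[both], b[both], rtol=1e-3, atol=1e-4)


# ---------------------------------------------------------- co-registration
def _iso(mask, at_flat, view="custom"):
    at = np.full(mask.inside.shape, np.nan)
    at.ravel()[mask.flat_indices] = at_flat
    return IsochroneMap(at, np.zeros_like(mask.inside), mask, view_name=view)


def test_register_views_removes_reference_offsets(sector_mask):
    ats = np.zeros(sector_mask.n_pixels)
    e1 = synthesize_ecg(400.0, qrs_onset_ms=100.0)
    e2 = synthesize_ecg(400.0, qrs_onset_ms=112.0)
    out, offsets = register_views([(_iso(sector_mask, ats), e1), (_iso(sector_mask, ats + 5.0), e2)])
    assert offsets == [0.0, 12.0]
    # the second view's times are shifted by -12 ms onto the common clock
    assert np.allclose(out[1].at_flat, -7.0)
    assert np.allclose(out[0].at_flat, 0.0)


def test_register_single_view_is_identity(sector_mask):
    ats = np.linspace(0, 50, sector_mask.n_pixels)
    ecg = synthesize_ecg(400.0, qrs_onset_ms=90.0)
    out, offsets = register_views([(_iso(sector_mask, ats), ecg)])
    assert offsets == [0.0]
    assert np.allclose(out[0].at_flat, ats)


def test_register_requires_reference_event(sector_mask):
    ecg = ECGTrace(np.zeros(100), 1000.0)  # neither QRS onset nor spike
    with pytest.raises(ValueError, match="reference"):
        register_views([(_iso(sector_mask, np.zeros(sector_mask.n_pixels)), ecg)])


# ------------------------------------------------------------ localization
def test_focal_minimum_localizes_segment_and_endo_layer(sector_mask):
    fld = simulate_activation(sector_mask, SourceSpec("LV-mid-inferoseptal", "endo"))
    iso = _iso(sector_mask, fld.at_flat, view="4ch")
    soo = localize_soo([iso])
    assert soo.segment == "LV-mid-inferoseptal"
    assert soo.layer == "endo"
    assert not soo.diffuse


def test_global_minimum_selects_the_earlier_view(sector_mask):
    f1 = simulate_activation(sector_mask, SourceSpec("LV-basal-inferoseptal", "mid"))
    f2 = simulate_activation(sector_mask, SourceSpec("LV-mid-anterolateral", "mid"))
    iso1 = _iso(sector_mask, f1.at_flat + 8.0, view="A")
    iso2 = _iso(sector_mask, f2.at_flat, view="B")
    soo = localize_soo([iso1, iso2])
    assert soo.view_name == "B"
    assert soo.segment == "LV-mid-anterolateral"
    assert soo.earliest_ms == pytest.approx(0.0)


def test_flat_early_plateau_is_diffuse(sector_mask):
    """An early plateau spanning three segments without a separated local
    minimum is flagged diffuse and reports layer 'diffuse'."""
    seg = sector_mask.segment_id.ravel()[sector_mask.flat_indices]
    plateau_ids = np.unique(seg)[:3]
    ats = np.where(np.isin(seg, plateau_ids), 0.0, 40.0)
    soo = localize_soo([_iso(sector_mask, ats, view="4ch")])
    assert soo.diffuse
    assert soo.layer == "diffuse"


def test_empty_views_rejected():
    with pytest.raises(ValueError):
        localize_soo([])
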