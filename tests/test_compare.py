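"""Bullseye extraction, EMD computation, subgroup tables, localization scoring."""

import warnings

import numpy as np
import pandas as pd
import pytest

from ewimap.compare import (
    SegmentBullseye,
    bullseye_from_isochrones,
    compute_emd,
    extract_bullseye,
    score_localization,
    subgroup_analysis,
)
from ewimap.mapping import IsochroneMap
from ewimap.segments import build_segment_model


def _bse(model, values, modality="EWI", subject="s0"):
    return SegmentBullseye(np.asarray(values, float), modality, subject, model)


# ---------------------------------------------------------------- bullseye
def test_uniform_activation_gives_uniform_bullseye(ring_mask, model):
    flat = ring_mask.flat_indices
    at = np.full(flat.size, 100.0)
    seg = ring_mask.segment_id.ravel()[flat]
    b = extract_bullseye(at, seg, model, "EWI")
    assert np.allclose(b.values, 100.0)
    assert b.covered.all()


def test_missing_segments_masked_with_warning(model):
    at = np.array([10.0, 20.0])
    seg = np.array([0, 1])
    with pytest.warns(UserWarning, match="masked"):
        b = extract_bullseye(at, seg, model, "EWI")
    assert b.covered.sum() == 2
    assert np.isnan(b.values[5])


def test_epicardial_linear_gradient_matches_analytic_segment_means(ring_mask, model):
    """AT linear in x: per-segment epicardial means match the area-weighted
    analytic mean over each segment's epicardial band."""
    flat = ring_mask.flat_indices
    xy = ring_mask.xy_of_flat(flat)
    at_img = np.full(ring_mask.inside.shape, np.nan)
    at_img.ravel()[flat] = 2.0 * xy[:, 0] + 50.0
    iso = IsochroneMap(at_img, np.zeros_like(ring_mask.inside), ring_mask)
    b = bullseye_from_isochrones([iso], model)
    depth = ring_mask.wall_depth.ravel()[flat]
    seg = ring_mask.segment_id.ravel()[flat]
    epi = depth >= 2.0 / 3.0
    for s in model:
        sel = epi & (seg == s.segment_id)
        if sel.any():
            analytic = (2.0 * xy[sel, 0] + 50.0).mean()
            assert b.values[s.segment_id] == pytest.approx(analytic, abs=1e-9)


def test_bullseye_coverage_conservation(model, rng):
    at = rng.normal(0, 10, 40)
    seg = rng.integers(0, 12, 40)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        b = extract_bullseye(at, seg, model, "EWI")
    assert b.covered.sum() + np.isnan(b.values).sum() == 24


# --------------------------------------------------------------------- EMD
def test_identical_bullseyes_give_zero_delta(model, rng):
    v = rng.normal(100, 20, 24)
    emd = compute_emd(_bse(model, v, "EWI"), _bse(model, v, "ECGI"))
    assert np.allclose(emd.table["delta_ms"], 0.0)
    assert emd.mean_ms == 0.0


def test_uniform_45ms_offset(model, rng):
    v = rng.normal(100, 20, 24)
    emd = compute_emd(_bse(model, v, "EWI"), _bse(model, v - 45.0, "ECGI"))
    assert emd.mean_ms == pytest.approx(45.0)
    assert emd.sd_ms == pytest.approx(0.0, abs=1e-9)
    assert emd.fraction_positive == 1.0


def test_emd_antisymmetric_under_modality_swap(model, rng):
    a = rng.normal(100, 20, 24)
    b = rng.normal(60, 20, 24)
    d1 = compute_emd(_bse(model, a, "EWI"), _bse(model, b, "ECGI"))
    d2 = compute_emd(_bse(model, b, "EWI"), _bse(model, a, "ECGI"))
    assert np.allclose(d1.table["delta_ms"].to_numpy(), -d2.table["delta_ms"].to_numpy())


def test_septal_segments_excluded_from_joint_coverage(model, rng):
    a = rng.normal(100, 20, 24)
    b = a - 40.0
    b[model.septal_ids] = np.nan  # ECGI does not cover the septum
    emd = compute_emd(_bse(model, a, "EWI"), _bse(model, b, "ECGI"))
    assert emd.n == 18
    assert not set(emd.table["segment_id"]) & set(model.septal_ids)


def test_disjoint_coverage_rejected(model):
    a = np.full(24, np.nan)
    a[0] = 1.0
    b = np.full(24, np.nan)
    b[1] = 1.0
    with pytest.raises(ValueError, match="jointly"):
        compute_emd(_bse(model, a, "EWI"), _bse(model, b, "ECGI"))


# ------------------------------------------------------- subgroup analysis
def _emd_table(model, rng, means={"LGE+ve": 50, "LVSD&LGE-ve": 39, "normal": 33},
               n_subj={"LGE+ve": 20, "LVSD&LGE-ve": 4, "normal": 9}, sd=10.0):
    rows = []
    i = 0
    for g, n in n_subj.items():
        for _ in range(n):
            draw = rng.normal(means[g], sd)
            for s in model:
                rows.append({"subject": f"s{i}", "segment_id": s.segment_id,
                             "segment": s.name, "level": s.level, "chamber": s.chamber,
                             "delta_ms": draw + rng.normal(0, 1), "subgroup": g})
            i += 1
    return pd.DataFrame(rows)


def test_subgroup_cells_recover_configured_means(model, rng):
    t = _emd_table(model, rng)
    rep = subgroup_analysis(t)
    for g, mu, n in (("LGE+ve", 50, 20), ("LVSD&LGE-ve", 39, 4), ("normal", 33, 9)):
        got = rep.cells.loc["Global", (g, "mean")]
        se = 10.0 / np.sqrt(n)
        assert abs(got - mu) < 3 * se
    assert rep.anova_p["Global"] < 0.05
    assert rep.cells.loc["Global", ("All", "n")] == 33 * 24


def test_subgroup_analysis_invariant_to_subject_order(model, rng):
    t = _emd_table(model, rng)
    shuffled = t.sample(frac=1.0, random_state=1).reset_index(drop=True)
    a, b = subgroup_analysis(t), subgroup_analysis(shuffled)
    pd.testing.assert_frame_equal(a.cells, b.cells)
    for row in a.anova_p:
        assert a.anova_p[row] == pytest.approx(b.anova_p[row], rel=1e-6)


def test_pairwise_tests_bonferroni_capped(model, rng):
    rep = subgroup_analysis(_emd_table(model, rng))
    pw = rep.pairwise_p["Global"]
    assert len(pw) == 3
    assert all(0.0 <= p <= 1.0 for p in pw.values())
    # clearly separated LGE+ve vs normal at these ns
    assert pw[("LGE+ve", "normal")] < 0.01


def test_single_subgroup_skips_anova_but_reports_means(model, rng):
    t = _emd_table(model, rng, means={"LGE+ve": 50}, n_subj={"LGE+ve": 5})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = subgroup_analysis(t, subgroups=("LGE+ve",))
    assert np.isnan(rep.anova_p["Global"])
    assert np.isfinite(rep.cells.loc["Global", ("All", "mean")])


# ------------------------------------------------------------- localization
def _toy_tables(n=10, correct=True):
    est = pd.DataFrame({
        "map_id": [f"m{i}" for i in range(n)],
        "ewi_segment": ["LV-basal-anterior"] * n,
        "ewi_layer": ["endo"] * n,
        "ewi_diffuse": [False] * n,
        "ecgi_segment": ["LV-basal-anterior"] * n,
    })
    truth = pd.DataFrame({
        "map_id": [f"m{i}" for i in range(n)],
        "segment": ["LV-basal-anterior" if correct else "LV-mid-inferior"] * n,
        "layer": ["endo"] * n,
    })
    return est, truth


def test_all_correct_toy_table(model):
    score = score_localization(*_toy_tables(10, True), model)
    assert score.ewi_segment_accuracy == 1.0
    assert score.ecgi_segment_accuracy == 1.0
    assert score.both_failed == 0.0
    assert score.both_correct == 1.0


def test_diffuse_calls_scored_axially_incorrect(model):
    est, truth = _toy_tables(4, True)
    est.loc[0, "ewi_diffuse"] = True
    score = score_localization(est, truth, model)
    assert score.ewi_axial_accuracy == pytest.approx(3 / 4)


def test_unknown_truth_segment_rejected(model):
    est, truth = _toy_tables(3, True)
    truth.loc[0, "segment"] = "LV-nowhere"
    with pytest.raises(KeyError, match="unknown segment"):
        score_localization(est, truth, model)


def test_aggregates_match_brute_force_counter(model, rng):
    """Aggregates equal hand-counted proportions on a random table."""
    n = 60
    names = model.names
    est = pd.DataFrame({
        "map_id": [f"m{i}" for i in range(n)],
        "ewi_segment": [names[rng.integers(24)] for _ in range(n)],
        "ewi_layer": [("endo", "mid", "epi")[rng.integers(3)] for _ in range(n)],
        "ewi_diffuse": rng.uniform(size=n) < 0.1,
        "ecgi_segment": [names[rng.integers(24)] for _ in range(n)],
    })
    est.loc[5, "ewi_segment"] = None  # one missing EWI map
    est.loc[5, "ewi_layer"] = None
    truth = pd.DataFrame({
        "map_id": [f"m{i}" for i in range(n)],
        "segment": [names[rng.integers(24)] for _ in range(n)],
        "layer": [("endo", "mid", "epi")[rng.integers(3)] for _ in range(n)],
    })
    score = score_localization(est, truth, model)
    # brute-force counts
    ewi_k = ewi_n = ecgi_k = bc = bf = ax_k = ax_n = 0
    for i in range(n):
        t_seg, t_lay = truth.loc[i, "segment"], truth.loc[i, "layer"]
        e_seg = est.loc[i, "ewi_segment"]
        c_ok = est.loc[i, "ecgi_segment"] == t_seg
        ecgi_k += c_ok
        if e_seg is not None:
            ewi_n += 1
            e_ok = e_seg == t_seg
            ewi_k += e_ok
            ax_n += 1
            ax_k += (est.loc[i, "ewi_layer"] == t_lay) and not est.loc[i, "ewi_diffuse"]
            bc += e_ok and c_ok
            bf += (not e_ok) and (not c_ok)
    assert score.ewi_segment_accuracy == pytest.approx(ewi_k / ewi_n)
    assert score.ecgi_segment_accuracy == pytest.approx(ecgi_k / n)
    assert score.ewi_axial_accuracy == pytest.approx(ax_k / ax_n)
    assert score.both_correct == pytest.approx(bc / n)
    assert score.both_failed == pytest.approx(bf / n)


def test_chance_level_accuracy_for_random_calls(model):
    """Random segment calls vs uniform truth: accuracy ~ 1/24."""
    rng = np.random.default_rng(99)
    n = 10_000
    names = model.names
    calls = rng.integers(0, 24, n)
    truth_idx = rng.integers(0, 24, n)
    est = pd.DataFrame({"map_id": np.arange(n), "ecgi_segment": [names[i] for i in calls]})
    truth = pd.DataFrame({"map_id": np.arange(n), "segment": [names[i] for i in truth_idx],
                          "layer": ["endo"] * n})
    score = score_localization(est, truth, model)
    p = 1.0 / 24.0
    se = np.sqrt(p * (1 - p) / n)
    assert abs(score.ecgi_segment_accuracy - p) < 4 * se
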