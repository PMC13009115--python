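"""Segmental EWI-vs-ECGI comparison: bullseyes, electromechanical delay,
subgroup statistics and localization-accuracy scoring.

Epicardial activation times from both modalities are reduced to one value
per segment of the biventricular 24-segment model (a "bullseye"). The
per-segment difference EWI_AT - ECGI_AT is the electromechanical delay (EMD);
it is positive when the electrical activation (ECGI) precedes the
electromechanical activation (EWI). Subgroup statistics follow the
scar-status grouping (LGE+ve / LVSD&LGE-ve / structurally normal) with
one-way ANOVA and Bonferroni-corrected pairwise t-tests. Localization
accuracy compares per-map segment (and, for EWI, transmural layer) calls
against ground truth with exact binomial confidence intervals.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ewimap.mapping import IsochroneMap
from ewimap.phantom.ecgi import ECGIMap
from ewimap.phantom.mask import UNASSIGNED
from ewimap.segments import SegmentModel24, build_segment_model

SUBGROUPS = ("LGE+ve", "LVSD&LGE-ve", "normal")
EPI_MIN_DEPTH = 2.0 / 3.0


@dataclass
class SegmentBullseye:
    """One value per segment of the 24-segment model (NaN where uncovered)."""

    values: np.ndarray  # (24,), NaN = missing
    modality: str  # "EWI" | "ECGI"
    subject_id: str = "s0"
    model: SegmentModel24 = field(default_factory=build_segment_model)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.model),):
            raise ValueError("bullseye needs one value per segment")

    @property
    def covered(self) -> np.ndarray:
        return np.isfinite(self.values)


def extract_bullseye(
    at_ms: np.ndarray,
    segment_ids: np.ndarray,
    model: SegmentModel24,
    modality: str,
    subject_id: str = "s0",
) -> SegmentBullseye:
    """Per-segment mean activation time from scattered samples.

    Samples with NaN activation or unassigned segments are ignored; segments
    with no samples are masked with a warning.
    """
    at = np.asarray(at_ms, dtype=float)
    seg = np.asarray(segment_ids)
    values = np.full(len(model), np.nan)
    ok = np.isfinite(at) & (seg != UNASSIGNED)
    for s in model:
        hit = ok & (seg == s.segment_id)
        if hit.any():
            values[s.segment_id] = at[hit].mean()
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        warnings.warn(f"bullseye[{modality}/{subject_id}]: {n_missing} segments masked (no samples)", stacklevel=2)
    return SegmentBullseye(values=values, modality=modality, subject_id=subject_id, model=model)


def bullseye_from_isochrones(
    views: list[IsochroneMap],
    model: SegmentModel24 | None = None,
    subject_id: str = "s0",
    min_depth: float = EPI_MIN_DEPTH,
) -> SegmentBullseye:
    """EWI bullseye: mean epicardial-band AT per segment over fused views."""
    if not views:
        raise ValueError("need at least one view")
    model = model or views[0].mask.model
    ats, segs = [], []
    for v in views:
        flat = v.mask.flat_indices
        depth = v.mask.wall_depth.ravel()[flat]
        epi = depth >= min_depth
        ats.append(v.at_flat[epi])
        segs.append(v.mask.segment_id.ravel()[flat][epi])
    return extract_bullseye(np.concatenate(ats), np.concatenate(segs), model, "EWI", subject_id)


def bullseye_from_ecgi(ecgi: ECGIMap, subject_id: str | None = None) -> SegmentBullseye:
    """ECGI bullseye: mean node LAT per segment (septal segments masked)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # septal segments are masked by design
        return extract_bullseye(
            ecgi.lat_by_node, ecgi.segment_ids, ecgi.model, "ECGI",
            subject_id or ecgi.subject_id,
        )


EMD_COLUMNS = ("subject", "segment_id", "segment", "level", "chamber", "delta_ms", "subgroup")


@dataclass
class EMDResult:
    """Per-segment EWI-ECGI activation-time differences and their summary."""

    table: pd.DataFrame
    mean_ms: float
    sd_ms: float
    fraction_positive: float  # fraction of segments where ECGI precedes EWI

    @property
    def n(self) -> int:
        return len(self.table)


def compute_emd(
    ewi: SegmentBullseye,
    ecgi: SegmentBullseye,
    subgroup: str = "",
) -> EMDResult:
    """Per-segment delta = EWI_AT - ECGI_AT over jointly covered segments.

    delta > 0 means ECGI (electrical) precedes EWI (electromechanical).
    """
    if ewi.subject_id != ecgi.subject_id:
        raise ValueError("bullseyes belong to different subjects")
    joint = ewi.covered & ecgi.covered
    if not joint.any():
        raise ValueError("no jointly covered segments")
    model = ewi.model
    rows = []
    for sid in np.flatnonzero(joint):
        s = model.by_id(int(sid))
        rows.append(
            {
                "subject": ewi.subject_id,
                "segment_id": s.segment_id,
                "segment": s.name,
                "level": s.level,
                "chamber": s.chamber,
                "delta_ms": float(ewi.values[sid] - ecgi.values[sid]),
                "subgroup": subgroup,
            }
        )
    table = pd.DataFrame(rows, columns=list(EMD_COLUMNS))
    d = table["delta_ms"].to_numpy()
    return EMDResult(
        table=table,
        mean_ms=float(d.mean()),
        sd_ms=float(d.std(ddof=1)) if d.size > 1 else float("nan"),
        fraction_positive=float((d > 0).mean()),
    )


_ROW_FILTERS = {
    "Global": lambda t: np.ones(len(t), bool),
    "Basal": lambda t: (t["level"] == "basal").to_numpy(),
    "Mid": lambda t: (t["level"] == "mid").to_numpy(),
    "Apical": lambda t: (t["level"] == "apical").to_numpy(),
    "RV": lambda t: (t["chamber"] == "RV").to_numpy(),
    "LV": lambda t: (t["chamber"] == "LV").to_numpy(),
}


@dataclass
class SubgroupReport:
    """Mean +/- SD EMD per anatomical row and subgroup column, with tests."""

    cells: pd.DataFrame  # MultiIndex columns (group, stat)
    anova_p: dict[str, float]  # per anatomical row, across subgroups
    pairwise_p: dict[str, dict[tuple[str, str], float]]  # Bonferroni-corrected
    level_anova_p: float  # basal vs mid vs apical (all subjects)
    chamber_p: float  # RV vs LV (all subjects)


def subgroup_analysis(
    emd_table: pd.DataFrame,
    subgroups: tuple[str, ...] = SUBGROUPS,
) -> SubgroupReport:
    """Anatomical x subgroup summary of segment-level EMD with ANOVA.

    Segment-level deltas are pooled within each cell. Rows are Global /
    Basal / Mid / Apical / RV / LV; columns are All plus each subgroup with
    at least 2 subjects (empty or singleton subgroups are dropped with a
    warning). One-way ANOVA tests subgroup differences per row; pairwise
    t-tests are Bonferroni-corrected over the subgroup pairs. The anatomical
    comparisons (basal vs mid vs apical ANOVA, RV vs LV t-test) pool all
    subjects.
    """
    t = emd_table
    present = []
    for g in subgroups:
        n_subj = t.loc[t["subgroup"] == g, "subject"].nunique()
        if n_subj >= 2:
            present.append(g)
        elif n_subj > 0:
            warnings.warn(f"subgroup {g!r} has < 2 subjects; dropped from ANOVA", stacklevel=2)
    run_anova = len(present) >= 2

    cols: dict[tuple[str, str], list[float]] = {}
    anova_p: dict[str, float] = {}
    pairwise_p: dict[str, dict[tuple[str, str], float]] = {}
    row_names = list(_ROW_FILTERS)
    for row in row_names:
        sel = t[_ROW_FILTERS[row](t)]
        for g in ["All", *present]:
            sub = sel if g == "All" else sel[sel["subgroup"] == g]
            d = sub["delta_ms"].to_numpy()
            cols.setdefault((g, "mean"), []).append(float(d.mean()) if d.size else float("nan"))
            cols.setdefault((g, "sd"), []).append(float(d.std(ddof=1)) if d.size > 1 else float("nan"))
            cols.setdefault((g, "n"), []).append(int(d.size))
        if run_anova:
            groups = [sel.loc[sel["subgroup"] == g, "delta_ms"].to_numpy() for g in present]
            groups = [g_ for g_ in groups if g_.size >= 2]
            anova_p[row] = float(stats.f_oneway(*groups).pvalue) if len(groups) >= 2 else float("nan")
            pw: dict[tuple[str, str], float] = {}
            pairs = [p for p in itertools.combinations(present, 2)]
            for g1, g2 in pairs:
                a = sel.loc[sel["subgroup"] == g1, "delta_ms"].to_numpy()
                b = sel.loc[sel["subgroup"] == g2, "delta_ms"].to_numpy()
                if a.size >= 2 and b.size >= 2:
                    p = float(stats.ttest_ind(a, b).pvalue)
                    pw[(g1, g2)] = min(1.0, p * len(pairs))  # Bonferroni
            pairwise_p[row] = pw
        else:
            anova_p[row] = float("nan")
            pairwise_p[row] = {}

    levels = [t.loc[t["level"] == lv, "delta_ms"].to_numpy() for lv in ("basal", "mid", "apical")]
    levels = [x for x in levels if x.size >= 2]
    level_p = float(stats.f_oneway(*levels).pvalue) if len(levels) >= 2 else float("nan")
    rv = t.loc[t["chamber"] == "RV", "delta_ms"].to_numpy()
    lv = t.loc[t["chamber"] == "LV", "delta_ms"].to_numpy()
    chamber_p = float(stats.ttest_ind(rv, lv).pvalue) if rv.size >= 2 and lv.size >= 2 else float("nan")

    cells = pd.DataFrame(cols, index=row_names)
    cells.columns = pd.MultiIndex.from_tuples(cells.columns, names=["group", "stat"])
    return SubgroupReport(
        cells=cells,
        anova_p=anova_p,
        pairwise_p=pairwise_p,
        level_anova_p=level_p,
        chamber_p=chamber_p,
    )


def _binom_ci(k: int, n: int) -> tuple[float, float]:
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
    return float(ci.low), float(ci.high)


@dataclass
class LocalizationScore:
    """Per-map correctness booleans and aggregate proportions.

    Proportions are fractions in [0, 1]; ``*_ci`` are exact (Clopper-Pearson)
    binomial 95% confidence intervals. Per-modality segment accuracy is over
    maps where that modality produced a call; both-correct / both-failed are
    over all maps (a missing call counts as neither correct nor failed).
    EWI axial (transmural) accuracy counts diffuse calls as incorrect.
    """

    per_map: pd.DataFrame
    ewi_segment_accuracy: float
    ecgi_segment_accuracy: float
    ewi_axial_accuracy: float
    both_correct: float
    both_failed: float
    axial_accuracy_by_layer: dict[str, float]
    ewi_segment_ci: tuple[float, float]
    ecgi_segment_ci: tuple[float, float]
    ewi_axial_ci: tuple[float, float]


def score_localization(
    estimates: pd.DataFrame,
    truth: pd.DataFrame,
    model: SegmentModel24 | None = None,
) -> LocalizationScore:
    """Score anatomical-segment and transmural calls against ground truth.

    ``estimates`` columns: map_id, ewi_segment, ewi_layer, ewi_diffuse,
    ecgi_segment (any of the call columns may hold NaN/None for a missing
    map). ``truth`` columns: map_id, segment, layer.
    """
    model = model or build_segment_model()
    need_e = {"map_id"}
    if not need_e <= set(estimates.columns):
        raise ValueError("estimates must carry a map_id column")
    if not {"map_id", "segment", "layer"} <= set(truth.columns):
        raise ValueError("truth must carry map_id, segment, layer columns")
    merged = estimates.merge(truth, on="map_id", how="left", suffixes=("", "_true"))
    if merged["segment"].isna().any():
        missing = merged.loc[merged["segment"].isna(), "map_id"].tolist()
        raise ValueError(f"maps without truth rows: {missing}")
    for s in merged["segment"]:
        model.by_name(s)  # raises on unknown truth segment

    def _match(col):
        out = np.full(len(merged), np.nan)
        if col in merged.columns:
            has = merged[col].notna().to_numpy()
            out[has] = (merged.loc[has, col] == merged.loc[has, "segment"]).to_numpy()
        return out

    ewi_ok = _match("ewi_segment")
    ecgi_ok = _match("ecgi_segment")
    axial_ok = np.full(len(merged), np.nan)
    if "ewi_layer" in merged.columns:
        has = merged["ewi_layer"].notna().to_numpy()
        diffuse = merged.get("ewi_diffuse", pd.Series(False, index=merged.index)).fillna(False).to_numpy(bool)
        axial_ok[has] = ((merged.loc[has, "ewi_layer"] == merged.loc[has, "layer"]).to_numpy()
                         & ~diffuse[has])

    per_map = merged.assign(ewi_correct=ewi_ok, ecgi_correct=ecgi_ok, ewi_axial_correct=axial_ok)

    def _prop(arr):
        ok = ~np.isnan(arr)
        k, n = int(np.nansum(arr)), int(ok.sum())
        return k, n, (k / n if n else float("nan"))

    ke, ne, pe = _prop(ewi_ok)
    kc, nc, pc = _prop(ecgi_ok)
    ka, na, pa = _prop(axial_ok)
    n_all = len(merged)
    both_correct = float(np.sum((ewi_ok == 1) & (ecgi_ok == 1)) / n_all)
    both_failed = float(np.sum((ewi_ok == 0) & (ecgi_ok == 0)) / n_all)
    by_layer = {}
    for layer in ("endo", "mid", "epi"):
        sel = (merged["layer"] == layer).to_numpy() & ~np.isnan(axial_ok)
        if sel.any():
            by_layer[layer] = float(np.nansum(axial_ok[sel]) / sel.sum())
    return LocalizationScore(
        per_map=per_map,
        ewi_segment_accuracy=pe,
        ecgi_segment_accuracy=pc,
        ewi_axial_accuracy=pa,
        both_correct=both_correct,
        both_failed=both_failed,
        axial_accuracy_by_layer=by_layer,
        ewi_segment_ci=_binom_ci(ke, ne) if ne else (float("nan"), float("nan")),
        ecgi_segment_ci=_binom_ci(kc, nc) if nc else (float("nan"), float("nan")),
        ewi_axial_ci=_binom_ci(ka, na) if na else (float("nan"), float("nan")),
    )
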