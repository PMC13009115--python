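"""Unipolar electrogram analysis for ECGI-style epicardial maps.

Implements the measurement operators applied to reconstructed epicardial
unipolar electrograms (UEGMs) sampled at 1000 Hz: beat averaging with a
correlation-threshold gate, local activation time (LAT) as the time of
maximum negative dV/dt, QS/rS morphology classification, slew rate, and the
layer-wise surrogate statistics (slew-rate ANOVA, morphology contingency).

All derivative-based measurements operate on the 100 Hz low-pass filtered
signal; the filter is a zero-phase 4th-order Butterworth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import butter, sosfiltfilt

DEFAULT_FS_HZ = 1000.0
DEFAULT_LOWPASS_HZ = 100.0
#: beat-averaging acceptance threshold (Pearson correlation with the template)
BEAT_CORR_THRESHOLD = 0.93


def lowpass_filter(
    samples: np.ndarray,
    fs_hz: float = DEFAULT_FS_HZ,
    cutoff_hz: float = DEFAULT_LOWPASS_HZ,
    order: int = 4,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (default 100 Hz at 1000 Hz sampling)."""
    sos = butter(order, cutoff_hz, btype="low", fs=fs_hz, output="sos")
    return sosfiltfilt(sos, np.asarray(samples, dtype=float), axis=axis)


@dataclass
class UnipolarEGM:
    """Reconstructed epicardial unipolar electrogram (mV at ``fs_hz``).

    ``t0_ms`` is the time of the first sample on the common clock (ms
    relative to QRS onset / pacing spike), so pre-reference activity can be
    represented. ``filtered`` must be set (by :func:`lowpass_filter`) before
    any derivative-based measurement.
    """

    samples_mv: np.ndarray
    fs_hz: float = DEFAULT_FS_HZ
    node_id: int = 0
    filtered: bool = False
    t0_ms: float = 0.0

    def __post_init__(self):
        self.samples_mv = np.asarray(self.samples_mv, dtype=float)
        if self.samples_mv.ndim != 1:
            raise ValueError("UEGM samples must be 1-D")
        if len(self.samples_mv) < 50:
            raise ValueError("UEGM must have at least 50 samples")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.fs_hz

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(len(self.samples_mv)) * self.dt_ms


def _central_diff_mv_ms(uegm: UnipolarEGM) -> np.ndarray:
    """Central first difference dV/dt on interior samples, mV/ms."""
    v = uegm.samples_mv
    return (v[2:] - v[:-2]) / (2.0 * uegm.dt_ms)


@dataclass(frozen=True)
class LATResult:
    lat_ms: float
    defined: bool


def compute_lat(uegm: UnipolarEGM) -> LATResult:
    """Local activation time: sample time of the maximum negative dV/dt.

    Ties are broken to the earliest sample. A signal with no negative slope
    anywhere is flagged undefined (NaN time).
    """
    if not uegm.filtered:
        raise ValueError("compute_lat requires a low-pass filtered UEGM")
    d = _central_diff_mv_ms(uegm)
    d_min = d.min()
    if d_min >= 0.0:
        return LATResult(lat_ms=float("nan"), defined=False)
    # earliest sample within rounding tolerance of the steepest descent
    tol = 1e-12 * max(1.0, abs(d_min))
    i = int(np.flatnonzero(d <= d_min + tol)[0])
    return LATResult(lat_ms=float(uegm.t0_ms + (i + 1) * uegm.dt_ms), defined=True)


def slew_rate(uegm: UnipolarEGM) -> float:
    """|maximum negative dV/dt| in mV/ms (0 for signals with no descent)."""
    if not uegm.filtered:
        raise ValueError("slew_rate requires a low-pass filtered UEGM")
    if len(uegm.samples_mv) < 2:
        raise ValueError("slew_rate undefined on < 2 samples")
    d = _central_diff_mv_ms(uegm)
    return float(max(0.0, -d.min()))


def classify_morphology(
    uegm: UnipolarEGM,
    r_threshold: float = 0.1,
    baseline_ms: float = 10.0,
) -> str:
    """Classify the UEGM as ``"QS"``, ``"rS"`` or ``"other"``.

    An initial positive (r) deflection exceeding ``r_threshold`` times the
    dominant negative amplitude, occurring before the dominant negative
    deflection, makes the beat rS; a dominant negative deflection without
    such an r wave is QS; a trace with no meaningful negative deflection is
    "other". The baseline is the mean over the leading ``baseline_ms``.
    """
    v = uegm.samples_mv
    if np.all(v == 0.0):
        raise ValueError("all-zero UEGM")
    n_base = max(1, int(round(baseline_ms / uegm.dt_ms)))
    base = float(np.mean(v[:n_base]))
    w = v - base
    i_min = int(np.argmin(w))
    neg = -w[i_min]
    if neg <= 0.05 * np.max(np.abs(w)) or neg <= 1e-12:
        return "other"
    r_amp = float(np.max(w[:i_min], initial=0.0))
    if r_amp > r_threshold * neg:
        return "rS"
    return "QS"


@dataclass
class AveragedBeat:
    samples_mv: np.ndarray
    n_accepted: int
    accepted: np.ndarray  # bool per input beat
    correlations: np.ndarray  # best-lag Pearson r per beat
    lags: np.ndarray  # best alignment lag per beat (samples)


def _best_lag_correlation(beat: np.ndarray, template: np.ndarray):
    """Pearson correlation with the template at every lag; return best."""
    k = len(template)
    n_lags = len(beat) - k + 1
    tc = template - template.mean()
    ts = float(np.sqrt((tc**2).sum()))
    best_r, best_lag = -np.inf, 0
    for lag in range(n_lags):
        seg = beat[lag : lag + k]
        sc = seg - seg.mean()
        denom = ts * float(np.sqrt((sc**2).sum()))
        r = float((sc @ tc) / denom) if denom > 0 else 0.0
        if r > best_r:
            best_r, best_lag = r, lag
    return best_r, best_lag


def average_beats(
    beats: np.ndarray,
    template: np.ndarray,
    threshold: float = BEAT_CORR_THRESHOLD,
) -> AveragedBeat:
    """Temporal signal averaging gated on template correlation.

    Each beat window is aligned to the template at its maximum-correlation
    lag; beats whose best-lag Pearson correlation falls below ``threshold``
    are rejected. The accepted, aligned windows are averaged pointwise.

    Raises
    ------
    ValueError
        If the template is longer than the beats, or zero beats are accepted.
    """
    beats = np.atleast_2d(np.asarray(beats, dtype=float))
    template = np.asarray(template, dtype=float)
    if len(template) > beats.shape[1]:
        raise ValueError("template longer than the beat windows")
    rs = np.empty(len(beats))
    lags = np.empty(len(beats), dtype=int)
    for i, beat in enumerate(beats):
        rs[i], lags[i] = _best_lag_correlation(beat, template)
    accepted = rs >= threshold
    if not accepted.any():
        raise ValueError("no beats accepted at the correlation threshold")
    k = len(template)
    aligned = np.stack([beats[i, lags[i] : lags[i] + k] for i in np.flatnonzero(accepted)])
    return AveragedBeat(
        samples_mv=aligned.mean(axis=0),
        n_accepted=int(accepted.sum()),
        accepted=accepted,
        correlations=rs,
        lags=lags,
    )


SURROGATE_COLUMNS = ("map_id", "layer", "morphology", "slew_rate")


@dataclass
class SurrogateSummary:
    """Layer-wise UEGM surrogate statistics (slew rate and QS fraction)."""

    table: pd.DataFrame
    anova_p: float
    chi2_p: float
    excluded_layers: tuple[str, ...] = field(default_factory=tuple)


def surrogate_stats(records: pd.DataFrame) -> SurrogateSummary:
    """Layer-wise means +/- SD of slew rate, QS proportions, and tests.

    One-way ANOVA compares slew rate across truth layers (layers with fewer
    than 2 records are excluded with a warning); a chi-square contingency
    test compares QS vs non-QS morphology across layers.
    """
    missing = [c for c in SURROGATE_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"surrogate records missing columns {missing}")
    layers = [l for l in ("endo", "mid", "epi") if l in set(records["layer"])]
    if len(layers) < 2:
        raise ValueError("surrogate_stats requires records from >= 2 layers")

    rows = []
    groups, excluded = [], []
    for layer in layers:
        sub = records[records["layer"] == layer]
        slew = sub["slew_rate"].to_numpy(dtype=float)
        n_qs = int((sub["morphology"] == "QS").sum())
        rows.append(
            {
                "layer": layer,
                "n": len(sub),
                "slew_mean": float(np.mean(slew)),
                "slew_sd": float(np.std(slew, ddof=1)) if len(slew) > 1 else float("nan"),
                "n_qs": n_qs,
                "qs_fraction": n_qs / len(sub),
            }
        )
        if len(sub) >= 2:
            groups.append(slew)
        else:
            excluded.append(layer)
            warnings.warn(f"layer {layer!r} has < 2 records; excluded from ANOVA", stacklevel=2)
    anova_p = float(stats.f_oneway(*groups).pvalue) if len(groups) >= 2 else float("nan")

    contingency = pd.crosstab(records["layer"], records["morphology"] == "QS")
    if contingency.shape[1] < 2:
        warnings.warn("single morphology class; chi-square undefined", stacklevel=2)
        chi2_p = float("nan")
    else:
        chi2_p = float(stats.chi2_contingency(contingency.to_numpy()).pvalue)
    return SurrogateSummary(
        table=pd.DataFrame(rows).set_index("layer"),
        anova_p=anova_p,
        chi2_p=chi2_p,
        excluded_layers=tuple(excluded),
    )
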