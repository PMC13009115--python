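"""ECGI-style epicardial activation maps with synthetic unipolar electrograms.

Nodes are sampled on the epicardial band of segments covered by ECGI (septal
segments are never covered). Each node's UEGM is constructed so that its
maximum negative dV/dt falls at the node's electrical activation time, with
QS morphology when the configured source layer is epicardial and rS
otherwise. The downstroke amplitude is calibrated after 100 Hz low-pass
filtering so the measured slew rate equals the configured value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ewimap.egm import DEFAULT_FS_HZ, UnipolarEGM, compute_lat, lowpass_filter, slew_rate
from ewimap.phantom.activation import ActivationField
from ewimap.segments import SegmentModel24


def synthesize_uegm(
    at_ms: float,
    *,
    t0_ms: float = -100.0,
    duration_ms: float = 500.0,
    fs_hz: float = DEFAULT_FS_HZ,
    amplitude_mv: float = 1.5,
    slew_mv_ms: float = 0.32,
    morphology: str = "QS",
    r_fraction: float = 0.2,
    r_lead_ms: float = 15.0,
    r_width_ms: float = 4.0,
    repol_ms: float = 180.0,
    noise_sd_mv: float = 0.0,
    node_id: int = 0,
    rng: np.random.Generator | None = None,
) -> UnipolarEGM:
    """Build a filtered UEGM whose LAT operator returns ``at_ms``.

    The intrinsic deflection is a tanh downstroke centred on ``at_ms``; a
    slow repolarization wave restores the baseline. For rS morphology a small
    positive r wave (``r_fraction`` of the downstroke amplitude) precedes the
    deflection by ``r_lead_ms``; its slopes are kept well below the
    downstroke slew so the LAT is unaffected. After zero-phase low-pass
    filtering the trace is rescaled so the measured slew rate equals
    ``slew_mv_ms`` exactly (slew scales linearly with amplitude).
    """
    if morphology not in ("QS", "rS"):
        raise ValueError("morphology must be 'QS' or 'rS'")
    # the downstroke and repolarization wave must fit inside the window
    duration_ms = max(duration_ms, at_ms + repol_ms + 120.0 - t0_ms)
    n = int(round(duration_ms * fs_hz / 1000.0))
    t = t0_ms + np.arange(n) * 1000.0 / fs_hz
    if not t[0] + 5.0 < at_ms:
        raise ValueError("activation time too close to the start of the UEGM window")
    w = amplitude_mv / (2.0 * slew_mv_ms)  # continuous-time width for the target slew
    v = -0.5 * amplitude_mv * (1.0 + np.tanh((t - at_ms) / w))
    v += 0.5 * amplitude_mv * (1.0 + np.tanh((t - at_ms - repol_ms) / 40.0))
    if morphology == "rS":
        v += r_fraction * amplitude_mv * np.exp(-0.5 * ((t - (at_ms - r_lead_ms)) / r_width_ms) ** 2)
    v = lowpass_filter(v, fs_hz=fs_hz)
    probe = UnipolarEGM(v, fs_hz=fs_hz, node_id=node_id, filtered=True, t0_ms=t0_ms)
    measured = slew_rate(probe)
    if measured > 0:
        v = v * (slew_mv_ms / measured)
    if noise_sd_mv > 0:
        rng = rng or np.random.default_rng()
        v = v + lowpass_filter(rng.normal(0.0, noise_sd_mv, n), fs_hz=fs_hz)
    return UnipolarEGM(v, fs_hz=fs_hz, node_id=node_id, filtered=True, t0_ms=t0_ms)


@dataclass
class ECGINode:
    """One epicardial node: position, electrical truth, UEGM and its LAT."""

    node_id: int
    xy_mm: tuple[float, float]
    segment_id: int
    at_ms: float  # true electrical activation time
    uegm: UnipolarEGM
    lat_ms: float  # LAT operator applied to the UEGM
    morphology: str


@dataclass
class ECGIMap:
    """Epicardial activation map: nodes on ECGI-covered segments only."""

    nodes: list[ECGINode]
    model: SegmentModel24
    subject_id: str = "s0"

    @property
    def lat_by_node(self) -> np.ndarray:
        return np.array([n.lat_ms for n in self.nodes])

    @property
    def segment_ids(self) -> np.ndarray:
        return np.array([n.segment_id for n in self.nodes])


def synthesize_ecgi(
    field: ActivationField,
    *,
    nodes_per_segment: int = 3,
    segments: list[str] | None = None,
    epi_min_depth: float = 2.0 / 3.0,
    subject_id: str = "s0",
    uegm_kwargs: dict | None = None,
    rng: np.random.Generator | None = None,
) -> ECGIMap:
    """Sample epicardial nodes and reconstruct their UEGMs.

    Node positions are drawn from the epicardial band (wall_depth >=
    ``epi_min_depth``) of each requested segment; by default all ECGI-covered
    segments present in the mask. UEGM morphology is QS when the field's
    source layer is epicardial, rS otherwise.

    Raises
    ------
    ValueError
        If nodes are requested on septal segments (not represented by ECGI).
    """
    rng = rng or np.random.default_rng()
    mask = field.mask
    model = mask.model
    if segments is None:
        seg_objs = [model.by_id(i) for i in sorted(set(mask.segment_id[mask.inside].tolist()))
                    if i >= 0 and model.by_id(i).ecgi_covered]
    else:
        seg_objs = [model.by_name(s) for s in segments]
        septal = [s.name for s in seg_objs if s.septal]
        if septal:
            raise ValueError(f"ECGI does not cover septal segments: {septal}")
    morphology = "QS" if field.truth.layer == "epi" else "rS"
    uegm_kwargs = dict(uegm_kwargs or {})
    # one common window long enough for the latest node keeps UEGMs stackable
    t0 = uegm_kwargs.get("t0_ms", -100.0)
    repol = uegm_kwargs.get("repol_ms", 180.0)
    max_at = float(np.nanmax(field.at_ms))
    uegm_kwargs.setdefault("duration_ms", max(500.0, max_at + repol + 120.0 - t0))

    flat = mask.flat_indices
    depth = mask.wall_depth.ravel()[flat]
    seg_of = mask.segment_id.ravel()[flat]
    at_of = field.at_ms.ravel()[flat]
    nodes: list[ECGINode] = []
    nid = 0
    for seg in seg_objs:
        cand = np.flatnonzero((seg_of == seg.segment_id) & (depth >= epi_min_depth) & np.isfinite(at_of))
        if cand.size == 0:
            continue
        take = min(nodes_per_segment, cand.size)
        chosen = rng.choice(cand, size=take, replace=False)
        for c in chosen:
            at = float(at_of[c])
            uegm = synthesize_uegm(at, morphology=morphology, node_id=nid, rng=rng, **uegm_kwargs)
            lat = compute_lat(uegm)
            xy = mask.xy_of_flat(np.array([flat[c]]))[0]
            nodes.append(
                ECGINode(
                    node_id=nid,
                    xy_mm=(float(xy[0]), float(xy[1])),
                    segment_id=seg.segment_id,
                    at_ms=at,
                    uegm=uegm,
                    lat_ms=float(lat.lat_ms),
                    morphology=morphology,
                )
            )
            nid += 1
    if not nodes:
        raise ValueError("no epicardial nodes could be sampled on covered segments")
    return ECGIMap(nodes=nodes, model=model, subject_id=subject_id)
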