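"""Typed HDF5 containers and CSV tables.

Conventions: times are milliseconds, lengths millimetres, strain
dimensionless. Every HDF5 container declares its units as attributes and
readers reject files where they are absent rather than silently assuming
them; CSV tables carry declared column schemas and readers name the missing
column on mismatch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import h5py

from ewimap.phantom.mask import MyocardialMask
from ewimap.phantom.rf import RFFrames
from ewimap.phantom.strain import ECGTrace, StrainMovie
from ewimap.segments import build_segment_model


class SchemaError(ValueError):
    """A container or table does not match its declared schema."""


def _ds(g, name, data):
    # track_times=False keeps files byte-identical under identical inputs
    g.create_dataset(name, data=data, track_times=False)


#: required columns per CSV table kind
CSV_SCHEMAS: dict[str, tuple[str, ...]] = {
    "truth": ("map_id", "subject", "segment", "layer"),
    "soo": ("map_id", "segment", "layer", "earliest_ms", "diffuse"),
    "surrogate": ("map_id", "layer", "morphology", "slew_rate"),
    "emd": ("subject", "segment_id", "segment", "level", "chamber", "delta_ms", "subgroup"),
    "localization": ("map_id", "ewi_correct", "ecgi_correct", "ewi_axial_correct"),
}


def write_table(df: pd.DataFrame, path, kind: str) -> None:
    missing = [c for c in CSV_SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} table missing column(s) {missing}")
    df.to_csv(path, index=False)


def read_table(path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CSV_SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} table at {path} missing column(s) {missing}")
    return df


def _require_attr(obj, name: str, path):
    if name not in obj.attrs:
        raise SchemaError(f"attribute {name!r} absent in {path}")
    return obj.attrs[name]


def _write_mask(g: h5py.Group, mask: MyocardialMask) -> None:
    _ds(g, "inside", mask.inside)
    _ds(g, "wall_depth", mask.wall_depth)
    _ds(g, "segment_id", mask.segment_id)
    g.attrs["spacing_mm"] = mask.spacing_mm
    g.attrs["origin_mm"] = mask.origin_mm
    g.attrs["units_length"] = "mm"
    g.attrs["view_name"] = mask.view_name
    g.attrs["segment_names"] = list(mask.segment_names)


def _read_mask(g: h5py.Group, path) -> MyocardialMask:
    spacing = float(_require_attr(g, "spacing_mm", path))
    _require_attr(g, "units_length", path)
    return MyocardialMask(
        inside=g["inside"][...].astype(bool),
        wall_depth=g["wall_depth"][...],
        segment_id=g["segment_id"][...],
        spacing_mm=spacing,
        origin_mm=tuple(g.attrs["origin_mm"]),
        view_name=str(g.attrs.get("view_name", "custom")),
        segment_names=tuple(str(s) for s in g.attrs.get("segment_names", [])),
        model=build_segment_model(),
    )


def save_strain_movie(path, movie: StrainMovie) -> None:
    with h5py.File(path, "w") as f:
        _ds(f, "strain", movie.frames)
        _ds(f, "pixel_flat", movie.pixel_flat)
        f.attrs["frame_rate_hz"] = movie.frame_rate_hz
        f.attrs["units_time"] = "ms"
        f.attrs["units_strain"] = "1"
        _write_mask(f.create_group("mask"), movie.mask)
        e = f.create_group("ecg")
        _ds(e, "samples_mv", movie.ecg.samples_mv)
        e.attrs["fs_hz"] = movie.ecg.fs_hz
        e.attrs["qrs_onset_ms"] = np.nan if movie.ecg.qrs_onset_ms is None else movie.ecg.qrs_onset_ms
        e.attrs["pacing_spike_ms"] = np.nan if movie.ecg.pacing_spike_ms is None else movie.ecg.pacing_spike_ms
        e.attrs["beat_type"] = movie.ecg.beat_type


def load_strain_movie(path) -> StrainMovie:
    with h5py.File(path, "r") as f:
        frame_rate = float(_require_attr(f, "frame_rate_hz", path))
        _require_attr(f, "units_time", path)
        _require_attr(f, "units_strain", path)
        mask = _read_mask(f["mask"], path)
        e = f["ecg"]
        qrs = float(e.attrs["qrs_onset_ms"])
        spike = float(e.attrs["pacing_spike_ms"])
        ecg = ECGTrace(
            samples_mv=e["samples_mv"][...],
            fs_hz=float(e.attrs["fs_hz"]),
            qrs_onset_ms=None if np.isnan(qrs) else qrs,
            pacing_spike_ms=None if np.isnan(spike) else spike,
            beat_type=str(e.attrs["beat_type"]),
        )
        return StrainMovie(
            frames=f["strain"][...],
            frame_rate_hz=frame_rate,
            pixel_flat=f["pixel_flat"][...],
            mask=mask,
            ecg=ecg,
        )


def save_rf(path, frames: RFFrames) -> None:
    with h5py.File(path, "w") as f:
        _ds(f, "rf", frames.data)
        f.attrs["fs_hz"] = frames.fs_hz
        f.attrs["frame_rate_hz"] = frames.frame_rate_hz
        f.attrs["c_m_s"] = frames.c_m_s
        f.attrs["units_time"] = "ms"


def load_rf(path) -> RFFrames:
    with h5py.File(path, "r") as f:
        _require_attr(f, "units_time", path)
        return RFFrames(
            data=f["rf"][...],
            fs_hz=float(_require_attr(f, "fs_hz", path)),
            frame_rate_hz=float(_require_attr(f, "frame_rate_hz", path)),
            c_m_s=float(f.attrs.get("c_m_s", 1540.0)),
        )


def save_isochrone(path, at_ms: np.ndarray, extrapolated: np.ndarray, mask: MyocardialMask) -> None:
    with h5py.File(path, "w") as f:
        _ds(f, "at_ms", at_ms)
        _ds(f, "extrapolated", extrapolated)
        f.attrs["units_time"] = "ms"
        _write_mask(f.create_group("mask"), mask)


def load_isochrone(path):
    from ewimap.mapping import IsochroneMap

    with h5py.File(path, "r") as f:
        _require_attr(f, "units_time", path)
        mask = _read_mask(f["mask"], path)
        return IsochroneMap(
            at_ms=f["at_ms"][...],
            extrapolated=f["extrapolated"][...].astype(bool),
            mask=mask,
            view_name=mask.view_name,
        )


def save_ecgi_nodes(path, ecgi) -> None:
    """Node table + stacked UEGM matrix for an ECGI map."""
    uegms = np.stack([n.uegm.samples_mv for n in ecgi.nodes])
    with h5py.File(path, "w") as f:
        _ds(f, "uegm_mv", uegms)
        _ds(f, "xy_mm", np.array([n.xy_mm for n in ecgi.nodes]))
        _ds(f, "segment_id", np.array([n.segment_id for n in ecgi.nodes]))
        _ds(f, "at_ms", np.array([n.at_ms for n in ecgi.nodes]))
        _ds(f, "lat_ms", ecgi.lat_by_node)
        f.attrs["fs_hz"] = ecgi.nodes[0].uegm.fs_hz
        f.attrs["t0_ms"] = ecgi.nodes[0].uegm.t0_ms
        f.attrs["filtered"] = True
        f.attrs["units_time"] = "ms"
        f.attrs["units_voltage"] = "mV"
        f.attrs["subject_id"] = ecgi.subject_id


def load_ecgi_nodes(path):
    """Load the node table back as (DataFrame, uegm matrix, fs, t0)."""
    with h5py.File(path, "r") as f:
        _require_attr(f, "units_time", path)
        _require_attr(f, "units_voltage", path)
        fs = float(_require_attr(f, "fs_hz", path))
        t0 = float(f.attrs.get("t0_ms", 0.0))
        table = pd.DataFrame(
            {
                "node_id": np.arange(f["uegm_mv"].shape[0]),
                "x_mm": f["xy_mm"][:, 0],
                "y_mm": f["xy_mm"][:, 1],
                "segment_id": f["segment_id"][...],
                "at_ms": f["at_ms"][...],
                "lat_ms": f["lat_ms"][...],
            }
        )
        return table, f["uegm_mv"][...], fs, t0
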