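"""Biventricular 24-segment model and per-view segment allocation.

The left ventricle follows the AHA convention (6 basal + 6 mid + 4 apical
segments); the right ventricle adds 8 segments (3 basal, 3 mid, 2 apical).
Septal segments carry a flag because epicardially reconstructed ECGI maps do
not represent the septum: those segments are never covered by ECGI nodes.

The allocation of segments to echocardiographic views is encoded as data
(``VIEW_SEGMENTS``): each view's myocardial arc is divided into contiguous
sub-arcs, one per listed segment, ordered along the arc. The six standard
views jointly cover all 24 segments. ``COHORT_SEGMENT_ORDER`` arranges all 24
segments around an idealized full-ring biventricular annulus used by the
cohort phantom.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

_LV_WALLS_6 = (
    "anterior",
    "anteroseptal",
    "inferoseptal",
    "inferior",
    "inferolateral",
    "anterolateral",
)
_LV_WALLS_APICAL = ("anterior", "septal", "inferior", "lateral")
_RV_BASAL = ("free-anterior", "free-lateral", "septal")
_RV_MID = ("free-anterior", "free-lateral", "inferior")
_RV_APICAL = ("anterior", "inferior")

LAYERS = ("endo", "mid", "epi")
LEVELS = ("basal", "mid", "apical")


@dataclass(frozen=True)
class Segment:
    segment_id: int
    name: str
    chamber: str  # "LV" | "RV"
    level: str  # "basal" | "mid" | "apical"
    wall: str
    septal: bool

    @property
    def ecgi_covered(self) -> bool:
        return not self.septal


class SegmentModel24:
    """The biventricular 24-segment model (16 LV + 8 RV)."""

    def __init__(self, segments: tuple[Segment, ...]):
        if len(segments) != 24:
            raise ValueError(f"expected 24 segments, got {len(segments)}")
        names = [s.name for s in segments]
        if len(set(names)) != 24:
            raise ValueError("segment names must be unique")
        self.segments = segments
        self._by_name = {s.name: s for s in segments}
        self._by_id = {s.segment_id: s for s in segments}

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.segments]

    @property
    def septal_ids(self) -> list[int]:
        return [s.segment_id for s in self.segments if s.septal]

    @property
    def ecgi_covered_ids(self) -> list[int]:
        return [s.segment_id for s in self.segments if s.ecgi_covered]

    def by_name(self, name: str) -> Segment:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown segment {name!r}") from None

    def by_id(self, segment_id: int) -> Segment:
        try:
            return self._by_id[int(segment_id)]
        except KeyError:
            raise KeyError(f"unknown segment id {segment_id}") from None

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment_id": [s.segment_id for s in self.segments],
                "name": self.names,
                "chamber": [s.chamber for s in self.segments],
                "level": [s.level for s in self.segments],
                "wall": [s.wall for s in self.segments],
                "septal": [s.septal for s in self.segments],
                "ecgi_covered": [s.ecgi_covered for s in self.segments],
            }
        )


def build_segment_model() -> SegmentModel24:
    """Build the canonical 24-segment model.

    LV: 6 basal, 6 mid, 4 apical; RV: 3 basal, 3 mid, 2 apical. The five LV
    septal segments (basal/mid antero- and inferoseptal, apical septal) and
    the RV basal septal segment carry the septal flag.
    """
    segs: list[Segment] = []
    i = 0
    for level, walls in (("basal", _LV_WALLS_6), ("mid", _LV_WALLS_6), ("apical", _LV_WALLS_APICAL)):
        for wall in walls:
            segs.append(
                Segment(i, f"LV-{level}-{wall}", "LV", level, wall, septal="sept" in wall)
            )
            i += 1
    for level, walls in (("basal", _RV_BASAL), ("mid", _RV_MID), ("apical", _RV_APICAL)):
        for wall in walls:
            segs.append(
                Segment(i, f"RV-{level}-{wall}", "RV", level, wall, septal="sept" in wall)
            )
            i += 1
    return SegmentModel24(tuple(segs))


#: Ordered segment lists per standard view (along the myocardial arc).
VIEW_SEGMENTS: dict[str, tuple[str, ...]] = {
    "4ch": (
        "LV-basal-inferoseptal",
        "LV-mid-inferoseptal",
        "LV-apical-septal",
        "LV-apical-lateral",
        "LV-mid-anterolateral",
        "LV-basal-anterolateral",
    ),
    "5ch": (
        "LV-basal-inferoseptal",
        "LV-mid-inferoseptal",
        "LV-apical-septal",
        "LV-apical-anterior",
        "LV-mid-anterolateral",
        "LV-basal-anterolateral",
    ),
    "3ch": (
        "LV-basal-inferolateral",
        "LV-mid-inferolateral",
        "LV-apical-lateral",
        "LV-apical-anterior",
        "LV-mid-anteroseptal",
        "LV-basal-anteroseptal",
    ),
    "2ch": (
        "LV-basal-inferior",
        "LV-mid-inferior",
        "LV-apical-inferior",
        "LV-apical-anterior",
        "LV-mid-anterior",
        "LV-basal-anterior",
    ),
    "RVIT": (
        "RV-basal-septal",
        "RV-mid-inferior",
        "RV-apical-inferior",
        "RV-apical-anterior",
        "RV-mid-free-anterior",
        "RV-basal-free-anterior",
    ),
    "3.5ch": (
        "RV-basal-free-lateral",
        "RV-mid-free-lateral",
        "RV-apical-anterior",
        "LV-apical-lateral",
        "LV-mid-anterolateral",
        "LV-basal-anterolateral",
    ),
}

#: All 24 segments ordered around the idealized full-ring cohort phantom:
#: LV free wall -> LV septum -> RV septum -> RV free wall, basal->apical->basal
#: within each wall group, so neighbouring sectors are anatomically adjacent.
COHORT_SEGMENT_ORDER: tuple[str, ...] = (
    "LV-basal-anterior",
    "LV-mid-anterior",
    "LV-apical-anterior",
    "LV-apical-lateral",
    "LV-mid-anterolateral",
    "LV-basal-anterolateral",
    "LV-basal-inferolateral",
    "LV-mid-inferolateral",
    "LV-apical-inferior",
    "LV-mid-inferior",
    "LV-basal-inferior",
    "LV-basal-inferoseptal",
    "LV-mid-inferoseptal",
    "LV-apical-septal",
    "LV-mid-anteroseptal",
    "LV-basal-anteroseptal",
    "RV-basal-septal",
    "RV-mid-inferior",
    "RV-apical-inferior",
    "RV-apical-anterior",
    "RV-mid-free-anterior",
    "RV-basal-free-anterior",
    "RV-basal-free-lateral",
    "RV-mid-free-lateral",
)
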