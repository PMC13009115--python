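"""Sector-scan view geometry for high-frame-rate echocardiographic acquisitions.

A view is a 2D ultrasound sector: ``n_lines`` scan lines fanned over
``sector_angle`` degrees from the transducer apex, sampled to ``depth_max_mm``.
The default parameters describe a 128-line, 90 degree sector acquired with a
single diverging wave at 2000 frames per second, i.e. a temporal resolution of
0.5 ms per frame.

Coordinates are Cartesian millimetres with the apex at ``apex_position`` and
the beam axis pointing along +y (increasing depth). Angles are measured from
the beam axis, positive towards +x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Standard transthoracic views used for biventricular coverage.
STANDARD_VIEW_NAMES = ("4ch", "5ch", "3.5ch", "3ch", "2ch", "RVIT")


@dataclass(frozen=True)
class ViewGeometry:
    """Geometry of one 2D sector view."""

    view_name: str = "4ch"
    n_lines: int = 128
    sector_angle_deg: float = 90.0
    depth_samples: int = 256
    depth_max_mm: float = 120.0
    apex_position_mm: tuple[float, float] = (0.0, 0.0)
    frame_rate_hz: float = 2000.0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if not 0.0 < self.sector_angle_deg <= 180.0:
            raise ValueError("sector_angle_deg must be in (0, 180]")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.depth_max_mm <= 0:
            raise ValueError("depth_max_mm must be positive")

    @property
    def frame_period_ms(self) -> float:
        """Temporal resolution: one frame period in ms (0.5 ms at 2000 fps)."""
        return 1000.0 / self.frame_rate_hz

    @property
    def line_angles_rad(self) -> np.ndarray:
        """Scan-line angles (radians from the beam axis), evenly fanned."""
        half = np.deg2rad(self.sector_angle_deg) / 2.0
        return np.linspace(-half, half, self.n_lines)

    def polar(self, x_mm, y_mm):
        """Map Cartesian mm to (range mm, angle rad) relative to the apex."""
        ax, ay = self.apex_position_mm
        dx = np.asarray(x_mm, dtype=float) - ax
        dy = np.asarray(y_mm, dtype=float) - ay
        r = np.hypot(dx, dy)
        theta = np.arctan2(dx, dy)
        return r, theta

    def cartesian(self, r_mm, theta_rad):
        """Inverse of :meth:`polar`; bijective on the sector."""
        ax, ay = self.apex_position_mm
        r = np.asarray(r_mm, dtype=float)
        t = np.asarray(theta_rad, dtype=float)
        return ax + r * np.sin(t), ay + r * np.cos(t)

    def contains(self, x_mm, y_mm):
        """Boolean: points inside the imaging sector."""
        r, theta = self.polar(x_mm, y_mm)
        half = np.deg2rad(self.sector_angle_deg) / 2.0
        return (r <= self.depth_max_mm) & (np.abs(theta) <= half)
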