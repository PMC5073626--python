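"""Core container for sampled vessel flow/area time series.

Unit conventions are fixed package-wide so that pulse wave velocity needs
no conversion factors:

* time in ms, flow in mL/s, area in mm², velocity in cm/s (VENC convention);
* 1 (mL/s)/mm² = 1 m/s and 1 mm/ms = 1 m/s, so both the flow–area slope and
  a distance/transit-time ratio are already in m/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Vessel sites used throughout: main, right and left pulmonary artery.
SITES = ("MPA", "RPA", "LPA", "other")


class CurveError(ValueError):
    """Raised when a flow/area curve violates its construction invariants."""


@dataclass
class FlowAreaCurve:
    """Flow Q(t) and cross-sectional area A(t) sampled at one vessel site.

    Parameters
    ----------
    site : str
        One of ``MPA``, ``RPA``, ``LPA`` or ``other``.
    times : array of float
        Frame times in ms, strictly increasing, frame-start convention.
    flow : array of float
        Flow per frame in mL/s (retrograde flow negative).
    area : array of float
        Vessel cross-sectional area per frame in mm², strictly positive.
    venc_exceeded : bool
        Set by the simulator when the mean velocity Q/A exceeds the
        velocity-encoding limit of the emulated sequence (no aliasing is
        simulated; this is a warning flag only).
    """

    site: str
    times: np.ndarray
    flow: np.ndarray
    area: np.ndarray
    venc_exceeded: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        if self.site not in SITES:
            raise CurveError(f"unknown site {self.site!r}; expected one of {SITES}")
        if not (self.times.shape == self.flow.shape == self.area.shape):
            raise CurveError("times, flow and area must have identical length")
        if self.times.ndim != 1 or self.times.size == 0:
            raise CurveError("curve must contain at least one frame")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise CurveError("times must be strictly increasing")
        if not np.all(self.area > 0):
            raise CurveError("area must be positive everywhere")

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    def velocity_cm_s(self) -> np.ndarray:
        """Mean through-plane velocity Q/A per frame, in cm/s."""
        return 100.0 * self.flow / self.area  # (mL/s)/mm² = m/s

    def restrict_to(self, t_max_ms: float) -> "FlowAreaCurve":
        """Frames with time ≤ ``t_max_ms`` (relative to the first frame)."""
        keep = self.times - self.times[0] <= t_max_ms + 1e-12
        return replace(
            self, times=self.times[keep], flow=self.flow[keep], area=self.area[keep]
        )

    def shifted(self, dt_ms: float) -> "FlowAreaCurve":
        """The same samples with all frame times translated by ``dt_ms``."""
        return replace(self, times=self.times + dt_ms)
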