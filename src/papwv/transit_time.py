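"""Transit-time pulse wave velocity between two imaging planes.

PWV = Δd / Δt, where Δd is the inter-plane path length (horizontal
centreline distance and vertical slice offset combined by Pythagoras) and
Δt is the difference in pulse-foot arrival time between the MPA and a
branch pulmonary artery.  The pulse foot is the intersection of the
least-squares line through the 20–80% band of the systolic upstroke with
the horizontal pre-systolic baseline.  With distance in mm and time in ms
the ratio is already in m/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import FlowAreaCurve
from .qa import DEFAULT_CAP, FitError, PWVEstimate, screen_validity


class GeometryError(ValueError):
    """Raised for invalid inter-plane geometry parameters."""


def path_distance(horizontal_length: float, slice_thickness: float,
                  n_slices: int) -> float:
    """Inter-plane path length in mm: sqrt(horizontal² + (thickness·slices)²)."""
    if horizontal_length < 0 or slice_thickness < 0 or n_slices < 0:
        raise GeometryError("geometry inputs must be nonnegative")
    vertical = slice_thickness * n_slices
    return float(np.hypot(horizontal_length, vertical))


@dataclass(frozen=True)
class PlaneGeometry:
    """Geometry between the MPA plane and a branch plane.

    ``horizontal_length`` is the centreline distance measured on axial
    images (mm); the vertical offset is ``slice_thickness × n_slices``.
    """

    horizontal_length: float
    slice_thickness: float = 6.0
    n_slices: int = 0

    @property
    def distance(self) -> float:
        return path_distance(self.horizontal_length, self.slice_thickness,
                             self.n_slices)


@dataclass
class UpstrokeFit:
    """Fitted systolic upstroke line and the pulse-foot time it implies.

    ``foot_time`` is the (continuous, not grid-snapped) intersection of the
    20–80% upstroke line with the pre-systolic baseline level.
    """

    slope: float  # (mL/s)/ms
    intercept: float  # mL/s
    baseline_level: float  # mL/s
    foot_time: float  # ms
    points_used: np.ndarray
    r_squared: float
    valid: bool = True
    invalid_reason: str = "none"


def detect_foot(curve: FlowAreaCurve) -> UpstrokeFit:
    """Locate the pulse foot of a flow curve.

    Procedure: (1) find the global flow maximum; (2) take the ascending limb
    from the deepest minimum before the peak (its last attainment, which is
    the last local minimum on smooth curves); (3) least-squares line
    through ascending-limb samples within [20%, 80%] of the maximum
    (inclusive); (4) baseline = minimum flow between cycle start and the
    first upward 20% crossing; (5) foot = where the fitted line meets the
    baseline.  Raises :class:`FitError` when fewer than two band samples
    exist or the fitted slope is not positive; a foot outside
    [cycle start, peak time] flags the fit invalid rather than raising.
    """
    q = curve.flow
    t = curve.times
    i_peak = int(np.argmax(q))
    q_max = q[i_peak]
    if q_max <= 0:
        raise FitError("flow maximum is not positive; no systolic upstroke")

    # ascending limb: from the deepest pre-peak minimum (last attainment) to
    # the peak — equals the last local minimum on smooth curves, but a noise
    # dip part-way up the upstroke cannot truncate the 20-80% band
    pre = q[: i_peak + 1]
    i0 = int(np.flatnonzero(pre == pre.min())[-1])
    limb = np.arange(i0, i_peak + 1)

    lo, hi = 0.2 * q_max, 0.8 * q_max
    band = limb[(q[limb] >= lo - 1e-12) & (q[limb] <= hi + 1e-12)]
    if band.size < 2:
        raise FitError(
            f"only {band.size} upstroke samples between 20% and 80% of peak"
        )
    slope, intercept = np.polyfit(t[band], q[band], 1)
    if slope <= 0:
        raise FitError("non-positive upstroke slope")
    resid = q[band] - (slope * t[band] + intercept)
    ss_tot = float(np.sum((q[band] - q[band].mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0

    # baseline: minimum flow from cycle start to the first upward 20% crossing
    above = np.flatnonzero(q[: i_peak + 1] >= lo)
    first_cross = int(above[0]) if above.size else i_peak
    baseline = float(np.min(q[: first_cross + 1]))

    foot = (baseline - intercept) / slope
    fit = UpstrokeFit(slope=float(slope), intercept=float(intercept),
                      baseline_level=baseline, foot_time=float(foot),
                      points_used=band, r_squared=r2)
    if not (t[0] <= foot <= t[i_peak]):
        fit.valid = False
        fit.invalid_reason = "foot_outside_upstroke"
    return fit


def tt_pwv(foot_mpa: UpstrokeFit, foot_branch: UpstrokeFit,
           geometry: PlaneGeometry, cap: float = DEFAULT_CAP) -> PWVEstimate:
    """Transit-time PWV between the MPA and a branch plane, m/s.

    Δt ≤ 0 (wave apparently arriving at the branch first) yields an invalid
    estimate rather than an exception, mirroring how physically impossible
    transit times are discarded rather than crash an analysis.
    """
    dt = foot_branch.foot_time - foot_mpa.foot_time
    dd = geometry.distance
    diagnostics = {
        "delta_t_ms": float(dt),
        "delta_d_mm": float(dd),
        "foot_mpa_ms": foot_mpa.foot_time,
        "foot_branch_ms": foot_branch.foot_time,
        "r_squared_mpa": foot_mpa.r_squared,
        "r_squared_branch": foot_branch.r_squared,
    }
    if not (foot_mpa.valid and foot_branch.valid):
        return PWVEstimate(method="TT", value=float("nan"), valid=False,
                           invalid_reason="fit_failed", diagnostics=diagnostics)
    if dt <= 0:
        return PWVEstimate(method="TT", value=float("inf") if dt == 0 else dd / dt,
                           valid=False, invalid_reason="nonpositive",
                           diagnostics=diagnostics)
    est = PWVEstimate(method="TT", value=float(dd / dt), n_points=2,
                      diagnostics=diagnostics)
    return screen_validity(est, cap=cap)


def estimate_tt(curve_mpa: FlowAreaCurve, curve_branch: FlowAreaCurve,
                geometry: PlaneGeometry, cap: float = DEFAULT_CAP) -> PWVEstimate:
    """Foot detection on both curves plus :func:`tt_pwv`, failures flagged."""
    try:
        f_mpa = detect_foot(curve_mpa)
        f_branch = detect_foot(curve_branch)
    except FitError as exc:
        return PWVEstimate(method="TT", value=float("nan"), valid=False,
                           invalid_reason="fit_failed",
                           diagnostics={"error": str(exc)})
    return tt_pwv(f_mpa, f_branch, geometry, cap=cap)
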