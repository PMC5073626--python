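"""Flow quantification from phase-contrast frames and ROI masks.

Mirrors what a clinical flow package computes once a vessel contour exists:
cross-sectional area (pixel count × pixel area), flow (per-pixel velocity
summed over the ROI), the per-site flow/area curve, and stroke volume /
cardiac output from the flow integral.  Contours arrive as binary masks;
segmentation itself is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import FlowAreaCurve
from .synth import PhaseContrastSeries


class MeasurementError(ValueError):
    """Raised for empty masks, shape mismatches or invalid frame ordering."""


@dataclass
class VelocityFrame:
    """One reconstructed cardiac phase: magnitude + velocity map.

    ``velocity`` is the through-plane velocity in cm/s; ``trigger_time`` is
    the frame-start time in ms after the R wave.
    """

    magnitude: np.ndarray
    velocity: np.ndarray
    pixel_spacing: float
    trigger_time: float
    venc: float = 150.0

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.magnitude.shape != self.velocity.shape:
            raise MeasurementError("magnitude and velocity shapes differ")
        if self.pixel_spacing <= 0:
            raise MeasurementError("pixel_spacing must be > 0")


def measure_area(roi: np.ndarray, pixel_spacing: float) -> float:
    """ROI area in mm²: pixel count × pixel_spacing²."""
    mask = np.asarray(roi)
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise MeasurementError("empty ROI mask")
    if pixel_spacing <= 0:
        raise MeasurementError("pixel_spacing must be > 0")
    return n * pixel_spacing**2


def measure_flow(frame: VelocityFrame, roi: np.ndarray) -> float:
    """Flow through the ROI in mL/s (sign preserved; retrograde negative).

    Per-pixel summation: Σ velocity [cm/s → mm/s] × pixel area [mm²],
    converted to mL/s (1 mL = 1000 mm³).  Identical to mean-velocity × area
    under plug flow; correct for arbitrary velocity profiles.
    """
    mask = np.asarray(roi).astype(bool)
    if mask.shape != frame.velocity.shape:
        raise MeasurementError("ROI shape does not match frame shape")
    if not mask.any():
        raise MeasurementError("empty ROI mask")
    v_mm_s = frame.velocity[mask] * 10.0  # cm/s -> mm/s
    return float(np.sum(v_mm_s) * frame.pixel_spacing**2 / 1000.0)


def build_flow_area_curve(frames, rois, site: str = "other") -> FlowAreaCurve:
    """Apply area/flow measurement per frame and assemble a curve.

    ``frames`` and ``rois`` are parallel sequences (one binary mask per
    frame); times come from each frame's trigger time and must be strictly
    increasing.
    """
    frames = list(frames)
    rois = list(rois)
    if len(frames) != len(rois):
        raise MeasurementError(
            f"{len(frames)} frames but {len(rois)} masks; need one mask per frame"
        )
    times, flow, area = [], [], []
    for k, (fr, roi) in enumerate(zip(frames, rois)):
        if roi is None:
            raise MeasurementError(f"missing ROI mask for frame {k}")
        try:
            area.append(measure_area(roi, fr.pixel_spacing))
            flow.append(measure_flow(fr, roi))
        except MeasurementError as exc:
            raise MeasurementError(f"frame {k}: {exc}") from exc
        times.append(fr.trigger_time)
    t = np.asarray(times)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise MeasurementError("trigger times must be strictly increasing")
    return FlowAreaCurve(site=site, times=t, flow=np.asarray(flow),
                         area=np.asarray(area))


def series_to_frames(series: PhaseContrastSeries):
    """Split a rendered series into (frames, masks) for curve building."""
    frames = [
        VelocityFrame(
            magnitude=series.magnitude[:, :, k],
            velocity=series.velocity[:, :, k],
            pixel_spacing=series.pixel_spacing,
            trigger_time=float(series.times[k]),
            venc=series.venc,
        )
        for k in range(series.times.size)
    ]
    masks = [series.masks[:, :, k] for k in range(series.times.size)]
    return frames, masks


def stroke_volume_and_cardiac_output(curve: FlowAreaCurve, heart_rate: float):
    """Stroke volume (mL) and cardiac output (L/min) from one cardiac cycle.

    Stroke volume is the trapezoidal integral of flow over the sampled
    cycle; cardiac output = SV × heart rate / 1000.
    """
    if heart_rate <= 0:
        raise MeasurementError("heart_rate must be > 0")
    sv = float(np.trapezoid(curve.flow, curve.times) / 1000.0)  # (mL/s)·ms -> mL
    co = sv * heart_rate / 1000.0
    return sv, co
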