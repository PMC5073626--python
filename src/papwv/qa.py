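"""Single-plane flow-area (QA) pulse wave velocity estimators.

During early systole, before reflected waves return, the linearized
water-hammer relation gives dQ = PWV · dA, so the slope of flow against
area is the local pulse wave velocity.  Three estimators are provided:

* ``qa_trad`` — least-squares slope of Q on A over the whole early-systole
  window (biased upward by an early backward expansion wave);
* ``qa_three`` — the same slope restricted to the first three window points
  (reflections usually arrive later, at the cost of precision);
* ``qa_inv`` — the reflection-insensitive sum-of-squares estimator
  PWV = sqrt(ΣΔQ² / ΣΔA²) over consecutive-frame increments, the Q–A
  analogue of the reciprocal pressure–velocity technique; it uses all
  early-systole points and is exact whenever the backward-wave increments
  are orthogonal to the forward-wave increments.

Early systole is the period during which vessel area and flow increase
simultaneously, sought within the first 200 ms of the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .curves import FlowAreaCurve
from .synth import SyntheticTruth

#: Default validity cap: estimates above this (m/s) are "excessively high".
DEFAULT_CAP = 20.0

#: Early-systole search horizon after the first frame, ms.
EARLY_SYSTOLE_HORIZON_MS = 200.0


class EstimationError(ValueError):
    """Base class for estimator failures."""


class WindowTooShortError(EstimationError):
    """Early-systole run has fewer than 3 frames."""


class FitError(EstimationError):
    """Degenerate regression (e.g. zero area variance, too few points)."""


@dataclass(frozen=True)
class SystoleWindow:
    """Contiguous frame indices of the early-systole upstroke."""

    indices: np.ndarray

    @property
    def n_points(self) -> int:
        return int(np.asarray(self.indices).size)


@dataclass
class PWVEstimate:
    """A method-tagged pulse wave velocity with validity bookkeeping."""

    method: str  # TT | QA_Trad | QA_3 | QA_Inv
    value: float
    n_points: int = 0
    valid: bool = True
    invalid_reason: str = "none"  # none|nonpositive|excessive|window_too_short|fit_failed
    diagnostics: dict = field(default_factory=dict)


@dataclass
class StudyRecord:
    """One analysed acquisition: estimates plus design labels.

    ``replicate`` distinguishes on-table repeats, ``visit`` separate scan
    sessions, ``observer``/``analysis`` repeated contouring; ``sequence``
    names the acquisition preset.  ``truth`` is present for simulated data.
    """

    subject: str
    site: str
    estimates: list
    group: str = ""
    sequence: str = "high-temporal"
    visit: int = 1
    replicate: int = 1
    observer: int = 1
    analysis: int = 1
    truth: Optional[SyntheticTruth] = None

    def estimate(self, method: str) -> Optional[PWVEstimate]:
        for e in self.estimates:
            if e.method == method:
                return e
        return None


def early_systole_window(curve: FlowAreaCurve) -> SystoleWindow:
    """Early-systole window: flow and area simultaneously increasing.

    The search is restricted to the first 200 ms of the cycle.  Increments
    must be strictly positive in both series (a tie — e.g. an area plateau
    from pixel quantization — terminates a run).  The window is the
    earliest of the longest such runs, so a one-frame noise blip in
    pre-systolic baseline never displaces the systolic upstroke; if even
    the longest run spans fewer than 3 frames a
    :class:`WindowTooShortError` is raised.
    """
    sub = curve.restrict_to(EARLY_SYSTOLE_HORIZON_MS)
    if sub.n_frames < 3:
        raise WindowTooShortError(
            f"only {sub.n_frames} frames within the first 200 ms"
        )
    up = (np.diff(sub.flow) > 0) & (np.diff(sub.area) > 0)
    if not up.any():
        raise WindowTooShortError("no simultaneously increasing increments")
    best_start, best_len = 0, 0
    i = 0
    while i < up.size:
        if up[i]:
            j = i
            while j < up.size and up[j]:
                j += 1
            if j - i > best_len:  # strict: earliest among equally long runs
                best_start, best_len = i, j - i
            i = j
        else:
            i += 1
    indices = np.arange(best_start, best_start + best_len + 1)
    if indices.size < 3:
        raise WindowTooShortError(
            f"longest early-systole run spans {indices.size} frames (<3)"
        )
    return SystoleWindow(indices=indices)


def _window_arrays(curve: FlowAreaCurve, window: SystoleWindow):
    idx = np.asarray(window.indices)
    if idx.size < 3:
        raise WindowTooShortError("window must contain at least 3 points")
    return curve.area[idx], curve.flow[idx]


def _slope(a: np.ndarray, q: np.ndarray) -> tuple:
    """Least-squares slope of q on a, with r²."""
    if np.ptp(a) == 0 or np.allclose(np.var(a), 0.0):
        raise FitError("zero area variance in window")
    slope, intercept = np.polyfit(a, q, 1)
    resid = q - (slope * a + intercept)
    ss_tot = np.sum((q - q.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(r2)


def qa_trad(curve: FlowAreaCurve, window: SystoleWindow) -> PWVEstimate:
    """Least-squares Q-on-A slope over the whole early-systole window, m/s."""
    a, q = _window_arrays(curve, window)
    slope, r2 = _slope(a, q)
    span = float(curve.times[window.indices[-1]] - curve.times[window.indices[0]])
    return PWVEstimate(method="QA_Trad", value=slope, n_points=a.size,
                       diagnostics={"r_squared": r2, "window_span_ms": span})


def qa_three(curve: FlowAreaCurve, window: SystoleWindow) -> PWVEstimate:
    """Slope over exactly the first three points of the upstroke, m/s."""
    a, q = _window_arrays(curve, window)
    slope, r2 = _slope(a[:3], q[:3])
    return PWVEstimate(method="QA_3", value=slope, n_points=3,
                       diagnostics={"r_squared": r2})


def qa_inv(curve: FlowAreaCurve, window: SystoleWindow) -> PWVEstimate:
    """Reflection-insensitive estimator sqrt(ΣΔQ² / ΣΔA²), m/s."""
    a, q = _window_arrays(curve, window)
    dq, da = np.diff(q), np.diff(a)
    denom = float(np.sum(da**2))
    if denom == 0.0:
        raise FitError("zero area increments in window")
    value = float(np.sqrt(np.sum(dq**2) / denom))
    return PWVEstimate(method="QA_Inv", value=value, n_points=a.size,
                       diagnostics={"n_increments": int(dq.size)})


def screen_validity(estimate: PWVEstimate, cap: float = DEFAULT_CAP) -> PWVEstimate:
    """Flag physically implausible estimates (non-positive or above ``cap``).

    Mirrors the exclusion of grossly inaccurate values — excessively high
    or negative PWV — from downstream statistics.
    """
    est = replace(estimate, diagnostics=dict(estimate.diagnostics))
    if not est.valid:
        return est
    if not np.isfinite(est.value) or est.value <= 0:
        est.valid = False
        est.invalid_reason = "nonpositive"
    elif est.value > cap:
        est.valid = False
        est.invalid_reason = "excessive"
    return est


_QA_FUNCS = {"QA_Trad": qa_trad, "QA_3": qa_three, "QA_Inv": qa_inv}


def estimate_qa(curve: FlowAreaCurve, method: str, cap: float = DEFAULT_CAP) -> PWVEstimate:
    """One QA estimate with failures folded into the validity flag."""
    try:
        window = early_systole_window(curve)
        est = _QA_FUNCS[method](curve, window)
    except WindowTooShortError as exc:
        return PWVEstimate(method=method, value=float("nan"), valid=False,
                           invalid_reason="window_too_short",
                           diagnostics={"error": str(exc)})
    except FitError as exc:
        return PWVEstimate(method=method, value=float("nan"), valid=False,
                           invalid_reason="fit_failed",
                           diagnostics={"error": str(exc)})
    return screen_validity(est, cap=cap)


def estimate_all_qa(curve: FlowAreaCurve, cap: float = DEFAULT_CAP) -> list:
    """All three QA estimates for one curve."""
    return [estimate_qa(curve, m, cap=cap) for m in _QA_FUNCS]
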