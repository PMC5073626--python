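"""Ground-truthed synthetic pulmonary hemodynamics.

Generates flow/area waveforms at the main, right and left pulmonary
arteries (MPA/RPA/LPA) that embody the linearized water-hammer physics the
flow-area PWV estimators assume: during early systole, in the absence of
reflected waves, increments obey dQ = c·dA where c is the pulse wave
velocity.  The generator superimposes a single discrete backward
(reflected) wave, adds measurement noise, quantizes area to the pixel grid
of an emulated phase-contrast sequence, and samples at the sequence's
temporal resolution — so every estimator can be validated against known
truth without any MRI data.

The model is deliberately minimal:

* forward wave: half-sinusoid systolic ejection, zero diastolic flow;
* backward wave: a scaled, delayed copy of the forward wave — an
  "expansion" reflection adds to observed flow and subtracts from area
  (raising the apparent Q–A slope), a "compression" reflection does the
  opposite;
* observed curves: Q = Q_f + Q_b and A = A0 + (Q_f − Q_b)/c.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import ClassVar, Mapping, Optional, Union

import numpy as np

from .curves import SITES, FlowAreaCurve


class ParameterError(ValueError):
    """Raised for physically or numerically invalid generator parameters."""


# ---------------------------------------------------------------------------
# acquisition emulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionProfile:
    """Phase-contrast sequence parameters that shape the sampled curves.

    Parameters
    ----------
    temporal_resolution : float
        Frame spacing in ms.
    pixel_spacing : float
        In-plane pixel size in mm (isotropic); area is quantized to an
        integer number of ``pixel_spacing**2`` pixels.
    slice_thickness : float
        Slice thickness in mm.
    venc : float
        Velocity-encoding limit in cm/s; exceeding it flags the curve.
    n_phases : int
        Number of reconstructed cardiac phases.
    rr_jitter_sd : float
        SD (ms) of the per-acquisition cardiac cycle-length jitter
        (Gaussian, truncated at ±3 SD); 0 disables jitter.
    quantize_area : bool
        When True (default), simulated area is rounded to an integer number
        of pixels; False gives the exact continuous area (useful for
        isolating temporal-resolution effects).
    """

    temporal_resolution: float
    pixel_spacing: float
    slice_thickness: float = 6.0
    venc: float = 150.0
    n_phases: int = 128
    rr_jitter_sd: float = 0.0
    quantize_area: bool = True

    def __post_init__(self) -> None:
        if self.temporal_resolution <= 0:
            raise ParameterError("temporal_resolution must be > 0")
        if self.pixel_spacing <= 0:
            raise ParameterError("pixel_spacing must be > 0")
        if self.venc <= 0:
            raise ParameterError("venc must be > 0")
        if self.n_phases < 2:
            raise ParameterError("n_phases must be >= 2")
        if self.rr_jitter_sd < 0:
            raise ParameterError("rr_jitter_sd must be >= 0")

    #: In-plane pixel size (mm) at which curve-level noise SDs are quoted.
    NOISE_REFERENCE_SPACING: ClassVar[float] = 1.25

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in mm²."""
        return self.pixel_spacing**2

    @property
    def noise_scale(self) -> float:
        """Curve-level noise multiplier relative to the 1.25 mm reference.

        Per-pixel SNR scales with voxel volume, so halving the in-plane
        pixel size quadruples per-pixel noise; summed over the ~4× more
        pixels of an ROI the measured flow/area noise grows like
        1/pixel_spacing.
        """
        return self.NOISE_REFERENCE_SPACING / self.pixel_spacing


#: 7 ms frames, 1.25 mm pixels, 128 phases (the high-temporal sequence).
HIGH_TEMPORAL = AcquisitionProfile(
    temporal_resolution=7.0, pixel_spacing=1.25, slice_thickness=6.0,
    venc=150.0, n_phases=128,
)

#: 12 ms frames, 0.625 mm pixels, 80 phases (the high-spatial sequence).
HIGH_SPATIAL = AcquisitionProfile(
    temporal_resolution=12.0, pixel_spacing=0.625, slice_thickness=6.0,
    venc=150.0, n_phases=80,
)

PRESETS: Mapping[str, AcquisitionProfile] = {
    "high-temporal": HIGH_TEMPORAL,
    "high-spatial": HIGH_SPATIAL,
}


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReflectionSpec:
    """One discrete backward wave: a scaled, delayed copy of the forward wave.

    ``kind="expansion"`` adds the backward component to observed flow and
    subtracts it from area (the early backward expansion wave seen in the
    pulmonary trunk); ``kind="compression"`` does the reverse.
    """

    coefficient: float = 0.0
    delay: float = 0.0
    kind: str = "expansion"

    def __post_init__(self) -> None:
        if not 0.0 <= self.coefficient < 1.0:
            raise ParameterError("reflection coefficient must be in [0, 1)")
        if self.delay < 0:
            raise ParameterError("reflection delay must be >= 0")
        if self.kind not in ("expansion", "compression"):
            raise ParameterError("reflection kind must be expansion|compression")


#: Fraction of MPA flow (and baseline area) carried by each site.
FLOW_FRACTION = {"MPA": 1.0, "RPA": 0.55, "LPA": 0.45, "other": 1.0}


@dataclass(frozen=True)
class SyntheticTruth:
    """Everything needed to regenerate one subject's curves, plus the answers.

    ``true_pwv`` (m/s) is the wave speed shared by all sites; ``site_delays``
    are the pulse arrival delays (ms) of the branch sites relative to the
    MPA; ``reflection`` is either one spec applied at every site or a
    per-site mapping.  ``baseline_area`` and ``peak_flow`` refer to the MPA;
    branch sites carry the fixed fractions in :data:`FLOW_FRACTION` of both
    (equal baseline mean velocity at all sites).  ``onset_ms`` is the
    electromechanical delay between the cycle start (R wave trigger) and
    ejection onset at the MPA — it gives every curve the pre-systolic
    baseline segment the pulse-foot method intersects.
    """

    true_pwv: float = 2.5
    site_delays: Mapping[str, float] = field(
        default_factory=lambda: {"MPA": 0.0, "RPA": 20.0, "LPA": 18.0}
    )
    reflection: Union[ReflectionSpec, Mapping[str, ReflectionSpec], None] = None
    baseline_area: float = 600.0
    peak_flow: float = 400.0
    flow_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(FLOW_FRACTION)
    )
    systole_duration: float = 300.0
    cycle_length: float = 900.0
    onset_ms: float = 60.0
    noise_sd_flow: float = 0.0
    noise_sd_area: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_pwv <= 0:
            raise ParameterError("true_pwv must be > 0")
        if self.baseline_area <= 0:
            raise ParameterError("baseline_area must be > 0")
        if not 0 < self.systole_duration < self.cycle_length:
            raise ParameterError("need 0 < systole_duration < cycle_length")
        if self.onset_ms < 0:
            raise ParameterError("onset_ms must be >= 0")
        if self.noise_sd_flow < 0 or self.noise_sd_area < 0:
            raise ParameterError("noise SDs must be >= 0")

    def delay_for(self, site: str) -> float:
        return float(self.site_delays.get(site, 0.0))

    def reflection_for(self, site: str) -> ReflectionSpec:
        if self.reflection is None:
            return ReflectionSpec(0.0, 0.0)
        if isinstance(self.reflection, ReflectionSpec):
            return self.reflection
        return self.reflection.get(site, ReflectionSpec(0.0, 0.0))


# ---------------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------------


def forward_flow(t_ms, peak_flow: float, systole_duration: float) -> np.ndarray:
    """Analytic forward flow Q_f(t): half-sinusoid over systole, else 0.

    Vectorized in ``t_ms``; negative times (pre-arrival) give 0.
    """
    t = np.asarray(t_ms, dtype=float)
    inside = (t >= 0.0) & (t <= systole_duration)
    out = np.zeros_like(t)
    out[inside] = peak_flow * np.sin(np.pi * t[inside] / systole_duration)
    return out


def forward_flow_wave(
    peak_flow: float,
    systole_duration: float,
    cycle_length: float,
    temporal_resolution: float,
) -> np.ndarray:
    """Sample the forward half-sinusoid at t = 0, dt, 2·dt, … < cycle_length.

    Returns the flow samples in mL/s; the implied time grid is
    ``np.arange(samples.size) * temporal_resolution``.
    """
    if systole_duration <= 0 or cycle_length <= 0 or temporal_resolution <= 0:
        raise ParameterError("durations and temporal resolution must be > 0")
    if systole_duration >= cycle_length:
        raise ParameterError("systole_duration must be < cycle_length")
    t = np.arange(0.0, cycle_length - 1e-9, temporal_resolution)
    return forward_flow(t, peak_flow, systole_duration)


_SITE_CODE = {s: i for i, s in enumerate(SITES)}


def _rng_for(seed: int, site: str, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _SITE_CODE[site], int(stream)])
    )


def _truncated_normal(rng: np.random.Generator, sd: float, n_sigma: float = 3.0) -> float:
    if sd == 0:
        return 0.0
    while True:  # rejection sampling; acceptance ~99.7%
        x = rng.normal(0.0, sd)
        if abs(x) <= n_sigma * sd:
            return float(x)


def compose_site_curve(
    truth: SyntheticTruth,
    site: str,
    profile: AcquisitionProfile,
    seed: Optional[int] = None,
) -> FlowAreaCurve:
    """Observed flow/area curve at one site under an acquisition profile.

    Construction: forward wave delayed by the site's arrival delay, plus the
    backward wave Q_b = ±R·Q_f(t−τ); observed Q = Q_f + Q_b and
    A = A0 + (Q_f − Q_b)/c; additive Gaussian noise (seeded); area
    quantization to an integer pixel count; frames at the profile's temporal
    resolution, truncated to the (jittered) cardiac cycle.

    ``seed`` overrides ``truth.seed`` (used for replicate acquisitions that
    share one ground truth but have independent noise).
    """
    if site not in SITES:
        raise ParameterError(f"unknown site {site!r}")
    rng = _rng_for(truth.seed if seed is None else seed, site)

    cycle = truth.cycle_length + _truncated_normal(rng, profile.rr_jitter_sd)
    cycle = max(cycle, truth.systole_duration + profile.temporal_resolution)
    dt = profile.temporal_resolution
    n = min(profile.n_phases, int(np.floor((cycle - 1e-9) / dt)) + 1)
    if n < 2:
        raise ParameterError("profile yields fewer than 2 frames per cycle")
    t = np.arange(n) * dt

    frac = float(truth.flow_fractions.get(site, 1.0))
    refl = truth.reflection_for(site)
    delay = truth.onset_ms + truth.delay_for(site)
    c = truth.true_pwv

    q_f = frac * forward_flow(t - delay, truth.peak_flow, truth.systole_duration)
    sign = 1.0 if refl.kind == "expansion" else -1.0
    q_b = sign * refl.coefficient * frac * forward_flow(
        t - delay - refl.delay, truth.peak_flow, truth.systole_duration
    )
    a0 = frac * truth.baseline_area
    flow = q_f + q_b
    area = a0 + (q_f - q_b) / c

    scale = profile.noise_scale  # SNR ~ voxel volume: finer pixels, noisier sums
    if truth.noise_sd_flow > 0:
        flow = flow + rng.normal(0.0, scale * truth.noise_sd_flow, size=n)
    if truth.noise_sd_area > 0:
        area = area + rng.normal(0.0, scale * truth.noise_sd_area, size=n)

    if profile.quantize_area:
        # pixel-grid quantization of area (>= 1 pixel)
        px = profile.pixel_area
        area = np.maximum(np.round(area / px), 1.0) * px

    venc_exceeded = bool(np.any(np.abs(100.0 * flow / area) > profile.venc))
    return FlowAreaCurve(site=site, times=t, flow=flow, area=area,
                         venc_exceeded=venc_exceeded)


# ---------------------------------------------------------------------------
# phase-contrast image rendering
# ---------------------------------------------------------------------------


@dataclass
class PhaseContrastSeries:
    """Rendered magnitude/velocity frames plus the true ROI masks.

    Arrays are (rows, cols, phases); ``velocity`` is in cm/s (plug profile:
    uniform Q/A inside the vessel disc, 0 outside), ``masks`` is 0/1.
    """

    magnitude: np.ndarray
    velocity: np.ndarray
    masks: np.ndarray
    times: np.ndarray
    pixel_spacing: float
    venc: float
    temporal_resolution: float


def render_phase_contrast_frames(
    curve: FlowAreaCurve,
    profile: AcquisitionProfile,
    fov: float = 320.0,
) -> PhaseContrastSeries:
    """Render a curve as a stack of synthetic phase-contrast frames.

    Each frame is a centred disc whose pixel count equals the curve's area
    divided by the pixel area (pixels admitted in order of distance from the
    centre, deterministic tie-break), with uniform (plug) velocity
    v = Q/A inside and 0 outside; magnitude is bright inside the disc.
    """
    ps = profile.pixel_spacing
    n_px = int(round(fov / ps))
    if n_px < 2:
        raise ParameterError("fov too small for pixel grid")
    r_max = np.sqrt(np.max(curve.area) / np.pi)
    if r_max > fov / 2.0:
        raise ParameterError(
            f"vessel radius {r_max:.1f} mm exceeds half the field of view"
        )

    centre = (n_px - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(n_px), np.arange(n_px), indexing="ij")
    r2 = ((ii - centre) ** 2 + (jj - centre) ** 2) * ps**2
    order = np.lexsort((jj.ravel(), ii.ravel(), r2.ravel()))

    n_t = curve.n_frames
    mag = np.full((n_px, n_px, n_t), 0.05)
    vel = np.zeros((n_px, n_px, n_t))
    masks = np.zeros((n_px, n_px, n_t), dtype=np.uint8)
    flat_rows, flat_cols = np.unravel_index(order, (n_px, n_px))
    for k in range(n_t):
        n_pix = int(round(curve.area[k] / profile.pixel_area))
        n_pix = max(min(n_pix, n_px * n_px), 1)
        r, cidx = flat_rows[:n_pix], flat_cols[:n_pix]
        masks[r, cidx, k] = 1
        v_cm_s = 100.0 * curve.flow[k] / curve.area[k]
        vel[r, cidx, k] = v_cm_s
        mag[r, cidx, k] = 1.0
    return PhaseContrastSeries(
        magnitude=mag, velocity=vel, masks=masks, times=curve.times.copy(),
        pixel_spacing=ps, venc=profile.venc,
        temporal_resolution=profile.temporal_resolution,
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthSampler:
    """Distribution over subject ground truths for simulated cohorts.

    Defaults emulate resting adult pulmonary hemodynamics: wave speed
    ~N(2.5, 0.4) m/s (truncated at 0.5), MPA→RPA/LPA centreline distances
    ~N(50, 5)/N(45, 5) mm (arrival delays follow as distance / wave speed),
    MPA peak flow ~N(400, 40) mL/s, baseline MPA area ~N(600, 60) mm²,
    systole ~N(300, 20) ms, cycle ~N(900, 60) ms (heart rate ≈ 65/min),
    ejection onset ~N(60, 5) ms after the trigger, an early-systolic
    expansion reflection with coefficient ``reflection_r`` arriving
    U(40, 80) ms behind the forward wave, and measurement noise of
    4 mL/s / 2 mm² on flow/area.
    """

    pwv_mean: float = 2.5
    pwv_sd: float = 0.4
    pwv_min: float = 0.5
    dist_rpa_mm: float = 50.0
    dist_lpa_mm: float = 45.0
    dist_sd_mm: float = 5.0
    peak_flow_mean: float = 400.0
    peak_flow_sd: float = 40.0
    baseline_area_mean: float = 600.0
    baseline_area_sd: float = 60.0
    systole_mean: float = 300.0
    systole_sd: float = 20.0
    cycle_mean: float = 900.0
    cycle_sd: float = 60.0
    onset_mean: float = 60.0
    onset_sd: float = 5.0
    reflection_r: float = 0.3
    reflection_kind: str = "expansion"
    reflection_delay_range: tuple = (40.0, 80.0)
    noise_sd_flow: float = 4.0
    noise_sd_area: float = 2.0

    def sample(self, rng: np.random.Generator, seed: int) -> SyntheticTruth:
        pwv = max(rng.normal(self.pwv_mean, self.pwv_sd), self.pwv_min)
        d_rpa = max(rng.normal(self.dist_rpa_mm, self.dist_sd_mm), 5.0)
        d_lpa = max(rng.normal(self.dist_lpa_mm, self.dist_sd_mm), 5.0)
        refl = ReflectionSpec(
            coefficient=self.reflection_r,
            delay=float(rng.uniform(*self.reflection_delay_range)),
            kind=self.reflection_kind,
        )
        return SyntheticTruth(
            true_pwv=float(pwv),
            site_delays={"MPA": 0.0, "RPA": d_rpa / pwv, "LPA": d_lpa / pwv},
            reflection=refl,
            baseline_area=float(max(rng.normal(self.baseline_area_mean,
                                               self.baseline_area_sd), 100.0)),
            peak_flow=float(max(rng.normal(self.peak_flow_mean,
                                           self.peak_flow_sd), 50.0)),
            systole_duration=float(max(rng.normal(self.systole_mean,
                                                  self.systole_sd), 150.0)),
            cycle_length=float(max(rng.normal(self.cycle_mean, self.cycle_sd),
                                   400.0)),
            onset_ms=float(max(rng.normal(self.onset_mean, self.onset_sd), 0.0)),
            noise_sd_flow=self.noise_sd_flow,
            noise_sd_area=self.noise_sd_area,
            seed=seed,
        )


@dataclass
class SubjectData:
    """One simulated subject: shared ground truth, replicate acquisitions."""

    subject_id: str
    truth: SyntheticTruth
    replicates: list  # list over replicates of {site: FlowAreaCurve}


def generate_study(
    n_subjects: int,
    truth_sampler: Optional[TruthSampler] = None,
    profile: AcquisitionProfile = HIGH_TEMPORAL,
    replicates: int = 1,
    seed: int = 0,
    sites: tuple = ("MPA", "RPA", "LPA"),
) -> list:
    """Simulate a cohort: per subject, ``replicates`` independently-noised
    acquisitions sharing one :class:`SyntheticTruth`; deterministic under
    ``seed``.
    """
    if n_subjects < 1 or replicates < 1:
        raise ParameterError("n_subjects and replicates must be >= 1")
    sampler = truth_sampler if truth_sampler is not None else TruthSampler()
    root = np.random.SeedSequence(seed)
    subjects = []
    for i, child in enumerate(root.spawn(n_subjects)):
        states = child.generate_state(replicates + 1)
        subj_seed = int(states[0] % (2**31))
        rng = np.random.default_rng(child)
        truth = sampler.sample(rng, seed=subj_seed)
        reps = []
        for r in range(replicates):
            rep_seed = int(states[r + 1] % (2**31))
            reps.append({
                site: compose_site_curve(truth, site, profile, seed=rep_seed)
                for site in sites
            })
        subjects.append(SubjectData(subject_id=f"S{i:03d}", truth=truth,
                                    replicates=reps))
    return subjects
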