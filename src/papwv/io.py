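"""File dialects: curve CSV, NIfTI image stacks, JSON sidecars.

Curves travel as plain CSV with the fixed header
``site,time_ms,flow_ml_s,area_mm2`` (UTF-8, comma separator, decimal
point), written at 17 significant digits so a write/read round trip is
lossless for finite doubles.  Image stacks are NIfTI (rows × cols ×
phases), one file per series, with a JSON sidecar carrying pixel spacing,
VENC and temporal resolution.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .curves import CurveError, FlowAreaCurve
from .synth import (AcquisitionProfile, PhaseContrastSeries, ReflectionSpec,
                    SyntheticTruth)

CURVE_HEADER = "site,time_ms,flow_ml_s,area_mm2"


class ParseError(ValueError):
    """Malformed curve CSV; the message names the offending line."""


def write_curve_csv(curve: FlowAreaCurve, path) -> Path:
    path = Path(path)
    lines = [CURVE_HEADER]
    for t, q, a in zip(curve.times, curve.flow, curve.area):
        lines.append(f"{curve.site},{t:.17g},{q:.17g},{a:.17g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_curve_csv(path) -> FlowAreaCurve:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].strip() != CURVE_HEADER:
        raise ParseError(
            f"{path}: line 1: expected header {CURVE_HEADER!r}, "
            f"got {lines[0].strip() if lines else ''!r}"
        )
    sites, times, flow, area = [], [], [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split(",")
        if len(parts) != 4:
            raise ParseError(f"{path}: line {lineno}: expected 4 fields, "
                             f"got {len(parts)}")
        try:
            times.append(float(parts[1]))
            flow.append(float(parts[2]))
            area.append(float(parts[3]))
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from None
        sites.append(parts[0])
    if not sites:
        raise ParseError(f"{path}: no data rows")
    if len(set(sites)) != 1:
        raise ParseError(f"{path}: mixed site labels {sorted(set(sites))}")
    try:
        return FlowAreaCurve(site=sites[0], times=np.array(times),
                             flow=np.array(flow), area=np.array(area))
    except CurveError as exc:
        raise ParseError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# JSON sidecars for ground truth and acquisition metadata
# ---------------------------------------------------------------------------


def _reflection_to_dict(refl):
    if refl is None:
        return None
    if isinstance(refl, ReflectionSpec):
        return dataclasses.asdict(refl)
    return {site: dataclasses.asdict(r) for site, r in refl.items()}


def _reflection_from_dict(obj):
    if obj is None:
        return None
    if "coefficient" in obj:
        return ReflectionSpec(**obj)
    return {site: ReflectionSpec(**r) for site, r in obj.items()}


def write_truth_sidecar(truth: SyntheticTruth, profile: AcquisitionProfile,
                        path) -> Path:
    path = Path(path)
    payload = {
        "truth": {**dataclasses.asdict(truth),
                  "site_delays": dict(truth.site_delays),
                  "reflection": _reflection_to_dict(truth.reflection)},
        "profile": dataclasses.asdict(profile),
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")
    return path


def read_truth_sidecar(path):
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    tr = dict(payload["truth"])
    tr["reflection"] = _reflection_from_dict(tr.get("reflection"))
    return SyntheticTruth(**tr), AcquisitionProfile(**payload["profile"])


# ---------------------------------------------------------------------------
# NIfTI image stacks
# ---------------------------------------------------------------------------


def write_series_nifti(series: PhaseContrastSeries, out_dir, stem: str) -> dict:
    """Write magnitude/velocity/mask stacks plus the metadata sidecar.

    Returns the paths written, keyed ``magnitude``/``velocity``/``masks``/
    ``meta``.
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ps = series.pixel_spacing
    affine = np.diag([ps, ps, 1.0, 1.0])
    paths = {}
    for name, data, dtype in (
        ("magnitude", series.magnitude, np.float32),
        ("velocity", series.velocity, np.float32),
        ("masks", series.masks, np.uint8),
    ):
        p = out_dir / f"{stem}.{name}.nii"
        nib.save(nib.Nifti1Image(np.asarray(data, dtype=dtype), affine), p)
        paths[name] = p
    meta = out_dir / f"{stem}.meta.json"
    meta.write_text(json.dumps({
        "pixel_spacing_mm": ps,
        "venc_cm_s": series.venc,
        "temporal_resolution_ms": series.temporal_resolution,
        "trigger_times_ms": [float(t) for t in series.times],
    }, indent=2) + "\n", encoding="utf-8")
    paths["meta"] = meta
    return paths


def read_series_nifti(out_dir, stem: str) -> PhaseContrastSeries:
    """Inverse of :func:`write_series_nifti`."""
    import nibabel as nib

    out_dir = Path(out_dir)
    meta = json.loads((out_dir / f"{stem}.meta.json").read_text(encoding="utf-8"))
    arrays = {}
    for name in ("magnitude", "velocity", "masks"):
        arrays[name] = np.asarray(
            nib.load(out_dir / f"{stem}.{name}.nii").get_fdata()
        )
    return PhaseContrastSeries(
        magnitude=arrays["magnitude"],
        velocity=arrays["velocity"],
        masks=arrays["masks"].astype(np.uint8),
        times=np.asarray(meta["trigger_times_ms"], dtype=float),
        pixel_spacing=float(meta["pixel_spacing_mm"]),
        venc=float(meta["venc_cm_s"]),
        temporal_resolution=float(meta["temporal_resolution_ms"]),
    )
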