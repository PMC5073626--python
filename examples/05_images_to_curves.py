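"""From phase-contrast images back to curves: the extraction round trip.

Renders a noisy MPA curve as magnitude/velocity frames with ROI masks,
re-measures area and flow from the pixels, and reports the agreement with
the generator's curve — bounded by the pixel-area quantization alone.
"""

import numpy as np

import papwv

truth = papwv.SyntheticTruth(true_pwv=2.5, noise_sd_flow=4.0,
                             noise_sd_area=2.0, seed=11)
curve = papwv.compose_site_curve(truth, "MPA",
                                 papwv.HIGH_TEMPORAL).restrict_to(200.0)

series = papwv.render_phase_contrast_frames(curve, papwv.HIGH_TEMPORAL,
                                            fov=80.0)
frames, masks = papwv.series_to_frames(series)
extracted = papwv.build_flow_area_curve(frames, masks, site="MPA")

print(f"rendered {series.masks.shape[2]} frames of "
      f"{series.masks.shape[0]}x{series.masks.shape[1]} px "
      f"({series.pixel_spacing:g} mm pixels)")
print(f"max |area error|  {np.max(np.abs(extracted.area - curve.area)):.3g} mm^2 "
      f"(pixel area {papwv.HIGH_TEMPORAL.pixel_area:.4g} mm^2)")
print(f"max |flow error|  {np.max(np.abs(extracted.flow - curve.flow)):.3g} mL/s")
print("\nThe disc is rendered with exactly the quantized pixel count and a "
      "uniform plug velocity, so mask-based extraction reproduces the "
      "generator curve to numerical precision.")
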