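"""The three flow-area estimators, with and without a reflected wave.

Shows that all three agree with the true wave speed on a reflection-free
curve, and how an early backward expansion wave (R=0.3, 50 ms behind the
forward wave) inflates QA_Trad while QA_3 stays unbiased.
"""

import dataclasses

import papwv

profile = dataclasses.replace(papwv.HIGH_TEMPORAL, quantize_area=False)

for label, reflection in (
    ("no reflection", None),
    ("expansion reflection R=0.3, 50 ms", papwv.ReflectionSpec(0.3, 50.0)),
):
    truth = papwv.SyntheticTruth(true_pwv=2.5, reflection=reflection)
    curve = papwv.compose_site_curve(truth, "MPA", profile)
    window = papwv.early_systole_window(curve)
    print(f"{label} (early-systole window: {window.n_points} frames)")
    for fn in (papwv.qa_trad, papwv.qa_three, papwv.qa_inv):
        est = fn(curve, window)
        print(f"  {est.method:8s} {est.value:6.3f} m/s")
    print()

print("True PWV is 2.500 m/s. The backward wave steepens the observed Q-A "
      "relation, so the whole-window slope (QA_Trad) overestimates; the "
      "first three points predate the reflection, so QA_3 is exact here.")
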