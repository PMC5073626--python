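# papwv — pulmonary pulse wave velocity from phase-contrast MRI curves

Pulse wave velocity (PWV), the speed at which the systolic pulse travels
along an artery, is a non-invasive surrogate for arterial stiffness that
needs no pressure measurement — which matters in the pulmonary
circulation, where pressures are only available by right-heart
catheterisation. `papwv` implements the two MRI approaches to pulmonary
PWV and the statistics used to compare them, for researchers analysing
flow/area curves from the main, right and left pulmonary arteries
(MPA/RPA/LPA):

* **Transit-time (TT)**: PWV = Δd/Δt, with Δd the inter-plane path length
  (horizontal centreline distance and vertical slice offset combined by
  Pythagoras) and Δt the difference in pulse-foot arrival times. The foot
  is the intersection of the least-squares line through the 20–80% band
  of the systolic upstroke with the pre-systolic baseline.
* **Flow–area (QA)**, single plane, from the water-hammer relation
  dQ = PWV·dA during early systole (the period when flow and area rise
  simultaneously): `QA_Trad` (least-squares slope of Q on A over the whole
  window), `QA_3` (slope over its first three points, dodging reflected
  waves), and `QA_Inv` = √(ΣΔQ²/ΣΔA²) over consecutive increments, which
  uses all points while cancelling reflections that are orthogonal to the
  forward wave.
* **Agreement statistics**: Bland–Altman with ±2 SD limits of agreement,
  paired t-tests, one-way ANOVA, and a reproducibility table ranking
  every (method, site, sequence) configuration by the SD of paired
  replicate differences.
* **A ground-truthed hemodynamics simulator** emulating the two
  phase-contrast sequences (7 ms / 1.25 mm "high-temporal", 12 ms /
  0.625 mm "high-spatial", VENC 150 cm/s): half-sinusoid ejection, branch
  arrival delays, discrete backward reflections, pixel-area quantization,
  voxel-volume-scaled noise, RR jitter — plus a renderer that turns curves
  into magnitude/velocity image stacks with ROI masks so the extraction
  stage (area, flow, stroke volume, cardiac output) can be tested
  end-to-end. See `docs/methods.md` for the model and its limits.

## Worked example

Estimate flow-area PWV on a synthetic MPA curve with a known wave speed of
2.5 m/s, with and without an early backward expansion wave
(`examples/03_flow_area_estimators.py`):

```
no reflection (early-systole window: 21 frames)
  QA_Trad   2.500 m/s
  QA_3      2.500 m/s
  QA_Inv    2.500 m/s

expansion reflection R=0.3, 50 ms (early-systole window: 20 frames)
  QA_Trad   3.794 m/s
  QA_3      2.500 m/s
  QA_Inv    3.484 m/s
```

Without reflections all three estimators return the true wave speed
exactly. The backward wave adds to flow while subtracting from area, so
the whole-window slope (`QA_Trad`) overestimates by ~50%; the first three
upstroke points predate the reflection, so `QA_3` stays exact.

A simulated on-table repeat study (`examples/04_reproducibility_study.py`,
50 subjects scanned twice with both sequences) ranks configurations by
replicate precision:

```
 method      sequence  n_pairs  mean_diff  sd_diff  loa_low  loa_high
 QA_Inv high-temporal       50      0.033    0.320   -0.608     0.674
 QA_Inv  high-spatial       50      0.029    0.452   -0.875     0.932
QA_Trad high-temporal       50      0.007    0.507   -1.007     1.021
...
Most reproducible: QA_Inv with the high-temporal sequence (SD of
replicate differences 0.320 m/s).
```

`QA_Inv` with the high-temporal sequence gives the tightest limits of
agreement: it averages over every early-systole increment, and the finer
temporal sampling supplies more of them.

The other examples cover curve synthesis and stroke volume/cardiac output
(`01`), transit-time estimation (`02`), and the image-to-curve extraction
round trip (`05`). A thin CLI wraps the same library calls:

```sh
papwv simulate --profile high-temporal --subjects 5 --replicates 2 --seed 1 --out sim/
papwv pwv-qa --curve sim/S000_rep1_MPA.csv --method all --out qa.json
papwv pwv-tt --mpa sim/S000_rep1_MPA.csv --branch sim/S000_rep1_RPA.csv \
             --horizontal-mm 50.6 --n-slices 4 --out tt.json
papwv run --subjects 20 --seed 1 --out study/
```

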