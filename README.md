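# fetallv

Finite-element modelling of human fetal left-ventricular (LV) growth from
mid-gestation to birth, aimed at researchers in cardiac biomechanics and
computational physiology studying how mechanical loading shapes the
developing heart — in particular the reduced ventricular filling thought
to underlie hypoplastic left heart syndrome (HLHS).

The model chain:

- an idealised axisymmetric truncated-ellipsoid LV at 22 weeks of
  gestation, meshed with 30 nodes / 20 cubic-Hermite finite elements in
  prolate spheroidal coordinates, with a rule-based helical myofiber field
  (+83° endocardium to −37° epicardium);
- passive inflation to end-diastolic pressure with an incompressible,
  transversely isotropic exponential myocardium,
  `W = C/2 (e^Q − 1)`, `Q = b_f E_ff² + b_t (E_cc² + E_rr² + 2E_cr²) +
  b_fs (2E_fc² + 2E_fr²)`, solved by a modified Newton–Raphson scheme with
  augmented-Lagrangian incompressibility;
- strain-driven multiplicative growth: a transversely isotropic growth
  tensor `F_g = diag(F_ff, F_cc, F_rr)` in the local fiber frame, updated
  weekly by saturating sigmoids of the end-diastolic fiber and cross-fiber
  strains (series vs parallel sarcomere addition), at constant
  end-diastolic pressure;
- candidate-geometry selection by cumulative z-scores, growth-rate
  calibration against a normative end-diastolic-volume (EDV) trajectory
  (1.1 mL at 22 weeks to 8.3 mL at 40 weeks), and patient-specific growth
  prediction from six-planar echocardiographic dimensions.

## Worked example

```python
from fetallv import FetalLVGrowthModel

model = FetalLVGrowthModel()      # reference 22-week geometry + constraints
results = model.fit()             # calibrates stiffness, shape, growth rate
print(results.summary())
```

prints the calibrated reference model (abridged):

```
        Fetal LV growth model: calibrated reference
============================================================
Unloaded geometry        LA  18.03 mm   SA  7.74 mm   WT 3.00 mm
Unloaded cavity volume      636.9 uL
Passive stress scale C     0.6000 kPa   (b_f 18.48, b_t 3.58, b_fs 1.63)
End-diastole @ 0.75 kPa  EDV  1015.8 uL   filling  379.0 uL
...
```

The unloaded ventricle holds 637 µL; inflating it to the median fetal
end-diastolic pressure of 0.75 kPa (5.63 mmHg) fills it to about 1.02 mL —
the clinical median EDV at 22 weeks — and the weekly growth loop then
expands it to the normative ~8.3 mL at term while predicting the
end-diastolic long- and short-axis growth. (The volumetric trajectory is
calibrated; the terminal dimensions are emergent and carry a known
sphericalisation bias of the recalibrated growth law — see
`docs/methods.md`, "The shape of simulated growth".) From the fitted results you can
run the scenario experiments and patient predictions with the frozen
calibrated constants:

```python
filling = results.filling_sensitivity((0.10, 0.20, 0.25, 0.30))
print(filling.slopes)             # % cavity/wall-volume loss per 10% filling loss

shape = results.shape_sensitivity(load_mode="constant_preload")
print(shape.slopes)               # % cavity-volume change per +10% WT / LA:SA

from fetallv import EchoMeasurements
echo = EchoMeasurements(gestational_age=23.1, inner_width_base=4.6,
                        outer_width_base=6.9, inner_width_mid=5.0,
                        outer_width_mid=7.3, inner_length=12.0,
                        outer_length=14.0)
pred = results.predict_patient(echo, target_age=30.0)
print(pred.predicted.cavity_volume)   # uL at 30 weeks
```

A thin command-line layer exposes the same pipeline
(`fetallv build-mesh`, `inflate`, `grow`, `select-geometry`,
`patient-predict`, `sensitivity-filling`, `sensitivity-shape`,
`fixtures`); outputs are text formats throughout (JSON meshes, legacy
ASCII VTK for visualisation, CSV trajectories with units in the headers).

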