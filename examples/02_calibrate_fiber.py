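"""Fit a fiber Bragg grating force calibration from bench data.

Known forces are applied to the fiber tip while the reflected-wavelength
shift is read out; an ordinary-least-squares line converts shift (nm) to
contact force (grams). The printed slope/intercept define the calibration
curve; the RMSE is the residual scatter of the bench points around it.
"""

import numpy as np

from mapgap import CalibrationPoint, apply_calibration, fit_calibration

rng = np.random.default_rng(0)
true_slope, true_intercept = 5.0, 0.0  # g per nm
forces = np.arange(0.0, 25.1, 2.5)
points = [
    CalibrationPoint(f, (f - true_intercept) / true_slope + rng.normal(0, 0.01))
    for f in forces
]

curve = fit_calibration(points, fiber_id="F1")
print(f"force = {curve.slope:.3f} g/nm * shift + {curve.intercept:.3f} g "
      f"(rmse {curve.rmse:.3f} g, n={curve.n_points})")

shift = np.array([0.5, 1.0, 2.0])
series = apply_calibration(np.arange(3.0), shift, curve)
for s, f in zip(shift, series.force):
    print(f"shift {s:.1f} nm -> {f:.2f} g")
print("-> the fitted line recovers the bench fiber's 5 g/nm response; negative"
      " calibrated forces would be clipped to zero.")
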