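"""G-optimal design for a quadratic model with random coefficients.

Ten individuals contribute five observations each; the intercept, slope and
curvature all vary between individuals with variances (0.2, 0.2, 0.3) in
units of the error variance.  The G-optimal design minimizes the worst-case
(over the design space [0, 2]) summed squared prediction error of the
individual response predictions.
"""

import numpy as np

import hierdesign as hd

model = hd.HierarchicalLinearModel(
    basis=hd.RegressionBasis.polynomial(2),
    D=np.diag([0.2, 0.2, 0.3]),
    n=10, m=5,
    space=hd.DesignSpace([0], [2]),
)

design, report = hd.find_g_optimal(model, k=3, restarts=3, seed=1)

print("G-optimal design (support point : weight)")
for pt, w in zip(design.points, design.weights):
    print(f"  x = {pt[0]:.4f} : {w:.4f}")
print(f"G-criterion value: {report.phi_bar:.4f}")
print(f"equivalence certificate: {'PASS' if report.passed else 'FAIL'} "
      f"(max sensitivity {report.max_sensitivity:.2e})")
print("measure mu* on the answering set:")
for pt, w in zip(report.measure.points, report.measure.weights):
    print(f"  x = {pt[0]:.4f} : {w:.4f}")
print()
print("The criterion value is the worst-case summed prediction variance;")
print("a PASS certificate means no design on [0, 2] can do better.")
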