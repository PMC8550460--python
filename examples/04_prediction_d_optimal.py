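"""Prediction D-optimal design and its relation to the G-optimal design.

The prediction D-criterion is the log product of the leading eigenvalues of
the MSE matrix of the individual predictors (reported per observation).
For the quadratic mixed model below, the resulting design is nearly
G-optimal as well -- the cross-efficiencies are close to 1.
"""

import numpy as np

import hierdesign as hd

model = hd.HierarchicalLinearModel(
    basis=hd.RegressionBasis.polynomial(2),
    D=np.diag([0.2, 0.2, 0.3]),
    n=10, m=5,
    space=hd.DesignSpace([0], [2]),
)

d_design, crit = hd.find_d_optimal_pred(model, k=3, restarts=3, seed=1)
g_design, _ = hd.find_g_optimal(model, k=3, restarts=3, seed=1, certify=False)

print("prediction D-optimal design:")
for pt, w in zip(d_design.points, d_design.weights):
    print(f"  x = {pt[0]:.4f} : {w:.4f}")
print(f"D-criterion value: {crit.value:.4f}")
print(f"G-efficiency of the D-design : "
      f"{hd.pred_efficiencies(d_design, g_design, model, 'G'):.4f}")
print(f"D-efficiency of the G-design : "
      f"{hd.pred_efficiencies(g_design, d_design, model, 'D'):.4f}")
print()
print("Cross-efficiencies near 1 suggest the two criteria nearly coincide")
print("for this model, as they provably do under a pure random intercept.")
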