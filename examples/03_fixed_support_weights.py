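"""Optimal weights on a fixed support for a no-intercept two-factor model.

Model y = b1*x1 + b2*x2 with both coefficients random (unit variance
factors) on [0,1]^2.  With the support fixed at (1,0), (0,1), (1,1) only
the weights are searched.
"""

import numpy as np

import hierdesign as hd

model = hd.HierarchicalLinearModel(
    basis=hd.RegressionBasis.main_effects(2, intercept=False),
    D=np.diag([1.0, 1.0]), n=10, m=5,
    space=hd.DesignSpace([0, 0], [1, 1]),
)

design, _ = hd.find_g_optimal(
    model, fixed_support=[[1, 0], [0, 1], [1, 1]],
    restarts=2, seed=3, certify=False, inner_grid=101,
)

print("optimal weights on the fixed support:")
for pt, w in zip(design.points, design.weights):
    print(f"  x = ({pt[0]:.0f}, {pt[1]:.0f}) : {w:.4f}")
print()
print("By symmetry (d1 = d2) the two single-factor corners share one weight;")
print("the joint corner (1,1) gets the rest.")
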