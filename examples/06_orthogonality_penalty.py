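"""The partition-function term of the multi-pattern posterior is a soft
orthogonality constraint.

For two inferred patterns with mutual overlap q, the intractable term
factorizes into Curie-Weiss blocks at rescaled temperatures beta(1 +- q).
The resulting per-spin penalty phi(q) is convex with its minimum at
q = 0: the posterior softly pushes students toward mutually orthogonal
patterns, which is why independent students + deflation works.
"""

import numpy as np

from hopinfer import phi_curve

for beta in (1.5, 2.0, 3.0):
    curve = phi_curve(beta, q_max=0.9, step=0.01)
    i = np.argsort(curve.phi_values)[:1][0]
    print(f"beta={beta}: phi(0) = {curve.phi_values[curve.q_grid == 0][0]:.4f}, "
          f"phi(0.5) = {curve.phi_values[np.isclose(curve.q_grid, 0.5)][0]:.4f}, "
          f"argmin = {curve.q_grid[i]:+.2f}")
print("-> the minimum sits at q = 0 at every temperature: overlapping")
print("   pattern pairs pay a free-energy price.")
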