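"""Build a Hopfield teacher and Glauber-sample equilibrium configurations.

In the retrieval phase (beta > 1) each chain stays in the basin of the
pattern it was initialized at, so the sample-pattern overlaps cluster at
the Curie-Weiss magnetization m* solving m = tanh(beta m).
"""

import numpy as np

from hopinfer import generate_teacher, sample_dataset, curie_weiss_magnetization

N, P, beta, M = 400, 3, 2.0, 30

teacher = generate_teacher(N, P, beta, seed=0)
dataset = sample_dataset(teacher, M, rng=1)

overlaps = np.abs(dataset.samples @ teacher.patterns.T) / N  # (M, P)
own = overlaps[np.arange(M), dataset.state_labels]

print(f"teacher: P={P} patterns of N={N} spins at beta={beta}")
print(f"sampled M={M} configurations, {M // P} per retrieval state")
print(f"overlap with own state: mean {own.mean():.3f} (min {own.min():.3f})")
print(f"Curie-Weiss fixed point m*(beta=2) = {curie_weiss_magnetization(beta):.3f}")
print("-> each sample magnetizes along exactly one pattern, at m*,")
print("   which is what makes the dataset 'clustered' for the inverse problem.")
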