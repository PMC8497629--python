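"""Retrieve all patterns of a multi-pattern teacher by score-selected
TAP students and rank-1 deflation.

Each round launches independent TAP students from random magnetizations,
keeps the best-scoring fixed point, and removes its rank-1 contribution
(gamma = M/P) from the data matrix.  The simplified likelihood L_hat grows
by ~ one state's score per round and kinks once all patterns are found;
the reconstruction error of J_rec = N^{-1} sum m m^T against the teacher
coupling bottoms out at that round.
"""

import numpy as np

from hopinfer import (
    generate_teacher,
    hebbian_coupling,
    match_to_teacher,
    retrieve_patterns,
    sample_dataset,
)

N, P, beta, M, students = 300, 5, 2.0, 100, 10

teacher = generate_teacher(N, P, beta, seed=0)
dataset = sample_dataset(teacher, M, rng=1)
trace = retrieve_patterns(dataset, beta, gamma=M / P, n_students=students,
                          rng=2, teacher_J=hebbian_coupling(teacher.patterns))
report = match_to_teacher(trace, teacher, threshold=0.7)

print(f"teacher: N={N}, P={P}, beta={beta}; data: M={M} ({M // P} per state)")
print(f"{'round':>5} {'best score':>12} {'L_hat':>10} {'eps':>8}")
for t in range(len(trace.retrieved)):
    print(f"{t + 1:5d} {trace.scores[t]:12.0f} {trace.L_hat[t]:10.1f} "
          f"{trace.eps[t]:8.4f}")
print(f"kink stopping round: {trace.tau_stop}")
print(f"patterns recovered (overlap >= 0.7 after gauge matching): "
      f"{report.n_recovered}/{P}")
print("-> score increments are flat while real states remain, then collapse;")
print("   eps is smallest once every pattern has been deflated exactly once.")
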