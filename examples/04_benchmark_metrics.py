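"""The benchmark metrics on hand-made configurations.

Shows what the ordering, divergence and neighborhood-mutation metrics
measure, on small synthetic layouts where the right answer is obvious.
"""

import numpy as np

from scderail import (
    CountMatrix,
    divergence_score,
    mutation_proportion,
    neighborhood_mutation_proportion,
    ordering_score,
)

rng = np.random.default_rng(0)

# ordering: five maturation stages on a line vs shuffled
stages = ["immature", "blast0", "blast1", "blast2", "blast3"]
labels = np.repeat(stages, 30)
line = np.c_[np.repeat(np.arange(5.0), 30), np.zeros(150)] + rng.normal(0, 0.05, (150, 2))
shuffled = line[rng.permutation(150)]
print(f"ordering score, stages on a line: {ordering_score(line, labels, stages):.2f}")
print(f"ordering score, shuffled layout:  {ordering_score(shuffled, labels, stages):.2f}")
print("(higher = consecutive stages are closer than non-consecutive ones)")

# divergence: two condition trajectories sharing an origin
cond_labels = np.repeat(["i", "b1", "b2", "e", "m", "l"], 25)
shared = np.zeros((150, 2))
shared[cond_labels == "i"] = [0, 1] + rng.normal(0, 0.1, (25, 2))
shared[cond_labels == "e"] = [0, -1] + rng.normal(0, 0.1, (25, 2))
for lab, pos in [("b1", [3, 2]), ("b2", [6, 3]), ("m", [3, -2]), ("l", [6, -3])]:
    shared[cond_labels == lab] = pos + rng.normal(0, 0.1, (25, 2))
div = divergence_score(shared, cond_labels, ["i", "b1", "b2"], ["e", "m", "l"], ("i", "e"))
print(f"\ndivergence score, forked geometry: {div:.1f}")
print("(positive = non-origin states diverge while the origins stay close)")

# mutation proportion smoothing
print(f"\nmutation proportion with m=3, w=7 neighbors: {mutation_proportion(3, 7):.3f}")
counts = rng.poisson(5, (100, 30))
counts[50:, :8] += 25  # mutant cells form an expression group
cm = CountMatrix(counts, [f"c{i}" for i in range(100)], [f"g{j}" for j in range(30)])
status = np.array(["wt"] * 50 + ["mut"] * 50)
props = neighborhood_mutation_proportion(cm, status, k=15, seed=0)
print(f"smoothed mutant fraction: wild-type group {props[:50].mean():.2f}, "
      f"mutant group {props[50:].mean():.2f}")
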