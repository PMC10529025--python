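"""Exercise the water-wave swarm optimizer on analytic objectives.

Propagation explores with an inertia-damped random step, breaking refines
around the global best with a shrinking probe radius, and refraction
recycles stagnant particles - together they solve smooth low-dimensional
problems to high precision.
"""

import numpy as np

import despeckle as dsp

sphere = lambda p: float(np.sum(p**2))  # noqa: E731
hits = 0
for seed in range(25):
    cfg = dsp.OptimizerConfig(swarm_size=20, iterations=100, seed=seed)
    _, cost, trace = dsp.minimize_function(sphere, [(-5.0, 5.0)] * 2, cfg)
    hits += np.sqrt(cost) < 1e-2
print(f"sphere benchmark: {hits}/25 runs reached ||x|| < 1e-2")

cfg = dsp.OptimizerConfig(swarm_size=20, iterations=100, seed=1)
best, _, trace = dsp.minimize_function(lambda p: (p[0] - 7.0) ** 2, [(0.0, 20.0)], cfg)
print(f"1-D quadratic with optimum at 7: recovered {best[0]:.6f}")
print(f"elitist trace is monotone: {all(b <= a for a, b in zip(trace, trace[1:]))}")
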