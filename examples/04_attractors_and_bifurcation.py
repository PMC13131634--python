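"""Mapping the attractor landscape and detecting a rest-task bifurcation.

Uses a scalar model whose fixed points are known analytically: bistable with
zero input, tilted to a single stable state by the task input.
"""

import numpy as np

import mindyx as mx

# x' = x + 0.3 psi(x) - 0.5 x + 0.5 u : the recurrent gain 0.3 * psi'(0)
# exceeds the decay 0.5, so the origin is unstable and saturation creates a
# stable state on each side.
params = mx.MindyXParams(Ws=[[0.3]], W1=[[0.0]], W2=[[0.0]],
                         alpha=[2.0], D=[0.5], B=[[0.5]])

for label, u in [("rest (u=0)", np.array([0.0])), ("task (u=1)", np.array([1.0]))]:
    attrs = mx.find_attractors(params, u, n_init=60,
                               rng=np.random.default_rng(4))
    eqs = sorted(round(float(e.x_star[0]), 4) for e in attrs.equilibria)
    print(f"{label}: topology={attrs.topology}, equilibria at {eqs}")

rest = mx.find_attractors(params, np.array([0.0]), n_init=60,
                          rng=np.random.default_rng(4))
task = mx.find_attractors(params, np.array([1.0]), n_init=60,
                          rng=np.random.default_rng(4))
print("bifurcated rest -> task:",
      mx.bifurcation_flag(rest.topology, task.topology))
# True: the task input collapsed a two-state landscape into a single-state
# one - the topological signature associated with task engagement.
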